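"""Charge-separation classification and reported summary quantities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from dmcwater.constants import K_BOLTZMANN
from dmcwater.dynamics import (
    ORIGIN_EXCITATION,
    ORIGIN_IONISATION,
    STATUS_ACTIVE,
    STATUS_THERMALISED,
    SimConfig,
    SimulationResult,
    run_simulation,
)
from dmcwater.observables import (
    ClassCounts,
    classify_final,
    energy_spectrum,
    g_from_w,
    g_hyd,
    g_total,
    maxwellian_pdf,
    penetration_range,
    ratio_ion_exc,
    spatial_distribution,
    summarise,
    w_from_g,
)


def _toy_result(dists, origins, E0=100.0, n_events=None, statuses=None):
    """Assemble a minimal single-history SimulationResult by hand."""
    n = len(dists)
    if statuses is None:
        statuses = [STATUS_THERMALISED] * n
    ev_n = n if n_events is None else n_events
    events = pd.DataFrame(
        {
            "history": [0] * ev_n,
            "t0": np.linspace(1.0, 10.0, ev_n),
            "x": 0.0, "y": 0.0, "z": 0.0,
            "kind": 0, "transfer": 15.0,
            "elec": np.arange(ev_n),
        }
    )
    electrons = pd.DataFrame(
        {
            "history": [0] * n,
            "index": np.arange(n),
            "origin": origins,
            "birth_t0": 1.0,
            "parent_x": 0.0, "parent_y": 0.0, "parent_z": 0.0,
            "x": dists, "y": 0.0, "z": 0.0,
            "vx": 0.0, "vy": 0.0, "vz": 0.0,
            "ke": 0.01, "t_i": 100.0,
            "status": statuses,
            "dist": dists,
            "has_parent": True,
        }
    )
    cfg = SimConfig(E0=E0, n_histories=1, seed=0)
    return SimulationResult(
        config=cfg,
        events=events,
        electrons=electrons,
        primary_paths=[np.array([[0.0, 0, 0, 0], [5.0, 1.0, 0, 0]])],
        snapshot_times=(300.0, 500.0, 1000.0),
        energy_residuals=np.zeros(1),
    )


class TestGTotal:
    def test_formula_instantiation(self):
        res = _toy_result([1.0] * 5, [ORIGIN_IONISATION] * 5, E0=100.0)
        g, _ = g_total(res, 1000.0)
        assert g == 5.0

    def test_zero_at_time_zero(self):
        res = _toy_result([1.0] * 5, [ORIGIN_IONISATION] * 5)
        g, _ = g_total(res, 0.0)
        assert g == 0.0

    def test_cumulative_is_non_decreasing(self):
        res = _toy_result([1.0] * 5, [ORIGIN_IONISATION] * 5)
        gs = [g_total(res, t)[0] for t in (0.0, 2.0, 5.0, 1000.0)]
        assert gs == sorted(gs)


class TestClassify:
    def test_definitions(self):
        res = _toy_result(
            [0.80, 0.50, 0.30, 0.90],
            [ORIGIN_IONISATION, ORIGIN_IONISATION,
             ORIGIN_EXCITATION, ORIGIN_EXCITATION],
        )
        c = classify_final(res, 0.75)
        assert c.n_delocalised == 2      # 0.80 ion + 0.90 exc
        assert c.n_relocalised == 1      # 0.50 ion
        assert c.n_localised == 1        # 0.30 exc
        assert c.n_total == 4

    def test_tie_at_radius_counts_as_delocalised(self):
        res = _toy_result([0.75], [ORIGIN_IONISATION])
        assert classify_final(res, 0.75).n_delocalised == 1

    def test_limiting_radii(self):
        res = _toy_result([0.5, 1.5, 3.0], [ORIGIN_IONISATION] * 3)
        assert classify_final(res, 1e9).p_ion == 0.0
        assert classify_final(res, 1e-9).p_ion == 1.0

    def test_p_ion_plus_p_exc_is_one(self):
        res = _toy_result([0.5, 1.5, 0.2, 3.0],
                          [0, 0, 1, 1])
        c = classify_final(res, 0.75)
        assert c.p_ion + c.p_exc == 1.0

    def test_active_electrons_rejected(self):
        res = _toy_result([0.5], [0], statuses=[STATUS_ACTIVE])
        with pytest.raises(ValueError, match="before horizon"):
            classify_final(res, 0.75)

    def test_rotation_invariance(self, default_table):
        res = run_simulation(SimConfig(E0=100.0, n_histories=5, seed=2),
                             default_table)
        c0 = classify_final(res)
        # rotate all coordinates by a random orthogonal matrix and recount
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        el = res.electrons
        pos = el[["x", "y", "z"]].to_numpy() @ q.T
        par = el[["parent_x", "parent_y", "parent_z"]].to_numpy() @ q.T
        el2 = el.copy()
        el2["dist"] = np.linalg.norm(pos - par, axis=1)
        res2 = SimulationResult(res.config, res.events, el2,
                                res.primary_paths, res.snapshot_times,
                                res.energy_residuals)
        c1 = classify_final(res2)
        assert (c0.n_delocalised, c0.n_localised, c0.n_relocalised) == (
            c1.n_delocalised, c1.n_localised, c1.n_relocalised
        )

    def test_counts_match_brute_force_scan(self, default_table):
        res = run_simulation(SimConfig(E0=300.0, n_histories=5, seed=8),
                             default_table)
        c = classify_final(res)
        r_sep = res.config.r_sep
        n_del = n_loc = n_rel = 0
        for row in res.electrons.itertuples():
            d = math.dist((row.x, row.y, row.z),
                          (row.parent_x, row.parent_y, row.parent_z))
            if d >= r_sep:
                n_del += 1
            elif row.origin == ORIGIN_EXCITATION:
                n_loc += 1
            else:
                n_rel += 1
        assert (c.n_delocalised, c.n_localised, c.n_relocalised) == (
            n_del, n_loc, n_rel
        )


class TestGHyd:
    def test_all_electrons_at_parent_gives_zero(self):
        res = _toy_result([0.0, 0.0, 0.0], [0, 1, 0])
        g, _ = g_hyd(res, 0.75)
        assert g == 0.0

    def test_bounded_by_g_total_with_equality_iff_all_delocalised(self):
        res = _toy_result([2.0, 3.0, 0.2], [0, 0, 1])
        gt, _ = g_total(res, 1000.0)
        gh, _ = g_hyd(res, 0.75)
        assert gh < gt
        res2 = _toy_result([2.0, 3.0, 1.2], [0, 0, 1])
        gh2, _ = g_hyd(res2, 0.75)
        gt2, _ = g_total(res2, 1000.0)
        assert gh2 == pytest.approx(gt2)

    def test_smaller_radius_never_decreases_yield(self):
        res = _toy_result([0.8, 0.9, 1.2, 0.3], [0, 0, 0, 1])
        g075, _ = g_hyd(res, 0.75)
        g100, _ = g_hyd(res, 1.00)
        assert g075 >= g100


class TestWConversion:
    def test_vapour_experiment_value(self):
        assert g_from_w(29.6) == pytest.approx(3.38, abs=0.005)
        assert round(g_from_w(29.6), 1) == 3.4

    def test_w_from_headline_g(self):
        assert w_from_g(4.30) == pytest.approx(23.26, abs=0.01)

    def test_mutually_inverse(self):
        for x in (0.5, 3.4, 4.3, 12.0):
            assert g_from_w(w_from_g(x)) == pytest.approx(x, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            w_from_g(0.0)
        with pytest.raises(ValueError):
            g_from_w(-2.0)


class TestRatio:
    def test_arithmetic(self):
        assert ratio_ion_exc(ClassCounts(2, 1, 0)) == 2.0

    def test_zero_denominator_flagged(self):
        assert math.isnan(ratio_ion_exc(ClassCounts(5, 0, 0)))


class TestMaxwellian:
    def test_normalised(self):
        val, _ = quad(lambda e: maxwellian_pdf(e, 300.0), 0, 2.0)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_energy(self):
        mean, _ = quad(lambda e: e * maxwellian_pdf(e, 300.0), 0, 2.0)
        assert mean == pytest.approx(1.5 * K_BOLTZMANN * 300.0, rel=1e-6)
        assert mean == pytest.approx(0.03878, abs=2e-4)

    def test_mode_at_half_kt(self):
        kt = K_BOLTZMANN * 300.0
        e = np.linspace(1e-4, 0.2, 20000)
        f = maxwellian_pdf(e, 300.0)
        assert e[np.argmax(f)] == pytest.approx(kt / 2, abs=1e-3)
        assert kt / 2 == pytest.approx(0.01293, abs=1e-4)


@pytest.fixture(scope="module")
def result(default_table):
    return run_simulation(
        SimConfig(E0=300.0, n_histories=30, seed=13), default_table
    )


class TestDistributions:
    def test_energy_spectrum_is_density_normalised(self, result):
        edges = np.geomspace(1e-4, 300.0, 50)
        dens, e = energy_spectrum(result, 1000.0, edges)
        assert np.sum(dens * np.diff(e)) == pytest.approx(1.0)

    def test_unknown_snapshot_time_rejected(self, result):
        with pytest.raises(ValueError, match="snapshot"):
            energy_spectrum(result, 123.0, np.geomspace(1e-4, 300.0, 10))

    def test_spatial_distribution_conserves_counts(self, result):
        edges = np.linspace(0.0, 1e4, 200)
        counts, _ = spatial_distribution(result, 1000.0, edges)
        total = counts.sum() * result.n_histories
        assert total == len(result.electrons)

    def test_radial_density_has_two_components(self, result):
        """Bound and escaped electrons form two components separated near
        r_sep: a dense bound peak inside 0.75 nm, a depleted region just
        beyond it, and a substantial delocalised population further out."""
        d = result.electrons["dist"].to_numpy()
        bound_peak = ((d >= 0.1) & (d < 0.75)).sum() / 0.65
        valley = ((d >= 1.2) & (d < 2.4)).sum() / 1.2
        n_bound = (d < 0.75).sum()
        n_deloc = (d >= 0.75).sum()
        assert valley < 0.3 * bound_peak
        assert n_bound > 0.1 * len(d)
        assert n_deloc > 0.3 * len(d)

    def test_penetration_zero_at_time_zero(self, result):
        assert penetration_range(result, 0.0) == 0.0

    def test_penetration_range_ordering_with_energy(self, default_table):
        r100 = penetration_range(
            run_simulation(SimConfig(E0=100.0, n_histories=10, seed=3),
                           default_table), 1000.0
        )
        r1k = penetration_range(
            run_simulation(SimConfig(E0=1000.0, n_histories=10, seed=3),
                           default_table), 1000.0
        )
        r30k = penetration_range(
            run_simulation(SimConfig(E0=30000.0, n_histories=2, seed=3),
                           default_table), 1000.0
        )
        # ~10 nm, several tens of nm, ~10 µm
        assert 1.0 < r100 < r1k < r30k
        assert 3e3 < r30k < 3e4

    def test_snapshots_converged_by_500_fs_below_kev(self, default_table):
        """At and below 1 keV all charge separation is over well before the
        horizon: the 500 fs and 1 ps ensembles coincide."""
        from scipy.stats import ks_2samp

        for e0, nh in ((100.0, 60), (1000.0, 20)):
            res = run_simulation(
                SimConfig(E0=e0, n_histories=nh, seed=6), default_table
            )
            el = res.electrons
            a = el["ke_at_500"].to_numpy()
            b = el["ke_at_1000"].to_numpy()
            m = np.isfinite(a) & np.isfinite(b)
            assert ks_2samp(a[m], b[m]).statistic < 0.05
            da = el["dist_at_500"].to_numpy()[m]
            db = el["dist_at_1000"].to_numpy()[m]
            assert ks_2samp(da, db).statistic < 0.05

    def test_localisation_grows_as_primary_energy_falls(self, default_table):
        """Low-energy primaries leave a larger fraction of their secondary
        electrons bound to the parent molecules."""
        res20 = run_simulation(
            SimConfig(E0=20.0, n_histories=250, seed=5), default_table
        )
        res1k = run_simulation(
            SimConfig(E0=1000.0, n_histories=40, seed=5), default_table
        )
        f20 = (res20.electrons["dist"] < 0.75).mean()
        f1k = (res1k.electrons["dist"] < 0.75).mean()
        assert f20 > f1k

    def test_hydrated_yield_non_decreasing_with_primary_energy(
        self, default_table
    ):
        """G_hyd rises from 20 eV through 100 eV to 1 keV (with MC error
        bars well separated at the end points)."""
        gs = []
        for e0, nh in ((20.0, 250), (100.0, 120), (1000.0, 40)):
            res = run_simulation(
                SimConfig(E0=e0, n_histories=nh, seed=15), default_table
            )
            gs.append(g_hyd(res))
        (g20, s20), (g100, s100), (g1k, s1k) = gs
        assert g20 - s20 < g100 + s100
        assert g100 - s100 < g1k + s1k
        assert g20 + 2 * s20 < g1k + 2 * s1k


class TestSummarise:
    def test_report_identities(self, default_table):
        res = run_simulation(SimConfig(E0=300.0, n_histories=10, seed=5),
                             default_table)
        rep = summarise(res)
        assert rep.p_ion + rep.p_exc == pytest.approx(1.0)
        assert rep.g_hyd == pytest.approx(rep.g_total * rep.p_ion, rel=1e-9)
        assert rep.w_value == pytest.approx(100.0 / rep.g_hyd, rel=1e-9)
        assert (
            rep.g_delocalised + rep.g_localised + rep.g_relocalised
            == pytest.approx(rep.g_total, rel=1e-9)
        )
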