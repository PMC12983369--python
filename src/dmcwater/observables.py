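"""Classification by the charge-separation radius and all reported summary
quantities.

The physicochemical-stage judgement of "ionisation vs electronic excitation"
is *spatial*: a tracked electron ending at 1 ps beyond the charge-separation
radius r_sep (default 0.75 nm, the H₃O⁺ + e_aq⁻ reaction radius) from its
own parent cation counts as ionisation — it will hydrate as e_aq⁻ —
regardless of which collision channel created it.  Within r_sep, electrons
born from excitation channels are *localised* and electrons born from
ionisation channels that were pulled back by the parent's Coulomb field are
*relocalised*; both count toward electronic excitation in the yields.

Quantities:

* G_total(t₀) = ⟨N_total(t₀)⟩ / E₀ × 100 per 100 eV — total yield of
  ionisation + electronic excitation events,
* P_ion(1 ps) = delocalised fraction, P_exc = 1 − P_ion,
* G_hyd(1 ps) = G_total(1 ps) × P_ion — the initial hydrated-electron yield,
* W = 100 / G_hyd — mean energy per (final) ionisation,
* penetration range, energy spectra, radial distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import K_BOLTZMANN
from .dynamics import (
    ORIGIN_EXCITATION,
    ORIGIN_IONISATION,
    STATUS_ACTIVE,
    SimulationResult,
)

__all__ = [
    "ClassCounts",
    "GReport",
    "g_total",
    "classify_final",
    "g_hyd",
    "w_from_g",
    "g_from_w",
    "ratio_ion_exc",
    "penetration_range",
    "energy_spectrum",
    "maxwellian_pdf",
    "spatial_distribution",
    "summarise",
]


@dataclass(frozen=True)
class ClassCounts:
    """Final-state classes of the N_e tracked electrons."""

    n_delocalised: int   # final distance to own parent >= r_sep
    n_localised: int     # excitation-channel origin, distance < r_sep
    n_relocalised: int   # ionisation-channel origin, distance < r_sep

    @property
    def n_total(self) -> int:
        return self.n_delocalised + self.n_localised + self.n_relocalised

    @property
    def p_ion(self) -> float:
        return self.n_delocalised / self.n_total

    @property
    def p_exc(self) -> float:
        return 1.0 - self.p_ion


@dataclass(frozen=True)
class GReport:
    """All reported summary quantities at the 1 ps horizon."""

    E0: float
    g_total: float             # /100 eV
    g_total_se: float
    p_ion: float
    p_exc: float
    g_hyd: float               # /100 eV
    g_hyd_se: float
    w_value: float             # eV
    ratio_ion_exc: float
    g_delocalised: float       # /100 eV
    g_localised: float
    g_relocalised: float
    counts: ClassCounts


def g_total(result: SimulationResult, t0: float):
    """Mean G_total(t₀) = N_total(t₀)/E₀ × 100 with its MC standard error."""
    if t0 > result.config.t_horizon:
        raise ValueError("t0 beyond the simulated horizon")
    nh = result.n_histories
    per_hist = np.zeros(nh)
    ev = result.events
    sel = ev[ev["t0"] <= t0]
    counts = sel.groupby("history").size()
    per_hist[counts.index.to_numpy()] = counts.to_numpy()
    g = per_hist / result.config.E0 * 100.0
    se = g.std(ddof=1) / math.sqrt(nh) if nh > 1 else 0.0
    return float(g.mean()), float(se)


def _final_distances(result: SimulationResult):
    el = result.electrons
    if (el["status"] == STATUS_ACTIVE).any():
        raise ValueError("classification before horizon: active electrons remain")
    return el["dist"].to_numpy(), el["origin"].to_numpy()


def classify_final(result: SimulationResult, r_sep: float | None = None) -> ClassCounts:
    """Count delocalised / localised / relocalised electrons at the horizon.

    Distance ties at exactly r_sep count as delocalised.
    """
    if r_sep is None:
        r_sep = result.config.r_sep
    dist, origin = _final_distances(result)
    deloc = dist >= r_sep
    return ClassCounts(
        n_delocalised=int(deloc.sum()),
        n_localised=int(((~deloc) & (origin == ORIGIN_EXCITATION)).sum()),
        n_relocalised=int(((~deloc) & (origin == ORIGIN_IONISATION)).sum()),
    )


def g_hyd(result: SimulationResult, r_sep: float | None = None):
    """Initial hydrated-electron yield G_hyd(1 ps) = G_total × P_ion,
    with MC standard error propagated from both factors."""
    counts = classify_final(result, r_sep)
    gt, gt_se = g_total(result, result.config.t_horizon)
    p = counts.p_ion
    n = counts.n_total
    p_se = math.sqrt(p * (1 - p) / n) if n else 0.0
    g = gt * p
    se = g * math.sqrt(
        (gt_se / gt) ** 2 + (p_se / p) ** 2 if gt > 0 and p > 0 else 0.0
    )
    return float(g), float(se)


def w_from_g(g: float) -> float:
    """W value (eV) from a G value (/100 eV): W = 100/G."""
    if g <= 0:
        raise ValueError("G must be > 0")
    return 100.0 / g


def g_from_w(w: float) -> float:
    """G value (/100 eV) from a W value (eV): G = 100/W."""
    if w <= 0:
        raise ValueError("W must be > 0")
    return 100.0 / w


def ratio_ion_exc(counts: ClassCounts) -> float:
    """Final ionisation / electronic-excitation ratio =
    delocalised / (localised + relocalised)."""
    den = counts.n_localised + counts.n_relocalised
    if den == 0:
        return math.nan
    return counts.n_delocalised / den


def penetration_range(result: SimulationResult, t0: float) -> float:
    """Mean straight-line distance of the primary electron from the origin
    at main-clock time t₀ (nm)."""
    if t0 > result.config.t_horizon:
        raise ValueError("t0 beyond the simulated horizon")
    dists = []
    el = result.electrons
    for h, path in enumerate(result.primary_paths):
        t = path[:, 0]
        if t0 <= t[0]:
            dists.append(0.0)
            continue
        if t0 >= t[-1]:
            # the primary has retired into the sub-excitation stage; use the
            # terminal state of its remainder electron (largest index of the
            # history that has no spawning event — the retired primary)
            hist = el[el["history"] == h]
            spawned = set(
                result.events[result.events["history"] == h]["elec"]
            )
            prim = hist[~hist["index"].isin(spawned)]
            if len(prim):
                row = prim.iloc[-1]
                dists.append(
                    float(np.sqrt(row.x**2 + row.y**2 + row.z**2))
                )
            else:
                p = path[-1, 1:]
                dists.append(float(np.linalg.norm(p)))
            continue
        j = int(np.searchsorted(t, t0))
        f = (t0 - t[j - 1]) / (t[j] - t[j - 1])
        p = path[j - 1, 1:] + f * (path[j, 1:] - path[j - 1, 1:])
        dists.append(float(np.linalg.norm(p)))
    return float(np.mean(dists))


def maxwellian_pdf(E, T: float = 300.0):
    """Maxwell–Boltzmann kinetic-energy density (per eV) at temperature T:
    f(E) = (2/√π) (k_BT)^(−3/2) √E exp(−E/k_BT)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("E must be >= 0")
    kt = K_BOLTZMANN * T
    f = 2.0 / math.sqrt(math.pi) * kt ** (-1.5) * np.sqrt(E) * np.exp(-E / kt)
    return f if f.ndim else float(f)


def _snapshot_column(result: SimulationResult, t: float, prefix: str):
    for ts in result.snapshot_times:
        if abs(ts - t) < 1e-9:
            return f"{prefix}_at_{ts:g}"
    raise ValueError(
        f"t = {t} fs was not a configured snapshot time "
        f"{result.snapshot_times}"
    )


def energy_spectrum(result: SimulationResult, t: float, bin_edges):
    """Density-normalised KE histogram of all electrons existing at t₀ = t.

    ``t`` must be one of the configured snapshot times.
    Returns (density, bin_edges).
    """
    col = _snapshot_column(result, t, "ke")
    ke = result.electrons[col].to_numpy()
    ke = ke[np.isfinite(ke)]
    if len(ke) == 0:
        raise ValueError("no electrons exist at the requested time")
    dens, edges = np.histogram(ke, bins=bin_edges, density=True)
    return dens, edges


def spatial_distribution(result: SimulationResult, t: float, bin_edges):
    """Histogram (counts per history) of electron–parent distances at t₀ = t.

    The integral over all bins equals ⟨N_e in range⟩ per history.
    """
    col = _snapshot_column(result, t, "dist")
    d = result.electrons[col].to_numpy()
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("no electrons exist at the requested time")
    counts, edges = np.histogram(d, bins=bin_edges)
    return counts / result.n_histories, edges


def summarise(result: SimulationResult, r_sep: float | None = None) -> GReport:
    """Full GReport at the horizon (classification is pure post-processing,
    so different r_sep values can be evaluated on one simulation)."""
    counts = classify_final(result, r_sep)
    gt, gt_se = g_total(result, result.config.t_horizon)
    gh, gh_se = g_hyd(result, r_sep)
    n = counts.n_total
    scale = gt / n if n else 0.0
    return GReport(
        E0=result.config.E0,
        g_total=gt,
        g_total_se=gt_se,
        p_ion=counts.p_ion if n else math.nan,
        p_exc=counts.p_exc if n else math.nan,
        g_hyd=gh,
        g_hyd_se=gh_se,
        w_value=w_from_g(gh) if gh > 0 else math.inf,
        ratio_ion_exc=ratio_ion_exc(counts),
        g_delocalised=counts.n_delocalised * scale,
        g_localised=counts.n_localised * scale,
        g_relocalised=counts.n_relocalised * scale,
        counts=counts,
    )
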