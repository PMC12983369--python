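"""The dynamic Monte Carlo engine.

Two stages per primary-electron history:

1. **Track generation** (main clock t₀): the primary starts at the origin
   moving along +z and alternates exponential free flights with sampled
   collisions.  Every ionisation and electronic excitation spawns a tracked
   electron and anchors a parent cation (or excitation hole) at the event
   position.  Spawned electrons above the tracking cutoff (default: the
   lowest electronic-excitation threshold) continue the collision cascade
   themselves; once any electron drops below the cutoff it becomes a
   sub-excitation electron.  The primary's own remainder below the cutoff is
   handled as one final sub-excitation electron anchored to the last cation
   it created.  Coulomb attraction is neglected in this fast stage.

2. **Femtosecond propagation** (per-electron clock t_i): every
   sub-excitation electron moves under the screened Coulomb force of its own
   parent (ε_r evaluated on t_i), interleaved with elastic, vibrational and
   quasi-elastic bath collisions, until it is arrested as thermalised
   (constant hydration-arrest hazard per collision once its kinetic energy
   is at thermal scale) or reaches its cutoff time t_cut,i.  Arrested
   electrons freeze where they stop, in thermal equilibrium with the bath.

Histories are independent: each gets its own counter-based RNG substream and
each sub-excitation electron its own kernel seed, so results are bit
reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .constants import ELECTRON_MASS, K_BOLTZMANN, speed_from_energy
from .dielectric import DielectricParams
from .xsec import (
    Channel,
    ChannelKind,
    CrossSectionTable,
    sample_energy_partition,
)

__all__ = [
    "SimConfig",
    "ElectronState",
    "SimulationResult",
    "generate_primary_track",
    "run_simulation",
    "propagate_secondary",
    "thermalisation_distance_experiment",
]

# event / origin kind codes used in the result tables
KIND_IONISATION = 0
KIND_EXC_DISCRETE = 1
KIND_EXC_COLLECTIVE = 2
KIND_ATTACHMENT = 3

ORIGIN_IONISATION = 0
ORIGIN_EXCITATION = 1

STATUS_ACTIVE = 0
STATUS_THERMALISED = 1
STATUS_CUTOFF = 2


@dataclass(frozen=True)
class SimConfig:
    """Run configuration (units: eV, nm, fs, K)."""

    E0: float = 1000.0
    n_histories: int = 100
    seed: int = 0
    t_horizon: float = 1000.0
    t_cut_secondary: float = 500.0
    r_sep: float = 0.75
    temperature: float = 300.0
    dt_max: float = 0.5
    disp_max: float = 0.05
    #: Plummer softening of the electron–cation force; stands in for the
    #: spatial extent of the newly born electron (classical point dynamics
    #: cannot resolve the angstrom-scale bound state)
    r_soft: float = 0.40
    #: electrons below this KE are handed to the femtosecond propagator
    tracking_cutoff: float = 8.4
    #: effective bath-particle mass (units of m_e) of the quasi-elastic
    #: phonon coupling
    bath_mass_me: float = 45.0
    #: spatial extent (Gaussian σ per axis, nm) of the excited-state orbital:
    #: discrete-excitation electrons are born displaced from the parent hole
    #: by a draw from this distribution rather than exactly on top of it
    exc_birth_radius: float = 0.30
    freeze_kT_multiple: float = 8.0
    freeze_dwell: int = 4
    dea_enabled: bool = False
    snapshot_times: tuple[float, ...] = (300.0, 500.0, 1000.0)

    def __post_init__(self) -> None:
        if not (20.0 <= self.E0 <= 30000.0):
            raise ValueError("E0 must be within the supported 20 eV – 30 keV range")
        if self.t_cut_secondary > self.t_horizon:
            raise ValueError("t_cut_secondary must be <= t_horizon")
        if self.r_sep <= 0:
            raise ValueError("r_sep must be > 0")
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")


@dataclass
class ElectronState:
    """One tracked electron."""

    index: int
    position: np.ndarray
    velocity: np.ndarray
    kinetic_energy: float
    parent_position: np.ndarray
    birth_time: float                  # on the main clock t0, fs
    local_clock: float = 0.0           # t_i, fs
    origin_kind: int = ORIGIN_IONISATION
    status: int = STATUS_ACTIVE
    has_parent: bool = True


# ---------------------------------------------------------------------------
# fast channel sampler on a dense log grid
# ---------------------------------------------------------------------------

class _ChannelSampler:
    """Dense-grid Λ(E) and channel-branching sampler for a channel subset."""

    def __init__(
        self,
        table: CrossSectionTable,
        keep: list[int],
        n_points: int = 700,
    ) -> None:
        from .xsec import sigma_at

        self.table = table
        self.keep = keep
        self.channels = [table.channels[c] for c in keep]
        self.grid = np.geomspace(table.e_min, table.e_max, n_points)
        self.log_e = np.log(self.grid)
        sig = np.empty((len(keep), n_points))
        for row, c in enumerate(keep):
            ch = table.channels[c]
            sig[row] = [sigma_at(table, ch, e) for e in self.grid]
        tot = sig.sum(axis=0)
        self.lam = table.number_density * tot
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, sig / tot, 0.0)
        self.cum = np.cumsum(frac, axis=0).T.copy()  # (G, C)
        # guard against round-off: last column exactly 1 where open
        open_ = tot > 0
        self.cum[open_, -1] = 1.0

    def lam_at(self, E: float) -> float:
        x = math.log(max(E, self.grid[0]))
        return float(np.interp(x, self.log_e, self.lam))

    def pick(self, E: float, u: float) -> Channel:
        x = math.log(min(max(E, self.grid[0]), self.grid[-1]))
        j = int(np.searchsorted(self.log_e, x))
        if j == 0:
            row = self.cum[0]
        elif j >= len(self.log_e):
            row = self.cum[-1]
        else:
            w = (x - self.log_e[j - 1]) / (self.log_e[j] - self.log_e[j - 1])
            row = self.cum[j - 1] * (1 - w) + self.cum[j] * w
        c = int(np.searchsorted(row, u))
        return self.channels[min(c, len(self.channels) - 1)]


_KIND_TO_KERNEL = {
    ChannelKind.ELASTIC: 0,
    ChannelKind.PHONON: 1,
    ChannelKind.VIBRATIONAL: 2,
}

_SOFT_KINDS = set(_KIND_TO_KERNEL)


def _make_samplers(table: CrossSectionTable):
    all_idx = list(range(len(table.channels)))
    soft_idx = [
        i for i in all_idx if table.channels[i].kind in _SOFT_KINDS
    ]
    return _ChannelSampler(table, all_idx), _ChannelSampler(table, soft_idx)


def _kernel_arrays(soft: _ChannelSampler):
    kind_code = np.array(
        [_KIND_TO_KERNEL[ch.kind] for ch in soft.channels], dtype=np.int64
    )
    quantum = np.array(
        [ch.threshold_energy for ch in soft.channels], dtype=float
    )
    if len(soft.channels) == 0:
        # degenerate: no soft channels → Λ = 0 everywhere
        return (
            np.array([0.0, 1.0]),
            np.zeros(2),
            np.ones((2, 1)),
            np.zeros(1, dtype=np.int64),
            np.zeros(1),
        )
    return soft.log_e, soft.lam, soft.cum, kind_code, quantum


def _eps_kernel_params(params: DielectricParams):
    comps = list(params.components)
    if len(comps) > 2:
        raise ValueError(
            "the propagation kernel supports at most two dielectric "
            "relaxation components"
        )
    while len(comps) < 2:
        comps.append((0.0, 1.0))
    (a1, t1), (a2, t2) = comps
    return params.eps_electronic, a1, t1, a2, t2


# ---------------------------------------------------------------------------
# stage 1: collision cascade on the main clock
# ---------------------------------------------------------------------------

def _rotate_dir(d: np.ndarray, mu: float, phi: float) -> np.ndarray:
    st = math.sqrt(max(0.0, 1.0 - mu * mu))
    if abs(d[2]) < 0.99:
        a = np.array([-d[1], d[0], 0.0])
    else:
        a = np.array([0.0, -d[2], d[1]])
    a /= np.linalg.norm(a)
    b = np.cross(d, a)
    return mu * d + st * (math.cos(phi) * a + math.sin(phi) * b)


def _elastic_mu(E: float, u: float) -> float:
    if E < 1.0:
        return 1.0 - 2.0 * u
    tau = E / 510998.95
    eta = 1.7e-5 * 7.42 ** (2.0 / 3.0) / (tau * (tau + 2.0))
    if eta > 10.0:
        return 1.0 - 2.0 * u
    return 1.0 - 2.0 * eta * u / (1.0 + eta - u)


def _isotropic_dir(rng) -> np.ndarray:
    mu = 1.0 - 2.0 * rng.random()
    phi = 2.0 * math.pi * rng.random()
    st = math.sqrt(max(0.0, 1.0 - mu * mu))
    return np.array([st * math.cos(phi), st * math.sin(phi), mu])


def generate_primary_track(
    config: SimConfig,
    table: CrossSectionTable,
    rng: np.random.Generator,
    sampler: _ChannelSampler | None = None,
):
    """Run the collision cascade of one history.

    Returns ``(events, handoffs, primary_path, energy_sinks)``:

    * events: list of (t0, x, y, z, kind_code, energy_transfer, elec_index)
      — ionisation and electronic-excitation events only,
    * handoffs: list of ElectronState below the tracking cutoff, ready for
      femtosecond propagation (the retired primary included, anchored at its
      last event),
    * primary_path: (k, 4) array of (t0, x, y, z) at every collision of the
      primary,
    * energy_sinks: total energy removed from tracked electrons (bindings,
      excitation/vibrational quanta net of released KE); together with the
      hand-off kinetic energies this reconstructs E0 exactly.
    """
    if config.E0 > table.e_max:
        raise ValueError(
            f"E0 = {config.E0} eV above table maximum {table.e_max} eV"
        )
    if not config.dea_enabled:
        for ch, sig in zip(table.channels, table.sigma):
            if ch.kind is ChannelKind.ATTACHMENT and np.any(sig > 0):
                raise ValueError(
                    "table carries a live attachment channel; set "
                    "dea_enabled=True to use it"
                )
    if sampler is None:
        sampler = _ChannelSampler(table, list(range(len(table.channels))))

    events: list[tuple] = []
    handoffs: list[ElectronState] = []
    path = [(0.0, 0.0, 0.0, 0.0)]
    sinks = 0.0
    n_spawned = 0

    # stack entries: (E, pos, dir, t0, origin_kind, parent_pos, is_primary, idx)
    stack = [
        (
            float(config.E0),
            np.zeros(3),
            np.array([0.0, 0.0, 1.0]),
            0.0,
            None,
            None,
            True,
            -1,
        )
    ]
    cutoff = config.tracking_cutoff

    while stack:
        E, pos, direction, t0, origin, parent, is_primary, own_idx = stack.pop()
        pos = pos.copy()
        direction = direction.copy()
        last_event_pos = None
        absorbed = False
        guard = 0
        while E > cutoff:
            guard += 1
            if guard > 2_000_000:
                raise RuntimeError("cascade did not terminate")
            lam = sampler.lam_at(E)
            if lam <= 0.0:
                break  # nothing can happen; retire as ballistic
            s = rng.exponential(1.0 / lam)
            t0 += s / speed_from_energy(E)
            pos += s * direction
            ch = sampler.pick(E, rng.random())
            k = ch.kind
            if is_primary:
                path.append((t0, pos[0], pos[1], pos[2]))
            if k is ChannelKind.ELASTIC:
                mu = _elastic_mu(E, rng.random())
                direction = _rotate_dir(direction, mu, 2 * math.pi * rng.random())
            elif k is ChannelKind.PHONON:
                # negligible energy exchange at cascade energies
                direction = _rotate_dir(
                    direction, 1.0 - 2.0 * rng.random(), 2 * math.pi * rng.random()
                )
            elif k is ChannelKind.VIBRATIONAL:
                if E > ch.threshold_energy:
                    E -= ch.threshold_energy
                    sinks += ch.threshold_energy
            elif k is ChannelKind.ATTACHMENT:
                if E > ch.threshold_energy:
                    sinks += E
                    E = 0.0
                    absorbed = True
                    break
            else:
                if E <= ch.threshold_energy:
                    continue
                transfer, w = sample_energy_partition(ch, E, rng)
                w = 0.0 if w is None else w
                if k is ChannelKind.IONISATION:
                    kind_code = KIND_IONISATION
                    new_origin = ORIGIN_IONISATION
                elif k is ChannelKind.EXCITATION_DISCRETE:
                    kind_code = KIND_EXC_DISCRETE
                    new_origin = ORIGIN_EXCITATION
                else:
                    kind_code = KIND_EXC_COLLECTIVE
                    new_origin = ORIGIN_EXCITATION
                idx = n_spawned
                n_spawned += 1
                events.append(
                    (t0, pos[0], pos[1], pos[2], kind_code, transfer, idx)
                )
                sinks += transfer - w
                sec_dir = _isotropic_dir(rng)
                birth_pos = pos.copy()
                if k is ChannelKind.EXCITATION_DISCRETE:
                    # excited-state orbital extent: the electron appears
                    # displaced from the hole it stays bound to
                    birth_pos = pos + config.exc_birth_radius * rng.standard_normal(3)
                if w > cutoff:
                    stack.append(
                        (w, birth_pos, sec_dir, t0, new_origin, pos.copy(),
                         False, idx)
                    )
                else:
                    handoffs.append(
                        ElectronState(
                            index=idx,
                            position=birth_pos,
                            velocity=float(speed_from_energy(w)) * sec_dir,
                            kinetic_energy=w,
                            parent_position=pos.copy(),
                            birth_time=t0,
                            origin_kind=new_origin,
                        )
                    )
                # projectile deflection (binary-encounter approximation)
                mu = math.sqrt(max(0.0, 1.0 - transfer / E))
                direction = _rotate_dir(direction, mu, 2 * math.pi * rng.random())
                E -= transfer
                last_event_pos = pos.copy()
                last_event_kind = new_origin
                if is_primary:
                    path.append((t0, pos[0], pos[1], pos[2]))
        # retire this electron below the cutoff
        if absorbed:
            continue
        if is_primary:
            if last_event_pos is None:
                # no inelastic event ever happened: anchor at current position
                anchor, o_kind, has_par = pos.copy(), ORIGIN_IONISATION, False
            else:
                anchor, o_kind, has_par = last_event_pos, last_event_kind, True
            idx = n_spawned
            n_spawned += 1
            handoffs.append(
                ElectronState(
                    index=idx,
                    position=pos.copy(),
                    velocity=float(speed_from_energy(E)) * direction,
                    kinetic_energy=E,
                    parent_position=anchor,
                    birth_time=t0,
                    origin_kind=o_kind,
                    has_parent=has_par,
                )
            )
        else:
            # a cascading secondary that has now dropped below the cutoff;
            # it stays anchored to its own birth cation
            handoffs.append(
                ElectronState(
                    index=own_idx,
                    position=pos.copy(),
                    velocity=float(speed_from_energy(E)) * direction,
                    kinetic_energy=E,
                    parent_position=parent.copy(),
                    birth_time=t0,
                    origin_kind=origin,
                )
            )
    return events, handoffs, np.asarray(path), sinks


# ---------------------------------------------------------------------------
# stage 2: batched femtosecond propagation
# ---------------------------------------------------------------------------

def _propagate_states(
    states: list[ElectronState],
    params: DielectricParams,
    table: CrossSectionTable,
    config: SimConfig,
    seeds: np.ndarray,
    snapshot_global: np.ndarray,
    soft: _ChannelSampler | None = None,
):
    """Run the kernel over a batch; returns final arrays."""
    n = len(states)
    n_snap = len(snapshot_global)
    pos = np.array([s.position for s in states], dtype=float)
    vel = np.array([s.velocity for s in states], dtype=float)
    par = np.array([s.parent_position for s in states], dtype=float)
    hasp = np.array([s.has_parent for s in states], dtype=np.uint8)
    birth = np.array([s.birth_time for s in states], dtype=float)
    t_cut = np.full(n, config.t_cut_secondary)
    # never propagate past the global horizon
    t_cut = np.minimum(t_cut, np.maximum(config.t_horizon - birth, 0.0))
    snaps_local = snapshot_global[None, :] - birth[:, None]
    if soft is None:
        _, soft = _make_samplers(table)
    log_e, lam, cum, kind_code, quantum = _kernel_arrays(soft)
    eps_el, a1, t1, a2, t2 = _eps_kernel_params(params)
    ke_out = np.empty(n)
    t_out = np.empty(n)
    status_out = np.empty(n, dtype=np.int64)
    snap_ke = np.empty((n, n_snap))
    snap_dist = np.empty((n, n_snap))
    kT = K_BOLTZMANN * config.temperature
    _kernel.propagate_batch(
        np.asarray(seeds, dtype=np.int64),
        pos,
        vel,
        par,
        hasp,
        t_cut,
        snaps_local,
        log_e,
        lam,
        cum,
        kind_code,
        quantum,
        ELECTRON_MASS,
        params.coulomb_constant,
        eps_el,
        a1,
        t1,
        a2,
        t2,
        kT,
        config.bath_mass_me * ELECTRON_MASS,
        config.r_soft**2,
        config.dt_max,
        config.disp_max,
        config.freeze_kT_multiple * kT,
        config.freeze_dwell,
        ke_out,
        t_out,
        status_out,
        snap_ke,
        snap_dist,
    )
    return pos, vel, ke_out, t_out, status_out, snap_ke, snap_dist


def propagate_secondary(
    state: ElectronState,
    params: DielectricParams,
    table: CrossSectionTable,
    config: SimConfig,
    seed: int = 0,
) -> ElectronState:
    """Propagate a single sub-excitation electron to thermalisation or its
    cutoff time; returns the final state (a new object)."""
    if state.status != STATUS_ACTIVE:
        raise ValueError("electron is not active")
    snaps = np.asarray([], dtype=float)
    pos, vel, ke, t, status, _, _ = _propagate_states(
        [state], params, table, config, np.array([seed]), snaps
    )
    return ElectronState(
        index=state.index,
        position=pos[0],
        velocity=vel[0],
        kinetic_energy=float(ke[0]),
        parent_position=state.parent_position.copy(),
        birth_time=state.birth_time,
        local_clock=float(t[0]),
        origin_kind=state.origin_kind,
        status=int(status[0]),
        has_parent=state.has_parent,
    )


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Aggregated output of ``run_simulation``.

    ``events`` (one row per ionisation/excitation event):
        history, t0, x, y, z, kind, transfer, elec
    ``electrons`` (one row per tracked electron, terminal state):
        history, index, origin, birth_t0, parent_x/y/z, x/y/z, vx/vy/vz,
        ke, t_i, status, dist  (+ ke_at_<t>/dist_at_<t> snapshot columns)
    """

    config: SimConfig
    events: pd.DataFrame
    electrons: pd.DataFrame
    primary_paths: list[np.ndarray]
    snapshot_times: tuple[float, ...]
    energy_residuals: np.ndarray  # per history, eV (bookkeeping check)

    @property
    def n_histories(self) -> int:
        return self.config.n_histories

    def n_total_series(self, t_grid) -> np.ndarray:
        """Mean cumulative number of ionisation+excitation events N_total(t0)."""
        t_grid = np.asarray(t_grid, dtype=float)
        t_ev = np.sort(self.events["t0"].to_numpy())
        counts = np.searchsorted(t_ev, t_grid, side="right") / self.n_histories
        return counts

    # -- serialisation -------------------------------------------------
    def save(self, path) -> None:
        """Write an HDF5 result container (events/electrons/paths)."""
        import h5py
        import json
        from dataclasses import asdict

        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["snapshot_times"] = list(self.snapshot_times)
            f.create_dataset("energy_residuals", data=self.energy_residuals)
            g = f.create_group("events")
            for col in self.events.columns:
                g.create_dataset(col, data=self.events[col].to_numpy())
            g = f.create_group("electrons")
            for col in self.electrons.columns:
                g.create_dataset(col, data=self.electrons[col].to_numpy())
            g = f.create_group("primary_paths")
            for i, p in enumerate(self.primary_paths):
                g.create_dataset(str(i), data=p)

    @classmethod
    def load(cls, path) -> "SimulationResult":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            cfg_d = json.loads(f.attrs["config"])
            cfg_d["snapshot_times"] = tuple(cfg_d["snapshot_times"])
            config = SimConfig(**cfg_d)
            snaps = tuple(f.attrs["snapshot_times"])
            resid = f["energy_residuals"][...]
            events = pd.DataFrame(
                {k: f["events"][k][...] for k in f["events"]}
            )
            electrons = pd.DataFrame(
                {k: f["electrons"][k][...] for k in f["electrons"]}
            )
            paths = [
                f["primary_paths"][k][...]
                for k in sorted(f["primary_paths"], key=int)
            ]
        return cls(config, events, electrons, paths, snaps, resid)


def run_simulation(
    config: SimConfig,
    table: CrossSectionTable,
    params: DielectricParams | None = None,
) -> SimulationResult:
    """Run ``config.n_histories`` independent histories.

    Fully reproducible given (seed, config, table, params): per-history
    Philox substreams drive the cascade, and every sub-excitation electron
    receives its own kernel seed drawn from its history's stream.
    """
    if params is None:
        params = DielectricParams()
    full, soft = _make_samplers(table)
    snaps = np.asarray(sorted(config.snapshot_times), dtype=float)

    ev_rows = []
    el_meta = []  # (history, state, seed)
    paths = []
    residuals = np.empty(config.n_histories)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_histories)
    all_states: list[ElectronState] = []
    all_seeds: list[int] = []
    for h in range(config.n_histories):
        rng = np.random.Generator(np.random.Philox(children[h]))
        events, handoffs, path, sinks = generate_primary_track(
            config, table, rng, sampler=full
        )
        for ev in events:
            ev_rows.append((h, *ev))
        paths.append(path)
        ke_sum = sum(e.kinetic_energy for e in handoffs)
        residuals[h] = config.E0 - (sinks + ke_sum)
        for e in handoffs:
            seed = int(rng.integers(0, 2**31 - 1))
            el_meta.append((h, e))
            all_states.append(e)
            all_seeds.append(seed)

    pos, vel, ke, t_i, status, snap_ke, snap_dist = _propagate_states(
        all_states, params, table, config, np.asarray(all_seeds), snaps, soft
    )

    events_df = pd.DataFrame(
        ev_rows,
        columns=["history", "t0", "x", "y", "z", "kind", "transfer", "elec"],
    )
    par = np.array([s.parent_position for s in all_states])
    dist = np.linalg.norm(pos - par, axis=1)
    el = {
        "history": [h for h, _ in el_meta],
        "index": [s.index for _, s in el_meta],
        "origin": [s.origin_kind for _, s in el_meta],
        "birth_t0": [s.birth_time for _, s in el_meta],
        "parent_x": par[:, 0] if len(all_states) else [],
        "parent_y": par[:, 1] if len(all_states) else [],
        "parent_z": par[:, 2] if len(all_states) else [],
        "x": pos[:, 0] if len(all_states) else [],
        "y": pos[:, 1] if len(all_states) else [],
        "z": pos[:, 2] if len(all_states) else [],
        "vx": vel[:, 0] if len(all_states) else [],
        "vy": vel[:, 1] if len(all_states) else [],
        "vz": vel[:, 2] if len(all_states) else [],
        "ke": ke,
        "t_i": t_i,
        "status": status,
        "dist": dist,
        "has_parent": [s.has_parent for _, s in el_meta],
    }
    electrons_df = pd.DataFrame(el)
    for k, ts in enumerate(snaps):
        electrons_df[f"ke_at_{ts:g}"] = snap_ke[:, k]
        electrons_df[f"dist_at_{ts:g}"] = snap_dist[:, k]
    return SimulationResult(
        config=config,
        events=events_df,
        electrons=electrons_df,
        primary_paths=paths,
        snapshot_times=tuple(snaps),
        energy_residuals=residuals,
    )


# ---------------------------------------------------------------------------
# injection experiment
# ---------------------------------------------------------------------------

def thermalisation_distance_experiment(
    e_inject: float,
    n: int,
    seed: int,
    table: CrossSectionTable,
    params: DielectricParams | None = None,
    config: SimConfig | None = None,
):
    """Mean straight-line injection-to-stop distance for mono-energetic
    electrons injected isotropically with no parent cation.

    Returns ``(mean_nm, standard_error_nm)``.
    """
    if not (0.0 < e_inject <= 10.0):
        raise ValueError("e_inject must be in (0, 10] eV")
    if params is None:
        params = DielectricParams()
    if config is None:
        config = SimConfig()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    states = []
    v0 = float(speed_from_energy(e_inject))
    for i in range(n):
        d = _isotropic_dir(rng)
        states.append(
            ElectronState(
                index=i,
                position=np.zeros(3),
                velocity=v0 * d,
                kinetic_energy=e_inject,
                parent_position=np.zeros(3),
                birth_time=0.0,
                has_parent=False,
            )
        )
    seeds = rng.integers(0, 2**31 - 1, size=n)
    pos, _, _, _, _, _, _ = _propagate_states(
        states, params, table, config, seeds, np.asarray([], dtype=float)
    )
    d = np.linalg.norm(pos, axis=1)
    return float(d.mean()), float(d.std(ddof=1) / math.sqrt(n))
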