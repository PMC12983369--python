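"""Channel-resolved electron–water cross sections: containers, file format,
interpolation, and the stochastic sampling primitives driving the transport.

A :class:`CrossSectionTable` holds a strictly increasing energy grid (eV) and
one cross-section column (nm²) per interaction channel.  Channels carry a
taxonomy (:class:`ChannelKind`): elastic scattering, ionisation shells,
discrete and collective electronic excitations, vibrational modes, a
quasi-elastic phonon/bath channel, and (disabled by default) dissociative
electron attachment.

Interpolation between grid nodes is log–log linear — cross sections span
many decades in both E and σ — with a linear–linear fallback whenever one of
the bracketing nodes is zero.  There is no extrapolation above the grid.

The TSV dialect (round-trips bit-exactly)::

    #phase=liquid
    #density_nm3=33.43
    #provenance=free text
    #channel <name> <kind> <threshold_eV> <loss_model> [param]
    E_eV<TAB>sigma_nm2_channel1<TAB>sigma_nm2_channel2 ...

The optional trailing ``param`` is the channel's differential-model parameter:
the Lorentzian width *a* (eV) of the secondary-energy spectrum for ionisation
channels, or the binding reference (eV) that fixes the released-electron
kinetic energy for collective-excitation channels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_NUMBER_DENSITY

__all__ = [
    "ChannelKind",
    "EnergyLossModel",
    "Channel",
    "CrossSectionTable",
    "CollisionDraw",
    "TableFormatError",
    "load_table",
    "write_table",
    "sigma_at",
    "inverse_mfp",
    "sample_flight",
    "sample_channel",
    "sample_energy_partition",
]


class TableFormatError(ValueError):
    """Raised when a cross-section file violates the dialect or invariants."""


class ChannelKind(str, enum.Enum):
    ELASTIC = "elastic"
    IONISATION = "ionisation"
    EXCITATION_DISCRETE = "excitation_discrete"
    EXCITATION_COLLECTIVE = "excitation_collective"
    VIBRATIONAL = "vibrational"
    PHONON = "phonon"
    ATTACHMENT = "attachment"


class EnergyLossModel(str, enum.Enum):
    FIXED_QUANTUM = "fixed_quantum"
    DIFFERENTIAL_TABLE = "differential_table"
    NONE = "none"


#: default Lorentzian width (eV) of the secondary-electron spectrum
DEFAULT_LORENTZ_A = 2.0


@dataclass(frozen=True)
class Channel:
    """One interaction channel.

    ``threshold_energy`` is the ionisation binding energy, the excitation
    transition energy, or the vibrational quantum (0 for elastic/phonon).
    ``param`` is the optional differential-model parameter (see module
    docstring).
    """

    name: str
    kind: ChannelKind
    threshold_energy: float
    energy_loss_model: EnergyLossModel
    param: float = float("nan")

    def __post_init__(self) -> None:
        if self.threshold_energy < 0:
            raise ValueError(f"channel {self.name}: threshold_energy < 0")


@dataclass
class CrossSectionTable:
    """Energy grid + per-channel cross sections.

    Attributes
    ----------
    energy_grid : (n,) array, eV, strictly increasing
    channels : list of Channel
    sigma : (n_channels, n) array, nm²
    number_density : molecules / nm³
    phase : "liquid" or "vapour"
    provenance : free-text origin of the numbers
    """

    energy_grid: np.ndarray
    channels: list[Channel]
    sigma: np.ndarray
    number_density: float = WATER_NUMBER_DENSITY
    phase: str = "liquid"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        g = self.energy_grid
        if g.ndim != 1 or len(g) < 2:
            raise TableFormatError("energy grid must be 1-D with >= 2 points")
        if np.any(np.diff(g) <= 0):
            i = int(np.flatnonzero(np.diff(g) <= 0)[0])
            raise TableFormatError(
                f"grid not strictly increasing at row {i + 1} (E = {g[i + 1]} eV)"
            )
        if self.sigma.shape != (len(self.channels), len(g)):
            raise TableFormatError(
                f"sigma shape {self.sigma.shape} does not match "
                f"{len(self.channels)} channels x {len(g)} grid points"
            )
        if np.any(self.sigma < 0):
            c, j = np.argwhere(self.sigma < 0)[0]
            raise TableFormatError(
                f"negative cross section in channel '{self.channels[c].name}' "
                f"at row {j}"
            )
        for c, ch in enumerate(self.channels):
            below = g < ch.threshold_energy
            if np.any(self.sigma[c, below] > 0):
                j = int(np.flatnonzero(below & (self.sigma[c] > 0))[0])
                raise TableFormatError(
                    f"channel '{ch.name}' has sigma > 0 below its threshold "
                    f"at row {j} (E = {g[j]} eV)"
                )
        kinds = {ch.kind for ch in self.channels}
        if ChannelKind.ELASTIC not in kinds:
            raise TableFormatError("table must contain an elastic channel")
        if ChannelKind.IONISATION not in kinds:
            raise TableFormatError("table must contain an ionisation channel")
        if self.number_density <= 0:
            raise TableFormatError("number_density must be > 0")

    # -- helpers -------------------------------------------------------
    def channel_index(self, channel: Channel | str) -> int:
        name = channel.name if isinstance(channel, Channel) else channel
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"no channel named '{name}'")

    @property
    def e_min(self) -> float:
        return float(self.energy_grid[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_grid[-1])


@dataclass(frozen=True)
class CollisionDraw:
    """One sampled interaction (plumbing between sampler and engine)."""

    flight_length: float          # nm
    channel: Channel
    energy_transfer: float        # eV
    secondary_kinetic_energy: float | None  # eV, None if no tracked electron
    deflection: tuple[float, float] = (0.0, 0.0)  # polar, azimuthal (rad)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_table(path) -> CrossSectionTable:
    """Read the TSV dialect; raises :class:`TableFormatError` on violations."""
    meta: dict[str, str] = {}
    channels: list[Channel] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#channel"):
                parts = line.split()
                if len(parts) not in (5, 6):
                    raise TableFormatError(
                        f"line {lineno}: expected "
                        "'#channel name kind threshold loss_model [param]'"
                    )
                try:
                    kind = ChannelKind(parts[2])
                    model = EnergyLossModel(parts[4])
                except ValueError as exc:
                    raise TableFormatError(f"line {lineno}: {exc}") from None
                param = float(parts[5]) if len(parts) == 6 else float("nan")
                channels.append(
                    Channel(parts[1], kind, float(parts[3]), model, param)
                )
            elif line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            else:
                try:
                    rows.append([float(x) for x in line.split("\t")])
                except ValueError:
                    raise TableFormatError(
                        f"line {lineno}: non-numeric data row"
                    ) from None
                if len(rows[-1]) != len(channels) + 1:
                    raise TableFormatError(
                        f"line {lineno}: expected {len(channels) + 1} columns, "
                        f"got {len(rows[-1])}"
                    )
    if not channels:
        raise TableFormatError("no #channel declarations found")
    if not rows:
        raise TableFormatError("no data rows found")
    data = np.asarray(rows, dtype=float)
    table = CrossSectionTable(
        energy_grid=data[:, 0],
        channels=channels,
        sigma=data[:, 1:].T,
        number_density=float(meta.get("density_nm3", WATER_NUMBER_DENSITY)),
        phase=meta.get("phase", "liquid"),
        provenance=meta.get("provenance", ""),
    )
    for ch, sig in zip(table.channels, table.sigma):
        if ch.kind is ChannelKind.ATTACHMENT and np.any(sig > 0):
            # DEA ships disabled: tables carrying live attachment cross
            # sections must be enabled explicitly at run time.
            table.provenance += " [attachment>0]"
    return table


def write_table(table: CrossSectionTable, path) -> None:
    """Write the TSV dialect.  ``load_table(write_table(t))`` is bit-exact
    because floats are serialised with shortest round-trip repr."""
    with open(path, "w") as fh:
        fh.write(f"#phase={table.phase}\n")
        fh.write(f"#density_nm3={table.number_density!r}\n")
        if table.provenance:
            fh.write(f"#provenance={table.provenance}\n")
        for ch in table.channels:
            line = (
                f"#channel {ch.name} {ch.kind.value} "
                f"{ch.threshold_energy!r} {ch.energy_loss_model.value}"
            )
            if not math.isnan(ch.param):
                line += f" {ch.param!r}"
            fh.write(line + "\n")
        for j, e in enumerate(table.energy_grid):
            cols = [repr(float(e))] + [
                repr(float(s)) for s in table.sigma[:, j]
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# interpolation and mean free path
# ---------------------------------------------------------------------------

def sigma_at(table: CrossSectionTable, channel: Channel | str, E) -> float:
    """Cross section (nm²) of one channel at energy E (eV).

    Log–log linear between bracketing nodes (linear–linear if either node is
    zero); exactly the tabulated value at a node; 0 below the channel
    threshold.  E above the grid raises (no extrapolation).
    """
    c = table.channel_index(channel)
    ch = table.channels[c]
    E = float(E)
    if E < ch.threshold_energy:
        return 0.0
    if E > table.e_max:
        raise ValueError(
            f"E = {E} eV above grid maximum {table.e_max} eV (no extrapolation)"
        )
    if E < table.e_min:
        raise ValueError(f"E = {E} eV below grid minimum {table.e_min} eV")
    g = table.energy_grid
    j = int(np.searchsorted(g, E))
    if g[j] == E:
        return float(table.sigma[c, j])
    lo, hi = j - 1, j
    s1, s2 = table.sigma[c, lo], table.sigma[c, hi]
    e1, e2 = g[lo], g[hi]
    if s1 > 0 and s2 > 0:
        f = (math.log(E) - math.log(e1)) / (math.log(e2) - math.log(e1))
        return float(math.exp(math.log(s1) + f * (math.log(s2) - math.log(s1))))
    f = (E - e1) / (e2 - e1)
    return float(s1 + f * (s2 - s1))


def inverse_mfp(table: CrossSectionTable, E) -> float:
    """Total inverse mean free path Λ(E) = n · Σ_c σ_c(E), in nm⁻¹."""
    return table.number_density * sum(
        sigma_at(table, ch, E) for ch in table.channels
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_flight(
    table: CrossSectionTable, E, rng: np.random.Generator, size=None
):
    """Exponential free-flight length(s) (nm) with mean 1/Λ(E).

    Returns ``inf`` when Λ(E) = 0 (no interaction possible; the caller
    transports ballistically to the horizon).
    """
    lam = inverse_mfp(table, E)
    if lam <= 0.0:
        return math.inf if size is None else np.full(size, math.inf)
    if size is None:
        return float(rng.exponential(1.0 / lam))
    return rng.exponential(1.0 / lam, size=size)


def sample_channel(
    table: CrossSectionTable, E, rng: np.random.Generator, size=None
):
    """Pick channel(s) with probability σ_c(E) / Σ σ(E)."""
    sig = np.array([sigma_at(table, ch, E) for ch in table.channels])
    tot = sig.sum()
    if tot <= 0:
        raise ValueError(f"no open channel at E = {E} eV (Lambda = 0)")
    idx = rng.choice(len(sig), p=sig / tot, size=size)
    if size is None:
        return table.channels[int(idx)]
    return [table.channels[i] for i in np.atleast_1d(idx)]


def lorentzian_secondary_cdf_inverse(u, a: float, w_max: float) -> float:
    """Inverse CDF of dσ/dW ∝ 1/(W² + a²) truncated to [0, w_max]."""
    return a * math.tan(u * math.atan(w_max / a))


def sample_energy_partition(
    channel: Channel, E, rng: np.random.Generator
) -> tuple[float, float | None]:
    """Energy transfer and tracked-electron initial KE for one collision.

    * ionisation: transfer = binding + W, W drawn from the channel's
      Lorentzian-tail differential model truncated at (E − B)/2 — the
      indistinguishability cap (the faster outgoing electron is, by
      convention, the projectile).
    * discrete excitation: transfer = transition energy; the tracked electron
      starts with KE = transfer − threshold = 0.
    * collective excitation: transfer = quantum; the electron is promoted
      above the ionisation continuum and released with
      KE = quantum − binding_reference (channel ``param``, default 10.9 eV).
    * vibrational: transfer = vibrational quantum, no tracked electron.
    * elastic / phonon: transfer 0 here (recoil / bath exchange is handled
      kinematically by the engine), no tracked electron.

    Returns ``(energy_transfer, secondary_KE_or_None)``.
    """
    E = float(E)
    k = channel.kind
    if k is ChannelKind.ELASTIC or k is ChannelKind.PHONON:
        return 0.0, None
    if E <= channel.threshold_energy:
        raise ValueError(
            f"E = {E} eV at or below threshold "
            f"{channel.threshold_energy} eV of channel '{channel.name}'"
        )
    if k is ChannelKind.VIBRATIONAL:
        return channel.threshold_energy, None
    if k is ChannelKind.EXCITATION_DISCRETE:
        return channel.threshold_energy, 0.0
    if k is ChannelKind.EXCITATION_COLLECTIVE:
        b_ref = channel.param
        if math.isnan(b_ref):
            b_ref = channel.threshold_energy
        ke = max(0.0, channel.threshold_energy - b_ref)
        return channel.threshold_energy, ke
    if k is ChannelKind.IONISATION:
        b = channel.threshold_energy
        a = channel.param if not math.isnan(channel.param) else DEFAULT_LORENTZ_A
        w_max = 0.5 * (E - b)
        w = lorentzian_secondary_cdf_inverse(float(rng.random()), a, w_max)
        return b + w, w
    if k is ChannelKind.ATTACHMENT:
        # the electron is absorbed; its whole KE is transferred
        return E, None
    raise ValueError(f"unknown channel kind {k}")
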