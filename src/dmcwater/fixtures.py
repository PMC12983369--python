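"""Deterministic synthetic cross-section tables for tests and examples.

Generated tables always satisfy the :class:`CrossSectionTable` invariants and
contain at least elastic + ionisation + excitation + vibrational channels with
plausible eV-scale thresholds.  An attachment column can be requested; it is
all-zero unless explicitly overridden (dissociative attachment ships
disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_NUMBER_DENSITY
from .xsec import Channel, ChannelKind, CrossSectionTable, EnergyLossModel

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic table."""

    seed: int = 0
    n_points: int = 40
    e_min: float = 0.01
    e_max: float = 2000.0
    n_ionisation: int = 1
    n_excitation: int = 1
    n_vibrational: int = 1
    include_attachment: bool = False
    attachment_sigma: float = 0.0
    magnitude: float = 0.05  # typical cross-section scale, nm²


def _smooth_positive(rng, grid, scale):
    """A smooth, strictly positive pseudo-random curve on the grid."""
    x = np.log(grid)
    a = rng.uniform(0.3, 1.0)
    b = rng.uniform(-0.5, 0.5)
    c = rng.uniform(0.5, 2.0)
    return scale * a * np.exp(b * np.sin(x / c)) / (1.0 + grid / grid[-1] * 3.0)


def generate_fixture(spec: FixtureSpec) -> CrossSectionTable:
    """Build a deterministic synthetic table from a spec (same seed → same
    table, bit for bit)."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    grid = np.geomspace(spec.e_min, spec.e_max, spec.n_points)
    channels: list[Channel] = []
    sigma: list[np.ndarray] = []

    channels.append(
        Channel("elastic", ChannelKind.ELASTIC, 0.0, EnergyLossModel.NONE)
    )
    sigma.append(_smooth_positive(rng, grid, spec.magnitude))

    for i in range(spec.n_vibrational):
        q = float(rng.uniform(0.1, 0.5))
        channels.append(
            Channel(
                f"vib{i}", ChannelKind.VIBRATIONAL, q, EnergyLossModel.FIXED_QUANTUM
            )
        )
        s = _smooth_positive(rng, grid, 0.1 * spec.magnitude)
        s[grid < q] = 0.0
        sigma.append(s)

    for i in range(spec.n_excitation):
        thr = float(rng.uniform(7.0, 12.0))
        channels.append(
            Channel(
                f"exc{i}",
                ChannelKind.EXCITATION_DISCRETE,
                thr,
                EnergyLossModel.FIXED_QUANTUM,
            )
        )
        s = _smooth_positive(rng, grid, 0.3 * spec.magnitude)
        s[grid < thr] = 0.0
        sigma.append(s)

    for i in range(spec.n_ionisation):
        b = float(rng.uniform(10.0, 18.0))
        channels.append(
            Channel(
                f"ion{i}",
                ChannelKind.IONISATION,
                b,
                EnergyLossModel.DIFFERENTIAL_TABLE,
                2.0,
            )
        )
        s = _smooth_positive(rng, grid, 0.5 * spec.magnitude)
        s[grid < b] = 0.0
        sigma.append(s)

    if spec.include_attachment:
        channels.append(
            Channel("dea", ChannelKind.ATTACHMENT, 6.5, EnergyLossModel.NONE)
        )
        s = np.full_like(grid, spec.attachment_sigma)
        s[grid < 6.5] = 0.0
        sigma.append(s)

    return CrossSectionTable(
        energy_grid=grid,
        channels=channels,
        sigma=np.vstack(sigma),
        number_density=WATER_NUMBER_DENSITY,
        phase="liquid",
        provenance=f"synthetic fixture (seed={spec.seed})",
    )
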