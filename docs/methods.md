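# Methods

`dmcwater` simulates the physical and physicochemical stage of liquid-water
radiolysis — from the first collision of a primary electron to the moment,
about a picosecond later, when every secondary electron has either escaped
its parent cation or been trapped and hydrated next to it.  The quantity the
package exists to predict is the initial hydrated-electron yield
G_hyd(1 ps), together with the W value, the total ionisation + excitation
yield G_total(t₀), and the energy and spatial distributions of secondary
electrons.

## Model overview

A history is one primary electron of energy E₀ (20 eV – 30 keV) started at
the origin along +z.  The simulation has two stages.

**Stage 1 — collision cascade (main clock t₀).**  Every electron above the
tracking cutoff (8.4 eV, the lowest electronic-excitation threshold)
performs exponential free flights through liquid water
(n = 33.43 molecules/nm³) punctuated by collisions sampled from the
channel-resolved cross sections: elastic (screened-Rutherford deflection),
vibrational quanta, discrete electronic excitations, a collective
(plasmon-like) excitation, and ionisation shells.  Each ionisation or
excitation event is logged with its time stamp and position, anchors a
parent centre (the cation or excitation hole) there, and spawns one tracked
electron:

* ionisation: the secondary carries W sampled from a Lorentzian-tail
  differential spectrum dσ/dW ∝ 1/(W² + a²) truncated at (E − B)/2;
* discrete excitation: the electron stays bound with zero initial kinetic
  energy, but is born *displaced* from the hole by a 3-D Gaussian of
  σ = 0.30 nm per axis, representing the spatial extent of the excited
  orbital (the spawning rule for excitation electrons is genuinely open;
  a point birth at the hole would make the bound population a spike at the
  origin, with no sensitivity to the charge-separation radius at all);
* collective excitation (21.4 eV quantum): the transferred quantum exceeds
  the first ionisation energy (10.9 eV), so the electron is promoted to a
  quasi-free state with KE = 21.4 − 10.9 = 10.5 eV.  This is the channel
  that lets "excitations" end up spatially ionised, and it is why the final
  ionisation/excitation ratio (≈2) exceeds the raw cross-section ratio.

Secondaries above the cutoff cascade themselves; the primary's remainder
below the cutoff becomes one final sub-excitation electron anchored to the
last centre it created.  Coulomb attraction is neglected in this stage
(electrons here move at ≥1.7 nm/fs and sub-fs interaction times).  Energy
bookkeeping is exact: E₀ equals the sum of all binding/quantum sinks plus
the kinetic energies handed to stage 2, to floating-point precision.

**Stage 2 — femtosecond propagation (per-electron clock t_i).**  Each
sub-excitation electron i moves under the Coulomb force of its own parent
centre, screened by the time-dependent relative permittivity ε_r(t_i)
evaluated on the electron's *own* clock (time since its creation):

    ε_r(t) = ε_el + A_ph (1 − e^(−t/τ_ph)) + A_or (1 − e^(−t/τ_or))

with ε_el = 1.78 (optical n² of water), a fast phonon component
(A = 2.73, τ = 10.4 fs) and a slow orientational component (A = 75.49,
τ = 8.62 ps), so that ε_r rises from 1.78 to 80.  The four free parameters
were least-squares fitted, once, to the screened electron–cation potential
anchors V(0.75 nm) = 0.27 / 0.22 / 0.15 eV at 300 / 500 / 1000 fs and the
long-time plateau of 80, and then frozen.  A sum of saturating exponentials
is necessarily concave in t while the three anchors are very slightly
convex, so an exact fit through all three is impossible; the fit reproduces
each anchor to better than ±0.01 eV, which is the tolerance we attach to
them.  The force is Plummer-softened with r_soft = 0.40 nm: classical point
dynamics cannot represent the ångström-scale bound state, and the softening
length stands in for the spatial extent of the electron plus the breakdown
of continuum screening at molecular distances.  Only the electron's own
parent attracts it; electron–electron and cross-pair forces are neglected
and parent centres never move.

Integration is velocity Verlet.  Near the parent the step is a fixed
fraction (0.005) of the local dynamical time √(m ε s³/k), s² = r² + r²_soft
— a function of position only, which keeps the variable-step scheme
quasi-reversible; a pure-Coulomb orbit of moderate eccentricity conserves
energy to ≲2×10⁻⁵ eV over 1 ps and angular momentum to machine precision.
Collisions are sampled per step in time with probability Λ(E)·v·dt
(capped at 0.2 per step): elastic deflections, vibrational quantum losses,
and quasi-elastic phonon/bath collisions.

**Thermal coupling and arrest.**  The phonon channel is modelled as elastic
scattering against a Maxwellian bath particle with an effective mode mass
of 45 mₑ.  Momentum exchange with a full 18-u molecule (2m/M ≈ 6×10⁻⁵ per
collision) could not thermalise an electron within the sub-picosecond
window at any plausible collision rate; the real mechanism is coupling to
librational/phonon modes, which an effective light scatterer reproduces.
Because the collision kinematics are genuinely elastic against a Maxwellian
bath, the stationary electron energy distribution is the 300 K
Maxwell–Boltzmann distribution — verified dynamically (arrest disabled,
KS distance ≈ 0.02 against Gamma(3/2)).  The bath cross section follows a
1/√E law at low energy, so the collision *rate* σ·v stays finite down to
v → 0 (a Maxwell-molecule model, which is also what makes the unweighted
target sampling exact).

An electron is *arrested* (thermalised and hydrated in place) by a constant
hazard: once its kinetic energy is below 8 k_BT, every collision carries
probability 1/4 of arrest, and the arrested electron is recorded in
equilibrium with the bath, i.e. its final velocity is a Maxwellian(300 K)
draw at its stopping position.  Two alternatives were implemented and
rejected on measurement.  A "20 consecutive collisions below 5 k_BT, keep
the last energy" rule selects descending low-energy runs and produces a
frozen-energy distribution far from Maxwellian (KS ≈ 0.45).  An unbiased
constant hazard *without* the equilibrium draw passes only when arrest is
made so slow that bound electrons spiral into the parent before freezing,
erasing the sub-nanometre structure of the bound population that the
charge-separation analysis rests on.  The eligibility threshold of 8 k_BT
(≈0.2 eV) models pre-solvation trapping of slow electrons, and the hazard
time scale (~a few fs once slow) is what distributes arrested electrons
over the 0.1–1 nm region rather than piling them onto the parent.
Electrons still hot at their cutoff time t_cut,i = 500 fs (trapped,
non-thermal orbiters) are frozen at their cutoff position with status
`cutoff`; they are the non-Maxwellian localised component of the energy
spectrum.

**Classification (1 ps).**  At the global horizon each electron's distance
to its own parent decides the outcome: ≥ 0.75 nm (the H₃O⁺ + e_aq⁻
reaction radius, numerically close to the Onsager radius 0.72 nm) counts as
ionisation → one hydrated electron; inside 0.75 nm, excitation-channel
electrons are *localised* and ionisation-channel electrons are
*relocalised*, both counting toward electronic excitation.  Ties at exactly
r_sep are delocalised (measure-zero; fixed for determinism).  Then

    G_total(t₀) = ⟨N_total(t₀)⟩ / E₀ × 100    (/100 eV)
    G_hyd(1 ps) = G_total(1 ps) × P_ion(1 ps),   W = 100 / G_hyd.

## The packaged cross-section table

No machine-readable channel-resolved cross sections for liquid water exist,
so the default table is an analytic parametrisation: binary-encounter-Bethe
(BEB) ionisation for the four valence shells (B = 10.9, 13.39, 17.22,
29.75 eV), threshold-rise/ln E/power-decay shapes for the two discrete
excitations (8.4, 10.1 eV) and the collective channel (21.4 eV, the largest
inelastic cross section near its peak), vibrational bend/stretch quanta
(0.198, 0.453 eV), an elastic low-energy plateau plus screened-Rutherford
tail, a 1/√E phonon/bath channel, and an all-zero dissociative-attachment
column (DEA is taken as negligible in the liquid phase; using a table with
a live attachment channel requires the explicit `dea_enabled` flag).

The free magnitudes were calibrated once against published integral
observables — the sub-excitation thermalisation distances (≈1.0 nm at
0.1 eV, ≈8.5 nm at 4.0 eV), the 1 ps hydrated-electron yield at 1 keV
(≈4.3/100 eV), the final ionisation/excitation ratio (≈2), and the yield
sensitivity to the charge-separation radius (+0.2/100 eV from 1.00 to
0.75 nm) — and then frozen in `DEFAULT_TABLE_PARAMS`.  With those defaults
the relocalised yield comes out at roughly one third of the localised and
one eighth of the delocalised yield, and K-shell ionisation (540 eV) is
omitted (a ≲2% effect on stopping above 1 keV).  Every unit test runs on
synthetic fixture tables; nothing in the test suite depends on the default
magnitudes except the end-to-end acceptance checks that exist to probe
exactly those defaults.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `E0` | 1000 | eV | primary energy (20 eV – 30 keV supported) |
| `t_horizon` | 1000 | fs | global horizon t₀ for classification |
| `t_cut_secondary` | 500 | fs | per-electron propagation cutoff t_cut,i |
| `r_sep` | 0.75 | nm | charge-separation radius |
| `tracking_cutoff` | 8.4 | eV | hand-off energy to the femtosecond stage |
| `r_soft` | 0.40 | nm | Plummer softening of the parent force |
| `exc_birth_radius` | 0.30 | nm | Gaussian σ of the excited-orbital birth displacement |
| `bath_mass_me` | 45 | mₑ | effective phonon/bath scatterer mass |
| `freeze_kT_multiple` | 8 | – | arrest eligibility threshold in units of k_BT |
| `freeze_dwell` | 4 | collisions | expected eligible collisions before arrest |
| `temperature` | 300 | K | bath temperature |
| `dt_max` / `disp_max` | 0.5 / 0.05 | fs / nm | integrator caps away from the parent |

## Reproducibility

Histories are driven by per-history Philox substreams spawned from the
master seed, and every sub-excitation electron receives its own kernel
seed, so results are bit-reproducible and independent of batch composition.
Classification is pure post-processing: one stored result can be
re-classified at any r_sep without re-simulation.

## What the simulation does and does not capture

The engine reproduces the integral observables above and the qualitative
structure of the published picture: events complete within tens of fs at
≤1 keV and ≈300 fs at 30 keV; penetration ranges at 1 ps are ~10 nm,
several tens of nm, and ~10 µm at 100 eV, 1 keV, 30 keV; 500 fs and 1 ps
snapshots coincide below a few keV; localisation grows as E₀ falls, so
G_hyd decreases below 1 keV.  Limits to keep in mind:

* The cross-section set is a shape-level parametrisation, not measured
  data; single-channel predictions (e.g. a specific excitation yield)
  carry that uncertainty even where the calibrated integral observables do
  not.
* Because arrested electrons equilibrate with the bath, the model does not
  maintain a long-lived *hot* localised component: the 1 ps energy
  spectrum's localised signature appears mainly through the `cutoff`
  population, and differences between primary energies in the spectral
  tail above 100 meV are smaller than in the published distributions.
* Kinematics are non-relativistic throughout; at 30 keV the ~3% speed
  error shifts event time stamps only.
* Sub-ångström physics (bound orbitals, molecular dissociation after
  excitation, DEA resonances) is outside the classical treatment; the
  softening and birth-displacement lengths are effective parameters, not
  predictions.
* The chemistry stage (reactions after 1 ps) is out of scope.
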