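# Methods

This note documents the physical models, the parameters that matter,
the numerical choices, and the known limits of the package. Everything
quantitative stated here is computed by the test suite or the
acceptance script; nothing is asserted beyond what the code reproduces.

## Crystal construction

The oxygen sublattice of hexagonal ice (ice Ih) is the
hexagonal-diamond (wurtzite-topology) network. We build it in the
orthorhombic representation — unit cell `(a, √3·a, c)` holding 8 water
molecules — so all box angles are 90° and replication is trivial. The
default lattice constants `a = 4.51825 Å`, `c = 7.3535 Å` reproduce the
768-molecule reference box `(36.146, 23.478, 29.414) Å` at replication
(8, 3, 4); the resulting mass density is 0.920 g/cm³ and the two
inequivalent nearest-neighbour O–O distances are 2.758 Å (along c) and
2.766 Å (off-axis), consistent with the canonical 2.75–2.76 Å value.

Protons are placed subject to the Bernal–Fowler ice rules: each O–O
contact within 3.0 Å is an edge of a 4-regular graph; each edge is
oriented donor→acceptor by a seeded random assignment followed by
path-reversal repair (walk from a surplus donor along outgoing edges,
reversing, until a deficit vertex absorbs the surplus; total imbalance
strictly decreases, so the repair terminates). For small cells a pair
can be hydrogen-bonded through two distinct periodic images, so the
neighbour graph is built over all 27 image shifts as a multigraph.
Hydrogens are placed in the plane of the two donated directions with
the rigid TIP3P geometry (r(O–H) = 0.9572 Å, ∠HOH = 104.52°). Net
dipole is *not* constrained; the proton realization is exposed as a
seed, and changing it never moves an oxygen.

## Collisional-radiative stand-in

The plasma stage is a deliberately compact screened-hydrogenic
rate-equation model, not a full NLTE code. States: O⁰…O⁸⁺ (ground
configurations, NIST ionization potentials) and H⁰/H⁺. Channels:

* **Photoionization** at the pulse photon energy with per-shell cross
  sections (`1.42e-22 cm²` per K electron, `3.8e-24 cm²` per L electron
  at 8 keV; totals match the ~3.0e-22 cm² photoelectric cross section
  of neutral O). K-shell events relax instantly by Auger decay
  (yield 0.992 while ≥ 2 L electrons remain), i.e. an effective double
  ionization; the fluorescence branch loses the K-hole energy as an
  escaping photon.
* **Impact ionization** with Lotz cross sections of the outermost
  occupied shell, Maxwellian-averaged over the electron bath. Acting on
  the valence shell only makes secondary ionization
  valence-preferential: the mean K-shell occupancy stays ≥ 1.8 while
  the mean O charge is ≤ 4 (a tested invariant).
* **Three-body recombination**, the detailed-balance partner of the
  impact channel, with coefficients fixed by the Saha relation
  (statistical-weight ratios taken as 1). Without it the electron
  temperature pins near the valence ionization potential while `n_e`
  grows without bound and the Debye length never settles; with it the
  electron subsystem approaches a quasi-Saha state and `λ_D(t)`
  plateaus, which is the behaviour the melting model needs.

Energy bookkeeping is explicit: absorbed photon energy = ionization
spending + thermal electron energy + ion heating + fluorescence losses,
and the inequality `absorbed ≥ spent` is a tested invariant. The
electron–ion coupling constant (0.00143 fs⁻¹) is the stand-in's single
calibration knob, fixed once so that the 10¹⁹ W/cm², 8 keV, 50 fs run
ends at an ion temperature of ≈ 4.9 eV; it is exposed in the API.
Integration is explicit with adaptive substeps (`dt ≤ 0.05/max rate`)
and exact exponential depletion per state, so pure photoabsorption
reproduces the Poisson survival `exp(−σF)` closed form.

With these choices the model gives, at the end of a 50 fs pulse: mean O
charge ≈ 4.4 and λ_D ≈ 1.3 Å at 10¹⁹ W/cm²; mean O charge ≈ 1.0 and
λ_D ≈ 1.1 Å at 10¹⁸ W/cm². The Debye length settles (|dλ/dt|/λ <
0.01/fs for the rest of the pulse) at ≈ 4.5 fs for 10¹⁹ and ≈ 14.5 fs
for 10¹⁸ W/cm² — the early-time electron-temperature transient of the
stand-in is slower at the lowest intensity than a full NLTE treatment
would give, which is a known fidelity limit of this stage.

## Charge assignment

Per-atom integer charges are drawn from the element's population
simplex by a fixed per-atom uniform variate pushed through the inverse
CDF. Because ionization only moves population upward, the CDF decreases
pointwise in time and each atom's charge is non-decreasing along a
trajectory — time-correlated sampling that encodes the physical
irreversibility of ionization, deterministic per seed.

## Molecular dynamics

Velocity-Verlet NVE in Å/fs/amu/kJ·mol⁻¹ units, minimum-image periodic
boundaries, no thermostat (the plasma stage's ion temperature is a
diagnostic, not a velocity constraint — whether the original
simulations rescaled velocities toward it is not implemented here).
Interactions:

* screened Coulomb `f·q_i q_j e^{−r/λ_D}/(4πε0 r)` with `f = 1` by
  default (exposed in the API), λ_D refreshed from the plasma history
  every step; the ∞ sentinel recovers bare Coulomb ("shielding off"
  comparison runs);
* screened Lennard-Jones: the whole 12-6 term multiplied by
  `e^{−r/λ_D}` (the simplest reading; per-term screening would differ
  only at sub-σ distances where repulsion dominates anyway). CHARMM
  TIP3P parameters with the hydrogen LJ site; per charge state the LJ
  radius is scaled by a shipped monotone ionic-radius table
  (1.0 … 0.22 for O⁰…O⁷⁺, 0 beyond) with ε unchanged, and an atom with
  no bound electrons loses its LJ site entirely. The table is a
  documented approximation standing in for unpublished DFT radii;
* Morse O–H bonds with D_e = 463 kJ/mol (≈ 4.8 eV), r₀ = 0.9572 Å and
  β = √(k/2D_e) = 1.426 Å⁻¹ from the TIP3P harmonic force constant
  k = 450 kcal/mol/Å². Angles and dihedrals are omitted: in the plasma
  regime many-body bonded terms have no meaning. Nonbonded pairs within
  one molecule are excluded (standard exclusion; intermolecular pairs
  always included).

The nonbonded cutoff is fixed once per run at the radius where the
screened unit-charge Coulomb force falls to 10⁻⁶ of its value at the
2.75 Å nearest-neighbour distance, computed from the time-averaged λ_D
of the whole run and clamped to half the shortest box edge. Timestep
guard: any single-step displacement above 0.5 Å aborts with a
diagnostic. Determinism: identical seeds give bit-identical
trajectories (tested).

Initial velocities default to zero; melt runs draw Maxwell–Boltzmann
velocities at 265 K (ice near melting) with net momentum removed.

## Observables

RDFs are minimum-image pair histograms normalized per frame by the
ideal-gas shell count. Partial structure factors are the radial Fourier
sine transform of `g − 1` with the total atomic number density and a
Lorch window against the 10 Å truncation:

    S_αβ(q) = 4π ρ ∫ r² (g_αβ − 1) sin(πr/r_max)/(πr/r_max) · sinc(qr) dr

so the per-atom intermolecular intensity is exactly
`Σ (2−δ) c_α c_β f_α f_β S_αβ` (verified against a direct Debye-sum
oracle on a 50-atom cluster, with the finite-N `(N−1)` pair-count
correction). Two documented artifacts of the truncated transform: (i)
below `q ≈ 1.2 Å⁻¹` a crystal's empty diffraction gap cannot be
represented and `I_total` oscillates slightly negative there, so the
positivity invariant is checked above that bound; (ii) the three
reflections near 4.6–5.0 Å⁻¹ (at 4.56, 4.82 and 4.96 Å⁻¹ for this
lattice) are not resolved at 10 Å truncation, and the merged third
intensity maximum lands at ≈ 4.87 Å⁻¹ rather than on the
multiplicity-dominant 4.96 ring.

Neutral form factors use the International-Tables (Cromer–Mann)
parameterization via gemmi; ionized configurations use a per-shell
screened-hydrogenic model (`N_shell/(1+(q n² a₀ / 2 Z_eff)²)²`, Slater
Z_eff) normalized to the bound-electron count, so `f(0)` equals the
number of bound electrons and f decreases pointwise with ionization at
low q. Free (plasma) electrons are assumed uniform and contribute no
coherent signal at the q of interest; Compton scattering is out of
scope.

Intensity half-lives are the first linear-interpolated crossing of
`I(q*, t) = I(q*, 0)/2`; the pipeline averages them over several
charge-assignment seeds with standard deviations.

## Diffraction

Oriented single-crystal patterns are computed by exact direct summation
`|Σ_i f_i(q) e^{i q·r_i}|²` over the Ewald-mapped per-pixel scattering
vectors (sphere curvature retained; at 8 keV the 200 μm/70 mm, 1024²
detector reaches q = 3.78 Å⁻¹ at the edge and 4.31 Å⁻¹ in the corners,
so the 1.66 and 2.98 rings are covered and the 4.95 ring is not). Each
atom carries the form factor of its instantaneous charge state. Solid
angle is corrected per pixel; polarization is off by default
(toggleable). Angular correlations resample the image to polar
coordinates (0.01 Å⁻¹ × 1° default) and compute
`⟨I(q,φ)I(q,φ+Δ)⟩_φ` by circular FFT with mask-aware normalization;
rings with no valid pixels are flagged, never silently zeroed.

## PADF

Oxygen-only ±1-supercell scheme: all interatomic vectors up to the
10 Å probe distance are taken from central-cell atoms; pairs of vectors
are histogrammed over (r, r′, Θ) in 0.1 Å × 0.1 Å × 2° bins.
Three-body counts are pairs sharing their apex atom (the angle is then
the physical bond angle at that atom — other single-share orientations
are the same three-atom arrangements with supplementary angles and are
skipped to avoid double counting); pairs sharing no atom form the
separately stored four-body channel. Θ bins are *centred* on
0°, 2°, …, 180° so the high-symmetry lattice angles (60°, 90°, 109.47°,
120°, 180°) fall mid-bin: otherwise float jitter flips identical
per-atom contributions across bin edges and defeats the convergence
control. Accumulation proceeds in seeded random atom order and stops
when the cosine dissimilarity of successive normalized volumes drops
below 10⁻¹¹ — in a perfect crystal every atom contributes an
essentially identical pattern and the loop stops after a handful of
atoms, while disordered frames run to exhaustion.

For the ideal crystal the r = r′ slice shows the nearest-neighbour
tetrahedral peak at (2.75 Å, 110° bin), the basal-plane hexagonal 120°
and square 90° features in the 4–6 Å band (with the 60° triangular
feature alongside), and the four-body channel peaks at r ≈ 5.25 Å —
the c-axis stacking arrangement.

Peak tracking works on the r = r′ slice: per time step, the local
background (median of the search box) is subtracted, the integration
region is re-derived as bins above `tolerance × (local max − bg)`
(default tolerance 0.5, exposed), the integral is normalized to its
t = 0 value, and the box recentres on the current maximum. Background
subtraction is what makes the four-body track meaningful: the diffuse
uncorrelated four-body background survives the melt and would otherwise
mask the decay of the coherent feature. Tracks whose corrected maximum
falls below a noise floor (0.5% of the initial) terminate rather than
extrapolate.

In the 10¹⁸ W/cm² melt (192-molecule cell, 50 fs) the tracked decays
order as the anisotropic-melting picture predicts: the
nearest-neighbour r₁ decays fastest, the in-plane hexagonal r₂ and the
square r₃ persist longest, and the four-body stacking r₄ decays faster
than the three-body features (r₂ ≈ 0.13 vs r₄ ≈ 0.05 of their initial
intensity at 40 fs).

## Problem sizes

The reference crystal (768 molecules) is used for all static
observables. Dynamic (melt) checks use a 192-molecule cell at
dt = 0.5 fs for 100 steps and a 10 Å PADF probe — large enough that
the box half-edge exceeds the RDF range used (7.5 Å) and the supercell
fully covers the PADF probe, small enough for interactive runs. The
full default pipeline config runs the 768-molecule cell with five
charge seeds.

## Known limitations

* The plasma stage is a calibrated stand-in: no radiative transfer, no
  spectral lines, no spatial beam profile, Maxwellian electrons only.
  Its single coupling knob is calibrated at 10¹⁹ W/cm²; behaviour at
  other intensities is prediction, not calibration. At 10¹⁸ W/cm² its
  Debye length settles at ≈ 14.5 fs, later than the ≤ 10 fs a full
  NLTE treatment reports.
* Ion form factors are free-ion screened-hydrogenic models; solid-state
  (bonded, compressed) ion densities would lose less amplitude at low
  q. Combined with the rapid disordering of the proton subsystem, this
  makes the low-q intensity decay early in our melt runs, so the
  half-life of the 1.66 Å⁻¹ peak comes out *shorter* than that of the
  4.95 Å⁻¹ peak — the opposite ordering of a hotter melt in which
  Debye-Waller decay at high q dominates. The real-space (PADF)
  orderings, which carry the anisotropic-melting result, are
  insensitive to form factors and are reproduced.
* Screening applies the same λ_D to all pair interactions; ion-ion
  correlations beyond linear Debye screening are not modelled.
* The intensity pipeline truncates the RDF at 10 Å; q features below
  ≈ 1.2 Å⁻¹ and reflection splittings finer than ≈ π/10 Å⁻¹ are not
  resolved (see Observables).
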