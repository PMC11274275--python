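# plasmice

Hybrid plasma/molecular-dynamics simulation of ultrafast, nonthermal
melting of hexagonal ice under intense femtosecond X-ray pulses, with
the full observable stack an XFEL experiment would see: radial
distribution functions, partial structure factors, damage-weighted
scattered intensity, 2D single-crystal diffraction with angular
correlations, and pair-angle distribution functions (PADF).

**Who it is for.** Researchers in serial femtosecond crystallography and
warm-dense-matter physics who want a desk-scale, fully scriptable model
of how a hydrogen-bonded crystal transitions into a transient
*crystalline plasma* — ions still on lattice sites, immersed in a dense
free-electron gas — and how that transition shows up in scattering.

## The model

The simulation is a two-step hybrid:

1. **Collisional-radiative stage** (`plasmice.ionization`). Rate
   equations advance charge-state populations `c_{α,j}(t)` of O and H
   under a flat-top pulse: K-shell photoionization with instantaneous
   Auger branching, Lotz electron-impact (secondary) ionization of the
   valence shell, and its detailed-balance partner, three-body
   recombination. Absorbed energy feeds a thermal electron bath
   (two-temperature model); ions heat through a fixed electron–ion
   coupling. The stage outputs `n_e(t)`, `T_e(t)`, `T_i(t)` and the
   Debye screening length

       λ_D(t) = sqrt(ε0 k_B T_e / (n_e e²)).

2. **Molecular-dynamics stage** (`plasmice.md`). Velocity-Verlet NVE
   dynamics with a force field updated every step from the plasma
   history: Yukawa-screened Coulomb `q_i q_j e^{-r/λ_D}/(4π ε0 r)`
   between integer ionic charges (sampled per atom, monotone in time),
   a Debye-screened 12-6 Lennard-Jones term whose radii shrink with
   charge state, and a Morse O–H bond (D_e = 463 kJ/mol) that lets
   bonds break. No thermostat: heating is emergent Coulomb repulsion.

Observables are built on top: `g_{αβ}(r,t)` → Lorch-windowed radial
Fourier transform → `S_{αβ}(q,t)` → intensity
`I = Σ c_α f_α² + Σ (2−δ_{αβ}) c_α c_β f_α f_β S_{αβ}` with
population-weighted form factors `f_α(q,t) = Σ_j w_{α,j}(t) f_{α,j}(q)`;
a virtual 1024² pixel detector (200 μm pixels at 70 mm, 8 keV) for
oriented single-crystal patterns; and oxygen-only PADF volumes over
(r, r′, Θ) with convergence-controlled accumulation, r = r′ slices and
time-resolved peak tracking.

## Worked example

```python
from plasmice import crystal, ionization, md, pipeline
from plasmice.padf import compute_padf, slice_requal
import numpy as np

# 1. a proton-disordered ice-Ih cell (the 768-molecule reference box)
ice = crystal.build_ice_ih((8, 3, 4), proton_seed=1)
print(ice.n_molecules, ice.n_atoms)      # 768 2304

# 2. plasma history for a 50 fs, 8 keV, 1e19 W/cm2 flat-top pulse
pulse = ionization.PulseSpec(8000.0, 1e19, 50.0)
hist = ionization.evolve_plasma(pulse, timestep=0.5)
print(round(float(hist.mean_charge("O")[-1]), 2))   # 4.41  (mean O charge)
print(round(float(hist.T_i[-1]), 2))                # 4.91  (ion temp, eV)
print(round(float(hist.lambda_d[-1]), 2))           # 1.34  (Debye length, Å)

# 3. screened melt of a smaller cell at 1e18 W/cm2, then the PADF
cell = crystal.build_ice_ih((4, 2, 3), proton_seed=11)
h18 = ionization.evolve_plasma(ionization.PulseSpec(8000.0, 1e18, 50.0),
                               timestep=0.5)
traj = md.integrate(cell, h18, dt=0.5, n_steps=100, seed=7, stride=10,
                    temperature_k=265.0)
io = np.flatnonzero(traj.species == "O")
vol = compute_padf(traj.frames[0].positions[io], traj.box, seed=0)
sl = slice_requal(vol)
r, th = vol.r_centres, vol.theta_centres
band = (r > 2.3) & (r < 3.2)
ir, it = np.unravel_index(np.argmax(sl[band]), sl[band].shape)
print(r[band][ir], th[it])               # 2.75 110.0  (tetrahedral contact)
```

The nearest-neighbour PADF peak at (2.75 Å, ~109°) is the tetrahedral
hydrogen-bond geometry of ice; during a melt run its track decays
faster than the basal-plane hexagonal feature at 120° — the melting is
anisotropic.

The same steps are available from a shell:

```bash
plasmice build --na 8 --nb 3 --nc 4 --seed 1 --out ice.pdb
plasmice ionize --intensity 1e18 --duration 50 --out plasma.csv
plasmice simulate --structure ice.pdb --plasma plasma.csv --steps 100 --out traj.xyz
plasmice analyze rdf --traj traj.xyz --pairs O-O --out rdf.csv
plasmice run --out runs/demo        # full two-step pipeline, seed-averaged
```

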