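"""Velocity-Verlet NVE dynamics with a dynamically updated force field.

Before every step the per-atom integer charges are refreshed from the
plasma history (seeded inverse-CDF sampling, monotone per atom), the
Debye length is refreshed, and the LJ radii follow the charge states.
Heating is emergent from the screened Coulomb repulsion between ions:
no thermostat is applied, and the plasma module's ion temperature is a
diagnostic, not a velocity constraint.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .constants import ACC_UNIT, KIN_UNIT, MASS_AMU
from .crystal import Structure
from .forcefield import ForceField, compute_forces, cutoff_radius
from .ionization import PlasmaHistory, assign_charges

__all__ = ["TrajectoryFrame", "Trajectory", "integrate", "coupling_parameter",
           "write_trajectory_xyz", "write_energies_csv"]

MAX_STEP_DISPLACEMENT = 0.5  # Å; larger one-step moves abort the run


@dataclasses.dataclass
class TrajectoryFrame:
    time_fs: float
    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    e_potential: float
    e_kinetic: float
    e_coulomb: float
    box: np.ndarray


@dataclasses.dataclass
class Trajectory:
    species: np.ndarray
    molecule: np.ndarray
    bonds: np.ndarray
    box: np.ndarray
    frames: list

    @property
    def times(self):
        return np.array([f.time_fs for f in self.frames])

    def positions_at(self, k: int) -> np.ndarray:
        return self.frames[k].positions

    def frame_nearest(self, t_fs: float) -> TrajectoryFrame:
        times = self.times
        return self.frames[int(np.argmin(np.abs(times - t_fs)))]


def _masses(species):
    return np.array([MASS_AMU[str(s)] for s in species])


def integrate(
    structure: Structure,
    plasma: PlasmaHistory | None,
    dt: float = 0.1,
    n_steps: int = 100,
    seed: int = 0,
    stride: int = 10,
    f_const: float = 1.0,
    screening: bool = True,
    fixed_charges: np.ndarray | None = None,
    fixed_lambda: float = np.inf,
    initial_velocities: np.ndarray | None = None,
    temperature_k: float = 0.0,
) -> Trajectory:
    """NVE velocity-Verlet trajectory with time-dependent ionization.

    Parameters
    ----------
    structure : initial configuration (defines species/topology/box).
    plasma : PlasmaHistory or None
        Source of charge-state populations and λ_D(t).  ``None`` runs
        neutral dynamics with ``fixed_charges``/``fixed_lambda``.
    dt : fs, must be ≤ 0.5.
    stride : emit a frame every this many steps (frame 0 always emitted).
    screening : if False, λ_D = ∞ (bare interactions) regardless of the
        plasma history — the "shielding off" comparison run.
    seed : controls the charge-assignment realization.

    The nonbonded cutoff is fixed once from the time-averaged Debye
    length: the radius where the screened unit-charge Coulomb force falls
    to 1e-6 of its nearest-neighbour-distance value, clamped to half the
    shortest box edge.
    """
    if dt > 0.5 or dt <= 0:
        raise ValueError("dt must be in (0, 0.5] fs")
    species = structure.species
    n = structure.n_atoms
    masses = _masses(species)[:, None]

    # cutoff from the time-averaged screening length over the whole run
    half_box = float(structure.box.min()) / 2.0
    if plasma is not None and screening:
        lam_series = [
            plasma.lambda_d_at(k * dt) for k in range(n_steps + 1)
        ]
        finite = [x for x in lam_series if np.isfinite(x)]
        lam_avg = float(np.mean(finite)) if finite else np.inf
        r_c = min(cutoff_radius(lam_avg, f_const), half_box)
    else:
        r_c = half_box if screening or fixed_lambda is np.inf else min(
            cutoff_radius(fixed_lambda, f_const), half_box
        )
    ff = ForceField(f_const=f_const, r_c=r_c)

    pos = structure.positions.copy()
    if initial_velocities is not None:
        vel = np.array(initial_velocities, dtype=float)
    elif temperature_k > 0:
        # Maxwell-Boltzmann draw, seeded; net momentum removed
        from .constants import BOLTZMANN_KJ_MOL_K

        rng = np.random.default_rng(seed + 1)
        sigma = np.sqrt(BOLTZMANN_KJ_MOL_K * temperature_k / (masses * KIN_UNIT))
        vel = rng.normal(0.0, 1.0, (n, 3)) * sigma
        vel -= np.sum(masses * vel, axis=0) / masses.sum()
    else:
        vel = np.zeros((n, 3))

    def refresh(t_fs):
        if plasma is not None:
            pops = {
                el: plasma.populations_at(el, t_fs) for el in plasma.populations
            }
            charges = assign_charges(pops, species, seed)
            lam = plasma.lambda_d_at(t_fs) if screening else np.inf
        else:
            charges = (
                np.zeros(n, dtype=int) if fixed_charges is None
                else np.asarray(fixed_charges, dtype=int)
            )
            lam = fixed_lambda if screening else np.inf
        ff.lambda_d = lam
        return charges

    charges = refresh(0.0)
    forces, energies = compute_forces(
        pos, species, charges, structure.molecule, structure.bonds,
        structure.box, ff,
    )

    frames = []

    def emit(k, charges, forces, energies):
        ekin = 0.5 * KIN_UNIT * float(np.sum(masses * vel**2))
        frames.append(
            TrajectoryFrame(
                time_fs=k * dt,
                positions=pos.copy(),
                velocities=vel.copy(),
                charges=charges.copy(),
                e_potential=energies["potential"],
                e_kinetic=ekin,
                e_coulomb=energies["coulomb"],
                box=structure.box.copy(),
            )
        )

    emit(0, charges, forces, energies)

    for k in range(1, n_steps + 1):
        acc = ACC_UNIT * forces / masses
        dr = vel * dt + 0.5 * acc * dt**2
        max_dr = float(np.linalg.norm(dr, axis=1).max())
        if max_dr > MAX_STEP_DISPLACEMENT:
            raise RuntimeError(
                f"step {k}: displacement {max_dr:.2f} Å exceeds "
                f"{MAX_STEP_DISPLACEMENT} Å — reduce dt"
            )
        pos += dr
        charges = refresh(k * dt)
        new_forces, energies = compute_forces(
            pos, species, charges, structure.molecule, structure.bonds,
            structure.box, ff,
        )
        vel += 0.5 * (acc + ACC_UNIT * new_forces / masses) * dt
        forces = new_forces
        if k % stride == 0 or k == n_steps:
            emit(k, charges, forces, energies)

    return Trajectory(
        species=species.copy(),
        molecule=structure.molecule.copy(),
        bonds=structure.bonds.copy(),
        box=structure.box.copy(),
        frames=frames,
    )


def coupling_parameter(trajectory: Trajectory):
    """Plasma coupling parameter Γ(t) = ⟨E_potential⟩ / ⟨E_kinetic⟩.

    The potential entering Γ is the magnitude of the Coulombic (screened
    electrostatic) energy; frames with zero kinetic energy yield NaN.
    Returns ``(times, gamma, t_cross)`` where ``t_cross`` is the linearly
    interpolated first crossing of Γ = 1 (NaN if never crossed).
    """
    times = trajectory.times
    gamma = np.empty(len(times))
    for k, fr in enumerate(trajectory.frames):
        gamma[k] = (
            abs(fr.e_coulomb) / fr.e_kinetic if fr.e_kinetic > 0 else np.nan
        )
    t_cross = np.nan
    finite = np.isfinite(gamma)
    if finite.any() and np.any(gamma[finite] >= 1.0):
        idx = np.flatnonzero(finite & (gamma >= 1.0))[0]
        if idx == 0 or not finite[idx - 1]:
            t_cross = float(times[idx])
        else:
            g0, g1 = gamma[idx - 1], gamma[idx]
            t0, t1 = times[idx - 1], times[idx]
            t_cross = float(t0 + (1.0 - g0) / (g1 - g0) * (t1 - t0))
    return times, gamma, t_cross


def write_trajectory_xyz(trajectory: Trajectory, path) -> None:
    """Multi-frame extended XYZ with a per-atom integer charge column."""
    box = trajectory.box
    lattice = f"{box[0]:.6f} 0.0 0.0 0.0 {box[1]:.6f} 0.0 0.0 0.0 {box[2]:.6f}"
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(f"{len(trajectory.species)}\n")
            fh.write(
                f'Lattice="{lattice}" '
                f"Properties=species:S:1:pos:R:3:charge:I:1 "
                f"Time={fr.time_fs:.4f}\n"
            )
            for sp, p, q in zip(trajectory.species, fr.positions, fr.charges):
                fh.write(f"{sp} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(q)}\n")


def write_energies_csv(trajectory: Trajectory, path) -> None:
    rows = [
        {
            "time_fs": fr.time_fs,
            "e_potential_kj_mol": fr.e_potential,
            "e_kinetic_kj_mol": fr.e_kinetic,
            "e_coulomb_kj_mol": fr.e_coulomb,
        }
        for fr in trajectory.frames
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
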