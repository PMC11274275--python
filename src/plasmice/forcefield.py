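"""Debye-screened force field for ionizing water.

Interactions:

* screened (Yukawa) Coulomb between integer ionic charges,
  E = f q_i q_j e^{-r/λ_D} / (4π ε0 r),
* Lennard-Jones 12-6 multiplied by the same e^{-r/λ_D} screening factor
  (the dispersion/repulsion also being electromagnetic in origin),
* a Morse potential on covalent O-H bonds (finite dissociation energy,
  since the pulse breaks bonds); angles and dihedrals are omitted — in
  the plasma regime many-body bonded terms are not meaningful.

LJ parameters derive from the CHARMM-variant TIP3P water model (the
hydrogen carries a small LJ site).  Ionized atoms shrink: per charge
state the LJ radius is scaled by a tabulated ionic/covalent radius
ratio with the well depth unchanged, and an atom stripped of all
electrons loses its LJ interaction entirely (no electron cloud, no
dispersion).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import KE_KJ_A

__all__ = [
    "ForceField",
    "screened_coulomb",
    "screened_lj",
    "morse",
    "lj_scaling_for_charge",
    "compute_forces",
    "MORSE_DE",
    "MORSE_BETA",
    "MORSE_R0",
    "cutoff_radius",
]

KCAL = 4.184  # kJ/mol

# CHARMM TIP3P LJ parameters: (epsilon kJ/mol, Rmin/2 Å)
_LJ_ATOM = {
    "O": (0.1521 * KCAL, 1.7682),
    "H": (0.0460 * KCAL, 0.2245),
}

# Ionic-radius contraction per charge state, as a fraction of the neutral
# LJ radius.  Monotone-decreasing approximation to DFT ionic radii:
# isoelectronic contraction ~1/Z_eff per removed valence electron, with
# the He-like and H-like oxygen core much smaller, and zero radius (no
# LJ site) once no bound electrons remain.
_RADIUS_RATIO = {
    "O": np.array([1.0, 0.90, 0.80, 0.70, 0.61, 0.52, 0.30, 0.22, 0.0]),
    "H": np.array([1.0, 0.0]),
}

# Morse O-H bond: D_e printed for water dissociation (~4.8 eV); beta from
# the TIP3P harmonic O-H force constant k = 450 kcal/mol/Å^2 via k = 2 D_e β².
MORSE_DE = 463.0                      # kJ/mol
_K_OH = 450.0 * KCAL                  # kJ/mol/Å^2
MORSE_BETA = float(np.sqrt(_K_OH / (2.0 * MORSE_DE)))   # ≈ 1.426 Å^-1
MORSE_R0 = 0.9572                     # Å


def screened_coulomb(r, q_i, q_j, lambda_d=np.inf, f: float = 1.0):
    """Yukawa-screened Coulomb energy (kJ/mol) and radial force (kJ/mol/Å).

    The force is the negative radial gradient; positive values push the
    pair apart.  ``lambda_d = inf`` recovers the bare Coulomb interaction.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("screened_coulomb: r must be positive")
    pref = f * KE_KJ_A * q_i * q_j
    if np.isinf(lambda_d):
        screen = 1.0
        energy = pref / r
        force = pref / r**2
    else:
        screen = np.exp(-r / lambda_d)
        energy = pref * screen / r
        force = pref * screen * (1.0 / r**2 + 1.0 / (r * lambda_d))
    return energy, force


def screened_lj(r, c12, c6, lambda_d=np.inf):
    """Screened Lennard-Jones energy (kJ/mol) and radial force (kJ/mol/Å).

    E(r) = (c12 / r^12 - c6 / r^6) · exp(-r/λ_D); the screening factor
    multiplies the whole 12-6 term.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("screened_lj: r must be positive")
    lj = c12 / r**12 - c6 / r**6
    dlj = -12.0 * c12 / r**13 + 6.0 * c6 / r**7
    if np.isinf(lambda_d):
        return lj, -dlj
    screen = np.exp(-r / lambda_d)
    energy = lj * screen
    force = -(dlj * screen - lj * screen / lambda_d)
    return energy, force


def morse(r, d_e=MORSE_DE, beta=MORSE_BETA, r0=MORSE_R0):
    """Morse bond energy (kJ/mol, zero at dissociation) and radial force."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("morse: r must be positive")
    ex = np.exp(-beta * (r - r0))
    energy = d_e * (1.0 - ex) ** 2 - d_e
    force = -2.0 * d_e * beta * (1.0 - ex) * ex
    return energy, force


def _atom_lj(species: str, charge: int):
    """(epsilon, Rmin/2) of one atom in the given charge state."""
    if species not in _LJ_ATOM:
        raise KeyError(f"no LJ parameters for species {species!r}")
    ratios = _RADIUS_RATIO[species]
    if not 0 <= charge < len(ratios):
        raise ValueError(f"charge state {charge} out of range for {species}")
    eps, half_rmin = _LJ_ATOM[species]
    ratio = ratios[charge]
    if ratio == 0.0:
        return 0.0, 0.0
    return eps, half_rmin * ratio


def _combine_lj(eps_i, h_i, eps_j, h_j):
    """CHARMM combination: Rmin arithmetic, epsilon geometric -> (c12, c6)."""
    eps = np.sqrt(eps_i * eps_j)
    rmin = h_i + h_j
    c12 = eps * rmin**12
    c6 = 2.0 * eps * rmin**6
    return c12, c6


def lj_scaling_for_charge(species: str, charge: int):
    """Homonuclear-pair LJ coefficients (c12, c6) for a given charge state.

    Charge 0 returns the unmodified CHARMM TIP3P pair coefficients; higher
    charge states shrink monotonically, and a fully stripped ion has
    c12 = c6 = 0.
    """
    eps, h = _atom_lj(species, charge)
    return _combine_lj(eps, h, eps, h)


def cutoff_radius(lambda_d: float, f: float = 1.0,
                  rel: float = 1e-6, r_ref: float = 2.75) -> float:
    """Nonbonded cutoff: radius where the screened unit-charge Coulomb force
    drops below ``rel`` times its value at the nearest-neighbour distance.

    For infinite λ_D the bare Coulomb force never reaches the threshold
    within any finite radius; ``inf`` is returned and the caller clamps to
    the half-box.
    """
    if np.isinf(lambda_d):
        return np.inf
    _, f_ref = screened_coulomb(r_ref, 1, 1, lambda_d, f)
    target = rel * f_ref
    r = r_ref
    while r < 1e4:
        _, fr = screened_coulomb(r, 1, 1, lambda_d, f)
        if fr < target:
            break
        r *= 1.05
    from scipy.optimize import brentq

    lo = r / 1.05
    return float(
        brentq(lambda x: screened_coulomb(x, 1, 1, lambda_d, f)[1] - target, lo, r)
    )


@dataclasses.dataclass
class ForceField:
    """Current force-field state for one MD step.

    ``lambda_d`` and per-atom charges are refreshed from the plasma history
    as the trajectory advances.
    """

    f_const: float = 1.0        # Eq-1 prefactor constant
    lambda_d: float = np.inf    # Å
    r_c: float = 10.0           # Å nonbonded cutoff
    morse_de: float = MORSE_DE
    morse_beta: float = MORSE_BETA
    morse_r0: float = MORSE_R0

    def atom_lj_params(self, species: np.ndarray, charges: np.ndarray):
        eps = np.empty(len(species))
        half = np.empty(len(species))
        for k, (sp, q) in enumerate(zip(species, charges)):
            eps[k], half[k] = _atom_lj(str(sp), int(q))
        return eps, half


def compute_forces(positions, species, charges, molecule, bonds, box,
                   ff: ForceField):
    """Pairwise forces and potential energy of one configuration.

    Minimum-image screened Coulomb + screened LJ over all intermolecular
    pairs within the cutoff, Morse on the covalent bond list.  Nonbonded
    interactions within one molecule are excluded.  Returns
    ``(forces (N,3), energies dict)`` with keys ``coulomb``, ``lj``,
    ``morse``, ``potential``.
    """
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(positions)
    if ff.r_c > box.min() / 2.0 + 1e-9:
        raise ValueError(
            f"cutoff {ff.r_c:.2f} Å exceeds half the shortest box edge "
            f"({box.min() / 2:.2f} Å): minimum-image violation"
        )
    forces = np.zeros((n, 3))
    energies = {"coulomb": 0.0, "lj": 0.0, "morse": 0.0}

    d = positions[None, :, :] - positions[:, None, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)

    iu, ju = np.triu_indices(n, k=1)
    mask = (r[iu, ju] < ff.r_c) & (molecule[iu] != molecule[ju])
    pi, pj = iu[mask], ju[mask]
    rij = r[pi, pj]
    uij = d[pi, pj] / rij[:, None]

    charges = np.asarray(charges)
    qq = charges[pi] * charges[pj]
    has_q = qq != 0
    if has_q.any():
        e, fmag = screened_coulomb(rij[has_q], 1, 1, ff.lambda_d, ff.f_const)
        e = e * qq[has_q]
        fmag = fmag * qq[has_q]
        energies["coulomb"] = float(np.sum(e))
        fv = fmag[:, None] * uij[has_q]
        np.add.at(forces, pj[has_q], fv)
        np.add.at(forces, pi[has_q], -fv)

    eps, half = ff.atom_lj_params(species, charges)
    eps_ij = np.sqrt(eps[pi] * eps[pj])
    has_lj = eps_ij > 0
    if has_lj.any():
        rmin = half[pi[has_lj]] + half[pj[has_lj]]
        c12 = eps_ij[has_lj] * rmin**12
        c6 = 2.0 * eps_ij[has_lj] * rmin**6
        e, fmag = screened_lj(rij[has_lj], c12, c6, ff.lambda_d)
        energies["lj"] = float(np.sum(e))
        fv = fmag[:, None] * uij[has_lj]
        np.add.at(forces, pj[has_lj], fv)
        np.add.at(forces, pi[has_lj], -fv)

    if len(bonds):
        bi, bj = bonds[:, 0], bonds[:, 1]
        db = positions[bj] - positions[bi]
        db -= box * np.round(db / box)
        rb = np.linalg.norm(db, axis=1)
        e, fmag = morse(rb, ff.morse_de, ff.morse_beta, ff.morse_r0)
        energies["morse"] = float(np.sum(e))
        ub = db / rb[:, None]
        fv = fmag[:, None] * ub
        np.add.at(forces, bj, fv)
        np.add.at(forces, bi, -fv)

    energies["potential"] = sum(energies.values())
    return forces, energies
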