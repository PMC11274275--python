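"""Real- and reciprocal-space 1D observables.

Pipeline: time-dependent radial distribution functions g_αβ(r, t) →
partial structure factors S_αβ(q, t) by radial Fourier transform of
g − 1 (Lorch-windowed against the 10 Å truncation) → damage-weighted
scattered intensity

    I(q, t) = Σ_α c_α f_α²(q, t)
            + Σ_{α≤β} (2 − δ_αβ) c_α c_β f_α(q, t) f_β(q, t) S_αβ(q, t)

with effective form factors f_α(q, t) = Σ_j w_αj(t) f_αj(q) weighted
over the charge-state populations.  Neutral-atom form factors use the
standard International-Tables (Cromer-Mann) parameterization; ionized
configurations use a screened-hydrogenic per-shell model normalized to
the bound-electron count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "RDFGrid",
    "FormFactorTable",
    "IntensityGrid",
    "compute_rdf",
    "rdf_from_positions",
    "partial_structure_factor",
    "neutral_form_factor",
    "ion_form_factor",
    "effective_form_factor",
    "water_form_factor_table",
    "scattered_intensity",
    "intensity_half_time",
    "peak_positions",
    "q_to_d",
]


def q_to_d(q):
    """Momentum transfer to real-space distance: d = 2π/q."""
    return 2.0 * np.pi / np.asarray(q, dtype=float)


# ---------------------------------------------------------------------------
# radial distribution functions


@dataclasses.dataclass
class RDFGrid:
    """g_αβ(r, t) on a fixed radial grid for one species pair."""

    r: np.ndarray            # bin centres, Å
    g: np.ndarray            # (n_times, n_bins)
    times: np.ndarray        # fs
    pair: tuple              # (α, β)
    bin_width: float
    number_densities: dict   # atoms/Å^3 per species


def rdf_from_positions(pos_a, pos_b, box, r_max=10.0, bin_width=0.02,
                       same_species=False):
    """Minimum-image pair-distance histogram normalized to the ideal gas."""
    box = np.asarray(box, dtype=float)
    if r_max > box.min() / 2.0 + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds half the shortest box edge {box.min() / 2:.2f}"
        )
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    d = pos_b[None, :, :] - pos_a[:, None, :]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=-1)
    if same_species:
        iu = np.triu_indices(len(pos_a), k=1)
        rvals = r[iu]
        n_pairs_per_shell = len(pos_a) * (len(pos_a) - 1) / 2.0
    else:
        rvals = r.ravel()
        n_pairs_per_shell = len(pos_a) * len(pos_b)
    hist, _ = np.histogram(rvals, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    vol = np.prod(box)
    shell = 4.0 * np.pi * centres**2 * bin_width
    ideal = n_pairs_per_shell * shell / vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return centres, g


def compute_rdf(trajectory, pair=("O", "O"), r_max=10.0,
                bin_width=0.02) -> RDFGrid:
    """Time-resolved RDF of a species pair over all trajectory frames.

    ``trajectory`` may be an md.Trajectory or a (Structure, ) single frame;
    a Structure is treated as one frame at t = 0.
    """
    from .crystal import Structure

    if isinstance(trajectory, Structure):
        frames = [(0.0, trajectory.positions)]
        species = trajectory.species
        box = trajectory.box
    else:
        frames = [(f.time_fs, f.positions) for f in trajectory.frames]
        species = trajectory.species
        box = trajectory.box

    a, b = pair
    idx_a = np.flatnonzero(species == a)
    idx_b = np.flatnonzero(species == b)
    same = a == b
    g_all, times = [], []
    for t, pos in frames:
        r, g = rdf_from_positions(
            pos[idx_a], pos[idx_b], box, r_max, bin_width, same_species=same
        )
        g_all.append(g)
        times.append(t)
    vol = np.prod(box)
    # densities of every species in the system: the structure-factor
    # normalization carries the total atomic density
    dens = {
        str(el): int(np.sum(species == el)) / vol for el in np.unique(species)
    }
    return RDFGrid(
        r=r,
        g=np.array(g_all),
        times=np.array(times),
        pair=(a, b),
        bin_width=bin_width,
        number_densities=dens,
    )


# ---------------------------------------------------------------------------
# partial structure factors


def _lorch_window(r, r_max):
    x = np.pi * r / r_max
    w = np.ones_like(r)
    nz = x != 0
    w[nz] = np.sin(x[nz]) / x[nz]
    return w


def partial_structure_factor(rdf: RDFGrid, q=None, window: str = "lorch"):
    """S_αβ(q, t): radial Fourier sine transform of g_αβ − 1.

    S_αβ(q) = 4π ρ ∫ r² (g_αβ(r) − 1) W(r) sin(qr)/(qr) dr with ρ the
    total atomic number density of the two species and W the Lorch
    window damping the finite-r truncation.  This convention makes the
    intermolecular intensity per atom exactly
    Σ (2 − δ) c_α c_β f_α f_β S_αβ (ideal gas → S ≡ 0).

    Returns ``(q, S)`` with S of shape (n_times, n_q).
    """
    if q is None:
        q = np.arange(0.05, 6.0 + 1e-9, 0.01)
    q = np.asarray(q, dtype=float)
    r = rdf.r
    dr = rdf.bin_width
    # concentrations are applied in the intensity formula, so the
    # transform carries the total atomic number density of the sample
    rho = sum(rdf.number_densities.values())
    if window == "lorch":
        w = _lorch_window(r, r[-1] + dr / 2)
    elif window is None or window == "none":
        w = np.ones_like(r)
    else:
        raise ValueError(f"unknown window {window!r}")
    qr = np.outer(q, r)
    sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    kern = 4.0 * np.pi * rho * (r**2 * w * dr)
    s = (rdf.g - 1.0) @ (sinc * kern[None, :]).T
    return q, s


# ---------------------------------------------------------------------------
# form factors

_A0 = 0.529177210903  # Bohr radius, Å

# (shell n, occupancy) per charge state; valence stripped first
_SHELL_N = {"1s": 1, "2s": 2, "2p": 2}


def _config(element, charge):
    from .constants import ATOMIC_NUMBER

    z = ATOMIC_NUMBER[element]
    nel = z - charge
    if nel < 0:
        raise ValueError(f"{element} cannot lose {charge} electrons")
    occ = {"1s": 0, "2s": 0, "2p": 0}
    left = nel
    for shell, cap in (("1s", 2), ("2s", 2), ("2p", 6)):
        take = min(left, cap)
        occ[shell] = take
        left -= take
    return occ


def _slater_zeff(element, occ, shell):
    """Slater-rule effective nuclear charge seen by ``shell`` electrons."""
    from .constants import ATOMIC_NUMBER

    z = ATOMIC_NUMBER[element]
    if shell == "1s":
        s = 0.30 * max(occ["1s"] - 1, 0)
    else:
        same = occ["2s"] + occ["2p"] - 1
        s = 0.35 * max(same, 0) + 0.85 * occ["1s"]
    return max(z - s, 1.0)


def neutral_form_factor(element, q):
    """Neutral-atom X-ray form factor (International Tables / Cromer-Mann)."""
    import gemmi

    q = np.asarray(q, dtype=float)
    coef = gemmi.Element(element).it92
    stol2 = (q / (4.0 * np.pi)) ** 2  # (sin θ / λ)^2
    a = np.asarray(coef.a)
    b = np.asarray(coef.b)
    f = coef.c + np.sum(
        a * np.exp(-b * stol2[..., None]), axis=-1
    )
    return f


def ion_form_factor(element, charge, q):
    """Screened-hydrogenic form factor of an ion, normalized to its
    bound-electron count at q = 0.

    Each occupied shell contributes N_shell / (1 + (q r_shell / 2)²)²
    with r_shell = n² a0 / Z_eff (Slater), the exact hydrogenic 1s form
    generalized by the shell's mean radius.
    """
    q = np.asarray(q, dtype=float)
    if charge == 0:
        return neutral_form_factor(element, q)
    occ = _config(element, charge)
    f = np.zeros_like(q)
    for shell, nocc in occ.items():
        if nocc == 0:
            continue
        n = _SHELL_N[shell]
        zeff = _slater_zeff(element, occ, shell)
        r_shell = n**2 * _A0 / zeff
        f = f + nocc / (1.0 + (q * r_shell / 2.0) ** 2) ** 2
    return f


@dataclasses.dataclass
class FormFactorTable:
    """f_αj(q) per element and charge state, plus time-dependent weights."""

    q: np.ndarray
    factors: dict  # element -> (n_states, n_q)

    def effective(self, element, weights):
        return effective_form_factor(self.factors[element], weights)


def water_form_factor_table(q) -> FormFactorTable:
    q = np.asarray(q, dtype=float)
    factors = {
        "O": np.array([ion_form_factor("O", j, q) for j in range(9)]),
        "H": np.array([ion_form_factor("H", j, q) for j in range(2)]),
    }
    return FormFactorTable(q=q, factors=factors)


def effective_form_factor(f_states: np.ndarray, weights) -> np.ndarray:
    """Population-weighted form factor f_α(q) = Σ_j w_j f_αj(q)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must lie on the simplex")
    return w @ np.asarray(f_states)


# ---------------------------------------------------------------------------
# scattered intensity


@dataclasses.dataclass
class IntensityGrid:
    q: np.ndarray
    i_self: np.ndarray       # (n_times, n_q)
    i_inter: np.ndarray
    times: np.ndarray
    concentrations: dict

    @property
    def i_total(self):
        return self.i_self + self.i_inter

    @property
    def d_spacing(self):
        return q_to_d(self.q)


def scattered_intensity(q, partial_s: dict, form_factors: dict,
                        concentrations: dict, times=None) -> IntensityGrid:
    """Damage-weighted 1D scattered intensity per atom.

    Parameters
    ----------
    partial_s : {(α, β): S array (n_times, n_q)}
        Partial structure factors on the common q grid.
    form_factors : {α: f array (n_times, n_q) or (n_q,)}
        Effective (population-weighted) form factors.
    concentrations : {α: number fraction}
    """
    q = np.asarray(q, dtype=float)
    some = next(iter(partial_s.values()))
    s_shape = np.atleast_2d(some).shape
    n_times = s_shape[0]
    if s_shape[1] != len(q):
        raise ValueError("S grids inconsistent with q grid")

    ff = {}
    for el, f in form_factors.items():
        f = np.atleast_2d(np.asarray(f, dtype=float))
        if f.shape[0] == 1 and n_times > 1:
            f = np.repeat(f, n_times, axis=0)
        if f.shape[1] != len(q):
            raise ValueError(f"form factor grid for {el} mismatches q grid")
        ff[el] = f

    elements = sorted(concentrations)
    i_self = np.zeros((n_times, len(q)))
    for el in elements:
        i_self += concentrations[el] * ff[el] ** 2

    i_inter = np.zeros((n_times, len(q)))
    for (a, b), s in partial_s.items():
        s = np.atleast_2d(s)
        mult = 1.0 if a == b else 2.0
        i_inter += (
            mult * concentrations[a] * concentrations[b] * ff[a] * ff[b] * s
        )
    return IntensityGrid(
        q=q,
        i_self=i_self,
        i_inter=i_inter,
        times=np.zeros(n_times) if times is None else np.asarray(times),
        concentrations=dict(concentrations),
    )


def peak_positions(x, y, n_peaks=3, min_rel_height=0.05, refine=True):
    """Positions of the ``n_peaks`` most prominent local maxima.

    Peak centres are refined by a quadratic fit through the maximum bin
    and its neighbours.  Returned sorted by position.
    """
    y = np.asarray(y, dtype=float)
    idx, props = find_peaks(y, prominence=min_rel_height * (y.max() - y.min()))
    if len(idx) == 0:
        return np.array([])
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    picks = np.sort(idx[order])
    out = []
    for i in picks:
        if refine and 0 < i < len(y) - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            dx = x[1] - x[0]
            out.append(x[i] + delta * dx)
        else:
            out.append(x[i])
    return np.array(out)


def intensity_half_time(times, series, sentinel=np.inf):
    """First time the series drops to half its t = 0 value.

    Linear interpolation between frames; returns ``sentinel`` if the
    series never crosses I(0)/2 within the covered span.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times[0] != 0:
        raise ValueError("series must start at t = 0")
    target = series[0] / 2.0
    below = series <= target
    if not below.any():
        return sentinel
    k = int(np.argmax(below))
    if k == 0:
        return 0.0
    t0, t1 = times[k - 1], times[k]
    y0, y1 = series[k - 1], series[k]
    return float(t0 + (y0 - target) / (y0 - y1) * (t1 - t0))
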