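"""Simplified collisional-radiative / two-temperature plasma model.

Produces the time-resolved inputs the screened molecular dynamics
consumes: per-element charge-state populations, free-electron density
and temperature, ion temperature and the Debye screening length.

The model is a screened-hydrogenic rate-equation stand-in for a full
NLTE collisional-radiative code.  Channels:

* photoionization with tabulated cross sections at the photon energy
  (K shell dominant at hard-X-ray energies),
* Auger relaxation of K-shell holes (branching by the Auger yield,
  treated as instantaneous, i.e. an effective double ionization),
* electron-impact (secondary) ionization with Lotz-type semi-empirical
  cross sections averaged over a Maxwellian electron distribution,
  acting on the valence shell of each charge state,
* three-body recombination, the detailed-balance partner of impact
  ionization, with coefficients fixed by the Saha relation (statistical
  weight ratios taken as unity).

Absorbed photon energy, minus the ionization-potential spending, feeds
a thermal electron bath (instant thermalization — the two-temperature
assumption); the ion temperature rises through a fixed electron-ion
coupling constant.  Radiative recombination is neglected on these
few-10-fs time scales.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .constants import DEBYE_PREF

__all__ = [
    "PulseSpec",
    "PlasmaHistory",
    "Material",
    "WATER_ICE",
    "evolve_plasma",
    "debye_length",
    "debye_convergence_time",
    "assign_charges",
    "read_plasma_table",
    "write_plasma_table",
    "LAMBDA_INF",
]

#: sentinel for "no screening" (neutral matter, n_e = 0)
LAMBDA_INF = np.inf

EV = 1.0  # temperatures/energies in this module are in eV

# ---------------------------------------------------------------------------
# atomic data (ground-state configurations; NIST ionization potentials, eV)

# oxygen charge states 0..7: (occ_1s, occ_2s, occ_2p), IP to the next state
_O_SHELLS = [
    (2, 2, 4), (2, 2, 3), (2, 2, 2), (2, 2, 1),
    (2, 2, 0), (2, 1, 0), (2, 0, 0), (1, 0, 0),
]
_O_IP = [13.618, 35.121, 54.936, 77.414, 113.90, 138.12, 739.29, 871.41]
_H_IP = [13.598]

#: O 1s binding energy (eV) used for the photoelectron energy
_O_K_EDGE = 543.1
#: K-shell Auger (KLL) yield for oxygen
_O_AUGER_YIELD = 0.992

# photoionization cross sections at 8 keV, cm^2 per electron; the K-shell
# value reproduces the photoelectric cross section of neutral O
# (~3.0e-22 cm^2 at 8 keV), of which the K shell carries ~95%.
_SIGMA_K_PER_E = 1.42e-22
_SIGMA_L_PER_E = 3.8e-24
_SIGMA_H_PER_E = 4.4e-27

#: electron-ion temperature coupling constant, fs^-1 (single calibration
#: knob of the stand-in; chosen so a 10^19 W/cm^2, 8 keV, 50 fs exposure of
#: ice reaches an ion temperature of ~4.9 eV at the end of the pulse)
DEFAULT_EI_COUPLING = 0.00143

_LOTZ_A = 4.5e-14  # cm^2 eV^2, Lotz constant

_ME_EV = 510998.95  # electron rest mass, eV


def _v_cm_per_s(energy_ev):
    """Non-relativistic electron speed in cm/s."""
    return 2.99792458e10 * np.sqrt(2.0 * energy_ev / _ME_EV)


@dataclasses.dataclass(frozen=True)
class PulseSpec:
    """Flat-top XFEL pulse.

    Attributes
    ----------
    photon_energy_ev : photon energy in eV (default 8 keV).
    intensity : peak intensity in W cm^-2.
    duration_fs : pulse duration in fs.
    """

    photon_energy_ev: float = 8000.0
    intensity: float = 1e18
    duration_fs: float = 50.0

    def __post_init__(self):
        if self.photon_energy_ev <= 0 or self.duration_fs <= 0 or self.intensity < 0:
            raise ValueError("pulse parameters must be positive (intensity >= 0)")

    def photon_flux(self, t_fs: float) -> float:
        """Photon flux in photons cm^-2 fs^-1 at time t (flat top)."""
        if 0.0 <= t_fs < self.duration_fs:
            joule = self.photon_energy_ev * 1.602176634e-19
            return self.intensity / joule * 1e-15
        return 0.0

    @property
    def fluence(self) -> float:
        """Time-integrated photon fluence, photons cm^-2."""
        joule = self.photon_energy_ev * 1.602176634e-19
        return self.intensity / joule * self.duration_fs * 1e-15


@dataclasses.dataclass(frozen=True)
class Material:
    """Stoichiometry and atomic number densities (cm^-3) per element."""

    number_density: dict  # element -> atoms per cm^3

    @property
    def elements(self):
        return list(self.number_density)


#: hexagonal ice at 0.92 g/cm^3: 3.077e22 H2O molecules per cm^3
WATER_ICE = Material({"O": 3.077e22, "H": 6.154e22})


@dataclasses.dataclass
class PlasmaHistory:
    """Time-resolved plasma state from the rate-equation model.

    ``populations[element]`` has shape (nt, n_states) and lives on the
    per-element probability simplex at every time.
    """

    time_fs: np.ndarray
    populations: dict
    n_e: np.ndarray          # cm^-3
    T_e: np.ndarray          # eV
    T_i: np.ndarray          # eV
    lambda_d: np.ndarray     # Å, inf where n_e = 0
    material: Material = dataclasses.field(default_factory=lambda: WATER_ICE)

    def mean_charge(self, element: str) -> np.ndarray:
        pops = self.populations[element]
        charges = np.arange(pops.shape[1])
        return pops @ charges

    def populations_at(self, element: str, t_fs: float) -> np.ndarray:
        """Charge-state populations linearly interpolated to time t."""
        pops = self.populations[element]
        out = np.array(
            [np.interp(t_fs, self.time_fs, pops[:, j]) for j in range(pops.shape[1])]
        )
        s = out.sum()
        return out / s if s > 0 else out

    def lambda_d_at(self, t_fs: float) -> float:
        lam = self.lambda_d
        finite = np.isfinite(lam)
        if not finite.any():
            return LAMBDA_INF
        t0 = self.time_fs[finite][0]
        if t_fs < t0:
            return LAMBDA_INF
        return float(np.interp(t_fs, self.time_fs[finite], lam[finite]))

    def validate(self, tol: float = 1e-9) -> None:
        for el, pops in self.populations.items():
            if np.any(pops < -tol):
                raise ValueError(f"negative population for {el}")
            err = np.abs(pops.sum(axis=1) - 1.0).max()
            if err > tol:
                raise ValueError(f"populations of {el} leave the simplex by {err:.2e}")


def debye_length(T_e: float, n_e: float) -> float:
    """Debye screening length in Å.

    λ_D = sqrt(ε0 k_B T_e / (n_e e²)); with T_e in eV and n_e in cm^-3.
    ``n_e = 0`` returns the ∞ sentinel (screening disabled).
    """
    if T_e <= 0 or n_e < 0:
        raise ValueError("require T_e > 0 and n_e >= 0")
    if n_e == 0:
        return LAMBDA_INF
    return DEBYE_PREF * np.sqrt(T_e / n_e)


def _lotz_sigma(energy_ev, shells, ips):
    """Lotz electron-impact ionization cross section, cm^2.

    ``shells``: (occupation, binding) for the shells allowed to ionize;
    here only the valence shell of each charge state is used, which makes
    secondary ionization valence-preferential by construction.
    """
    sig = np.zeros_like(np.asarray(energy_ev, dtype=float))
    for occ, p in zip(shells, ips):
        mask = energy_ev > p
        e = np.where(mask, energy_ev, p * np.e)
        sig += np.where(mask, _LOTZ_A * occ * np.log(e / p) / (e * p), 0.0)
    return sig


def _impact_rate_coeff(T_e, occ, ip):
    """Maxwellian-averaged <σv> for the Lotz cross section, cm^3/s."""
    if T_e <= 0:
        return 0.0
    # 48-node Gauss-Legendre on E in [ip, ip + 30 T_e]
    x, w = np.polynomial.legendre.leggauss(48)
    a, b = ip, ip + 30.0 * T_e
    e = 0.5 * (b - a) * x + 0.5 * (b + a)
    wt = 0.5 * (b - a) * w
    f = 2.0 * np.sqrt(e / np.pi) * T_e ** -1.5 * np.exp(-e / T_e)
    sig = _lotz_sigma(e, [occ], [ip])
    return float(np.sum(wt * f * sig * _v_cm_per_s(e)))


class _RateTable:
    """Per-transition impact-rate coefficients tabulated over log T_e."""

    def __init__(self, transitions):
        self.logT = np.linspace(np.log10(0.2), np.log10(20000.0), 160)
        T = 10 ** self.logT
        self.tables = []
        for occ, ip in transitions:
            self.tables.append(np.array([_impact_rate_coeff(t, occ, ip) for t in T]))

    def __call__(self, T_e):
        if T_e <= 0:
            return np.zeros(len(self.tables))
        lt = np.clip(np.log10(T_e), self.logT[0], self.logT[-1])
        return np.array([np.interp(lt, self.logT, tab) for tab in self.tables])


_SAHA_NQ = 3.017e21  # (2π m_e k_B T / h^2)^{3/2} in cm^-3 for T in eV


def _saha_factor(T_e: float, ip: float) -> float:
    """Saha ratio n_e * n_{j+1} / n_j at LTE, cm^-3 (statistical weights ~ 1).

    Detailed balance fixes the three-body recombination coefficient as
    the impact-ionization rate coefficient divided by this factor.
    """
    if T_e <= 0:
        return 0.0
    x = ip / T_e
    if x > 200.0:
        return 0.0
    return 2.0 * _SAHA_NQ * T_e**1.5 * np.exp(-x)


def _valence_shell(j):
    """(occupation, label) of the outermost occupied shell of O^j+."""
    occ1s, occ2s, occ2p = _O_SHELLS[j]
    if occ2p > 0:
        return occ2p
    if occ2s > 0:
        return occ2s
    return occ1s


def evolve_plasma(
    pulse: PulseSpec,
    material: Material = WATER_ICE,
    timestep: float = 0.1,
    t_end: float | None = None,
    ei_coupling: float = DEFAULT_EI_COUPLING,
    t_room_ev: float = 0.0235,
    impact_ionization: bool = True,
    recombination: bool = True,
) -> PlasmaHistory:
    """Advance the rate equations through (and optionally past) the pulse.

    Parameters
    ----------
    pulse : PulseSpec
    material : Material
        Defaults to H2O at ice density.
    timestep : fs
        Output grid spacing; must be ≤ 1 fs.  Internal substeps are
        adaptively refined for stiffness.
    t_end : fs
        End of the simulation; defaults to the pulse duration.
    ei_coupling : fs^-1
        Electron-ion temperature coupling constant.
    """
    if timestep > 1.0 or timestep <= 0:
        raise ValueError("timestep must be in (0, 1] fs")
    t_end = pulse.duration_fs if t_end is None else t_end

    n_o = material.number_density.get("O", 0.0)
    n_h = material.number_density.get("H", 0.0)
    n_atoms = n_o + n_h

    n_out = int(round(t_end / timestep)) + 1
    time_fs = np.linspace(0.0, t_end, n_out)

    c_o = np.zeros(9)
    c_o[0] = 1.0
    c_h = np.zeros(2)
    c_h[0] = 1.0
    u_e = 0.0          # thermal electron energy density, eV/cm^3
    t_i = t_room_ev
    absorbed = 0.0     # absorbed photon energy density, eV/cm^3
    spent_ip = 0.0     # energy spent on ionization potentials, eV/cm^3

    if not hasattr(evolve_plasma, "_rates_o"):
        evolve_plasma._rates_o = _RateTable(
            [(_valence_shell(j), _O_IP[j]) for j in range(8)]
        )
        evolve_plasma._rates_h = _RateTable([(1, _H_IP[0])])
    rates_o = evolve_plasma._rates_o
    rates_h = evolve_plasma._rates_h

    out = {
        "c_o": np.zeros((n_out, 9)),
        "c_h": np.zeros((n_out, 2)),
        "n_e": np.zeros(n_out),
        "T_e": np.zeros(n_out),
        "T_i": np.zeros(n_out),
        "absorbed": np.zeros(n_out),
        "spent_ip": np.zeros(n_out),
    }

    def electron_density():
        zbar_o = np.dot(c_o, np.arange(9))
        zbar_h = np.dot(c_h, np.arange(2))
        return n_o * zbar_o + n_h * zbar_h

    def record(k):
        ne = electron_density()
        te = (2.0 / 3.0) * u_e / ne if ne > 0 else 0.0
        te = max(te, t_room_ev if ne > 0 else 0.0)
        out["c_o"][k] = c_o
        out["c_h"][k] = c_h
        out["n_e"][k] = ne
        out["T_e"][k] = te
        out["T_i"][k] = t_i
        out["absorbed"][k] = absorbed
        out["spent_ip"][k] = spent_ip

    record(0)
    e_ph = pulse.photon_energy_ev

    for k in range(1, n_out):
        t0, t1 = time_fs[k - 1], time_fs[k]
        t = t0
        while t < t1 - 1e-12:
            ne = electron_density()
            te = (2.0 / 3.0) * u_e / ne if ne > 0 else 0.0
            flux = pulse.photon_flux(t)  # photons cm^-2 fs^-1

            # --- rates per atom, fs^-1
            # oxygen photoionization (K and L shells)
            r_ph_o = np.zeros(8)
            for j in range(8):
                k_occ, s_occ, p_occ = _O_SHELLS[j]
                sig = _SIGMA_K_PER_E * k_occ + _SIGMA_L_PER_E * (s_occ + p_occ)
                r_ph_o[j] = sig * flux
            r_ph_h = _SIGMA_H_PER_E * c_h[0] * 0 + _SIGMA_H_PER_E * flux

            # impact ionization, fs^-1 (rate coeff cm^3/s * n_e, to fs)
            if ne > 0 and impact_ionization:
                rc_o = rates_o(te) * ne * 1e-15
                rc_h = rates_h(te) * ne * 1e-15
            else:
                rc_o = np.zeros(8)
                rc_h = np.zeros(1)
            # three-body recombination per ion (detailed balance with Lotz)
            rrec_o = np.zeros(8)
            rrec_h = np.zeros(1)
            if ne > 0 and te > 0 and recombination:
                for j in range(8):
                    phi = _saha_factor(te, _O_IP[j])
                    rrec_o[j] = rc_o[j] * ne / phi if phi > 0 else 0.0
                phi_h = _saha_factor(te, _H_IP[0])
                rrec_h[0] = rc_h[0] * ne / phi_h if phi_h > 0 else 0.0

            total_rate = max(
                float(np.max((r_ph_o + rc_o) * (c_o[:8] > 0))),
                float(np.max(rrec_o * (c_o[1:] > 0))),
                float(rc_h[0] + r_ph_h) * (c_h[0] > 0),
                float(rrec_h[0]) * (c_h[1] > 0),
                1e-30,
            )
            dt = min(t1 - t, 0.05 / total_rate, 0.25)

            # --- oxygen transitions
            d_c = np.zeros(9)
            d_ue = 0.0
            d_abs = 0.0
            d_ip = 0.0
            for j in range(8):
                if c_o[j] <= 0:
                    continue
                # exact exponential depletion over the substep, split
                # proportionally between the photo and impact channels
                r_tot = r_ph_o[j] + rc_o[j]
                depleted = c_o[j] * -np.expm1(-r_tot * dt) if r_tot > 0 else 0.0
                # photoionization: K-shell events branch through Auger decay
                k_occ, s_occ, p_occ = _O_SHELLS[j]
                l_occ = s_occ + p_occ
                n_ph = depleted * (r_ph_o[j] / r_tot) if r_tot > 0 else 0.0
                if n_ph > 0:
                    frac_k = (_SIGMA_K_PER_E * k_occ) / (
                        _SIGMA_K_PER_E * k_occ + _SIGMA_L_PER_E * l_occ
                    ) if (k_occ + l_occ) else 0.0
                    n_k = n_ph * frac_k
                    n_l = n_ph - n_k
                    d_abs += n_ph * e_ph * n_o
                    # L-shell (valence) photoionization: j -> j+1
                    if n_l > 0:
                        d_c[j] -= n_l
                        d_c[j + 1] += n_l
                        d_ue += n_l * (e_ph - _O_IP[j]) * n_o
                        d_ip += n_l * _O_IP[j] * n_o
                    # K-shell photoionization
                    if n_k > 0:
                        auger_ok = l_occ >= 2 and j + 2 <= 8
                        p_a = _O_AUGER_YIELD if auger_ok else 0.0
                        # photoelectron always carries E_ph - B_K
                        d_ue += n_k * (e_ph - _O_K_EDGE) * n_o
                        d_abs_extra = 0.0
                        # Auger branch: j -> j+2, Auger electron carries
                        # B_K - IP(j) - IP(j+1)
                        n_a = n_k * p_a
                        n_f = n_k - n_a
                        if n_a > 0:
                            d_c[j] -= n_a
                            d_c[j + 2] += n_a
                            e_auger = max(_O_K_EDGE - _O_IP[j] - _O_IP[j + 1], 0.0)
                            d_ue += n_a * e_auger * n_o
                            d_ip += n_a * (_O_IP[j] + _O_IP[j + 1]) * n_o
                        # fluorescence branch: j -> j+1, photon escapes
                        if n_f > 0:
                            d_c[j] -= n_f
                            d_c[j + 1] += n_f
                            d_ip += n_f * _O_IP[j] * n_o
                            # remaining K-hole energy leaves as a photon
                            d_abs_extra = -n_f * (_O_K_EDGE - _O_IP[j]) * n_o
                        d_abs += d_abs_extra
                # impact ionization: j -> j+1, bath pays the IP
                n_im = depleted - n_ph
                if n_im > 0:
                    n_im = min(n_im, c_o[j] + d_c[j])
                    d_c[j] -= n_im
                    d_c[j + 1] += n_im
                    d_ue -= n_im * _O_IP[j] * n_o
                    d_ip += n_im * _O_IP[j] * n_o
            for j in range(8):
                # three-body recombination: j+1 -> j, bath recovers the IP
                n_rec = c_o[j + 1] * -np.expm1(-rrec_o[j] * dt)
                if n_rec > 0:
                    n_rec = min(n_rec, c_o[j + 1] + d_c[j + 1])
                    d_c[j + 1] -= n_rec
                    d_c[j] += n_rec
                    d_ue += n_rec * _O_IP[j] * n_o
                    d_ip -= n_rec * _O_IP[j] * n_o
            c_o = c_o + d_c

            # --- hydrogen transitions
            d_h = 0.0
            if c_h[0] > 0:
                r_tot_h = r_ph_h + rc_h[0]
                out_h = c_h[0] * -np.expm1(-r_tot_h * dt) if r_tot_h > 0 else 0.0
                n_ph = out_h * (r_ph_h / r_tot_h) if r_tot_h > 0 else 0.0
                n_im = out_h - n_ph
                d_h = out_h
                d_abs += n_ph * e_ph * n_h
                d_ue += n_ph * (e_ph - _H_IP[0]) * n_h - n_im * _H_IP[0] * n_h
                d_ip += (n_ph + n_im) * _H_IP[0] * n_h
            if c_h[1] > 0 and rrec_h[0] > 0:
                n_rec = min(rrec_h[0] * c_h[1] * dt, c_h[1])
                d_h -= n_rec
                d_ue += n_rec * _H_IP[0] * n_h
                d_ip -= n_rec * _H_IP[0] * n_h
            c_h = c_h + np.array([-d_h, d_h])

            u_e = max(u_e + d_ue, 0.0)
            absorbed += d_abs
            spent_ip += d_ip

            # --- two-temperature electron-ion coupling
            ne = electron_density()
            if ne > 0:
                te = max((2.0 / 3.0) * u_e / ne, t_room_ev)
                dT = ei_coupling * (te - t_i) * (ne / n_atoms) * dt
                t_i = t_i + dT
                u_e = max(u_e - 1.5 * n_atoms * dT, 0.0)
                if t_i < 0:
                    raise RuntimeError("negative ion temperature (stiffness)")

            # simplex guard
            if np.any(c_o < -1e-8) or np.any(c_h < -1e-8):
                raise RuntimeError(
                    "charge-state populations left the simplex; reduce timestep"
                )
            c_o = np.clip(c_o, 0.0, None)
            c_o /= c_o.sum()
            c_h = np.clip(c_h, 0.0, None)
            c_h /= c_h.sum()
            t += dt

        record(k)

    lam = np.full(n_out, LAMBDA_INF)
    pos = out["n_e"] > 0
    lam[pos] = DEBYE_PREF * np.sqrt(out["T_e"][pos] / out["n_e"][pos])

    hist = PlasmaHistory(
        time_fs=time_fs,
        populations={"O": out["c_o"], "H": out["c_h"]},
        n_e=out["n_e"],
        T_e=out["T_e"],
        T_i=out["T_i"],
        lambda_d=lam,
        material=material,
    )
    hist.absorbed_energy = out["absorbed"]
    hist.spent_ionization = out["spent_ip"]
    hist.validate(tol=1e-9)
    return hist


def debye_convergence_time(history: PlasmaHistory, rel_tol: float = 0.01) -> float:
    """Earliest time after which |dλ_D/dt|/λ_D stays below ``rel_tol`` (per fs).

    Returns the sentinel ``inf`` if the screening length never settles
    within the covered time span.
    """
    t = history.time_fs
    lam = history.lambda_d
    finite = np.isfinite(lam)
    if finite.sum() < 2:
        return float("inf")
    tf, lf = t[finite], lam[finite]
    dldt = np.gradient(lf, tf)
    rel = np.abs(dldt) / lf
    ok = rel < rel_tol
    # time must also be past any non-finite (unscreened) prefix
    for i in range(len(tf)):
        if ok[i:].all():
            return float(tf[i])
    return float("inf")


def assign_charges(populations: dict, species: np.ndarray, seed: int) -> np.ndarray:
    """Sample integer per-atom charges from per-element populations.

    Uses a fixed per-atom uniform variate (from ``seed``) pushed through
    the inverse CDF of the element's charge-state distribution.  Because
    ionization only moves population to higher charge states, the CDF
    decreases pointwise in time and each atom's charge is therefore
    non-decreasing across successive calls within one trajectory —
    charge assignment is correlated in time, as physical irreversibility
    requires.
    """
    species = np.asarray(species)
    rng = np.random.default_rng(seed)
    u = rng.random(len(species))
    charges = np.zeros(len(species), dtype=int)
    for el in np.unique(species):
        c = np.asarray(populations[str(el)], dtype=float)
        if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-6:
            raise ValueError(f"populations of {el} are not on the simplex")
        cdf = np.cumsum(c / c.sum())
        idx = species == el
        charges[idx] = np.searchsorted(cdf, u[idx], side="right")
        charges[idx] = np.clip(charges[idx], 0, len(c) - 1)
    return charges


# ---------------------------------------------------------------------------
# tabular interface for externally supplied CR histories

_REQUIRED_SCALARS = ["time_fs", "n_e_cm3", "T_e_eV", "T_i_eV"]


def write_plasma_table(history: PlasmaHistory, path) -> None:
    """Write a PlasmaHistory as a CSV table (one row per time point)."""
    data = {"time_fs": history.time_fs}
    for el, pops in history.populations.items():
        for j in range(pops.shape[1]):
            data[f"{el}_c{j}"] = pops[:, j]
    data["n_e_cm3"] = history.n_e
    data["T_e_eV"] = history.T_e
    data["T_i_eV"] = history.T_i
    data["lambda_D_A"] = history.lambda_d
    pd.DataFrame(data).to_csv(path, index=False)


def read_plasma_table(path, simplex_tol: float = 1e-6) -> PlasmaHistory:
    """Read a plasma-history CSV, validating the population simplex.

    Raises ``ValueError`` naming the offending row/column on malformed
    input (missing required column, or Σ_j c_j differing from 1 by more
    than ``simplex_tol``).
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_SCALARS:
        if col not in df.columns:
            raise ValueError(f"plasma table is missing required column {col!r}")
    pop_cols = {}
    for col in df.columns:
        if "_c" in col:
            el, j = col.rsplit("_c", 1)
            if j.isdigit():
                pop_cols.setdefault(el, []).append((int(j), col))
    if not pop_cols:
        raise ValueError("plasma table has no charge-state population columns")
    populations = {}
    for el, cols in pop_cols.items():
        cols = [c for _, c in sorted(cols)]
        pops = df[cols].to_numpy(dtype=float)
        sums = pops.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > simplex_tol)
        if len(bad):
            raise ValueError(
                f"row {int(bad[0]) + 1}: populations of {el} sum to "
                f"{sums[bad[0]]:.6f} (simplex violation)"
            )
        if np.any(pops < -simplex_tol):
            bad = np.flatnonzero((pops < -simplex_tol).any(axis=1))
            raise ValueError(f"row {int(bad[0]) + 1}: negative population for {el}")
        populations[el] = pops
    lam = (
        df["lambda_D_A"].to_numpy(dtype=float)
        if "lambda_D_A" in df.columns
        else np.where(
            df["n_e_cm3"] > 0,
            DEBYE_PREF * np.sqrt(df["T_e_eV"] / df["n_e_cm3"].replace(0, np.nan)),
            LAMBDA_INF,
        )
    )
    return PlasmaHistory(
        time_fs=df["time_fs"].to_numpy(dtype=float),
        populations=populations,
        n_e=df["n_e_cm3"].to_numpy(dtype=float),
        T_e=df["T_e_eV"].to_numpy(dtype=float),
        T_i=df["T_i_eV"].to_numpy(dtype=float),
        lambda_d=lam,
    )
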