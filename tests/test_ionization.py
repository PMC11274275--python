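"""Collisional-radiative stand-in: closed forms, invariants, table I/O."""

import numpy as np
import pytest

from plasmice import ionization
from plasmice.ionization import (
    LAMBDA_INF,
    PlasmaHistory,
    PulseSpec,
    assign_charges,
    debye_convergence_time,
    debye_length,
    evolve_plasma,
    read_plasma_table,
    write_plasma_table,
)


class TestDebyeLength:
    def test_reference_value(self):
        # closed form with CODATA constants: 1 eV, 1e21 cm^-3 -> 2.35 Å
        assert debye_length(1.0, 1e21) == pytest.approx(2.351, abs=0.005)

    def test_sqrt_scaling_in_temperature(self):
        assert debye_length(4.0, 1e21) == pytest.approx(
            2.0 * debye_length(1.0, 1e21)
        )

    def test_zero_density_returns_sentinel(self):
        assert debye_length(10.0, 0.0) == LAMBDA_INF

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            debye_length(-1.0, 1e21)
        with pytest.raises(ValueError):
            debye_length(1.0, -1e21)


class TestEvolvePlasma:
    def test_zero_intensity_freezes_neutral(self):
        h = evolve_plasma(PulseSpec(8000.0, 0.0, 10.0), timestep=0.5)
        assert np.all(h.populations["O"][:, 0] == 1.0)
        assert np.all(h.n_e == 0.0)
        assert np.all(np.isinf(h.lambda_d))

    def test_photoionization_survival_closed_form(self):
        """Photoionization only: neutral fraction follows Poisson survival
        exp(-sigma*F) with the shipped O cross section."""
        pulse = PulseSpec(8000.0, 1e21, 10.0)
        h = evolve_plasma(pulse, timestep=0.25, impact_ionization=False)
        sigma = (
            2 * ionization._SIGMA_K_PER_E + 6 * ionization._SIGMA_L_PER_E
        )
        expected = np.exp(-sigma * pulse.fluence)
        assert h.populations["O"][-1, 0] == pytest.approx(expected, rel=0.02)

    def test_simplex_invariant(self, plasma18):
        for el, pops in plasma18.populations.items():
            np.testing.assert_allclose(pops.sum(axis=1), 1.0, atol=1e-9)
            assert pops.min() >= -1e-12

    def test_quasi_neutrality(self, plasma18):
        dens = plasma18.material.number_density
        z_o = plasma18.mean_charge("O")
        z_h = plasma18.mean_charge("H")
        expected = dens["O"] * z_o + dens["H"] * z_h
        np.testing.assert_allclose(plasma18.n_e, expected, rtol=1e-9)

    def test_mean_charge_monotone_during_pulse(self, plasma18):
        assert np.all(np.diff(plasma18.mean_charge("O")) >= -1e-9)

    def test_energy_bookkeeping(self, plasma19):
        # absorbed photon energy covers ionization spending at all times
        assert np.all(
            plasma19.absorbed_energy + 1e-6 >= plasma19.spent_ionization
        )

    def test_valence_preferential_ionization(self, plasma19):
        # K-shell occupancy stays >= 1.8 while mean O charge <= 4
        pops = plasma19.populations["O"]
        k_occ = np.array([occ[0] for occ in ionization._O_SHELLS] + [0])
        mean_k = pops @ k_occ
        zbar = plasma19.mean_charge("O")
        assert np.all(mean_k[zbar <= 4.0] >= 1.8)

    def test_timestep_guard(self):
        with pytest.raises(ValueError):
            evolve_plasma(PulseSpec(), timestep=2.0)


class TestDebyeConvergence:
    def test_constant_series_converges_at_zero(self):
        h = _history_from_lambda(np.linspace(0, 50, 101), lambda t: 3.0)
        assert debye_convergence_time(h) == 0.0

    def test_exponential_relaxation_matches_scan(self):
        # lambda(t) = A + B exp(-t/tau): brute-force scan oracle
        a_const, b_const, tau = 2.0, 8.0, 2.0
        t = np.linspace(0, 50, 501)
        lam = a_const + b_const * np.exp(-t / tau)
        h = _history_from_lambda(t, lambda tt: np.interp(tt, t, lam))
        rel_tol = 0.01
        result = debye_convergence_time(h, rel_tol=rel_tol)
        dldt = np.gradient(lam, t)
        rel = np.abs(dldt) / lam
        scan = next(t[i] for i in range(len(t)) if np.all(rel[i:] < rel_tol))
        assert result == pytest.approx(scan, abs=0.2)

    def test_never_converging_returns_sentinel(self):
        t = np.linspace(0, 10, 101)
        h = _history_from_lambda(t, lambda tt: 10.0 * np.exp(-tt))
        assert debye_convergence_time(h, rel_tol=1e-6) == np.inf


def _history_from_lambda(t, fn):
    lam = np.array([fn(tt) for tt in t])
    n = len(t)
    return PlasmaHistory(
        time_fs=t,
        populations={"O": np.tile([0.5, 0.5] + [0.0] * 7, (n, 1))},
        n_e=np.full(n, 1e22),
        T_e=np.full(n, 10.0),
        T_i=np.full(n, 1.0),
        lambda_d=lam,
    )


class TestAssignCharges:
    def test_degenerate_distribution(self):
        species = np.array(["O"] * 10)
        charges = assign_charges({"O": [1.0, 0.0]}, species, seed=1)
        assert np.all(charges == 0)

    def test_sampling_fraction_within_binomial_noise(self):
        n = 10000
        species = np.array(["O"] * n)
        charges = assign_charges({"O": [0.5, 0.5]}, species, seed=2)
        frac = np.mean(charges == 1)
        sigma = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * sigma

    def test_determinism(self):
        species = np.array(["O", "H", "O", "H"])
        pops = {"O": [0.3, 0.7], "H": [0.6, 0.4]}
        a = assign_charges(pops, species, seed=9)
        b = assign_charges(pops, species, seed=9)
        assert np.array_equal(a, b)

    def test_monotone_in_time(self, plasma18):
        """An atom's sampled charge never decreases along the pulse."""
        species = np.array(["O"] * 200 + ["H"] * 400)
        prev = None
        for t in np.linspace(0.0, 50.0, 11):
            pops = {
                el: plasma18.populations_at(el, t)
                for el in plasma18.populations
            }
            charges = assign_charges(pops, species, seed=4)
            if prev is not None:
                assert np.all(charges >= prev)
            prev = charges

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            assign_charges({"O": [0.7, 0.5]}, np.array(["O"]), seed=0)


class TestPlasmaTable:
    def test_round_trip(self, tmp_path, plasma18):
        path = tmp_path / "plasma.csv"
        write_plasma_table(plasma18, path)
        back = read_plasma_table(path)
        np.testing.assert_allclose(back.time_fs, plasma18.time_fs)
        np.testing.assert_allclose(
            back.populations["O"], plasma18.populations["O"], atol=1e-9
        )
        np.testing.assert_allclose(back.T_i, plasma18.T_i, rtol=1e-9)

    def test_simplex_violation_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_fs,O_c0,O_c1,n_e_cm3,T_e_eV,T_i_eV\n"
            "0.0,1.0,0.0,0.0,1.0,0.1\n"
            "1.0,0.7,0.5,1e20,1.0,0.1\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_plasma_table(path)

    def test_missing_column_rejected_by_name(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_fs,O_c0,O_c1,n_e_cm3,T_e_eV\n0,1,0,0,1\n")
        with pytest.raises(ValueError, match="T_i_eV"):
            read_plasma_table(path)
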