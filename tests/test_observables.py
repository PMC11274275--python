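"""RDF, partial structure factors, form factors, intensity, half-times."""

import numpy as np
import pytest

from plasmice.crystal import Structure
from plasmice.observables import (
    compute_rdf,
    effective_form_factor,
    intensity_half_time,
    ion_form_factor,
    neutral_form_factor,
    partial_structure_factor,
    peak_positions,
    q_to_d,
    rdf_from_positions,
    scattered_intensity,
    water_form_factor_table,
)


def test_q_to_d_is_exact():
    q = np.array([1.66, 2.98, 4.95])
    np.testing.assert_allclose(q_to_d(q) * q / (2 * np.pi), 1.0)


class TestRDF:
    def test_ideal_ice_first_and_second_peak(self, ice768):
        rdf = compute_rdf(ice768, ("O", "O"), r_max=10.0, bin_width=0.01)
        g = rdf.g[0]
        first = rdf.r[np.argmax(g * (rdf.r < 3.5))]
        assert first == pytest.approx(2.75, abs=0.03)
        beyond = rdf.r > 3.5
        second = rdf.r[beyond][np.argmax(g[beyond] * (rdf.r[beyond] < 5.0))]
        assert second == pytest.approx(4.5, abs=0.05)

    def test_uniform_gas_is_flat(self):
        rng = np.random.default_rng(0)
        box = np.full(3, 30.0)
        pos = rng.random((4000, 3)) * box
        r, g = rdf_from_positions(pos, pos, box, r_max=10.0, bin_width=0.25,
                                  same_species=True)
        sel = r > 1.0
        counts = 4000 * 3999 / 2 * 4 * np.pi * r[sel] ** 2 * 0.25 / box.prod()
        np.testing.assert_allclose(
            g[sel], 1.0, atol=(5.0 / np.sqrt(counts)).max()
        )

    def test_rmax_beyond_half_box_rejected(self, ice_mini):
        with pytest.raises(ValueError):
            compute_rdf(ice_mini, ("O", "O"), r_max=10.0)


class TestStructureFactor:
    def test_uncorrelated_rdf_gives_zero(self):
        from plasmice.observables import RDFGrid

        r = np.arange(0.01, 10.0, 0.02)
        grid = RDFGrid(r, np.ones((1, len(r))), np.array([0.0]), ("O", "O"),
                       0.02, {"O": 0.03})
        q, sq = partial_structure_factor(grid)
        assert np.abs(sq[0][q > 0.3]).max() < 1e-3

    def test_debye_equation_oracle_on_cluster(self):
        """Transform route matches the direct Debye sum for a random
        50-atom cluster (2% RMS)."""
        rng = np.random.default_rng(7)
        box = np.full(3, 60.0)
        pos = rng.random((50, 3)) * 8.0 + 26.0
        species = np.array(["O"] * 50)
        s = Structure(species, pos, np.arange(50),
                      np.empty((0, 2), dtype=int), box)
        rdf = compute_rdf(s, ("O", "O"), r_max=14.0, bin_width=0.002)
        q = np.arange(0.3, 6.0, 0.01)
        _, sq = partial_structure_factor(rdf, q, window="none")
        f = neutral_form_factor("O", q)
        grid = scattered_intensity(q, {("O", "O"): sq}, {"O": f}, {"O": 1.0})
        # Debye equation cross term per atom
        d = pos[None, :, :] - pos[:, None, :]
        r = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(50, k=1)
        rij = r[iu]
        qr = np.outer(q, rij)
        # finite-N: the RDF route normalizes by N(N-1)/2 ideal pairs while
        # carrying rho = N/V, so the transform equals 2 Σ sinc / (N - 1)
        cross = 2.0 * f**2 * np.sum(np.sinc(qr / np.pi), axis=1) / 49
        rms = np.sqrt(np.mean((grid.i_inter[0] - cross) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(cross**2))

    def test_ideal_ice_bragg_features(self, ice768):
        rdf = compute_rdf(ice768, ("O", "O"), r_max=10.0, bin_width=0.01)
        q, sq = partial_structure_factor(rdf)
        peaks = peak_positions(q, sq[0], n_peaks=2)
        assert np.any(np.abs(peaks - 1.66) < 0.05)
        assert np.any(np.abs(peaks - 2.98) < 0.06)

    def test_roundtrip_recovers_disordered_rdf(self, melt_traj):
        """g -> S -> g on a disordered (late-melt) frame.

        The frame histogram is smoothed to a statistically meaningful
        liquid-like g before transforming; the inverse sine transform of
        the unwindowed S must reproduce it on 2-7 Å.
        """
        from scipy.ndimage import gaussian_filter1d

        from plasmice.observables import RDFGrid

        rdf = compute_rdf(melt_traj, ("O", "O"), r_max=7.5, bin_width=0.02)
        g = gaussian_filter1d(rdf.g[-3:].mean(axis=0), sigma=4)
        rho = sum(rdf.number_densities.values())
        q = np.arange(0.01, 40.0, 0.01)
        grid = RDFGrid(rdf.r, g[None, :], np.array([0.0]), ("O", "O"),
                       rdf.bin_width, rdf.number_densities)
        _, sq = partial_structure_factor(grid, q, window="none")
        r = rdf.r
        qr = np.outer(r, q)
        g_rec = 1.0 + (
            (sq[0] * q) @ np.sin(qr.T) * 0.01 / (2 * np.pi**2 * rho)
        ) / r
        sel = (r > 2.0) & (r < 7.0)
        rms = np.sqrt(np.mean((g_rec[sel] - g[sel]) ** 2))
        assert rms < 0.03 * np.sqrt(np.mean(g[sel] ** 2))


class TestFormFactors:
    def test_neutral_oxygen_electron_count(self):
        assert neutral_form_factor("O", 0.0) == pytest.approx(8.0, abs=0.01)

    def test_ion_zero_q_counts_bound_electrons(self):
        for j in range(9):
            f0 = ion_form_factor("O", j, np.array([0.0]))[0]
            assert f0 == pytest.approx(8.0 - j, abs=0.01)

    def test_effective_form_factor_weighting(self):
        q = np.array([0.0, 1.0])
        tab = water_form_factor_table(q)
        f = effective_form_factor(tab.factors["O"], [0.5, 0, 0.5] + [0] * 6)
        assert f[0] == pytest.approx(7.0, abs=0.01)

    def test_weights_permutation_invariance(self):
        q = np.linspace(0, 4, 9)
        tab = water_form_factor_table(q)
        w = np.array([0.2, 0.3, 0.5] + [0.0] * 6)
        f1 = effective_form_factor(tab.factors["O"], w)
        # permuting (weight, state) pairs together leaves the sum unchanged
        perm = np.array([2, 0, 1] + list(range(3, 9)))
        f2 = effective_form_factor(tab.factors["O"][perm], w[perm])
        np.testing.assert_allclose(f1, f2)

    def test_simplex_violation_rejected(self):
        q = np.array([0.0])
        tab = water_form_factor_table(q)
        with pytest.raises(ValueError):
            effective_form_factor(tab.factors["O"], [0.9] * 2 + [0.0] * 7)

    def test_monotone_decrease_with_mean_charge(self, plasma19):
        """Increasing ionization lowers f_O(q) pointwise at low q."""
        q = np.arange(0.05, 2.0, 0.05)
        tab = water_form_factor_table(q)
        prev = None
        for t in (0.0, 10.0, 25.0, 50.0):
            w = plasma19.populations_at("O", t)
            f = effective_form_factor(tab.factors["O"], w)
            if prev is not None:
                assert np.all(f <= prev + 1e-9)
            prev = f


class TestIntensity:
    def test_zero_structure_factor_gives_self_only(self):
        q = np.linspace(0.1, 5.0, 50)
        f = neutral_form_factor("O", q)
        grid = scattered_intensity(
            q, {("O", "O"): np.zeros((1, 50))}, {"O": f}, {"O": 1.0}
        )
        np.testing.assert_array_equal(grid.i_total, grid.i_self)
        np.testing.assert_allclose(grid.i_self[0], f**2)

    def test_ideal_ice_dominant_peaks(self, ice768):
        from plasmice.pipeline import intensity_vs_time

        class OneFrame:
            species = ice768.species
            box = ice768.box
            frames = [
                type("F", (), {"time_fs": 0.0, "positions": ice768.positions})()
            ]

        grid, _ = intensity_vs_time(OneFrame(), None)
        y = grid.i_inter[0]
        peaks = peak_positions(grid.q, np.where(y > 0, y, 0.0), n_peaks=3)
        assert np.any(np.abs(peaks - 1.66) < 0.05)
        assert np.any(np.abs(peaks - 2.98) < 0.05)

    def test_total_intensity_nonnegative(self, melt_intensity):
        """I_total >= 0 at every time for q above the crystal diffraction
        gap (~1.2 Å^-1).  Below the first reflection a crystal has
        essentially zero diffuse intensity, and the finite-r windowed
        transform oscillates around that zero, so the positivity bound
        only applies where the transform resolves structure."""
        sel = melt_intensity.q >= 1.2
        assert melt_intensity.i_total[:, sel].min() > -1e-9

    def test_hydrogen_contribution_is_secondary(self, ice768):
        """Dropping H changes the total intensity at q1 by a bounded
        fraction, and much less at high q (H scatters weakly there)."""
        from plasmice.pipeline import intensity_vs_time

        class OneFrame:
            species = ice768.species
            box = ice768.box
            frames = [
                type("F", (), {"time_fs": 0.0, "positions": ice768.positions})()
            ]

        grid, rdfs = intensity_vs_time(OneFrame(), None)
        q = grid.q
        s_oo = partial_structure_factor(rdfs[("O", "O")], q)[1]
        f_o = neutral_form_factor("O", q)
        no_h = scattered_intensity(
            q, {("O", "O"): s_oo}, {"O": f_o}, {"O": 1.0 / 3.0}
        )
        # compare I_total without the H terms (concentrations kept)
        i_with = grid.i_total[0]
        i_without = no_h.i_total[0] + 0.0
        for qstar, bound in [(1.66, 0.35), (4.95, 0.10)]:
            iq = np.argmin(np.abs(q - qstar))
            rel = abs(i_with[iq] - i_without[iq]) / i_with[iq]
            assert rel < bound


class TestHalfTime:
    def test_constant_series_returns_sentinel(self):
        t = np.linspace(0, 50, 11)
        assert intensity_half_time(t, np.ones(11)) == np.inf

    def test_exponential_closed_form(self):
        tau = 12.0
        t = np.linspace(0, 60, 601)
        ht = intensity_half_time(t, np.exp(-t / tau))
        assert ht == pytest.approx(tau * np.log(2), abs=0.01)

    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            intensity_half_time(np.array([1.0, 2.0]), np.array([1.0, 0.1]))
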