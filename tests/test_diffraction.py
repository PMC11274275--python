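"""Detector geometry, direct-sum patterns, angular correlations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plasmice.diffraction import (
    DetectorImage,
    DetectorSpec,
    angular_correlation,
    load_image_h5,
    save_image_h5,
    simulate_pattern,
)
from plasmice.observables import ion_form_factor

SMALL_DET = DetectorSpec(n_fast=96, n_slow=96, pixel_size_um=2200.0)


class TestDetectorSpec:
    def test_wavelength_at_8_kev(self):
        assert DetectorSpec().wavelength == pytest.approx(1.5498, abs=1e-3)

    def test_q_map_range_of_reference_detector(self):
        _, qmag, _, _ = DetectorSpec().q_map()
        # 1024 x 200 um pixels at 70 mm and 8 keV cover the 1.66 and 2.98
        # rings fully; the corners stop short of the 4.95 ring
        ny, nx = qmag.shape
        assert qmag[ny // 2, 0] > 2.98
        assert 4.0 < qmag.max() < 4.95

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DetectorSpec(distance_mm=-1)


class TestSimulatePattern:
    def test_single_atom_smooth_profile(self):
        img = simulate_pattern(
            np.zeros((1, 3)), np.array(["O"]), None, SMALL_DET
        )
        _, qmag, _, omega = SMALL_DET.q_map()
        expected = ion_form_factor("O", 0, qmag) ** 2 * omega / omega.max()
        np.testing.assert_allclose(img.intensity, expected, rtol=1e-10)

    def test_two_scatterers_fringe_spacing(self):
        d = 2.0
        pos = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        img = simulate_pattern(
            pos, np.array(["O", "O"]), None, SMALL_DET, apply_solid_angle=False
        )
        qvec, qmag, _, _ = SMALL_DET.q_map()
        pred = 2 * ion_form_factor("O", 0, qmag) ** 2 * (
            1 + np.cos(qvec[..., 0] * d)
        )
        np.testing.assert_allclose(img.intensity, pred, atol=1e-8 * pred.max())

    def test_direct_sum_oracle(self):
        """Vectorized pattern equals the naive pixel/atom double loop."""
        rng = np.random.default_rng(3)
        n = 60
        pos = rng.random((n, 3)) * 8.0
        species = np.array(["O"] * 40 + ["H"] * 20)
        charges = rng.integers(0, 3, n)
        charges[40:] = rng.integers(0, 2, 20)
        det = DetectorSpec(n_fast=24, n_slow=24, pixel_size_um=8000.0)
        img = simulate_pattern(pos, species, charges, det,
                               apply_solid_angle=False)
        qvec, qmag, _, _ = det.q_map()
        naive = np.zeros(qmag.shape)
        for iy in range(24):
            for ix in range(24):
                amp = 0j
                for k in range(n):
                    f = ion_form_factor(
                        str(species[k]), int(charges[k]),
                        np.array([qmag[iy, ix]]),
                    )[0]
                    amp += f * np.exp(1j * qvec[iy, ix] @ pos[k])
                naive[iy, ix] = abs(amp) ** 2
        np.testing.assert_allclose(img.intensity, naive, rtol=1e-10)

    def test_friedel_symmetry_low_q(self):
        """I(q) = I(-q) in the flat-Ewald limit (central crop)."""
        rng = np.random.default_rng(5)
        pos = rng.random((40, 3)) * 10.0
        det = DetectorSpec(n_fast=64, n_slow=64, pixel_size_um=400.0)
        img = simulate_pattern(pos, np.array(["O"] * 40), None, det,
                               apply_solid_angle=False)
        inten = img.intensity
        flipped = inten[::-1, ::-1]
        c = slice(24, 40)  # central low-q crop
        np.testing.assert_allclose(inten[c, c], flipped[c, c], rtol=0.02)

    def test_ideal_crystal_maxima_on_reciprocal_shells(self, ice768):
        """Strong pixels of an oriented ideal crystal lie on reciprocal-
        lattice shells |G| of the hexagonal cell (the 1.6-1.8 Å^-1 family
        around the strongest ring, the 102/110/112 shells, ...)."""
        det = DetectorSpec(n_fast=256, n_slow=256, pixel_size_um=800.0)
        img = simulate_pattern(
            ice768.positions, ice768.species, None, det,
            orientation=Rotation.from_euler("xyz", [20, 35, 10], degrees=True),
        )
        qmag = img.q_mag
        work = img.intensity.copy()
        work[qmag < 1.2] = 0.0
        hot = np.argsort(work.ravel())[::-1][:40]
        qhot = qmag.ravel()[hot]
        # reciprocal shells of the orthorhombic (a, √3a, c) cell
        a, c = 4.51825, 7.3535
        hs = np.arange(-8, 9)
        g = 2 * np.pi * np.sqrt(
            (hs[:, None, None] / a) ** 2
            + (hs[None, :, None] / (np.sqrt(3) * a)) ** 2
            + (hs[None, None, :] / c) ** 2
        ).ravel()
        shells = np.unique(np.round(g[(g > 1.0) & (g < 5.0)], 3))
        dist = np.min(np.abs(qhot[:, None] - shells[None, :]), axis=1)
        assert np.median(dist) < 0.05

    def test_size_guard(self):
        pos = np.zeros((11, 3))
        with pytest.raises(ValueError):
            simulate_pattern(pos, np.array(["O"] * 11), None, SMALL_DET,
                             max_atoms=10)


class TestAngularCorrelation:
    def test_uniform_image_flat_correlation(self):
        _, qmag, phi, _ = SMALL_DET.q_map()
        img = DetectorImage(
            intensity=np.ones_like(qmag), q_mag=qmag, phi=phi, spec=SMALL_DET
        )
        q, delta, corr, valid = angular_correlation(img, q_step=0.2,
                                                    angle_step_deg=2.0)
        row = corr[valid][2]
        cv = np.nanstd(row) / np.nanmean(row)
        assert cv < 1e-6

    def test_sixfold_synthetic_pattern(self):
        """Six equal Gaussian peaks 60° apart give correlation maxima at
        Δ = 0°, 60°, ..., 300°."""
        det = DetectorSpec(n_fast=256, n_slow=256, pixel_size_um=550.0)
        _, qmag, phi, _ = det.q_map()
        q0 = 2.0
        inten = np.zeros_like(qmag)
        for k in range(6):
            phik = np.deg2rad(60 * k + 15)
            inten += np.exp(
                -(((qmag - q0) / 0.1) ** 2)
                - ((np.remainder(phi - phik + np.pi, 2 * np.pi) - np.pi) / 0.12) ** 2
            )
        img = DetectorImage(intensity=inten, q_mag=qmag, phi=phi, spec=det)
        q, delta, corr, valid = angular_correlation(img, q_step=0.05,
                                                    angle_step_deg=1.0)
        iq = np.argmin(np.abs(q - q0))
        assert valid[iq]
        row = corr[iq]
        # brute-force check of maxima positions
        found = []
        for k in range(0, 360, 60):
            window = [(k + d) % 360 for d in range(-10, 11)]
            found.append(delta[window][np.nanargmax(row[window])])
        for k, f in zip(range(0, 360, 60), found):
            assert min(abs(f - k), 360 - abs(f - k)) <= 2.0

    def test_correlation_symmetry(self):
        rng = np.random.default_rng(11)
        _, qmag, phi, _ = SMALL_DET.q_map()
        img = DetectorImage(
            intensity=rng.random(qmag.shape), q_mag=qmag, phi=phi,
            spec=SMALL_DET,
        )
        q, delta, corr, valid = angular_correlation(img, q_step=0.3,
                                                    angle_step_deg=1.0)
        row = corr[valid][1]
        mirrored = np.concatenate([row[:1], row[1:][::-1]])
        np.testing.assert_allclose(row, mirrored, rtol=1e-8)

    def test_empty_ring_flagged(self):
        _, qmag, phi, _ = SMALL_DET.q_map()
        img = DetectorImage(
            intensity=np.ones_like(qmag), q_mag=qmag, phi=phi,
            mask=np.zeros_like(qmag, dtype=bool), spec=SMALL_DET,
        )
        q, delta, corr, valid = angular_correlation(img, q_step=0.5,
                                                    angle_step_deg=5.0)
        assert not valid.any()


def test_image_h5_round_trip(tmp_path):
    img = simulate_pattern(np.zeros((1, 3)), np.array(["O"]), None, SMALL_DET)
    path = tmp_path / "img.h5"
    save_image_h5(img, path)
    back = load_image_h5(path)
    np.testing.assert_array_equal(back.intensity, img.intensity)
    np.testing.assert_array_equal(back.q_mag, img.q_mag)
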