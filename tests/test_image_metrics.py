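"""Profile fitting, pseudo-multiple-replica SNR/g-factor, compartment reports."""

import numpy as np
import pytest

from dantespace import image_metrics as im
from dantespace import phantom_synth as phs


def _gauss(x, amp, c, sigma, base):
    return amp * np.exp(-((x - c) ** 2) / (2 * sigma**2)) + base


@pytest.fixture(scope="module")
def small_setup():
    """32x32, 4-coil phantom setup for fast Monte Carlo tests."""
    spec = phs.PhantomSpec(matrix=(32, 32, 1), lumen_radius_mm=1.2, wall_thickness_mm=0.6,
                           csf_ring_mm=1.0)
    vol, masks, _ = phs.make_vessel_phantom(spec)
    coils = phs.make_coil_model(4, (32, 32), seed=21)
    cov = coils.noise_cov * (0.02**2)
    ksp = phs.fft2c(coils.sensitivities * vol[:, :, 0][None])
    obj = vol[:, :, 0] > 0.05
    return vol, masks, coils, cov, ksp, obj


class TestFitLineProfile:
    def test_recovers_noiseless_gaussian_sigma(self):
        x = np.arange(11, dtype=float)
        y = _gauss(x, 2.0, 5.3, 1.2, 0.1)
        fit = im.fit_line_profile(im.LineProfile(x, y))
        assert fit.sigma == pytest.approx(1.2, abs=1e-6)
        assert fit.fwhm_px == pytest.approx(2.3548 * 1.2, abs=1e-4)
        assert fit.center == pytest.approx(5.3, abs=1e-6)

    def test_offset_invariance(self):
        """Adding a constant shifts the baseline, not the width."""
        x = np.arange(9, dtype=float)
        y = _gauss(x, 1.5, 4.1, 0.9, 0.0)
        f0 = im.fit_line_profile(im.LineProfile(x, y))
        f1 = im.fit_line_profile(im.LineProfile(x, y + 0.7))
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-8)
        assert f1.baseline == pytest.approx(f0.baseline + 0.7, abs=1e-6)

    def test_edge_maximum_rejected(self):
        x = np.arange(7, dtype=float)
        y = np.exp(-x / 2.0)
        with pytest.raises(ValueError):
            im.fit_line_profile(im.LineProfile(x, y))

    def test_flat_profile_rejected(self):
        x = np.arange(7, dtype=float)
        with pytest.raises(ValueError):
            im.fit_line_profile(im.LineProfile(x, np.ones(7)))


class TestPseudoMultipleReplica:
    def test_r1_g_near_unity(self, small_setup):
        """Without acceleration the pseudo-replica noise matches the analytic
        reference, so g ~ 1 up to Monte Carlo tolerance."""
        _, _, coils, cov, ksp, obj = small_setup
        cfg = im.ReplicaConfig(n_replicas=256, seed=1)
        _, gmap = im.pseudo_multiple_replica(ksp, cov, 1, cfg)
        assert gmap.g[obj].mean() == pytest.approx(1.0, abs=0.05)

    def test_r2_sense_recon_matches_analytic_g(self, small_setup):
        """The Monte Carlo estimator with an unbiased SENSE unfolding agrees
        with the closed-form g-factor within 5% RMS over the object."""
        _, _, coils, cov, ksp, obj = small_setup
        cfg = im.ReplicaConfig(n_replicas=256, seed=2, method="sense")
        _, gmap = im.pseudo_multiple_replica(
            ksp, cov, 2, cfg, sensitivities=coils.sensitivities
        )
        gs = im.sense_g_factor(coils.sensitivities, cov, 2)
        rel = (gmap.g[obj] - gs[obj]) / gs[obj]
        assert np.sqrt((rel**2).mean()) < 0.05

    def test_replica_count_scaling(self, small_setup):
        """Quadrupling the replica count halves the spread of the g estimate."""
        _, _, coils, cov, ksp, obj = small_setup
        gs = im.sense_g_factor(coils.sensitivities, cov, 2)

        def spread(n_replicas, seed):
            cfg = im.ReplicaConfig(n_replicas=n_replicas, seed=seed, method="sense")
            _, gm = im.pseudo_multiple_replica(
                ksp, cov, 2, cfg, sensitivities=coils.sensitivities
            )
            return ((gm.g[obj] - gs[obj]) / gs[obj]).std()

        s_small = np.mean([spread(64, s) for s in (1, 2, 3)])
        s_large = np.mean([spread(256, s) for s in (4, 5, 6)])
        assert s_large < s_small
        assert s_large == pytest.approx(0.5 * s_small, rel=0.4)

    def test_g_at_least_one_for_unbiased_recon(self, small_setup):
        _, _, coils, cov, ksp, obj = small_setup
        cfg = im.ReplicaConfig(n_replicas=256, seed=3, method="sense")
        _, gmap = im.pseudo_multiple_replica(
            ksp, cov, 2, cfg, sensitivities=coils.sensitivities
        )
        assert gmap.g[obj].min() > 1 - 0.05

    def test_singular_covariance_rejected(self, small_setup):
        _, _, coils, cov, ksp, _ = small_setup
        with pytest.raises(np.linalg.LinAlgError):
            im.pseudo_multiple_replica(ksp, np.zeros_like(cov), 1)

    def test_too_few_replicas_rejected(self, small_setup):
        _, _, _, cov, ksp, _ = small_setup
        with pytest.raises(ValueError):
            im.pseudo_multiple_replica(ksp, cov, 1, im.ReplicaConfig(n_replicas=10))

    def test_snr_linearity(self, small_setup):
        """Scaling image and noise together leaves the SNR map unchanged."""
        _, _, coils, cov, ksp, obj = small_setup
        cfg = im.ReplicaConfig(n_replicas=128, seed=7)
        snr_a, _ = im.pseudo_multiple_replica(ksp, cov, 1, cfg)
        snr_b, _ = im.pseudo_multiple_replica(3.0 * ksp, 9.0 * cov, 1, cfg)
        np.testing.assert_allclose(snr_a[obj], snr_b[obj], rtol=1e-7)


class TestGRatio:
    def test_uniform_map_gives_unity(self):
        gmap = im.GFactorMap(g=np.ones((32, 32)), accel=2, n_replicas=64, seed=0)
        t = np.zeros((32, 32), dtype=bool)
        t[10:20, 10:20] = True
        n = im.corner_noise_mask((32, 32), 8)
        assert im.g_ratio(gmap, t, n) == 1.0

    def test_central_vessel_roi_gives_g_above_one(self):
        """At the protocol acceleration (R = 4) the FOV centre is the
        worst-conditioned region for perimeter coils, so a centred vessel ROI
        against a corner noise ROI yields G > 1; G equals the direct ratio of
        ROI means."""
        coils = phs.make_coil_model(8, (64, 64), seed=1)
        g = im.sense_g_factor(coils.sensitivities, coils.noise_cov, 4)
        gmap = im.GFactorMap(g=g, accel=4, n_replicas=0, seed=0)
        vessel = np.zeros((64, 64), dtype=bool)
        vessel[26:38, 26:38] = True
        noise = im.corner_noise_mask((64, 64), 8)
        G = im.g_ratio(gmap, vessel, noise)
        assert G > 1.0
        assert G == pytest.approx(g[vessel].mean() / g[noise].mean(), rel=1e-12)

    def test_empty_roi_raises(self):
        gmap = im.GFactorMap(g=np.ones((8, 8)), accel=1, n_replicas=64, seed=0)
        with pytest.raises(ValueError):
            im.g_ratio(gmap, np.zeros((8, 8), dtype=bool), np.ones((8, 8), dtype=bool))


class TestCompartmentReport:
    def _masks(self):
        wall = np.zeros((16, 16), dtype=bool)
        csf = np.zeros_like(wall)
        lumen = np.zeros_like(wall)
        wall[4:6, 4:12] = True
        csf[8:10, 4:12] = True
        lumen[12:14, 4:12] = True
        noise = im.corner_noise_mask((16, 16), 3)
        return {"wall": wall, "csf": csf, "lumen": lumen, "noise": noise}

    def test_equal_signals_zero_cnr_unit_sr(self):
        rng = np.random.default_rng(0)
        img = np.full((16, 16), 5.0)
        img += 0.01 * rng.standard_normal((16, 16))
        masks = self._masks()
        img[masks["wall"]] = 5.0
        img[masks["csf"]] = 5.0
        rep = im.compartment_report(img, masks, G=1.0)
        assert rep.cnr["wall/csf"] == pytest.approx(0.0, abs=1e-9)
        assert rep.sr["wall/csf"] == pytest.approx(1.0, abs=1e-9)

    def test_cnr_antisymmetry_and_eq3(self):
        """CNR_a/b = -CNR_b/a and SNR = S/(G sigma) hold by construction."""
        rng = np.random.default_rng(1)
        img = 0.1 * rng.standard_normal((16, 16))
        masks = self._masks()
        img[masks["wall"]] += 4.0
        img[masks["csf"]] += 2.5
        img[masks["lumen"]] += 1.0
        G = 1.3
        rep = im.compartment_report(img, masks, G=G)
        sigma = img[masks["noise"]].std()
        assert rep.snr["wall"] == pytest.approx(
            img[masks["wall"]].mean() / (G * sigma), rel=1e-12
        )
        assert rep.cnr["wall/csf"] == pytest.approx(
            -(rep.snr["csf"] - rep.snr["wall"]), rel=1e-12
        )

    def test_snr_scale_invariance(self):
        rng = np.random.default_rng(2)
        img = 0.1 * rng.standard_normal((16, 16)) + 1.0
        masks = self._masks()
        a = im.compartment_report(img, masks, G=1.1)
        b = im.compartment_report(7.0 * img, masks, G=1.1)
        for c in ("wall", "csf", "lumen"):
            assert a.snr[c] == pytest.approx(b.snr[c], rel=1e-12)

    def test_missing_or_empty_masks_raise(self):
        img = np.ones((16, 16))
        masks = self._masks()
        with pytest.raises(ValueError):
            im.compartment_report(img, {k: v for k, v in masks.items() if k != "csf"})
        masks["wall"] = np.zeros((16, 16), dtype=bool)
        with pytest.raises(ValueError):
            im.compartment_report(img, masks)
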