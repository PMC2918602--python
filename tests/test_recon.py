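import numpy as np
import pytest

from mousecmr.fourier import cfft2, cifft
from mousecmr.phantom import (PhantomConfig, default_noise_covariance,
                              make_heart_frame, simulate_coils,
                              time_averaged_frame)
from mousecmr.protocol import phase_encode_pattern
from mousecmr.recon import (NoiseStats, ReconError, estimate_sensitivities,
                            g_factor_map, noise_mask, sense_unfold,
                            sos_reference, reconstruct_cine)


def direct_least_squares(kspace, maps, pattern, n_pe):
    """Independent oracle: explicit stacked encoding matrix per readout
    column, solved with lstsq."""
    n_coils, n_samp, n_ro = kspace.shape
    proj = cifft(kspace, axis=-1)
    f = (np.asarray(pattern) - n_pe // 2)[:, None]
    y = (np.arange(n_pe) - n_pe // 2)[None, :]
    F = np.exp(-2j * np.pi * f * y / n_pe)
    out = np.empty((n_pe, n_ro), dtype=complex)
    for x in range(n_ro):
        E = np.concatenate([F * maps[c, :, x][None, :] for c in range(n_coils)])
        rhs = proj[:, :, x].reshape(-1)
        out[:, x] = np.linalg.lstsq(E, rhs, rcond=None)[0]
    return out


@pytest.fixture(scope="module")
def scene():
    cfg = PhantomConfig(matrix=48, n_slices=1, resp_amplitude_mm=0.0,
                        noise_sigma_image=0.0)
    coils = simulate_coils(4, 48, 25.0)
    frame = make_heart_frame(cfg, 0.3, 0.0, 0)
    ks = cfft2(coils.maps * frame[None])
    return cfg, coils, frame, ks


class TestSosReference:
    def test_single_coil(self):
        img = (np.random.default_rng(0).standard_normal((1, 8, 8))
               + 1j * np.random.default_rng(1).standard_normal((1, 8, 8)))
        mag, phase = sos_reference(img)
        assert np.allclose(mag, np.abs(img[0]))
        assert np.allclose(phase, np.angle(img[0]))

    def test_two_identical_coils_scale_sqrt2(self):
        img = np.ones((8, 8)) * (1 + 2j)
        mag, _ = sos_reference(np.stack([img, img]))
        assert np.allclose(mag, np.sqrt(2) * np.abs(img))

    def test_conjugate_pair_has_zero_phase(self):
        img = np.exp(1j * np.linspace(0, 1, 64)).reshape(8, 8)
        _, phase = sos_reference(np.stack([img, img.conj()]))
        assert np.allclose(phase, 0.0, atol=1e-12)


class TestNoiseMask:
    def test_threshold_formula(self):
        assert NoiseStats(mean=10.0, sd=2.0, factor=2.0).threshold == 14.0

    def test_pure_noise_mask_nearly_empty(self):
        rng = np.random.default_rng(5)
        mag = np.abs(rng.standard_normal((128, 128))
                     + 1j * rng.standard_normal((128, 128)))
        stats = NoiseStats(mean=float(mag.mean()), sd=float(mag.std()))
        frac = (mag > stats.threshold).mean()  # before connectivity cleanup
        assert frac < 0.05

    def test_bright_disc_mask_covers_disc_without_holes(self):
        rng = np.random.default_rng(6)
        img = 0.05 * np.abs(rng.standard_normal((64, 64)))
        yy, xx = np.indices(img.shape)
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 < 15 ** 2
        img[disc] += 1.0
        img[30:34, 30:34] = 0.0  # dark hole inside the object
        mask = noise_mask(img, NoiseStats(mean=0.04, sd=0.02))
        assert np.all(mask[disc])


class TestEstimateSensitivities:
    def test_noiseless_maps_recovered_inside_mask(self, scene):
        cfg, coils, _, _ = scene
        obj = time_averaged_frame(cfg, 0)
        imgs = coils.maps * obj[None]
        sm = estimate_sensitivities(imgs, NoiseStats(mean=0.005, sd=0.002),
                                    smooth_sigma=0.0, min_rel_signal=0.0)
        sos = np.sqrt((np.abs(coils.maps) ** 2).sum(axis=0))
        rel = coils.maps / (sos * np.exp(1j * np.angle(coils.maps.sum(axis=0))))
        err = np.abs(sm.maps - rel)[:, sm.mask]
        ref = np.abs(rel[:, sm.mask])
        assert np.sqrt((err ** 2).mean()) / np.sqrt((ref ** 2).mean()) < 0.01

    def test_uniform_single_coil_gives_unit_map(self):
        obj = np.zeros((32, 32))
        obj[8:24, 8:24] = 1.0
        sm = estimate_sensitivities(obj[None].astype(complex),
                                    NoiseStats(mean=0.01, sd=0.005),
                                    smooth_sigma=0.0)
        assert np.allclose(np.abs(sm.maps[0][sm.mask]), 1.0, atol=1e-9)
        assert np.allclose(np.angle(sm.maps[0][sm.mask]), 0.0, atol=1e-9)

    def test_maps_finite_everywhere_after_region_growing(self, scene):
        cfg, coils, _, _ = scene
        obj = time_averaged_frame(cfg, 0)
        sm = estimate_sensitivities(coils.maps * obj[None],
                                    NoiseStats(mean=0.005, sd=0.002))
        assert np.all(np.isfinite(sm.maps))

    def test_empty_mask_raises(self):
        with pytest.raises(ReconError):
            estimate_sensitivities(np.zeros((2, 16, 16), dtype=complex),
                                   NoiseStats(mean=1.0, sd=0.5))


class TestSenseUnfold:
    def test_full_sampling_identity(self, scene):
        _, coils, frame, ks = scene
        pat = phase_encode_pattern(48, 1)
        res = sense_unfold(ks[:, pat, :], coils.maps, pat, lam_rel=0.0)
        assert np.abs(res.image - frame).max() < 1e-10 * frame.max()

    @pytest.mark.parametrize("R", [2, 3])
    def test_integer_r_matches_direct_least_squares(self, scene, R):
        _, coils, frame, ks = scene
        pat = phase_encode_pattern(48, R)
        res = sense_unfold(ks[:, pat, :], coils.maps, pat, lam_rel=0.0)
        oracle = direct_least_squares(ks[:, pat, :], coils.maps, pat, 48)
        assert np.abs(res.image - oracle).max() < 1e-8 * np.abs(oracle).max()
        assert np.abs(res.image - frame).max() < 1e-8 * frame.max()

    def test_fractional_r_matches_direct_least_squares(self, scene):
        _, coils, frame, ks = scene
        pat = phase_encode_pattern(48, 1.5)
        res = sense_unfold(ks[:, pat, :], coils.maps, pat, lam_rel=0.0)
        oracle = direct_least_squares(ks[:, pat, :], coils.maps, pat, 48)
        assert np.abs(res.image - oracle).max() < 1e-8 * np.abs(oracle).max()

    def test_identical_coils_singular_then_regularized(self, scene):
        _, coils, frame, _ = scene
        same = np.stack([coils.maps[0], coils.maps[0]])
        ks = cfft2(same * frame[None])
        pat = phase_encode_pattern(48, 2)
        with pytest.raises(ReconError):
            sense_unfold(ks[:, pat, :], same, pat, lam_rel=0.0)
        res = sense_unfold(ks[:, pat, :], same, pat, lam_rel=1e-3)
        assert np.all(np.isfinite(res.image))

    def test_linearity(self, scene):
        _, coils, frame, ks = scene
        pat = phase_encode_pattern(48, 2)
        other = cfft2(coils.maps * np.roll(frame, 5, axis=0)[None])
        a, b = 1.7, -0.6 + 0.2j
        lhs = sense_unfold(a * ks[:, pat, :] + b * other[:, pat, :],
                           coils.maps, pat, lam_rel=1e-3).image
        rhs = (a * sense_unfold(ks[:, pat, :], coils.maps, pat, lam_rel=1e-3).image
               + b * sense_unfold(other[:, pat, :], coils.maps, pat,
                                  lam_rel=1e-3).image)
        assert np.abs(lhs - rhs).max() < 1e-8 * np.abs(rhs).max()

    def test_prewhitening_equivalence(self, scene):
        _, coils, frame, ks = scene
        pat = phase_encode_pattern(48, 2)
        psi = default_noise_covariance(4, sigma=1.5)
        res = sense_unfold(ks[:, pat, :], coils.maps, pat, psi=psi, lam_rel=0.0)
        # whiten data and maps externally, then solve with identity covariance
        white = np.linalg.inv(np.linalg.cholesky(psi))
        ksw = np.tensordot(white, ks[:, pat, :], axes=(1, 0))
        mw = np.tensordot(white, coils.maps, axes=(1, 0))
        ref = sense_unfold(ksw, mw, pat, psi=None, lam_rel=0.0)
        assert (np.abs(res.image - ref.image).max()
                < 1e-8 * np.abs(ref.image).max())


class TestGFactor:
    def test_unity_at_full_sampling(self, scene):
        _, coils, _, _ = scene
        g = g_factor_map(coils.maps, phase_encode_pattern(48, 1), 48)
        assert np.allclose(g, 1.0, atol=1e-9)

    def test_orthonormal_aliased_pair_gives_unity(self):
        # two pixels aliased at R=2, two coils with orthonormal columns
        maps = np.zeros((2, 2, 4), dtype=complex)
        maps[0, 0, :] = 1.0
        maps[1, 1, :] = 1.0
        g = g_factor_map(maps, np.array([1]), 2)
        assert np.allclose(g, 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("R", [2, 3])
    def test_g_never_below_one(self, seed, R):
        rng = np.random.default_rng(seed)
        coils = simulate_coils(4, 48, 25.0,
                               start_angle_deg=float(rng.uniform(0, 90)),
                               falloff_mm=float(rng.uniform(5, 12)))
        g = g_factor_map(coils.maps, phase_encode_pattern(48, R), 48)
        assert np.nanmin(g) >= 1.0 - 1e-6


class TestReconstructCine:
    def test_shapes_and_frame_count(self, gated64, coils64):
        series, _, binned = gated64
        cine = reconstruct_cine(binned, coils64.maps, None, series.protocol)
        assert cine.frames.shape == (10, 2, 64, 64)
        assert cine.g_maps.shape == (2, 64, 64)

    def test_round_trip_against_bin_center_truth(self, gated64, coils64,
                                                 phantom64):
        """Noiseless fully sampled gated recon matches the phantom at the
        bin-center phases (trigger sits at end-systole)."""
        series, assignment, binned = gated64
        cine = reconstruct_cine(binned, coils64.maps, None, series.protocol,
                                lam_rel=0.0, compute_g=False)
        hr = phantom64.heart_rate_bpm / 60000.0
        phi0 = np.angle(np.mean(np.exp(
            2j * np.pi * np.mod(assignment.cardiac_triggers_ms * hr, 1.0)
        ))) / (2 * np.pi) % 1.0
        errs = []
        for f in range(10):
            for s in range(2):
                truth = make_heart_frame(phantom64,
                                         (phi0 + (f + 0.5) / 10) % 1.0, 0.0, s)
                err = np.sqrt(np.mean((cine.frames[f, s] - truth) ** 2))
                errs.append(err / np.sqrt(np.mean(truth ** 2)))
        assert np.mean(errs) < 0.02
        assert np.max(errs) < 0.035

    def test_noise_amplification_follows_g_sqrt_r(self, scene):
        """SENSE noise propagation: pixel-noise SD ratio between R=3 and
        R=1 matches g*sqrt(3) in the well-conditioned central region."""
        _, coils, _, _ = scene
        psi = default_noise_covariance(4)
        rng = np.random.default_rng(11)
        pats = {R: phase_encode_pattern(48, R) for R in (1, 3)}
        draws = {R: [] for R in (1, 3)}
        for _ in range(48):
            noise = (rng.standard_normal((4, 48, 48))
                     + 1j * rng.standard_normal((4, 48, 48)))
            w, v = np.linalg.eigh(psi)
            root = (v * np.sqrt(w)) @ v.conj().T
            noise = np.tensordot(root, noise, axes=(1, 0))
            for R in (1, 3):
                res = sense_unfold(noise[:, pats[R], :], coils.maps, pats[R],
                                   psi=psi, lam_rel=0.0)
                draws[R].append(res.image)
        sd1 = np.std(np.stack(draws[1]), axis=0)
        sd3 = np.std(np.stack(draws[3]), axis=0)
        g = g_factor_map(coils.maps, pats[3], 48, psi)
        center = np.s_[14:34, 14:34]
        ratio = (sd3 / sd1)[center] / (g[center] * np.sqrt(3))
        # sqrt(3) also accounts for the 3x fewer acquired samples at R=3
        assert abs(np.median(ratio) - 1.0) < 0.15
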