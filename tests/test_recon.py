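import numpy as np
import pytest

from smslge.phantom import CoilMaps
from smslge.recon import (
    apply_grappa,
    build_acs,
    calibrate_grappa,
    coil_combine,
    partition_fov,
    partition_fov_multicoil,
    psir,
    reconstruct_shot,
)
from smslge.sms_encode import (
    KSpaceData,
    ProtocolParams,
    encode_sms,
    ifft2c,
    sampling_mask,
)


@pytest.fixture(scope="module")
def sms_reps(slice_images, coils8, sms_params):
    i1, i2 = slice_images
    return [
        encode_sms(i1, i2, coils8, sms_params, rep_index=r) for r in range(8)
    ]


@pytest.fixture(scope="module")
def singleband_refs(slice_images, coils8, full_params):
    """Fully sampled single-band reconstruction of each slice."""
    refs = []
    for img in slice_images:
        k = encode_sms(img, None, coils8, full_params, 0)
        mb1 = ProtocolParams(
            n_slices=2, multiband=1, inplane_accel=1, phase_oversampling=2.0,
            matrix=(64, 64),
        )
        refs.append(partition_fov_multicoil(k.data, coils8, mb1)[0])
    return refs


class TestBuildAcs:
    def test_r1_identity(self, slice_images, coils8, full_params):
        i1, i2 = slice_images
        k = encode_sms(i1, i2, coils8, full_params, 0)
        assert np.array_equal(build_acs([k]), k.data)

    def test_static_interleaves_merge_to_full(
        self, sms_reps, slice_images, coils8, full_params
    ):
        i1, i2 = slice_images
        full = encode_sms(i1, i2, coils8, full_params, 0)
        acs = build_acs(sms_reps)
        assert np.allclose(acs, full.data, atol=1e-12)

    def test_missing_offset_reported(self, sms_reps):
        with pytest.raises(ValueError, match=r"\[4\]"):
            build_acs(sms_reps[:4])


class TestCalibrateGrappa:
    def test_r1_passthrough(self, sms_reps):
        w = calibrate_grappa(build_acs(sms_reps), R=1)
        assert w.weights == {}

    def test_self_consistency_exactly_representable(self):
        """Point-source object with complex-exponential coils admits an exact
        shift-invariant predictor: held-out ACS lines reproduce < 1e-6."""
        ny, nx, nc = 60, 16, 8
        yy, xx = np.mgrid[0:ny, 0:nx]
        rng = np.random.default_rng(0)
        obj_k = np.exp(
            -2j * np.pi * (7 * yy / ny + 3 * xx / nx)
        )  # point source k-space
        coil_modes = [
            np.exp(2j * np.pi * (p * yy / ny + q * xx / nx))
            for p, q in [(0, 0), (1, 0), (-1, 0), (0, 1), (2, 0), (-2, 0),
                         (1, 1), (-1, 1)]
        ]
        acs = np.stack([obj_k * m for m in coil_modes])
        w = calibrate_grappa(acs, R=5, lam=1e-12)
        mask = sampling_mask(ny, 5, 0)
        und = acs.copy()
        und[:, ~mask, :] = 0
        k = KSpaceData(data=und, mask=mask, rep_index=0, R=5)
        filled = apply_grappa(k, w)
        interior = slice(10, ny - 10)
        err = np.linalg.norm(
            (filled - acs)[:, interior]
        ) / np.linalg.norm(acs[:, interior])
        assert err < 1e-6

    def test_singular_without_ridge(self):
        acs = np.zeros((2, 40, 8), complex)
        acs[:, 20, 4] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            calibrate_grappa(acs, R=2, lam=0.0)

    def test_underdetermined_flags_quality(self, sms_reps):
        acs = build_acs(sms_reps)[:1]  # 1 coil at R=2
        w = calibrate_grappa(acs, R=2)
        assert w.quality_flag

    def test_acs_too_short(self):
        acs = np.zeros((4, 10, 8), complex)
        with pytest.raises(ValueError, match="span"):
            calibrate_grappa(acs, R=5)


class TestApplyGrappa:
    def test_fully_sampled_unchanged(self, slice_images, coils8, full_params):
        i1, i2 = slice_images
        k = encode_sms(i1, i2, coils8, full_params, 0)
        w = calibrate_grappa(k.data, R=1)
        assert np.array_equal(apply_grappa(k, w), k.data)

    def test_zero_input_zero_output(self, sms_reps):
        w = calibrate_grappa(build_acs(sms_reps), R=5)
        z = KSpaceData(
            data=np.zeros_like(sms_reps[0].data),
            mask=sms_reps[0].mask.copy(),
            rep_index=0,
            R=5,
        )
        assert np.abs(apply_grappa(z, w)).max() == 0

    def test_sms_r5_fidelity(
        self, sms_reps, coils8, sms_params, singleband_refs
    ):
        """Accelerated recon within 5% NRMSE of the fully sampled single-band
        reference inside object support, for every repetition."""
        w = calibrate_grappa(build_acs(sms_reps), R=5)
        for rep in sms_reps:
            slices = reconstruct_shot(rep, w, coils8, sms_params)
            for s, ref in zip(slices, singleband_refs):
                sup = np.abs(ref) > 0.05 * np.abs(ref).max()
                nrmse = np.linalg.norm((s - ref)[sup]) / np.linalg.norm(
                    ref[sup]
                )
                assert nrmse < 0.05

    def test_r_mismatch(self, sms_reps):
        w = calibrate_grappa(build_acs(sms_reps), R=3)
        with pytest.raises(ValueError):
            apply_grappa(sms_reps[0], w)

    def test_noise_amplification_g_factor(
        self, slice_images, coils8, sms_params, full_params
    ):
        """Reconstructed noise SD at R=5 exceeds the R=1 SD on matched data
        (empirical g-factor >= 1, and within a physically plausible range)."""
        from smslge.sms_encode import add_noise

        i1, i2 = slice_images
        sigma = 0.003
        sds = {}
        for params in (full_params, sms_params):
            R = params.inplane_accel
            reps = [
                encode_sms(i1, i2, coils8, params, r) for r in range(max(R, 1))
            ]
            w = calibrate_grappa(build_acs(reps), R)
            clean = reconstruct_shot(reps[0], w, coils8, params)[0]
            sup = np.abs(clean) > 0.05 * np.abs(clean).max()
            resid = []
            for trial in range(3):
                noisy = add_noise(reps[0], sigma, seed=50 + trial)
                rec = reconstruct_shot(noisy, w, coils8, params)[0]
                resid.append(np.abs(rec - clean)[sup].std())
            sds[R] = np.mean(resid)
        ratio = sds[5] / sds[1]
        assert ratio >= 1.0
        assert ratio < 20.0  # sane amplification, not a pathological fit


class TestCoilCombine:
    def test_single_unit_coil_is_ifft(self):
        rng = np.random.default_rng(1)
        k = rng.normal(size=(1, 32, 32)) + 1j * rng.normal(size=(1, 32, 32))
        coils = CoilMaps(1, np.ones((1, 32, 32), complex))
        assert np.allclose(coil_combine(k, coils), ifft2c(k)[0], atol=1e-12)

    def test_round_trip_full_sampling(
        self, slice_images, coils8, full_params
    ):
        i1, _ = slice_images
        k = encode_sms(i1, None, coils8, full_params, 0)
        combined = coil_combine(k.data, coils8)
        y0 = (full_params.ny_ext - 64) // 2
        recovered = combined[y0 : y0 + 64]
        sup = np.abs(i1) > 1e-6
        err = np.linalg.norm((recovered - i1)[sup]) / np.linalg.norm(i1[sup])
        assert err < 1e-8

    def test_grid_mismatch(self, coils8):
        with pytest.raises(ValueError):
            coil_combine(np.zeros((2, 16, 16), complex), coils8)


class TestPartitionFov:
    def test_point_sources_recovered(self, unit_coils):
        ny, nx = 64, 64
        params = ProtocolParams(
            n_slices=2, multiband=2, inplane_accel=1, phase_oversampling=2.0,
            matrix=(ny, nx),
        )
        img1 = np.zeros((ny, nx), complex)
        img2 = np.zeros((ny, nx), complex)
        img1[10, 12] = 2.0
        img2[40, 50] = 1.5
        k = encode_sms(img1, img2, unit_coils, params, 0)
        composite = coil_combine(k.data, unit_coils)
        a, b = partition_fov(composite, params)
        assert np.allclose(a, img1, atol=1e-12)
        assert np.allclose(b, img2, atol=1e-12)

    def test_empty_second_slice(self, slice_images, coils8, full_params):
        i1, _ = slice_images
        k = encode_sms(i1, None, coils8, full_params, 0)
        _, b = partition_fov_multicoil(k.data, coils8, full_params)
        assert np.abs(b).max() < 1e-10 * np.abs(i1).max() + 1e-12

    def test_round_trip_stacking(self, unit_coils):
        """Stacking the partitioned bands per the shift convention rebuilds
        the composite."""
        ny, nx = 64, 64
        params = ProtocolParams(
            n_slices=2, multiband=2, inplane_accel=1, phase_oversampling=2.0,
            matrix=(ny, nx),
        )
        rng = np.random.default_rng(3)
        img1 = rng.normal(size=(ny, nx)) + 0j
        img2 = rng.normal(size=(ny, nx)) + 0j
        k = encode_sms(img1, img2, unit_coils, params, 0)
        composite = coil_combine(k.data, unit_coils)
        a, b = partition_fov(composite, params)
        rebuilt = np.zeros_like(composite)
        y0 = (params.ny_ext - ny) // 2
        rebuilt[y0 : y0 + ny] = a
        rebuilt += np.roll(
            np.pad(b, ((y0, y0), (0, 0))), params.ny_ext // 2, axis=0
        )
        assert np.allclose(rebuilt, composite, atol=1e-10)

    def test_multiband1_crop(self):
        params = ProtocolParams(
            n_slices=2, multiband=1, inplane_accel=1, phase_oversampling=1.2,
            matrix=(64, 64),
        )
        composite = np.arange(params.ny_ext * 64, dtype=float).reshape(
            params.ny_ext, 64
        )
        a, b = partition_fov(composite, params)
        assert b is None
        assert a.shape == (64, 64)


class TestPsir:
    def test_aligned_phase_positive(self):
        rng = np.random.default_rng(0)
        mag = rng.uniform(0.1, 1.0, (16, 16))
        phase = rng.uniform(-np.pi, np.pi, (16, 16))
        ir = mag * np.exp(1j * phase)
        ref = np.exp(1j * phase)
        out = psir(ir, ref)
        assert np.allclose(out.values, mag)

    def test_opposed_phase_negative(self):
        rng = np.random.default_rng(1)
        mag = rng.uniform(0.1, 1.0, (16, 16))
        phase = rng.uniform(-np.pi, np.pi, (16, 16))
        ir = mag * np.exp(1j * (phase + np.pi))
        ref = np.exp(1j * phase)
        out = psir(ir, ref)
        assert np.allclose(out.values, -mag)

    def test_magnitude_bound(self):
        rng = np.random.default_rng(2)
        ir = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        ref = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        out = psir(ir, ref)
        assert np.all(np.abs(out.values) <= np.abs(ir) + 1e-12)

    def test_background_forced_positive(self):
        ir = np.full((8, 8), -1.0 + 0j)
        ir[0, 0] = 1.0  # max reference magnitude lives elsewhere
        ref = np.zeros((8, 8), complex)
        ref[0, 0] = 1.0
        out = psir(ir, ref)
        assert out.values[1:, :].min() >= 0

    def test_tissue_polarity_through_pipeline(
        self, phantom_small, coils8, full_params
    ):
        """PSIR signs at tissue centroids match the closed-form IR signal."""
        from scipy import ndimage

        from smslge.phantom import LABEL_BLOOD, LABEL_MYOCARDIUM, LABEL_SCAR
        from smslge.phantom import render_single_shot, ir_signal

        ti = 270.0  # between scar/blood nulls and the myocardium null
        ir1 = render_single_shot(phantom_small, 0, ti)
        ref1 = render_single_shot(phantom_small, 0, None)
        k_ir = encode_sms(ir1, None, coils8, full_params, 0)
        k_ref = encode_sms(ref1, None, coils8, full_params, 0)
        img_ir = partition_fov_multicoil(k_ir.data, coils8, full_params)[0]
        img_ref = partition_fov_multicoil(k_ref.data, coils8, full_params)[0]
        out = psir(img_ir, img_ref)
        labels = phantom_small.labels[0]
        for label in (LABEL_BLOOD, LABEL_MYOCARDIUM, LABEL_SCAR):
            mask = ndimage.binary_erosion(labels == label, iterations=2)
            tissue = phantom_small.tissue_table[label]
            expected = np.sign(ir_signal(tissue, ti))
            assert np.sign(np.mean(out.values[mask])) == expected
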