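"""NIR misalignment estimation and correction."""

import numpy as np
import pytest

from canopyspec.errors import DegenerateImageError
from canopyspec.registration import (
    RegistrationTransform,
    apply_transform,
    estimate_affine,
    estimate_shift,
    register_stack,
    warp_raster,
)
from canopyspec.synthetic import Ellipse, SyntheticSceneSpec, generate_scene

from conftest import brute_force_integer_shift


def _scene(nir_shift=(0.0, 0.0), nir_affine=None, noise_sd=0.01, seed=0, size=128):
    spec = SyntheticSceneSpec(
        height=size,
        width=size,
        canopy=[Ellipse(size / 2, size / 2, size * 0.3, size * 0.3)],
        noise_sd=noise_sd,
        nir_shift=nir_shift,
        nir_affine=nir_affine,
        seed=seed,
    )
    return generate_scene(spec)


class TestEstimateShift:
    def test_identical_arrays_align_at_zero(self):
        stack, _ = _scene()
        red = stack.channel("red")
        t = estimate_shift(red, red, upsample=1)
        assert (t.dy, t.dx) == (0.0, 0.0)
        assert t.peak_confidence == pytest.approx(1.0)

    def test_integer_shift_matches_brute_force_oracle(self):
        stack, truth = _scene(nir_shift=(3.0, -5.0), seed=5)
        red, nir = stack.channel("red"), stack.channel("nir")
        t = estimate_shift(red, nir, upsample=1)
        assert (t.dy, t.dx) == (3.0, -5.0)
        assert brute_force_integer_shift(red, nir) == (3, -5)

    def test_subpixel_shift_recovered_within_tenth_pixel(self):
        stack, _ = _scene(nir_shift=(2.5, -1.25), noise_sd=0.0, seed=2)
        t = estimate_shift(stack.channel("red"), stack.channel("nir"), upsample=20)
        assert abs(t.dy - 2.5) <= 0.1
        assert abs(t.dx + 1.25) <= 0.1

    def test_zero_variance_input_rejected(self):
        flat = np.zeros((32, 32))
        varied = np.random.default_rng(0).random((32, 32))
        with pytest.raises(DegenerateImageError):
            estimate_shift(flat, varied)
        with pytest.raises(DegenerateImageError):
            estimate_shift(varied, flat)

    @pytest.mark.parametrize("dy,dx", [(1, 0), (0, -7), (10, 10), (-4, 6)])
    def test_recovery_across_shift_magnitudes(self, dy, dx):
        stack, _ = _scene(nir_shift=(float(dy), float(dx)), seed=abs(dy * 13 + dx))
        t = estimate_shift(stack.channel("red"), stack.channel("nir"), upsample=1)
        assert (t.dy, t.dx) == (dy, dx)


def _textured_scene(nir_shift=(0.0, 0.0), nir_affine=None, noise_sd=0.0, seed=0,
                    size=320, n_blobs=120, bit_depth=16):
    """Scene with blobs scattered across the frame: texture in every tile."""
    from canopyspec.synthetic import scattered_canopy

    spec = SyntheticSceneSpec(
        height=size,
        width=size,
        canopy=scattered_canopy(size, size, n_blobs=n_blobs, seed=seed + 40),
        noise_sd=noise_sd,
        nir_shift=nir_shift,
        nir_affine=nir_affine,
        bit_depth=bit_depth,
        seed=seed,
    )
    return generate_scene(spec)


class TestEstimateAffine:
    def test_identity_warp_fits_identity(self):
        stack, _ = _textured_scene(size=192, n_blobs=40)
        t = estimate_affine(stack.channel("red"), stack.channel("nir"), grid=4)
        assert np.allclose(t.full_matrix(), [[1, 0, 0], [0, 1, 0]], atol=1e-6)

    def test_known_affine_recovered(self):
        matrix = np.array([[1.02, 0.0, 4.0], [0.0, 1.02, 2.0]])
        stack, _ = _textured_scene(nir_affine=matrix, seed=9)
        t = estimate_affine(stack.channel("red"), stack.channel("nir"), grid=4)
        assert np.max(np.abs(t.matrix - matrix)) < 0.005

    def test_known_affine_recovered_under_noise(self):
        matrix = np.array([[1.02, 0.0, 4.0], [0.0, 1.02, 2.0]])
        stack, _ = _textured_scene(
            nir_affine=matrix, noise_sd=0.01, seed=3, size=256, n_blobs=80, bit_depth=8
        )
        t = estimate_affine(stack.channel("red"), stack.channel("nir"), grid=4)
        assert np.max(np.abs(t.matrix - matrix)) < 0.05

    def test_pure_translation_gives_negligible_off_diagonals(self):
        stack, _ = _textured_scene(
            nir_shift=(2.0, 3.0), noise_sd=0.005, seed=4, size=256, n_blobs=80
        )
        t = estimate_affine(stack.channel("red"), stack.channel("nir"), grid=4)
        assert abs(t.matrix[0, 1]) < 0.01
        assert abs(t.matrix[1, 0]) < 0.01
        shift = estimate_shift(stack.channel("red"), stack.channel("nir"))
        assert abs(t.matrix[0, 2] - shift.dy) < 0.5
        assert abs(t.matrix[1, 2] - shift.dx) < 0.5


class TestApplyTransform:
    def test_identity_transform_is_bitwise_identity(self, shifted_scene):
        stack, _ = shifted_scene
        out = apply_transform(stack, RegistrationTransform.identity("nir"))
        assert np.array_equal(out.channel("nir"), stack.channel("nir"))

    def test_round_trip_shift_within_interpolation_error(self):
        stack, _ = _scene(noise_sd=0.0)
        fwd = RegistrationTransform(dy=3.0, dx=-5.0, moving_channel="nir")
        back = RegistrationTransform(dy=-3.0, dx=5.0, moving_channel="nir")
        round_tripped = apply_transform(apply_transform(stack, fwd), back)
        original = stack.channel("nir")
        interior = ~round_tripped.invalid_mask()
        # crop a margin: the first warp zero-fills its frame edge
        interior[:8, :] = interior[-8:, :] = False
        interior[:, :8] = interior[:, -8:] = False
        dev = np.abs(round_tripped.channel("nir") - original)[interior]
        assert dev.max() < 0.02

    def test_integer_shift_exact_on_interior(self):
        stack, _ = _scene(noise_sd=0.0)
        t = RegistrationTransform(dy=3.0, dx=-5.0, moving_channel="nir")
        out = apply_transform(stack, t)
        nir = stack.channel("nir")
        # corrected(r, c) samples moving at (r + 3, c - 5): exact for integers
        assert np.array_equal(out.channel("nir")[10:-10, 10:-10], nir[13:-7, 5:-15])

    def test_other_channels_untouched(self, shifted_scene):
        stack, truth = shifted_scene
        out = apply_transform(stack, truth.injected_transform)
        for name in ("red", "green", "blue", "chlf"):
            assert np.array_equal(out.channel(name), stack.channel(name))

    def test_out_of_frame_pixels_zeroed_and_flagged(self):
        stack, _ = _scene(noise_sd=0.0)
        t = RegistrationTransform(dy=-10.0, dx=0.0, moving_channel="nir")
        out = apply_transform(stack, t)
        # correction samples the moving image at row - 10: the top rows
        # fall outside the moving frame
        assert np.all(out.invalid_mask()[:10, :])
        assert np.all(out.channel("nir")[:10, :] == 0.0)
        assert not out.invalid_mask()[10:, :].any()


class TestRegisterStack:
    def test_correction_restores_alignment(self, shifted_scene):
        stack, truth = shifted_scene
        registered, transform = register_stack(stack, mode="shift")
        assert transform.dy == pytest.approx(truth.injected_transform.dy, abs=0.1)
        assert transform.dx == pytest.approx(truth.injected_transform.dx, abs=0.1)
        # after correction, re-estimating finds (almost) nothing left
        residual = estimate_shift(
            registered.channel("red"), registered.channel("nir"), upsample=20
        )
        assert abs(residual.dy) < 0.2 and abs(residual.dx) < 0.2

    def test_noisy_integer_recovery_is_reliable(self):
        """Integer shifts up to +/-10 px recovered exactly despite sensor noise."""
        rng = np.random.default_rng(1234)
        hits = 0
        trials = 25
        for i in range(trials):
            dy, dx = (int(v) for v in rng.integers(-10, 11, size=2))
            stack, _ = _scene(
                nir_shift=(float(dy), float(dx)), noise_sd=0.02, seed=1000 + i
            )
            t = estimate_shift(stack.channel("red"), stack.channel("nir"), upsample=1)
            hits += (t.dy, t.dx) == (dy, dx)
        assert hits == trials

    def test_low_confidence_falls_back_to_identity(self):
        rng = np.random.default_rng(0)
        stack, _ = _scene(noise_sd=0.0)
        # replace NIR with unrelated noise: no credible alignment exists
        stack.channels["nir"] = rng.random(stack.shape)
        registered, transform = register_stack(stack, mode="shift")
        assert transform.is_identity
        assert np.array_equal(registered.channel("nir"), stack.channel("nir"))
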