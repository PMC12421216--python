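"""k-t kernel geometry, least-squares calibration, and interpolation.

The calibration is checked against an independently coded dense
normal-equations solver, and the interpolation against data constructed to
obey an exact shift-invariant k-t linear predictive model.
"""

import numpy as np
import pytest

from gastrokt.recon import (
    calibrate,
    enumerate_kernel_geometry,
    interpolate,
    kt_reconstruct,
    reconstruct_images,
)
from gastrokt.sampling import SamplingPattern, apply_mask
from gastrokt.types import KSpaceSeries


def _random_kspace(nkx=16, n_pe=16, n_slices=1, nt=6, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(nkx, n_pe, n_slices, nt)) + 1j * rng.normal(
        size=(nkx, n_pe, n_slices, nt)
    )
    return KSpaceSeries(
        v, np.ones((n_pe, n_slices, nt), bool), (1, 1, 1), np.arange(nt, dtype=float)
    )


def _model_kspace(nkx=16, n_pe=18, nt=6, mode=5, seed=0):
    """Separable k-space with exact k-t linear predictive structure.

    A single spatial harmonic (periodic in ky, matching the DFT convention)
    modulated by a temporal phasor: every sample is an exact fixed linear
    combination of any neighbour, so kernel interpolation must be exact.
    """
    rng = np.random.default_rng(seed)
    alpha = np.exp(2j * np.pi * mode / n_pe)
    beta = np.exp(1j * 0.5)
    f = rng.normal(size=nkx) + 1j * rng.normal(size=nkx)
    ky = np.arange(n_pe)
    t = np.arange(nt)
    v = (
        f[:, None, None, None]
        * (alpha**ky)[None, :, None, None]
        * (beta**t)[None, None, None, :]
    )
    return KSpaceSeries(v, np.ones((n_pe, 1, nt), bool), (1, 1, 1), t.astype(float))


def _oracle_weights(kspace, kernels):
    """Brute-force normal-equations solution for every calibrated kernel shape.

    Assembled with explicit loops over ACS targets, independent of the
    calibration code path.
    """
    data = kspace.values
    nkx, n_pe, n_slices, nt = data.shape
    acs = [r for r in range(n_pe) if kspace.mask[r].all()]
    w = kernels.kx_halfwidth
    taps = list(range(-w, w + 1))
    jobs = {}
    for phase in range(1, kernels.reduction):
        for t in range(nt):
            key = kernels.shape_for(phase, t, nt)
            jobs.setdefault(key, set()).add(t)
    out = {}
    for key, frames in jobs.items():
        sources = kernels.shapes[key]
        rows, b = [], []
        for ky in acs:
            if not all((ky + dky) in acs for dky, _ in sources):
                continue
            for t in sorted(frames):
                for kx in range(w, nkx - w):
                    for s in range(n_slices):
                        row = [
                            data[kx + dkx, ky + dky, s, t + dt]
                            for (dky, dt) in sources
                            for dkx in taps
                        ]
                        rows.append(row)
                        b.append(data[kx, ky, s, t])
        A = np.asarray(rows)
        b = np.asarray(b)
        out[key] = np.linalg.solve(A.conj().T @ A, A.conj().T @ b)
    return out


class TestGeometry:
    @pytest.mark.parametrize("reduction, n_shapes", [(2, 1), (3, 2), (4, 3)])
    def test_one_shape_per_missing_phase(self, reduction, n_shapes):
        kset = enumerate_kernel_geometry(reduction)
        assert len(kset.shapes) == n_shapes

    def test_r4_shapes_have_enough_sources(self):
        kset = enumerate_kernel_geometry(4)
        for key, sources in kset.shapes.items():
            assert len(sources) >= 4
            assert len({dt for _, dt in sources}) >= 2

    def test_r1_rejected(self):
        with pytest.raises(ValueError):
            enumerate_kernel_geometry(1)

    def test_max_dky_prunes_span(self):
        kset = enumerate_kernel_geometry(11, max_dky=5)
        for sources in kset.shapes.values():
            assert max(abs(dky) for dky, _ in sources) <= 5


class TestCalibration:
    def test_oracle_equivalence_on_toy_dataset(self):
        """lstsq weights match dense normal equations to 1e-8 relative."""
        full = _random_kspace(16, 16, 1, 6)
        und = apply_mask(full, SamplingPattern(n_pe=16, n_acs=6, reduction=3))
        geo = enumerate_kernel_geometry(3, kx_halfwidth=1, max_dky=2)
        kernels, report = calibrate(und, geo)
        oracle = _oracle_weights(und, kernels)
        for key, w in kernels.weights.items():
            ref = oracle[key]
            rel = np.linalg.norm(w.ravel() - ref) / np.linalg.norm(ref)
            assert rel < 1e-8, f"kernel {key}: relative deviation {rel}"
            assert report.n_equations[key] >= w.size

    def test_exact_model_zero_residual(self):
        und = apply_mask(_model_kspace(), SamplingPattern(n_pe=18, n_acs=6, reduction=3))
        geo = enumerate_kernel_geometry(3, kx_halfwidth=0, max_dky=2)
        _, report = calibrate(und, geo)
        assert all(r < 1e-10 for r in report.residuals.values())

    def test_duplicated_equations_leave_weights_unchanged(self):
        full = _random_kspace(16, 16, 1, 6, seed=2)
        und = apply_mask(full, SamplingPattern(n_pe=16, n_acs=6, reduction=3))
        # duplicating every slice duplicates every fit equation
        doubled = KSpaceSeries(
            np.concatenate([und.values, und.values], axis=2),
            np.concatenate([und.mask, und.mask], axis=1),
            und.voxel_size,
            und.frame_times,
        )
        geo = enumerate_kernel_geometry(3, kx_halfwidth=1, max_dky=2)
        k1, _ = calibrate(und, geo)
        k2, _ = calibrate(doubled, geo)
        for key in k1.weights:
            np.testing.assert_allclose(k1.weights[key], k2.weights[key], atol=1e-10)

    def test_underdetermined_system_raises(self):
        und = apply_mask(
            _random_kspace(6, 16, 1, 2), SamplingPattern(n_pe=16, n_acs=6, reduction=3)
        )
        geo = enumerate_kernel_geometry(3, kx_halfwidth=2, max_dky=2)
        with pytest.raises(ValueError, match="(underdetermined|temporal)"):
            calibrate(und, geo)


class TestInterpolation:
    def test_exact_recovery_of_model_data(self):
        full = _model_kspace()
        und = apply_mask(full, SamplingPattern(n_pe=18, n_acs=6, reduction=3))
        geo = enumerate_kernel_geometry(3, kx_halfwidth=0, max_dky=2)
        kernels, _ = calibrate(und, geo)
        filled = interpolate(und, kernels)
        re = np.linalg.norm(filled.values - full.values) / np.linalg.norm(full.values)
        assert re < 1e-8

    def test_data_consistency(self):
        full = _random_kspace(16, 18, 2, 6)
        und = apply_mask(full, SamplingPattern(n_pe=18, n_acs=6, reduction=3))
        geo = enumerate_kernel_geometry(3, kx_halfwidth=1, max_dky=2)
        kernels, _ = calibrate(und, geo)
        filled = interpolate(und, kernels)
        sampled = und.mask[None, :, :, :]
        np.testing.assert_array_equal(
            np.broadcast_to(sampled, filled.values.shape) * filled.values,
            np.broadcast_to(sampled, und.values.shape) * und.values,
        )
        assert filled.mask.all()

    def test_fully_sampled_input_passthrough(self):
        full = _random_kspace()
        img, report = kt_reconstruct(full, reduction=1)
        assert not report.residuals
        np.testing.assert_allclose(
            img.values,
            np.abs(np.fft.ifft2(np.fft.ifftshift(full.values, axes=(0, 1)), axes=(0, 1))),
        )


class TestReconstructImages:
    def test_round_trip_from_phantom(self, static_tube):
        from gastrokt.phantom import phantom_to_kspace

        series, _ = static_tube
        img = reconstruct_images(phantom_to_kspace(series))
        assert np.abs(img.values - series.values).max() < 1e-10

    def test_zero_kspace_gives_zero_image(self):
        k = KSpaceSeries(
            np.zeros((8, 8, 1, 2), complex), np.ones((8, 1, 2), bool), (1, 1, 1), [0.0, 1.0]
        )
        assert np.all(reconstruct_images(k).values == 0)

    def test_single_dc_sample_gives_constant_image(self):
        v = np.zeros((8, 8, 1, 1), complex)
        v[4, 4, 0, 0] = 64.0
        k = KSpaceSeries(v, np.ones((8, 1, 1), bool), (1, 1, 1), [0.0])
        img = reconstruct_images(k)
        np.testing.assert_allclose(img.values, 1.0)

    def test_unfilled_kspace_rejected(self):
        full = _random_kspace()
        und = apply_mask(full, SamplingPattern(n_pe=16, n_acs=6, reduction=3))
        with pytest.raises(ValueError, match="unfilled"):
            reconstruct_images(und)


class TestEndToEnd:
    def test_per_slice_option_runs(self):
        full = _random_kspace(16, 18, 2, 6)
        und = apply_mask(full, SamplingPattern(n_pe=18, n_acs=6, reduction=3))
        img, report = kt_reconstruct(und, reduction=3, n_acs=6, kx_halfwidth=1, per_slice=True)
        assert img.shape == (16, 18, 2, 6)
        assert report.residuals

    def test_degradation_ordering_on_phantom(self, default_phantom, recon_by_reduction):
        """More aggressive undersampling cannot improve fidelity (R = 2, 3, 11)."""
        from gastrokt.quality import evaluate

        series, _ = default_phantom
        res = {r: evaluate(img, series) for r, (img, _) in recon_by_reduction.items()}
        assert res[2].re <= res[3].re <= res[11].re
        assert res[2].ssim >= res[3].ssim >= res[11].ssim
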