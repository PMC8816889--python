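"""Degradation transform: reslicing, noise cascade, moments, fitting."""

import numpy as np
import pytest

from lofisim.transform import (
    FitConfig,
    TransformParams,
    apply_lf_transform,
    fit_transform_params,
    histogram_moments,
    reslice,
    reslice_labels,
)
from lofisim.volume import LabelMap, Volume


def _toy_volume(shape=(32, 32, 8), spacing=(1.0, 1.0, 5.0), seed=0, masked=True):
    rng = np.random.default_rng(seed)
    data = 1.0 + 0.2 * rng.standard_normal(shape)
    mask = np.zeros(shape, dtype=bool)
    mask[4:-4, 4:-4, 1:-1] = True
    data[~mask] = 0.0
    return Volume(data, spacing, mask if masked else None)


class TestReslice:
    def test_identity_when_target_equals_input_spacing(self):
        vol = _toy_volume()
        out = reslice(vol, vol.spacing_mm)
        assert np.array_equal(out.data, vol.data)
        assert out.shape == vol.shape

    def test_output_shape_covers_physical_extent(self):
        vol = Volume(np.zeros((120, 120, 120)), (1.0, 1.0, 1.0))
        out = reslice(vol, (1.6, 1.6, 5.0))
        assert out.shape == (75, 75, 24)  # ceil(120/1.6), ceil(120/5)

    def test_constant_volume_stays_constant(self):
        vol = Volume(np.full((40, 40, 10), 3.7), (1.0, 1.0, 2.0))
        out = reslice(vol, (1.6, 1.6, 5.0))
        assert np.allclose(out.data, 3.7)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            reslice(_toy_volume(), (1.6, 0.0, 5.0))

    def test_labels_resliced_nearest_neighbor_stay_integer(self):
        labels = LabelMap(np.random.default_rng(0).integers(0, 4, (40, 40, 10)), (1.0, 1.0, 2.0))
        out = reslice_labels(labels, (1.6, 1.6, 5.0))
        assert out.labels.dtype.kind == "i"
        assert set(np.unique(out.labels)) <= set(np.unique(labels.labels))


class TestApplyLfTransform:
    def test_identity_parameters_return_input(self):
        vol = _toy_volume()
        out = apply_lf_transform(vol, TransformParams(0.0, 0.0, 0.0, 0.0), seed=1)
        assert np.allclose(out.data, vol.data)

    def test_missing_mask_is_an_error(self):
        vol = _toy_volume(masked=False)
        with pytest.raises(ValueError, match="mask"):
            apply_lf_transform(vol, TransformParams(0.1, 1.0, 0.1, 1.0), seed=0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            TransformParams(-0.1, 1.0, 0.1, 1.0)

    def test_background_stays_exactly_zero(self):
        vol = _toy_volume()
        out = apply_lf_transform(vol, TransformParams(0.5, 2.0, 0.3, 1.0), seed=3)
        assert not out.data[~vol.mask].any()

    def test_seeded_determinism(self):
        vol = _toy_volume()
        p = TransformParams(0.3, 1.5, 0.2, 1.0)
        assert np.array_equal(
            apply_lf_transform(vol, p, seed=9).data, apply_lf_transform(vol, p, seed=9).data
        )

    def test_first_noise_field_variance_matches_monte_carlo(self):
        """Variance of amplitude * presmoothed(eps) tracks amplitude^2 *
        var(presmoothed(eps)) estimated over independent seeds."""
        from scipy import ndimage

        shape = (40, 40, 12)
        mask = np.ones(shape, dtype=bool)
        base = Volume(np.zeros(shape), (1.6, 1.6, 5.0), mask)
        amp = 0.37
        p = TransformParams(amp, 0.0, 0.0, 0.0)
        var_field = np.mean(
            [apply_lf_transform(base, p, seed=s).data.var() for s in range(50)]
        )
        rng = np.random.default_rng(12345)
        var_ref = np.mean(
            [
                ndimage.gaussian_filter(rng.standard_normal(shape), 0.5).var()
                for _ in range(50)
            ]
        )
        assert var_field == pytest.approx(amp**2 * var_ref, rel=0.05)


class TestHistogramMoments:
    def test_constant_in_mask_intensity(self):
        data = np.full((10, 10, 3), 4.2)
        mask = np.ones_like(data, dtype=bool)
        m = histogram_moments(Volume(data, (1, 1, 1), mask))
        assert (m.mean, m.sd, m.skewness) == (4.2, 0.0, 0.0)
        assert m.degenerate

    def test_three_point_hand_computation(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = np.ones_like(data, dtype=bool)
        m = histogram_moments(Volume(data, (1, 1, 1), mask))
        assert m.mean == pytest.approx(2.0)
        assert m.sd == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)  # population sd
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_distribution_has_near_zero_skewness(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(30, 30, 10))
        mask = np.ones_like(data, dtype=bool)
        m = histogram_moments(Volume(data, (1, 1, 1), mask))
        assert abs(m.skewness) < 0.1

    def test_requires_mask(self):
        with pytest.raises(ValueError):
            histogram_moments(Volume(np.ones((4, 4, 4)), (1, 1, 1)))


class TestFit:
    def _pair(self, theta, seed=0):
        vol = _toy_volume(shape=(36, 36, 10), spacing=(1.6, 1.6, 5.0), seed=seed)
        target = apply_lf_transform(vol, theta, seed=seed + 100)
        return vol, target

    def test_moments_self_consistent_at_generating_parameters(self):
        # a re-simulation with the true parameters reproduces the target's
        # moments up to noise-realization variance
        theta = TransformParams(0.3, 2.0, 0.2, 1.0)
        hf, lf = self._pair(theta)
        sim = apply_lf_transform(hf, theta, seed=7)
        a, b = histogram_moments(sim), histogram_moments(lf)
        assert a.mean == pytest.approx(b.mean, abs=0.05)
        assert a.sd == pytest.approx(b.sd, rel=0.10)
        assert a.skewness == pytest.approx(b.skewness, abs=0.2)

    def test_trace_is_monotone_non_increasing(self):
        theta = TransformParams(0.3, 2.0, 0.2, 1.0)
        pairs = [self._pair(theta)]
        res = fit_transform_params(
            pairs, FitConfig(seed=2, n_starts=2, maxiter=40, n_realizations=2, normalization="none")
        )
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-15).all()

    def test_fit_is_deterministic_under_fixed_seed(self):
        theta = TransformParams(0.3, 2.0, 0.2, 1.0)
        pairs = [self._pair(theta)]
        cfg = FitConfig(seed=5, n_starts=1, maxiter=25, n_realizations=2, normalization="none")
        r1 = fit_transform_params(pairs, cfg)
        r2 = fit_transform_params(pairs, cfg)
        assert r1.params == r2.params
        assert r1.objective == r2.objective

    def test_objective_invariant_to_global_rescaling_of_pairs(self):
        theta = TransformParams(0.3, 2.0, 0.2, 1.0)
        hf, lf = self._pair(theta)
        cfg = FitConfig(seed=3, n_starts=1, maxiter=10, n_realizations=2)
        r1 = fit_transform_params([(hf, lf)], cfg)
        r2 = fit_transform_params(
            [(hf.with_data(hf.data * 2.0), lf.with_data(lf.data * 2.0))], cfg
        )
        assert r1.objective == pytest.approx(r2.objective, rel=1e-9)
        assert r1.params == r2.params

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_transform_params([], FitConfig())
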