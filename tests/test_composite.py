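import numpy as np
import pytest

from rseikit import (
    ConfigurationError,
    DegenerateDataError,
    IndicatorRaster,
    build_index,
    compute_indicators,
    make_indicator_stack,
    normalize01,
    normalize_stack,
    orient_pc1,
    pca,
    pca_report,
)


def _indicator(name, values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return IndicatorRaster(name, values, valid)


def _normalized_stack_from_matrix(X, names=("NDVI", "WET", "NDSI", "DI")):
    """IndicatorStack whose joint-valid pixels reproduce matrix X (n, k)."""
    n, k = X.shape
    inds = [_indicator(names[j], X[:, j].reshape(n, 1)) for j in range(k)]
    stack = make_indicator_stack(inds)
    stack.normalized = True
    return stack


def brute_force_pca(X):
    """Independent oracle: two-pass population covariance + generic eig."""
    n, k = X.shape
    mu = [sum(X[:, j]) / n for j in range(k)]
    cov = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            cov[a, b] = sum((X[i, a] - mu[a]) * (X[i, b] - mu[b]) for i in range(n)) / n
    eigvals, eigvecs = np.linalg.eig(cov)
    order = np.argsort(eigvals.real)[::-1]
    return eigvals.real[order], eigvecs.real[:, order], cov


class TestNormalize01:
    def test_hand_values(self):
        out = normalize01(_indicator("X", [[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_idempotent_at_extremes(self):
        vals = [[0.0, 0.25, 1.0]]
        out = normalize01(_indicator("X", vals))
        np.testing.assert_allclose(out.values, vals)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        ind = _indicator("X", rng.normal(size=(6, 6)))
        once = normalize01(ind)
        twice = normalize01(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-15)

    def test_constant_raster_degenerate(self):
        with pytest.raises(DegenerateDataError):
            normalize01(_indicator("X", np.full((3, 3), 1.7)))


class TestPca:
    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(42)
        X = rng.random((400, 4))
        stack = _normalized_stack_from_matrix(X)
        result = pca(stack)
        ev, vecs, _ = brute_force_pca(X)
        np.testing.assert_allclose(result.eigenvalues, ev, atol=1e-10)
        for j in range(4):
            dot = abs(np.dot(result.loadings[:, j], vecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            result.contribution_rates, 100.0 * ev / ev.sum(), atol=1e-9
        )

    def test_loadings_orthonormal_and_contributions_sum(self):
        rng = np.random.default_rng(1)
        stack = _normalized_stack_from_matrix(rng.random((200, 4)))
        result = pca(stack)
        np.testing.assert_allclose(
            result.loadings.T @ result.loadings, np.eye(4), atol=1e-12
        )
        assert result.contribution_rates.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)
        assert np.all(result.eigenvalues >= 0)

    def test_duplicated_indicators_get_equal_loadings(self):
        rng = np.random.default_rng(2)
        base = rng.random(300)
        other = rng.random((300, 2))
        X = np.column_stack([base, base, other])
        result = pca(_normalized_stack_from_matrix(X))
        assert result.loadings[0, 0] == pytest.approx(result.loadings[1, 0], abs=1e-10)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(DegenerateDataError):
            pca(_normalized_stack_from_matrix(np.random.default_rng(0).random((4, 4))))

    def test_unnormalized_stack_rejected(self):
        rng = np.random.default_rng(3)
        stack = _normalized_stack_from_matrix(rng.random((50, 4)))
        stack.normalized = False
        with pytest.raises(ConfigurationError):
            pca(stack)


class TestOrientPc1:
    def _result(self, ndvi_loading, wet_loading=0.1):
        rng = np.random.default_rng(4)
        stack = _normalized_stack_from_matrix(rng.random((100, 4)))
        result = pca(stack)
        result.loadings[:, 0] = [ndvi_loading, wet_loading, -0.3, -0.4]
        return result

    def test_negative_ndvi_loading_flips(self):
        result = self._result(-0.8)
        scores_before = result.pc1_raster.copy()
        out = orient_pc1(result)
        assert out.loadings[0, 0] == pytest.approx(0.8)
        np.testing.assert_allclose(
            out.pc1_raster[out.valid_mask], -scores_before[result.valid_mask]
        )
        assert out.oriented

    def test_positive_ndvi_loading_unchanged(self):
        result = self._result(0.7)
        scores_before = result.pc1_raster.copy()
        out = orient_pc1(result)
        assert out.loadings[0, 0] == pytest.approx(0.7)
        np.testing.assert_allclose(
            out.pc1_raster[out.valid_mask], scores_before[result.valid_mask]
        )

    def test_zero_ndvi_ties_break_on_wet(self):
        result = self._result(0.0, wet_loading=-0.5)
        out = orient_pc1(result)
        assert out.loadings[1, 0] == pytest.approx(0.5)


class TestBuildIndex:
    def test_output_spans_unit_interval(self, default_scene):
        _, stack, _ = default_scene
        index, _ = build_index(compute_indicators(stack, "DRSEI"), "DRSEI")
        vals = index.values[index.valid_mask]
        assert vals.min() == 0.0 and vals.max() == 1.0

    def test_sign_pattern_on_synthetic_scene(self, default_scene):
        _, stack, _ = default_scene
        _, result = build_index(compute_indicators(stack, "DRSEI"), "DRSEI")
        signs = [np.sign(result.loading(n)) for n in ("NDVI", "WET", "NDSI", "DI")]
        assert signs == [1.0, 1.0, -1.0, -1.0]

    def test_substitution_identity_di_equals_lst(self):
        rng = np.random.default_rng(6)
        shared = rng.random((8, 8, 4))
        names_d = ("NDVI", "WET", "NDSI", "DI")
        names_r = ("NDVI", "WET", "NDSI", "LST")
        inds_d = [_indicator(n, shared[:, :, j]) for j, n in enumerate(names_d)]
        inds_r = [_indicator(n, shared[:, :, j]) for j, n in enumerate(names_r)]
        idx_d, _ = build_index(make_indicator_stack(inds_d), "DRSEI")
        idx_r, _ = build_index(make_indicator_stack(inds_r), "RSEI")
        np.testing.assert_allclose(idx_d.values, idx_r.values, equal_nan=True)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        raw = rng.random((10, 10, 4))
        names = ("NDVI", "WET", "NDSI", "DI")
        inds = [_indicator(n, raw[:, :, j]) for j, n in enumerate(names)]
        idx_a, _ = build_index(make_indicator_stack(inds), "DRSEI")
        rescaled = [
            _indicator(n, 3.0 * raw[:, :, j] + 11.0 if n == "NDSI" else raw[:, :, j])
            for j, n in enumerate(names)
        ]
        idx_b, _ = build_index(make_indicator_stack(rescaled), "DRSEI")
        np.testing.assert_allclose(idx_a.values, idx_b.values, atol=1e-9, equal_nan=True)

    def test_wrong_indicator_set_rejected(self, default_scene):
        _, stack, _ = default_scene
        with pytest.raises(ConfigurationError):
            build_index(compute_indicators(stack, "DRSEI"), "RSEI")

    def test_index_tracks_ground_truth(self, default_scene):
        _, stack, truth = default_scene
        index, _ = build_index(compute_indicators(stack, "DRSEI"), "DRSEI")
        q = truth.quality[index.valid_mask]
        v = index.values[index.valid_mask]
        r = np.corrcoef(q, v)[0, 1]
        assert r > 0.8

    def test_report_layout(self, default_scene):
        _, stack, _ = default_scene
        _, result = build_index(compute_indicators(stack, "DRSEI"), "DRSEI")
        row = pca_report(result, "DRSEI", scene="seed7")
        assert set(row) == {"scene", "model", "contribution_pc1", "loading_NDVI",
                            "loading_WET", "loading_NDSI", "loading_DI"}
        assert 0 < row["contribution_pc1"] <= 100


class TestNormalizeStack:
    def test_unit_interval_on_joint_mask(self, default_scene):
        _, stack, _ = default_scene
        normed = normalize_stack(compute_indicators(stack, "DRSEI"))
        for ind in normed.indicators:
            vals = ind.values[normed.joint_valid_mask]
            assert vals.min() == 0.0 and vals.max() == 1.0
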