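import numpy as np
import pytest

from glcm_oracle import brute_force_glcm_stats
from wheatlai.raster import Affine, Raster
from wheatlai.texture import (GLCMConfig, STAT_NAMES, TextureIndexDef,
                              TextureStack, _window_stats_block,
                              compute_texture_index, enumerate_texture_indices,
                              evaluate_index, glcm_raster, glcm_statistics,
                              quantize_band, texture_stack)


def _raster(vals):
    vals = np.asarray(vals, dtype=float)
    return Raster(vals, Affine.from_origin(0, vals.shape[0] * 0.1, 0.1, 0.1))


class TestQuantize:
    def test_endpoints_map_to_extremes(self):
        q = quantize_band(_raster([[0.0, 1.0]]), levels=64)
        assert q.values.tolist() == [[0.0, 63.0]]

    def test_two_levels_threshold_at_midpoint(self):
        ramp = np.linspace(0, 1, 100).reshape(1, -1)
        q = quantize_band(_raster(ramp), levels=2).values.ravel()
        assert np.all(q[ramp.ravel() < 0.5] == 0)
        assert np.all(q[ramp.ravel() > 0.5] == 1)

    def test_midpoint_value_rounds_down(self):
        q = quantize_band(_raster([[0.0, 0.5, 1.0]]), levels=64)
        assert q.values.tolist() == [[0.0, 31.0, 63.0]]

    def test_constant_raster_rejected(self):
        with pytest.raises(ValueError):
            quantize_band(_raster([[1.0, 1.0]]), levels=4)

    def test_nan_preserved(self):
        q = quantize_band(_raster([[0.0, np.nan, 1.0]]), levels=8)
        assert np.isnan(q.values[0, 1])


class TestGlcmStatistics:
    def test_constant_window_degenerate_values(self):
        s = glcm_statistics(np.zeros((3, 3)), GLCMConfig(levels=2))
        assert s["CON"] == 0 and s["DIS"] == 0 and s["ENT"] == 0
        assert s["SEC"] == 1 and s["HOM"] == 1

    def test_hand_enumerated_window(self):
        # 6 directed pairs {(0,0)x1, (0,1)x2, (1,1)x3}, symmetrized
        win = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float)
        s = glcm_statistics(win, GLCMConfig(levels=2, offset=(1, 0)))
        assert s["CON"] == pytest.approx(1 / 3, abs=1e-12)
        assert s["SEC"] == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_oracle(self, rng, symmetric):
        offsets = [(1, 0), (0, 1), (1, 1), (1, -1), (2, 1)]
        for _ in range(60):
            w = int(rng.choice([3, 5, 7]))
            levels = int(rng.integers(2, 9))
            off = offsets[int(rng.integers(len(offsets)))]
            if max(abs(off[0]), abs(off[1])) >= w:
                off = (1, 1)
            cfg = GLCMConfig(window=w, levels=levels, offset=off,
                             symmetric=symmetric)
            win = rng.integers(0, levels, (w, w)).astype(float)
            got = glcm_statistics(win, cfg)
            expect = brute_force_glcm_stats(win, levels, off, symmetric)
            fast = _window_stats_block(win[None, None], cfg)
            for k in STAT_NAMES:
                assert got[k] == pytest.approx(expect[k], abs=1e-12), k
                assert float(fast[k][0, 0]) == pytest.approx(expect[k],
                                                             abs=1e-12), k

    def test_probability_bounds_on_random_windows(self, rng):
        cfg = GLCMConfig(levels=8)
        for _ in range(50):
            win = rng.integers(0, 8, (3, 3)).astype(float)
            s = glcm_statistics(win, cfg)
            assert 0 < s["SEC"] <= 1
            assert 0 < s["HOM"] <= 1
            assert s["ENT"] >= 0
            assert -1 <= s["COR"] <= 1

    def test_all_nan_window_is_nodata(self):
        s = glcm_statistics(np.full((3, 3), np.nan), GLCMConfig(levels=2))
        assert all(np.isnan(v) for v in s.values())

    def test_bad_configs_rejected(self):
        for kwargs in (dict(window=2), dict(window=3, levels=1),
                       dict(offset=(0, 0)), dict(window=3, offset=(3, 0))):
            with pytest.raises(ValueError):
                GLCMConfig(**kwargs)


class TestTextureStack:
    def test_thirty_two_layers(self, small_stack):
        assert len(small_stack.layers) == 32
        multi = small_stack.to_raster()
        assert multi.count == 32
        assert multi.band_names[0] == "G_MEA"

    def test_constant_band_flat_texture(self):
        r = _raster(np.full((9, 9), 0.4))
        stats = glcm_raster(r)
        interior = (slice(1, -1), slice(1, -1))
        assert np.all(stats["MEA"].values[interior] == 0.0)
        assert np.all(stats["CON"].values[interior] == 0.0)
        assert np.all(np.isnan(stats["CON"].values[0]))  # border nodata

    def test_perturbation_locality(self):
        vals = np.full((15, 15), 0.2)
        vals[7, 7] = 0.9
        con = glcm_raster(_raster(vals))["CON"].values
        hot = np.argwhere(con > 0)
        # CON is affected only within window+offset reach of the perturbed
        # pixel: |dr|,|dc| <= half-window + offset = 2
        assert hot.size > 0
        assert np.all(np.abs(hot - 7).max(axis=1) <= 2)

    def test_stack_agrees_with_single_window_path(self, rng):
        vals = rng.random((12, 12))
        r = _raster(vals)
        cfg = GLCMConfig(levels=8)
        stats = glcm_raster(r, cfg)
        q = quantize_band(r, cfg.levels).values
        for _ in range(10):
            row, col = rng.integers(1, 11, size=2)
            win = q[row - 1:row + 2, col - 1:col + 2]
            expect = glcm_statistics(win, cfg)
            for s in STAT_NAMES:
                assert stats[s].values[row, col] == pytest.approx(
                    expect[s], abs=1e-12), s

    def test_window_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            glcm_raster(_raster(np.random.rand(2, 2)), GLCMConfig(window=3))


class TestTextureIndices:
    @pytest.mark.parametrize("n_layers,expected", [(2, 4), (4, 24), (32, 1984)])
    def test_enumeration_counts(self, n_layers, expected):
        names = [("G", s) for s in STAT_NAMES] + [("R", s) for s in STAT_NAMES] \
            + [("RE", s) for s in STAT_NAMES] + [("NIR", s) for s in STAT_NAMES]
        defs = enumerate_texture_indices(names[:n_layers])
        assert len(defs) == expected
        assert len({d.name for d in defs}) == expected  # all distinct

    def test_hand_values(self):
        t1, t2 = np.array([3.0]), np.array([1.0])
        assert evaluate_index("NDTI", t1, t2)[0] == pytest.approx(0.5)
        assert evaluate_index("DTI", t1, t2)[0] == pytest.approx(2.0)
        assert evaluate_index("RTI", t1, t2)[0] == pytest.approx(3.0)

    def test_identity_case(self, rng):
        t = rng.random(20) + 0.5
        assert np.allclose(evaluate_index("NDTI", t, t), 0.0)
        assert np.allclose(evaluate_index("DTI", t, t), 0.0)
        assert np.allclose(evaluate_index("RTI", t, t), 1.0)

    def test_antisymmetry_and_reciprocity(self, rng):
        a, b = rng.random(50) + 0.1, rng.random(50) + 0.1
        assert np.allclose(evaluate_index("NDTI", a, b),
                           -evaluate_index("NDTI", b, a))
        assert np.allclose(evaluate_index("DTI", a, b),
                           -evaluate_index("DTI", b, a))
        assert np.allclose(evaluate_index("RTI", a, b)
                           * evaluate_index("RTI", b, a), 1.0)

    def test_singularities_are_nodata(self):
        assert np.isnan(evaluate_index("RTI", np.array([1.0]), np.array([0.0]))[0])
        assert np.isnan(evaluate_index("NDTI", np.array([1.0]), np.array([-1.0]))[0])

    def test_compute_on_stack(self, small_stack):
        d = TextureIndexDef("NDTI", ("NIR", "MEA"), ("RE", "MEA"))
        out = compute_texture_index(d, small_stack)
        t1 = small_stack.layer("NIR", "MEA").values
        t2 = small_stack.layer("RE", "MEA").values
        interior = np.isfinite(t1) & np.isfinite(t2) & ((t1 + t2) != 0)
        np.testing.assert_allclose(out.values[interior],
                                   ((t1 - t2) / (t1 + t2))[interior])

    def test_equal_layers_rejected(self):
        with pytest.raises(ValueError):
            TextureIndexDef("RTI", ("G", "MEA"), ("G", "MEA"))
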