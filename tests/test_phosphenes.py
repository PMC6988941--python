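"""Phosphene simulator: sampling, quantization, dropout and rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spvsim import (
    ActivationGrid,
    PhospheneGridConfig,
    make_dropout,
    quantize,
    render,
    sample_activations,
    simulate,
)


# ---------------------------------------------------------------------------
# sampling

class TestSampleActivations:
    def test_constant_image_preserves_mean_exactly(self, default_config):
        img = np.full((128, 128), 0.6)
        acts = sample_activations(img, default_config)
        assert acts.shape == (32, 32)
        np.testing.assert_allclose(acts, 0.6)

    def test_black_image_gives_zero(self, default_config):
        acts = sample_activations(np.zeros((64, 64)), default_config)
        assert (acts == 0).all()

    def test_half_white_image_tile_means(self):
        """64x64 image, white left half, 2x2 grid -> [[1,0],[1,0]]."""
        cfg = PhospheneGridConfig(rows=2, cols=2, output_px=64)
        img = np.zeros((64, 64))
        img[:, :32] = 1.0
        np.testing.assert_allclose(sample_activations(img, cfg), [[1, 0], [1, 0]])

    def test_matches_brute_force_tile_means(self, rng):
        """Remainder-absorbing tiling agrees with an explicit loop oracle."""
        cfg = PhospheneGridConfig(rows=3, cols=5, output_px=64)
        img = rng.random((17, 23))  # not divisible by 3 or 5
        acts = sample_activations(img, cfg)
        h, w = img.shape
        th, tw = h // 3, w // 5
        for i in range(3):
            for j in range(5):
                r1 = (i + 1) * th if i < 2 else h
                c1 = (j + 1) * tw if j < 4 else w
                assert acts[i, j] == pytest.approx(img[i * th : r1, j * tw : c1].mean())

    def test_rejects_bad_input(self, default_config):
        with pytest.raises(ValueError):
            sample_activations(np.zeros((0, 0)), default_config)
        with pytest.raises(ValueError):
            sample_activations(np.full((64, 64), 1.5), default_config)
        with pytest.raises(ValueError):
            sample_activations(np.full((8, 8), 0.5), default_config)  # < grid


# ---------------------------------------------------------------------------
# quantization

class TestQuantize:
    @pytest.mark.parametrize(
        "intensity,expected",
        [
            (0.0, 0),
            (1.0, 7),
            (0.5, 4),  # 3.5 rounds half-up
            (1 / 7, 1),  # exact level is a fixed point
            (0.5 / 7 - 1e-9, 0),  # just below the first bin edge
            (0.5 / 7 + 1e-9, 1),  # just above it
        ],
    )
    def test_bin_edges_eight_levels(self, intensity, expected, default_config):
        grid = quantize(np.array([[intensity]]), default_config.replace(rows=1, cols=1))
        assert grid.levels[0, 0] == expected

    def test_idempotent_on_level_intensities(self, default_config):
        cfg = default_config.replace(rows=1, cols=8)
        levels = np.arange(8)
        grid = quantize(levels[None, :] / 7.0, cfg)
        np.testing.assert_array_equal(grid.levels, levels[None, :])

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone(self, a, b):
        cfg = PhospheneGridConfig(rows=1, cols=1, output_px=32)
        qa = quantize(np.array([[min(a, b)]]), cfg).levels[0, 0]
        qb = quantize(np.array([[max(a, b)]]), cfg).levels[0, 0]
        assert qa <= qb

    def test_rejects_too_few_levels(self):
        with pytest.raises(ValueError):
            PhospheneGridConfig(n_levels=1)


# ---------------------------------------------------------------------------
# dropout

class TestDropout:
    def test_extreme_rates(self, default_config):
        assert make_dropout(default_config.replace(dropout_rate=0.0)).alive.all()
        assert not make_dropout(default_config.replace(dropout_rate=1.0)).alive.any()

    def test_reproducible_given_seed(self, default_config):
        a = make_dropout(default_config, seed=99)
        b = make_dropout(default_config, seed=99)
        np.testing.assert_array_equal(a.alive, b.alive)
        assert not np.array_equal(a.alive, make_dropout(default_config, seed=100).alive)

    def test_binomial_moments(self, default_config):
        """Dead counts over seeds match Binomial(1024, 0.1) within 3 SE."""
        n_rep, n, p = 10_000, 1024, 0.1
        dead = np.array(
            [(~make_dropout(default_config, seed=s).alive).sum() for s in range(n_rep)]
        )
        mean_se = np.sqrt(n * p * (1 - p) / n_rep)
        assert abs(dead.mean() - n * p) < 3 * mean_se
        var = n * p * (1 - p)
        # SE of the sample variance of a binomial, normal approximation
        var_se = var * np.sqrt(2 / (n_rep - 1))
        assert abs(dead.var(ddof=1) - var) < 3 * var_se


# ---------------------------------------------------------------------------
# rendering

def _brute_force_render(levels, alive, cfg):
    """Per-pixel max over all electrodes' truncated Gaussians."""
    ys, xs = cfg.centers()
    lmax = cfg.n_levels - 1
    sig_max = cfg.sigma_fraction * cfg.spacing_px
    out = np.zeros((cfg.output_px, cfg.output_px))
    for py in range(cfg.output_px):
        for px in range(cfg.output_px):
            best = 0.0
            for i in range(cfg.rows):
                for j in range(cfg.cols):
                    lv = levels[i, j]
                    if lv == 0 or not alive[i, j]:
                        continue
                    sig = sig_max * lv / lmax
                    d2 = (py - ys[i]) ** 2 + (px - xs[j]) ** 2
                    if d2 > (cfg.truncate_sigmas * sig) ** 2:
                        continue
                    best = max(best, (lv / lmax) * np.exp(-0.5 * d2 / sig**2))
            out[py, px] = best
    return out


class TestRender:
    def test_all_off_is_black(self, small_config):
        grid = ActivationGrid(np.zeros((4, 4), dtype=int), small_config)
        img = render(grid, make_dropout(small_config))
        assert (img.pixels == 0).all()

    def test_single_max_dot_gaussian_profile(self):
        # output_px 64 puts the lone phosphene center exactly on pixel (32, 32)
        cfg = PhospheneGridConfig(rows=1, cols=1, output_px=64, dropout_rate=0.0)
        grid = ActivationGrid(np.array([[7]]), cfg)
        img = render(grid, make_dropout(cfg)).pixels
        cy = cx = 32
        assert img[cy, cx] == pytest.approx(1.0, abs=1e-12)
        sigma = cfg.sigma_fraction * cfg.spacing_px  # 16 px
        d = int(sigma)
        assert img[cy, cx + d] == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_radial_monotonicity(self):
        """Luminance never increases along rays away from a dot center."""
        cfg = PhospheneGridConfig(rows=1, cols=1, output_px=81, dropout_rate=0.0)
        img = render(ActivationGrid(np.array([[7]]), cfg), make_dropout(cfg)).pixels
        c = 81 // 2
        for dy, dx in [(0, 1), (1, 0), (1, 1), (-1, 1), (2, 1)]:
            vals = []
            y, x = c, c
            while 0 <= y < 81 and 0 <= x < 81:
                vals.append(img[y, x])
                y, x = y + dy, x + dx
            diffs = np.diff(vals)
            assert (diffs <= 1e-12).all()

    def test_matches_brute_force_oracle(self, small_config, rng):
        levels = rng.integers(0, 8, size=(4, 4))
        alive = rng.random((4, 4)) > 0.3
        grid = ActivationGrid(levels, small_config)
        from spvsim.phosphenes import DropoutMask

        img = render(grid, DropoutMask(alive=alive, seed=0), small_config)
        np.testing.assert_allclose(
            img.pixels, _brute_force_render(levels, alive, small_config), atol=1e-12
        )

    def test_dead_electrodes_render_nothing(self, small_config):
        grid = ActivationGrid(np.full((4, 4), 7), small_config)
        from spvsim.phosphenes import DropoutMask

        alive = np.zeros((4, 4), dtype=bool)
        alive[0, 0] = True
        img = render(grid, DropoutMask(alive=alive, seed=0), small_config).pixels
        ys, xs = small_config.centers()
        # far corner (near the dead electrode at (3,3)) stays black
        assert img[int(ys[3]), int(xs[3])] == 0.0
        assert img[int(ys[0]), int(xs[0])] > 0.9

    def test_shape_mismatch_rejected(self, small_config, default_config):
        grid = ActivationGrid(np.zeros((4, 4), dtype=int), small_config)
        with pytest.raises(ValueError):
            render(grid, make_dropout(default_config), small_config)


# ---------------------------------------------------------------------------
# end-to-end

class TestSimulate:
    def test_default_grid_has_1024_sites(self, default_config):
        assert default_config.n_electrodes == 1024

    def test_peak_luminances_quantized(self, default_config, rng):
        """Dot peaks only ever take the n_levels quantized values."""
        img = simulate(rng.random((256, 256)), default_config)
        peaks = np.unique(img.pixels)
        allowed = np.arange(8) / 7.0
        # every local peak equals some level; check max values present
        for v in peaks[-5:]:
            assert np.any(np.abs(allowed - v) < 1e-9) or v < 1.0

    def test_at_most_n_levels_distinct_peaks(self, rng):
        cfg = PhospheneGridConfig(dropout_rate=0.0, output_px=256)
        img = simulate(rng.random((256, 256)), cfg)
        acts = quantize(sample_activations(rng.random((256, 256)), cfg), cfg)
        assert acts.levels.max() <= 7

    def test_white_input_no_dropout_all_dots_max(self):
        cfg = PhospheneGridConfig(dropout_rate=0.0, output_px=256)
        grid = quantize(sample_activations(np.ones((256, 256)), cfg), cfg)
        assert (grid.levels == 7).all()
        assert grid.levels.size == 1024
        img = render(grid, make_dropout(cfg), cfg)
        ys, xs = cfg.centers()
        centers = img.pixels[np.round(ys).astype(int)[:, None], np.round(xs).astype(int)[None, :]]
        assert (centers > 0.95).all()

    def test_background_far_from_dots_is_zero(self):
        """Pixels beyond every dot's truncation radius stay exactly 0."""
        cfg = PhospheneGridConfig(rows=4, cols=4, output_px=256, dropout_rate=0.0)
        levels = np.zeros((4, 4), dtype=int)
        levels[0, 0] = 7  # one dot at (32, 32), truncation radius 48 px
        img = render(ActivationGrid(levels, cfg), make_dropout(cfg), cfg).pixels
        assert img[255, 255] == 0.0
        assert img[32, 32] > 0.99
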