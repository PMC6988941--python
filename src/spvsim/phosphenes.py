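"""Phosphene map simulation for retinal-prosthesis stimuli.

A processed grayscale stimulus drives a rectangular array of electrodes
(default 32 x 32, i.e. 1024 sites).  Each electrode samples the mean
luminance of its image tile, the sample is quantized to a small number of
discrete luminance levels (default 8, the range reported attainable in
human retinal-implant trials), a fixed fraction of electrodes is randomly
dead (default 10%), and every live, non-zero electrode is rendered as a
circular dot with a Gaussian luminance profile whose peak brightness and
radius are proportional to its level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhospheneGridConfig",
    "ActivationGrid",
    "DropoutMask",
    "PhospheneImage",
    "sample_activations",
    "quantize",
    "make_dropout",
    "render",
    "simulate",
]


@dataclass(frozen=True)
class PhospheneGridConfig:
    """All simulator parameters: grid geometry, quantization, dropout.

    Parameters
    ----------
    rows, cols : int
        Electrode lattice dimensions (default 32 x 32 = 1024 sites).
    n_levels : int
        Number of luminance levels including "off" (default 8).
    dropout_rate : float
        Probability that an electrode is dead, in [0, 1] (default 0.10).
    field_of_view_deg : float
        Simulated visual field subtended by the rendered image, degrees.
    output_px : int
        Side length of the rendered square percept in pixels.
    sigma_fraction : float
        Gaussian sigma of a max-level dot as a fraction of the
        inter-phosphene spacing.  The default 0.25 makes adjacent
        max-level dots just touch at two sigma.
    truncate_sigmas : float
        Dots are cut off at this many sigma from the center.
    seed : int
        Seed for the dropout mask (dead electrodes are a property of the
        implant, so one mask is reused for a whole session).
    """

    rows: int = 32
    cols: int = 32
    n_levels: int = 8
    dropout_rate: float = 0.10
    field_of_view_deg: float = 20.0
    output_px: int = 512
    sigma_fraction: float = 0.25
    truncate_sigmas: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one electrode")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2 (off plus one level)")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.field_of_view_deg <= 0:
            raise ValueError("field_of_view_deg must be positive")
        if self.output_px < max(self.rows, self.cols):
            raise ValueError("output_px must be >= max(rows, cols)")
        if self.sigma_fraction <= 0 or self.truncate_sigmas <= 0:
            raise ValueError("sigma_fraction and truncate_sigmas must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    @property
    def spacing_px(self) -> float:
        """Inter-phosphene spacing in output pixels (grid fills the image)."""
        return self.output_px / max(self.rows, self.cols)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Phosphene centers (row, col arrays in pixels), grid centered."""
        s = self.spacing_px
        y0 = (self.output_px - self.rows * s) / 2.0
        x0 = (self.output_px - self.cols * s) / 2.0
        ys = y0 + (np.arange(self.rows) + 0.5) * s
        xs = x0 + (np.arange(self.cols) + 0.5) * s
        return ys, xs

    def replace(self, **kwargs) -> "PhospheneGridConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ActivationGrid:
    """Per-electrode quantized stimulation levels in {0, ..., n_levels-1}."""

    levels: np.ndarray
    config: PhospheneGridConfig

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.shape != (self.config.rows, self.config.cols):
            raise ValueError("levels shape does not match config grid")
        if not np.issubdtype(lv.dtype, np.integer):
            raise TypeError("levels must be integers")
        if lv.min(initial=0) < 0 or lv.max(initial=0) > self.config.n_levels - 1:
            raise ValueError("levels out of [0, n_levels-1]")


@dataclass(frozen=True)
class DropoutMask:
    """Which electrodes are alive; fully determined by (config, seed)."""

    alive: np.ndarray
    seed: int


@dataclass(frozen=True)
class PhospheneImage:
    """Rendered percept: output_px x output_px luminance raster in [0, 1]."""

    pixels: np.ndarray
    config: PhospheneGridConfig | None = field(default=None, compare=False)


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D grayscale raster")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


def sample_activations(
    image: np.ndarray, config: PhospheneGridConfig
) -> np.ndarray:
    """Mean luminance of each electrode's rectangular image tile.

    The image is partitioned into ``rows x cols`` equal tiles; when the
    image size is not divisible by the grid, the last row/column of tiles
    absorbs the remainder pixels.
    """
    img = _check_image(image)
    h, w = img.shape
    if h < config.rows or w < config.cols:
        raise ValueError(
            f"image {h}x{w} smaller than the {config.rows}x{config.cols} grid"
        )
    rb = np.arange(config.rows) * (h // config.rows)
    cb = np.arange(config.cols) * (w // config.cols)
    # reduceat sums from each boundary to the next (last segment to the end)
    sums = np.add.reduceat(np.add.reduceat(img, rb, axis=0), cb, axis=1)
    heights = np.diff(np.append(rb, h))
    widths = np.diff(np.append(cb, w))
    areas = heights[:, None] * widths[None, :]
    return sums / areas


def quantize(intensities: np.ndarray, config: PhospheneGridConfig) -> ActivationGrid:
    """Quantize sampled intensities to integer luminance levels.

    ``level = round(intensity * (n_levels - 1))`` with exact half-values
    rounded up, so the map is monotone and idempotent on intensities that
    already sit on a level (k / (n_levels - 1)).
    """
    x = np.asarray(intensities, dtype=float)
    if x.min(initial=0.0) < 0.0 or x.max(initial=0.0) > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    # half-up rounding: floor(x + 1/2); numpy's round() would round half to even
    levels = np.floor(x * (config.n_levels - 1) + 0.5).astype(np.int64)
    levels = np.clip(levels, 0, config.n_levels - 1)
    return ActivationGrid(levels=levels, config=config)


def make_dropout(config: PhospheneGridConfig, seed: int | None = None) -> DropoutMask:
    """Draw the session's dead-electrode mask.

    Each electrode is independently dead with probability
    ``config.dropout_rate``.  Deterministic given the seed; the same mask
    is reused for every stimulus of a session, since dead electrodes are a
    property of the implant rather than of the frame.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    alive = rng.random((config.rows, config.cols)) >= config.dropout_rate
    return DropoutMask(alive=alive, seed=seed)


def render(
    grid: ActivationGrid,
    mask: DropoutMask,
    config: PhospheneGridConfig | None = None,
) -> PhospheneImage:
    """Render Gaussian-profile dots for every live, non-zero electrode.

    A dot at level ``l`` has peak luminance ``l / (n_levels - 1)`` and an
    isotropic Gaussian profile with ``sigma = sigma_fraction * spacing *
    l / (n_levels - 1)`` truncated at ``truncate_sigmas`` sigma, so both
    brightness and radius grow linearly with the level.  Overlapping dots
    combine by pointwise maximum; dead and level-0 electrodes render
    nothing, and the background is exactly 0.
    """
    cfg = config or grid.config
    if grid.levels.shape != (cfg.rows, cfg.cols):
        raise ValueError("activation grid shape does not match config")
    if mask.alive.shape != (cfg.rows, cfg.cols):
        raise ValueError("dropout mask shape does not match config")

    out = np.zeros((cfg.output_px, cfg.output_px), dtype=float)
    ys, xs = cfg.centers()
    lmax = cfg.n_levels - 1
    sigma_max = cfg.sigma_fraction * cfg.spacing_px

    live = np.argwhere(mask.alive & (grid.levels > 0))
    for i, j in live:
        level = int(grid.levels[i, j])
        peak = level / lmax
        sigma = sigma_max * level / lmax
        radius = cfg.truncate_sigmas * sigma
        cy, cx = ys[i], xs[j]
        y_lo = max(int(np.floor(cy - radius)), 0)
        y_hi = min(int(np.ceil(cy + radius)) + 1, cfg.output_px)
        x_lo = max(int(np.floor(cx - radius)), 0)
        x_hi = min(int(np.ceil(cx + radius)) + 1, cfg.output_px)
        if y_lo >= y_hi or x_lo >= x_hi:
            continue
        yy = np.arange(y_lo, y_hi)[:, None] - cy
        xx = np.arange(x_lo, x_hi)[None, :] - cx
        r2 = yy * yy + xx * xx
        dot = peak * np.exp(-0.5 * r2 / (sigma * sigma))
        dot[r2 > radius * radius] = 0.0
        patch = out[y_lo:y_hi, x_lo:x_hi]
        np.maximum(patch, dot, out=patch)

    return PhospheneImage(pixels=out, config=cfg)


def simulate(
    stimulus: np.ndarray,
    config: PhospheneGridConfig | None = None,
    dropout: DropoutMask | None = None,
) -> PhospheneImage:
    """Full stimulus-to-percept pipeline: sample, quantize, drop out, render.

    Accepts a raw [0, 1] raster or a :class:`~spvsim.stimuli.StimulusImage`
    (anything with a ``pixels`` attribute).  An explicit ``dropout`` mask
    lets one implant state be reused across the stimuli of a session.
    """
    cfg = config or PhospheneGridConfig()
    pixels = getattr(stimulus, "pixels", stimulus)
    acts = sample_activations(pixels, cfg)
    grid = quantize(acts, cfg)
    if dropout is None:
        dropout = make_dropout(cfg)
    return render(grid, dropout, cfg)
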