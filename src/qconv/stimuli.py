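"""Stimulus movies, patch geometry, and lagged patch extraction.

The encoding model treats the stimulus as a grayscale movie and evaluates
identical subunits on overlapping patches extracted at a grid of spatial
offsets and a range of temporal lags.  This module owns that geometry: the
canonical flattening of a patch into a pixel vector and the canonical
ordering of (lag, grid position) slots that the pooling weights refer to.

Conventions
-----------
* Frames are indexed ``frames[t, y, x]`` (0-based, row-major pixels).
* A patch position is labeled by its top-left corner on the pixel grid;
  grid position ``(gy, gx)`` covers rows ``gy*stride .. gy*stride+patch_h``.
* Lag ``l`` refers to the patch taken from frame ``t - l``; responses at
  ``t`` depend on the present and past frames only.
* Pooling slots are ordered lag-major, then row-major over the grid:
  ``k = l * (Gy*Gx) + gy*Gx + gx``.  This is the order of the pooling
  weight vector ``v2`` everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "StimulusMovie",
    "PatchConfig",
    "extract_patches",
    "patch_vector_length",
    "pooling_vector_length",
    "grid_shape",
    "design_tensor",
]


@dataclass
class StimulusMovie:
    """A T x H x W grayscale movie with a fixed frame duration.

    The movie is mean-centered on construction (``center=True``, the
    default); the subtracted offset is kept in ``raw_mean``.  No variance
    normalization is applied -- the model's bias terms absorb offsets and
    leaving the scale alone keeps the quadratic kernel interpretable.
    """

    frames: np.ndarray
    bin_ms: float
    center: bool = True
    raw_mean: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {frames.shape}")
        if not np.all(np.isfinite(frames)):
            raise ValueError("stimulus frames contain non-finite values")
        if not (np.isscalar(self.bin_ms) or np.ndim(self.bin_ms) == 0) or not (
            float(self.bin_ms) > 0
        ):
            raise ValueError(f"bin_ms must be a positive scalar, got {self.bin_ms!r}")
        self.bin_ms = float(self.bin_ms)
        if self.center:
            self.raw_mean = float(frames.mean())
            frames = frames - self.raw_mean
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class PatchConfig:
    """Patch size, grid stride, and number of temporal lags."""

    patch_h: int
    patch_w: int
    stride: int = 1
    n_lags: int = 1

    def __post_init__(self) -> None:
        for name in ("patch_h", "patch_w", "stride", "n_lags"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def patch_pixels(self) -> int:
        return self.patch_h * self.patch_w


def patch_vector_length(cfg: PatchConfig) -> int:
    """Length of a flattened patch vector (pixels per patch)."""
    return cfg.patch_pixels


def grid_shape(frame_shape: tuple[int, int], cfg: PatchConfig) -> tuple[int, int]:
    """Number of valid patch positions (Gy, Gx) for the given frame size.

    Per axis the grid extent is ``floor((H - patch) / stride) + 1``; the
    patch must fit inside the frame.
    """
    H, W = frame_shape
    if cfg.patch_h > H or cfg.patch_w > W:
        raise ValueError(
            f"patch {cfg.patch_h}x{cfg.patch_w} larger than frame {H}x{W}"
        )
    gy = (H - cfg.patch_h) // cfg.stride + 1
    gx = (W - cfg.patch_w) // cfg.stride + 1
    return gy, gx


def pooling_vector_length(frame_shape: tuple[int, int], cfg: PatchConfig) -> int:
    """Length of the pooling weight vector: grid positions times lags."""
    gy, gx = grid_shape(frame_shape, cfg)
    return gy * gx * cfg.n_lags


def _grid_positions(
    frame_shape: tuple[int, int],
    cfg: PatchConfig,
    convolutional: bool = True,
) -> list[tuple[int, int]]:
    """Grid coordinates (gy, gx) in canonical row-major order.

    With ``convolutional=False`` the grid collapses to the single most
    central position (ties resolved toward the top-left).
    """
    gy, gx = grid_shape(frame_shape, cfg)
    if convolutional:
        return [(iy, ix) for iy in range(gy) for ix in range(gx)]
    return [((gy - 1) // 2, (gx - 1) // 2)]


def extract_patches(movie: StimulusMovie, cfg: PatchConfig, t: int) -> np.ndarray:
    """All lagged patch vectors feeding the response at frame ``t``.

    Returns an array of shape ``(n_lags * Gy * Gx, patch_pixels)`` in the
    canonical lag-major, then row-major-grid order.  Requires
    ``t >= n_lags - 1`` so that the full lag history exists.
    """
    gy, gx = grid_shape(movie.frame_shape, cfg)
    if t < cfg.n_lags - 1 or t >= movie.n_frames:
        raise IndexError(
            f"frame {t} lacks full lag history or is out of range "
            f"(need {cfg.n_lags - 1} <= t < {movie.n_frames})"
        )
    out = np.empty((cfg.n_lags, gy * gx, cfg.patch_pixels))
    for lag in range(cfg.n_lags):
        frame = movie.frames[t - lag]
        win = sliding_window_view(frame, (cfg.patch_h, cfg.patch_w))
        win = win[:: cfg.stride, :: cfg.stride]
        out[lag] = win.reshape(gy * gx, cfg.patch_pixels)
    return out.reshape(cfg.n_lags * gy * gx, cfg.patch_pixels)


def design_tensor(
    movie: StimulusMovie,
    cfg: PatchConfig,
    positions: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Stacked patch vectors for every frame with full lag history.

    Returns ``X`` of shape ``(T - n_lags + 1, K, P)`` where
    ``K = n_lags * len(positions)`` and ``P = patch_pixels``; row ``i``
    corresponds to frame ``t = i + n_lags - 1``.  ``positions`` defaults
    to the full grid in canonical order; passing an explicit subset (for
    example the single central position of a non-convolutional model)
    keeps slot ordering lag-major, then positions in the given order.
    """
    gy, gx = grid_shape(movie.frame_shape, cfg)
    if positions is None:
        positions = _grid_positions(movie.frame_shape, cfg)
    T = movie.n_frames
    if T < cfg.n_lags:
        raise ValueError(f"movie has {T} frames but {cfg.n_lags} lags are required")
    win = sliding_window_view(movie.frames, (cfg.patch_h, cfg.patch_w), axis=(1, 2))
    win = win[:, :: cfg.stride, :: cfg.stride]  # (T, Gy, Gx, ph, pw)
    rows = np.array([p[0] for p in positions])
    cols = np.array([p[1] for p in positions])
    if rows.size and (rows.max() >= gy or cols.max() >= gx):
        raise ValueError("position index outside pooling grid")
    sel = win[:, rows, cols].reshape(T, len(positions), cfg.patch_pixels)
    L = cfg.n_lags
    n_valid = T - L + 1
    lagged = [sel[L - 1 - lag : T - lag] for lag in range(L)]
    X = np.stack(lagged, axis=1)  # (n_valid, L, n_pos, P)
    return X.reshape(n_valid, L * len(positions), cfg.patch_pixels)
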