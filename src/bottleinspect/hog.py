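"""Histogram-of-oriented-gradients descriptor with multi-scale blocks.

One descriptor is computed per detected target crop (no sliding-window image
scan): the crop is resized to a square window, gradients are taken by
central differences with replicated borders, and each pixel's gradient
magnitude votes for the two orientation bins bracketing its (unsigned)
direction, split linearly by distance to the bin centres.  Cell histograms
are grouped into blocks at several (cells_per_side, stride) scales, each
block is L2- or L2-Hys-normalised, and all blocks are concatenated in a
fixed order: scales in config order, block positions row-major, cells within
a block row-major, bins innermost.  The descriptor length is fully
determined by the config; gradients are invariant to additive intensity
shifts, so the descriptor is too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256
from typing import List, Literal, Tuple

import numpy as np
from skimage.transform import resize

from .synthetic import ConfigurationError


@dataclass
class HOGConfig:
    window: int = 64                 # crops are resized to window x window
    cell: int = 8                    # cell side, px
    n_bins: int = 9                  # unsigned orientation bins over [0, 180)
    block_scales: List[Tuple[int, int]] = field(
        default_factory=lambda: [(2, 1), (4, 2)])  # (cells per block side, stride in cells)
    norm: Literal["L2", "L2-Hys"] = "L2-Hys"
    clip: float = 0.2                # L2-Hys clipping level
    eps: float = 1e-10

    def validate(self) -> None:
        if self.window % self.cell != 0:
            raise ConfigurationError("window must be divisible by cell")
        if self.cell < 1 or self.n_bins < 2:
            raise ConfigurationError("invalid cell size or bin count")
        n_cells = self.window // self.cell
        for bs, stride in self.block_scales:
            if bs > n_cells or stride < 1:
                raise ConfigurationError(f"block scale {(bs, stride)} does not fit the window")

    @property
    def descriptor_length(self) -> int:
        n_cells = self.window // self.cell
        total = 0
        for bs, stride in self.block_scales:
            pos = (n_cells - bs) // stride + 1
            total += pos * pos * bs * bs * self.n_bins
        return total

    def hash(self) -> str:
        parts = (self.window, self.cell, self.n_bins, tuple(map(tuple, self.block_scales)),
                 self.norm, self.clip, self.eps)
        return sha256(repr(parts).encode()).hexdigest()[:16]


def _gradients(img: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Central differences with edge-replicated borders: (g_row, g_col)."""
    padded = np.pad(img, 1, mode="edge")
    g_row = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    g_col = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return g_row, g_col


def cell_histograms(img: np.ndarray, config: HOGConfig) -> np.ndarray:
    """Orientation-interpolated, magnitude-weighted cell histograms.

    Returns an (n_cells, n_cells, n_bins) array.  The vote of a pixel with
    unsigned orientation theta splits between the two bins whose centres
    bracket theta, with weights proportional to 1 - distance/bin_width
    (wrapping 180 -> 0).  No spatial sharing across cells.
    """
    g_row, g_col = _gradients(img.astype(np.float64))
    magnitude = np.hypot(g_row, g_col)
    theta = np.rad2deg(np.arctan2(g_row, g_col)) % 180.0

    width = 180.0 / config.n_bins
    pos = theta / width - 0.5  # bin centres at (k + 0.5) * width
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo_bin = lo % config.n_bins
    hi_bin = (lo + 1) % config.n_bins

    n_cells = config.window // config.cell
    hist = np.zeros((n_cells, n_cells, config.n_bins))
    rows, cols = img.shape
    cell_r = (np.arange(rows) // config.cell)[:, None] * np.ones(cols, dtype=int)
    cell_c = np.ones((rows, 1), dtype=int) * (np.arange(cols) // config.cell)[None, :]
    flat_cell = (cell_r * n_cells + cell_c).ravel()
    np.add.at(hist.reshape(-1, config.n_bins).reshape(-1),
              flat_cell * config.n_bins + lo_bin.ravel(),
              (magnitude * (1.0 - frac)).ravel())
    np.add.at(hist.reshape(-1, config.n_bins).reshape(-1),
              flat_cell * config.n_bins + hi_bin.ravel(),
              (magnitude * frac).ravel())
    return hist


def _normalize_block(vec: np.ndarray, config: HOGConfig) -> np.ndarray:
    norm = np.sqrt(np.sum(vec**2) + config.eps**2)
    out = vec / norm
    if config.norm == "L2-Hys":
        out = np.minimum(out, config.clip)
        norm = np.sqrt(np.sum(out**2) + config.eps**2)
        out = out / norm
    return out


def compute_hog(crop: np.ndarray, config: HOGConfig | None = None) -> np.ndarray:
    """Descriptor of one grayscale crop (resized to the config window)."""
    config = config or HOGConfig()
    config.validate()
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim != 2:
        raise ValueError("crop must be a 2-D grayscale array")
    if min(crop.shape) < 2:
        raise ValueError("crop too small")
    if crop.shape != (config.window, config.window):
        crop = resize(crop, (config.window, config.window), order=1,
                      anti_aliasing=False, preserve_range=True)
    hist = cell_histograms(crop, config)
    n_cells = config.window // config.cell
    pieces: List[np.ndarray] = []
    for bs, stride in config.block_scales:
        for br in range(0, n_cells - bs + 1, stride):
            for bc in range(0, n_cells - bs + 1, stride):
                block = hist[br : br + bs, bc : bc + bs, :].ravel()
                pieces.append(_normalize_block(block, config))
    return np.concatenate(pieces)


def rbf_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Radial basis similarity exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


class HOGDescriptor:
    """sklearn-style transformer: list/stack of crops -> (n, descriptor_length)."""

    def __init__(self, config: HOGConfig | None = None):
        self.config = config or HOGConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **kwargs) -> "HOGDescriptor":
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "HOGDescriptor":  # stateless
        self.config.validate()
        self.n_features_out_ = self.config.descriptor_length
        return self

    def transform(self, crops) -> np.ndarray:
        return np.stack([compute_hog(c, self.config) for c in crops])

    def fit_transform(self, crops, y=None) -> np.ndarray:
        return self.fit().transform(crops)
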