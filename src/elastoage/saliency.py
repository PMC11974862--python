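"""Occlusion-sensitivity saliency maps per age bin.

A fitted model's spatial reliance is probed by zeroing cubic blocks of the
(normalised) input — zero coincides with background by construction — and
recording the change in mean absolute error of the predictions. The block
origins form a regular grid (13 positions per axis at the full 91x109x91
geometry reproduces the exact stride-7 tiling, 13^3 = 2197 origins); the
superior-most slices, which carry no brain tissue, are excluded from
occlusion. The delta-MAE grid is percentile-clipped, cubically upsampled to
the volume geometry, zero-padded over the excluded slab and min-max scaled
to [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .evaluation import absolute_error_summary
from .models import BrainAgeModel, predict

__all__ = [
    "SaliencyConfig",
    "SaliencyMap",
    "assign_age_bins",
    "occlusion_origins",
    "delta_mae_grid",
    "postprocess",
    "compute_saliency",
]

#: axis index of the inferior->superior direction in our RAS volumes
SI_AXIS = 2


@dataclass
class SaliencyConfig:
    block: int = 7
    excluded_superior_slices: int = 9
    positions_per_axis: int = 13
    clip_percentiles: tuple = (5.0, 95.0)
    n_age_bins: int = 5
    fill_value: float = 0.0

    def __post_init__(self):
        if self.block < 1 or self.positions_per_axis < 1:
            raise ValueError("block and positions_per_axis must be >= 1")
        lo, hi = self.clip_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")


@dataclass
class SaliencyMap:
    data: np.ndarray          # values in [0, 1], full volume geometry
    age_range: tuple          # (lo, hi) of the age bin


def assign_age_bins(test_ages, n_bins: int):
    """Quantile-based age bins: (labels, edges). Empty bins caused by ties are
    merged into their lower neighbour with a warning."""
    ages = np.asarray(test_ages, dtype=float)
    if len(ages) < n_bins:
        raise ValueError(f"need at least {n_bins} subjects for {n_bins} bins")
    edges = np.quantile(ages, np.linspace(0, 1, n_bins + 1))
    labels = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        if not np.any(labels == b):
            warnings.warn(f"age bin {b} empty after ties; merging with neighbour",
                          stacklevel=2)
            labels[labels > b] -= 1
    return labels, edges


def _axis_positions(extent: int, config: SaliencyConfig, excluded: int = 0):
    max_origin = extent - excluded - config.block
    if max_origin < 0:
        raise ValueError(
            f"axis extent {extent} leaves no room for a {config.block}-voxel "
            f"block with {excluded} excluded slices"
        )
    return np.round(np.linspace(0, max_origin, config.positions_per_axis)).astype(int)


def occlusion_origins(volume_shape, config: SaliencyConfig):
    """Ordered block origins: rounded even spacing over each admissible axis
    extent (exact stride-`block` tiling when the extent divides cleanly)."""
    volume_shape = tuple(volume_shape)
    pos = []
    for ax, extent in enumerate(volume_shape):
        excl = config.excluded_superior_slices if ax == SI_AXIS else 0
        pos.append(_axis_positions(extent, config, excl))
    return [tuple(o) for o in itertools.product(*pos)]


def delta_mae_grid(model: BrainAgeModel, volumes, ages, config: SaliencyConfig) -> np.ndarray:
    """Delta MAE (occluded minus original) for every block origin.

    `volumes` are the normalised model inputs of one age bin, shape
    (n, c, D, H, W); the block is filled with `fill_value` in all channels.
    """
    v = np.asarray(volumes, dtype=float)
    if v.ndim == 4:
        v = v[:, None]
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 1:
        raise ValueError("need at least one subject in the bin")
    base_mae, _ = absolute_error_summary(predict(model, v), ages)
    origins = occlusion_origins(v.shape[2:], config)
    p = config.positions_per_axis
    grid = np.empty(p**3)
    b = config.block
    for j, (x, y, z) in enumerate(origins):
        occluded = v.copy()
        occluded[:, :, x : x + b, y : y + b, z : z + b] = config.fill_value
        try:
            pred = predict(model, occluded)
        except Exception as exc:
            raise RuntimeError(f"prediction failed at occlusion origin {(x, y, z)}") from exc
        mae, _ = absolute_error_summary(pred, ages)
        grid[j] = mae - base_mae
    return grid.reshape(p, p, p)


def postprocess(grid: np.ndarray, config: SaliencyConfig, target_shape) -> SaliencyMap:
    """Clip -> cubic upsample -> zero-pad excluded slab -> min-max to [0, 1]."""
    grid = np.asarray(grid, dtype=float)
    target_shape = tuple(target_shape)
    if np.ptp(grid) == 0:
        warnings.warn("constant delta-MAE grid: returning all-zero saliency map",
                      stacklevel=2)
        return SaliencyMap(np.zeros(target_shape), age_range=(np.nan, np.nan))
    lo, hi = np.percentile(grid, config.clip_percentiles)
    clipped = np.clip(grid, lo, hi)

    inner = list(target_shape)
    inner[SI_AXIS] -= config.excluded_superior_slices
    coords = np.meshgrid(*[np.linspace(0, g - 1, t) for g, t in zip(grid.shape, inner)],
                         indexing="ij")
    up = map_coordinates(clipped, np.array(coords), order=3, mode="nearest")
    if np.ptp(up) == 0:
        warnings.warn("degenerate min-max after clipping: all-zero map", stacklevel=2)
        return SaliencyMap(np.zeros(target_shape), age_range=(np.nan, np.nan))
    up = (up - up.min()) / np.ptp(up)

    out = np.zeros(target_shape)
    sl = [slice(None)] * 3
    sl[SI_AXIS] = slice(0, inner[SI_AXIS])
    out[tuple(sl)] = up
    return SaliencyMap(out, age_range=(np.nan, np.nan))


def compute_saliency(model: BrainAgeModel, volumes, ages, config: SaliencyConfig):
    """Per-age-bin saliency maps for a test set: {bin index: SaliencyMap}."""
    v = np.asarray(volumes, dtype=float)
    if v.ndim == 4:
        v = v[:, None]
    labels, edges = assign_age_bins(ages, config.n_age_bins)
    ages = np.asarray(ages, dtype=float)
    maps = {}
    for b in np.unique(labels):
        sel = labels == b
        grid = delta_mae_grid(model, v[sel], ages[sel], config)
        smap = postprocess(grid, config, v.shape[2:])
        smap.age_range = (float(ages[sel].min()), float(ages[sel].max()))
        maps[int(b)] = smap
    return maps
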