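"""Viscoelastic property maps derived from the complex shear modulus.

MRE inversion yields the complex shear modulus G* = G' + iG'' per voxel.
Two scalar properties summarise it:

* stiffness  ``mu = 2|G*|^2 / (G' + |G*|)``   (kPa) — the magnitude-weighted
  shear stiffness commonly reported for brain tissue, and
* damping ratio ``xi = G'' / (2 G')``          (dimensionless) — the relative
  viscous energy dissipation.

This module computes those maps, inverts them back to (G', G''), applies
coverage masking to the anatomical channel and implements the two
normalisation modes (dataset-level pooled z-scoring vs per-image z-scoring).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComplexModulusMap",
    "PropertyMaps",
    "NormalizationState",
    "compute_properties",
    "invert_properties",
    "normalize",
    "denormalize",
    "apply_coverage_mask",
]


@dataclass
class ComplexModulusMap:
    """Voxel grids of the storage (G') and loss (G'') moduli plus coverage mask."""

    g_storage: np.ndarray
    g_loss: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.g_storage = np.asarray(self.g_storage, dtype=float)
        self.g_loss = np.asarray(self.g_loss, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.g_storage.shape == self.g_loss.shape == self.mask.shape):
            raise ValueError("g_storage, g_loss and mask must share one shape")

    def validate(self) -> None:
        m = self.mask
        if np.any(self.g_storage[m] <= 0):
            raise ValueError("G' must be strictly positive inside the mask")
        if np.any(self.g_loss[m] < 0):
            raise ValueError("G'' must be non-negative inside the mask")


@dataclass
class PropertyMaps:
    """Stiffness mu (kPa) and damping ratio xi (dimensionless) with mask."""

    mu: np.ndarray
    xi: np.ndarray
    mask: np.ndarray


def compute_properties(modulus: ComplexModulusMap) -> PropertyMaps:
    """Voxelwise stiffness and damping ratio from a complex modulus map.

    ``mu = 2|G*|^2/(G' + |G*|)`` and ``xi = G''/(2G')`` with
    ``|G*| = sqrt(G'^2 + G''^2)``. Voxels outside the coverage mask are 0.
    """
    m = modulus.mask
    gp = modulus.g_storage
    gpp = modulus.g_loss
    if np.any(gp[m] == 0):
        raise ZeroDivisionError("G' = 0 inside the coverage mask: xi undefined")
    modulus.validate()
    mu = np.zeros_like(gp)
    xi = np.zeros_like(gp)
    gabs = np.sqrt(gp[m] ** 2 + gpp[m] ** 2)
    mu[m] = 2.0 * gabs**2 / (gp[m] + gabs)
    xi[m] = gpp[m] / (2.0 * gp[m])
    return PropertyMaps(mu=mu, xi=xi, mask=m.copy())


def invert_properties(mu, xi):
    """Algebraic inverse of :func:`compute_properties`.

    With ``q = sqrt(1 + 4 xi^2)``: ``G' = mu (1 + q) / (2 q^2)`` and
    ``G'' = 2 xi G'``. Round-trips through ``compute_properties`` to
    better than 1e-10.
    """
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    if np.any(xi < 0):
        raise ValueError("xi must be non-negative")
    q = np.sqrt(1.0 + 4.0 * xi**2)
    g_storage = mu * (1.0 + q) / (2.0 * q**2)
    g_loss = 2.0 * xi * g_storage
    return g_storage, g_loss


@dataclass
class NormalizationState:
    """Per-channel affine normalisation parameters, reusable on held-out data.

    ``mode='dataset'`` stores one (location, scale) pair per channel pooled
    over every in-mask voxel of the fitting set; ``mode='image'`` has no
    state to store (each volume is z-scored independently).
    """

    mode: str
    loc: list = field(default_factory=list)
    scale: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "loc": self.loc, "scale": self.scale})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationState":
        d = json.loads(text)
        return cls(mode=d["mode"], loc=d["loc"], scale=d["scale"])


def _channel_stack(volumes: np.ndarray) -> np.ndarray:
    """Coerce to (n, channels, *spatial)."""
    v = np.asarray(volumes, dtype=float)
    if v.ndim == 4:  # (n, D, H, W) single channel
        v = v[:, None]
    if v.ndim != 5:
        raise ValueError("expected volumes of shape (n, [c,] D, H, W)")
    return v


def normalize(volumes, masks, mode: str = "dataset", state: NormalizationState | None = None):
    """Z-score volumes in-mask; out-of-mask voxels are set to exactly 0.

    Parameters
    ----------
    volumes : array, shape (n, c, D, H, W) or (n, D, H, W)
    masks : boolean array, shape (n, D, H, W)
    mode : 'dataset' pools statistics per channel over all in-mask voxels of
        the fitting set; 'image' z-scores every (volume, channel) on its own.
    state : a previously fitted :class:`NormalizationState` to apply without
        refitting (dataset mode only — this is how held-out and disease
        subjects are normalised with training statistics).

    Returns
    -------
    (normalized volumes, NormalizationState)
    """
    v = _channel_stack(volumes).copy()
    masks = np.asarray(masks, dtype=bool)
    n, c = v.shape[:2]
    if n < 1:
        raise ValueError("need at least one volume")
    if masks.shape != (n,) + v.shape[2:]:
        raise ValueError("masks must have shape (n, D, H, W)")

    if mode == "dataset":
        if state is None:
            loc, scale = [], []
            for ch in range(c):
                pooled = np.concatenate([v[i, ch][masks[i]] for i in range(n)])
                mu, sd = float(pooled.mean()), float(pooled.std())
                if sd == 0:
                    raise ValueError(f"zero variance in channel {ch}: cannot normalize")
                loc.append(mu)
                scale.append(sd)
            state = NormalizationState(mode="dataset", loc=loc, scale=scale)
        for ch in range(c):
            v[:, ch] = (v[:, ch] - state.loc[ch]) / state.scale[ch]
    elif mode == "image":
        for i in range(n):
            for ch in range(c):
                vals = v[i, ch][masks[i]]
                sd = vals.std()
                if sd == 0:
                    raise ValueError(f"zero variance in volume {i}, channel {ch}")
                v[i, ch] = (v[i, ch] - vals.mean()) / sd
        state = NormalizationState(mode="image")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    v[~np.broadcast_to(masks[:, None], v.shape)] = 0.0
    if np.asarray(volumes).ndim == 4:
        v = v[:, 0]
    return v, state


def denormalize(volumes, masks, state: NormalizationState):
    """Invert a dataset-mode normalisation (out-of-mask voxels stay 0)."""
    if state.mode != "dataset":
        raise ValueError("only dataset-mode states are invertible")
    v = _channel_stack(volumes).copy()
    masks = np.asarray(masks, dtype=bool)
    for ch in range(v.shape[1]):
        v[:, ch] = v[:, ch] * state.scale[ch] + state.loc[ch]
    v[~np.broadcast_to(masks[:, None], v.shape)] = 0.0
    if np.asarray(volumes).ndim == 4:
        v = v[:, 0]
    return v


def apply_coverage_mask(anatomical: np.ndarray, property_mask: np.ndarray) -> np.ndarray:
    """Zero anatomical voxels outside the mechanical coverage mask.

    Masking happens before the anatomical channel's per-image normalisation,
    so both modalities share one field of view.
    """
    anatomical = np.asarray(anatomical, dtype=float)
    property_mask = np.asarray(property_mask, dtype=bool)
    if anatomical.shape != property_mask.shape:
        raise ValueError(
            f"shape mismatch: anatomical {anatomical.shape} vs mask {property_mask.shape}"
        )
    out = anatomical.copy()
    out[~property_mask] = 0.0
    return out
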