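"""Splits, error metrics and the multi-seed model-comparison protocol.

The protocol mirrors the standard brain-age evaluation: healthy subjects
only, an 80:20 train/test split per seed, fresh normalisation fitted on the
training split, a fresh model fit, and both the mean- and median-absolute
error on the held-out set, repeated over several seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrastive import NeighbourhoodSchedule
from .mech import compute_properties, normalize
from .models import (TrainConfig, fit_null, fit_pca_gp, fit_ssl,
                     fit_supervised_cnn, predict)
from .nn import EncoderConfig
from .synthetic import (CohortSpec, PhantomAtlas, build_participants,
                        generate_anatomical, generate_subject_maps)

__all__ = [
    "PhantomDataset",
    "SplitSpec",
    "build_phantom_dataset",
    "split_dataset",
    "absolute_error_summary",
    "modality_volumes",
    "fit_family",
    "run_protocol",
]

MODALITIES = ("stiffness", "damping", "mre", "anatomical")


@dataclass
class PhantomDataset:
    """In-memory phantom cohort: property maps per subject plus coverage mask."""

    participants: pd.DataFrame
    mu: np.ndarray    # (n, D, H, W)
    xi: np.ndarray
    anat: np.ndarray
    mask: np.ndarray  # (D, H, W) shared coverage

    @property
    def ages(self) -> np.ndarray:
        return self.participants["age"].to_numpy(dtype=float)


def build_phantom_dataset(spec: CohortSpec, atlas: PhantomAtlas) -> PhantomDataset:
    """Generate a cohort and run every subject through the property pipeline
    (G', G'' -> stiffness/damping), exactly as real data would be processed."""
    participants = build_participants(spec)
    n = len(participants)
    mu = np.empty((n,) + atlas.shape)
    xi = np.empty_like(mu)
    anat = np.empty_like(mu)
    for i, row in participants.iterrows():
        modulus = generate_subject_maps(atlas, row["age"], row["cohort"], spec,
                                        seed=spec.seed + 1000 + i)
        props = compute_properties(modulus)
        mu[i], xi[i] = props.mu, props.xi
        anat[i] = generate_anatomical(atlas, row["age"], spec, seed=spec.seed + 1000 + i)
    return PhantomDataset(participants=participants, mu=mu, xi=xi, anat=anat,
                          mask=atlas.mask.copy())


def modality_volumes(ds: PhantomDataset, modality: str) -> np.ndarray:
    """Stack the channels a modality feeds to a model: (n, c, D, H, W)."""
    if modality == "stiffness":
        return ds.mu[:, None]
    if modality == "damping":
        return ds.xi[:, None]
    if modality == "mre":
        return np.stack([ds.mu, ds.xi], axis=1)
    if modality in ("anatomical", "mri"):
        return ds.anat[:, None]
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(participants: pd.DataFrame, spec: SplitSpec):
    """Deterministic train/test split over healthy subjects only."""
    healthy = participants.loc[participants["cohort"] == "healthy", "participant_id"]
    ids = healthy.to_numpy()
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 healthy subjects, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(round(spec.train_fraction * n))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def absolute_error_summary(predictions, ages):
    """(mean absolute error, median absolute error) in years."""
    predictions = np.asarray(predictions, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if predictions.shape != ages.shape or predictions.size == 0:
        raise ValueError("predictions and ages must be equal-length, non-empty")
    err = np.abs(predictions - ages)
    return float(err.mean()), float(np.median(err))


# --------------------------------------------------------------------------
# Family dispatch with desk-scale defaults
# --------------------------------------------------------------------------

@dataclass
class FamilyConfig:
    """Desk-scale model settings; override any field for other regimes."""

    pca_k: int = 10
    pca_lr: float = 0.05
    stage_channels: list = field(default_factory=lambda: [4, 8, 16, 32])
    embedding_dim: int = 32
    head_hidden: int = 16
    dropout: float = 0.0
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    noise_sd: float = 0.0
    nn_metric: str = "manhattan"
    nn_step: int = 1
    nn_end: int = 5
    sigma: float = 2.0
    ridge_alpha: float = 1.0


def fit_family(family: str, volumes, ages, mask, seed: int,
               config: FamilyConfig | None = None, modality: str = ""):
    """Fit one model family on already-normalised volumes."""
    cfg = config or FamilyConfig()
    volumes = np.asarray(volumes)
    if family == "null":
        return fit_null(ages, modality=modality)
    if family == "pca_gp":
        n_feat = int(np.asarray(mask, dtype=bool).sum()) * volumes.shape[1]
        k = min(cfg.pca_k, len(ages) - 1, n_feat)
        tc = TrainConfig(epochs=50, batch_size=len(ages), learning_rate=cfg.pca_lr,
                         noise_sd=cfg.noise_sd, seed=seed)
        return fit_pca_gp(volumes, ages, mask, k=k, train_config=tc, modality=modality)
    enc = EncoderConfig(input_channels=volumes.shape[1],
                        stage_channels=list(cfg.stage_channels),
                        embedding_dim=cfg.embedding_dim, dropout=cfg.dropout,
                        head_hidden=cfg.head_hidden)
    tc = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                     learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay,
                     noise_sd=cfg.noise_sd, seed=seed)
    if family == "supervised_cnn":
        return fit_supervised_cnn(volumes, ages, mask, enc, tc, modality=modality)
    if family == "ssl_contrastive":
        sched = NeighbourhoodSchedule(step=cfg.nn_step, end_count=cfg.nn_end,
                                      metric=cfg.nn_metric)
        return fit_ssl(volumes, ages, mask, enc, tc, sched, sigma=cfg.sigma,
                       ridge_alpha=cfg.ridge_alpha, modality=modality)
    raise ValueError(f"unknown family {family!r}")


def run_protocol(ds: PhantomDataset, families, modalities, n_seeds: int = 10,
                 config: FamilyConfig | None = None, train_fraction: float = 0.8,
                 norm_mode: str = "dataset") -> pd.DataFrame:
    """Full (family x modality x seed) comparison table.

    Per cell: fresh 80:20 split of the healthy subjects, normalisation
    fitted on the training split only, fresh model fit, held-out metrics.
    A failed fit is recorded (status column) and the protocol continues.
    """
    part = ds.participants
    idx_of = {pid: i for i, pid in enumerate(part["participant_id"])}
    rows = []
    for modality in modalities:
        vols_raw = modality_volumes(ds, modality)
        for seed in range(n_seeds):
            tr_ids, te_ids = split_dataset(part, SplitSpec(train_fraction, seed))
            tr = [idx_of[i] for i in tr_ids]
            te = [idx_of[i] for i in te_ids]
            masks_tr = np.broadcast_to(ds.mask, (len(tr),) + ds.mask.shape)
            masks_te = np.broadcast_to(ds.mask, (len(te),) + ds.mask.shape)
            if norm_mode == "dataset":
                v_tr, state = normalize(vols_raw[tr], masks_tr, mode="dataset")
                v_te, _ = normalize(vols_raw[te], masks_te, mode="dataset", state=state)
            else:
                v_tr, _ = normalize(vols_raw[tr], masks_tr, mode="image")
                v_te, _ = normalize(vols_raw[te], masks_te, mode="image")
            ages_tr = ds.ages[tr]
            ages_te = ds.ages[te]
            for family in families:
                try:
                    model = fit_family(family, v_tr, ages_tr, ds.mask, seed,
                                       config, modality)
                    pred = predict(model, v_te)
                    mae_mean, mae_median = absolute_error_summary(pred, ages_te)
                    rows.append(dict(family=family, modality=modality, seed=seed,
                                     mae_mean=mae_mean, mae_median=mae_median,
                                     status="ok"))
                except Exception as exc:  # recorded, protocol continues
                    rows.append(dict(family=family, modality=modality, seed=seed,
                                     mae_mean=np.nan, mae_median=np.nan,
                                     status=f"failed: {exc}"))
    return pd.DataFrame(rows)


def summarize_protocol(table: pd.DataFrame) -> pd.DataFrame:
    """Across-seed mean and sd of both error metrics per (family, modality)."""
    ok = table[table["status"] == "ok"]
    return (ok.groupby(["family", "modality"])[["mae_mean", "mae_median"]]
              .agg(["mean", "std", "count"]).reset_index())
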