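"""The three brain-age model families behind one train/predict contract.

* ``pca_gp``         — PCA feature extraction followed by exact Gaussian-process
  regression with a linear kernel; kernel variance and noise variance are
  optimised by Adam on the log marginal likelihood (50 steps by default),
  with fresh Gaussian noise on the inputs at every step as augmentation.
* ``supervised_cnn`` — the 3D residual encoder with a two-layer MLP head
  (embedding -> 64 -> 1), trained end-to-end with the L1 loss.
* ``ssl_contrastive`` — the same encoder trained with the adaptive-neighbourhood
  contrastive regression loss on L2-normalised embeddings; age is read out
  by ridge regression on the frozen embeddings.

All fits are deterministic given their seed (pure numpy on CPU), and
``predict`` is noise- and dropout-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from ._tensor import Adam, Tensor
from .contrastive import EmbeddingBatch, NeighbourhoodSchedule, loss_adaptive, select_neighbours
from .mech import NormalizationState
from .nn import Encoder3D, EncoderConfig, RegressionHead

__all__ = [
    "TrainConfig",
    "BrainAgeModel",
    "fit_pca_gp",
    "fit_supervised_cnn",
    "fit_ssl",
    "fit_null",
    "predict",
    "save_model",
    "load_model",
    "PAPER_PRESETS",
    "DESK_PRESET",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    noise_sd: float = 0.0
    lr_decay: float = 0.9
    lr_decay_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 3:
            raise ValueError("batch_size must be >= 3 (contrastive denominators need n >= 3)")

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.lr_decay ** (epoch // self.lr_decay_every)


@dataclass
class BrainAgeModel:
    """Fitted model container; `state` holds family-specific components."""

    family: str
    modality: str = ""
    state: dict = field(default_factory=dict)
    normalization: NormalizationState | None = None


def _check_volumes(volumes) -> np.ndarray:
    v = np.asarray(volumes, dtype=float)
    if v.ndim == 4:
        v = v[:, None]
    if v.ndim != 5:
        raise ValueError("expected volumes of shape (n, c, D, H, W)")
    return v


def _flatten_masked(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n, c, D, H, W) -> (n, c * n_mask_voxels), channels concatenated."""
    return v[:, :, mask].reshape(v.shape[0], -1)


# --------------------------------------------------------------------------
# PCA + Gaussian process with linear kernel
# --------------------------------------------------------------------------

def _gp_nll_and_grads(Z, y, log_v, log_s, jitter=1e-8):
    """Negative log marginal likelihood of K = v ZZ' + s I and its gradients
    w.r.t. (log v, log s)."""
    n = Z.shape[0]
    v, s = np.exp(log_v), np.exp(log_s)
    K = v * (Z @ Z.T) + (s + jitter) * np.eye(n)
    L = np.linalg.cholesky(K)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Kinv = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(n)))
    nll = 0.5 * y @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)
    dK_dv = v * (Z @ Z.T)
    dK_ds = s * np.eye(n)
    g_v = -0.5 * (alpha @ dK_dv @ alpha) + 0.5 * np.trace(Kinv @ dK_dv)
    g_s = -0.5 * (alpha @ dK_ds @ alpha) + 0.5 * s * np.trace(Kinv)
    return nll, g_v, g_s


def fit_pca_gp(train_volumes, ages, mask, k: int, train_config: TrainConfig,
               modality: str = "") -> BrainAgeModel:
    """PCA (k components) on flattened in-mask voxels, then an exact GP with a
    linear kernel on the scores. 50 training epochs = 50 Adam steps on the
    marginal likelihood with fresh Gaussian input noise each step."""
    v = _check_volumes(train_volumes)
    ages = np.asarray(ages, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    X = _flatten_masked(v, mask)
    n = X.shape[0]
    kmax = min(n, X.shape[1])
    if k > kmax:
        raise ValueError(f"k = {k} too large; admissible maximum is {kmax}")
    pca = PCA(n_components=k, random_state=train_config.seed)
    Z = pca.fit_transform(X)
    ymean = ages.mean()
    y = ages - ymean

    rng = np.random.default_rng(train_config.seed)
    theta = np.array([0.0, 0.0])  # log kernel variance, log noise variance
    m = np.zeros(2)
    vv = np.zeros(2)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, train_config.epochs + 1):
        Z_aug = Z + train_config.noise_sd * rng.normal(size=Z.shape)
        _, gv, gs = _gp_nll_and_grads(Z_aug, y, theta[0], theta[1])
        g = np.array([gv, gs])
        m = b1 * m + (1 - b1) * g
        vv = b2 * vv + (1 - b2) * g**2
        theta -= train_config.learning_rate * (m / (1 - b1**t)) / (np.sqrt(vv / (1 - b2**t)) + eps)

    kv, sv = np.exp(theta)
    K = kv * (Z @ Z.T) + (sv + 1e-8) * np.eye(n)
    alpha = np.linalg.solve(K, y)
    state = {
        "pca": pca, "Z": Z, "alpha": alpha, "kernel_var": kv, "noise_var": sv,
        "ymean": ymean, "mask": mask, "channels": v.shape[1],
    }
    return BrainAgeModel(family="pca_gp", modality=modality, state=state)


# --------------------------------------------------------------------------
# Supervised CNN
# --------------------------------------------------------------------------

def _batches(n, batch_size, rng, min_size=1):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        b = idx[start : start + batch_size]
        if len(b) >= min_size:
            yield b


def _abs(t: Tensor) -> Tensor:
    return t.relu() + (-t).relu()


def fit_supervised_cnn(train_volumes, ages, mask, encoder_config: EncoderConfig,
                       train_config: TrainConfig, modality: str = "",
                       log_path=None) -> BrainAgeModel:
    """End-to-end L1 regression: residual encoder -> MLP head.

    The head predicts the deviation from the training-mean age, which centres
    the optimisation without changing the model class. Gaussian augmentation
    noise is added inside the coverage mask only, after normalisation.
    """
    v = _check_volumes(train_volumes)
    ages = np.asarray(ages, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if v.shape[1] != encoder_config.input_channels:
        raise ValueError(f"volumes have {v.shape[1]} channels, config wants "
                         f"{encoder_config.input_channels}")
    enc = Encoder3D(encoder_config, seed=train_config.seed)
    enc.check_shape(v.shape[2:])
    head = RegressionHead(encoder_config.embedding_dim, encoder_config.head_hidden,
                          seed=train_config.seed + 1)
    params = enc.params() + head.params()
    opt = Adam(params, lr=train_config.learning_rate, weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed + 2)
    ymean = ages.mean()
    log_rows = []
    for epoch in range(train_config.epochs):
        opt.lr = train_config.lr_at(epoch)
        losses = []
        for b in _batches(len(ages), train_config.batch_size, rng):
            x = v[b].copy()
            if train_config.noise_sd > 0:
                x += train_config.noise_sd * rng.normal(size=x.shape) * mask
            pred = head(enc(Tensor(x), train=True))
            loss = _abs(pred - Tensor(ages[b] - ymean)).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log_rows.append((epoch, float(np.mean(losses)), opt.lr, ""))
    _write_log(log_path, log_rows)
    state = {"encoder": enc, "head": head, "ymean": ymean, "mask": mask,
             "config": encoder_config, "train_config": train_config}
    return BrainAgeModel(family="supervised_cnn", modality=modality, state=state)


# --------------------------------------------------------------------------
# Self-supervised contrastive model + ridge readout
# --------------------------------------------------------------------------

def fit_ssl(train_volumes, ages, mask, encoder_config: EncoderConfig,
            train_config: TrainConfig, schedule: NeighbourhoodSchedule,
            sigma: float = 2.0, ridge_alpha: float = 1.0, modality: str = "",
            log_path=None) -> BrainAgeModel:
    """Encoder trained on the adaptive-neighbourhood contrastive loss.

    Neighbour sets are recomputed per batch from the current (L2-normalised)
    embeddings at the epoch's scheduled size. After training, embeddings of
    the training set are frozen and a ridge regressor maps them to age.
    Batches smaller than max(3, end_count + 1) are dropped — the loss needs
    at least three samples and a neighbour pool larger than the end count.
    """
    v = _check_volumes(train_volumes)
    ages = np.asarray(ages, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if schedule.end_count >= train_config.batch_size:
        raise ValueError("schedule end_count must be < batch_size")
    enc = Encoder3D(encoder_config, seed=train_config.seed)
    enc.check_shape(v.shape[2:])
    opt = Adam(enc.params(), lr=train_config.learning_rate,
               weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed + 2)
    min_b = max(3, schedule.end_count + 1)
    log_rows = []
    for epoch in range(train_config.epochs):
        opt.lr = train_config.lr_at(epoch)
        losses, nn_size = [], None
        for b in _batches(len(ages), train_config.batch_size, rng, min_size=min_b):
            x = v[b].copy()
            if train_config.noise_sd > 0:
                x += train_config.noise_sd * rng.normal(size=x.shape) * mask
            emb = enc(Tensor(x), train=True).l2_normalize()
            nsets = select_neighbours(emb.data, epoch, schedule)
            nn_size = len(nsets[0])
            loss = loss_adaptive(EmbeddingBatch(emb, ages[b]), sigma, nsets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log_rows.append((epoch, float(np.mean(losses)), opt.lr, nn_size))
    _write_log(log_path, log_rows)

    emb_train = _embed(enc, v)
    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(emb_train, ages)
    state = {"encoder": enc, "ridge": ridge, "mask": mask, "config": encoder_config,
             "train_config": train_config, "schedule": schedule, "sigma": sigma}
    return BrainAgeModel(family="ssl_contrastive", modality=modality, state=state)


def _embed(enc: Encoder3D, v: np.ndarray, chunk: int = 16) -> np.ndarray:
    out = []
    for start in range(0, v.shape[0], chunk):
        e = enc(Tensor(v[start : start + chunk]), train=False).l2_normalize()
        out.append(e.data)
    return np.concatenate(out, axis=0)


def fit_null(ages, modality: str = "") -> BrainAgeModel:
    """Null predictor: always the training-set mean age."""
    return BrainAgeModel(family="null", modality=modality,
                         state={"ymean": float(np.mean(ages))})


def _write_log(log_path, rows):
    if log_path is None:
        return
    with open(log_path, "w") as fh:
        fh.write("epoch\tloss\tlr\tnn_size\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

def predict(model: BrainAgeModel, volumes) -> np.ndarray:
    """Predicted ages, one per volume; deterministic (no noise, no dropout)."""
    if model.family == "null":
        v = np.asarray(volumes)
        n = v.shape[0]
        return np.full(n, model.state["ymean"])
    v = _check_volumes(volumes)
    st = model.state
    if model.family == "pca_gp":
        if v.shape[1] != st["channels"]:
            raise ValueError(f"volumes have {v.shape[1]} channels, model expects {st['channels']}")
        X = _flatten_masked(v, st["mask"])
        z = st["pca"].transform(X)
        kstar = st["kernel_var"] * (z @ st["Z"].T)
        return kstar @ st["alpha"] + st["ymean"]
    cfg = st["config"]
    if v.shape[1] != cfg.input_channels:
        raise ValueError(f"volumes have {v.shape[1]} channels, model expects {cfg.input_channels}")
    if model.family == "supervised_cnn":
        emb = st["encoder"](Tensor(v), train=False)
        return st["head"](emb).data + st["ymean"]
    if model.family == "ssl_contrastive":
        emb = _embed(st["encoder"], v)
        return st["ridge"].predict(emb)
    raise ValueError(f"unknown model family {model.family!r}")


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def save_model(model: BrainAgeModel, path) -> None:
    """Checkpoint to .npz with embedded JSON config; reload is bit-identical."""
    arrays, meta = {}, {"family": model.family, "modality": model.modality}
    if model.normalization is not None:
        meta["normalization"] = json.loads(model.normalization.to_json())
    st = model.state
    if model.family == "null":
        meta["ymean"] = st["ymean"]
    elif model.family == "pca_gp":
        arrays.update(pca_mean=st["pca"].mean_, pca_components=st["pca"].components_,
                      Z=st["Z"], alpha=st["alpha"], mask=st["mask"])
        meta.update(kernel_var=st["kernel_var"], noise_var=st["noise_var"],
                    ymean=st["ymean"], channels=st["channels"])
    else:
        for i, p in enumerate(st["encoder"].params()):
            arrays[f"enc_{i}"] = p.data
        arrays["mask"] = st["mask"]
        meta["encoder_config"] = asdict(st["config"])
        if model.family == "supervised_cnn":
            for i, p in enumerate(st["head"].params()):
                arrays[f"head_{i}"] = p.data
            meta["ymean"] = st["ymean"]
        else:
            arrays["ridge_coef"] = st["ridge"].coef_
            meta["ridge_intercept"] = float(st["ridge"].intercept_)
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> BrainAgeModel:
    with np.load(path) as npz:
        data = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(data.pop("_meta")).decode())
    family = meta["family"]
    norm = None
    if "normalization" in meta:
        norm = NormalizationState(**meta["normalization"])
    if family == "null":
        return BrainAgeModel("null", meta["modality"], {"ymean": meta["ymean"]}, norm)
    if family == "pca_gp":
        pca = PCA(n_components=data["pca_components"].shape[0])
        pca.mean_ = data["pca_mean"]
        pca.components_ = data["pca_components"]
        st = {"pca": pca, "Z": data["Z"], "alpha": data["alpha"],
              "kernel_var": meta["kernel_var"], "noise_var": meta["noise_var"],
              "ymean": meta["ymean"], "mask": data["mask"].astype(bool),
              "channels": meta["channels"]}
        return BrainAgeModel("pca_gp", meta["modality"], st, norm)
    cfg = EncoderConfig(**meta["encoder_config"])
    enc = Encoder3D(cfg, seed=0)
    for i, p in enumerate(enc.params()):
        p.data = data[f"enc_{i}"]
    st = {"encoder": enc, "mask": data["mask"].astype(bool), "config": cfg}
    if family == "supervised_cnn":
        head = RegressionHead(cfg.embedding_dim, cfg.head_hidden, seed=0)
        for i, p in enumerate(head.params()):
            p.data = data[f"head_{i}"]
        st.update(head=head, ymean=meta["ymean"])
        return BrainAgeModel("supervised_cnn", meta["modality"], st, norm)
    ridge = Ridge()
    ridge.coef_ = data["ridge_coef"]
    ridge.intercept_ = meta["ridge_intercept"]
    st["ridge"] = ridge
    return BrainAgeModel("ssl_contrastive", meta["modality"], st, norm)


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

#: Best published hyperparameters per modality (dataset-level normalisation).
PAPER_PRESETS = {
    "pca_gp": {
        "stiffness": dict(lr=0.001, k=100, noise_sd=0.02),
        "damping": dict(lr=0.001, k=100, noise_sd=0.1),
        "mre": dict(lr=0.1, k=100, noise_sd=0.15),
        "mri": dict(lr=0.1, k=100, noise_sd=0.2),
    },
    "supervised_cnn": {
        "stiffness": dict(dropout=0.1, weight_decay=1e-4, noise_sd=0.2),
        "damping": dict(dropout=0.1, weight_decay=1e-4, noise_sd=0.1),
        "mre": dict(dropout=0.1, weight_decay=5e-5, noise_sd=0.15),
        "mri": dict(dropout=0.1, weight_decay=5e-5, noise_sd=0.15),
    },
    "ssl_contrastive": {
        "stiffness": dict(metric="euclidean", weight_decay=5e-5, noise_sd=0.15,
                          nn_step=2, nn_end=8),
        "damping": dict(metric="euclidean", weight_decay=1e-4, noise_sd=0.2,
                        nn_step=1, nn_end=14),
        "mre": dict(metric="manhattan", weight_decay=5e-5, noise_sd=0.1,
                    nn_step=5, nn_end=9),
        "mri": dict(metric="euclidean", weight_decay=5e-5, noise_sd=0.15,
                    nn_step=1, nn_end=12),
    },
}

#: Desk-scale profile: the whole pipeline runs CPU-only in minutes.
DESK_PRESET = {
    "grid": (24, 24, 24),
    "stage_channels": [4, 8, 16, 32],
    "embedding_dim": 32,
    "head_hidden": 16,
    "epochs": 20,
    "batch_size": 16,
    "learning_rate": 1e-3,
}
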