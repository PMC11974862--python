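"""Config-driven end-to-end runs with a provenance manifest.

A run executes up to eight stages in dependency order — generate,
preprocess, train, evaluate, saliency, bag, regional, at_risk — from a
single YAML/dict configuration. Every stage records its status and output
paths in a JSON manifest; a failed stage marks its dependents skipped, and
identical (config, seed) reruns produce identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (compare_groups, cohort_profile, flag_at_risk,
                     leave_cohort_out_refit, predict_disease_bags,
                     regional_refit_and_profile)
from .evaluation import (FamilyConfig, SplitSpec, build_phantom_dataset,
                         fit_family, modality_volumes, run_protocol,
                         split_dataset, summarize_protocol)
from .mech import normalize
from .models import save_model
from .saliency import SaliencyConfig, compute_saliency
from .synthetic import AgeMixture, CohortSpec, build_atlas, generate_cohort

__all__ = ["RunConfig", "RunManifest", "run"]

STAGES = ("generate", "preprocess", "train", "evaluate", "saliency", "bag",
          "regional", "at_risk")
_DEPS = {
    "preprocess": ("generate",),
    "train": ("preprocess",),
    "evaluate": ("preprocess",),
    "saliency": ("train",),
    "bag": ("preprocess",),
    "regional": ("preprocess",),
    "at_risk": ("regional",),
}


@dataclass
class RunConfig:
    out: str = "runs/run"
    seed: int = 0
    grid: tuple = (24, 24, 24)
    voxel_size_mm: float = 2.0
    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    families: list = field(default_factory=lambda: ["pca_gp", "ssl_contrastive"])
    modalities: list = field(default_factory=lambda: ["mre"])
    n_seeds: int = 3
    norm_mode: str = "dataset"
    model: dict = field(default_factory=dict)       # FamilyConfig overrides
    saliency: dict = field(default_factory=dict)    # SaliencyConfig overrides
    at_risk_threshold: float = 0.7
    write_volumes: bool = False                     # NIfTI cohort dump
    stages: dict = field(default_factory=dict)      # stage name -> bool

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # name -> {status, outputs, ...}

    def record(self, stage: str, status: str, outputs=(), error: str = ""):
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        if error:
            self.stages[stage]["error"] = error

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "version": self.version,
                       "stages": self.stages}, fh, indent=2)


def _cohort_spec(config: RunConfig) -> CohortSpec:
    kw = dict(config.cohort)
    if "age_mixture" in kw:
        kw["age_mixture"] = AgeMixture(**kw["age_mixture"])
    kw.setdefault("seed", config.seed)
    return CohortSpec(**kw)


def run(config: RunConfig) -> RunManifest:
    """Execute all enabled stages; the manifest is written even on failure."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.content_hash(), version=__version__)
    ctx: dict = {}

    def ready(stage: str) -> bool:
        return all(manifest.stages.get(d, {}).get("status") == "ok"
                   for d in _DEPS.get(stage, ()))

    for stage in STAGES:
        if not config.enabled(stage):
            manifest.record(stage, "disabled")
            continue
        if not ready(stage):
            manifest.record(stage, "skipped")
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, ctx, out)
            manifest.record(stage, "ok", outputs)
        except Exception:
            manifest.record(stage, "failed", error=traceback.format_exc(limit=3))
    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_generate(config, ctx, out):
    ctx["atlas"] = build_atlas(config.grid, config.voxel_size_mm, seed=config.seed)
    ctx["spec"] = _cohort_spec(config)
    outputs = []
    if config.write_volumes:
        generate_cohort(ctx["spec"], ctx["atlas"], out / "cohort")
        outputs.append(out / "cohort")
    return outputs


def _stage_preprocess(config, ctx, out):
    ctx["ds"] = build_phantom_dataset(ctx["spec"], ctx["atlas"])
    path = out / "participants.tsv"
    ctx["ds"].participants.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return [path]


def _stage_train(config, ctx, out):
    ds = ctx["ds"]
    family, modality = config.families[0], config.modalities[0]
    fam_cfg = FamilyConfig(**config.model)
    tr_ids, te_ids = split_dataset(ds.participants, SplitSpec(seed=config.seed))
    idx_of = {pid: i for i, pid in enumerate(ds.participants["participant_id"])}
    tr = [idx_of[i] for i in tr_ids]
    te = [idx_of[i] for i in te_ids]
    vols = modality_volumes(ds, modality)
    masks = np.broadcast_to(ds.mask, (len(tr),) + ds.mask.shape)
    v_tr, state = normalize(vols[tr], masks, mode=config.norm_mode,
                            state=None)
    model = fit_family(family, v_tr, ds.ages[tr], ds.mask, config.seed,
                       fam_cfg, modality)
    model.normalization = state
    ctx.update(model=model, norm_state=state, train_idx=tr, test_idx=te,
               ref_modality=modality)
    path = out / f"model_{family}_{modality}.npz"
    save_model(model, path)
    return [path]


def _stage_evaluate(config, ctx, out):
    table = run_protocol(ctx["ds"], config.families + ["null"], config.modalities,
                         n_seeds=config.n_seeds,
                         config=FamilyConfig(**config.model),
                         norm_mode=config.norm_mode)
    tpath = out / "evaluation.csv"
    table.to_csv(tpath, index=False)
    spath = out / "evaluation_summary.json"
    summary = summarize_protocol(table)
    summary.columns = ["_".join(filter(None, map(str, c))) if isinstance(c, tuple)
                       else c for c in summary.columns]
    summary.to_json(spath, orient="records", indent=2)
    return [tpath, spath]


def _stage_saliency(config, ctx, out):
    import nibabel as nib

    ds, model = ctx["ds"], ctx["model"]
    te = ctx["test_idx"]
    vols = modality_volumes(ds, ctx["ref_modality"])
    masks = np.broadcast_to(ds.mask, (len(te),) + ds.mask.shape)
    v_te, _ = normalize(vols[te], masks, mode=config.norm_mode,
                        state=ctx["norm_state"] if config.norm_mode == "dataset" else None)
    scfg = SaliencyConfig(**config.saliency)
    maps = compute_saliency(model, v_te, ds.ages[te], scfg)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    outputs = []
    for b, smap in maps.items():
        lo, hi = smap.age_range
        path = out / f"saliency_bin{b}_{lo:.0f}-{hi:.0f}yr.nii.gz"
        nib.save(nib.Nifti1Image(smap.data.astype(np.float32), affine), path)
        outputs.append(path)
    return outputs


def _diseases(ctx):
    cohorts = set(ctx["ds"].participants["cohort"])
    return [d for d in ("MCI", "AD") if d in cohorts]


def _stage_bag(config, ctx, out):
    outputs = []
    fam_cfg = FamilyConfig(**config.model)
    family, modality = config.families[0], config.modalities[0]
    stats = {}
    for disease in _diseases(ctx):
        model, state, (tr, ctrl, dis) = leave_cohort_out_refit(
            ctx["ds"], disease, family, modality, seed=config.seed, config=fam_cfg)
        bags = predict_disease_bags(ctx["ds"], model, state, ctrl, dis, modality)
        path = out / f"bag_{disease}.csv"
        bags.to_csv(path, index=False)
        outputs.append(path)
        rep = compare_groups(bags.loc[bags.cohort == disease, "bag"],
                             bags.loc[bags.cohort == "control", "bag"])
        stats[disease] = {"test": rep.test_name, "statistic": rep.statistic,
                          "p_value": rep.p_value,
                          "median_bag": float(bags.loc[bags.cohort == disease, "bag"].median())}
    spath = out / "bag_stats.json"
    with open(spath, "w") as fh:
        json.dump(stats, fh, indent=2)
    outputs.append(spath)
    return outputs


def _stage_regional(config, ctx, out):
    outputs = []
    fam_cfg = FamilyConfig(**config.model)
    family, modality = config.families[0], config.modalities[0]
    ctx["profiles"] = {}
    for disease in _diseases(ctx):
        prof = regional_refit_and_profile(ctx["ds"], ctx["atlas"], disease,
                                          family, modality, seed=config.seed,
                                          config=fam_cfg)
        ctx["profiles"][disease] = prof
        path = out / f"regional_profiles_{disease}.csv"
        prof.to_csv(path, index=False)
        outputs.append(path)
    return outputs


def _stage_at_risk(config, ctx, out):
    outputs = []
    for disease, prof in ctx.get("profiles", {}).items():
        reference = cohort_profile(prof, disease)
        controls = prof[prof["cohort"] == "control"]
        ranking = flag_at_risk(controls, reference, threshold=config.at_risk_threshold)
        path = out / f"at_risk_{disease}.csv"
        ranking.to_csv(path, index=False)
        outputs.append(path)
    return outputs


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "saliency": _stage_saliency,
    "bag": _stage_bag,
    "regional": _stage_regional,
    "at_risk": _stage_at_risk,
}
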