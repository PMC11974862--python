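"""Brain-age gaps, regional profiles, at-risk flagging and group statistics.

The brain-age gap (BAG) of a subject is the bias-corrected predicted age
minus the chronological age; positive values indicate accelerated aging.
Bias correction follows the robust convention: a Theil-Sen line (median of
pairwise slopes) is fitted to predicted-vs-chronological age on a held-out
healthy control cohort and subtracted, so any affine prediction rule maps
to exactly zero BAG.

Regional profiles repeat the whole pipeline per atlas region (volumes
masked to the region, model refitted, BAG recomputed), giving each subject
a 12-entry vector in a fixed region order. Cohort profiles are entrywise
means; healthy subjects are flagged as "at risk" when the Pearson
correlation of their profile with a disease cohort profile exceeds a
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import FamilyConfig, PhantomDataset, fit_family, modality_volumes
from .mech import normalize
from .models import BrainAgeModel, predict
from .synthetic import REGIONS, PhantomAtlas

__all__ = [
    "BiasModel",
    "StatReport",
    "fit_bias",
    "compute_bag",
    "leave_cohort_out_refit",
    "predict_disease_bags",
    "regional_refit_and_profile",
    "cohort_profile",
    "flag_at_risk",
    "compare_groups",
]


@dataclass
class BiasModel:
    """Theil-Sen line of predicted age vs chronological age on controls."""

    slope: float
    intercept: float

    def expected(self, ages) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ages, dtype=float)


def fit_bias(control_predictions, control_ages) -> BiasModel:
    """Median-of-pairwise-slopes fit; intercept = median(y - slope * x)."""
    y = np.asarray(control_predictions, dtype=float)
    x = np.asarray(control_ages, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 control subjects")
    if np.unique(x).size < 2:
        raise ValueError("control ages are all equal; slope undefined")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return BiasModel(slope=float(slope), intercept=float(intercept))


def compute_bag(predictions, ages, bias: BiasModel, subject_ids=None,
                cohorts=None) -> pd.DataFrame:
    """Per-subject BAG records: bag = prediction - (intercept + slope * age);
    the corrected prediction is age + bag."""
    predictions = np.asarray(predictions, dtype=float)
    ages = np.asarray(ages, dtype=float)
    bag = predictions - bias.expected(ages)
    return pd.DataFrame({
        "participant_id": subject_ids if subject_ids is not None
        else [f"s{i}" for i in range(len(ages))],
        "age": ages,
        "raw_prediction": predictions,
        "corrected_prediction": ages + bag,
        "bag": bag,
        "cohort": cohorts if cohorts is not None else [""] * len(ages),
    })


def _leave_cohort_out_indices(participants: pd.DataFrame, disease_label: str):
    cohort = participants["cohort"].to_numpy()
    control_for = participants.get("control_for")
    if control_for is None:
        raise ValueError("participants table has no 'control_for' column")
    control_for = control_for.fillna("").to_numpy()
    train = np.where((cohort == "healthy") & (control_for != disease_label))[0]
    controls = np.where((cohort == "healthy") & (control_for == disease_label))[0]
    disease = np.where(cohort == disease_label)[0]
    if len(controls) == 0:
        raise ValueError(f"no matched controls flagged for {disease_label}")
    return train, controls, disease


def leave_cohort_out_refit(ds: PhantomDataset, disease_label: str, family: str,
                           modality: str = "mre", seed: int = 0,
                           config: FamilyConfig | None = None):
    """Refit on healthy-minus-matched-controls; the disease cohort and its
    control subset are never seen in training.

    Returns (model, normalization state, train/control/disease index arrays).
    """
    train, controls, disease = _leave_cohort_out_indices(ds.participants, disease_label)
    vols = modality_volumes(ds, modality)
    masks = np.broadcast_to(ds.mask, (len(train),) + ds.mask.shape)
    v_tr, state = normalize(vols[train], masks, mode="dataset")
    model = fit_family(family, v_tr, ds.ages[train], ds.mask, seed, config, modality)
    return model, state, (train, controls, disease)


def predict_disease_bags(ds: PhantomDataset, model: BrainAgeModel, state,
                         controls, disease, modality: str = "mre") -> pd.DataFrame:
    """Predict controls + disease, fit the bias line on controls, emit BAGs."""
    vols = modality_volumes(ds, modality)
    idx = np.concatenate([controls, disease])
    masks = np.broadcast_to(ds.mask, (len(idx),) + ds.mask.shape)
    v, _ = normalize(vols[idx], masks, mode="dataset", state=state)
    pred = predict(model, v)
    n_ctrl = len(controls)
    bias = fit_bias(pred[:n_ctrl], ds.ages[controls])
    part = ds.participants
    return compute_bag(
        pred, ds.ages[idx], bias,
        subject_ids=part["participant_id"].to_numpy()[idx],
        cohorts=["control"] * n_ctrl + list(part["cohort"].to_numpy()[disease]),
    )


def regional_refit_and_profile(ds: PhantomDataset, atlas: PhantomAtlas,
                               disease_label: str, family: str,
                               modality: str = "mre", seed: int = 0,
                               config: FamilyConfig | None = None) -> pd.DataFrame:
    """Per-region leave-cohort-out BAGs: one profile row per control/disease
    subject, columns in the canonical region order.

    Regions with no in-mask voxels are skipped (recorded as NaN columns),
    never silently dropped from the ordering.
    """
    train, controls, disease = _leave_cohort_out_indices(ds.participants, disease_label)
    vols = modality_volumes(ds, modality)
    idx_eval = np.concatenate([controls, disease])
    part = ds.participants
    out = pd.DataFrame({
        "participant_id": part["participant_id"].to_numpy()[idx_eval],
        "age": ds.ages[idx_eval],
        "cohort": ["control"] * len(controls) + list(part["cohort"].to_numpy()[disease]),
    })
    for region in REGIONS:
        rmask = atlas.region_mask(region) & ds.mask
        if not rmask.any():
            warnings.warn(f"region {region} has no in-mask voxels; skipped", stacklevel=2)
            out[region] = np.nan
            continue
        rv = vols * rmask  # zero everything outside the region
        masks_tr = np.broadcast_to(rmask, (len(train),) + rmask.shape)
        v_tr, state = normalize(rv[train], masks_tr, mode="dataset")
        model = fit_family(family, v_tr, ds.ages[train], rmask, seed, config, modality)
        masks_ev = np.broadcast_to(rmask, (len(idx_eval),) + rmask.shape)
        v_ev, _ = normalize(rv[idx_eval], masks_ev, mode="dataset", state=state)
        pred = predict(model, v_ev)
        bias = fit_bias(pred[: len(controls)], ds.ages[controls])
        out[region] = pred - bias.expected(ds.ages[idx_eval])
    return out


def cohort_profile(profiles: pd.DataFrame, cohort: str) -> pd.Series:
    """Entrywise mean profile of one cohort, canonical region order."""
    sel = profiles[profiles["cohort"] == cohort]
    if len(sel) == 0:
        raise ValueError(f"no subjects in cohort {cohort!r}")
    return sel[list(REGIONS)].mean(axis=0)


def flag_at_risk(healthy_profiles: pd.DataFrame, reference: pd.Series,
                 threshold: float = 0.7) -> pd.DataFrame:
    """Rank healthy subjects by Pearson correlation of their regional profile
    with a disease cohort profile; similarity >= threshold sets the flag.

    Zero-variance profiles (similarity undefined) are excluded with a warning.
    """
    ref = reference[list(REGIONS)].to_numpy(dtype=float)
    rows = []
    for _, row in healthy_profiles.iterrows():
        vec = row[list(REGIONS)].to_numpy(dtype=float)
        if np.std(vec) == 0 or np.std(ref) == 0:
            warnings.warn(f"zero-variance profile for {row['participant_id']}; excluded",
                          stacklevel=2)
            continue
        r = float(np.corrcoef(vec, ref)[0, 1])
        rows.append(dict(participant_id=row["participant_id"], similarity=r,
                         flagged=r >= threshold))
    return (pd.DataFrame(rows)
            .sort_values("similarity", ascending=False)
            .reset_index(drop=True))


@dataclass
class StatReport:
    test_name: str
    statistic: float
    p_value: float
    paired: bool
    normality_p: tuple  # Shapiro-Wilk p per group


def compare_groups(values_a, values_b, paired: bool = False,
                   alpha_normality: float = 0.05) -> StatReport:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups normal (p > alpha) -> paired/independent t-test; otherwise
    Wilcoxon signed-rank (paired) or Mann-Whitney U (independent).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length groups")
    pa = float(stats.shapiro(a).pvalue)
    pb = float(stats.shapiro(b).pvalue)
    if pa > alpha_normality and pb > alpha_normality:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "independent t-test"
    else:
        if paired:
            res = stats.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    return StatReport(test_name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), paired=paired,
                      normality_p=(pa, pb))
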