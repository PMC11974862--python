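"""Synthetic viscoelastic brain phantoms for end-to-end pipeline testing.

Real MRE cohorts are shared only under data agreements, so this module
generates phantom cohorts whose *statistical* structure matches what the
analysis assumes: volumes in a common space (desk-scale 32x40x32 by default,
with the full 91x109x91 geometry available), a young-skewed age
distribution, global aging trends in stiffness (-0.33 %/yr) and damping
ratio (+0.34 %/yr), regional heterogeneity over ten subcortical structures
plus grey and white matter, and localized disease signatures (damping
elevation in hippocampus/brain stem for MCI, stiffness loss in
thalamus/pallidum for AD).

Maps are emitted as (G', G'') storage/loss modulus pairs via the algebraic
inverse of the property formulas, so the downstream stiffness/damping
computation is exercised on every phantom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mech import ComplexModulusMap, PropertyMaps, invert_properties

__all__ = [
    "REGIONS",
    "PhantomAtlas",
    "AgeMixture",
    "CohortSpec",
    "build_atlas",
    "sample_ages",
    "target_property_maps",
    "generate_subject_maps",
    "generate_anatomical",
    "generate_cohort",
    "load_cohort",
]

#: Canonical region order shared by every profile the pipeline emits.
REGIONS = (
    "caudate", "thalamus", "putamen", "pallidum", "hippocampus", "amygdala",
    "nucleus-accumbens", "ventral-diencephalon", "brain-stem", "cerebellum",
    "grey-matter", "white-matter",
)

# Fractional geometry: (centre fractions, radius fractions, paired?)
# Paired structures are placed in the left hemisphere and mirrored exactly.
_GEOMETRY = {
    "caudate": ((0.40, 0.62, 0.62), (0.050, 0.070, 0.080), True),
    "thalamus": ((0.40, 0.50, 0.58), (0.070, 0.070, 0.060), True),
    "putamen": ((0.33, 0.60, 0.56), (0.045, 0.070, 0.060), True),
    "pallidum": ((0.36, 0.55, 0.52), (0.035, 0.045, 0.040), True),
    "hippocampus": ((0.35, 0.42, 0.46), (0.040, 0.090, 0.040), True),
    "amygdala": ((0.33, 0.58, 0.44), (0.035, 0.040, 0.040), True),
    "nucleus-accumbens": ((0.38, 0.68, 0.48), (0.025, 0.030, 0.030), True),
    "ventral-diencephalon": ((0.43, 0.46, 0.48), (0.035, 0.050, 0.045), True),
    "brain-stem": ((0.50, 0.42, 0.26), (0.060, 0.070, 0.160), False),
    "cerebellum": ((0.50, 0.24, 0.30), (0.320, 0.200, 0.200), False),
    "grey-matter": ((0.50, 0.72, 0.34), (0.240, 0.160, 0.140), False),
    "white-matter": ((0.50, 0.58, 0.62), (0.260, 0.220, 0.160), False),
}

# Painting order: subcortical first (they keep their full extent), then the
# large compartments fill what is left.
_PAINT_ORDER = (
    "caudate", "thalamus", "putamen", "pallidum", "hippocampus", "amygdala",
    "nucleus-accumbens", "ventral-diencephalon", "brain-stem", "cerebellum",
    "white-matter", "grey-matter",
)


@dataclass
class PhantomAtlas:
    """Integer region-label volume; 0 = background, axis 2 = inferior->superior."""

    labels: np.ndarray
    region_table: dict  # region id -> name
    voxel_size_mm: float

    @property
    def shape(self):
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def region_mask(self, name: str) -> np.ndarray:
        rid = {v: k for k, v in self.region_table.items()}[name]
        return self.labels == rid

    def region_sizes(self) -> dict:
        return {name: int((self.labels == rid).sum()) for rid, name in self.region_table.items()}


def _ellipsoid(shape, centre_vox, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = 0.0
    for g, c, r in zip(grids, centre_vox, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def build_atlas(grid_shape, voxel_size_mm: float = 2.0, seed: int = 0) -> PhantomAtlas:
    """Deterministic phantom atlas with 12 regions.

    Paired subcortical structures get exactly mirror-symmetric voxel sets;
    the seed applies a small (+-3 %) jitter to region radii, identical for
    the two sides of a pair. Raises if any region ends up empty, naming the
    first region that does not fit.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 16:
        raise ValueError("each grid dimension must be >= 16")
    rng = np.random.default_rng(seed)
    jitter = {name: 1.0 + 0.03 * rng.uniform(-1, 1, size=3) for name in _PAINT_ORDER}
    X = grid_shape[0]
    labels = np.zeros(grid_shape, dtype=np.int16)
    region_table = {i + 1, REGIONS[i]} if False else {i + 1: REGIONS[i] for i in range(12)}
    name_to_id = {v: k for k, v in region_table.items()}

    for name in _PAINT_ORDER:
        (fx, fy, fz), (rx, ry, rz), paired = _GEOMETRY[name]
        radii = np.array([rx * X, ry * grid_shape[1], rz * grid_shape[2]]) * jitter[name]
        # x-centres are expressed against (X - 1) so the midline sits exactly
        # between voxels and mirroring x -> X-1-x is an exact symmetry
        centre = np.array([fx * (X - 1), fy * grid_shape[1], fz * grid_shape[2]])
        mask = _ellipsoid(grid_shape, centre, radii)
        if paired:
            mirror_centre = centre.copy()
            mirror_centre[0] = (X - 1) - centre[0]
            mask = mask | _ellipsoid(grid_shape, mirror_centre, radii)
        paint = mask & (labels == 0)
        if not paint.any():
            raise ValueError(
                f"grid {grid_shape} too small: region '{name}' does not fit"
            )
        labels[paint] = name_to_id[name]
    return PhantomAtlas(labels=labels, region_table=region_table, voxel_size_mm=voxel_size_mm)


@dataclass
class AgeMixture:
    """Two-component uniform mixture emulating a young-skewed cohort."""

    weights: tuple = (0.5, 0.5)
    bounds: tuple = ((18.0, 35.0), (35.0, 90.0))

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(lo >= hi for lo, hi in self.bounds):
            raise ValueError("each mixture component needs lo < hi")

    @property
    def mean(self) -> float:
        return sum(w * (lo + hi) / 2.0 for w, (lo, hi) in zip(self.weights, self.bounds))

    @property
    def range(self):
        return (min(lo for lo, _ in self.bounds), max(hi for _, hi in self.bounds))


def sample_ages(n: int, mixture: AgeMixture | None = None, seed: int = 0) -> np.ndarray:
    """Sample `n` ages from the two-component uniform mixture."""
    if n < 0:
        raise ValueError("n must be >= 0")
    mixture = mixture or AgeMixture()
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture.weights), size=n, p=mixture.weights)
    lo = np.array([b[0] for b in mixture.bounds])
    hi = np.array([b[1] for b in mixture.bounds])
    return lo[comp] + rng.random(n) * (hi[comp] - lo[comp])


_BASELINE_MU = {  # kPa, literature-plausible placeholders (configurable)
    "caudate": 2.3, "thalamus": 2.5, "putamen": 2.4, "pallidum": 2.6,
    "hippocampus": 2.1, "amygdala": 2.2, "nucleus-accumbens": 2.3,
    "ventral-diencephalon": 2.5, "brain-stem": 2.4, "cerebellum": 1.9,
    "grey-matter": 2.2, "white-matter": 2.6,
}
_BASELINE_XI = {
    "caudate": 0.28, "thalamus": 0.26, "putamen": 0.27, "pallidum": 0.25,
    "hippocampus": 0.30, "amygdala": 0.29, "nucleus-accumbens": 0.28,
    "ventral-diencephalon": 0.26, "brain-stem": 0.24, "cerebellum": 0.23,
    "grey-matter": 0.29, "white-matter": 0.27,
}


@dataclass
class CohortSpec:
    """Everything that defines a phantom cohort.

    Aging rates default to the global trends of the real data
    (-0.33 %/yr stiffness, +0.34 %/yr damping); disease effects are
    fractional offsets applied inside their target regions only.
    """

    n_healthy: int = 60
    n_mci: int = 0
    n_ad: int = 0
    age_mixture: AgeMixture = field(default_factory=AgeMixture)
    disease_age_range: tuple = (60.0, 88.0)
    beta_mu: float = -0.0033  # fractional stiffness change per year
    beta_xi: float = 0.0034   # fractional damping change per year
    regional_rate_modifiers: dict = field(default_factory=dict)  # region -> multiplier
    baseline_mu: dict = field(default_factory=lambda: dict(_BASELINE_MU))
    baseline_xi: dict = field(default_factory=lambda: dict(_BASELINE_XI))
    disease_effects: dict = field(default_factory=lambda: {
        "MCI": [("hippocampus", "xi", 0.10), ("brain-stem", "xi", 0.05)],
        "AD": [("thalamus", "mu", -0.15), ("pallidum", "mu", -0.08)],
    })
    noise_sd: float = 0.02        # relative voxel noise scale
    smooth_sigma: float = 1.0     # voxels; spatial autocorrelation of the noise
    age_ref: float = 41.0         # years; age at which maps equal their baselines
    anat_beta: float = -0.001     # weak aging slope of the anatomical channel
    anat_noise_sd: float = 0.05
    p_female: float = 183.0 / 311.0
    n_control_mci: int = 0        # healthy subjects flagged as MCI-matched controls
    n_control_ad: int = 0
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.baseline_mu.values()):
            raise ValueError("baseline_mu must be > 0 everywhere")
        if any(not (0 < v < 1) for v in self.baseline_xi.values()):
            raise ValueError("baseline_xi must lie in (0, 1)")

    @property
    def age_range(self):
        lo, hi = self.age_mixture.range
        return (min(lo, self.disease_age_range[0]), max(hi, self.disease_age_range[1]))


def _region_value(spec: CohortSpec, region: str, prop: str, age: float, cohort: str) -> float:
    base = (spec.baseline_mu if prop == "mu" else spec.baseline_xi)[region]
    beta = spec.beta_mu if prop == "mu" else spec.beta_xi
    mod = spec.regional_rate_modifiers.get(region, 1.0)
    value = base * (1.0 + mod * beta * (age - spec.age_ref))
    for reg, p, off in spec.disease_effects.get(cohort, []):
        if reg == region and p == prop:
            value *= 1.0 + off
    return value


def target_property_maps(atlas: PhantomAtlas, age: float, cohort: str,
                         spec: CohortSpec) -> PropertyMaps:
    """Noise-free per-region target stiffness/damping fields."""
    mu = np.zeros(atlas.shape)
    xi = np.zeros(atlas.shape)
    for rid, name in atlas.region_table.items():
        m = atlas.labels == rid
        mu[m] = _region_value(spec, name, "mu", age, cohort)
        xi[m] = _region_value(spec, name, "xi", age, cohort)
    return PropertyMaps(mu=mu, xi=xi, mask=atlas.mask)


def generate_subject_maps(atlas: PhantomAtlas, age: float, cohort: str,
                          spec: CohortSpec, seed: int = 0) -> ComplexModulusMap:
    """One subject's (G', G'') maps: regional targets + smoothed relative noise.

    With ``noise_sd = 0`` the emitted maps invert exactly back to the target
    stiffness/damping fields. Values are clipped to keep mu > 0 and
    xi in (0, 1); clipping at extreme parameters logs a warning.
    """
    lo, hi = spec.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside cohort range [{lo}, {hi}]")
    target = target_property_maps(atlas, age, cohort, spec)
    mu, xi = target.mu.copy(), target.xi.copy()
    mask = atlas.mask
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        n_mu = gaussian_filter(rng.standard_normal(atlas.shape), spec.smooth_sigma)
        n_xi = gaussian_filter(rng.standard_normal(atlas.shape), spec.smooth_sigma)
        mu *= 1.0 + spec.noise_sd * n_mu
        xi *= 1.0 + spec.noise_sd * n_xi
    clipped = (mu[mask] <= 0).sum() + ((xi[mask] <= 0) | (xi[mask] >= 1)).sum()
    if clipped:
        warnings.warn(f"{int(clipped)} voxel(s) clipped to keep mu > 0, xi in (0, 1)",
                      stacklevel=2)
    mu[mask] = np.clip(mu[mask], 1e-3, None)
    xi[mask] = np.clip(xi[mask], 1e-4, 0.999)
    mu[~mask] = 0.0
    xi[~mask] = 0.0
    g_storage, g_loss = invert_properties(mu, xi)
    return ComplexModulusMap(g_storage=g_storage, g_loss=g_loss, mask=mask)


def generate_anatomical(atlas: PhantomAtlas, age: float, spec: CohortSpec,
                        seed: int = 0) -> np.ndarray:
    """Anatomical channel: monotone transform of the label map + noise,
    carrying a (configurably weak) aging slope."""
    intensity = 0.4 + 0.6 * atlas.labels.astype(float) / len(atlas.region_table)
    intensity[~atlas.mask] = 0.0
    vol = intensity * (1.0 + spec.anat_beta * (age - spec.age_ref))
    if spec.anat_noise_sd > 0:
        rng = np.random.default_rng(seed + 7)
        vol = vol + spec.anat_noise_sd * gaussian_filter(
            rng.standard_normal(atlas.shape), spec.smooth_sigma) * atlas.mask
    return vol


def build_participants(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic participants table (id, age, sex, cohort, control_for)."""
    rng = np.random.default_rng(spec.seed)
    ages_h = sample_ages(spec.n_healthy, spec.age_mixture, seed=spec.seed + 1)
    lo, hi = spec.disease_age_range
    ages_d = lo + rng.random(spec.n_mci + spec.n_ad) * (hi - lo)
    ages = np.concatenate([ages_h, ages_d])
    cohorts = ["healthy"] * spec.n_healthy + ["MCI"] * spec.n_mci + ["AD"] * spec.n_ad
    sexes = np.where(rng.random(len(ages)) < spec.p_female, "F", "M")
    control_for = [""] * len(ages)
    # Flag the oldest healthy subjects as matched controls (disease cohorts
    # are old, so age-matching the bias-fitting cohort mirrors the study design).
    order = np.argsort(ages_h)[::-1]
    picks = order[: spec.n_control_mci + spec.n_control_ad]
    for j, idx in enumerate(picks):
        control_for[idx] = "MCI" if j < spec.n_control_mci else "AD"
    return pd.DataFrame({
        "participant_id": [f"sub-{i + 1:03d}" for i in range(len(ages))],
        "age": np.round(ages, 6),
        "sex": sexes,
        "cohort": cohorts,
        "control_for": control_for,
    })


def generate_cohort(spec: CohortSpec, atlas: PhantomAtlas, output_dir) -> pd.DataFrame:
    """Write a full phantom cohort to disk (NIfTI volumes + participants TSV).

    Per subject: ``<id>_gstorage.nii.gz``, ``<id>_gloss.nii.gz`` and
    ``<id>_anat.nii.gz``; plus ``atlas.nii.gz`` and ``participants.tsv``.
    Fully reproducible from (spec, atlas).
    """
    import nibabel as nib

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([atlas.voxel_size_mm] * 3 + [1.0])
    participants = build_participants(spec)
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), out / "atlas.nii.gz")
    for i, row in participants.iterrows():
        sid = row["participant_id"]
        modulus = generate_subject_maps(atlas, row["age"], row["cohort"], spec,
                                        seed=spec.seed + 1000 + i)
        anat = generate_anatomical(atlas, row["age"], spec, seed=spec.seed + 1000 + i)
        for name, vol in (("gstorage", modulus.g_storage), ("gloss", modulus.g_loss),
                          ("anat", anat)):
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                     out / f"{sid}_{name}.nii.gz")
    participants.to_csv(out / "participants.tsv", sep="\t", index=False,
                        float_format="%.6f")
    return participants


def load_cohort(directory):
    """Read back a generated cohort: (participants, atlas labels, volumes dict)."""
    import nibabel as nib

    d = Path(directory)
    participants = pd.read_csv(d / "participants.tsv", sep="\t",
                               keep_default_na=False)
    labels = np.asarray(nib.load(d / "atlas.nii.gz").dataobj).astype(np.int16)
    vols = {}
    for sid in participants["participant_id"]:
        vols[sid] = {
            name: np.asarray(nib.load(d / f"{sid}_{name}.nii.gz").dataobj, dtype=float)
            for name in ("gstorage", "gloss", "anat")
        }
    return participants, labels, vols
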