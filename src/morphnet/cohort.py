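"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a case-control gray-matter morphometry study: per
subject and per parcellation region it draws a sample of voxel-level GM
values from a region-specific Gaussian mixture. The design goals, in order:

* **Realistic similarity networks.** Each region's mixture has K (default
  8) semi-resolved components at shared locations spanning the GM value
  range; regions differ by small per-component perturbations of component
  means, widths and weights. Because every component's parameters are
  independently visible in the density, regional "shape space" is
  high-dimensional (~3K), which is what gives divergence-based similarity
  networks the small-world regime real morphometry shows (elevated
  clustering, near-random path length) rather than a modular-lattice
  regime. A two-component family was tried first and rejected: its shape
  space collapses to a few effective dimensions (overlapping components
  can compensate each other), producing near-disconnected cliques at
  sparse thresholds.
* **Community structure.** Region perturbations are drawn around latent
  community centroids on a hypersphere (default 26 small communities,
  emulating families of morphologically alike regions such as homotopic
  pairs and gyral subdivisions), so within-community similarity is
  elevated and thresholded graphs acquire clustered structure.
* **A recoverable group effect.** Patients receive a downward
  (atrophy-like) shift of the dominant mixture component in the configured
  effect nodes, scaled per subject by a random severity exposure and by a
  fixed per-node multiplier, so both nodal metrics and edge-wise
  connectivity differ between groups in a known location.
* **Clinical covariates** matching the emulated cohort's printed ranges,
  with the motor score generated to decrease and disease duration to
  increase with the realized exposure, so association recovery is testable
  with known signs.

Everything derives from one integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ClinicalSpec",
    "CohortConfig",
    "SubjectMorphometry",
    "RegionMixtures",
    "generate_cohort",
    "export_cohort",
    "parcellation_manifest",
    "population_similarity",
    "population_similarity_change",
]

PATIENT = "patient"
CONTROL = "control"

# mixture-family geometry (module constants; region-level variation and all
# cohort-level knobs live in CohortConfig)
_N_COMPONENTS = 8
_COMPONENT_RANGE = (0.20, 0.95)
_COMPONENT_SD = 0.05
_DOMINANT_WEIGHT = 5.0  # relative weight of component 1 before normalization
_MEAN_SCALE = 0.022  # per-component mean spread across regions
_DOMINANT_MEAN_SCALE = 0.005  # the GM background peak barely varies by region
_LOGSD_SCALE = 0.15  # per-component log-width spread
_LOGW_SCALE = 0.30  # per-component log-weight spread
_SUBJECT_DOMINANT_FRACTION = 0.5  # subject jitter damping on the background peak
_SUBJECT_LOGSD = 0.03  # subject-level width jitter
_SUBJECT_LOGW = 0.06  # subject-level weight jitter


@dataclass(frozen=True)
class ClinicalSpec:
    """Means/SDs/ranges of the clinical covariates (years unless noted).

    Defaults match the emulated cohort: pediatric patients aged 5-17
    (mean 10.37, SD 3.81), controls 6-20 (mean 10.30, SD 3.54), 24:14
    male:female in both groups of 38, onset 2.55 +/- 2.59 (0.5-12),
    duration 7.78 +/- 3.61 (2-16.5) and a 0-66 integer motor score
    (33 items scored 0-2).
    """

    age_mean_patient: float = 10.37
    age_sd_patient: float = 3.81
    age_range_patient: tuple[float, float] = (5.0, 17.0)
    age_mean_control: float = 10.30
    age_sd_control: float = 3.54
    age_range_control: tuple[float, float] = (6.0, 20.0)
    male_fraction: float = 24 / 38
    onset_mean: float = 2.55
    onset_sd: float = 2.59
    onset_range: tuple[float, float] = (0.5, 12.0)
    duration_mean: float = 7.78
    duration_sd: float = 3.61
    duration_range: tuple[float, float] = (2.0, 16.5)
    hfmse_max: int = 66
    hfmse_slope: float = 1.0  # logistic slope on standardized exposure
    hfmse_noise_sd: float = 0.5
    duration_exposure_corr: float = 0.6


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    ``effect_size`` is a standardized mean shift: each patient's
    effect-node distributions move their dominant component by
    ``exposure * subject_sd * m_j`` where the subject's severity exposure
    averages ``effect_size`` and the fixed per-node multipliers ``m_j``
    span 0.7-1.3 (so effect nodes are not all altered identically).
    ``subject_sd`` is the total between-subject location variability; it is
    split evenly across mixture components.
    """

    n_per_group: int = 38
    n_regions: int = 116
    voxels_per_region: tuple[int, int] = (400, 2000)
    n_communities: int | None = None  # default: ~4-5 regions per community
    effect_nodes: tuple = ()
    effect_size: float = 0.0
    subject_sd: float = 0.04
    clinical: ClinicalSpec = field(default_factory=ClinicalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.voxels_per_region
        if lo < 10 or hi < lo:
            raise ValueError("voxels_per_region must satisfy 10 <= lo <= hi")
        if self.n_communities is None:
            object.__setattr__(
                self, "n_communities", max(2, min(26, self.n_regions // 4))
            )
        if self.n_communities < 1 or self.n_communities > self.n_regions:
            raise ValueError("n_communities must be in [1, n_regions]")
        bad = [r for r in self.effect_nodes if r not in set(self.region_ids)]
        if bad:
            raise ValueError(
                f"effect node(s) {bad} outside the parcellation "
                f"(valid ids 1..{self.n_regions})"
            )
        object.__setattr__(self, "effect_nodes", tuple(self.effect_nodes))

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.n_regions + 1))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clinical = raw.pop("clinical", None)
        for key in ("voxels_per_region", "effect_nodes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if clinical is not None:
            for key in ("age_range_patient", "age_range_control",
                        "onset_range", "duration_range"):
                if key in clinical:
                    clinical[key] = tuple(clinical[key])
            return cls(clinical=ClinicalSpec(**clinical), **raw)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        d["voxels_per_region"] = list(self.voxels_per_region)
        d["effect_nodes"] = list(self.effect_nodes)
        d["clinical"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.clinical).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SubjectMorphometry:
    """One subject's per-region voxel-value samples."""

    subject_id: str
    group: str
    region_values: dict

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
        for rid, vals in self.region_values.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size == 0:
                raise ValueError(f"region {rid!r}: empty sample")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"region {rid!r}: non-finite values")
            self.region_values[rid] = vals


@dataclass(frozen=True)
class RegionMixtures:
    """Population-level mixture parameters of every region (one cohort).

    Arrays are (n_regions, K). ``community`` maps region index ->
    community label. The patient-group effect is *not* baked in here;
    see :func:`population_similarity_change`.
    """

    community: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    voxel_counts: np.ndarray


def parcellation_manifest(n_regions: int) -> pd.DataFrame:
    """Region id/name table standing in for an atlas lookup."""
    return pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "region_name": [f"region_{i:03d}" for i in range(1, n_regions + 1)],
        }
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; exact and cheap at these sizes."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _region_mixtures(rng, config: CohortConfig) -> RegionMixtures:
    """Draw the cohort's region-level mixture parameters.

    Regions live on a latent hypersphere in d = 3K dimensions; community
    centroids are random directions (near-equidistant in high dimension,
    so communities have no metric ordering among themselves) and regions
    scatter around their centroid with relative spread 0.3. The latent
    coordinates perturb, per component: the mean (scale 0.022), log-width
    (0.15) and log-weight (0.30) around the shared component layout.
    """
    n_regions = config.n_regions
    n_comm = config.n_communities
    K = _N_COMPONENTS
    d = 3 * K
    community = np.arange(n_regions) % n_comm

    centers = rng.normal(size=(n_comm, d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    z = centers[community] + 0.30 * rng.normal(size=(n_regions, d))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    z *= np.sqrt(d)  # unit-ish variance per coordinate

    locs = np.linspace(*_COMPONENT_RANGE, K)
    # the dominant component is the shared GM background peak: it sits at
    # nearly the same location in every region, so a disease shift of it is
    # a monotone similarity loss against every neighbor; regional identity
    # lives in the remaining components
    mean_scales = np.full(K, _MEAN_SCALE)
    mean_scales[0] = _DOMINANT_MEAN_SCALE
    means = locs[None, :] + mean_scales[None, :] * z[:, :K]
    sds = _COMPONENT_SD * np.exp(_LOGSD_SCALE * z[:, K : 2 * K])
    w_base = np.full(K, 1.0)
    w_base[0] = _DOMINANT_WEIGHT
    weights = w_base[None, :] * np.exp(_LOGW_SCALE * z[:, 2 * K :])
    weights /= weights.sum(axis=1, keepdims=True)

    lo_v, hi_v = config.voxels_per_region
    voxel_counts = rng.integers(lo_v, hi_v + 1, size=n_regions)
    return RegionMixtures(
        community=community, means=means, sds=sds, weights=weights,
        voxel_counts=voxel_counts,
    )


def _effect_shift_matrix(config: CohortConfig, exposure: float) -> np.ndarray:
    """Per-region dominant-component shift for one patient (length N)."""
    shift = np.zeros(config.n_regions)
    if config.effect_nodes:
        idx = np.array([r - 1 for r in config.effect_nodes])
        mult = np.linspace(0.7, 1.3, idx.size) if idx.size > 1 else np.ones(1)
        shift[idx] = -exposure * config.subject_sd * mult
    return shift


def _draw_subject_values(rng, mix: RegionMixtures, config: CohortConfig,
                         shift: np.ndarray) -> dict:
    n_regions, K = mix.means.shape
    subject_scales = np.full(K, config.subject_sd / np.sqrt(K))
    subject_scales[0] *= _SUBJECT_DOMINANT_FRACTION
    mu = mix.means + rng.normal(0, 1.0, (n_regions, K)) * subject_scales[None, :]
    mu[:, 0] += shift
    sd = mix.sds * np.exp(rng.normal(0, _SUBJECT_LOGSD, (n_regions, K)))
    w = mix.weights * np.exp(rng.normal(0, _SUBJECT_LOGW, (n_regions, K)))
    w /= w.sum(axis=1, keepdims=True)
    region_values = {}
    for i in range(n_regions):
        counts = rng.multinomial(mix.voxel_counts[i], w[i])
        parts = [rng.normal(mu[i, k], sd[i, k], counts[k]) for k in range(K)]
        vals = np.concatenate(parts)
        rng.shuffle(vals)
        region_values[i + 1] = np.clip(vals, 1e-3, None)
    return region_values


def generate_cohort(config: CohortConfig):
    """Generate ``(subjects, clinical)`` for one seeded synthetic cohort.

    Returns a list of :class:`SubjectMorphometry` (patients first) and a
    clinical :class:`pandas.DataFrame` with one row per subject and columns
    ``subject_id, group, age, sex, onset, duration, hfmse`` (the last three
    NaN for controls). Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    mix = _region_mixtures(rng, config)

    # per-patient severity exposure around the configured effect size
    if config.effect_size > 0:
        exposure = np.clip(
            config.effect_size * (1.0 + 0.3 * rng.normal(size=n)),
            0.2 * config.effect_size,
            None,
        )
    else:
        exposure = np.zeros(n)

    subjects: list[SubjectMorphometry] = []
    for group in (PATIENT, CONTROL):
        for s in range(n):
            sid = f"{'P' if group == PATIENT else 'C'}{s + 1:03d}"
            if group == PATIENT:
                shift = _effect_shift_matrix(config, exposure[s])
            else:
                shift = np.zeros(config.n_regions)
            subjects.append(
                SubjectMorphometry(sid, group, _draw_subject_values(rng, mix, config, shift))
            )

    clinical = _generate_clinical(rng, config, exposure)
    return subjects, clinical


def _generate_clinical(rng, config: CohortConfig, exposure: np.ndarray) -> pd.DataFrame:
    spec = config.clinical
    n = config.n_per_group
    n_male = int(round(spec.male_fraction * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))

    age_p = _truncated_normal(
        rng, spec.age_mean_patient, spec.age_sd_patient, *spec.age_range_patient, size=n
    )
    age_c = _truncated_normal(
        rng, spec.age_mean_control, spec.age_sd_control, *spec.age_range_control, size=n
    )
    onset = _truncated_normal(rng, spec.onset_mean, spec.onset_sd, *spec.onset_range, size=n)

    # duration positively coupled to exposure (more severe, longer duration)
    if exposure.std() > 0:
        z_e = (exposure - exposure.mean()) / exposure.std()
    else:
        z_e = np.zeros(n)
    rho = spec.duration_exposure_corr
    z = rho * z_e + np.sqrt(1 - rho**2) * rng.normal(size=n)
    duration = np.clip(spec.duration_mean + spec.duration_sd * z, *spec.duration_range)

    # motor score decreasing in exposure: round(max * logistic(-a*e + noise)),
    # centered so a cohort at the configured mean exposure averages ~ max/2
    lin = (
        spec.hfmse_slope * (config.effect_size - exposure)
        + rng.normal(0, spec.hfmse_noise_sd, size=n)
    )
    hfmse = np.clip(np.round(spec.hfmse_max * expit(lin)), 0, spec.hfmse_max).astype(int)

    rows = []
    for s in range(n):
        rows.append(
            {"subject_id": f"P{s + 1:03d}", "group": PATIENT, "age": age_p[s],
             "sex": sexes[s], "onset": onset[s], "duration": duration[s],
             "hfmse": hfmse[s]}
        )
    for s in range(n):
        rows.append(
            {"subject_id": f"C{s + 1:03d}", "group": CONTROL, "age": age_c[s],
             "sex": sexes[s], "onset": np.nan, "duration": np.nan, "hfmse": np.nan}
        )
    return pd.DataFrame(rows)


def _mixture_density(grid: np.ndarray, means, sds, weights) -> np.ndarray:
    z = (grid[:, None] - means[None, :]) / sds[None, :]
    comp = np.exp(-0.5 * z * z) / (sds[None, :] * np.sqrt(2 * np.pi))
    return comp @ weights


def population_similarity(
    config: CohortConfig,
    shifted: bool = False,
    n_points: int = 512,
    epsilon: float = 1e-10,
) -> np.ndarray:
    """Noise-free KLDs similarity matrix of the cohort's region mixtures.

    Evaluates the exact mixture densities (no sampling, no KDE) on a
    common grid. With ``shifted=True`` the patient group's
    dominant-component shift is applied at the mean exposure
    (``effect_size``).
    """
    rng = np.random.default_rng(config.seed)
    mix = _region_mixtures(rng, config)
    shift = _effect_shift_matrix(config, config.effect_size if shifted else 0.0)
    n = config.n_regions
    lo = mix.means.min() - 4 * mix.sds.max()
    hi = mix.means.max() + 4 * mix.sds.max()
    grid = np.linspace(lo, hi, n_points)

    dens = np.empty((n, n_points))
    for i in range(n):
        mu = mix.means[i].copy()
        mu[0] += shift[i]
        d = _mixture_density(grid, mu, mix.sds[i], mix.weights[i])
        d = np.maximum(d, epsilon)
        dens[i] = d / d.sum()

    logd = np.log(dens)
    w = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            skl = np.sum((dens[i] - dens[j]) * (logd[i] - logd[j]))
            w[i, j] = w[j, i] = np.exp(-skl)
    return w


def population_similarity_change(config: CohortConfig, n_points: int = 512) -> np.ndarray:
    """Noise-free group difference of the similarity matrix (patient - control).

    This is the generator's ground truth for which edges an inference
    procedure *should* flag; tests use it to define the planted component.
    """
    return population_similarity(config, shifted=True, n_points=n_points) - \
        population_similarity(config, shifted=False, n_points=n_points)


def export_cohort(subjects: Sequence[SubjectMorphometry], clinical: pd.DataFrame, path):
    """Write the long-format voxel table and clinical table as TSV.

    Creates ``cohort.tsv`` (columns subject_id, region_id, value) and
    ``clinical.tsv`` under ``path``; returns the two file paths. The pair
    round-trips losslessly through :func:`morphnet.io.read_cohort_table` /
    :func:`morphnet.io.read_clinical_table`.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort_path = path / "cohort.tsv"
    clinical_path = path / "clinical.tsv"

    frames = []
    for subj in subjects:
        for rid, vals in subj.region_values.items():
            frames.append(
                pd.DataFrame(
                    {"subject_id": subj.subject_id, "region_id": rid, "value": vals}
                )
            )
    if frames:
        long = pd.concat(frames, ignore_index=True)
    else:
        long = pd.DataFrame(columns=["subject_id", "region_id", "value"])
    long.to_csv(cohort_path, sep="\t", index=False, float_format="%.17g")
    clinical.to_csv(clinical_path, sep="\t", index=False, float_format="%.17g")
    return cohort_path, clinical_path
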