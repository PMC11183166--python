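"""File formats and run configuration.

Cohorts travel as a long-format TSV (subject_id, region_id, value) plus a
clinical TSV; similarity matrices as a compressed ``.npz`` stack with a
JSON metadata sidecar; real gray-matter data can optionally be ingested
from a NIfTI pair (GM value map + integer atlas label volume).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SubjectMorphometry
from .similarity import SimilarityMatrix
from .topology import SparsityGrid

__all__ = [
    "RunConfig",
    "read_cohort_table",
    "read_clinical_table",
    "read_parcellation",
    "read_nifti_pair",
    "save_matrix_stack",
    "load_matrix_stack",
    "save_matrix_tsv",
    "read_matrix_tsv",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ("subject_id", "region_id", "value")
CLINICAL_COLUMNS = ("subject_id", "group", "age", "sex", "onset", "duration", "hfmse")


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end analysis run needs.

    Defaults reproduce the reference analysis settings: 36-threshold
    sparsity grid 0.05-0.40 step 0.01, 10,000 permutations for global/nodal
    AUC tests, 5000 NBS permutations at primary t = 3.2, BH-FDR at
    q = 0.05.
    """

    cohort_table: str | None = None
    clinical_table: str | None = None
    output_dir: str = "morphnet_output"
    measure: str = "KLDs"
    grid: SparsityGrid = field(default_factory=SparsityGrid)
    n_null: int = 100
    n_perm_global: int = 10_000
    n_perm_nbs: int = 5000
    primary_t: float = 3.2
    q_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure not in ("KLDs", "JSDs"):
            raise ValueError("measure must be 'KLDs' or 'JSDs'")
        for name in ("n_null", "n_perm_global", "n_perm_nbs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.q_fdr < 1):
            raise ValueError("q_fdr must lie in (0, 1)")
        if self.primary_t <= 0:
            raise ValueError("primary_t must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grid = raw.pop("grid", None)
        cfg = cls(**raw) if grid is None else cls(grid=SparsityGrid(**grid), **raw)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_cohort_table(
    path,
    clinical: pd.DataFrame | None = None,
    parcellation: pd.DataFrame | None = None,
) -> list[SubjectMorphometry]:
    """Read a long-format voxel table into per-subject structures.

    Groups are taken from ``clinical`` when given (otherwise 'control' is
    assumed so standalone matrices can still be built). When a
    ``parcellation`` manifest is supplied, region ids outside it are
    rejected with the offending first row number.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COHORT_COLUMNS, path)
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
        raise ValueError(f"{path}: non-numeric or non-finite value at line {row}")
    df = df.assign(value=values)
    if parcellation is not None:
        valid = set(parcellation["region_id"])
        unknown = ~df["region_id"].isin(valid)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0]) + 2
            rid = df["region_id"].iloc[int(np.flatnonzero(unknown)[0])]
            raise ValueError(f"{path}: unknown region {rid!r} at line {row}")
    group_of = {}
    if clinical is not None:
        group_of = dict(zip(clinical["subject_id"], clinical["group"]))
    subjects = []
    for sid, sub in df.groupby("subject_id", sort=True):
        region_values = {
            rid: g["value"].to_numpy(dtype=float)
            for rid, g in sub.groupby("region_id", sort=True)
        }
        subjects.append(
            SubjectMorphometry(
                subject_id=str(sid),
                group=group_of.get(sid, "control"),
                region_values=region_values,
            )
        )
    return subjects


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("subject_id", "group"), path)
    return df


def read_parcellation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("region_id", "region_name"), path)
    return df


def read_nifti_pair(gm_path, atlas_path, subject_id: str = "subject", group: str = "control"):
    """Extract per-region gray-matter value samples from a NIfTI pair.

    Region ``k``'s sample is the set of GM-map values at voxels with atlas
    label ``k`` and GM value > 0. Atlas labels must be integers on the same
    voxel grid as the GM map; label 0 is background. Regions with no usable
    voxels are dropped with a logged warning.
    """
    import nibabel as nib

    gm_img = nib.load(str(gm_path))
    atlas_img = nib.load(str(atlas_path))
    gm = np.asarray(gm_img.dataobj, dtype=float)
    labels = np.asarray(atlas_img.dataobj)
    if gm.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: GM map {gm.shape} vs atlas {labels.shape}"
        )
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("atlas labels must be integer-valued")
    labels = labels.astype(np.int64)
    region_values = {}
    dropped = []
    for k in np.unique(labels):
        if k == 0:
            continue
        sample = gm[(labels == k) & (gm > 0)]
        if sample.size == 0:
            dropped.append(int(k))
            continue
        region_values[int(k)] = sample
    if dropped:
        logger.warning("dropped empty region(s): %s", dropped)
    if not region_values:
        raise ValueError("no usable voxels: every region is empty")
    return SubjectMorphometry(subject_id=subject_id, group=group, region_values=region_values)


def save_matrix_tsv(path, matrix: SimilarityMatrix) -> None:
    """Write one similarity matrix as delimited text with a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.regions, columns=matrix.regions)
    df.to_csv(path, sep="\t", index_label="region_id", float_format="%.12g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"measure": matrix.measure, "construction": matrix.meta},
                  fh, indent=2, default=str)


def read_matrix_tsv(path) -> SimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    meta = {}
    measure = "KLDs"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            raw = json.load(fh)
        measure = raw.get("measure", measure)
        meta = raw.get("construction", {})
    values = df.to_numpy()
    values = (values + values.T) / 2  # text round-trip can break exact symmetry
    return SimilarityMatrix(measure=measure, regions=list(df.index),
                            values=values, meta=meta)


def save_matrix_stack(path, matrices: list[SimilarityMatrix]) -> None:
    """Save a cohort's similarity matrices plus a JSON metadata sidecar."""
    path = Path(path)
    stack = np.stack([m.values for m in matrices])
    subject_ids = [m.meta.get("subject_id", str(i)) for i, m in enumerate(matrices)]
    np.savez_compressed(path, stack=stack)
    meta = {
        "measure": matrices[0].measure,
        "regions": list(matrices[0].regions),
        "subject_ids": subject_ids,
        "construction": matrices[0].meta,
    }
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_matrix_stack(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    stack = np.load(path)["stack"]
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return stack, meta
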