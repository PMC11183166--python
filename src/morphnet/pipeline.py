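"""End-to-end orchestration of the individual morphological network analysis.

Stages, in order: build one similarity network per subject; compute global
and nodal metric curves over the sparsity grid and their AUCs; compare AUCs
between groups by permutation (BH-FDR across regions within each nodal
metric family); localize altered connectivity with the network-based
statistic in both directions on the FDR-selected node set; correlate
altered nodal metrics with clinical variables (partial correlation, age and
sex as covariates); and compare demographics. All randomness derives from a
single root seed through named per-stage substreams, so partial re-runs are
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associate_metrics
from .cohort import CONTROL, PATIENT, SubjectMorphometry
from .inference import (
    bh_fdr,
    compare_demographics,
    nbs,
    permutation_test_auc_matrix,
)
from .io import RunConfig, read_clinical_table, read_cohort_table, save_matrix_stack
from .similarity import PDFGridSpec, build_similarity_matrix
from .topology import GLOBAL_METRICS, NODAL_METRICS, auc, metric_curves

__all__ = [
    "stage_seed",
    "build_cohort_matrices",
    "cohort_metric_tables",
    "nodal_group_tests",
    "global_group_tests",
    "run_pipeline",
]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    mix = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


def build_cohort_matrices(
    subjects: list[SubjectMorphometry],
    measure: str = "KLDs",
    spec: PDFGridSpec = PDFGridSpec(),
):
    """One similarity matrix per subject, tagged with its subject id."""
    matrices = []
    for subj in subjects:
        m = build_similarity_matrix(subj, measure=measure, spec=spec)
        m.meta["subject_id"] = subj.subject_id
        m.meta["group"] = subj.group
        matrices.append(m)
    return matrices


def cohort_metric_tables(
    matrices,
    grid,
    n_null: int,
    seed: int,
    compute_betweenness: bool = True,
    compute_eloc: bool = True,
):
    """Metric curves and AUC tables for a whole cohort.

    Returns ``(global_curves, nodal_curves, global_auc, nodal_auc)`` tidy
    frames. AUC frames are long: (subject_id, group, metric, auc) and
    (subject_id, group, node, metric, auc).
    """
    rng = np.random.default_rng(seed)
    g_frames, n_frames = [], []
    for m in matrices:
        sid = m.meta.get("subject_id")
        gdf, ndf = metric_curves(
            m,
            grid=grid,
            n_null=n_null,
            seed=int(rng.integers(2**31)),
            subject_id=sid,
            compute_betweenness=compute_betweenness,
            compute_eloc=compute_eloc,
        )
        gdf["group"] = m.meta.get("group")
        ndf["group"] = m.meta.get("group")
        g_frames.append(gdf)
        n_frames.append(ndf)
    global_curves = pd.concat(g_frames, ignore_index=True)
    nodal_curves = pd.concat(n_frames, ignore_index=True)

    g_auc_rows = []
    for (sid, grp), sub in global_curves.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values("threshold")
        for metric in GLOBAL_METRICS:
            col = "lambda" if metric == "lambda" else metric
            curve = sub[col].to_numpy()
            if np.isnan(curve).all():
                continue
            g_auc_rows.append(
                {"subject_id": sid, "group": grp, "metric": metric,
                 "auc": auc(curve, grid)}
            )
    n_auc_rows = []
    for (sid, grp, node), sub in nodal_curves.groupby(
        ["subject_id", "group", "node"], sort=True
    ):
        sub = sub.sort_values("threshold")
        for metric in NODAL_METRICS:
            curve = sub[metric].to_numpy()
            if np.isnan(curve).all():
                continue
            n_auc_rows.append(
                {"subject_id": sid, "group": grp, "node": node, "metric": metric,
                 "auc": auc(curve, grid)}
            )
    return global_curves, nodal_curves, pd.DataFrame(g_auc_rows), pd.DataFrame(n_auc_rows)


def _auc_matrix(auc_table: pd.DataFrame, metric: str, index: str = "node"):
    """Pivot one metric's AUCs to (subjects x variables) plus patient labels."""
    sub = auc_table[auc_table["metric"] == metric]
    wide = sub.pivot_table(index="subject_id", columns=index, values="auc", sort=True)
    groups = sub.drop_duplicates("subject_id").set_index("subject_id")["group"]
    labels = (groups.loc[wide.index] == PATIENT).to_numpy()
    return wide, labels


def global_group_tests(
    global_auc: pd.DataFrame, n_perm: int, seed: int
) -> pd.DataFrame:
    """Permutation tests on every global metric's AUC."""
    rows = []
    for metric in GLOBAL_METRICS:
        sub = global_auc[global_auc["metric"] == metric]
        if sub.empty:
            continue
        x = sub["auc"].to_numpy()[:, None]
        labels = (sub["group"] == PATIENT).to_numpy()
        obs, p, null = permutation_test_auc_matrix(
            x, labels, n_perm=n_perm, seed=stage_seed(seed, f"global:{metric}")
        )
        rows.append(
            {"metric": metric, "observed_diff": float(obs[0]), "p_value": float(p[0]),
             "threshold_95": float(np.percentile(np.abs(null[:, 0]), 95)),
             "n_perm": n_perm}
        )
    return pd.DataFrame(rows)


def nodal_group_tests(
    nodal_auc: pd.DataFrame, n_perm: int, seed: int, q: float = 0.05
) -> pd.DataFrame:
    """Per-node permutation tests with BH-FDR within each metric family."""
    rows = []
    for metric in NODAL_METRICS:
        if metric not in set(nodal_auc["metric"]):
            continue
        wide, labels = _auc_matrix(nodal_auc, metric)
        obs, p, _ = permutation_test_auc_matrix(
            wide.to_numpy(), labels, n_perm=n_perm,
            seed=stage_seed(seed, f"nodal:{metric}"),
        )
        fdr = bh_fdr(p, q=q)
        for j, node in enumerate(wide.columns):
            rows.append(
                {"node": node, "metric": metric, "observed_diff": float(obs[j]),
                 "p_raw": float(p[j]), "p_fdr": float(fdr.p_adjusted[j]),
                 "significant": bool(fdr.significant[j])}
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectMorphometry] | None = None,
    clinical: pd.DataFrame | None = None,
) -> Path:
    """Run every stage and write the full output tree.

    Inputs may be passed in memory or read from the configured TSV paths.
    Emits under ``config.output_dir``: the similarity stack, metric curves,
    AUC tables, global/nodal permutation results with FDR decisions, NBS
    component reports for both directions, the clinical correlation table,
    demographics, and a JSON manifest recording seeds and settings.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if clinical is None:
        if config.clinical_table is None:
            raise ValueError("no clinical table provided")
        clinical = read_clinical_table(config.clinical_table)
    if subjects is None:
        if config.cohort_table is None:
            raise ValueError("no cohort table provided")
        subjects = read_cohort_table(config.cohort_table, clinical=clinical)

    matrices = build_cohort_matrices(subjects, measure=config.measure)
    save_matrix_stack(out / "similarity_stack.npz", matrices)

    (global_curves, nodal_curves, global_auc, nodal_auc) = cohort_metric_tables(
        matrices, config.grid, config.n_null, stage_seed(config.seed, "curves")
    )
    global_curves.to_csv(out / "global_curves.tsv", sep="\t", index=False)
    nodal_curves.to_csv(out / "nodal_curves.tsv", sep="\t", index=False)
    global_auc.to_csv(out / "global_auc.tsv", sep="\t", index=False)
    nodal_auc.to_csv(out / "nodal_auc.tsv", sep="\t", index=False)

    global_tests = global_group_tests(
        global_auc, config.n_perm_global, config.seed
    )
    global_tests.to_csv(out / "global_tests.tsv", sep="\t", index=False)
    nodal_tests = nodal_group_tests(
        nodal_auc, config.n_perm_global, config.seed, q=config.q_fdr
    )
    nodal_tests.to_csv(out / "nodal_tests.tsv", sep="\t", index=False)

    # NBS on the sub-matrix of nodes significant in any nodal metric family
    sig_nodes = np.array(
        sorted(set(nodal_tests.loc[nodal_tests["significant"], "node"])), dtype=int
    )
    stack = np.stack([m.values for m in matrices])
    labels = np.array([s.group == PATIENT for s in subjects])
    nbs_report = {}
    if sig_nodes.size >= 2:
        for direction in ("patient>control", "patient<control"):
            res = nbs(
                stack,
                labels,
                node_mask=sig_nodes,
                primary_t=config.primary_t,
                n_perm=config.n_perm_nbs,
                direction=direction,
                seed=stage_seed(config.seed, f"nbs:{direction}"),
            )
            nbs_report[direction] = [
                {"nodes": list(c.nodes), "edges": [list(e) for e in c.edges],
                 "size": c.size, "corrected_p": c.corrected_p}
                for c in res.components
            ]
    else:
        nbs_report["note"] = "fewer than 2 FDR-significant nodes; NBS skipped"
    with open(out / "nbs_report.json", "w") as fh:
        json.dump(nbs_report, fh, indent=2)

    demo = compare_demographics(clinical)
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)

    # correlate significant nodal metrics with the clinical variables
    sig_pairs = nodal_tests.loc[nodal_tests["significant"], ["node", "metric"]]
    node_ids = sorted({r for s in subjects for r in s.region_values})
    targets = [
        (node_ids[int(row.node)], row.metric, var)
        for row in sig_pairs.itertuples()
        for var in ("duration", "hfmse")
    ]
    nodal_auc_named = nodal_auc.assign(
        node=[node_ids[i] for i in nodal_auc["node"]]
    )
    if targets:
        correlations = associate_metrics(nodal_auc_named, clinical, targets)
    else:
        correlations = pd.DataFrame(
            columns=["node", "metric", "clinical_variable", "r", "p", "n",
                     "covariates", "uncorrected"]
        )
    correlations.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)

    manifest = {
        "morphnet_version": __version__,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "grid"},
            "grid": dataclasses.asdict(config.grid),
        },
        "n_subjects": len(subjects),
        "n_regions": matrices[0].n_regions,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("curves", "nbs:patient>control", "nbs:patient<control")
        },
        "decisions": {
            "bandwidth_rule": "silverman",
            "pair_grid": "pooled range +/- padding*bandwidth, 256 points",
            "density_floor": 1e-10,
            "path_length_convention": "Lp = 1/Eg (harmonic mean)",
            "null_model": f"{config.n_null} degree-preserving rewired graphs, 10x|E| swaps",
            "tie_break": "descending similarity, then ascending (i, j)",
            "fdr_family": "within each nodal metric, across regions",
            "nbs_node_selection": "BH-FDR significant in any nodal metric",
            "nbs_component_size": "edge count",
            "p_value_smoothing": "none (raw proportion)",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
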