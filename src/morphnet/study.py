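"""Reference study conditions and the experiments run on them.

This module fixes the synthetic study designs that the package's headline
analyses (and the reproduction script) operate on, and implements the
experiments at those conditions:

* the **default cohort** — 38 subjects per group over a 116-region
  parcellation, the scale of the emulated study — with its group-mean
  small-world curves;
* the **effect-recovery design** — 38 per group over a 50-region
  parcellation with five effect nodes in one community at a standardized
  effect size of 1.5 — used for replicate-based power checks (nodal FDR
  detection, planted-component NBS recovery, clinical association signs).
  The reduced parcellation keeps a 20-replicate Monte-Carlo affordable
  while preserving the cohort size the inference actually sees.

Both the test suite and ``scripts/acceptance.py`` import from here so the
conditions cannot drift apart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import partial_correlation
from .cohort import (
    CohortConfig,
    generate_cohort,
    population_similarity,
    population_similarity_change,
)
from .inference import bh_fdr, nbs, permutation_test_auc_matrix
from .pipeline import build_cohort_matrices
from .similarity import SimilarityMatrix
from .topology import SparsityGrid, auc, small_world, threshold_by_sparsity

__all__ = [
    "default_cohort_config",
    "effect_recovery_config",
    "group_mean_small_world",
    "nodal_degree_auc",
    "effect_recovery_replicate",
]


def default_cohort_config(seed: int) -> CohortConfig:
    """The headline study design: 38 vs 38, 116 regions, no group effect."""
    return CohortConfig(seed=seed)


def effect_recovery_config(seed: int, effect_size: float = 1.5) -> CohortConfig:
    """Effect-recovery design: 50 regions, 5 well-connected effect nodes.

    The planted lesion targets regions that are established members of the
    similarity network (highest population-level similarity degree, one per
    community), mirroring pathology that strikes connected structures: a
    region with no strong similarities has no connectivity to lose, so
    peripheral targets would make the recovery question degenerate. The
    choice uses only the noise-free population model, never generated data.
    """
    base = CohortConfig(
        n_per_group=38,
        n_regions=50,
        voxels_per_region=(150, 400),
        effect_size=effect_size,
        seed=seed,
    )
    pop = population_similarity(base)
    popdeg = pop.sum(axis=0)
    community = np.arange(base.n_regions) % base.n_communities
    chosen: list[int] = []
    used = set()
    for idx in np.argsort(-popdeg):
        if community[idx] in used:
            continue
        chosen.append(int(idx) + 1)
        used.add(community[idx])
        if len(chosen) == 5:
            break
    return CohortConfig(
        n_per_group=base.n_per_group,
        n_regions=base.n_regions,
        voxels_per_region=base.voxels_per_region,
        effect_nodes=tuple(sorted(chosen)),
        effect_size=effect_size,
        seed=seed,
    )


def group_mean_small_world(
    matrices: list[SimilarityMatrix],
    groups: list[str],
    grid: SparsityGrid = SparsityGrid(),
    n_null: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-mean gamma/lambda/sigma at every sparsity threshold.

    Returns a tidy frame (group, threshold, gamma, lambda, sigma) where
    each entry is the mean over that group's subjects of the per-subject
    normalized metric (``n_null`` rewired nulls per subject per threshold).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m, grp in zip(matrices, groups):
        for s in grid.thresholds:
            g = threshold_by_sparsity(m, s)
            gamma, lam, sigma = small_world(
                g, n_null=n_null, seed=int(rng.integers(2**31))
            )
            rows.append(
                {"group": grp, "threshold": float(s), "gamma": gamma,
                 "lambda": lam, "sigma": sigma}
            )
    per_subject = pd.DataFrame(rows)
    return (
        per_subject.groupby(["group", "threshold"], as_index=False)
        [["gamma", "lambda", "sigma"]].mean()
    )


def nodal_degree_auc(
    matrices: list[SimilarityMatrix], grid: SparsityGrid = SparsityGrid()
) -> np.ndarray:
    """(n_subjects, n_nodes) matrix of nodal-degree AUCs over the grid."""
    out = []
    thresholds = grid.thresholds
    for m in matrices:
        degs = np.empty((thresholds.size, m.n_regions))
        for k, s in enumerate(thresholds):
            degs[k] = threshold_by_sparsity(m, s).degrees
        out.append([auc(degs[:, i], grid) for i in range(m.n_regions)])
    return np.asarray(out)


def effect_recovery_replicate(
    seed: int,
    effect_size: float = 1.5,
    n_perm_nodal: int = 1000,
    n_perm_nbs: int = 500,
    q: float = 0.05,
) -> dict:
    """One seeded replicate of the effect-recovery experiment.

    Generates the effect-recovery cohort, builds KLDs networks, and
    reports:

    - ``effect_nodes_significant``: all effect nodes FDR-significant in
      the nodal-degree AUC permutation tests;
    - ``effect_nodes_top_decile``: all effect nodes rank in the top decile
      of |group AUC difference|;
    - ``nbs_recall``: fraction of planted edges (population-truth
      similarity change at least half the maximum) covered by NBS
      components significant at corrected p <= 0.05
      (hypo-connectivity direction, full node set);
    - ``r_hfmse`` / ``r_duration``: partial correlations (age and sex as
      covariates, patients only) between the strongest effect node's
      degree AUC and the two clinical scores. Designed signs: positive
      for the motor score, negative for duration.
    """
    config = effect_recovery_config(seed, effect_size)
    subjects, clinical = generate_cohort(config)
    matrices = build_cohort_matrices(subjects, measure="KLDs")
    labels = np.array([s.group == "patient" for s in subjects])

    auc_matrix = nodal_degree_auc(matrices)
    observed, p, _ = permutation_test_auc_matrix(
        auc_matrix, labels, n_perm=n_perm_nodal, seed=seed
    )
    fdr = bh_fdr(p, q=q)
    effect_idx = np.array([r - 1 for r in config.effect_nodes])
    n_top = max(1, config.n_regions // 10)
    top = np.argsort(-np.abs(observed))[:n_top]

    # planted edges from the generator's population-level ground truth
    delta = population_similarity_change(config)
    iu = np.triu_indices(config.n_regions, 1)
    magnitude = np.abs(delta[iu])
    planted_mask = magnitude >= 0.5 * magnitude.max()
    planted = {
        (int(iu[0][k]), int(iu[1][k]))
        for k in np.flatnonzero(planted_mask)
    }

    stack = np.stack([m.values for m in matrices])
    res = nbs(
        stack, labels, primary_t=3.2, n_perm=n_perm_nbs,
        direction="patient<control", seed=seed,
    )
    detected = {
        tuple(sorted(e))
        for c in res.components if c.corrected_p <= 0.05
        for e in c.edges
    }
    recall = len(planted & detected) / len(planted) if planted else float("nan")

    # clinical association of the planted-node degree signature (mean AUC
    # over effect nodes; averaging suppresses node-level rank noise)
    node_auc = auc_matrix[: config.n_per_group, effect_idx].mean(axis=1)
    patients = clinical[clinical["group"] == "patient"]
    cov = np.column_stack(
        [patients["age"].to_numpy(), (patients["sex"] == "M").astype(float)]
    )
    r_hfmse = partial_correlation(
        node_auc, patients["hfmse"].to_numpy(dtype=float), cov
    ).r
    r_duration = partial_correlation(
        node_auc, patients["duration"].to_numpy(dtype=float), cov
    ).r

    return {
        "effect_nodes_significant": bool(fdr.significant[effect_idx].all()),
        "effect_nodes_top_decile": bool(np.isin(effect_idx, top).all()),
        "n_significant_nodes": int(fdr.significant.sum()),
        "nbs_recall": float(recall),
        "nbs_significant": bool(any(c.corrected_p <= 0.05 for c in res.components)),
        "r_hfmse": float(r_hfmse),
        "r_duration": float(r_duration),
    }
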