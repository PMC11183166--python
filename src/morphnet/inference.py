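"""Group inference: permutation tests, BH-FDR and the network-based statistic.

AUC metrics are compared between groups with a label-permutation test on
the group-mean difference (two-tailed, raw-proportion p-values, with an
exhaustive enumeration mode for tiny samples). Nodal-metric discovery is
controlled with the Benjamini-Hochberg step-up procedure. Altered
connectivity is localized with the network-based statistic (NBS): edge-wise
two-sample t statistics on raw similarity values within a node mask, a
primary height threshold, connected-component extraction, and family-wise
error control from the permutation distribution of the maximal component
size (size = edge count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .cohort import CONTROL, PATIENT

__all__ = [
    "PermutationResult",
    "FDRDecision",
    "NBSComponent",
    "NBSResult",
    "permutation_test_auc",
    "permutation_test_auc_matrix",
    "bh_fdr",
    "nbs",
    "compare_demographics",
]


@dataclass(frozen=True)
class PermutationResult:
    metric: str
    observed_diff: float
    p_value: float
    n_perm: int
    threshold_95: float
    null_distribution: np.ndarray = field(repr=False)
    seed: int | None = None
    exhaustive: bool = False


@dataclass(frozen=True)
class FDRDecision:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    q: float


@dataclass(frozen=True)
class NBSComponent:
    nodes: tuple
    edges: tuple
    size: int
    corrected_p: float


@dataclass(frozen=True)
class NBSResult:
    direction: str
    primary_t: float
    n_perm: int
    components: tuple
    max_null_sizes: np.ndarray = field(repr=False)
    edge_t: np.ndarray = field(repr=False)
    node_mask: tuple = ()
    seed: int | None = None


def _perm_matrix(n_total: int, n_a: int, n_perm: int, rng) -> np.ndarray:
    """Boolean (n_perm, n_total) matrix; each row marks a resampled group A.

    Ranking iid uniforms gives a uniform random subset per row without a
    Python-level loop.
    """
    return np.argsort(rng.random((n_perm, n_total)), axis=1) < n_a


def permutation_test_auc_matrix(
    x: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized permutation tests across columns of ``x``.

    ``x`` is (n_subjects, n_variables); ``labels`` is boolean with True for
    group A. Returns ``(observed_diff, p_values, null_diffs)`` where the
    null is built by reassigning subjects to groups without replacement and
    ``p = mean(|null| >= |observed|)`` per column (two-tailed).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_a = int(labels.sum())
    n_b = labels.size - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    observed = x[labels].mean(axis=0) - x[~labels].mean(axis=0)
    rng = np.random.default_rng(seed)
    total = x.sum(axis=0)
    sel = _perm_matrix(labels.size, n_a, n_perm, rng)
    sum_a = sel.astype(float) @ x  # (n_perm, n_vars)
    null = sum_a / n_a - (total - sum_a) / n_b
    p = (np.abs(null) >= np.abs(observed)[None, :]).mean(axis=0)
    return observed, p, null


def permutation_test_auc(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    metric: str = "",
    exhaustive: bool | None = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Two-tailed permutation test on the group-mean difference of AUCs.

    Group labels are reshuffled without replacement ``n_perm`` times; the
    p-value is the raw proportion of permuted |differences| at least as
    large as the observed one, and ``threshold_95`` is the 95th percentile
    of the null |difference| distribution (the significance threshold the
    procedure uses at alpha = 0.05). When ``exhaustive`` is true (default
    for <= 10 subjects in total) every group assignment is enumerated and
    the p-value is exact. ``smoothed=True`` switches to the
    add-one-permutation estimate ``(count + 1)/(n_perm + 1)`` (never
    exactly zero); the default raw proportion matches the reference
    procedure.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, a.size + b.size
    observed = a.mean() - b.mean()
    if exhaustive is None:
        exhaustive = n_total <= 10
    if exhaustive:
        null = np.array(
            [
                pooled[list(idx)].mean()
                - np.delete(pooled, list(idx)).mean()
                for idx in combinations(range(n_total), n_a)
            ]
        )
    else:
        labels = np.zeros(n_total, dtype=bool)
        labels[:n_a] = True
        _, _, null = permutation_test_auc_matrix(
            pooled[:, None], labels, n_perm=n_perm, seed=seed
        )
        null = null[:, 0]
    count = int((np.abs(null) >= abs(observed)).sum())
    if smoothed and not exhaustive:
        p = (count + 1) / (null.size + 1)
    else:
        p = count / null.size
    return PermutationResult(
        metric=metric,
        observed_diff=float(observed),
        p_value=p,
        n_perm=null.size,
        threshold_95=float(np.percentile(np.abs(null), 95)),
        null_distribution=null,
        seed=seed,
        exhaustive=bool(exhaustive),
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> FDRDecision:
    """Benjamini-Hochberg step-up control of the false discovery rate."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return FDRDecision(p, p.copy(), np.zeros(0, dtype=bool), q)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRDecision(p_raw=p, p_adjusted=p_adj, significant=reject, q=q)


def _edge_t_stats(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of ``x`` (A minus B)."""
    n_a = labels.sum()
    n_b = labels.size - n_a
    xa, xb = x[labels], x[~labels]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    return np.where(se > 0, t, 0.0)


def _max_component_sizes(
    t_cols: np.ndarray, primary_t: float, iu: np.ndarray, ju: np.ndarray, n_nodes: int
) -> int:
    """Largest connected-component edge count among suprathreshold edges."""
    mask = t_cols >= primary_t
    if not mask.any():
        return 0
    rows, cols = iu[mask], ju[mask]
    g = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, assign = sparse.csgraph.connected_components(g, directed=False)
    comp_of_edge = assign[rows]
    return int(np.bincount(comp_of_edge).max())


def nbs(
    stack: np.ndarray,
    labels: np.ndarray,
    node_mask: np.ndarray | None = None,
    primary_t: float = 3.2,
    n_perm: int = 5000,
    direction: str = "patient>control",
    seed: int = 0,
    batch: int = 500,
    smoothed: bool = False,
) -> NBSResult:
    """Network-based statistic on a stack of similarity matrices.

    Parameters
    ----------
    stack:
        Array ``(n_subjects, N, N)`` of raw (unthresholded) similarity
        matrices.
    labels:
        Boolean per subject, True = patient (group A).
    node_mask:
        Indices of the nodes forming the sub-connection matrix (e.g. nodes
        with group differences in nodal metrics); all nodes when None.
    direction:
        ``'patient>control'`` tests hyper-connectivity (t >= primary_t on
        A-minus-B statistics), ``'patient<control'`` hypo-connectivity.

    Each suprathreshold connected component of size ``k`` (edge count)
    receives ``corrected_p = #(permutation max component size >= k) /
    n_perm``, where every permutation relabels subjects and re-runs the
    edge-test / threshold / component procedure on the same sub-matrix.
    An absence of suprathreshold edges yields an empty component list.
    """
    stack = np.asarray(stack, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_subj, n_total_nodes = stack.shape[0], stack.shape[1]
    if labels.size != n_subj:
        raise ValueError("labels length must match the stack")
    if direction not in ("patient>control", "patient<control"):
        raise ValueError(f"unknown direction {direction!r}")
    if node_mask is None:
        node_mask = np.arange(n_total_nodes)
    node_mask = np.asarray(node_mask, dtype=int)
    if node_mask.size == 0:
        raise ValueError("node_mask must be non-empty")

    sub = stack[:, node_mask[:, None], node_mask[None, :]]
    m = node_mask.size
    iu, ju = np.triu_indices(m, 1)
    x = sub[:, iu, ju]  # (n_subj, n_edges)
    sign = 1.0 if direction == "patient>control" else -1.0
    t_obs = sign * _edge_t_stats(x, labels)

    # observed components
    comps: list[NBSComponent] = []
    obs_mask = t_obs >= primary_t
    if obs_mask.any():
        rows, cols = iu[obs_mask], ju[obs_mask]
        g = sparse.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(m, m))
        n_comp, assign = sparse.csgraph.connected_components(g, directed=False)
        comp_of_edge = assign[rows]
        for c in range(n_comp):
            sel = comp_of_edge == c
            if not sel.any():
                continue
            edges = [
                (int(node_mask[r]), int(node_mask[cc]))
                for r, cc in zip(rows[sel], cols[sel])
            ]
            nodes = sorted({v for e in edges for v in e})
            comps.append(
                NBSComponent(
                    nodes=tuple(nodes), edges=tuple(edges), size=int(sel.sum()),
                    corrected_p=float("nan"),
                )
            )

    # permutation null of the maximal component size
    rng = np.random.default_rng(seed)
    n_a = int(labels.sum())
    max_sizes = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        sel = _perm_matrix(n_subj, n_a, nb, rng)
        for i in range(nb):
            t_perm = sign * _edge_t_stats(x, sel[i])
            max_sizes[done + i] = _max_component_sizes(t_perm, primary_t, iu, ju, m)
        done += nb

    def corrected(k: int) -> float:
        count = int((max_sizes >= k).sum())
        if smoothed:
            return (count + 1) / (n_perm + 1)
        return count / n_perm  # raw proportion, as in the reference procedure

    comps = [
        NBSComponent(nodes=c.nodes, edges=c.edges, size=c.size,
                     corrected_p=corrected(c.size))
        for c in comps
    ]
    comps.sort(key=lambda c: (-c.size, c.nodes))
    return NBSResult(
        direction=direction,
        primary_t=primary_t,
        n_perm=n_perm,
        components=tuple(comps),
        max_null_sizes=max_sizes,
        edge_t=t_obs,
        node_mask=tuple(int(v) for v in node_mask),
        seed=seed,
    )


def compare_demographics(clinical: pd.DataFrame) -> pd.DataFrame:
    """Between-group demographic comparison (age t-test, sex chi-square).

    Returns a tidy table with one row per variable: the group summaries,
    the test statistic and its two-tailed p-value, plus descriptive rows
    (no test) for the patient-only clinical variables. A Shapiro-Wilk
    normality p-value for age is reported descriptively per group.
    """
    patients = clinical[clinical["group"] == PATIENT]
    controls = clinical[clinical["group"] == CONTROL]
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 subjects per group")

    rows = []
    age_p, age_c = patients["age"].to_numpy(), controls["age"].to_numpy()
    t_stat, t_p = stats.ttest_ind(age_p, age_c, equal_var=True)
    sw_p = stats.shapiro(age_p).pvalue if len(age_p) >= 3 else np.nan
    sw_c = stats.shapiro(age_c).pvalue if len(age_c) >= 3 else np.nan
    rows.append(
        {
            "variable": "age",
            "patient_summary": f"{age_p.mean():.2f} +/- {age_p.std(ddof=1):.2f}",
            "control_summary": f"{age_c.mean():.2f} +/- {age_c.std(ddof=1):.2f}",
            "test": "two-sample t",
            "statistic": float(t_stat),
            "p_value": float(t_p),
            "shapiro_p_patient": float(sw_p),
            "shapiro_p_control": float(sw_c),
        }
    )

    table = pd.crosstab(clinical["group"], clinical["sex"]).reindex(
        index=[PATIENT, CONTROL], columns=["M", "F"], fill_value=0
    )
    observed = table.to_numpy()
    nonzero = observed[:, observed.sum(axis=0) > 0]
    if nonzero.shape[1] < 2:  # single-sex cohort: no association to test
        chi2, chi_p = 0.0, 1.0
    else:
        chi2, chi_p, _, _ = stats.chi2_contingency(nonzero, correction=False)
    fmt = lambda row: ":".join(str(int(v)) for v in row)
    rows.append(
        {
            "variable": "sex (M:F)",
            "patient_summary": fmt(table.loc[PATIENT, ["M", "F"]]),
            "control_summary": fmt(table.loc[CONTROL, ["M", "F"]]),
            "test": "chi-square",
            "statistic": float(chi2),
            "p_value": float(chi_p),
            "shapiro_p_patient": np.nan,
            "shapiro_p_control": np.nan,
        }
    )

    for var in ("onset", "duration", "hfmse"):
        if var in clinical.columns and patients[var].notna().any():
            vals = patients[var].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "variable": var,
                    "patient_summary": f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f}",
                    "control_summary": "NA",
                    "test": "none",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "shapiro_p_patient": np.nan,
                    "shapiro_p_control": np.nan,
                }
            )
    return pd.DataFrame(rows)
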