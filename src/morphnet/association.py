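"""Clinical association via Pearson partial correlation.

Altered nodal AUC metrics are correlated with clinical variables in the
patient group while controlling for age and sex: both variables are
residualized on the covariates (with an intercept) and the Pearson
correlation of the residuals is reported, with a two-tailed p-value from
the t transform at ``df = n - 2 - n_covariates``. Reported p-values are
uncorrected for multiple comparisons, and the output flags them as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PATIENT

__all__ = ["PartialCorrelationResult", "partial_correlation", "associate_metrics"]


@dataclass(frozen=True)
class PartialCorrelationResult:
    x_name: str
    y_name: str
    covariate_names: tuple
    r: float
    p: float
    n: int
    df: int


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple = (),
) -> PartialCorrelationResult:
    """Pearson partial correlation of ``x`` and ``y`` given covariates.

    With no covariates this reduces to the ordinary Pearson correlation
    (residualization on the intercept only mean-centers the variables).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    design = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant variable after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        x_name=x_name,
        y_name=y_name,
        covariate_names=tuple(covariate_names),
        r=r,
        p=p,
        n=n,
        df=df,
    )


def associate_metrics(
    nodal_auc: pd.DataFrame,
    clinical: pd.DataFrame,
    targets: list[tuple],
    covariates: tuple = ("age", "sex"),
) -> pd.DataFrame:
    """Partial correlations between nodal AUC metrics and clinical scores.

    Parameters
    ----------
    nodal_auc:
        Tidy frame with columns ``subject_id, node, metric, auc``.
    clinical:
        The cohort clinical table; only patients are used.
    targets:
        Tuples ``(node, metric, clinical_variable)``; each yields one row.
    covariates:
        Clinical columns to control for. ``sex`` is encoded as a binary
        indicator (M=1, F=0). Rows with missing values are dropped
        listwise per target.

    The returned table carries an ``uncorrected`` flag: p-values are not
    adjusted for the number of targets.
    """
    patients = clinical[clinical["group"] == PATIENT].copy()
    rows = []
    for node, metric, clin_var in targets:
        sub = nodal_auc[(nodal_auc["node"] == node) & (nodal_auc["metric"] == metric)]
        if sub.empty:
            raise ValueError(f"unknown node/metric pair ({node!r}, {metric!r})")
        if clin_var not in patients.columns:
            raise ValueError(f"unknown clinical variable {clin_var!r}")
        merged = patients.merge(
            sub[["subject_id", "auc"]], on="subject_id", how="inner"
        )
        cols = ["auc", clin_var, *covariates]
        merged = merged.dropna(subset=[c for c in cols if c in merged.columns])
        cov_arrays = []
        for cv in covariates:
            v = merged[cv]
            if cv == "sex":
                v = (v == "M").astype(float)
            cov_arrays.append(v.to_numpy(dtype=float))
        cov = np.column_stack(cov_arrays) if cov_arrays else None
        res = partial_correlation(
            merged["auc"].to_numpy(dtype=float),
            merged[clin_var].to_numpy(dtype=float),
            cov,
            x_name=f"{metric}@{node}",
            y_name=clin_var,
            covariate_names=covariates,
        )
        rows.append(
            {
                "node": node,
                "metric": metric,
                "clinical_variable": clin_var,
                "r": res.r,
                "p": res.p,
                "n": res.n,
                "covariates": ",".join(covariates),
                "uncorrected": True,
            }
        )
    return pd.DataFrame(rows)
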