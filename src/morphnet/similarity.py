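"""Divergence-based morphological similarity networks.

A single subject's morphological brain network is built by treating each
parcellation region's voxel-level gray-matter values as a sample from an
unknown distribution, estimating that distribution with a Gaussian-kernel
KDE, and scoring every region pair by how close the two distributions are.
Two similarity measures are provided:

* ``KLDs`` — ``exp(-SKL)`` where ``SKL = KL(P||Q) + KL(Q||P)`` (natural
  log), mapping the symmetric Kullback-Leibler divergence into ``(0, 1]``.
* ``JSDs`` — ``1 - JSD(P, Q)`` with the Jensen-Shannon divergence taken in
  base 2 so that ``JSD`` (and hence the similarity) lies in ``[0, 1]``.

Distributions for a pair are discretized on a common grid spanning the
pooled value range plus a few bandwidths of padding, floored at a small
epsilon and renormalized, so that every divergence is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import rel_entr

__all__ = [
    "PDFGridSpec",
    "RegionalPDF",
    "SimilarityMatrix",
    "silverman_bandwidth",
    "estimate_region_pdf",
    "kl_symmetric",
    "klds",
    "jsds",
    "build_similarity_matrix",
]

Measure = Literal["KLDs", "JSDs"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class PDFGridSpec:
    """Discretization settings for regional probability distributions.

    Parameters
    ----------
    n_points:
        Number of evaluation points on each pair-specific common grid.
    padding:
        Extent added beyond the pooled sample min/max, in units of the
        (larger) kernel bandwidth, so KDE tails are not truncated abruptly.
    epsilon:
        Density floor applied per grid point before renormalization; keeps
        Kullback-Leibler terms finite when one distribution's support does
        not cover the other's.
    fine_points:
        Resolution of the per-region KDE cache used by the fast
        interpolating matrix builder.
    """

    n_points: int = 256
    padding: float = 3.0
    epsilon: float = 1e-10
    fine_points: int = 512

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.fine_points < self.n_points:
            raise ValueError("fine_points must be >= n_points")


@dataclass(frozen=True)
class RegionalPDF:
    """A region's value distribution discretized on a grid.

    ``density`` holds per-grid-point probability masses (not densities):
    after flooring at ``epsilon`` the vector is renormalized to sum to one,
    which is the discrete form all divergences operate on.
    """

    region_id: object
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float = float("nan")

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)
        if grid.ndim != 1 or grid.shape != density.shape:
            raise ValueError("grid and density must be 1-D and equally long")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.isclose(density.sum(), 1.0, atol=1e-9):
            raise ValueError("density must sum to 1")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric region-by-region similarity for one subject."""

    measure: str
    regions: tuple
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "regions", tuple(self.regions))
        n = len(self.regions)
        if values.shape != (n, n):
            raise ValueError("values must be N x N for N regions")
        if np.max(np.abs(values - values.T)) != 0:
            raise ValueError("similarity matrix must be exactly symmetric")
        if not np.allclose(np.diag(values), 1.0):
            raise ValueError("diagonal must be 1")
        if values.min() < 0 or values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel.

    ``h = 0.9 * min(sd, IQR/1.34) * n**(-1/5)``, falling back to the sample
    standard deviation when the interquartile range is degenerate.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("bandwidth undefined for zero-spread sample")
    return float(0.9 * scale * n ** (-0.2))


def _validate_sample(values: np.ndarray, region_id: object) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 10:
        raise ValueError(f"region {region_id!r}: need at least 10 values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"region {region_id!r}: sample contains non-finite values")
    if np.ptp(values) == 0:
        raise ValueError(
            f"region {region_id!r}: all values equal; kernel bandwidth is undefined"
        )
    return values


def _kde_on_grid(values: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Exact Gaussian-kernel density evaluated at every grid point."""
    z = (grid[:, None] - values[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * _SQRT2PI)


def _floor_and_normalize(density: np.ndarray, epsilon: float) -> np.ndarray:
    floored = np.maximum(density, epsilon)
    return floored / floored.sum()


def estimate_region_pdf(
    values: np.ndarray,
    region_id: object = None,
    bandwidth_rule: Callable[[np.ndarray], float] = silverman_bandwidth,
    spec: PDFGridSpec = PDFGridSpec(),
    grid: np.ndarray | None = None,
) -> RegionalPDF:
    """Discretized Gaussian-KDE distribution of one region's values.

    When ``grid`` is omitted the evaluation grid spans the sample range plus
    ``spec.padding`` bandwidths on each side with ``spec.n_points`` points;
    a caller-supplied grid (e.g. a pair-specific common grid) is used as-is.
    The evaluated density is floored at ``spec.epsilon`` and renormalized to
    sum to one.
    """
    values = _validate_sample(values, region_id)
    h = float(bandwidth_rule(values))
    if not np.isfinite(h) or h <= 0:
        raise ValueError(f"region {region_id!r}: invalid bandwidth {h}")
    if grid is None:
        lo = values.min() - spec.padding * h
        hi = values.max() + spec.padding * h
        grid = np.linspace(lo, hi, spec.n_points)
    else:
        grid = np.asarray(grid, dtype=float)
    density = _floor_and_normalize(_kde_on_grid(values, grid, h), spec.epsilon)
    return RegionalPDF(region_id=region_id, grid=grid, density=density, bandwidth=h)


def _check_same_grid(p: RegionalPDF, q: RegionalPDF) -> None:
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise ValueError("distributions must share an identical grid")


def kl_symmetric(p: RegionalPDF, q: RegionalPDF) -> float:
    """Symmetric Kullback-Leibler divergence ``KL(P||Q) + KL(Q||P)``.

    Natural logarithm, over the discretized (floored, renormalized)
    distributions; always finite and >= 0.
    """
    _check_same_grid(p, q)
    return _skl_arrays(p.density, q.density)


def _skl_arrays(pd_: np.ndarray, qd: np.ndarray) -> float:
    # rel_entr handles zero-mass bins: 0*log(0/q) = 0, p*log(p/0) = inf
    return float(rel_entr(pd_, qd).sum() + rel_entr(qd, pd_).sum())


def klds(p: RegionalPDF, q: RegionalPDF) -> float:
    """Symmetric-KL-based similarity ``exp(-SKL)`` in ``(0, 1]``."""
    return float(np.exp(-kl_symmetric(p, q)))


def _jsd_arrays(pd_: np.ndarray, qd: np.ndarray) -> float:
    m = 0.5 * (pd_ + qd)
    kl_pm = rel_entr(pd_, m).sum()
    kl_qm = rel_entr(qd, m).sum()
    return float((0.5 * kl_pm + 0.5 * kl_qm) / np.log(2.0))


def jsds(p: RegionalPDF, q: RegionalPDF) -> float:
    """Jensen-Shannon-based similarity ``1 - JSD`` with base-2 logs.

    The base-2 Jensen-Shannon divergence of two distributions lies in
    ``[0, 1]``, so the similarity does too.
    """
    _check_same_grid(p, q)
    return 1.0 - _jsd_arrays(p.density, q.density)


def _measure_from_arrays(measure: str) -> Callable[[np.ndarray, np.ndarray], float]:
    if measure == "KLDs":
        return lambda pd_, qd: float(np.exp(-_skl_arrays(pd_, qd)))
    if measure == "JSDs":
        return lambda pd_, qd: 1.0 - _jsd_arrays(pd_, qd)
    raise ValueError(f"unknown measure {measure!r}; expected 'KLDs' or 'JSDs'")


def build_similarity_matrix(
    subject,
    measure: Measure = "KLDs",
    spec: PDFGridSpec = PDFGridSpec(),
    bandwidth_rule: Callable[[np.ndarray], float] = silverman_bandwidth,
    method: Literal["interp", "exact"] = "interp",
) -> SimilarityMatrix:
    """Build one subject's morphological similarity network.

    For each unordered region pair, both regions' KDEs are discretized on a
    pair-specific common grid spanning the pooled value range plus
    ``spec.padding`` bandwidths, floored and renormalized, and converted to
    the requested similarity. The diagonal is fixed at 1 (self-similarity
    carries no information and is excluded from downstream thresholding).

    ``method='interp'`` (default) evaluates each region's KDE once on a fine
    per-region grid and linearly interpolates onto pair grids — orders of
    magnitude faster at whole-cohort scale and accurate to well under a
    percent of the exact values. ``method='exact'`` performs the literal
    per-pair KDE evaluation.

    ``subject`` may be a ``SubjectMorphometry`` (anything with a
    ``region_values`` mapping) or a plain mapping ``region_id -> values``.
    """
    region_values: Mapping = getattr(subject, "region_values", subject)
    regions = list(region_values.keys())
    n = len(regions)
    if n < 2:
        raise ValueError("need at least 2 regions")

    failures = []
    samples = {}
    for rid in regions:
        try:
            samples[rid] = _validate_sample(region_values[rid], rid)
        except ValueError as exc:
            failures.append(str(exc))
    if failures:
        raise ValueError("invalid region samples:\n" + "\n".join(failures))

    sim_fn = _measure_from_arrays(measure)

    bandwidths = {rid: float(bandwidth_rule(samples[rid])) for rid in regions}
    lows = {rid: samples[rid].min() - spec.padding * bandwidths[rid] for rid in regions}
    highs = {rid: samples[rid].max() + spec.padding * bandwidths[rid] for rid in regions}

    if method == "interp":
        # cache each region's KDE on a grid reaching well beyond the pair
        # padding: pair grids of separated regions sample this region's far
        # tail, where truncating to zero would distort the KL log-ratios
        fine_pad = max(spec.padding, 8.0)
        fine: dict = {}
        for rid in regions:
            h = bandwidths[rid]
            g = np.linspace(
                samples[rid].min() - fine_pad * h,
                samples[rid].max() + fine_pad * h,
                spec.fine_points,
            )
            fine[rid] = (g, _kde_on_grid(samples[rid], g, bandwidths[rid]))
    elif method != "exact":
        raise ValueError(f"unknown method {method!r}")

    values = np.eye(n)
    for a in range(n):
        ra = regions[a]
        for b in range(a + 1, n):
            rb = regions[b]
            lo = min(lows[ra], lows[rb])
            hi = max(highs[ra], highs[rb])
            g = np.linspace(lo, hi, spec.n_points)
            if method == "interp":
                ga, da = fine[ra]
                gb, db = fine[rb]
                pd_ = np.interp(g, ga, da, left=0.0, right=0.0)
                qd = np.interp(g, gb, db, left=0.0, right=0.0)
            else:
                pd_ = _kde_on_grid(samples[ra], g, bandwidths[ra])
                qd = _kde_on_grid(samples[rb], g, bandwidths[rb])
            pd_ = _floor_and_normalize(pd_, spec.epsilon)
            qd = _floor_and_normalize(qd, spec.epsilon)
            s = min(max(sim_fn(pd_, qd), 0.0), 1.0)
            values[a, b] = values[b, a] = s

    meta = {
        "measure": measure,
        "method": method,
        "n_points": spec.n_points,
        "padding": spec.padding,
        "epsilon": spec.epsilon,
        "bandwidth_rule": getattr(bandwidth_rule, "__name__", "custom"),
    }
    return SimilarityMatrix(measure=measure, regions=regions, values=values, meta=meta)
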