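"""Common allometric component (CAC) / residual shape component (RSC)
decomposition and group-comparison statistics for size variables.

The CAC is the pooled within-group direction of covariation between shape and
log centroid size: shapes and sizes are centred by their group means (so
between-group differences do not leak into the axis estimate), the axis is the
normalised within-group regression of shape on size, and the residual shape
components are the principal components of the within-group shape variation
orthogonal to that axis.  Scores for both CAC and RSCs are computed from
grand-mean-centred shapes, so group structure stays visible in the score
plots while the axis itself is a pooled within-group estimate.

The module also houses the scalar size statistics used alongside the shape
analysis: Wilcoxon rank-sum contrasts between groups (e.g. oval window area
by site), a standard-deviation separation statistic, and the all-one-sex
binomial probability used when arguing about sex ratios in small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .procrustes import GPAResult, _fix_signs


class AllometryError(ValueError):
    """Degenerate input to the allometric decomposition."""


@dataclass
class AllometryResult:
    cac_axis: np.ndarray          # unit vector in shape space, (3p,)
    cac_scores: np.ndarray        # per specimen, grand-mean-centred projection
    rsc_axes: np.ndarray          # (d, 3p), orthonormal, orthogonal to cac_axis
    rsc_scores: np.ndarray        # (n, d)
    slope: float                  # pooled within-group regression slope
    r2: float                     # CAC scores vs log CS, pooled
    p_value: float
    ids: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()


def _group_center(X: np.ndarray, groups: Sequence[str]) -> np.ndarray:
    out = X.astype(float).copy()
    garr = np.asarray(groups)
    for g in np.unique(garr):
        m = garr == g
        out[m] = out[m] - out[m].mean(axis=0)
    return out


def cac_rsc(aligned_shapes: np.ndarray, log_cs: np.ndarray,
            groups: Sequence[str], n_rsc: int | None = None,
            ids: Sequence[str] = ()) -> AllometryResult:
    """Decompose shape variation into the common allometric component and
    residual shape components.

    ``aligned_shapes`` may be (n, p, 3) Procrustes-aligned coordinates or the
    (n, 3p) vectorised form.  ``log_cs`` is the natural log of centroid size.

    Raises
    ------
    AllometryError
        If log centroid size has (numerically) zero within-group variance,
        which leaves the allometric direction undefined.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    s = np.asarray(log_cs, dtype=float)
    groups = tuple(groups)
    n, q = X.shape
    g = len(set(groups))
    if n != len(s) or n != len(groups):
        raise AllometryError("shapes, log_cs and groups must share n")
    if not np.all(np.isfinite(s)):
        raise AllometryError("log centroid sizes must be finite")
    if n <= g + 1:
        raise AllometryError(f"need n > g + 1 specimens (n={n}, g={g})")

    Xw = _group_center(X, groups)
    sw = _group_center(s[:, None], groups)[:, 0]
    ss = float(sw @ sw)
    if ss <= 1e-12 * n * max(np.var(s), 1e-300):
        raise AllometryError("log centroid size is constant within every group; "
                             "CAC is undefined")
    a = Xw.T @ sw / ss                  # within-group regression of shape on size
    slope = float(np.linalg.norm(a))
    if slope <= 0:
        raise AllometryError("within-group shape/size covariance is zero")
    a_hat = a / slope

    Xg = X - X.mean(axis=0)             # grand-mean centring for scores
    cac_scores = Xg @ a_hat

    W = Xw - np.outer(Xw @ a_hat, a_hat)
    U, sv, Vt = np.linalg.svd(W, full_matrices=False)
    d = int((sv ** 2 > 1e-12 * max(sv[0] ** 2, 1e-300)).sum())
    if n_rsc is not None:
        d = min(d, n_rsc)
    rsc_axes = Vt[:d]
    rsc_scores = (Xg - np.outer(Xg @ a_hat, a_hat)) @ rsc_axes.T
    rsc_axes, rsc_scores = _fix_signs(rsc_axes, rsc_scores)

    r2, p = _pearson_r2(cac_scores, s)
    return AllometryResult(cac_axis=a_hat, cac_scores=cac_scores,
                           rsc_axes=rsc_axes, rsc_scores=rsc_scores,
                           slope=slope, r2=r2, p_value=p,
                           ids=tuple(ids), groups=groups)


def cac_rsc_from_gpa(gpa_result: GPAResult, log_cs: np.ndarray | None = None,
                     **kwargs) -> AllometryResult:
    """Convenience wrapper: run :func:`cac_rsc` on a GPA result, defaulting
    ``log_cs`` to the log of the GPA centroid sizes."""
    s = np.log(gpa_result.centroid_sizes) if log_cs is None else log_cs
    return cac_rsc(gpa_result.flattened(), s, gpa_result.sample.groups,
                   ids=gpa_result.sample.ids, **kwargs)


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise AllometryError("zero variance in regression variable")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r ** 2), float(p)


def allometry_regression(cac_scores: np.ndarray, log_cs: np.ndarray,
                         grouping: Sequence[str] | None = None) -> dict:
    """Correlation of allometric scores with log centroid size.

    Ungrouped: simple linear correlation r² with its two-sided p-value.
    Grouped: ordinary least squares of score on log CS plus the group as a
    categorical covariate (an ANCOVA-style model); reports the model r² and
    its F-test p-value.
    """
    x = np.asarray(log_cs, dtype=float)
    y = np.asarray(cac_scores, dtype=float)
    if len(x) < 4:
        raise AllometryError("need at least 4 specimens")
    if grouping is None:
        r2, p = _pearson_r2(y, x)
        return {"r2": r2, "p": p, "model": "score ~ log_cs"}
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"score": y, "log_cs": x, "group": list(grouping)})
    fit = smf.ols("score ~ log_cs + C(group)", data=df).fit()
    return {"r2": float(fit.rsquared), "p": float(fit.f_pvalue),
            "model": "score ~ log_cs + C(group)"}


# ---------------------------------------------------------------------------
# Scalar size statistics
# ---------------------------------------------------------------------------


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray, seed: int = 0) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small samples without ties; an exact permutation
    test for small samples with ties; the normal approximation with
    continuity correction otherwise.  No multiple-testing correction is
    applied (see the test table's ``correction`` column).
    """
    small = min(len(a), len(b)) <= 25
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if small and not ties:
        method = "exact"
    elif small:
        method = scipy.stats.PermutationMethod(
            n_resamples=9999, rng=np.random.default_rng(seed))
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def sd_separation(a: np.ndarray, b: np.ndarray) -> float:
    """How many sample standard deviations of A the smallest B value lies
    above A's mean: ``(min(B) - mean(A)) / SD(A)`` with SD using n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sd = float(np.std(a, ddof=1))
    if sd == 0:
        raise AllometryError("group A has zero standard deviation")
    return float((b.min() - a.mean()) / sd)


def group_size_tests(values: np.ndarray, groups: Sequence[str],
                     comparisons: Sequence[tuple[str, str]] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum contrasts of a scalar (e.g. OWA, centroid
    size) between groups, with descriptives and the SD-separation statistic.

    Returns one row per requested pair with columns: group_a, group_b, n_a,
    n_b, mean_a, mean_b, sd_a, sd_b, p_wilcoxon, sd_separation (how many SDs
    of A the minimum of B lies above A's mean), correction ("none").
    """
    vals = np.asarray(values, dtype=float)
    garr = np.asarray(list(groups))
    labels = sorted(set(garr))
    by = {g: vals[garr == g] for g in labels}
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels)
                       for b in labels[i + 1:]]
    for a, b in comparisons:
        for g in (a, b):
            if g not in by or len(by[g]) == 0:
                raise AllometryError(f"empty or unknown group {g!r}")
    rows = []
    for a, b in comparisons:
        va, vb = by[a], by[b]
        if min(len(va), len(vb)) < 2:
            p = np.nan
        else:
            p = _wilcoxon_rank_sum(va, vb, seed=seed)
        rows.append({
            "group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb),
            "mean_a": va.mean(), "mean_b": vb.mean(),
            "sd_a": np.std(va, ddof=1) if len(va) > 1 else np.nan,
            "sd_b": np.std(vb, ddof=1) if len(vb) > 1 else np.nan,
            "p_wilcoxon": p,
            "sd_separation": (sd_separation(va, vb)
                              if len(va) > 1 and np.std(va, ddof=1) > 0 else np.nan),
            "correction": "none",
        })
    return pd.DataFrame(rows)


def sexratio_probability(n: int, p_female: float = 0.5) -> float:
    """Probability that all ``n`` independently sexed specimens are female
    under a female probability ``p_female`` — the extreme tail of a
    Binomial(n, p) at k = n.  With a balanced ratio and n = 4 this is
    0.5^4 = 0.0625."""
    if n < 0:
        raise AllometryError("n must be >= 0")
    if not 0.0 <= p_female <= 1.0:
        raise AllometryError("p_female must be in [0, 1]")
    return float(p_female ** n)
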