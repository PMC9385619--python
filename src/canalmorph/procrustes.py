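"""Procrustes superimposition, ordination, permutation tests and classification.

Implements the shape-statistics core: generalized Procrustes analysis with
scaling (reflections forbidden — left sides are mirrored explicitly upstream),
PCA and between-group PCA of the aligned coordinates, a permutation test on
the between-group share of total inertia, canonical variate analysis on
retained principal components with leave-one-out classification and Mahalanobis
distances, projection of indeterminate specimens into frozen ordination spaces,
and per-landmark displacement fields between group mean shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .geometry import CANAL_ORDER, LandmarkConfiguration


class ShapeStatsError(ValueError):
    """Invalid input to a shape-statistics routine."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ShapeSample:
    """n specimens x p landmarks x 3 coordinates with ids and group labels."""

    coords: np.ndarray
    ids: tuple[str, ...]
    groups: tuple[str, ...]
    k: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeStatsError("coords must have shape (n, p, 3)")
        n = self.coords.shape[0]
        if n < 2:
            raise ShapeStatsError("need at least 2 specimens")
        if len(self.ids) != n or len(self.groups) != n:
            raise ShapeStatsError("ids/groups length must match n")
        self.ids = tuple(self.ids)
        self.groups = tuple(self.groups)

    @classmethod
    def from_configurations(cls, configs: Sequence[LandmarkConfiguration],
                            groups: Sequence[str]) -> "ShapeSample":
        ks = {c.k for c in configs}
        if len(ks) != 1:
            raise ShapeStatsError(f"mixed semilandmark densities: {sorted(ks)}")
        return cls(coords=np.stack([c.points for c in configs]),
                   ids=tuple(c.specimen_id for c in configs),
                   groups=tuple(groups), k=ks.pop())

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.coords.shape[1]


@dataclass
class GPAResult:
    aligned: np.ndarray          # (n, p, 3), centred, unit centroid size
    consensus: np.ndarray        # (p, 3), unit centroid size
    centroid_sizes: np.ndarray   # per specimen, original units
    iterations: int
    final_change: float
    converged: bool
    sample: ShapeSample

    def flattened(self) -> np.ndarray:
        """Aligned shapes vectorised to (n, 3p)."""
        return self.aligned.reshape(self.aligned.shape[0], -1)


@dataclass
class OrdinationResult:
    scores: np.ndarray            # (n, d)
    axes: np.ndarray              # (d, 3p) rows are axis vectors in shape space
    variance_explained: np.ndarray
    method: str                   # "PCA" | "bgPCA" | "CVA"
    mean: np.ndarray              # grand mean used for centring, (3p,)
    ids: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()
    projected: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class PermutationTestResult:
    observed: float               # between-group / total inertia, in [0, 1]
    n_permutations: int
    p_value: float
    seed: int
    permuted: np.ndarray | None = None


@dataclass
class ClassificationResult:
    rates: dict[str, float]               # per-group correct-classification %
    confusion: np.ndarray                 # rows true group, cols assigned
    group_labels: tuple[str, ...]
    mahalanobis: np.ndarray               # (g, g) distances between group means
    scheme: str = "leave-one-out"
    chance_rate: float | None = None      # mean rate (%) under label permutation


# ---------------------------------------------------------------------------
# Centroid size and single-shape helpers
# ---------------------------------------------------------------------------


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared distances of the points from their centroid."""
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2:
        raise ShapeStatsError("configuration must be a (p, d) array")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs <= 0:
        raise ShapeStatsError("all points identical: centroid size is zero")
    return cs


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    pts = np.asarray(config, dtype=float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs <= 0:
        raise ShapeStatsError("degenerate configuration (zero centroid size)")
    return centered / cs, cs


def proper_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (det +1; reflections forbidden) mapping ``source`` onto
    ``target`` in the least-squares sense.  Both inputs must be centred."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def opa_align(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Ordinary Procrustes: centre, scale to unit size and rotate ``config``
    onto ``reference`` (assumed centred, unit size)."""
    unit, _ = _center_scale(config)
    R = proper_rotation(unit, reference)
    return unit @ R.T


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations (after
    centring, unit scaling and optimal proper rotation)."""
    ua, _ = _center_scale(a)
    ub, _ = _center_scale(b)
    aligned = opa_align(ua, ub)
    return float(np.linalg.norm(aligned - ub))


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------


def gpa(sample: ShapeSample, tol: float = 1e-10, max_iter: int = 1000) -> GPAResult:
    """Iterative GPA with scaling.

    Every configuration is centred and scaled to unit centroid size, then
    rotated to the running consensus by proper orthogonal Procrustes; the
    consensus is the renormalised mean and the loop runs until its change
    falls below ``tol``.  The consensus is initialised from the first
    specimen and iterated to convergence, which makes the result
    deterministic and, at convergence, independent of input order up to a
    global rotation.
    """
    if sample.p < 3:
        raise ShapeStatsError("need at least 3 landmarks")
    n = sample.n
    units = []
    sizes = np.empty(n)
    for i in range(n):
        u, cs = _center_scale(sample.coords[i])
        units.append(u)
        sizes[i] = cs
    aligned = np.stack(units)
    consensus = aligned[0].copy()
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R = proper_rotation(aligned[i], consensus)
            aligned[i] = aligned[i] @ R.T
        new_consensus = aligned.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if change < tol:
            break
    converged = change < tol
    if not converged:
        import warnings

        warnings.warn(f"GPA did not converge in {max_iter} iterations "
                      f"(final consensus change {change:.3g})")
    return GPAResult(aligned=aligned, consensus=consensus, centroid_sizes=sizes,
                     iterations=iterations, final_change=change,
                     converged=converged, sample=sample)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


def _fix_signs(axes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: each axis's largest-|loading| entry positive."""
    axes = axes.copy()
    scores = scores.copy()
    for j in range(axes.shape[0]):
        i = int(np.argmax(np.abs(axes[j])))
        if axes[j, i] < 0:
            axes[j] = -axes[j]
            scores[:, j] = -scores[:, j]
    return axes, scores


def pca(gpa_result: GPAResult) -> OrdinationResult:
    """PCA of the vectorised aligned coordinates (covariance eigenstructure)."""
    X = gpa_result.flattened()
    n = X.shape[0]
    if n < 3:
        raise ShapeStatsError("PCA needs at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    total = var.sum()
    frac = var / total if total > 0 else var
    scores = U * s
    axes, scores = _fix_signs(Vt, scores)
    return OrdinationResult(scores=scores, axes=axes, variance_explained=frac,
                            method="PCA", mean=mean, ids=gpa_result.sample.ids,
                            groups=gpa_result.sample.groups)


def _group_means(X: np.ndarray, groups: Sequence[str]) -> tuple[list[str], np.ndarray]:
    labels = sorted(set(groups))
    means = np.stack([X[np.asarray(groups) == g].mean(axis=0) for g in labels])
    return labels, means


def bgpca(gpa_result: GPAResult, groups: Sequence[str] | None = None) -> OrdinationResult:
    """Between-group PCA: PCA of the group mean shapes, all specimens projected.

    With g groups at most g-1 axes carry variance; higher axes are reported
    with exactly zero variance.
    """
    X = gpa_result.flattened()
    groups = tuple(groups if groups is not None else gpa_result.sample.groups)
    labels, means = _group_means(X, groups)
    g = len(labels)
    if g < 2:
        raise ShapeStatsError("bgPCA needs at least 2 groups")
    grand = means.mean(axis=0)
    Mc = means - grand
    _, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    var = s ** 2 / g
    # g centred means have rank <= g-1: axes beyond that carry exactly zero
    d = min(g, Vt.shape[0])
    axes = Vt[:d]
    var = var[:d].copy()
    var[s[:d] ** 2 <= 1e-24 * max(s[0] ** 2, 1.0)] = 0.0
    total = var.sum()
    frac = var / total if total > 0 else var
    scores = (X - grand) @ axes.T
    axes, scores = _fix_signs(axes, scores)
    return OrdinationResult(scores=scores, axes=axes, variance_explained=frac,
                            method="bgPCA", mean=grand, ids=gpa_result.sample.ids,
                            groups=groups)


# ---------------------------------------------------------------------------
# Permutation test on between-group inertia
# ---------------------------------------------------------------------------


def _inertia_ratio(X: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total <= 0:
        return 0.0
    between = 0.0
    for gi in range(n_groups):
        sub = X[group_idx == gi]
        if len(sub) == 0:
            continue
        between += len(sub) * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return between / total


def permutation_inertia_test(gpa_result: GPAResult,
                             groups: Sequence[str] | None = None,
                             n_perm: int = 999, seed: int = 0,
                             keep_null: bool = False) -> PermutationTestResult:
    """Monte-Carlo test of group separation in shape space.

    The statistic is the between-group share of total inertia of the
    vectorised aligned shapes; the null is built by permuting group labels
    over specimens.  The p-value uses the add-one rule
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ShapeStatsError("n_perm must be >= 99")
    X = gpa_result.flattened()
    groups = tuple(groups if groups is not None else gpa_result.sample.groups)
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ShapeStatsError("need at least 2 groups")
    gmap = {g: i for i, g in enumerate(labels)}
    idx = np.array([gmap[g] for g in groups])
    observed = _inertia_ratio(X, idx, len(labels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _inertia_ratio(X, rng.permutation(idx), len(labels))
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_perm)
    return PermutationTestResult(observed=observed, n_permutations=n_perm,
                                 p_value=p, seed=seed,
                                 permuted=null if keep_null else None)


# ---------------------------------------------------------------------------
# Canonical variate analysis
# ---------------------------------------------------------------------------


def retain_pcs(variance_explained: np.ndarray, n: int, g: int,
               target: float = 0.90) -> int:
    """Smallest number of PCs explaining >= ``target`` variance, capped at
    n - g - 1 (keeps the pooled within-group scatter invertible)."""
    cap = max(1, n - g - 1)
    cum = np.cumsum(variance_explained)
    m = int(np.searchsorted(cum, target - 1e-12) + 1)
    return min(m, cap, len(variance_explained))


def _cva_axes(scores: np.ndarray, idx: np.ndarray, n_groups: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical axes, group means (in CV space) and eigenvalues."""
    n, m = scores.shape
    grand = scores.mean(axis=0)
    Sw = np.zeros((m, m))
    Sb = np.zeros((m, m))
    means = np.empty((n_groups, m))
    for gi in range(n_groups):
        sub = scores[idx == gi]
        mu = sub.mean(axis=0)
        means[gi] = mu
        if len(sub) > 1:
            dev = sub - mu
            Sw += dev.T @ dev
        Sb += len(sub) * np.outer(mu - grand, mu - grand)
    dof = n - n_groups
    if dof <= 0:
        raise ShapeStatsError("no within-group degrees of freedom")
    Sw /= dof
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        raise ShapeStatsError(
            f"pooled within-group scatter is singular (cond={cond:.3g}); "
            "retain fewer PCs")
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    d = min(n_groups - 1, m)
    evals = np.clip(evals[order[:d]], 0.0, None)
    axes = evecs[:, order[:d]].T           # rows are canonical axes
    # normalise so within-group variance along each axis is 1
    for j in range(d):
        scale = float(np.sqrt(axes[j] @ Sw @ axes[j]))
        if scale > 0:
            axes[j] = axes[j] / scale
    return axes, means, evals


def cva(pc_scores: np.ndarray, groups: Sequence[str],
        n_axes_rule: int | None = None, n_perm_rates: int = 0,
        seed: int = 0) -> tuple[OrdinationResult, ClassificationResult]:
    """CVA on retained PC scores with leave-one-out classification.

    ``pc_scores`` is (n, m) with m already restricted to the retained PCs.
    Returns the canonical ordination (axes expressed in PC-score space) and a
    classification result: nearest-group-mean assignment in canonical space
    under leave-one-out refitting, Mahalanobis distances between group means,
    and — if ``n_perm_rates`` > 0 — the chance-level correct-classification
    rate under label permutation is appended to the result's ``scheme`` tag.
    """
    scores_in = np.asarray(pc_scores, dtype=float)
    groups = tuple(groups)
    labels = sorted(set(groups))
    g = len(labels)
    if g < 2:
        raise ShapeStatsError("CVA needs at least 2 groups")
    gmap = {lab: i for i, lab in enumerate(labels)}
    idx = np.array([gmap[x] for x in groups])
    if n_axes_rule is not None:
        scores_in = scores_in[:, :n_axes_rule]
    axes, means, evals = _cva_axes(scores_in, idx, g)
    cv_scores = scores_in @ axes.T
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    axes_fixed, cv_scores = _fix_signs(axes, cv_scores)

    # Mahalanobis distances between group means (within-group metric = identity
    # in canonical space by construction)
    cv_means = means @ axes.T
    gdist = np.linalg.norm(cv_means[:, None, :] - cv_means[None, :, :], axis=2)

    n = len(groups)
    assigned = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            ax_i, means_i, _ = _cva_axes(scores_in[mask], idx[mask], g)
        except ShapeStatsError:
            ax_i, means_i = axes, means
        held = scores_in[i] @ ax_i.T
        mu = means_i @ ax_i.T
        assigned[i] = int(np.argmin(np.linalg.norm(mu - held, axis=1)))
    confusion = np.zeros((g, g), dtype=int)
    for true, est in zip(idx, assigned):
        confusion[true, est] += 1
    rates = {lab: 100.0 * confusion[gi, gi] / confusion[gi].sum()
             for gi, lab in enumerate(labels)}

    chance_rate = None
    if n_perm_rates > 0:
        rng = np.random.default_rng(seed)
        chance = []
        for _ in range(n_perm_rates):
            perm = rng.permutation(idx)
            try:
                ax_p, means_p, _ = _cva_axes(scores_in, perm, g)
            except ShapeStatsError:
                continue
            sc = scores_in @ ax_p.T
            mu = means_p @ ax_p.T
            counts = np.bincount(perm, minlength=g)
            dists = np.linalg.norm(sc[:, None, :] - mu[None, :, :], axis=2)
            # leave each point out of its own (permuted) group mean, else the
            # self-contribution biases the chance rate above 100/g
            for i in range(n):
                gi = perm[i]
                if counts[gi] > 1:
                    mu_i = (counts[gi] * mu[gi] - sc[i]) / (counts[gi] - 1)
                    dists[i, gi] = np.linalg.norm(sc[i] - mu_i)
            est = np.argmin(dists, axis=1)
            chance.append(100.0 * float((est == perm).mean()))
        if chance:
            chance_rate = float(np.mean(chance))

    ordination = OrdinationResult(scores=cv_scores, axes=axes_fixed,
                                  variance_explained=frac, method="CVA",
                                  mean=scores_in.mean(axis=0), groups=groups)
    classification = ClassificationResult(rates=rates, confusion=confusion,
                                          group_labels=tuple(labels),
                                          mahalanobis=gdist,
                                          scheme="leave-one-out",
                                          chance_rate=chance_rate)
    return ordination, classification


# ---------------------------------------------------------------------------
# Projection of indeterminate specimens
# ---------------------------------------------------------------------------


def project_indeterminate(ordination: OrdinationResult, gpa_result: GPAResult,
                          configs: dict[str, np.ndarray],
                          n_axes: int | None = None) -> dict[str, dict]:
    """Project held-out configurations into a frozen ordination space.

    Each configuration is superimposed onto the GPA consensus by ordinary
    Procrustes (no GPA re-run), vectorised, centred with the ordination's
    stored mean and projected on its axes.  Returns per-specimen scores and a
    nearest-group report by Euclidean distance in the retained axes (ties
    broken toward the lexicographically smallest label).
    """
    if ordination.method == "CVA":
        raise ShapeStatsError("project raw configurations into PCA/bgPCA spaces")
    d = ordination.axes.shape[0] if n_axes is None else n_axes
    have_groups = bool(ordination.groups)
    if have_groups:
        labels, gmeans = _group_means(ordination.scores[:, :d],
                                      ordination.groups)
    out: dict[str, dict] = {}
    for sid, config in configs.items():
        config = np.asarray(config, dtype=float)
        if config.shape != gpa_result.consensus.shape:
            raise ShapeStatsError(
                f"{sid}: expected {gpa_result.consensus.shape[0]} points, "
                f"got {config.shape[0]}")
        aligned = opa_align(config, gpa_result.consensus)
        scores = (aligned.reshape(-1) - ordination.mean) @ ordination.axes.T
        entry: dict = {"scores": scores}
        if have_groups:
            dists = np.linalg.norm(gmeans - scores[:d], axis=1)
            best = min(range(len(labels)), key=lambda i: (dists[i], labels[i]))
            entry["nearest_group"] = labels[best]
            entry["distances"] = dict(zip(labels, dists))
        out[sid] = entry
    return out


# ---------------------------------------------------------------------------
# Displacement fields between mean shapes
# ---------------------------------------------------------------------------


def vector_displacement_field(mean_a: np.ndarray, mean_b: np.ndarray,
                              k: int | None = None) -> dict:
    """Per-landmark displacement vectors ``b - a`` with summary statistics.

    If ``k`` (semilandmarks per canal) is given, per-canal mean displacement
    norms are reported using the fixed Ld1..Ld5-then-canal-blocks layout.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeStatsError("mean configurations must have equal point counts")
    vectors = b - a
    norms = np.linalg.norm(vectors, axis=1)
    out = {"vectors": vectors, "norms": norms, "max_norm": float(norms.max()),
           "mean_norm": float(norms.mean())}
    if k is not None:
        per_canal = {"fixed": float(norms[:5].mean())}
        for i, canal in enumerate(CANAL_ORDER):
            start = 5 + i * k
            per_canal[canal] = float(norms[start:start + k].mean())
        out["per_canal_mean_norm"] = per_canal
    return out
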