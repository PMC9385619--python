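"""Size-independent curve dissimilarities and their planar embedding.

Two routes to a symmetric specimen-by-specimen distance matrix:

* the **currents metric** — a Gaussian-kernel inner product between oriented
  curves that needs no point correspondence.  Each polyline is reduced to
  segment midpoints and (length-weighted) tangent vectors; the inner product
  sums ``exp(-|c_i - c_j|^2 / sigma^2) * (tau_i . tau_j)`` over segment
  pairs, and the induced distance is the norm of the difference of the two
  curves as currents.  Specimens are centred and scaled to unit centroid
  size first, so the distances are size-independent.
* **imported displacement fields** — externally computed per-pair control
  point displacements (e.g. from a diffeomorphic registration) summarised by
  the average L2 norm of the displacement vectors.

The distance matrix is embedded in the plane by non-metric multidimensional
scaling (monotone-regression stress majorisation, best of several seeded
starts including a classical-scaling start), reporting Kruskal stress-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.manifold import MDS

from .geometry import CANAL_ORDER, CenterlineSet


class DissimilarityError(ValueError):
    """Invalid input to a dissimilarity or embedding routine."""


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: tuple[str, ...]
    metric: str

    def __post_init__(self) -> None:
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise DissimilarityError("distance matrix must be square")
        if len(self.ids) != D.shape[0]:
            raise DissimilarityError("ids must match matrix size")
        if not np.all(np.isfinite(D)):
            raise DissimilarityError("distances must be finite")
        if np.abs(D - D.T).max() > 1e-12:
            raise DissimilarityError("distance matrix must be symmetric")
        if np.abs(np.diag(D)).max() > 1e-12:
            raise DissimilarityError("diagonal must be zero")
        if D.min() < 0:
            raise DissimilarityError("distances must be nonnegative")
        self.values = (D + D.T) / 2
        np.fill_diagonal(self.values, 0.0)
        self.ids = tuple(self.ids)


@dataclass
class MDSEmbedding:
    coords: np.ndarray        # (n, dim), centred at the origin
    stress: float             # Kruskal stress-1
    n_init: int
    seed: int
    converged: bool
    ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Currents metric
# ---------------------------------------------------------------------------


def _segments(curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DissimilarityError("curve needs at least 2 points")
    tangents = np.diff(pts, axis=0)                  # length-weighted
    if np.linalg.norm(tangents, axis=1).sum() <= 0:
        raise DissimilarityError("curve has zero length")
    midpoints = (pts[:-1] + pts[1:]) / 2
    return midpoints, tangents


def currents_inner(curve_a: np.ndarray, curve_b: np.ndarray, sigma: float) -> float:
    """Gaussian-kernel currents inner product of two oriented polylines."""
    if sigma <= 0:
        raise DissimilarityError("kernel width sigma must be positive")
    ca, ta = _segments(curve_a)
    cb, tb = _segments(curve_b)
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-d2 / sigma ** 2)
    return float((K * (ta @ tb.T)).sum())


def currents_distance(curve_a: np.ndarray, curve_b: np.ndarray, sigma: float) -> float:
    """Norm of the difference of two curves in the currents metric:
    ``sqrt(<A,A> + <B,B> - 2<A,B>)``.  Zero for identical curves; symmetric.
    Curves are compared with their stored orientation (ampulla toward
    common crus), so reversing one flips tangent signs and increases the
    distance — orient inputs consistently."""
    aa = currents_inner(curve_a, curve_a, sigma)
    bb = currents_inner(curve_b, curve_b, sigma)
    ab = currents_inner(curve_a, curve_b, sigma)
    return float(np.sqrt(max(aa + bb - 2 * ab, 0.0)))


def displacement_distance(field: np.ndarray) -> float:
    """Average L2 norm of a displacement-vector field (e.g. control-point
    displacements from an external registration)."""
    f = np.asarray(field, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1:
        raise DissimilarityError("displacement field must be a nonempty (m, d) array")
    return float(np.linalg.norm(f, axis=1).mean())


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------


def _normalized_curves(c: CenterlineSet) -> dict[str, np.ndarray]:
    """Mirror lefts, move to the intrinsic canonical pose and scale to unit
    centroid size, so currents distances measure shape rather than the
    specimen's arbitrary position, orientation, chirality or size."""
    from .geometry import canonical_pose

    c = canonical_pose(c)
    pts = c.all_points()
    cs = float(np.sqrt((pts ** 2).sum()))
    if cs <= 0:
        raise DissimilarityError("degenerate specimen (zero centroid size)")
    return {k: c.canals[k] / cs for k in CANAL_ORDER if k in c.canals}


def default_kernel_width(specimens: Sequence[CenterlineSet]) -> float:
    """Default sigma: 10% of the mean canal arc length after size
    normalisation."""
    from .geometry import polyline_arc_length

    arcs = [polyline_arc_length(v)
            for c in specimens for v in _normalized_curves(c).values()]
    return 0.1 * float(np.mean(arcs))


def pairwise_matrix(specimens: Sequence[CenterlineSet] | Sequence[str],
                    metric: str = "currents", sigma: float | None = None,
                    displacement_fields: Mapping[tuple[str, str], np.ndarray] | None = None,
                    ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Symmetric specimen-by-specimen dissimilarity matrix.

    ``metric="currents"``: specimens are :class:`CenterlineSet` objects;
    each is centred and scaled to unit centroid size, then the squared
    currents distances of corresponding canals are summed and rooted.
    ``sigma`` defaults to 10% of the mean normalised canal arc length.

    ``metric="imported_displacement"``: specimens are ids and
    ``displacement_fields`` must map every unordered pair to its control
    point displacement field; the distance is the average L2 norm.
    """
    if metric == "currents":
        specs = list(specimens)
        if len(specs) < 3:
            raise DissimilarityError("need at least 3 specimens")
        the_ids = tuple(ids) if ids is not None else tuple(
            s.specimen_id or f"spec{i}" for i, s in enumerate(specs))
        if sigma is None:
            sigma = default_kernel_width(specs)
        curves = [_normalized_curves(s) for s in specs]
        n = len(specs)
        # cache self inner products per canal
        selfs = [{k: currents_inner(cv[k], cv[k], sigma) for k in cv}
                 for cv in curves]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sq = 0.0
                for k in curves[i]:
                    ab = currents_inner(curves[i][k], curves[j][k], sigma)
                    sq += max(selfs[i][k] + selfs[j][k] - 2 * ab, 0.0)
                D[i, j] = D[j, i] = np.sqrt(sq)
        return DistanceMatrix(values=D, ids=the_ids,
                              metric=f"currents(sigma={sigma:.4g})")

    if metric == "imported_displacement":
        the_ids = tuple(specimens)
        if len(the_ids) < 3:
            raise DissimilarityError("need at least 3 specimens")
        if displacement_fields is None:
            raise DissimilarityError("imported mode needs displacement_fields")
        fields = {frozenset(k): v for k, v in displacement_fields.items()}
        n = len(the_ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = frozenset((the_ids[i], the_ids[j]))
                if key not in fields:
                    raise DissimilarityError(
                        f"missing displacement field for pair "
                        f"({the_ids[i]}, {the_ids[j]})")
                D[i, j] = D[j, i] = displacement_distance(fields[key])
        return DistanceMatrix(values=D, ids=the_ids, metric="imported_displacement")

    raise DissimilarityError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Non-metric MDS
# ---------------------------------------------------------------------------


def _classical_scaling(D: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson classical scaling used as a deterministic starting point."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def kruskal_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against dissimilarities ``D``, with
    disparities from isotonic (monotone) regression, ties handled by the
    primary approach (tied dissimilarities are free to embed at different
    distances)."""
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices_from(D, k=1)
    d_obs = D[iu]
    d_emb = pdist(coords)
    order = np.argsort(d_obs, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(d_emb)
    disp[order] = iso.fit_transform(np.arange(len(order)), d_emb[order])
    denom = float((d_emb ** 2).sum())
    if denom <= 0:
        return 0.0
    return float(np.sqrt(((d_emb - disp) ** 2).sum() / denom))


def nmds(D: DistanceMatrix | np.ndarray, dim: int = 2, n_init: int = 8,
         seed: int = 0, init: np.ndarray | None = None,
         max_iter: int = 500) -> MDSEmbedding:
    """Non-metric MDS by stress majorisation (SMACOF with monotone
    regression).

    Runs ``n_init`` random starts plus a classical-scaling start (plus
    ``init`` if supplied), keeps the solution with the lowest Kruskal
    stress-1, and centres it at the origin.  Deterministic given ``seed``.
    """
    if isinstance(D, DistanceMatrix):
        ids = D.ids
        Dm = D.values
    else:
        Dm = np.asarray(D, dtype=float)
        ids = tuple(f"s{i}" for i in range(Dm.shape[0]))
        DistanceMatrix(values=Dm, ids=ids, metric="raw")  # validates
    n = Dm.shape[0]
    if n < dim + 1:
        raise DissimilarityError(f"need at least dim + 1 = {dim + 1} specimens")

    inits: list[np.ndarray | None] = [_classical_scaling(Dm, dim)]
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (n, dim):
            raise DissimilarityError("init must have shape (n, dim)")
        inits.append(init)

    best_coords: np.ndarray | None = None
    best_stress = np.inf
    rng = np.random.default_rng(seed)
    scale = max(Dm.max(), 1e-12)
    trials = inits + [scale * rng.standard_normal((n, dim))
                      for _ in range(n_init)]
    import warnings

    for start in trials:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = MDS(n_components=dim, metric=False,
                        dissimilarity="precomputed", n_init=1,
                        max_iter=max_iter, eps=1e-9, random_state=0,
                        normalized_stress=True)
            coords = model.fit_transform(Dm, init=start)
        for cand in (coords, start):
            stress = kruskal_stress(Dm, cand)
            if stress < best_stress:
                best_stress = stress
                best_coords = cand
    assert best_coords is not None
    best_coords = best_coords - best_coords.mean(axis=0)
    return MDSEmbedding(coords=best_coords, stress=best_stress,
                        n_init=len(trials), seed=seed, converged=True, ids=ids)
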