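"""Centerline geometry of the bony-labyrinth semicircular canals.

This module turns per-specimen canal centerlines (anterior, posterior and
horizontal semicircular canals: ASC, PSC, HSC) into the quantities the rest
of the pipeline consumes:

* best-fitting canal planes (total least squares);
* the five fixed landmarks (Ld1..Ld5) anchored on the ampullae, the
  common-crus bifurcation and the crossings of the HSC centerline with the
  ASC best-fit plane;
* equal-arc-length semilandmarks along each canal (k per canal, giving
  configurations of 5 + 3k points for k in {1, 7, 18, 48});
* mirroring of left-side specimens onto the right-side convention;
* the posterior-canal index PSCI1 (arc length of the PSC below versus above
  the horizontal-canal plane);
* a 35-variable morphometric profile (1 area, 6 arc lengths, 6 linear
  distances, 12 dimensionless indices, 10 angles).

All coordinates are continuous 3D in the units of the input centerlines
(millimetres for real labyrinths).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

#: Canal keys, in the order semilandmark blocks are appended to configurations.
CANAL_ORDER: tuple[str, ...] = ("HSC", "PSC", "ASC")

#: Semilandmark densities used for the density-sensitivity analyses.
K_PRESETS: tuple[int, ...] = (1, 7, 18, 48)

#: Tolerance for the common-crus marker coinciding with an ASC/PSC endpoint,
#: relative to the canal's arc length.
COMMON_CRUS_REL_TOL = 0.05

FIXED_LANDMARK_NAMES: tuple[str, ...] = ("Ld1", "Ld2", "Ld3", "Ld4", "Ld5")


class GeometryError(ValueError):
    """Base class for geometric failures in centerline processing."""


class DegenerateGeometryError(GeometryError):
    """Input geometry is rank-deficient (collinear points, parallel planes...)."""


class LandmarkingError(GeometryError):
    """A fixed landmark could not be located on the centerlines."""


class DegenerateIndexError(GeometryError):
    """A ratio index is undefined (e.g. a canal entirely on one side of a plane)."""


# ---------------------------------------------------------------------------
# Planes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``normal . x = offset`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,):
            raise GeometryError("plane normal must be a 3-vector")
        norm = float(np.linalg.norm(n))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise GeometryError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances; positive on the side the normal points into."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.normal - self.offset


def fit_plane(points: np.ndarray, orient_axis: Iterable[float] = (0.0, 0.0, 1.0)) -> Plane:
    """Total-least-squares plane through ``points``.

    Minimises the sum of squared orthogonal distances.  The normal is oriented
    to have a positive component along ``orient_axis`` (the canal set's
    superior axis by default); if exactly perpendicular, the first nonzero
    component is made positive.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are given or the points are collinear.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # singular values sorted descending; s[1] == 0 <=> points collinear
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise DegenerateGeometryError("points are collinear; plane is undetermined")
    normal = vt[2]
    axis = np.asarray(tuple(orient_axis), dtype=float)
    comp = float(normal @ axis)
    if comp < 0:
        normal = -normal
    elif comp == 0.0:
        nz = np.nonzero(normal)[0]
        if normal[nz[0]] < 0:
            normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


# ---------------------------------------------------------------------------
# Centerline containers
# ---------------------------------------------------------------------------


def _is_collinear(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] <= 1e-12 * max(s[0], 1.0))


@dataclass
class CenterlineSet:
    """Labeled canal centerlines for one specimen.

    ``canals`` maps canal key (``"ASC"``, ``"PSC"``, ``"HSC"``) to an ordered
    ``(N, 3)`` polyline running from the ampullar end.  ``ampullae`` holds the
    digitised ampulla centres, ``common_crus`` the bifurcation point shared by
    the ASC and PSC.  ``cochlear_apex`` (Ld6) is carried along but excluded
    from canal shape configurations.
    """

    canals: dict[str, np.ndarray]
    ampullae: dict[str, np.ndarray]
    common_crus: np.ndarray
    cochlear_apex: np.ndarray | None = None
    side: str = "right"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")
        self.canals = {k: np.asarray(v, dtype=float) for k, v in self.canals.items()}
        self.ampullae = {k: np.asarray(v, dtype=float) for k, v in self.ampullae.items()}
        self.common_crus = np.asarray(self.common_crus, dtype=float)
        for key, pts in self.canals.items():
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
                raise GeometryError(f"{key}: polyline needs >= 3 points")
            if _is_collinear(pts):
                raise GeometryError(f"{key}: polyline points are collinear")
        # Orient each polyline to run from its ampullar end.
        for key, pts in self.canals.items():
            amp = self.ampullae.get(key)
            if amp is None:
                continue
            if np.linalg.norm(pts[-1] - amp) < np.linalg.norm(pts[0] - amp):
                self.canals[key] = pts[::-1].copy()
        for key in ("ASC", "PSC"):
            pts = self.canals.get(key)
            if pts is None:
                continue
            tol = COMMON_CRUS_REL_TOL * polyline_arc_length(pts)
            d = min(np.linalg.norm(pts[0] - self.common_crus),
                    np.linalg.norm(pts[-1] - self.common_crus))
            if d > tol:
                raise GeometryError(
                    f"common-crus point is {d:.3g} from both {key} endpoints "
                    f"(tolerance {tol:.3g})")

    def all_points(self) -> np.ndarray:
        """All canal centerline points stacked (HSC, PSC, ASC order)."""
        return np.vstack([self.canals[k] for k in CANAL_ORDER if k in self.canals])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CenterlineSet":
        """Apply ``x -> R x + t`` to every stored point."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return replace(
            self,
            canals={k: v @ R.T + t for k, v in self.canals.items()},
            ampullae={k: R @ v + t for k, v in self.ampullae.items()},
            common_crus=R @ self.common_crus + t,
            cochlear_apex=None if self.cochlear_apex is None else R @ self.cochlear_apex + t,
        )


@dataclass
class LandmarkConfiguration:
    """Ordered (semi)landmark configuration: Ld1..Ld5 then HSC, PSC, ASC blocks.

    ``points`` has shape ``(5 + 3k, 3)``.  The cochlear apex, when present on
    the source centerlines, is not part of the configuration.
    """

    points: np.ndarray
    k: int
    specimen_id: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.k < 1:
            raise GeometryError("k must be >= 1")
        expected = 5 + 3 * self.k
        if self.points.shape != (expected, 3):
            raise GeometryError(
                f"expected {expected} points for k={self.k}, got {self.points.shape}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def canal_slice(self, canal: str) -> slice:
        """Row slice of ``points`` holding a canal's semilandmark block."""
        i = CANAL_ORDER.index(canal)
        start = 5 + i * self.k
        return slice(start, start + self.k)


def point_block_labels(k: int) -> list[str]:
    """Names for each row of a configuration: Ld1..Ld5 then canal blocks."""
    labels = list(FIXED_LANDMARK_NAMES)
    for canal in CANAL_ORDER:
        labels.extend(f"{canal}_s{i + 1}" for i in range(k))
    return labels


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------


def mirror(obj: "CenterlineSet | LandmarkConfiguration"):
    """Reflect across the x = 0 plane and toggle the side flag.

    An exact involution: ``mirror(mirror(x))`` has bit-identical coordinates.
    """
    flip = np.array([-1.0, 1.0, 1.0])
    other = {"left": "right", "right": "left"}
    if isinstance(obj, CenterlineSet):
        return replace(
            obj,
            canals={k: v * flip for k, v in obj.canals.items()},
            ampullae={k: v * flip for k, v in obj.ampullae.items()},
            common_crus=obj.common_crus * flip,
            cochlear_apex=None if obj.cochlear_apex is None else obj.cochlear_apex * flip,
            side=other[obj.side],
        )
    if isinstance(obj, LandmarkConfiguration):
        return replace(obj, points=obj.points * flip, side=other[obj.side])
    raise TypeError(f"cannot mirror {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Arc-length utilities and semilandmarks
# ---------------------------------------------------------------------------


def polyline_arc_length(polyline: np.ndarray) -> float:
    pts = np.asarray(polyline, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _cumulative_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc_length(pts: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(pts) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    return pts[i] + t * (pts[i + 1] - pts[i])


def resample_semilandmarks(polyline: np.ndarray, k: int) -> np.ndarray:
    """``k`` points at equal arc-length spacing strictly inside the polyline.

    Spacing is ``L / (k + 1)`` so the endpoints themselves (which carry fixed
    landmarks) are never duplicated; ordering follows the polyline from its
    ampullar end.
    """
    if k < 1:
        raise GeometryError("k must be >= 1")
    pts = np.asarray(polyline, dtype=float)
    cum = _cumulative_lengths(pts)
    L = cum[-1]
    if L <= 0:
        raise GeometryError("polyline has zero arc length")
    targets = L * np.arange(1, k + 1) / (k + 1)
    return np.array([_point_at_arc_length(pts, cum, s) for s in targets])


# ---------------------------------------------------------------------------
# Fixed landmarks
# ---------------------------------------------------------------------------


def _plane_crossings(polyline: np.ndarray, plane: Plane) -> list[tuple[float, np.ndarray]]:
    """(arc position, point) of every crossing of ``polyline`` with ``plane``."""
    pts = np.asarray(polyline, dtype=float)
    d = plane.signed_distance(pts)
    cum = _cumulative_lengths(pts)
    out: list[tuple[float, np.ndarray]] = []
    for i in range(len(pts) - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            out.append((cum[i], pts[i].copy()))
        elif a * b < 0:
            t = a / (a - b)
            out.append((cum[i] + t * (cum[i + 1] - cum[i]),
                        pts[i] + t * (pts[i + 1] - pts[i])))
    if len(pts) and d[-1] == 0.0:
        out.append((cum[-1], pts[-1].copy()))
    return out


def extract_fixed_landmarks(c: CenterlineSet) -> dict[str, np.ndarray]:
    """Locate the five fixed landmarks on a centerline set.

    Ld1 and Ld2 are the crossings of the HSC centerline with the ASC best-fit
    plane nearest (by arc length) to the lateral/ampullar and medial ends of
    the HSC respectively; Ld3 and Ld5 are the PSC and ASC ampulla centres;
    Ld4 is the common-crus bifurcation.  Crossings are linearly interpolated
    within the crossing segment.
    """
    for key in CANAL_ORDER:
        if key not in c.canals:
            raise LandmarkingError(f"canal {key} missing from centerline set")
    asc_plane = fit_plane(c.canals["ASC"])
    hsc = c.canals["HSC"]
    crossings = _plane_crossings(hsc, asc_plane)
    if len(crossings) < 2:
        d = asc_plane.signed_distance(hsc)
        raise LandmarkingError(
            "HSC centerline crosses the ASC plane "
            f"{len(crossings)} time(s); need 2 (signed distance range "
            f"[{d.min():.3g}, {d.max():.3g}])")
    total = polyline_arc_length(hsc)
    ld1 = min(crossings, key=lambda sc: sc[0])[1]          # nearest ampullar end
    ld2 = min(crossings, key=lambda sc: total - sc[0])[1]  # nearest medial end
    try:
        ld3 = c.ampullae["PSC"]
        ld5 = c.ampullae["ASC"]
    except KeyError as exc:
        raise LandmarkingError(f"missing ampulla marker: {exc}") from exc
    return {
        "Ld1": np.asarray(ld1, dtype=float),
        "Ld2": np.asarray(ld2, dtype=float),
        "Ld3": np.asarray(ld3, dtype=float),
        "Ld4": np.asarray(c.common_crus, dtype=float),
        "Ld5": np.asarray(ld5, dtype=float),
    }


def build_configuration(c: CenterlineSet, k: int) -> LandmarkConfiguration:
    """Assemble the ``5 + 3k`` configuration for one specimen.

    Left-side specimens are mirrored to the right-side convention first, so
    every configuration entering statistics shares one chirality.
    """
    if k < 1:
        raise GeometryError("k must be >= 1")
    src = mirror(c) if c.side == "left" else c
    lds = extract_fixed_landmarks(src)
    rows = [lds[name] for name in FIXED_LANDMARK_NAMES]
    for canal in CANAL_ORDER:
        rows.append(resample_semilandmarks(src.canals[canal], k))
    points = np.vstack([np.atleast_2d(r) for r in rows])
    return LandmarkConfiguration(points=points, k=k,
                                 specimen_id=c.specimen_id, side="right")


# ---------------------------------------------------------------------------
# PSCI1 and plane-partitioned arc lengths
# ---------------------------------------------------------------------------


def _arc_lengths_by_side(polyline: np.ndarray, plane: Plane) -> tuple[float, float]:
    """(arc length on negative side, arc length on positive side) of ``plane``.

    Crossing segments are split by linear interpolation; segments lying in the
    plane contribute half to each side.
    """
    pts = np.asarray(polyline, dtype=float)
    d = plane.signed_distance(pts)
    below = above = 0.0
    for i in range(len(pts) - 1):
        seg = float(np.linalg.norm(pts[i + 1] - pts[i]))
        a, b = d[i], d[i + 1]
        if a < 0 and b < 0:
            below += seg
        elif a > 0 and b > 0:
            above += seg
        elif a == 0 and b == 0:
            below += seg / 2
            above += seg / 2
        else:
            t = a / (a - b) if a != b else 0.5
            if a < b:  # rising: below first
                below += t * seg
                above += (1 - t) * seg
            else:
                above += t * seg
                below += (1 - t) * seg
    return below, above


def horizontal_canal_plane(c: CenterlineSet) -> Plane:
    """Best-fit HSC plane with its normal oriented toward the common crus.

    The common crus sits superior to the horizontal canal, so this fixes the
    superior side intrinsically — independent of how the specimen happens to
    be positioned in space.
    """
    if "HSC" not in c.canals:
        raise LandmarkingError("HSC canal missing")
    pts = c.canals["HSC"]
    return fit_plane(pts, orient_axis=c.common_crus - pts.mean(axis=0))


def canonical_pose(c: CenterlineSet) -> CenterlineSet:
    """Map a centerline set to an intrinsic anatomical pose.

    Left sides are mirrored to the right-side convention; the centroid moves
    to the origin; the superior HSC-plane normal (oriented toward the common
    crus) becomes +z and the ASC-plane normal's component orthogonal to it
    becomes +y (signed toward the HSC ampulla).  Purely intrinsic, so any
    rigid motion of the input yields the same output.
    """
    if c.side == "left":
        c = mirror(c)
    for key in ("HSC", "ASC"):
        if key not in c.canals:
            raise LandmarkingError(f"canonical pose needs the {key} canal")
    centroid = c.all_points().mean(axis=0)
    e3 = horizontal_canal_plane(c).normal
    a = fit_plane(c.canals["ASC"]).normal
    e2 = a - (a @ e3) * e3
    nrm = np.linalg.norm(e2)
    if nrm < 1e-9:
        raise DegenerateGeometryError("ASC plane parallel to HSC plane")
    e2 = e2 / nrm
    ref = c.ampullae.get("HSC", c.canals["HSC"][0]) - centroid
    if e2 @ ref < 0:
        e2 = -e2
    e1 = np.cross(e2, e3)
    R = np.vstack([e1, e2, e3])  # rows: new axes -> R maps world to canonical
    return c.transformed(R, -R @ centroid)


def psci1(psc_polyline: np.ndarray, hsc_plane: Plane) -> float:
    """Posterior-canal index 1: PSC arc length below / above the HSC plane.

    "Below" is the negative side of the oriented HSC-plane normal; pass a
    plane whose normal points to the superior side (see
    :func:`horizontal_canal_plane`) so below means inferior.
    """
    below, above = _arc_lengths_by_side(psc_polyline, hsc_plane)
    if below <= 0 or above <= 0:
        raise DegenerateIndexError(
            f"PSC does not cross the HSC plane (below={below:.3g}, above={above:.3g})")
    return below / above


# ---------------------------------------------------------------------------
# 35-variable morphometric profile
# ---------------------------------------------------------------------------

#: Registry of the 35 profile variables: name -> (category, units, definition,
#: provenance).  Only OWA and PSCI1 follow published definitions; the rest are
#: documented stand-ins chosen to be similarity-invariant where dimensionless.
VARIABLE_REGISTRY: dict[str, tuple[str, str, str, str]] = {
    "OWA": ("area", "mm^2", "oval window area, passed through from measurement", "published"),
    # 6 arc lengths
    "ARC_HSC": ("arc_length", "mm", "HSC centerline arc length", "stand-in"),
    "ARC_PSC": ("arc_length", "mm", "PSC centerline arc length", "stand-in"),
    "ARC_ASC": ("arc_length", "mm", "ASC centerline arc length", "stand-in"),
    "ARC_CC": ("arc_length", "mm",
               "common-crus length: orthogonal distance of Ld4 from the HSC plane",
               "stand-in"),
    "ARC_PSC_INF": ("arc_length", "mm", "PSC arc length below (inferior to) the HSC plane",
                    "stand-in"),
    "ARC_PSC_SUP": ("arc_length", "mm", "PSC arc length above the HSC plane", "stand-in"),
    # 6 linear distances
    "H_HSC": ("distance", "mm", "HSC loop height (major in-plane extent)", "stand-in"),
    "W_HSC": ("distance", "mm", "HSC loop width (minor in-plane extent)", "stand-in"),
    "H_PSC": ("distance", "mm", "PSC loop height", "stand-in"),
    "W_PSC": ("distance", "mm", "PSC loop width", "stand-in"),
    "H_ASC": ("distance", "mm", "ASC loop height", "stand-in"),
    "W_ASC": ("distance", "mm", "ASC loop width", "stand-in"),
    # 12 indices
    "PSCI1": ("index", "-", "PSC arc length below / above the HSC plane", "published"),
    "HWI_HSC": ("index", "-", "HSC height / width", "stand-in"),
    "HWI_PSC": ("index", "-", "PSC height / width", "stand-in"),
    "HWI_ASC": ("index", "-", "ASC height / width", "stand-in"),
    "ACI_HSC": ("index", "-", "HSC arc length / end-to-end chord", "stand-in"),
    "ACI_PSC": ("index", "-", "PSC arc length / end-to-end chord", "stand-in"),
    "ACI_ASC": ("index", "-", "ASC arc length / end-to-end chord", "stand-in"),
    "ARI_AP": ("index", "-", "ASC / PSC arc-length ratio", "stand-in"),
    "ARI_AH": ("index", "-", "ASC / HSC arc-length ratio", "stand-in"),
    "ARI_PH": ("index", "-", "PSC / HSC arc-length ratio", "stand-in"),
    "CCI": ("index", "-", "common-crus length / HSC arc length", "stand-in"),
    "PSCF": ("index", "-", "fraction of PSC arc length below the HSC plane", "stand-in"),
    # 10 angles
    "ANG_ASC_PSC": ("angle", "deg", "ASC/PSC inter-plane angle", "stand-in"),
    "ANG_ASC_HSC": ("angle", "deg", "ASC/HSC inter-plane angle", "stand-in"),
    "ANG_PSC_HSC": ("angle", "deg", "PSC/HSC inter-plane angle", "stand-in"),
    "SPAN_HSC": ("angle", "deg", "angle subtended at the HSC centroid by its endpoints",
                 "stand-in"),
    "SPAN_PSC": ("angle", "deg", "angle subtended at the PSC centroid by its endpoints",
                 "stand-in"),
    "SPAN_ASC": ("angle", "deg", "angle subtended at the ASC centroid by its endpoints",
                 "stand-in"),
    "ANG_AMP": ("angle", "deg", "angle Ld3-Ld4-Ld5 (ampullae subtended at the common crus)",
                "stand-in"),
    "ANG_HSCCHORD_ASCP": ("angle", "deg", "angle of the Ld1-Ld2 chord to the ASC plane normal",
                          "stand-in"),
    "ANG_HSCCHORD_PSCP": ("angle", "deg", "angle of the Ld1-Ld2 chord to the PSC plane normal",
                          "stand-in"),
    "ANG_CC_HSCP": ("angle", "deg",
                    "angle of the centroid-to-Ld4 axis to the HSC plane normal", "stand-in"),
}

assert len(VARIABLE_REGISTRY) == 35

_PER_CANAL_VARIABLES: dict[str, tuple[str, ...]] = {
    "HSC": ("ARC_HSC", "H_HSC", "W_HSC", "HWI_HSC", "ACI_HSC", "SPAN_HSC"),
    "PSC": ("ARC_PSC", "H_PSC", "W_PSC", "HWI_PSC", "ACI_PSC", "SPAN_PSC"),
    "ASC": ("ARC_ASC", "H_ASC", "W_ASC", "HWI_ASC", "ACI_ASC", "SPAN_ASC"),
}


@dataclass
class MorphometricProfile:
    """The 35-variable profile; ``missing`` names entries that could not be
    computed (e.g. because a canal was absent)."""

    values: dict[str, float]
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(VARIABLE_REGISTRY)
        if unknown:
            raise GeometryError(f"unknown profile variables: {sorted(unknown)}")
        overlap = set(self.values) & set(self.missing)
        if overlap:
            raise GeometryError(f"variables both present and missing: {sorted(overlap)}")
        if len(self.values) + len(self.missing) != 35:
            raise GeometryError("profile must account for exactly 35 variables")

    @property
    def complete(self) -> bool:
        return not self.missing

    def as_series(self):
        import pandas as pd

        return pd.Series({n: self.values.get(n, np.nan) for n in VARIABLE_REGISTRY},
                         name="value")


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _axis_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between undirected axes, in [0, 90] degrees (mirror-invariant)."""
    c = abs(float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v))))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def _loop_extents(polyline: np.ndarray, plane: Plane) -> tuple[float, float]:
    """Height (major) and width (minor) extents of a canal loop in its plane."""
    pts = np.asarray(polyline, dtype=float)
    centered = pts - pts.mean(axis=0)
    in_plane = centered - np.outer(centered @ plane.normal, plane.normal)
    _, _, vt = np.linalg.svd(in_plane, full_matrices=False)
    e1 = in_plane @ vt[0]
    e2 = in_plane @ vt[1]
    return float(e1.max() - e1.min()), float(e2.max() - e2.min())


def compute_profile(c: CenterlineSet, owa: float) -> MorphometricProfile:
    """Compute the 35-variable profile for one specimen.

    ``owa`` (mm^2) is measured externally on the surface mesh and passed
    through.  Every other variable is computed from the centerlines and the
    best-fitting canal planes.  Missing canals yield an incomplete profile
    with the affected variables listed in ``missing`` rather than an error.
    """
    if owa <= 0:
        raise GeometryError("OWA must be positive")
    values: dict[str, float] = {"OWA": float(owa)}
    missing: list[str] = []

    present = {k: c.canals[k] for k in CANAL_ORDER if k in c.canals}
    planes: dict[str, Plane] = {}
    for key, pts in present.items():
        if key == "HSC":
            # superior orientation is intrinsic: the crus is above the HSC
            planes[key] = horizontal_canal_plane(c)
        else:
            planes[key] = fit_plane(pts)

    arcs: dict[str, float] = {}
    for key in CANAL_ORDER:
        names = _PER_CANAL_VARIABLES[key]
        if key not in present:
            missing.extend(names)
            continue
        pts = present[key]
        arc = polyline_arc_length(pts)
        arcs[key] = arc
        h, w = _loop_extents(pts, planes[key])
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        centroid = pts.mean(axis=0)
        span = _angle_deg(pts[0] - centroid, pts[-1] - centroid)
        values[names[0]] = arc
        values[names[1]] = h
        values[names[2]] = w
        values[names[3]] = h / w
        values[names[4]] = arc / chord if chord > 0 else np.inf
        values[names[5]] = span

    for a, b, name in (("ASC", "PSC", "ANG_ASC_PSC"),
                       ("ASC", "HSC", "ANG_ASC_HSC"),
                       ("PSC", "HSC", "ANG_PSC_HSC")):
        if a in planes and b in planes:
            values[name] = _axis_angle_deg(planes[a].normal, planes[b].normal)
        else:
            missing.append(name)

    for a, b, name in (("ASC", "PSC", "ARI_AP"), ("ASC", "HSC", "ARI_AH"),
                       ("PSC", "HSC", "ARI_PH")):
        if a in arcs and b in arcs:
            values[name] = arcs[a] / arcs[b]
        else:
            missing.append(name)

    if "PSC" in present and "HSC" in planes:
        below, above = _arc_lengths_by_side(present["PSC"], planes["HSC"])
        if below > 0 and above > 0:
            values["ARC_PSC_INF"] = below
            values["ARC_PSC_SUP"] = above
            values["PSCI1"] = below / above
            values["PSCF"] = below / (below + above)
        else:
            missing.extend(["ARC_PSC_INF", "ARC_PSC_SUP", "PSCI1", "PSCF"])
    else:
        missing.extend(["ARC_PSC_INF", "ARC_PSC_SUP", "PSCI1", "PSCF"])

    if "HSC" in planes:
        cc_len = abs(float(planes["HSC"].signed_distance(c.common_crus[None])[0]))
        values["ARC_CC"] = cc_len
        values["CCI"] = cc_len / arcs["HSC"]
    else:
        missing.extend(["ARC_CC", "CCI"])

    try:
        lds = extract_fixed_landmarks(c)
    except (LandmarkingError, GeometryError):
        lds = None
    if lds is not None:
        values["ANG_AMP"] = _angle_deg(lds["Ld3"] - lds["Ld4"], lds["Ld5"] - lds["Ld4"])
        chord = lds["Ld2"] - lds["Ld1"]
        if "ASC" in planes:
            values["ANG_HSCCHORD_ASCP"] = _axis_angle_deg(chord, planes["ASC"].normal)
        else:
            missing.append("ANG_HSCCHORD_ASCP")
        if "PSC" in planes:
            values["ANG_HSCCHORD_PSCP"] = _axis_angle_deg(chord, planes["PSC"].normal)
        else:
            missing.append("ANG_HSCCHORD_PSCP")
        if "HSC" in planes:
            axis = lds["Ld4"] - c.all_points().mean(axis=0)
            values["ANG_CC_HSCP"] = _axis_angle_deg(axis, planes["HSC"].normal)
        else:
            missing.append("ANG_CC_HSCP")
    else:
        missing.extend(["ANG_AMP", "ANG_HSCCHORD_ASCP", "ANG_HSCCHORD_PSCP", "ANG_CC_HSCP"])

    return MorphometricProfile(values=values, missing=tuple(missing))
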