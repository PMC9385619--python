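"""Synthetic labyrinth cohorts with known group structure, allometry and noise.

The generator builds each specimen's three semicircular-canal centerlines from
a shared circular-arc template, then layers on, in order:

1. a group-specific mean-shape offset (smooth per-canal radius and centre
   perturbations, drawn once per group from the cohort seed);
2. an allometric displacement proportional to the specimen's centred log
   centroid size, acting as a radial expansion of the posterior canal — so
   larger specimens carry a proportionally more developed posterior canal,
   the pattern of evolutionary allometry the pipeline is designed to detect;
3. a global similarity scaling setting the specimen's true centroid size;
4. iid Gaussian digitisation noise on every centerline point;
5. a random proper rotation and translation, and a reflection for left-side
   specimens.

Oval window area (OWA) is drawn lognormally per group, independent of canal
centroid size; sex is balanced and has no effect on canal size by default.
Every generated quantity is recorded in a truth table so downstream estimates
can be checked against the parameters that produced them.  Output is a pure
function of the cohort specification, including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.stats import special_ortho_group

from .geometry import CANAL_ORDER, CenterlineSet, GeometryError

#: Superior axis of the template frame; HSC lies in the z = 0 plane.
SUPERIOR_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CanalTemplateParams:
    """Circular-arc template for the three canals, sized like a hominin
    labyrinth (radii in mm, spans in degrees)."""

    radius_hsc: float = 3.0
    radius_psc: float = 2.8
    radius_asc: float = 3.2
    # HSC span leaves both ASC-plane crossings (at asc_tilt and asc_tilt+180
    # degrees on the arc from -60) well away from the arc ends, so noisy
    # plane fits still find two crossings
    span_hsc: float = 300.0
    span_psc: float = 240.0
    span_asc: float = 230.0
    #: tilt (deg) of the ASC plane normal away from +y, about the z axis;
    #: the PSC plane normal stays at +x, so 90 deg would degenerate.
    asc_tilt: float = 10.0
    points_per_canal: int = 100

    def __post_init__(self) -> None:
        for name in ("span_hsc", "span_psc", "span_asc"):
            v = getattr(self, name)
            if not 0.0 < v < 360.0:
                raise GeometryError(f"{name} must be in (0, 360) degrees, got {v}")
        for name in ("radius_hsc", "radius_psc", "radius_asc"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.points_per_canal < 10:
            raise GeometryError("points_per_canal must be >= 10")
        # pairwise non-parallel canal planes: HSC normal is +z, PSC normal +x,
        # ASC normal is +y rotated by asc_tilt about z
        if abs(abs(self.asc_tilt) - 90.0) < 1e-9:
            raise GeometryError("ASC plane parallel to PSC plane (asc_tilt = ±90°)")


@dataclass(frozen=True)
class GroupSpec:
    """One a-priori group: label, size, mean log centroid size (as an offset
    from the template's log centroid size, so 0 means template-sized) and the
    magnitude (in template length units) of its mean-shape offset."""

    label: str
    n: int
    mean_log_cs: float = 0.0
    shape_offset: float = 0.0
    owa_mean_mm2: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeometryError("group n must be >= 1")
        if self.owa_mean_mm2 <= 0:
            raise GeometryError("OWA mean must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort.

    ``allometric_slope`` is the relative radial expansion of the posterior
    canal per unit of (centred) log centroid size; ``noise_sd`` is the iid
    per-point digitisation noise in template length units; ``sd_log_cs`` the
    within-group spread of log centroid size; ``sex_size_effect`` defaults to
    zero (no sexual dimorphism in canal size).
    """

    groups: tuple[GroupSpec, ...]
    allometric_slope: float = 0.0
    noise_sd: float = 0.0
    side_fraction: float = 0.0
    sd_log_cs: float = 0.1
    sex_size_effect: float = 0.0
    owa_sigma_log: float = 0.15
    seed: int = 0
    template: CanalTemplateParams = field(default_factory=CanalTemplateParams)

    def __post_init__(self) -> None:
        if not self.groups:
            raise GeometryError("cohort needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise GeometryError("group labels must be unique")
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be >= 0")
        if not 0.0 <= self.side_fraction <= 1.0:
            raise GeometryError("side_fraction must be in [0, 1]")
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class SpecimenRecord:
    """One simulated specimen with its centerlines and scalar measurements."""

    specimen_id: str
    group: str
    sex: str
    side: str
    log_cs: float
    centerlines: CenterlineSet
    owa_mm2: float
    subarcuate_opening_pct: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise GeometryError("side must be 'left' or 'right'")
        if self.owa_mm2 <= 0:
            raise GeometryError("OWA must be positive")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def _arc(center: np.ndarray, radius: float, u: np.ndarray, w: np.ndarray,
         start_deg: float, span_deg: float, n: int) -> np.ndarray:
    theta = np.radians(start_deg + np.linspace(0.0, span_deg, n))
    return center + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * w)


def generate_canal_template(params: CanalTemplateParams | None = None) -> CenterlineSet:
    """Build the noise-free right-side canal template.

    The horizontal canal is a circular arc in the z = 0 plane; the anterior
    canal stands in a near-vertical plane whose best-fit plane crosses the
    HSC arc twice (so Ld1/Ld2 exist); the posterior canal hangs from the
    common crus, dipping below the HSC plane (so PSCI1 exists).  Polylines
    run from their ampullar ends; the ASC and PSC share the common-crus
    endpoint exactly.
    """
    p = params or CanalTemplateParams()
    n = p.points_per_canal
    ez = SUPERIOR_AXIS

    # HSC: arc in z=0 from the lateral (ampullar) end, centred at the origin.
    ex, ey = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    hsc = _arc(np.zeros(3), p.radius_hsc, ex, ey, -60.0, p.span_hsc, n)

    # ASC: vertical plane with normal ~ +y tilted by asc_tilt about z.
    t = np.radians(p.asc_tilt)
    asc_u = np.array([np.cos(t), np.sin(t), 0.0])  # in-plane horizontal axis
    asc_center = np.array([0.0, 0.0, p.radius_asc * 0.9])
    # ampullar end low-lateral, sweeping over the top to the common crus
    asc = _arc(asc_center, p.radius_asc, asc_u, ez, -10.0, p.span_asc, n)
    crus = asc[-1].copy()

    # PSC: plane normal +x, translated so one endpoint meets the common crus.
    psc_u, psc_w = ey, ez
    phi_end = 80.0
    psc_center = crus - p.radius_psc * (np.cos(np.radians(phi_end)) * psc_u
                                        + np.sin(np.radians(phi_end)) * psc_w)
    # runs from the ampullar (free) end at phi_end - span toward the crus
    psc = _arc(psc_center, p.radius_psc, psc_u, psc_w,
               phi_end - p.span_psc, p.span_psc, n)
    psc[-1] = crus  # exact junction (kills the last-ulp rounding)

    return CenterlineSet(
        canals={"HSC": hsc, "PSC": psc, "ASC": asc},
        ampullae={"HSC": hsc[0].copy(), "PSC": psc[0].copy(), "ASC": asc[0].copy()},
        common_crus=crus,
        side="right",
        specimen_id="template",
    )


def posterior_displacement_field(template: CenterlineSet) -> dict[str, np.ndarray]:
    """Unit-slope allometric displacement field: radial expansion of the PSC
    anchored at the common crus (so the ASC/PSC junction stays shared), zero
    on the other canals."""
    field = {k: np.zeros_like(v) for k, v in template.canals.items()}
    psc = template.canals["PSC"]
    field["PSC"] = psc - template.common_crus
    return field


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _group_offset_field(template: CenterlineSet, rng: np.random.Generator,
                        magnitude: float) -> dict[str, np.ndarray]:
    """Smooth per-group shape offset scaled to ``magnitude`` RMS displacement.

    ASC and PSC receive random homotheties anchored at the common crus (the
    junction point stays exactly shared); the HSC a random homothety about
    its own centre plus a small rigid shift."""
    raw: dict[str, np.ndarray] = {}
    for key in CANAL_ORDER:
        pts = template.canals[key]
        scale = rng.normal()
        if key == "HSC":
            shift = rng.normal(size=3)
            raw[key] = scale * (pts - pts.mean(axis=0)) + shift
        else:
            raw[key] = scale * (pts - template.common_crus)
    if magnitude == 0:
        return {k: np.zeros_like(v) for k, v in raw.items()}
    sq = sum(float((v ** 2).sum()) for v in raw.values())
    npts = sum(v.shape[0] for v in raw.values())
    rms = np.sqrt(sq / npts)
    return {k: magnitude * v / rms for k, v in raw.items()}


def _apply_fields(template: CenterlineSet, *fields_and_scales) -> CenterlineSet:
    canals = {k: v.copy() for k, v in template.canals.items()}
    for fld, scale in fields_and_scales:
        for k in canals:
            canals[k] = canals[k] + scale * fld[k]
    # markers ride along with their endpoints
    return dataclasses.replace(
        template,
        canals=canals,
        ampullae={k: canals[k][0].copy() for k in canals},
        common_crus=canals["ASC"][-1].copy(),
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[SpecimenRecord], dict[str, Any]]:
    """Generate a cohort and its truth table.

    Returns ``(records, truth)`` where ``truth`` records every generative
    parameter (per-group offset fields, per-specimen sizes, rigid motions,
    the allometric field) as plain lists so it serialises to JSON.
    """
    rng = np.random.default_rng(spec.seed)
    template = generate_canal_template(spec.template)
    allo_field = posterior_displacement_field(template)
    base_cs = centerline_centroid_size(template)

    log_base = float(np.log(base_cs))
    grand_mean_logcs = log_base + float(np.mean([g.mean_log_cs for g in spec.groups]))

    group_fields = {g.label: _group_offset_field(template, rng, g.shape_offset)
                    for g in spec.groups}

    records: list[SpecimenRecord] = []
    truth: dict[str, Any] = {
        "seed": spec.seed,
        "allometric_slope": spec.allometric_slope,
        "noise_sd": spec.noise_sd,
        "grand_mean_log_cs": grand_mean_logcs,
        "groups": {g.label: dataclasses.asdict(g) for g in spec.groups},
        "group_offset_fields": {
            lbl: {k: v.tolist() for k, v in fld.items()}
            for lbl, fld in group_fields.items()},
        "allometric_field": {k: v.tolist() for k, v in allo_field.items()},
        "specimens": [],
    }

    idx = 0
    for g in spec.groups:
        for _ in range(g.n):
            sex = "F" if rng.random() < 0.5 else "M"
            log_cs = log_base + g.mean_log_cs + spec.sd_log_cs * rng.normal()
            if spec.sex_size_effect and sex == "M":
                log_cs += spec.sex_size_effect
            delta = spec.allometric_slope * (log_cs - grand_mean_logcs)
            shaped = _apply_fields(template,
                                   (group_fields[g.label], 1.0),
                                   (allo_field, delta))
            scale = np.exp(log_cs) / base_cs
            canals = {k: v * scale for k, v in shaped.canals.items()}
            if spec.noise_sd > 0:
                canals = {k: v + spec.noise_sd * rng.normal(size=v.shape)
                          for k, v in canals.items()}
            R = special_ortho_group.rvs(3, random_state=rng)
            t = rng.normal(scale=5.0, size=3)
            canals = {k: v @ R.T + t for k, v in canals.items()}
            side = "left" if rng.random() < spec.side_fraction else "right"
            if side == "left":
                canals = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in canals.items()}
            # with noise the two crus-end digitisations disagree slightly;
            # the marker is their midpoint, as a human digitiser would place it
            cls = CenterlineSet(
                canals=canals,
                ampullae={k: canals[k][0].copy() for k in canals},
                common_crus=(canals["ASC"][-1] + canals["PSC"][-1]) / 2,
                side=side,
                specimen_id=f"{g.label}_{idx:03d}",
            )
            owa = float(g.owa_mean_mm2 * np.exp(spec.owa_sigma_log * rng.normal()
                                                - spec.owa_sigma_log ** 2 / 2))
            saf = float(np.clip(rng.normal(10.0, 4.0), 0.0, 100.0))
            rec = SpecimenRecord(
                specimen_id=cls.specimen_id, group=g.label, sex=sex, side=side,
                log_cs=log_cs, centerlines=cls, owa_mm2=owa,
                subarcuate_opening_pct=saf)
            records.append(rec)
            truth["specimens"].append({
                "specimen_id": rec.specimen_id, "group": g.label, "sex": sex,
                "side": side, "log_cs": log_cs, "allometric_delta": delta,
                "rotation": R.tolist(), "translation": t.tolist(),
                "owa_mm2": owa,
            })
            idx += 1
    return records, truth


def centerline_centroid_size(c: CenterlineSet) -> float:
    """Centroid size of the full centerline point set (all three canals)."""
    pts = c.all_points()
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------


def write_cohort(records: list[SpecimenRecord], truth: dict[str, Any],
                 outdir: str | Path) -> dict[str, Path]:
    """Write polyline CSV, manifest CSV and truth JSON; returns the paths."""
    import json

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for canal in CANAL_ORDER:
            pts = rec.centerlines.canals[canal]
            amp = rec.centerlines.ampullae[canal]
            crus = rec.centerlines.common_crus
            for i, (x, y, z) in enumerate(pts):
                label = ""
                if np.allclose(pts[i], amp):
                    label = "ampulla"
                elif np.allclose(pts[i], crus):
                    label = "common_crus"
                rows.append((rec.specimen_id, canal, i, x, y, z, label))
    poly = pd.DataFrame(rows, columns=["specimen_id", "canal", "point_index",
                                       "x", "y", "z", "label"])
    poly_path = outdir / "centerlines.csv"
    poly.to_csv(poly_path, index=False)

    manifest = pd.DataFrame(
        [(r.specimen_id, r.group, r.sex, r.side, r.log_cs, r.owa_mm2,
          r.subarcuate_opening_pct) for r in records],
        columns=["id", "group", "sex", "side", "log_cs", "owa_mm2",
                 "subarcuate_opening_pct"])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"centerlines": poly_path, "manifest": manifest_path, "truth": truth_path}


def read_cohort(outdir: str | Path) -> list[SpecimenRecord]:
    """Read back a cohort written by :func:`write_cohort`."""
    import pandas as pd

    outdir = Path(outdir)
    poly = pd.read_csv(outdir / "centerlines.csv")
    manifest = pd.read_csv(outdir / "manifest.csv").set_index("id")
    records: list[SpecimenRecord] = []
    for sid, sub in poly.groupby("specimen_id", sort=False):
        canals = {}
        for canal, cs in sub.groupby("canal", sort=False):
            cs = cs.sort_values("point_index")
            canals[canal] = cs[["x", "y", "z"]].to_numpy(dtype=float)
        meta = manifest.loc[sid]
        cls = CenterlineSet(
            canals=canals,
            ampullae={k: canals[k][0].copy() for k in canals},
            common_crus=canals["ASC"][-1].copy(),
            side=str(meta["side"]), specimen_id=str(sid))
        records.append(SpecimenRecord(
            specimen_id=str(sid), group=str(meta["group"]), sex=str(meta["sex"]),
            side=str(meta["side"]), log_cs=float(meta["log_cs"]),
            centerlines=cls, owa_mm2=float(meta["owa_mm2"]),
            subarcuate_opening_pct=float(meta["subarcuate_opening_pct"])))
    return records


def default_nine_group_spec(seed: int = 0, n_per_group: int = 4) -> CohortSpec:
    """A nine-group cohort echoing the structure of a multi-site fossil
    sample: groups differ in mean size and mean shape, sizes drive a
    posterior-canal allometric trend, and a fraction of specimens are
    left-sided."""
    labels = [f"G{i + 1}" for i in range(9)]
    sizes = np.linspace(-0.15, 0.15, 9)
    groups = tuple(GroupSpec(label=lbl, n=n_per_group, mean_log_cs=float(m),
                             shape_offset=0.3,
                             owa_mean_mm2=float(4.0 * np.exp(m)))
                   for lbl, m in zip(labels, sizes))
    return CohortSpec(groups=groups, allometric_slope=0.5, noise_sd=0.15,
                      side_fraction=0.3, seed=seed)
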