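"""Readers and writers for the pipeline's on-disk formats.

Formats (all plain text):

* wide landmark CSV — one row per specimen: ``id, group, side`` then
  ``x1, y1, z1, x2, ...`` in the fixed Ld1..Ld5-then-semilandmark order,
  1-based landmark numbering in the header;
* TPS landmark files — ``LM3=<p>`` records with one ``x y z`` line per point
  and an ``ID=`` record per specimen (no image or scale records);
* square distance-matrix CSV with the id list as header row and column;
* per-pair displacement-field CSV (``pair_id, point_index, dx, dy, dz``)
  with ``pair_id`` of the form ``idA|idB``;
* embedding TSV (``id, mds1, mds2, ...``) with stress and seed recorded in
  ``#``-prefixed metadata header lines.

Numeric round-trips are lossless to 1e-12 (coordinates are written with
repr-level precision).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix, MDSEmbedding
from .procrustes import ShapeSample


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Wide landmark CSV
# ---------------------------------------------------------------------------


def write_landmarks_wide(sample: ShapeSample, path: str | Path,
                         metadata: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    n, p, _ = sample.coords.shape
    header = ["id", "group", "side"] + [f"{ax}{i + 1}" for i in range(p)
                                        for ax in ("x", "y", "z")]
    with path.open("w", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        w = csv.writer(fh)
        w.writerow(header)
        for i in range(n):
            row = [sample.ids[i], sample.groups[i], "right"]
            row.extend(FLOAT_FMT % v for v in sample.coords[i].reshape(-1))
            w.writerow(row)


def read_landmarks_wide(path: str | Path, k: int | None = None) -> ShapeSample:
    """Read a wide landmark CSV into a :class:`ShapeSample`.

    Raises :class:`FormatError` naming the line for ragged rows, non-numeric
    cells, or a point count disagreeing with a declared ``k`` (expected
    ``5 + 3k`` points).
    """
    path = Path(path)
    ids: list[str] = []
    groups: list[str] = []
    coords: list[np.ndarray] = []
    with path.open() as fh:
        lines = [(i + 1, ln) for i, ln in enumerate(fh)
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = next(csv.reader([lines[0][1]]))
    ncols = len(header)
    if ncols < 12 or (ncols - 3) % 3 != 0:
        raise FormatError(f"{path}:{lines[0][0]}: header must be id,group,side "
                          "plus x/y/z triplets")
    p = (ncols - 3) // 3
    if k is not None and p != 5 + 3 * k:
        raise FormatError(f"{path}: {p} points per specimen but k={k} "
                          f"declares {5 + 3 * k}")
    for lineno, ln in lines[1:]:
        row = next(csv.reader([ln]))
        if len(row) != ncols:
            raise FormatError(f"{path}:{lineno}: expected {ncols} fields, "
                              f"got {len(row)} (ragged row)")
        try:
            vals = np.array([float(v) for v in row[3:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate "
                              f"({exc})") from None
        ids.append(row[0])
        groups.append(row[1])
        coords.append(vals.reshape(p, 3))
        if row[2] == "left":
            # stored configurations follow the right-side convention; a left
            # flag means the row was written pre-mirroring
            coords[-1] = coords[-1] * np.array([-1.0, 1.0, 1.0])
    return ShapeSample(coords=np.stack(coords), ids=tuple(ids),
                       groups=tuple(groups),
                       k=(p - 5) // 3 if (p - 5) % 3 == 0 else None)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def write_tps(sample: ShapeSample, path: str | Path) -> None:
    """Write LM3 + ID records (no image/scale records)."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(sample.n):
            fh.write(f"LM3={sample.p}\n")
            for x, y, z in sample.coords[i]:
                fh.write(f"{FLOAT_FMT % x} {FLOAT_FMT % y} {FLOAT_FMT % z}\n")
            fh.write(f"ID={sample.ids[i]}\n")


def read_tps(path: str | Path, groups: Mapping[str, str] | None = None) -> ShapeSample:
    """Read an LM3 TPS file; ``groups`` optionally maps specimen id to group
    label (defaulting to ``"all"``)."""
    path = Path(path)
    coords: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] | None = None
    expected = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if current is not None:
                    raise FormatError(f"{path}:{lineno}: LM3 record before "
                                      "previous ID record")
                expected = int(line.split("=", 1)[1])
                current = []
            elif upper.startswith("ID="):
                if current is None or len(current) != expected:
                    got = 0 if current is None else len(current)
                    raise FormatError(f"{path}:{lineno}: expected {expected} "
                                      f"points, got {got}")
                coords.append(np.array(current))
                ids.append(line.split("=", 1)[1])
                current = None
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: coordinates outside "
                                      "an LM3 record")
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 coordinates")
                try:
                    current.append([float(v) for v in parts])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric "
                                      "coordinate") from None
    if current is not None:
        raise FormatError(f"{path}: trailing LM3 record without ID")
    if not coords:
        raise FormatError(f"{path}: no configurations found")
    ps = {c.shape[0] for c in coords}
    if len(ps) != 1:
        raise FormatError(f"{path}: inconsistent point counts {sorted(ps)}")
    p = ps.pop()
    grp = tuple((groups or {}).get(i, "all") for i in ids)
    return ShapeSample(coords=np.stack(coords), ids=tuple(ids), groups=grp,
                       k=(p - 5) // 3 if (p - 5) % 3 == 0 else None)


# ---------------------------------------------------------------------------
# Distance matrices, displacement fields, embeddings
# ---------------------------------------------------------------------------


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(D.values, index=list(D.ids), columns=list(D.ids))
    df.to_csv(Path(path), float_format=FLOAT_FMT)


def read_distance_matrix(path: str | Path, metric: str = "imported") -> DistanceMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: header row and column must agree")
    return DistanceMatrix(values=df.to_numpy(dtype=float),
                          ids=tuple(str(i) for i in df.index), metric=metric)


def write_displacement_fields(fields: Mapping[tuple[str, str], np.ndarray],
                              path: str | Path) -> None:
    rows = []
    for (a, b), f in fields.items():
        f = np.asarray(f, dtype=float)
        for i, vec in enumerate(f):
            rows.append((f"{a}|{b}", i, *vec))
    pd.DataFrame(rows, columns=["pair_id", "point_index", "dx", "dy", "dz"]) \
        .to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_displacement_fields(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    df = pd.read_csv(Path(path))
    out: dict[tuple[str, str], np.ndarray] = {}
    for pair, sub in df.groupby("pair_id", sort=False):
        a, _, b = str(pair).partition("|")
        if not b:
            raise FormatError(f"{path}: pair_id {pair!r} is not of the form "
                              "'idA|idB'")
        sub = sub.sort_values("point_index")
        out[(a, b)] = sub[["dx", "dy", "dz"]].to_numpy(dtype=float)
    return out


def write_embedding(emb: MDSEmbedding, path: str | Path,
                    metadata: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    dim = emb.coords.shape[1]
    with path.open("w") as fh:
        fh.write(f"# stress={emb.stress!r}\n# n_init={emb.n_init}\n"
                 f"# seed={emb.seed}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("id\t" + "\t".join(f"mds{j + 1}" for j in range(dim)) + "\n")
        for sid, row in zip(emb.ids, emb.coords):
            fh.write(sid + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_embedding(path: str | Path) -> MDSEmbedding:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, list[float]]] = []
    header_seen = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            elif not header_seen:
                header_seen = True
            elif line.strip():
                parts = line.split("\t")
                rows.append((parts[0], [float(v) for v in parts[1:]]))
    return MDSEmbedding(coords=np.array([r[1] for r in rows]),
                        stress=float(meta.get("stress", "nan")),
                        n_init=int(meta.get("n_init", "0")),
                        seed=int(meta.get("seed", "0")),
                        converged=True,
                        ids=tuple(r[0] for r in rows))
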