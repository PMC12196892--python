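"""Point-cloud containers and text I/O (ASCII PLY, XYZ, CSV).

Coordinates are millimetres throughout; no unit conversion is performed.
Labels, when present, are integer class codes (see :mod:`halfscsa.classes`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PointCloud", "CloudParseError", "read_cloud", "write_cloud"]

_FORMATS = ("ply", "xyz", "csv")
_VALID_LABELS = frozenset((0, 1, 2, 3))


class CloudParseError(ValueError):
    """Malformed cloud file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class PointCloud:
    """An ordered set of 3D points with optional per-point class labels.

    Parameters
    ----------
    coords
        ``(n, 3)`` float array of x, y, z in millimetres; all finite.
    labels
        Optional ``(n,)`` integer array of class codes in ``{0, 1, 2, 3}``.
    """

    coords: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.coords),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{len(self.coords)} points"
                )
            bad = set(np.unique(self.labels)) - _VALID_LABELS
            if bad:
                raise ValueError(f"invalid label codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None


def _infer_format(path: str, format: str | None) -> str:
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return format


def read_cloud(path: str, format: str | None = None) -> PointCloud:
    """Read a point cloud from ``path``.

    ``format`` is one of ``"ply"`` (ASCII), ``"xyz"`` (whitespace triples,
    optional fourth label column) or ``"csv"`` (header ``x,y,z[,label]``);
    when omitted it is inferred from the file extension. An empty file
    yields an empty cloud.
    """
    format = _infer_format(path, format)
    if os.path.getsize(path) == 0:
        return PointCloud(np.empty((0, 3)))
    if format == "xyz":
        return _read_xyz(path)
    if format == "csv":
        return _read_csv(path)
    return _read_ply(path)


def write_cloud(cloud: PointCloud, path: str, format: str | None = None) -> None:
    """Write ``cloud`` to ``path``; coordinates round-trip to 6+ significant
    digits and labels exactly."""
    format = _infer_format(path, format)
    if format == "xyz":
        _write_xyz(cloud, path)
    elif format == "csv":
        _write_csv(cloud, path)
    else:
        _write_ply(cloud, path)


# ---------------------------------------------------------------------------
# XYZ

def _read_xyz(path: str) -> PointCloud:
    rows, labels = [], []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if ncols is None:
                ncols = len(parts)
                if ncols not in (3, 4):
                    raise CloudParseError(
                        f"expected 3 or 4 whitespace-separated fields, got {len(parts)}",
                        lineno,
                    )
            if len(parts) != ncols:
                raise CloudParseError(
                    f"expected {ncols} fields, got {len(parts)}", lineno
                )
            try:
                rows.append([float(v) for v in parts[:3]])
                if ncols == 4:
                    labels.append(int(parts[3]))
            except ValueError as exc:
                raise CloudParseError(str(exc), lineno) from exc
    if not rows:
        return PointCloud(np.empty((0, 3)))
    return PointCloud(np.array(rows), np.array(labels) if labels else None)


def _write_xyz(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(cloud.coords):
            if cloud.has_labels:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {cloud.labels[i]:d}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# CSV (comma-separated, header "x,y,z[,label]")

def _read_csv(path: str) -> PointCloud:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return PointCloud(np.empty((0, 3)))
    except (pd.errors.ParserError, ValueError) as exc:
        raise CloudParseError(str(exc)) from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for c in ("x", "y", "z"):
        if c not in cols:
            raise CloudParseError(f"missing required column {c!r}", line=1)
    try:
        coords = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise CloudParseError(str(exc)) from exc
    labels = None
    if "label" in cols:
        labels = df["label"].to_numpy(dtype=np.int64)
    return PointCloud(coords, labels)


def _write_csv(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        if cloud.has_labels:
            fh.write("x,y,z,label\n")
            for i, (x, y, z) in enumerate(cloud.coords):
                fh.write(f"{x:.9g},{y:.9g},{z:.9g},{cloud.labels[i]:d}\n")
        else:
            fh.write("x,y,z\n")
            for x, y, z in cloud.coords:
                fh.write(f"{x:.9g},{y:.9g},{z:.9g}\n")


# ---------------------------------------------------------------------------
# ASCII PLY (element vertex; properties x y z [label])

_PLY_FLOAT_TYPES = {"float", "float32", "float64", "double"}
_PLY_INT_TYPES = {"char", "uchar", "short", "ushort", "int", "uint",
                  "int8", "uint8", "int16", "uint16", "int32", "uint32"}


def _read_ply(path: str) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudParseError("not a PLY file (missing 'ply' magic)", 1)
    n_vertex = None
    properties: list[str] = []
    in_vertex = False
    body_start = None
    for lineno, raw in enumerate(lines[1:], start=2):
        parts = raw.split()
        if not parts:
            continue
        kw = parts[0]
        if kw == "format":
            if len(parts) < 2 or parts[1] != "ascii":
                raise CloudParseError("only ASCII PLY is supported", lineno)
        elif kw == "comment":
            continue
        elif kw == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                try:
                    n_vertex = int(parts[2])
                except (IndexError, ValueError) as exc:
                    raise CloudParseError("malformed vertex element", lineno) from exc
        elif kw == "property":
            if in_vertex:
                if len(parts) != 3 or parts[1] == "list":
                    raise CloudParseError(
                        "only scalar vertex properties are supported", lineno
                    )
                properties.append(parts[2])
        elif kw == "end_header":
            body_start = lineno
            break
        else:
            raise CloudParseError(f"unknown header keyword {kw!r}", lineno)
    if body_start is None or n_vertex is None:
        raise CloudParseError("incomplete PLY header (no end_header or vertex element)")
    for c in ("x", "y", "z"):
        if c not in properties:
            raise CloudParseError(f"vertex element lacks property {c!r}")
    ix, iy, iz = (properties.index(c) for c in ("x", "y", "z"))
    il = properties.index("label") if "label" in properties else None

    coords = np.empty((n_vertex, 3))
    labels = np.empty(n_vertex, dtype=np.int64) if il is not None else None
    row = 0
    for lineno in range(body_start + 1, len(lines) + 1):
        if row >= n_vertex:
            break
        parts = lines[lineno - 1].split()
        if not parts:
            continue
        if len(parts) != len(properties):
            raise CloudParseError(
                f"expected {len(properties)} values, got {len(parts)}", lineno
            )
        try:
            coords[row] = (float(parts[ix]), float(parts[iy]), float(parts[iz]))
            if labels is not None:
                labels[row] = int(parts[il])
        except ValueError as exc:
            raise CloudParseError(str(exc), lineno) from exc
        row += 1
    if row != n_vertex:
        raise CloudParseError(
            f"header declares {n_vertex} vertices but body has {row}"
        )
    return PointCloud(coords, labels)


def _write_ply(cloud: PointCloud, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if cloud.has_labels:
            fh.write("property int label\n")
        fh.write("end_header\n")
        for i, (x, y, z) in enumerate(cloud.coords):
            if cloud.has_labels:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {cloud.labels[i]:d}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
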