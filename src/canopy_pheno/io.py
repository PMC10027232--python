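"""Readers and writers for the ASCII point-cloud formats the pipeline touches.

Supported formats
-----------------
``xyz``
    Whitespace-separated text, 3 columns (X Y Z) or 4 (X Y Z label).
    ``#`` comment lines and blank lines are skipped.
``ply``
    ASCII PLY with ``x y z`` vertex properties and an optional integer
    ``label`` property. Binary PLY is rejected.
``pcd``
    ASCII PCD v0.7 with fields ``x y z`` and optional ``label``.
    ``DATA binary`` is rejected.

Coordinates are centimetres. Writers emit 6 decimal places, so round trips
preserve coordinates to better than 1e-4 cm.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from canopy_pheno.cloud import PlotMap, PointCloud

_FORMATS = ("xyz", "ply", "pcd")


class PointCloudFormatError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext not in _FORMATS:
        raise ValueError(
            f"cannot infer format from extension {path.suffix!r}; "
            f"pass format= explicitly"
        )
    return ext


def read_point_cloud(path: str | os.PathLike, format: str | None = None) -> PointCloud:
    """Read a point cloud, auto-detecting the format from the extension.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    PointCloudFormatError
        On malformed records; the message names the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    fmt = _detect_format(path, format)
    text = path.read_text()
    if fmt == "xyz":
        return _parse_xyz(text, path)
    if fmt == "ply":
        return _parse_ply(text, path)
    return _parse_pcd(text, path)


def write_point_cloud(
    cloud: PointCloud, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a cloud in one of the ASCII formats (chosen by extension).

    Labels, when present, are stored as a fourth integer column/property.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        text = _format_xyz(cloud)
    elif fmt == "ply":
        text = _format_ply(cloud)
    else:
        text = _format_pcd(cloud)
    path.write_text(text)


# ---------------------------------------------------------------- XYZ


def _parse_records(
    lines: list[tuple[int, str]], path: Path, what: str = "record"
) -> PointCloud:
    """Parse 3- or 4-column numeric records; line numbers are 1-based."""
    pts: list[list[float]] = []
    labels: list[int] = []
    ncols: int | None = None
    for lineno, line in lines:
        tokens = line.split()
        if len(tokens) not in (3, 4):
            raise PointCloudFormatError(
                f"{path}: line {lineno}: expected 3 or 4 columns, got {len(tokens)}"
            )
        if ncols is None:
            ncols = len(tokens)
        elif len(tokens) != ncols:
            raise PointCloudFormatError(
                f"{path}: line {lineno}: inconsistent column count"
            )
        try:
            x, y, z = (float(t) for t in tokens[:3])
            if ncols == 4:
                labels.append(int(round(float(tokens[3]))))
        except ValueError as exc:
            raise PointCloudFormatError(
                f"{path}: line {lineno}: malformed {what}: {line!r}"
            ) from exc
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            raise PointCloudFormatError(
                f"{path}: line {lineno}: non-finite coordinate"
            )
        pts.append([x, y, z])
    points = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    return PointCloud(points=points, labels=np.asarray(labels) if labels else None)


def _parse_xyz(text: str, path: Path) -> PointCloud:
    lines = [
        (i + 1, line)
        for i, line in enumerate(text.splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return _parse_records(lines, path)


def _format_xyz(cloud: PointCloud) -> str:
    return "".join(_data_lines(cloud))


def _data_lines(cloud: PointCloud) -> list[str]:
    out = []
    lab = cloud.labels
    for i, (x, y, z) in enumerate(cloud.points):
        if lab is not None:
            out.append(f"{x:.6f} {y:.6f} {z:.6f} {int(lab[i])}\n")
        else:
            out.append(f"{x:.6f} {y:.6f} {z:.6f}\n")
    return out


# ---------------------------------------------------------------- PLY


def _parse_ply(text: str, path: Path) -> PointCloud:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PointCloudFormatError(f"{path}: line 1: missing 'ply' magic")
    n_vertex: int | None = None
    props: list[str] = []
    header_end = None
    for i, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] != "ascii":
                raise PointCloudFormatError(
                    f"{path}: line {i}: only ASCII PLY is supported"
                )
        elif tokens[0] == "element":
            if tokens[1] == "vertex":
                n_vertex = int(tokens[2])
            elif n_vertex is not None:
                break
        elif tokens[0] == "property" and n_vertex is not None:
            props.append(tokens[-1])
        elif tokens[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vertex is None:
        raise PointCloudFormatError(f"{path}: incomplete PLY header")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise PointCloudFormatError(f"{path}: vertex property {axis!r} missing")
    if any(p not in ("x", "y", "z", "label") for p in props):
        extra = [p for p in props if p not in ("x", "y", "z", "label")]
        raise PointCloudFormatError(f"{path}: unsupported vertex properties {extra}")
    data = [
        (header_end + 1 + j, lines[header_end + j])
        for j in range(n_vertex)
        if header_end + j < len(lines)
    ]
    if len(data) != n_vertex:
        raise PointCloudFormatError(
            f"{path}: header declares {n_vertex} vertices, found {len(data)}"
        )
    cloud = _parse_records(data, path, what="vertex")
    if "label" in props and cloud.labels is None and n_vertex > 0:
        raise PointCloudFormatError(f"{path}: label property declared but absent")
    return cloud


def _format_ply(cloud: PointCloud) -> str:
    has_labels = cloud.labels is not None
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if has_labels:
        header.append("property int label")
    header.append("end_header")
    return "\n".join(header) + "\n" + "".join(_data_lines(cloud))


# ---------------------------------------------------------------- PCD


def _parse_pcd(text: str, path: Path) -> PointCloud:
    lines = text.splitlines()
    meta: dict[str, list[str]] = {}
    data_start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") or not line.strip():
            continue
        tokens = line.split()
        key = tokens[0].upper()
        meta[key] = tokens[1:]
        if key == "DATA":
            if tokens[1:] != ["ascii"]:
                raise PointCloudFormatError(
                    f"{path}: line {i + 1}: only 'DATA ascii' is supported"
                )
            data_start = i + 1
            break
    if data_start is None:
        raise PointCloudFormatError(f"{path}: missing PCD DATA section")
    fields = meta.get("FIELDS")
    if fields is None or fields[:3] != ["x", "y", "z"]:
        raise PointCloudFormatError(f"{path}: PCD FIELDS must start with x y z")
    if len(fields) > 4 or (len(fields) == 4 and fields[3] != "label"):
        raise PointCloudFormatError(f"{path}: unsupported PCD fields {fields}")
    n = int(meta.get("POINTS", ["0"])[0])
    data = [
        (data_start + 1 + j, lines[data_start + j])
        for j in range(n)
        if data_start + j < len(lines)
    ]
    if len(data) != n:
        raise PointCloudFormatError(
            f"{path}: header declares {n} points, found {len(data)}"
        )
    return _parse_records(data, path, what="point")


def _format_pcd(cloud: PointCloud) -> str:
    has_labels = cloud.labels is not None
    fields = "x y z label" if has_labels else "x y z"
    ncol = 4 if has_labels else 3
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        f"FIELDS {fields}",
        "SIZE " + " ".join(["8"] * 3 + (["4"] if has_labels else [])),
        "TYPE " + " ".join(["F"] * 3 + (["I"] if has_labels else [])),
        "COUNT " + " ".join(["1"] * ncol),
        f"WIDTH {len(cloud)}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {len(cloud)}",
        "DATA ascii",
    ]
    return "\n".join(header) + "\n" + "".join(_data_lines(cloud))


# ---------------------------------------------------------------- tables


def read_plot_map(path: str | os.PathLike) -> PlotMap:
    """Read a plot map CSV with header plot_id,variety,xmin,xmax,ymin,ymax."""
    return PlotMap.from_frame(pd.read_csv(path))


def write_plot_map(plots: PlotMap, path: str | os.PathLike) -> None:
    plots.to_frame().to_csv(path, index=False)
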