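"""File formats: PLY (ASCII + binary little-endian), PCD (ASCII), XYZ,
skeleton / labeled-skeleton JSON, pruning-plan CSV, YAML config.

Only the point-cloud subset of PLY is handled: an optional ``red green
blue`` uchar triple and an optional integer ``label`` scalar per vertex
are preserved; other properties are read and dropped.
"""
from __future__ import annotations

import csv
import json
import struct
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from .analyze import LabeledSkeleton, PruningPlan, PruningPoint
from .cloud import PointCloud
from .constants import DEFAULTS
from .skeleton import Skeleton

PathLike = Union[str, Path]

_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


class ParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# PLY


def write_ply(path: PathLike, cloud: PointCloud, binary: bool = False) -> None:
    path = Path(path)
    props = ["property float x", "property float y", "property float z"]
    if cloud.colors is not None:
        props += [f"property uchar {c}" for c in ("red", "green", "blue")]
    if cloud.labels is not None:
        props.append("property int label")
    fmt = "binary_little_endian" if binary else "ascii"
    header = "\n".join(
        ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"] + props + ["end_header", ""]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for i in range(len(cloud)):
            row: List = list(cloud.points[i])
            pack = "<3f"
            if cloud.colors is not None:
                row += list(cloud.colors[i])
                pack += "3B"
            if cloud.labels is not None:
                row.append(int(cloud.labels[i]))
                pack += "i"
            if binary:
                fh.write(struct.pack(pack, *[float(v) if isinstance(v, np.floating) else v
                                             for v in row]))
            else:
                text = " ".join(
                    f"{v:.6f}" if isinstance(v, (float, np.floating)) else str(int(v))
                    for v in row
                )
                fh.write((text + "\n").encode("ascii"))


def read_ply(path: PathLike) -> PointCloud:
    path = Path(path)
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise ParseError(f"{path}: line 1: not a PLY file")
        fmt = None
        n_vertex = None
        props: List[Tuple[str, str]] = []
        in_vertex = False
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise ParseError(f"{path}: line {lineno}: unexpected end of header")
            tok = raw.decode("ascii", "replace").strip().split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise ParseError(f"{path}: line {lineno}: list properties unsupported")
                if tok[1] not in _PLY_TYPES:
                    raise ParseError(f"{path}: line {lineno}: unknown type {tok[1]}")
                props.append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported format {fmt}")
        if n_vertex is None:
            raise ParseError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for axis in "xyz":
            if axis not in names:
                raise ParseError(f"{path}: vertex element lacks property {axis}")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                raw = fh.readline()
                lineno += 1
                vals = raw.split()
                if len(vals) < len(props):
                    raise ParseError(f"{path}: line {lineno}: expected {len(props)} values")
                rows.append([float(v) for v in vals[: len(props)]])
            data = np.array(rows) if rows else np.zeros((0, len(props)))
        else:
            rec = struct.Struct("<" + "".join(p[1] for p in props))
            buf = fh.read(rec.size * n_vertex)
            if len(buf) < rec.size * n_vertex:
                raise ParseError(f"{path}: truncated binary body")
            data = np.array([rec.unpack_from(buf, i * rec.size) for i in range(n_vertex)],
                            dtype=np.float64).reshape(n_vertex, len(props))
    col = {name: data[:, i] for i, (name, _) in enumerate(props)} if n_vertex else {}
    pts = (np.column_stack([col["x"], col["y"], col["z"]])
           if n_vertex else np.zeros((0, 3)))
    colors = None
    if n_vertex and all(c in col for c in ("red", "green", "blue")):
        colors = np.column_stack([col["red"], col["green"], col["blue"]]).astype(np.uint8)
    labels = col["label"].astype(np.int64) if n_vertex and "label" in col else None
    return PointCloud(pts, colors, labels)


# ----------------------------------------------------------------------
# PCD (ASCII) and XYZ


def write_pcd(path: PathLike, cloud: PointCloud) -> None:
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\nVERSION 0.7\n"
        "FIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for p in cloud.points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_pcd(path: PathLike) -> PointCloud:
    path = Path(path)
    fields: List[str] = []
    with open(path) as fh:
        data_mode = None
        lineno = 0
        for line in fh:
            lineno += 1
            tok = line.strip().split()
            if not tok or tok[0] == "#":
                continue
            if tok[0] == "FIELDS":
                fields = tok[1:]
            elif tok[0] == "DATA":
                data_mode = tok[1]
                break
        if data_mode != "ascii":
            raise ParseError(f"{path}: only ASCII PCD is supported")
        try:
            ix, iy, iz = fields.index("x"), fields.index("y"), fields.index("z")
        except ValueError as e:
            raise ParseError(f"{path}: FIELDS lacks x/y/z") from e
        pts = []
        for line in fh:
            lineno += 1
            tok = line.split()
            if not tok:
                continue
            try:
                pts.append((float(tok[ix]), float(tok[iy]), float(tok[iz])))
            except (ValueError, IndexError) as e:
                raise ParseError(f"{path}: line {lineno}: bad row") from e
    return PointCloud(np.array(pts) if pts else np.zeros((0, 3)))


def write_xyz(path: PathLike, cloud: PointCloud) -> None:
    np.savetxt(path, cloud.points, fmt="%.6f")


def read_xyz(path: PathLike) -> PointCloud:
    path = Path(path)
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) < 3:
                raise ParseError(f"{path}: line {lineno}: need 3 coordinates")
            try:
                pts.append((float(tok[0]), float(tok[1]), float(tok[2])))
            except ValueError as e:
                raise ParseError(f"{path}: line {lineno}: bad number") from e
    return PointCloud(np.array(pts) if pts else np.zeros((0, 3)))


def read_point_cloud(path: PathLike, fmt: Optional[str] = None) -> PointCloud:
    """Dispatch on ``fmt`` or the file suffix (.ply / .pcd / .xyz / .txt)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    readers = {"ply": read_ply, "pcd": read_pcd, "xyz": read_xyz, "txt": read_xyz}
    if fmt not in readers:
        raise ValueError(f"unknown point cloud format {fmt!r}")
    return readers[fmt](path)


def write_point_cloud(path: PathLike, cloud: PointCloud, fmt: Optional[str] = None,
                      binary: bool = False) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        write_ply(path, cloud, binary=binary)
    elif fmt == "pcd":
        write_pcd(path, cloud)
    elif fmt in ("xyz", "txt"):
        write_xyz(path, cloud)
    else:
        raise ValueError(f"unknown point cloud format {fmt!r}")


# ----------------------------------------------------------------------
# skeleton / labeled JSON, plan CSV, OBJ lines


def write_skeleton(path: PathLike, skeleton: Skeleton) -> None:
    Path(path).write_text(json.dumps(skeleton.to_dict(), indent=1))


def read_skeleton(path: PathLike) -> Skeleton:
    return Skeleton.from_dict(json.loads(Path(path).read_text()))


def write_labeled(path: PathLike, labeled: LabeledSkeleton) -> None:
    d = labeled.skeleton.to_dict()
    d["edge_class"] = [[p, c, labeled.edge_class[(p, c)].name] for p, c in labeled.skeleton.edges()]
    d["trunk"] = {"vertices": labeled.trunk.vertices, "psi_max": labeled.trunk.psi_max}
    d["branches"] = [
        {"id": b.branch_id, "origin": b.origin, "path": b.path, "length_cm": b.length}
        for b in labeled.branches
    ]
    if labeled.plan is not None:
        d["pruning_points"] = [
            {"branch_id": p.branch_id, "xyz": np.asarray(p.position).tolist(),
             "host_edge": list(p.host_edge), "fraction": p.fraction}
            for p in labeled.plan.points
        ]
    Path(path).write_text(json.dumps(d, indent=1))


def write_plan_csv(path: PathLike, plan: PruningPlan) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "z", "branch_id"])
        for i, p in enumerate(plan.points):
            w.writerow([i, f"{p.position[0]:.6f}", f"{p.position[1]:.6f}",
                        f"{p.position[2]:.6f}", p.branch_id])


def read_plan_csv(path: PathLike) -> List[dict]:
    with open(path, newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh)]


def write_skeleton_obj(path: PathLike, skeleton: Skeleton) -> None:
    """OBJ line elements, one polyline segment per edge (for viewers)."""
    ids = skeleton.node_ids
    index = {nid: i + 1 for i, nid in enumerate(ids)}
    with open(path, "w") as fh:
        for nid in ids:
            x, y, z = skeleton.position(nid)
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
        for p, c in skeleton.edges():
            fh.write(f"l {index[p]} {index[c]}\n")


# ----------------------------------------------------------------------
# config


def load_config(path: Optional[PathLike] = None, overrides: Optional[Dict] = None) -> Dict:
    """Defaults, optionally updated from a YAML file and CLI overrides."""
    cfg = dict(DEFAULTS)
    cfg.setdefault("seed", 0)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    _validate_config(cfg)
    return cfg


def dump_config(path: PathLike, cfg: Dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _validate_config(cfg: Dict) -> None:
    if cfg["sor_k"] < 1:
        raise ValueError("sor_k must be >= 1")
    if not (0 < cfg["Ds"] <= cfg["Rd"] <= cfg["R"]):
        raise ValueError("need 0 < Ds <= Rd <= R")
    if not (0 < cfg["theta"] < 90):
        raise ValueError("theta must be in (0, 90)")
    if not (0 < cfg["prune_fraction"] < 1):
        raise ValueError("prune_fraction must be in (0, 1)")
    if cfg["min_branch_length"] < 0:
        raise ValueError("min_branch_length must be >= 0")
    if cfg["pipe_exponent"] <= 0 or cfg["root_radius"] <= 0:
        raise ValueError("pipe_exponent and root_radius must be positive")
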