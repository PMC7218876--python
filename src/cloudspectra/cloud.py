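"""Attributed point clouds: containers, PLY/XYZ I/O, kd-tree indexing, normals.

A cloud is a set of 3D points with optional unit normals, RGB colors in
[0, 1], and named per-point scalar attributes (band reflectances, NDVI,
cluster labels...).  Everything downstream — radiometric mapping,
registration, clustering — consumes this container.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "SpatialIndex",
    "CloudFormatError",
    "read_cloud",
    "write_cloud",
    "build_index",
    "estimate_normals",
]


class CloudFormatError(ValueError):
    """Raised when a cloud file cannot be parsed as the named format."""


@dataclass
class PointCloud:
    """Point cloud with optional normals, colors and named scalar attributes.

    Parameters
    ----------
    positions : (n, 3) float array
        Point coordinates in meters, local scene frame.
    normals : (n, 3) float array, optional
        Unit normals.
    colors : (n, 3) float array, optional
        RGB in [0, 1].
    attributes : dict of str -> (n,) array, optional
        Extra per-point scalars (e.g. ``red_refl``, ``ndvi``, ``label``).
    """

    positions: np.ndarray
    normals: np.ndarray | None = None
    colors: np.ndarray | None = None
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        n = len(self.positions)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != (n, 3):
                raise ValueError("normals must match positions shape")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != (n, 3):
                raise ValueError("colors must match positions shape")
        clean = {}
        for name, arr in self.attributes.items():
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ValueError(f"attribute {name!r} must be a length-{n} vector")
            clean[name] = arr
        self.attributes = clean

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def attribute_schema(self) -> list[str]:
        return sorted(self.attributes)

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.positions.copy(),
            None if self.normals is None else self.normals.copy(),
            None if self.colors is None else self.colors.copy(),
            {k: v.copy() for k, v in self.attributes.items()},
        )

    def select(self, idx: np.ndarray) -> "PointCloud":
        """Sub-cloud at integer or boolean indices, order preserved."""
        return PointCloud(
            self.positions[idx],
            None if self.normals is None else self.normals[idx],
            None if self.colors is None else self.colors[idx],
            {k: v[idx] for k, v in self.attributes.items()},
        )


@dataclass
class SpatialIndex:
    """kd-tree over cloud positions; nearest-neighbor and radius queries."""

    cloud: PointCloud
    tree: cKDTree

    def knn(self, query: np.ndarray, k: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Distances and indices of the ``k`` nearest points to each query."""
        d, i = self.tree.query(np.atleast_2d(query), k=k)
        return d, i

    def radius(self, query: np.ndarray, r: float) -> list[np.ndarray]:
        """Indices of points within ``r`` of each query point."""
        out = self.tree.query_ball_point(np.atleast_2d(query), r)
        return [np.asarray(sorted(ix), dtype=np.intp) for ix in out]


def build_index(cloud: PointCloud) -> SpatialIndex:
    if len(cloud) < 1:
        raise ValueError("cannot index an empty cloud")
    return SpatialIndex(cloud, cKDTree(cloud.positions))


# ---------------------------------------------------------------------------
# PLY I/O
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_COLOR_NAMES = ("red", "green", "blue")
_NORMAL_NAMES = ("nx", "ny", "nz")


def _parse_ply_header(fh: io.BufferedReader) -> tuple[str, int, list[tuple[str, str]], int]:
    """Returns (fmt, n_vertices, [(prop_name, dtype_char)...], header_len)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise CloudFormatError("not a PLY file: missing 'ply' magic")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise CloudFormatError(f"line {lineno}: unexpected EOF in PLY header")
        tok = raw.decode("ascii", errors="replace").split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise CloudFormatError(f"line {lineno}: list properties not supported on vertices")
            if tok[1] not in _PLY_DTYPES:
                raise CloudFormatError(f"line {lineno}: unknown PLY type {tok[1]!r}")
            props.append((tok[2], _PLY_DTYPES[tok[1]]))
        elif tok[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise CloudFormatError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise CloudFormatError("PLY header has no vertex element")
    for need in ("x", "y", "z"):
        if need not in [p[0] for p in props]:
            raise CloudFormatError(f"PLY vertex element lacks property {need!r}")
    return fmt, n_vertex, props, fh.tell()


def _read_ply(path: str) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n, props, _ = _parse_ply_header(fh)
        dtype = np.dtype([(name, "<" + code) for name, code in props])
        if fmt == "binary_little_endian":
            buf = fh.read(n * dtype.itemsize)
            if len(buf) < n * dtype.itemsize:
                raise CloudFormatError(
                    f"byte {fh.tell()}: truncated PLY body "
                    f"({len(buf)} of {n * dtype.itemsize} bytes)")
            rec = np.frombuffer(buf, dtype=dtype, count=n)
        else:
            text = fh.read().decode("ascii")
            rows = [ln.split() for ln in text.splitlines() if ln.strip()]
            if len(rows) < n:
                raise CloudFormatError(f"ASCII PLY body has {len(rows)} rows, header says {n}")
            try:
                arr = np.array(rows[:n], dtype=np.float64)
            except ValueError as exc:
                raise CloudFormatError(f"malformed ASCII PLY record: {exc}") from exc
            if arr.shape[1] != len(props):
                raise CloudFormatError(
                    f"ASCII PLY rows have {arr.shape[1]} fields, header declares {len(props)}")
            rec = np.zeros(n, dtype=dtype)
            for j, (name, _) in enumerate(props):
                rec[name] = arr[:, j]
    names = [p[0] for p in props]
    pos = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    normals = None
    if all(nm in names for nm in _NORMAL_NAMES):
        normals = np.stack([rec[nm] for nm in _NORMAL_NAMES], axis=1).astype(np.float64)
    colors = None
    if all(c in names for c in _COLOR_NAMES):
        cols = np.stack([rec[c] for c in _COLOR_NAMES], axis=1).astype(np.float64)
        # 8-bit color convention: integer-typed channels are scaled to [0, 1]
        if dtype["red"].kind == "u" or dtype["red"].kind == "i":
            cols /= 255.0
        colors = cols
    used = {"x", "y", "z", *_NORMAL_NAMES, *_COLOR_NAMES}
    attrs = {nm: np.asarray(rec[nm]).copy() for nm in names if nm not in used}
    return PointCloud(pos, normals, colors, attrs)


def _write_ply(cloud: PointCloud, path: str, binary: bool = False) -> None:
    fields: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.positions[:, 0]),
        ("y", "double", cloud.positions[:, 1]),
        ("z", "double", cloud.positions[:, 2]),
    ]
    if cloud.normals is not None:
        for j, nm in enumerate(_NORMAL_NAMES):
            fields.append((nm, "double", cloud.normals[:, j]))
    if cloud.colors is not None:
        rgb = np.clip(np.round(cloud.colors * 255.0), 0, 255).astype(np.uint8)
        for j, c in enumerate(_COLOR_NAMES):
            fields.append((c, "uchar", rgb[:, j]))
    for name in sorted(cloud.attributes):
        arr = cloud.attributes[name]
        if np.issubdtype(arr.dtype, np.integer):
            fields.append((name, "int", arr.astype(np.int32)))
        else:
            fields.append((name, "double", arr.astype(np.float64)))
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {typ} {nm}" for nm, typ, _ in fields]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(nm, "<" + _PLY_DTYPES[typ]) for nm, typ, _ in fields])
            rec = np.zeros(len(cloud), dtype=dtype)
            for nm, _, col in fields:
                rec[nm] = col
            fh.write(rec.tobytes())
        else:
            cols = []
            for nm, typ, col in fields:
                if typ in ("uchar", "int"):
                    cols.append([str(int(v)) for v in col])
                else:
                    cols.append([format(float(v), ".17g") for v in col])
            lines = (" ".join(row) for row in zip(*cols))
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# XYZ I/O  (x y z [nx ny nz] [r g b], whitespace-delimited)
# ---------------------------------------------------------------------------

def _read_xyz(path: str) -> PointCloud:
    try:
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise CloudFormatError(f"malformed XYZ file: {exc}") from exc
    if data.size == 0:
        raise CloudFormatError("empty XYZ file")
    ncol = data.shape[1]
    if ncol not in (3, 6, 9):
        raise CloudFormatError(f"XYZ file must have 3, 6 or 9 columns, got {ncol}")
    pos = data[:, :3]
    normals = data[:, 3:6] if ncol >= 6 else None
    colors = data[:, 6:9] if ncol == 9 else None
    if colors is not None and colors.max(initial=0.0) > 1.0 + 1e-9:
        colors = colors / 255.0
    return PointCloud(pos, normals, colors)


def _write_xyz(cloud: PointCloud, path: str) -> None:
    cols = [cloud.positions]
    if cloud.normals is not None:
        cols.append(cloud.normals)
        if cloud.colors is not None:
            cols.append(cloud.colors)
    elif cloud.colors is not None:
        # column layout requires normals before colors
        cols.append(np.zeros_like(cloud.positions))
        cols.append(cloud.colors)
    np.savetxt(path, np.hstack(cols), fmt="%.17g")


def read_cloud(path: str, format: str | None = None) -> PointCloud:
    """Read a point cloud from PLY or XYZ.

    ``format`` defaults to the file extension.  LAS is recognized but not
    supported (no LAS codec shipped); a :class:`CloudFormatError` is raised.
    """
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "ply":
        return _read_ply(str(path))
    if fmt in ("xyz", "txt"):
        return _read_xyz(str(path))
    if fmt == "las":
        raise CloudFormatError("LAS I/O is not supported; convert to PLY or XYZ")
    raise CloudFormatError(f"unknown cloud format {fmt!r}")


def write_cloud(cloud: PointCloud, path: str, format: str | None = None,
                binary: bool = False) -> None:
    """Write a cloud; extra attributes become named scalar PLY properties."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty cloud")
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "ply":
        _write_ply(cloud, str(path), binary=binary)
    elif fmt in ("xyz", "txt"):
        _write_xyz(cloud, str(path))
    elif fmt == "las":
        raise CloudFormatError("LAS I/O is not supported; use PLY or XYZ")
    else:
        raise CloudFormatError(f"unknown cloud format {fmt!r}")


# ---------------------------------------------------------------------------
# Normal estimation
# ---------------------------------------------------------------------------

def estimate_normals(cloud: PointCloud, k: int = 16,
                     viewpoint: np.ndarray | None = None) -> PointCloud:
    """Per-point unit normals from local PCA plane fits over k neighbors.

    The normal is the eigenvector of the neighborhood covariance with the
    smallest eigenvalue.  If ``viewpoint`` is given, normals are flipped to
    face it.  Degenerate (collinear) neighborhoods get an arbitrary unit
    vector orthogonal to the dominant direction; the count of such points is
    stored on the returned cloud as ``cloud.attributes`` is untouched —
    see the ``n_degenerate`` entry of the function attribute
    ``estimate_normals.last_warnings``.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n < k:
        raise ValueError(f"cloud has {n} points, fewer than k={k}")
    tree = cKDTree(cloud.positions)
    _, idx = tree.query(cloud.positions, k=k)
    neigh = cloud.positions[idx]                       # (n, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    w, v = np.linalg.eigh(cov)                         # ascending eigenvalues
    normals = v[:, :, 0]
    # collinear neighborhoods: two near-zero eigenvalues
    scale = np.maximum(w[:, 2], 1e-300)
    degenerate = w[:, 1] / scale < 1e-12
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        dom = v[degenerate][:, :, 2]                   # dominant direction
        pick = np.where(np.abs(dom[:, [0]]) < 0.9,
                        np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
        ortho = np.cross(dom, pick)
        ortho /= np.linalg.norm(ortho, axis=1, keepdims=True)
        normals[degenerate] = ortho
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    if viewpoint is not None:
        to_vp = np.asarray(viewpoint, dtype=float) - cloud.positions
        flip = np.einsum("ij,ij->i", normals, to_vp) < 0
        normals[flip] *= -1.0
    estimate_normals.last_warnings = {"n_degenerate": n_degenerate}
    out = cloud.copy()
    out.normals = normals
    return out


estimate_normals.last_warnings = {"n_degenerate": 0}
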