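"""Raster data model and I/O shared by every pipeline stage.

Grids are plain 2-D numpy arrays wrapped with the minimal metadata the
pipeline needs: a class scheme for categorical layers, a cell size in
meters, and a nodata sentinel.  Row 0 is the northernmost row; indices are
0-based; cells are squares.  Every stage requires all rasters to share
shape and cell size and fails fast otherwise.

Two file formats are supported: single-band TIFF (cell size and nodata
carried in the image-description tag) and ESRI ASCII grid.  Inputs are
assumed pre-aligned — no reprojection or resampling is done here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassEntry",
    "ClassScheme",
    "LandCoverGrid",
    "DriverStack",
    "MaskGrid",
    "GLOBELAND30",
    "read_categorical_raster",
    "write_categorical_raster",
    "read_float_raster",
    "write_float_raster",
    "minmax_normalize",
    "distance_raster",
    "class_areas",
]


@dataclass(frozen=True)
class ClassEntry:
    code: int
    name: str
    is_green_space: bool


@dataclass(frozen=True)
class ClassScheme:
    """Ordered land-cover legend: integer codes, names, green-space flags.

    The default scheme follows the Globeland30 coding with seven classes;
    cultivated land, forest, grassland, wetland and water count as green
    space, artificial surfaces and bare land do not.
    """

    entries: tuple[ClassEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate class codes in scheme: {codes}")
        if not self.entries:
            raise ValueError("scheme must contain at least one class")

    @property
    def codes(self) -> np.ndarray:
        return np.array([e.code for e in self.entries], dtype=np.int64)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def green_codes(self) -> np.ndarray:
        return np.array(
            [e.code for e in self.entries if e.is_green_space], dtype=np.int64
        )

    def index_of(self, code: int) -> int:
        """Position of ``code`` in the scheme order (x1..xn)."""
        for i, e in enumerate(self.entries):
            if e.code == code:
                return i
        raise KeyError(f"code {code} not in scheme")

    def code_to_index(self, values: np.ndarray) -> np.ndarray:
        """Vectorized code -> scheme-index map; unknown codes become -1."""
        lut = {e.code: i for i, e in enumerate(self.entries)}
        out = np.full(values.shape, -1, dtype=np.int64)
        for code, idx in lut.items():
            out[values == code] = idx
        return out


GLOBELAND30 = ClassScheme(
    entries=(
        ClassEntry(10, "cultivated", True),
        ClassEntry(20, "forest", True),
        ClassEntry(30, "grassland", True),
        ClassEntry(50, "wetland", True),
        ClassEntry(60, "water", True),
        ClassEntry(80, "artificial", False),
        ClassEntry(90, "bare", False),
    )
)


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster.

    Parameters
    ----------
    values : (rows, cols) integer array of class codes or nodata.
    cell_size : cell edge length in meters (default 100 m, i.e. 0.01 km²
        per cell).
    nodata : sentinel code for cells outside the study region.
    scheme : the class legend the codes must belong to.
    """

    values: np.ndarray
    cell_size: float = 100.0
    nodata: int = -9999
    scheme: ClassScheme = GLOBELAND30

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.values != self.nodata
        known = np.isin(self.values[valid], self.scheme.codes)
        if not known.all():
            bad = np.unique(self.values[valid][~known])
            raise ValueError(f"codes not in scheme: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def class_indices(self) -> np.ndarray:
        """Scheme-index view of the map; nodata cells are -1."""
        idx = self.scheme.code_to_index(self.values)
        idx[~self.valid_mask] = -1
        return idx

    def copy_with(self, values: np.ndarray) -> "LandCoverGrid":
        return LandCoverGrid(
            values=np.asarray(values, dtype=np.int64),
            cell_size=self.cell_size,
            nodata=self.nodata,
            scheme=self.scheme,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandCoverGrid):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.cell_size == other.cell_size
            and self.nodata == other.nodata
            and self.scheme == other.scheme
        )


@dataclass
class DriverStack:
    """Stack of continuous driver layers aligned to one grid."""

    layers: list[tuple[str, np.ndarray]]
    normalized: bool = False

    def __post_init__(self) -> None:
        shapes = {arr.shape for _, arr in self.layers}
        if len(shapes) > 1:
            raise ValueError(f"driver layers disagree on shape: {shapes}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0][1].shape

    def as_matrix(self, valid: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) feature matrix over ``valid`` cells."""
        stack = np.stack([arr for _, arr in self.layers], axis=-1)
        if valid is None:
            return stack.reshape(-1, len(self.layers))
        return stack[valid]

    def normalize(self) -> "DriverStack":
        """Min-max rescale each layer to [0, 1] (idempotent)."""
        if self.normalized:
            return self
        return DriverStack(
            layers=[(n, minmax_normalize(a)) for n, a in self.layers],
            normalized=True,
        )


@dataclass
class MaskGrid:
    """Boolean restriction mask: True = conversion forbidden."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# numerics


def minmax_normalize(layer: np.ndarray) -> np.ndarray:
    """Rescale finite values to [0, 1] via (X - min)/(max - min).

    Non-finite cells (nodata stored as NaN) are propagated unchanged.  A
    constant layer maps to all zeros: it carries no information and the
    formula is otherwise undefined.
    """
    out = np.asarray(layer, dtype=float).copy()
    finite = np.isfinite(out)
    if not finite.any():
        raise ValueError("layer has no finite values")
    lo = out[finite].min()
    hi = out[finite].max()
    if hi == lo:
        out[finite] = 0.0
        return out
    out[finite] = (out[finite] - lo) / (hi - lo)
    return out


def distance_raster(features: MaskGrid, cell_size: float = 100.0) -> np.ndarray:
    """Center-to-center Euclidean distance (meters) to the nearest feature cell.

    Feature cells (True) get distance 0.  Used to derive distance-to-river /
    distance-to-road style driver layers.
    """
    feat = features.values
    if not feat.any():
        raise ValueError("feature set is empty")
    dist_cells = ndimage.distance_transform_edt(~feat)
    return dist_cells * float(cell_size)


def class_areas(grid: LandCoverGrid) -> np.ndarray:
    """Per-class area vector in km², in scheme order."""
    idx = grid.class_indices()
    counts = np.bincount(idx[idx >= 0], minlength=grid.scheme.n_classes)
    return counts * grid.cell_area_km2


def class_counts(grid: LandCoverGrid) -> np.ndarray:
    idx = grid.class_indices()
    return np.bincount(idx[idx >= 0], minlength=grid.scheme.n_classes)


# ---------------------------------------------------------------------------
# file I/O


def _is_ascii(path: Path) -> bool:
    return path.suffix.lower() in {".asc", ".txt"}


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, float]:
    """Parse an ESRI ASCII grid; returns (values, cell_size, nodata)."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    if "ncols" not in header or "nrows" not in header:
        raise IOError(f"{path}: missing ESRI ASCII header")
    values = np.loadtxt(data_lines, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    return (
        values,
        float(header.get("cellsize", 100.0)),
        float(header.get("nodata_value", -9999)),
    )


def _write_ascii_grid(
    path: Path, values: np.ndarray, cell_size: float, nodata: float, fmt: str
) -> None:
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner 0.0\nyllcorner 0.0\n"
            f"cellsize {cell_size}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, values, fmt=fmt)


def _read_tiff(path: Path) -> tuple[np.ndarray, float, float]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return (
        values,
        float(meta.get("cell_size", 100.0)),
        float(meta.get("nodata", -9999)),
    )


def _write_tiff(
    path: Path, values: np.ndarray, cell_size: float, nodata: float
) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        values,
        description=json.dumps({"cell_size": cell_size, "nodata": nodata}),
    )


def read_categorical_raster(
    path: str | Path, scheme: ClassScheme = GLOBELAND30
) -> LandCoverGrid:
    """Read a single-band categorical raster (TIFF or ESRI ASCII grid).

    Codes are validated against ``scheme``; a grid containing unknown codes
    raises a ``ValueError`` listing the offending codes.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_ascii(path):
        values, cell_size, nodata = _read_ascii_grid(path)
    else:
        values, cell_size, nodata = _read_tiff(path)
    return LandCoverGrid(
        values=np.asarray(values, dtype=np.int64),
        cell_size=cell_size,
        nodata=int(nodata),
        scheme=scheme,
    )


def write_categorical_raster(grid: LandCoverGrid, path: str | Path) -> None:
    path = Path(path)
    if _is_ascii(path):
        _write_ascii_grid(path, grid.values, grid.cell_size, grid.nodata, fmt="%d")
    else:
        _write_tiff(path, grid.values.astype(np.int32), grid.cell_size, grid.nodata)


def read_float_raster(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a continuous layer; returns (values, cell_size). Nodata -> NaN."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_ascii(path):
        values, cell_size, nodata = _read_ascii_grid(path)
    else:
        values, cell_size, nodata = _read_tiff(path)
    values = np.asarray(values, dtype=float)
    values[values == nodata] = np.nan
    return values, cell_size


def write_float_raster(
    values: np.ndarray, path: str | Path, cell_size: float = 100.0
) -> None:
    path = Path(path)
    out = np.asarray(values, dtype=float).copy()
    nodata = -9999.0
    out[~np.isfinite(out)] = nodata
    if _is_ascii(path):
        _write_ascii_grid(path, out, cell_size, nodata, fmt="%.8g")
    else:
        _write_tiff(path, out.astype(np.float32), cell_size, nodata)


def write_mask(mask: MaskGrid, path: str | Path, cell_size: float = 100.0) -> None:
    path = Path(path)
    values = mask.values.astype(np.int64)
    if _is_ascii(path):
        _write_ascii_grid(path, values, cell_size, -9999, fmt="%d")
    else:
        _write_tiff(path, values.astype(np.uint8), cell_size, -9999)


def read_mask(path: str | Path) -> MaskGrid:
    path = Path(path)
    if _is_ascii(path):
        values, _, _ = _read_ascii_grid(path)
    else:
        values, _, _ = _read_tiff(path)
    return MaskGrid(values=values.astype(bool))


def require_aligned(*shapes: Sequence[int]) -> None:
    """Fail fast when any two rasters disagree on shape."""
    uniq = {tuple(s) for s in shapes}
    if len(uniq) > 1:
        raise ValueError(f"misaligned rasters: shapes {sorted(uniq)}")
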