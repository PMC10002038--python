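"""Class- and landscape-level pattern indices on categorical rasters.

Implements the standard raster definitions used throughout landscape
ecology: patch count (NP), edge density (ED, m/ha), largest patch index
(LPI, %), aggregation index (AI, %), Shannon diversity (SHDI, nats) and
evenness (SHEI), contagion (CONTAG, %), and the landscape division index
(DIVISION).

Conventions (all standard, all switchable where meaningful):

* patches are connected components of equal-valued cells, 8-connectivity
  by default;
* adjacency-based indices (AI, CONTAG) use rook (4-neighbor) adjacencies;
* the landscape boundary and nodata edges count toward patch perimeter
  but not toward ED, whose edge total is interior inter-class edges only;
* degenerate single-class landscapes take the limits SHEI = 0 and
  CONTAG = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from greenscape.grid import LandCoverGrid

__all__ = [
    "PatchSet",
    "MetricsReport",
    "label_patches",
    "class_level_metrics",
    "landscape_level_metrics",
]


@dataclass
class PatchSet:
    """Labeled patches of one map.

    ``labels`` assigns every valid cell a patch id >= 1 (0 = nodata);
    ``table`` has one row per patch: id, class code, area in cells,
    perimeter in meters (cell edges adjacent to a different class, nodata
    or the landscape boundary).
    """

    labels: np.ndarray
    table: pd.DataFrame
    connectivity: int
    grid: LandCoverGrid


@dataclass
class MetricsReport:
    class_level: pd.DataFrame  # NP, ED, LPI, AI per class
    landscape_level: dict[str, float]  # SHDI, SHEI, CONTAG, DIVISION


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def label_patches(grid: LandCoverGrid, connectivity: int = 8) -> PatchSet:
    """Connected-component patches of equal-valued cells."""
    struct = _structure(connectivity)
    idx = grid.class_indices()
    labels = np.zeros(grid.shape, dtype=np.int64)
    records = []
    next_id = 1
    for k, code in enumerate(grid.scheme.codes):
        cls_mask = idx == k
        if not cls_mask.any():
            continue
        lab, n = ndimage.label(cls_mask, structure=struct)
        labels[cls_mask] = lab[cls_mask] + (next_id - 1)
        areas = np.bincount(lab[cls_mask])[1:]
        for p in range(n):
            records.append(
                {"patch_id": next_id + p, "code": int(code), "area_cells": int(areas[p])}
            )
        next_id += n
    table = pd.DataFrame.from_records(
        records, columns=["patch_id", "code", "area_cells"]
    )
    table["perimeter_m"] = _patch_perimeters(labels, next_id - 1) * grid.cell_size
    return PatchSet(labels=labels, table=table, connectivity=connectivity, grid=grid)


def _patch_perimeters(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """Edge counts per patch against anything that is not the same patch...

    ...except that two different patches of the same class cannot touch by
    construction (they would have been merged), so counting edges against
    different *labels* equals counting edges against different classes,
    nodata, or the boundary.
    """
    padded = np.pad(labels, 1, constant_values=0)
    edges = np.zeros(n_patches + 1, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nbr = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        diff = (padded != nbr) & (padded > 0)
        edges += np.bincount(padded[diff], minlength=n_patches + 1)
    return edges[1:]


def _rook_adjacency(idx: np.ndarray, n_classes: int) -> np.ndarray:
    """Single-count 4-neighbor adjacency matrix over valid cells.

    ``adj[i, j]`` is the number of unordered cell-side adjacencies between
    classes i and j (like adjacencies counted once).
    """
    adj = np.zeros((n_classes, n_classes), dtype=np.int64)
    pairs = [
        (idx[:-1, :], idx[1:, :]),  # vertical neighbors
        (idx[:, :-1], idx[:, 1:]),  # horizontal neighbors
    ]
    for a, b in pairs:
        ok = (a >= 0) & (b >= 0)
        flat = a[ok] * n_classes + b[ok]
        counts = np.bincount(flat, minlength=n_classes * n_classes)
        adj += counts.reshape(n_classes, n_classes)
    return adj + adj.T - np.diag(np.diag(adj))  # symmetrize off-diagonals


def _max_like_adjacencies(a: int) -> int:
    """Largest possible single-count like-adjacency count for ``a`` cells.

    Achieved by the most square arrangement: with n = floor(sqrt(a)) and
    m = a - n², the maximum is 2n(n-1) plus 0, 2m-1 or 2m-2 according to
    m = 0, m <= n, or m > n.
    """
    n = int(np.floor(np.sqrt(a)))
    m = a - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


def class_level_metrics(patches: PatchSet) -> pd.DataFrame:
    """NP, ED (m/ha), LPI (%) and AI (%) per class.

    Classes absent from the map get NaN rows.  AI of a single-cell class
    (no like adjacency possible) is NaN.
    """
    grid = patches.grid
    scheme = grid.scheme
    idx = grid.class_indices()
    n_valid = grid.n_valid
    area_ha = n_valid * grid.cell_size**2 / 1e4
    adj = _rook_adjacency(idx, scheme.n_classes)
    rows = []
    for k, code in enumerate(scheme.codes):
        sub = patches.table[patches.table["code"] == code]
        a_cells = int((idx == k).sum())
        if a_cells == 0:
            rows.append(
                {"code": int(code), "name": scheme.names[k], "NP": np.nan,
                 "ED": np.nan, "LPI": np.nan, "AI": np.nan}
            )
            continue
        np_i = len(sub)
        # interior inter-class edges only (no boundary, no nodata)
        edge_m = (adj[k].sum() - adj[k, k]) * grid.cell_size
        ed = edge_m / area_ha
        lpi = 100.0 * sub["area_cells"].max() / n_valid
        g_max = _max_like_adjacencies(a_cells)
        ai = 100.0 * adj[k, k] / g_max if g_max > 0 else np.nan
        rows.append(
            {"code": int(code), "name": scheme.names[k], "NP": np_i,
             "ED": ed, "LPI": lpi, "AI": ai}
        )
    return pd.DataFrame(rows).set_index("code")


def landscape_level_metrics(
    grid: LandCoverGrid, connectivity: int = 8
) -> dict[str, float]:
    """SHDI, SHEI, CONTAG and DIVISION for the whole landscape.

    SHDI = -sum p_i ln p_i over classes present; SHEI = SHDI / ln m;
    CONTAG is the adjacency-entropy contagion over rook adjacencies
    (double-count convention); DIVISION = 1 - sum (patch area / A)².
    """
    if grid.n_valid == 0:
        raise ValueError("grid has no valid cells")
    idx = grid.class_indices()
    k = grid.scheme.n_classes
    counts = np.bincount(idx[idx >= 0], minlength=k)
    present = counts > 0
    p = counts[present] / counts.sum()
    shdi = float(-(p * np.log(p)).sum())
    m = int(present.sum())
    shei = float(shdi / np.log(m)) if m > 1 else 0.0

    if m == 1:
        contag = 100.0
    else:
        adj = _rook_adjacency(idx, k).astype(float)
        # double-count: each adjacency in both directions (doubles g_ii)
        g = adj + np.diag(np.diag(adj))
        g = g[np.ix_(present, present)]
        row_tot = g.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p[:, None] * g / row_tot).ravel()
        q = q[np.isfinite(q) & (q > 0)]
        contag = float((1.0 + (q * np.log(q)).sum() / (2.0 * np.log(m))) * 100.0)

    patches = label_patches(grid, connectivity=connectivity)
    frac = patches.table["area_cells"].to_numpy() / grid.n_valid
    division = float(1.0 - (frac**2).sum())
    return {"SHDI": shdi, "SHEI": shei, "CONTAG": contag, "DIVISION": division}
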