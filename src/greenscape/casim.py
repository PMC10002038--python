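"""Markov demand, scenario adjustment, and roulette-selection CA allocation.

The simulator allocates future land-cover maps by combining, per cell and
candidate class k:

    TP_k = suitability_k * Omega_k * inertia_k

where ``Omega_k`` is the fraction of class-k cells in the moving window
(center excluded) scaled by a per-class expansion weight, and ``inertia_k``
is an adaptive multiplier steering allocation toward the demanded class
totals.  A binary conversion-cost matrix and a restriction mask act as
hard filters (TP = 0).  The next class of a cell is drawn by roulette over
TP; a drawn change is committed only when it moves both the source and the
target class toward their demand targets, so each committed change
strictly shrinks the total demand gap.  Iteration stops when every class
is within tolerance of its target.

Demand comes from a Markov chain: the empirical transition-probability
matrix between the two observed dates, powered forward.  Scenario policies
(e.g. halving the forest -> artificial transfer probability) are expressed
as multiplicative adjustments whose mass change is absorbed by the
diagonal stay probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from greenscape.change import TransitionMatrix
from greenscape.grid import LandCoverGrid, MaskGrid, require_aligned
from greenscape.suitability import SuitabilityCube

__all__ = [
    "ConversionCostMatrix",
    "NeighborhoodWeights",
    "ScenarioConfig",
    "DemandSeries",
    "SimulationReport",
    "project_demand",
    "apply_scenario",
    "simulate",
    "kappa_oa",
    "STATUS_QUO",
    "ECOLOGICAL_PROTECTION",
    "ECONOMIC_DEVELOPMENT",
]


@dataclass
class ConversionCostMatrix:
    """Binary permission matrix: allow[i, j] = 1 lets class i become j."""

    allow: np.ndarray

    def __post_init__(self) -> None:
        self.allow = np.asarray(self.allow, dtype=np.int8)
        if self.allow.ndim != 2 or self.allow.shape[0] != self.allow.shape[1]:
            raise ValueError("cost matrix must be square")
        if not np.isin(self.allow, (0, 1)).all():
            raise ValueError("cost matrix entries must be 0 or 1")
        if not (np.diag(self.allow) == 1).all():
            raise ValueError("a class must always be allowed to keep itself")

    @classmethod
    def all_allowed(cls, n: int) -> "ConversionCostMatrix":
        return cls(allow=np.ones((n, n), dtype=np.int8))


@dataclass
class NeighborhoodWeights:
    """Per-class expansion weights in [0, 1] and the window size.

    A weight near 1 means the class expands easily into neighborhoods
    where it is already present; the window is the odd edge length of the
    moving neighborhood (default 3, i.e. the 8 surrounding cells).
    """

    w: np.ndarray
    window: int = 3

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if ((self.w < 0) | (self.w > 1)).any():
            raise ValueError("neighborhood weights must lie in [0, 1]")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")

    @classmethod
    def uniform(cls, n: int, value: float = 1.0, window: int = 3):
        return cls(w=np.full(n, value), window=window)


@dataclass
class ScenarioConfig:
    """Named multiplicative adjustments to transition probabilities.

    ``multipliers`` maps (from-index, to-index) pairs to positive factors;
    e.g. {(1, 5): 0.5} halves the forest -> artificial transfer
    probability.  The empty map is the status-quo scenario.
    """

    name: str
    multipliers: dict[tuple[int, int], float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        for key, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {key} must be positive")


# The three simulation scenarios, with policy adjustments read as
# multiplicative factors on the affected transfer probabilities.
# Scheme order: 0=cultivated 1=forest 2=grassland 3=wetland 4=water
# 5=artificial 6=bare.
STATUS_QUO = ScenarioConfig(
    name="status_quo",
    notes="continuation of the observed transfer trend; no adjustment",
)
ECOLOGICAL_PROTECTION = ScenarioConfig(
    name="ecological_protection",
    multipliers={
        (1, 5): 0.5,  # forest -> artificial reduced to 50%
        (0, 5): 0.3,  # cultivated -> artificial reduced to 30%
        (0, 1): 1.2,  # cultivated -> forest increased by 20%
        (0, 2): 1.2,  # cultivated -> grassland increased by 20%
    },
    notes="restrain urbanization; safeguard forests, wetlands and water",
)
ECONOMIC_DEVELOPMENT = ScenarioConfig(
    name="economic_development",
    multipliers={
        (1, 5): 1.5,  # forest -> artificial increased by 50%
        (2, 5): 1.5,  # grassland -> artificial increased by 50%
        (1, 0): 1.3,  # forest -> cultivated increased by 30%
    },
    notes="prioritize artificial-surface and cultivated-land growth",
)


@dataclass
class DemandSeries:
    """Projected class totals, in cells, at the simulation horizon."""

    target_cells: np.ndarray
    tolerance: float = 0.001
    max_iterations: int = 300

    def __post_init__(self) -> None:
        self.target_cells = np.asarray(self.target_cells, dtype=np.int64)
        if (self.target_cells < 0).any():
            raise ValueError("demand cells must be non-negative")


@dataclass
class SimulationReport:
    iterations: int
    converged: bool
    demand_gap: np.ndarray  # final |allocated - target| per class, cells
    changed_cells: int


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quota).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def project_demand(
    tm: TransitionMatrix,
    current_areas: np.ndarray,
    steps: int,
    cell_area: float = 1.0,
    tolerance: float = 0.001,
    max_iterations: int = 300,
) -> DemandSeries:
    """Markov projection of class demand ``steps`` intervals ahead.

    The empirical matrix is row-normalized into transition probabilities P
    (classes with zero initial area keep themselves), and the current area
    vector is propagated through P**steps.  Areas are converted to whole
    cells by largest-remainder rounding so the cell total is preserved.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    P = tm.row_probabilities()
    areas = np.asarray(current_areas, dtype=float)
    for _ in range(steps):
        areas = areas @ P
    quota = areas / cell_area
    total = int(round(np.asarray(current_areas, dtype=float).sum() / cell_area))
    cells = _largest_remainder(quota, total)
    return DemandSeries(
        target_cells=cells, tolerance=tolerance, max_iterations=max_iterations
    )


def apply_scenario(tm: TransitionMatrix, scn: ScenarioConfig) -> TransitionMatrix:
    """Scale targeted transition probabilities, absorbing mass in the diagonal.

    For each adjusted row the probability change of the targeted entries
    is compensated by the stay probability, keeping the row stochastic; a
    compensation that would drive the stay probability negative raises an
    error naming the row.
    """
    P = tm.row_probabilities()
    adjusted = P.copy()
    by_row: dict[int, list[tuple[int, float]]] = {}
    for (i, j), m in scn.multipliers.items():
        by_row.setdefault(i, []).append((j, m))
    for i, items in by_row.items():
        delta = 0.0
        for j, m in items:
            if i == j:
                raise ValueError("cannot adjust a diagonal (stay) probability")
            new = P[i, j] * m
            delta += new - P[i, j]
            adjusted[i, j] = new
        adjusted[i, i] = P[i, i] - delta
        if adjusted[i, i] < 0:
            raise ValueError(
                f"scenario '{scn.name}' drives the stay probability of row "
                f"{i} negative ({adjusted[i, i]:.4f})"
            )
        adjusted[i] /= adjusted[i].sum()
    area = adjusted * tm.t0_areas[:, None]
    return TransitionMatrix(area=area, years=tm.years, class_names=tm.class_names)


def _neighborhood(idx: np.ndarray, n_classes: int, window: int) -> np.ndarray:
    """(rows, cols, k) windowed same-class fraction, center cell excluded."""
    kernel = np.ones((window, window))
    kernel[window // 2, window // 2] = 0.0
    denom = window * window - 1
    out = np.empty(idx.shape + (n_classes,), dtype=float)
    for k in range(n_classes):
        onehot = (idx == k).astype(float)
        out[:, :, k] = ndimage.convolve(onehot, kernel, mode="constant", cval=0.0)
    return out / denom


def simulate(
    grid0: LandCoverGrid,
    cube: SuitabilityCube,
    demand: DemandSeries,
    cost: ConversionCostMatrix | None = None,
    weights: NeighborhoodWeights | None = None,
    mask: MaskGrid | None = None,
    seed: int = 0,
) -> tuple[LandCoverGrid, SimulationReport]:
    """Allocate the demanded class totals onto the map by roulette CA.

    Masked cells never change; conversions with cost 0 never occur; the
    total cell count is conserved.  Raises before iterating when the
    demand is infeasible under the mask and cost constraints.  If the
    demand gap is still above tolerance after ``max_iterations``, a
    warning is issued and the best-effort map is returned with
    diagnostics.
    """
    k = grid0.scheme.n_classes
    if cost is None:
        cost = ConversionCostMatrix.all_allowed(k)
    if weights is None:
        weights = NeighborhoodWeights.uniform(k)
    require_aligned(grid0.shape, cube.valid.shape)
    if mask is not None:
        require_aligned(grid0.shape, mask.shape)
    if cost.allow.shape != (k, k) or len(weights.w) != k:
        raise ValueError("cost/weights dimensions disagree with the scheme")

    idx = grid0.class_indices()
    valid = idx >= 0
    if not np.array_equal(valid, cube.valid):
        raise ValueError("suitability cube valid mask disagrees with the grid")
    n_valid = int(valid.sum())
    target = demand.target_cells
    if len(target) != k:
        raise ValueError("demand vector length disagrees with the scheme")
    if target.sum() != n_valid:
        raise ValueError(
            f"demand totals {target.sum()} cells but the map has {n_valid}"
        )
    frozen = np.zeros(grid0.shape, dtype=bool) if mask is None else mask.values

    # feasibility: growth of class j needs convertible, unfrozen donor cells
    allocated = np.bincount(idx[valid], minlength=k)
    mutable = valid & ~frozen
    for j in range(k):
        need = target[j] - allocated[j]
        if need > 0:
            donors = 0
            for i in range(k):
                if i != j and cost.allow[i, j]:
                    donors += int((mutable & (idx == i)).sum())
            if donors < need:
                raise ValueError(
                    f"infeasible demand: class {j} needs {need} more cells "
                    f"but only {donors} convertible cells exist"
                )

    dense_prob = np.zeros(grid0.shape + (k,))
    dense_prob[valid] = cube.prob
    rng = np.random.default_rng(seed)
    inertia = np.ones(k)
    tol_cells = max(1.0, demand.tolerance * n_valid)
    current = idx.copy()
    iterations = 0
    converged = bool(np.abs(allocated - target).max() <= tol_cells)

    while not converged and iterations < demand.max_iterations:
        iterations += 1
        omega = _neighborhood(current, k, weights.window) * weights.w
        tp = dense_prob * omega * inertia
        # hard filters: conversion cost (by current class) and mask
        allow_from = cost.allow[np.clip(current, 0, None)].astype(float)
        tp *= allow_from
        tp[frozen | ~valid] = 0.0

        totals = tp.sum(axis=-1)
        drawable = valid & ~frozen & (totals > 0)
        draw = current.copy()
        if drawable.any():
            p = tp[drawable] / totals[drawable, None]
            u = rng.random(p.shape[0])
            draw[drawable] = (u[:, None] >= np.cumsum(p, axis=1)).sum(axis=1)

        # commit drawn changes in seeded random order, only while they
        # shrink both the donor surplus and the receiver deficit
        cand = np.flatnonzero((draw != current).ravel() & drawable.ravel())
        rng.shuffle(cand)
        cur_flat = current.ravel()
        draw_flat = draw.ravel()
        for c in cand:
            old, new = cur_flat[c], draw_flat[c]
            if allocated[old] > target[old] and allocated[new] < target[new]:
                cur_flat[c] = new
                allocated[old] -= 1
                allocated[new] += 1
        current = cur_flat.reshape(grid0.shape)

        gap = allocated - target
        converged = bool(np.abs(gap).max() <= tol_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(allocated > 0, target / np.maximum(allocated, 1), 2.0)
        inertia *= np.clip(ratio, 0.5, 2.0)
        inertia = np.clip(inertia, 1e-6, 1e6)

    if not converged:
        warnings.warn(
            "CA allocation did not converge within "
            f"{demand.max_iterations} iterations; residual gap "
            f"{np.abs(allocated - target).max()} cells",
            stacklevel=2,
        )
    out_codes = np.where(
        current >= 0, grid0.scheme.codes[np.clip(current, 0, None)], grid0.nodata
    )
    report = SimulationReport(
        iterations=iterations,
        converged=converged,
        demand_gap=np.abs(allocated - target),
        changed_cells=int(((current != idx) & valid).sum()),
    )
    return grid0.copy_with(out_codes), report


def kappa_oa(
    actual: LandCoverGrid, simulated: LandCoverGrid
) -> tuple[float, float, np.ndarray]:
    """Cohen's kappa, overall accuracy and the confusion matrix.

    OA is the fraction of agreeing valid cells; kappa corrects OA for the
    chance agreement implied by the two maps' marginals.  When both maps
    are single-class (chance agreement 1), kappa is defined as 1 for
    identical maps and 0 otherwise.
    """
    require_aligned(actual.shape, simulated.shape)
    if actual.scheme != simulated.scheme:
        raise ValueError("maps use different class schemes")
    ia = actual.class_indices()
    ib = simulated.class_indices()
    both = (ia >= 0) & (ib >= 0)
    k = actual.scheme.n_classes
    flat = ia[both] * k + ib[both]
    confusion = np.bincount(flat, minlength=k * k).reshape(k, k).astype(float)
    total = confusion.sum()
    if total == 0:
        raise ValueError("no jointly valid cells")
    p_o = np.trace(confusion) / total
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum() / total**2)
    if p_e >= 1.0 - 1e-12:
        kappa = 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), float(p_o), confusion
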