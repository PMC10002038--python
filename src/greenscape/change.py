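"""Transition accounting and landscape-composition dynamic degrees.

The single dynamic degree K annualizes the relative area change of one
class between two dates:

    K = (U_b - U_a) / U_a * (1/T) * 100   [% per year]

The comprehensive dynamic degree Lc annualizes the total transferred
(off-diagonal) area relative to twice the total initial area:

    Lc = [ sum_{i != j} dLU_ij / (2 * sum_i LU_i) ] * (1/T) * 100

Both are reported in percent per year; T is a real number of years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from greenscape.grid import LandCoverGrid, class_areas, require_aligned

__all__ = [
    "TransitionMatrix",
    "DynamicsReport",
    "transition_matrix",
    "single_dynamic_degree",
    "comprehensive_dynamic_degree",
    "dynamics_report",
]


@dataclass
class TransitionMatrix:
    """From-class x to-class transferred areas (km²) between two dates.

    ``area[i, j]`` is the area that was class i at t0 and class j at t1;
    row sums equal the t0 class areas and column sums the t1 areas, so
    total area is conserved.  ``years`` is the interval length T.
    """

    area: np.ndarray
    years: float
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.area.ndim != 2 or self.area.shape[0] != self.area.shape[1]:
            raise ValueError("transition area matrix must be square")
        if (self.area < 0).any():
            raise ValueError("transferred areas must be non-negative")
        if self.years <= 0:
            raise ValueError("years must be positive")

    @property
    def t0_areas(self) -> np.ndarray:
        return self.area.sum(axis=1)

    @property
    def t1_areas(self) -> np.ndarray:
        return self.area.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.area.sum())

    def row_probabilities(self) -> np.ndarray:
        """Row-stochastic transition probabilities; empty rows -> identity."""
        P = self.area.copy()
        rows = P.sum(axis=1)
        for i, r in enumerate(rows):
            if r > 0:
                P[i] /= r
            else:
                P[i] = 0.0
                P[i, i] = 1.0
        return P


@dataclass
class DynamicsReport:
    single_K: np.ndarray  # % per year, one entry per class
    comprehensive_Lc: float  # % per year
    class_names: list[str] | None = None


def transition_matrix(
    a: LandCoverGrid, b: LandCoverGrid, years: float
) -> TransitionMatrix:
    """Cross-tabulate two aligned maps into transferred areas (km²).

    Cells that are nodata in either map are excluded from both, so the
    matrix marginals stay consistent with per-map class areas over the
    common valid region.
    """
    require_aligned(a.shape, b.shape)
    if a.scheme != b.scheme:
        raise ValueError("grids use different class schemes")
    if a.cell_size != b.cell_size:
        raise ValueError("grids use different cell sizes")
    ia = a.class_indices()
    ib = b.class_indices()
    both = (ia >= 0) & (ib >= 0)
    k = a.scheme.n_classes
    flat = ia[both] * k + ib[both]
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    return TransitionMatrix(
        area=counts * a.cell_area_km2,
        years=years,
        class_names=a.scheme.names,
    )


def single_dynamic_degree(u_a: float, u_b: float, years: float) -> float:
    """Annualized relative change of one class, in % per year."""
    if u_a <= 0:
        raise ValueError("initial area must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return (u_b - u_a) / u_a / years * 100.0


def comprehensive_dynamic_degree(tm: TransitionMatrix) -> float:
    """Annualized total-transfer rate, in % per year.

    The numerator is the off-diagonal (changed) area only; an identity
    transition matrix therefore gives exactly 0, and doubling all areas
    leaves the value unchanged.
    """
    total = tm.t0_areas.sum()
    if total <= 0:
        raise ValueError("zero total area")
    transferred = tm.area.sum() - np.trace(tm.area)
    return transferred / (2.0 * total) / tm.years * 100.0


def dynamics_report(tm: TransitionMatrix) -> DynamicsReport:
    """Per-class K and landscape Lc from one transition matrix.

    Classes absent at t0 get K = NaN (the rate is undefined without an
    initial area).
    """
    t0 = tm.t0_areas
    t1 = tm.t1_areas
    K = np.full(len(t0), np.nan)
    for i in range(len(t0)):
        if t0[i] > 0:
            K[i] = single_dynamic_degree(t0[i], t1[i], tm.years)
    return DynamicsReport(
        single_K=K,
        comprehensive_Lc=comprehensive_dynamic_degree(tm),
        class_names=tm.class_names,
    )
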