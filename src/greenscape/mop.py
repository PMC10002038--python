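"""Weighted ecological–economic LP over the land-cover quantity structure.

The optimization allocates a fixed total land area across the seven
land-cover classes x1..x7 to maximize

    max  alpha * Ed(x) + beta * Ep(x),      alpha + beta = 1,

with Ep(x) = sum p_i x_i (ecological benefit) and Ed(x) = sum d_i x_i
(economic benefit), subject to per-class box bounds and the total-area
equality.  For this box-plus-one-equality structure the optimum has an
exact greedy closed form: start every variable at its lower bound and
hand the remaining slack to variables in descending order of the weighted
coefficient alpha*d_i + beta*p_i, each up to its upper bound.  That exact
path is the primary solver; a floating-point simplex
(:func:`solve_lp_simplex`, scipy HiGHS) is kept as a cross-check.

The shipped ``harbin2030`` preset carries the benefit coefficients and
2030 constraint set for Harbin (coefficients in CNY million per km² as
printed in their source; benefits are reported divided by 100, the single
rescaling that matches the published benefit magnitudes — see the methods
note for the unit discussion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BenefitModel",
    "LPProblem",
    "LPSolution",
    "build_lp",
    "solve_lp",
    "solve_lp_simplex",
    "evaluate_benefits",
    "weight_sweep",
    "harbin2030",
    "HARBIN_BENEFITS",
    "HARBIN_BOUNDS",
]


@dataclass
class BenefitModel:
    """Per-class ecological (p) and economic (d) benefit coefficients.

    ``report_divisor`` rescales the raw coefficient-times-area sums when
    reporting benefits in CNY million; the LP argmax is invariant to any
    common rescaling, so the divisor affects reporting only.
    """

    p: np.ndarray
    d: np.ndarray
    report_divisor: float = 100.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.p.shape != self.d.shape:
            raise ValueError("p and d must have equal length")
        if (self.p < 0).any() or (self.d < 0).any():
            raise ValueError("benefit coefficients must be non-negative")
        if self.report_divisor <= 0:
            raise ValueError("report_divisor must be positive")


#: Ecological / economic benefit coefficients for the seven classes
#: (cultivated, forest, grassland, wetland, water, artificial, bare).
HARBIN_BENEFITS = BenefitModel(
    p=np.array([86.78, 432.73, 271.97, 1142.82, 1492.56, 0.0, 4.39]),
    d=np.array([284.18, 17.09, 749.28, 123.90, 125.98, 20261.03, 0.0]),
)

#: 2030 constraint set: per-class lower bounds (food security, ecological
#: floors), upper caps on artificial surface and bare land, and the fixed
#: municipal total.
HARBIN_BOUNDS = {
    "lower": np.array(
        [22299.88, 19379.10, 4271.00, 920.74, 842.63, 2230.62, 17.24]
    ),
    "upper": np.array(
        [np.inf, np.inf, np.inf, np.inf, np.inf, 2453.68, 17.31]
    ),
    "total": 53990.18,
}

#: Observed 2020 class areas (km²), the baseline the optimum is compared to.
HARBIN_2020_AREAS = np.array(
    [26235.15, 19379.10, 4271.00, 920.74, 936.26, 2230.62, 17.31]
)


@dataclass
class LPProblem:
    benefits: BenefitModel
    lower: np.ndarray
    upper: np.ndarray
    total: float
    alpha: float = 0.60
    beta: float = 0.40

    @property
    def weighted_coefficients(self) -> np.ndarray:
        return self.alpha * self.benefits.d + self.beta * self.benefits.p

    @property
    def slack(self) -> float:
        return self.total - float(self.lower.sum())


@dataclass
class LPSolution:
    x: np.ndarray
    objective: float
    Ep: float
    Ed: float
    comprehensive: float
    binding: list[str]


def build_lp(
    benefits: BenefitModel = HARBIN_BENEFITS,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    total: float | None = None,
    alpha: float = 0.60,
    beta: float = 0.40,
) -> LPProblem:
    """Assemble and validate the LP; defaults to the ``harbin2030`` preset.

    Raises when any lower bound exceeds its upper bound, when the lower
    bounds already exceed the total (naming the gap), or when the upper
    bounds cannot absorb the total.
    """
    lower = HARBIN_BOUNDS["lower"].copy() if lower is None else np.asarray(lower, float)
    upper = HARBIN_BOUNDS["upper"].copy() if upper is None else np.asarray(upper, float)
    total = HARBIN_BOUNDS["total"] if total is None else float(total)
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha + beta must equal 1")
    if lower.shape != benefits.p.shape or upper.shape != benefits.p.shape:
        raise ValueError("bounds length disagrees with the benefit model")
    if (lower > upper).any():
        bad = ", ".join(f"x{i + 1}" for i in np.flatnonzero(lower > upper))
        raise ValueError(f"lower bound exceeds upper bound for {bad}")
    if lower.sum() > total + 1e-9:
        raise ValueError(
            f"infeasible: lower bounds total {lower.sum():.2f} km² "
            f"exceeds the area total {total:.2f} km² "
            f"(gap {lower.sum() - total:.2f})"
        )
    if upper.sum() < total - 1e-9:
        raise ValueError("infeasible: upper bounds cannot absorb the total area")
    return LPProblem(
        benefits=benefits, lower=lower, upper=upper, total=total,
        alpha=alpha, beta=beta,
    )


def solve_lp(problem: LPProblem) -> LPSolution:
    """Exact greedy maximizer of the weighted objective.

    Slack above the lower bounds is allocated to variables in descending
    weighted coefficient (ties broken by ascending index), each up to its
    upper bound.  For a box-plus-one-equality LP this is the exact
    optimum; :func:`solve_lp_simplex` must agree to 1e-6 km².
    """
    c = problem.weighted_coefficients
    x = problem.lower.astype(float).copy()
    slack = problem.slack
    if slack < -1e-9:
        raise ValueError("infeasible problem")
    order = sorted(range(len(c)), key=lambda i: (-c[i], i))
    for i in order:
        if slack <= 0:
            break
        headroom = problem.upper[i] - problem.lower[i]
        add = min(slack, headroom)
        x[i] += add
        slack -= add
    binding = []
    for i in range(len(x)):
        if abs(x[i] - problem.lower[i]) <= 1e-9:
            binding.append(f"x{i + 1} >= {problem.lower[i]:.2f}")
        if np.isfinite(problem.upper[i]) and abs(x[i] - problem.upper[i]) <= 1e-9:
            binding.append(f"x{i + 1} <= {problem.upper[i]:.2f}")
    Ep, Ed, comp = evaluate_benefits(x, problem.benefits)
    objective = float(c @ x)
    return LPSolution(
        x=x, objective=objective, Ep=Ep, Ed=Ed, comprehensive=comp, binding=binding
    )


def solve_lp_simplex(problem: LPProblem) -> LPSolution:
    """Cross-check solver: scipy's HiGHS on the same problem."""
    from scipy.optimize import linprog

    c = problem.weighted_coefficients
    n = len(c)
    res = linprog(
        -c,
        A_eq=np.ones((1, n)),
        b_eq=[problem.total],
        bounds=list(zip(problem.lower, problem.upper)),
        method="highs",
    )
    if not res.success:
        raise ValueError(f"LP solve failed: {res.message}")
    x = res.x
    Ep, Ed, comp = evaluate_benefits(x, problem.benefits)
    return LPSolution(
        x=x, objective=float(c @ x), Ep=Ep, Ed=Ed, comprehensive=comp, binding=[]
    )


def evaluate_benefits(
    x: np.ndarray, benefits: BenefitModel = HARBIN_BENEFITS
) -> tuple[float, float, float]:
    """(Ep, Ed, comprehensive) in CNY million for an area vector in km²."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("areas must be non-negative")
    Ep = float(benefits.p @ x) / benefits.report_divisor
    Ed = float(benefits.d @ x) / benefits.report_divisor
    return Ep, Ed, Ep + Ed


def weight_sweep(problem: LPProblem, alphas) -> list[dict]:
    """Exact solve along a list of economic weights (Pareto exploration)."""
    rows = []
    for a in sorted(alphas):
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        sub = LPProblem(
            benefits=problem.benefits, lower=problem.lower,
            upper=problem.upper, total=problem.total, alpha=a, beta=1.0 - a,
        )
        sol = solve_lp(sub)
        rows.append({"alpha": a, "x": sol.x, "Ep": sol.Ep, "Ed": sol.Ed})
    return rows


def harbin2030(alpha: float = 0.60, beta: float = 0.40) -> LPProblem:
    """The shipped preset: Harbin 2030 coefficients, bounds and weights."""
    return build_lp(alpha=alpha, beta=beta)
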