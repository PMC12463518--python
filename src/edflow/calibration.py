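"""Parameter calibration against reference KPIs, and distribution-fit
diagnostics (histogram / P-P / Q-Q data).

Calibration is a budgeted, seeded derivative-free search (Nelder–Mead
with box projection and restarts) over named scenario parameters,
minimizing by default the sum of squared KPI percentage differences.
The simulator is evaluated with a fixed seed throughout, so the
objective is deterministic up to common random numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .kpi import percentage_difference

__all__ = [
    "FreeParameter",
    "CalibrationProblem",
    "CalibrationResult",
    "FitDiagnostics",
    "calibrate",
    "qq_pp",
    "kpi_discrepancy",
]


@dataclass(frozen=True)
class FreeParameter:
    name: str
    low: float
    high: float
    initial: float

    def __post_init__(self):
        if not self.low <= self.initial <= self.high:
            raise ValueError(
                f"initial value of {self.name!r} outside [{self.low}, {self.high}]"
            )


@dataclass
class CalibrationProblem:
    """Free parameters, a reference KPI target and a discrepancy rule."""

    params: List[FreeParameter]
    target: Dict[str, float]
    kpi_labels: Optional[Sequence[str]] = None
    discrepancy: str = "pct_diff_sq"  # or "quantile"

    def labels(self) -> List[str]:
        return list(self.kpi_labels) if self.kpi_labels else list(self.target)


@dataclass
class CalibrationResult:
    values: Dict[str, float]
    discrepancy: float
    initial_discrepancy: float
    trace: List[float]  # best-so-far, non-increasing
    n_evals: int
    converged: bool


def kpi_discrepancy(sim: Dict[str, float], target: Dict[str, float], labels) -> float:
    """Sum of squared signed percentage differences over the KPI labels."""
    return float(
        sum(percentage_difference(sim[lb], target[lb]) ** 2 for lb in labels)
    )


def _quantile_discrepancy(sim_samples, target_samples, probes: int = 50) -> float:
    p = (np.arange(probes) + 0.5) / probes
    qa = np.quantile(np.asarray(sim_samples, dtype=float), p)
    qb = np.quantile(np.asarray(target_samples, dtype=float), p)
    return float(np.max(np.abs(qa - qb)))


def calibrate(
    problem: CalibrationProblem,
    simulate_fn: Callable[[Dict[str, float]], Dict[str, float]],
    budget: int = 200,
    seed: int = 0,
) -> CalibrationResult:
    """Fit the free parameters so the simulator matches the target KPIs.

    Parameters
    ----------
    problem : CalibrationProblem
    simulate_fn : callable
        ``{name: value} -> {kpi_label: minutes}`` (for the default
        discrepancy) or ``-> samples`` (for ``discrepancy="quantile"``).
        Should run the simulator with a fixed internal seed so common
        random numbers make the objective quasi-deterministic.
    budget : int
        Maximum objective evaluations (>= 10 when parameters are free).
    seed : int
        Seeds the restart perturbations; identical seeds reproduce the
        identical search.

    Returns
    -------
    CalibrationResult
        Never raises on a flat search; ``converged`` is False when the
        budget ran out without improving on the initial discrepancy.
    """
    labels = problem.labels()

    def measure(values: Dict[str, float]) -> float:
        out = simulate_fn(values)
        if problem.discrepancy == "pct_diff_sq":
            return kpi_discrepancy(out, problem.target, labels)
        if problem.discrepancy == "quantile":
            return sum(
                _quantile_discrepancy(out[lb], problem.target[lb]) for lb in labels
            )
        raise ValueError(f"unknown discrepancy {problem.discrepancy!r}")

    x0 = np.array([p.initial for p in problem.params], dtype=float)
    initial = measure({p.name: p.initial for p in problem.params})

    if not problem.params:
        return CalibrationResult(
            values={},
            discrepancy=initial,
            initial_discrepancy=initial,
            trace=[initial],
            n_evals=1,
            converged=True,
        )
    if budget < 10:
        raise ValueError("budget must be >= 10")

    lo = np.array([p.low for p in problem.params])
    hi = np.array([p.high for p in problem.params])
    names = [p.name for p in problem.params]

    state = {"evals": 1, "best": initial, "best_x": x0.copy(), "trace": [initial]}

    def objective(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        value = measure(dict(zip(names, xc)))
        # soft penalty steers the simplex back into the box
        value += 1e3 * float(np.sum((x - xc) ** 2))
        state["evals"] += 1
        if value < state["best"]:
            state["best"] = value
            state["best_x"] = xc.copy()
        state["trace"].append(state["best"])
        return value

    rng = np.random.default_rng(seed)
    start = x0
    while state["evals"] < budget:
        remaining = budget - state["evals"]
        if remaining < 2 * len(names) + 2:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            optimize.minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={
                    "maxfev": remaining,
                    "xatol": 1e-4 * float(np.mean(hi - lo)),
                    "fatol": 1e-10,
                },
            )
        # restart near the incumbent
        span = (hi - lo) * 0.1
        start = np.clip(state["best_x"] + rng.normal(0.0, span), lo, hi)

    return CalibrationResult(
        values=dict(zip(names, state["best_x"])),
        discrepancy=state["best"],
        initial_discrepancy=initial,
        trace=state["trace"],
        n_evals=state["evals"],
        converged=state["best"] <= initial,
    )


@dataclass
class FitDiagnostics:
    """Histogram / P-P / Q-Q data for comparing two duration samples."""

    hist_edges: np.ndarray
    hist_a: np.ndarray
    hist_b: np.ndarray
    pp: np.ndarray  # (n, 2): ECDF_a vs ECDF_b on pooled support
    qq: np.ndarray  # (probes, 2): matched quantiles
    max_quantile_gap: float


def qq_pp(sample_a, sample_b, probes: int = 100) -> FitDiagnostics:
    """Quantile-quantile and probability-probability comparison data.

    Q-Q pairs are matched quantiles at equally spaced probe
    probabilities; P-P pairs are the two empirical CDFs evaluated on
    the pooled sorted support.  ``probes`` is reduced (with a warning)
    when either sample is smaller.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_min = min(len(a), len(b))
    if n_min < probes:
        warnings.warn(f"reducing probes from {probes} to {n_min}", UserWarning)
        probes = n_min
    p = (np.arange(probes) + 0.5) / probes
    qa = np.quantile(a, p)
    qb = np.quantile(b, p)
    qq = np.column_stack([qa, qb])

    pooled = np.union1d(a, b)
    ecdf_a = np.searchsorted(a, pooled, side="right") / len(a)
    ecdf_b = np.searchsorted(b, pooled, side="right") / len(b)
    pp = np.column_stack([ecdf_a, ecdf_b])

    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins="auto")
    hist_a, _ = np.histogram(a, bins=edges)
    hist_b, _ = np.histogram(b, bins=edges)

    return FitDiagnostics(
        hist_edges=edges,
        hist_a=hist_a,
        hist_b=hist_b,
        pp=pp,
        qq=qq,
        max_quantile_gap=float(np.max(np.abs(qa - qb))),
    )
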