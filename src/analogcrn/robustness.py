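"""Chernoff-sized Monte-Carlo robustness analysis of closed loops.

Every rate parameter ``p`` in the loop is replaced by ``p (1 + Delta u)``
with ``u ~ Uniform(0, 1)`` drawn independently per parameter (one-sided:
the printed worst-case parameter ranges all sit at or above nominal; a
symmetric option exists behind a flag).  For each sample the step
response is simulated and classified stable/unstable; worst cases are
sample maxima over the stable runs.

The number of samples needed for accuracy ``eps`` with confidence ``c``
follows the Chernoff bound ``N >= ln(2/(1-c)) / (2 eps^2)``; the
published setting (0.05, 99 %) gives N = 1060.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, log

import numpy as np

from .control import (ClosedLoopSystem, simulate_step, step_metrics,
                      StepMetrics, StepTrajectory)

__all__ = [
    "chernoff_sample_size",
    "UncertaintySpec",
    "sample_params",
    "instability_flag",
    "run_monte_carlo",
    "MCResult",
    "critical_delta",
    "MC_HORIZON",
    "BLOWUP_FACTOR",
    "SETTLE_FRACTION",
    "SETTLE_TOL",
]

#: Monte-Carlo observation horizon per process kind (s): roughly twice the
#: worst printed settling time (499 s linear, 49 196 s nonlinear), so that
#: every response the study reports as finite settles comfortably inside.
MC_HORIZON = {"linear": 1000.0, "nonlinear": 1e5}
#: |y| > BLOWUP_FACTOR * r terminates a run as divergent
BLOWUP_FACTOR = 100.0
#: a run counts as settled when the response stays inside the settling band
#: of its own final value from this fraction of the horizon onwards
SETTLE_FRACTION = 0.95
#: settling band for the stability classification (fraction of final value)
SETTLE_TOL = 0.02


def chernoff_sample_size(accuracy: float, confidence: float) -> int:
    """N = ceil( ln(2/(1-confidence)) / (2 accuracy^2) )."""
    if not 0 < accuracy < 1 or not 0 < confidence < 1:
        raise ValueError("accuracy and confidence must lie in (0, 1)")
    return ceil(log(2.0 / (1.0 - confidence)) / (2.0 * accuracy ** 2))


@dataclass
class UncertaintySpec:
    """Perturbation level, parameter list, sample count and seed."""

    delta: float
    n_samples: int = 200
    seed: int = 0
    parameters: tuple[str, ...] = ()  # empty = system's printed p-list
    two_sided: bool = False

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def sample_params(nominal: dict[str, float], delta: float,
                  rng: np.random.Generator,
                  two_sided: bool = False) -> dict[str, float]:
    """One perturbed parameter map: p -> p (1 + delta u)."""
    lo = -1.0 if two_sided else 0.0
    return {name: value * (1.0 + delta * rng.uniform(lo, 1.0))
            for name, value in nominal.items()}


def instability_flag(traj: StepTrajectory, r_final: float | None = None,
                     settle_tol: float = SETTLE_TOL,
                     settle_fraction: float = SETTLE_FRACTION) -> bool:
    """Classify a step response as unstable.

    True when the state diverged (early termination, non-finite values or
    an excursion beyond 100x the reference) or when the response has not
    settled within the observation horizon: unstable unless the output
    stays inside the ``settle_tol`` band of its own final value from
    ``settle_fraction`` of the horizon onwards.  Settling towards a
    biased final value still counts as stable -- under one-sided
    perturbation the loops carry large steady-state errors, and those
    appear in the printed worst cases as finite numbers, not
    instabilities.  The 600 s / 1e5 s horizons are the study's
    step-response windows; every printed finite settling time fits
    inside them.
    """
    r = traj.r_final if r_final is None else r_final
    y = traj.y
    if traj.terminated_early or not np.all(np.isfinite(y)):
        return True
    if np.max(np.abs(y)) > BLOWUP_FACTOR * max(abs(r), 1e-300):
        return True
    y_final = float(y[-1])
    tail = y[traj.t >= traj.t[-1] * settle_fraction]
    band = settle_tol * max(abs(y_final), 1e-300)
    return bool(np.max(np.abs(tail - y_final)) > band)


@dataclass
class MCResult:
    delta: float
    n_samples: int
    seed: int
    n_unstable: int
    samples: list[dict] = field(repr=False)
    worst: dict[str, float] = field(default_factory=dict)
    worst_params: dict[str, dict[str, float]] = field(default_factory=dict)
    worst_param_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    conventions: dict = field(default_factory=dict)

    @property
    def all_unstable(self) -> bool:
        return self.n_unstable == self.n_samples


METRIC_NAMES = ("t_r", "t_s", "M_OV", "e_ss")


def run_monte_carlo(system: ClosedLoopSystem, spec: UncertaintySpec,
                    r1: float = 1.0, t_final: float | None = None) -> MCResult:
    """N perturbed step responses with worst-case extraction.

    Unstable samples are excluded from the worst-case maxima and counted
    separately.  For each metric the parameter draw attaining the maximum
    is recorded; the min-max envelope across those four draws gives the
    reported worst-case parameter ranges.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.parameters) or system.perturbed_parameter_names()
    nominal = {}
    for name in names:
        for obj in (system.subtractor, system.controller_params,
                    system.process_params):
            if hasattr(obj, name):
                nominal[name] = getattr(obj, name)
                break
        else:
            raise KeyError(f"no parameter named {name!r}")
    horizon = t_final if t_final is not None else MC_HORIZON[system.process]

    samples = []
    for i in range(spec.n_samples):
        draw = sample_params(nominal, spec.delta, rng, spec.two_sided)
        perturbed = system.with_parameters(draw)
        traj = simulate_step(perturbed, r1, t_final=horizon, n_points=2001,
                             rtol=1e-8, atol=1e-10,
                             blowup=BLOWUP_FACTOR * max(abs(r1), 1e-300))
        unstable = instability_flag(traj, r1)
        metrics = None if unstable else step_metrics(traj, r1)
        samples.append({"index": i, "params": draw, "unstable": unstable,
                        "metrics": metrics})

    n_unstable = sum(s["unstable"] for s in samples)
    worst, worst_params = {}, {}
    for metric in METRIC_NAMES:
        best_value, best_draw = -np.inf, None
        for s in samples:
            if s["unstable"]:
                continue
            value = getattr(s["metrics"], metric)
            if np.isfinite(value) and value > best_value:
                best_value, best_draw = value, s["params"]
        if best_draw is not None:
            worst[metric] = best_value
            worst_params[metric] = best_draw
    ranges = {}
    for name in names:
        values = [wp[name] for wp in worst_params.values()]
        if values:
            ranges[name] = (min(values), max(values))
    return MCResult(
        delta=spec.delta, n_samples=spec.n_samples, seed=spec.seed,
        n_unstable=n_unstable, samples=samples, worst=worst,
        worst_params=worst_params, worst_param_ranges=ranges,
        conventions={
            "perturbation": "one-sided p(1+delta*U(0,1))" if not spec.two_sided
                            else "two-sided p(1+delta*U(-1,1))",
            "horizon_s": horizon,
            "instability": f"divergence beyond {BLOWUP_FACTOR}*r, non-finite "
                           f"state, or failure to stay within {SETTLE_TOL} "
                           f"of the final value from {SETTLE_FRACTION} of "
                           "the horizon onwards",
        })


def critical_delta(system: ClosedLoopSystem, deltas, n_per_point: int = 500,
                   seed: int = 0, r1: float = 1.0,
                   t_final: float | None = None):
    """Smallest perturbation level on a grid showing any unstable sample.

    Scans ``deltas`` in increasing order with ``n_per_point`` Monte-Carlo
    samples each; returns ``(delta or None, per-level results)``.  A
    stochastic estimate: report it together with N and the seed.
    """
    results = {}
    for delta in sorted(deltas):
        spec = UncertaintySpec(delta=delta, n_samples=n_per_point, seed=seed)
        res = run_monte_carlo(system, spec, r1=r1, t_final=t_final)
        res.samples = []  # keep the scan light
        results[delta] = res
        if res.n_unstable > 0:
            return delta, results
    return None, results
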