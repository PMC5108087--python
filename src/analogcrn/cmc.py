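"""The covalent modification cycle (CMC): reaction motif, reduced ODEs,
steady-state input-output map, regime presets and regime fitting.

A substrate shuttles between an inactive form ``x_p`` and an active form
``x_out`` under two opposing enzymatic legs (kinase-like input ``x_in``,
phosphatase-like ``x_e``), through intermediate complexes ``x_C1`` and
``x_C2``.  Two totals are conserved: the phosphatase ``x_e + x_C2`` and
the substrate ``x_p + x_out + x_C1 + x_C2``.  Depending on the four rate
constants the steady-state map from input to active output takes one of
four characteristic shapes: hyperbolic (log-like saturation),
ultrasensitive (switch), signal-transducing (linear then plateau) and
threshold-hyperbolic (dead zone then near-linear rise).

The input convention throughout is the *total* amount of input species
introduced (free plus complexed in ``x_C1``); the cycle conserves it.
The printed rate constants for each regime are kept verbatim in
:data:`REGIME_PRESETS`; the substrate totals are not printed anywhere and
are calibrated here against each regime's design target (see the methods
note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize

from .crn import CRN, DEFAULT_ETA

__all__ = [
    "CMCParams",
    "RegimePreset",
    "REGIME_PRESETS",
    "build_cmc_crn",
    "cmc_rhs",
    "steady_state_output",
    "regime_curve",
    "fit_regime",
    "FitResult",
    "preset",
]


@dataclass(frozen=True)
class CMCParams:
    """Rates and conservation totals of one covalent modification cycle."""

    k1: float  # binding, /M/s
    k2: float  # catalytic release, /s
    k3: float  # back-binding, /M/s
    k4: float  # back release, /s
    xe_total: float  # x_e + x_C2, molar
    substrate_total: float | None = None  # x_p + x_out + x_C1 + x_C2, molar
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "xe_total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.substrate_total is not None and not self.substrate_total > 0:
            raise ValueError("substrate_total must be positive")

    def rates(self) -> tuple[float, float, float, float]:
        return self.k1, self.k2, self.k3, self.k4


@dataclass(frozen=True)
class RegimePreset:
    label: str
    params: CMCParams
    description: str = ""


# Printed regime rate constants, verbatim.  Substrate totals are calibrated:
# hyperbolic against the natural-log target on [2, 10]; ultrasensitive
# against the +/-1e-3 switch range; threshold-hyperbolic against the
# unity-gradient rise; signal-transducing preserving the linear-then-plateau
# shape over the abs-circuit working range.
REGIME_PRESETS: dict[str, RegimePreset] = {
    "hyperbolic": RegimePreset(
        "hyperbolic",
        CMCParams(0.22, 0.43, 1.03, 35.10, xe_total=1.0, substrate_total=10.53),
        "saturating, log-like map"),
    "ultrasensitive": RegimePreset(
        "ultrasensitive",
        CMCParams(5000.0, 5.0, 50.0, 0.05, xe_total=1e-7, substrate_total=1e-3),
        "switch-like map, output range ~1e-3"),
    "threshold_hyperbolic": RegimePreset(
        "threshold_hyperbolic",
        CMCParams(0.0027, 16640.0, 0.043, 0.008, xe_total=3.5,
                  substrate_total=10.0),
        "dead zone followed by near-linear rise"),
    "signal_transducing": RegimePreset(
        "signal_transducing",
        CMCParams(5.0, 100.0, 5.0, 630.0, xe_total=1.8, substrate_total=150.0),
        "linear response followed by a plateau"),
}


def build_cmc_crn(params: CMCParams, dual_rail: bool = True,
                  input_name: str = "x_in", output_name: str = "x_out",
                  prefix: str = "", input_value: float = 0.0) -> CRN:
    """The CMC reaction set: 14 reactions dual-rail, 4 single-rail.

    ``input_value`` is the initially introduced amount of the input species
    (signed in the dual-rail variant).  The phosphatase ``x_e`` is never
    railed -- it is externally introduced.
    """
    k1, k2, k3, k4 = params.rates()
    S = params.substrate_total
    E = params.xe_total
    pr = prefix
    xp, c1, c2, xe = f"{pr}x_p", f"{pr}x_C1", f"{pr}x_C2", f"{pr}x_e"
    xin, xout = input_name, output_name
    crn = CRN(eta=params.eta)
    if not dual_rail:
        for name, init in ((xp, S if S is not None else 1.0), (xin, input_value),
                           (xout, 0.0), (c1, 0.0), (c2, 0.0), (xe, E)):
            crn.add_species(name, init)
        crn.add_reaction((xp, xin), (c1,), k1, "cmc:bind")
        crn.add_reaction((c1,), (xout, xin), k2, "cmc:release")
        crn.add_reaction((xout, xe), (c2,), k3, "cmc:backbind")
        crn.add_reaction((c2,), (xp, xe), k4, "cmc:backrelease")
        crn.add_conservation({xe: 1.0, c2: 1.0}, E)
        if S is not None:
            crn.add_conservation({xp: 1, xout: 1, c1: 1, c2: 1}, S)
        return crn

    crn.add_dual_pair(xp, S if S is not None else 1.0)
    crn.add_dual_pair(xin, input_value)
    for base in (c1, xout, c2):
        crn.add_dual_pair(base)
    crn.add_species(xe, E)
    # binding: like rails -> C1 plus, unlike rails -> C1 minus
    for a, b, out in ((f"{xp}_p", f"{xin}_p", f"{c1}_p"),
                      (f"{xp}_m", f"{xin}_m", f"{c1}_p"),
                      (f"{xp}_p", f"{xin}_m", f"{c1}_m"),
                      (f"{xp}_m", f"{xin}_p", f"{c1}_m")):
        crn.add_reaction((a, b), (out,), k1, "cmc:bind")
    for s in ("p", "m"):
        crn.add_reaction((f"{c1}_{s}",), (f"{xout}_{s}", f"{xin}_{s}"), k2,
                         "cmc:release")
        crn.add_reaction((f"{xout}_{s}", xe), (f"{c2}_{s}",), k3, "cmc:backbind")
        crn.add_reaction((f"{c2}_{s}",), (f"{xp}_{s}", xe), k4, "cmc:backrelease")
    for base in (xp, c1, xout, c2):
        crn.add_annihilation(base)
    crn.add_conservation({xe: 1.0, f"{c2}_p": 1.0, f"{c2}_m": 1.0}, E)
    return crn


def cmc_rhs(params: CMCParams, state, x_in: float):
    """Reduced ODE right-hand side for (x_out, x_C1, x_C2).

    ``x_e`` is recovered from the phosphatase conservation and ``x_p`` from
    the substrate conservation (buffered at 1 M when no substrate total is
    given, the buffer level being absorbed into k1).  ``x_in`` here is the
    free input concentration.
    """
    x_out, x_c1, x_c2 = state
    k1, k2, k3, k4 = params.rates()
    x_e = params.xe_total - x_c2
    if params.substrate_total is None:
        x_p = 1.0
    else:
        x_p = params.substrate_total - x_out - x_c1 - x_c2
    d_out = k2 * x_c1 - k3 * x_out * x_e
    d_c1 = k1 * x_p * x_in - k2 * x_c1
    d_c2 = k3 * x_out * x_e - k4 * x_c2
    return np.array([d_out, d_c1, d_c2])


def steady_state_output(params: CMCParams, x_in: float,
                        input_mode: str = "total") -> float:
    """Unique non-negative steady-state ``x_out`` for input ``x_in >= 0``.

    Solved from the cyclic flux balance ``v = k1 x_p x_in_free = k2 x_C1 =
    k3 x_out x_e = k4 x_C2`` under both conservation laws; the defining
    equation is strictly monotone in the flux, so a bracketed scalar root
    suffices.  ``input_mode="total"`` (default) interprets ``x_in`` as the
    total amount introduced (free + bound in ``x_C1``); ``"clamped"`` holds
    the free concentration fixed.
    """
    if x_in < 0:
        raise ValueError("steady_state_output is defined for x_in >= 0; "
                         "signed responses come from dual-rail simulation")
    if x_in == 0:
        return 0.0
    k1, k2, k3, k4 = params.rates()
    E = params.xe_total
    S = params.substrate_total
    if input_mode not in ("total", "clamped"):
        raise ValueError(f"unknown input_mode {input_mode!r}")
    if S is None:
        # buffered substrate x_p = 1: v = k1 * x_in directly
        v = k1 * x_in
        if v >= k4 * E:
            raise ValueError("input exceeds the cycle's backward capacity "
                             "for a buffered substrate")
        return v / (k3 * (E - v / k4))

    # Root in the output itself: the flux through the cycle is
    # v(out) = k3 out E / (1 + k3 out / k4) < k4 E, and the substrate
    # balance residual is strictly increasing in out, so a bracketed
    # scalar root on [0, S] is exact and free of cancellation.
    def residual(out):
        v = k3 * out * E / (1.0 + k3 * out / k4)
        free = x_in - v / k2 if input_mode == "total" else x_in
        if free <= 0.0:
            return 1e300
        x_p = v / (k1 * free)
        return x_p + v / k2 + out + v / k4 - S

    hi = S
    if residual(hi) <= 0:  # cannot happen: residual(S) >= out - S = 0
        raise RuntimeError("no substrate balance found")
    return brentq(residual, 0.0, hi, xtol=S * 1e-16, rtol=8.9e-16,
                  maxiter=200)


def regime_curve(params: CMCParams, x_in_grid,
                 input_mode: str = "total") -> np.ndarray:
    """Vectorised steady-state map over a non-negative input grid."""
    return np.array([steady_state_output(params, float(x), input_mode)
                     for x in np.asarray(x_in_grid, dtype=float)])


@dataclass
class FitResult:
    params: CMCParams
    sse: float
    sse_initial: float
    improved: bool
    degenerate: bool = False
    message: str = ""
    n_iterations: int = 0


def fit_regime(target, initial: CMCParams,
               bounds: tuple[float, float] = (1e-6, 1e6),
               seed: int | None = 0,
               fit_substrate: bool = False,
               objective: str = "sse",
               max_iter: int = 2000) -> FitResult:
    """Fit the four rate constants to a target input-output curve.

    Derivative-free Nelder-Mead simplex search on log10-transformed rates
    (optionally also the substrate total), restarted once from the best
    point; rates are kept inside the biologically-plausible ``bounds``.
    ``target`` is a sequence of ``(x_in, desired x_out)`` pairs.
    ``objective="sse"`` minimises the summed squared error,
    ``"minimax"`` the worst relative error.  Deterministic for a given
    seed and initial point.
    """
    target = np.asarray(target, dtype=float)
    xs, ys = target[:, 0], target[:, 1]
    norm = float(np.sum(ys ** 2))
    if norm == 0.0:
        return FitResult(initial, 0.0, 0.0, False, degenerate=True,
                         message="degenerate constant-zero target")
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])

    def unpack(p) -> CMCParams:
        k = 10.0 ** np.clip(p[:4], lo, hi)
        kwargs = dict(k1=k[0], k2=k[1], k3=k[2], k4=k[3])
        if fit_substrate:
            kwargs["substrate_total"] = 10.0 ** p[4]
        return replace(initial, **kwargs)

    def cost(p):
        if np.any(p[:4] < lo) or np.any(p[:4] > hi):
            return 1e9 + float(np.sum(np.square(p)))
        try:
            f = regime_curve(unpack(p), xs)
        except (ValueError, RuntimeError):
            return 1e9
        if not np.all(np.isfinite(f)):
            return 1e9
        if objective == "minimax":
            scale = np.where(np.abs(ys) > 0, np.abs(ys), 1.0)
            return float(np.max(np.abs(f - ys) / scale))
        return float(np.sum((f - ys) ** 2))

    p0 = list(np.log10(initial.rates()))
    if fit_substrate:
        if initial.substrate_total is None:
            raise ValueError("fit_substrate requires an initial substrate_total")
        p0.append(np.log10(initial.substrate_total))
    p0 = np.asarray(p0)
    c0 = cost(p0)

    opts = dict(maxiter=max_iter, xatol=1e-10, fatol=1e-14)
    res = minimize(cost, p0, method="Nelder-Mead", options=opts)
    res2 = minimize(cost, res.x, method="Nelder-Mead", options=opts)
    best = res2 if res2.fun <= res.fun else res
    params = unpack(best.x)
    sse = float(np.sum((regime_curve(params, xs) - ys) ** 2))
    sse0 = float(np.sum((regime_curve(initial, xs) - ys) ** 2)) if c0 < 1e9 else np.inf
    # absolute slack absorbs the log10 round-trip when the start is
    # already on target
    improved = sse <= sse0 + 1e-12 * norm
    msg = "ok"
    if not improved:
        msg = "objective not reduced from the initial point"
        warnings.warn(msg)
        params, sse = initial, sse0
    return FitResult(params, sse, sse0, improved, message=msg,
                     n_iterations=int(res.nit + res2.nit))


def preset(label: str) -> CMCParams:
    """Look up a regime preset's parameters by label."""
    try:
        return REGIME_PRESETS[label].params
    except KeyError:
        raise KeyError(
            f"unknown regime {label!r}; one of {sorted(REGIME_PRESETS)}") from None
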