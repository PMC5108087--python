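"""Elementary analog operators compiled to dual-rail reaction sets.

Each operator is a small CRN fragment acting on dual-rail signals.  The
catalytic production / degradation structure gives every operator a
reduced ("effective") ODE for its output signal:

==============  =========================================  =========
operator        effective ODE                              reactions
==============  =========================================  =========
gain            dy/dt = gamma_K (K x - y)                  5
summation       dy/dt = gamma_Sm (x1 + x2 - y)             7
subtraction     dy/dt = gamma_Sb (x1 - x2 - y)             7
integration     dy/dt = K_I x                              3
multiplication  dy/dt = gamma_M (x1 x2 - y)                7
power (order n) cascade of n-1 multiplications, 7(n-1)     7(n-1)
==============  =========================================  =========

The subtrahend of a subtraction feeds the *opposite* rail of the output
(``x2^± -> x2^± + y^∓``) so that the signed fixed point is ``x1 - x2``.
The reaction listing in the source text shows uncrossed rails, but its own
ODE requires the crossed form; the ODE wins.  Signs multiply through the
rails in products and powers: like rails produce the plus rail, unlike
rails the minus rail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .crn import CRN, DEFAULT_ETA

__all__ = [
    "OperatorSpec",
    "operator_reaction_count",
    "compile_gain",
    "compile_summation",
    "compile_subtraction",
    "compile_integrator",
    "compile_multiplication",
    "compile_power",
    "compile_operator",
]

#: default operator rate when a circuit does not specify one (/s or /M/s)
DEFAULT_RATE = 1.0


@dataclass
class OperatorSpec:
    """Declarative description of one operator block."""

    kind: str  # gain | summation | subtraction | integration | multiplication | power
    output: str
    inputs: tuple[str, ...]
    params: dict = field(default_factory=dict)
    order: int = 2  # power only

    def __post_init__(self) -> None:
        kinds = ("gain", "summation", "subtraction", "integration",
                 "multiplication", "power")
        if self.kind not in kinds:
            raise ValueError(f"unknown operator kind {self.kind!r}")
        if self.kind == "power" and self.order < 2:
            raise ValueError("power operator needs order n >= 2")
        for v in self.params.values():
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"operator parameters must be positive: {self.params}")


def operator_reaction_count(kind: str, order: int = 2) -> int:
    """Abstract-reaction cost of one operator (pure arithmetic)."""
    counts = {"gain": 5, "summation": 7, "subtraction": 7, "integration": 3,
              "multiplication": 7, "cmc": 14}
    if kind == "power":
        if order < 2:
            raise ValueError("power operator needs order n >= 2")
        return 7 * (order - 1)
    try:
        return counts[kind]
    except KeyError:
        raise ValueError(f"unknown operator kind {kind!r}") from None


def _rails(crn: CRN, *bases: str) -> None:
    for base in bases:
        crn.add_dual_pair(base)


def compile_gain(output: str, inp: str, K: float = 1.0,
                 gamma: float = DEFAULT_RATE, eta: float = DEFAULT_ETA) -> CRN:
    """``y = K x``: catalytic production at gamma*K, degradation at gamma."""
    if not (K > 0 and gamma > 0):
        raise ValueError("gain parameters must be positive")
    crn = CRN(eta=eta)
    _rails(crn, inp, output)
    for s in ("p", "m"):
        crn.add_reaction((f"{inp}_{s}",), (f"{inp}_{s}", f"{output}_{s}"),
                         gamma * K, f"gain:{output}:prod_{s}")
        crn.add_reaction((f"{output}_{s}",), (), gamma, f"gain:{output}:deg_{s}")
    crn.add_annihilation(output)
    return crn


def compile_summation(output: str, in1: str, in2: str,
                      gamma: float = DEFAULT_RATE, eta: float = DEFAULT_ETA) -> CRN:
    """``y = x1 + x2``."""
    crn = CRN(eta=eta)
    _rails(crn, in1, in2, output)
    for inp in (in1, in2):
        for s in ("p", "m"):
            crn.add_reaction((f"{inp}_{s}",), (f"{inp}_{s}", f"{output}_{s}"),
                             gamma, f"sum:{output}:prod_{s}")
    for s in ("p", "m"):
        crn.add_reaction((f"{output}_{s}",), (), gamma, f"sum:{output}:deg_{s}")
    crn.add_annihilation(output)
    return crn


def compile_subtraction(output: str, minuend: str, subtrahend: str,
                        gamma: float = DEFAULT_RATE,
                        gamma_minuend: float | None = None,
                        gamma_subtrahend: float | None = None,
                        gamma_deg: float | None = None,
                        eta: float = DEFAULT_ETA) -> CRN:
    """``y = x1 - x2``; the subtrahend feeds the opposite output rail.

    The three reaction templates may carry split rates (``gamma_minuend``,
    ``gamma_subtrahend``, ``gamma_deg``), defaulting to the shared ``gamma``.
    """
    g1 = gamma if gamma_minuend is None else gamma_minuend
    g2 = gamma if gamma_subtrahend is None else gamma_subtrahend
    g3 = gamma if gamma_deg is None else gamma_deg
    crn = CRN(eta=eta)
    _rails(crn, minuend, subtrahend, output)
    other = {"p": "m", "m": "p"}
    for s in ("p", "m"):
        crn.add_reaction((f"{minuend}_{s}",), (f"{minuend}_{s}", f"{output}_{s}"),
                         g1, f"sub:{output}:minuend_{s}")
        crn.add_reaction((f"{subtrahend}_{s}",),
                         (f"{subtrahend}_{s}", f"{output}_{other[s]}"),
                         g2, f"sub:{output}:subtrahend_{s}")
        crn.add_reaction((f"{output}_{s}",), (), g3, f"sub:{output}:deg_{s}")
    crn.add_annihilation(output)
    return crn


def compile_integrator(output: str, inp: str, K_I: float = DEFAULT_RATE,
                       eta: float = DEFAULT_ETA) -> CRN:
    """``dy/dt = K_I x``: two catalytic reactions plus the annihilation."""
    crn = CRN(eta=eta)
    _rails(crn, inp, output)
    for s in ("p", "m"):
        crn.add_reaction((f"{inp}_{s}",), (f"{inp}_{s}", f"{output}_{s}"),
                         K_I, f"int:{output}:prod_{s}")
    crn.add_annihilation(output)
    return crn


def _product_stage(crn: CRN, output: str, in1: str, in2: str, gamma: float,
                   label: str) -> None:
    """Seven-reaction multiplication template with rail sign rules."""
    pairs_plus = ((f"{in1}_p", f"{in2}_p"), (f"{in1}_m", f"{in2}_m"))
    pairs_minus = ((f"{in1}_p", f"{in2}_m"), (f"{in1}_m", f"{in2}_p"))
    for a, b in pairs_plus:
        crn.add_reaction((a, b), (a, b, f"{output}_p"), gamma, f"{label}:prod_p")
    for a, b in pairs_minus:
        crn.add_reaction((a, b), (a, b, f"{output}_m"), gamma, f"{label}:prod_m")
    for s in ("p", "m"):
        crn.add_reaction((f"{output}_{s}",), (), gamma, f"{label}:deg_{s}")
    crn.add_annihilation(output)


def compile_multiplication(output: str, in1: str, in2: str,
                           gamma: float = DEFAULT_RATE,
                           eta: float = DEFAULT_ETA) -> CRN:
    """``y = x1 * x2`` with sign rules carried by the rails."""
    crn = CRN(eta=eta)
    _rails(crn, in1, in2, output)
    _product_stage(crn, output, in1, in2, gamma, f"mult:{output}")
    return crn


def compile_power(output: str, inp: str, order: int,
                  gamma: float = DEFAULT_RATE, eta: float = DEFAULT_ETA) -> CRN:
    """``y = x^n`` as a cascade ``x*x -> x^2``, ``x*x^2 -> x^3``, ...

    Each of the n-1 stages is a seven-reaction multiplication by the input,
    re-using the previous intermediate, for 7(n-1) reactions in total.
    """
    if order < 2:
        raise ValueError("power operator needs order n >= 2")
    crn = CRN(eta=eta)
    _rails(crn, inp, output)
    prev = inp
    for k in range(2, order + 1):
        stage = output if k == order else f"{output}_pow{k}"
        _rails(crn, stage)
        _product_stage(crn, stage, inp, prev, gamma, f"pow{k}:{output}")
        prev = stage
    return crn


def compile_operator(spec: OperatorSpec, eta: float = DEFAULT_ETA) -> CRN:
    """Dispatch an :class:`OperatorSpec` to its compiler."""
    p = spec.params
    if spec.kind == "gain":
        return compile_gain(spec.output, spec.inputs[0],
                            K=p.get("K", 1.0), gamma=p.get("gamma", DEFAULT_RATE),
                            eta=eta)
    if spec.kind == "summation":
        return compile_summation(spec.output, *spec.inputs[:2],
                                 gamma=p.get("gamma", DEFAULT_RATE), eta=eta)
    if spec.kind == "subtraction":
        return compile_subtraction(
            spec.output, *spec.inputs[:2], gamma=p.get("gamma", DEFAULT_RATE),
            gamma_minuend=p.get("gamma_minuend"),
            gamma_subtrahend=p.get("gamma_subtrahend"),
            gamma_deg=p.get("gamma_deg"), eta=eta)
    if spec.kind == "integration":
        return compile_integrator(spec.output, spec.inputs[0],
                                  K_I=p.get("K_I", DEFAULT_RATE), eta=eta)
    if spec.kind == "multiplication":
        return compile_multiplication(spec.output, *spec.inputs[:2],
                                      gamma=p.get("gamma", DEFAULT_RATE), eta=eta)
    if spec.kind == "power":
        return compile_power(spec.output, spec.inputs[0], spec.order,
                             gamma=p.get("gamma", DEFAULT_RATE), eta=eta)
    raise ValueError(f"unknown operator kind {spec.kind!r}")
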