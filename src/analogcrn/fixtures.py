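"""Synthetic target curves for regime fitting and testing.

Each fixture emulates one of the four characteristic CMC input-output
shapes: a natural-log curve (hyperbolic regime target), a sharp sigmoid
step (ultrasensitive), a dead zone followed by a linear rise
(threshold-hyperbolic) and a saturating linear ramp (signal-transducing).
Optional additive Gaussian noise with a stated sigma; deterministic for
a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FixtureCurve", "generate_fixture", "FIXTURE_LABELS"]

FIXTURE_LABELS = ("log_curve", "sigmoid_step", "deadzone_linear",
                  "saturating_linear")


@dataclass
class FixtureCurve:
    label: str
    x: np.ndarray
    y: np.ndarray
    params: dict
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("fixture curves must be finite")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("fixture x grid must be strictly increasing")

    def pairs(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def generate_fixture(label: str, grid, params: dict | None = None,
                     seed: int = 0, sigma: float = 0.0) -> FixtureCurve:
    """Deterministic synthetic target curve.

    Parameters per label (with defaults):

    * ``log_curve``: ``scale * ln(x)``; grid must be positive.
    * ``sigmoid_step``: ``amplitude * x^h / (x^h + threshold^h)`` with a
      large Hill exponent ``h`` (switch at ``threshold``).
    * ``deadzone_linear``: ``slope * max(0, x - threshold)``.
    * ``saturating_linear``: ``min(slope * x, plateau)``.
    """
    x = np.asarray(grid, dtype=float)
    p = dict(params or {})
    if label == "log_curve":
        if np.any(x <= 0):
            raise ValueError("log_curve needs a positive grid")
        y = p.get("scale", 1.0) * np.log(x)
    elif label == "sigmoid_step":
        amp = p.setdefault("amplitude", 1e-3)
        thr = p.setdefault("threshold", 1e-9)
        h = p.setdefault("hill", 8.0)
        with np.errstate(over="ignore"):
            y = amp * x ** h / (x ** h + thr ** h)
    elif label == "deadzone_linear":
        thr = p.setdefault("threshold", 0.0)
        y = p.setdefault("slope", 1.0) * np.clip(x - thr, 0.0, None)
    elif label == "saturating_linear":
        slope = p.setdefault("slope", 20.0)
        y = np.minimum(slope * x, p.setdefault("plateau", 120.0))
    else:
        raise ValueError(f"unknown fixture label {label!r}; "
                         f"one of {FIXTURE_LABELS}")
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=y.shape)
    return FixtureCurve(label, x, y, p, sigma, seed)
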