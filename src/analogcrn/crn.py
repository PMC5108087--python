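"""Chemical reaction network (CRN) data model, dual-rail encoding and
mass-action simulation.

A signed signal ``x`` is carried by a pair of non-negative species
``x_p``/``x_m`` with value ``x = x_p - x_m``; a fast bimolecular
annihilation ``x_p + x_m -> 0`` (rate ``eta``) keeps one rail near zero
so that the difference is well defined.  Externally buffered species
(such as the phosphatase of a covalent modification cycle) stay
un-railed ("plain").

Only unimolecular and bimolecular reactions are allowed: this is the
compilability condition for DNA strand displacement chemistry, for which
:func:`expand_bimolecular_dsd` provides the two-step template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "Trajectory",
    "CRNError",
    "SimulationError",
    "mass_action_rhs",
    "simulate",
    "dual_value",
    "count_reactions",
    "expand_bimolecular_dsd",
    "DEFAULT_ETA",
]

#: Default annihilation rate (/M/s).  The source designs only require it to
#: be "fast"; results must be insensitive to any value above ~1e4.
DEFAULT_ETA = 1e6


class CRNError(ValueError):
    """Raised for malformed networks or states."""


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the solver message."""

    def __init__(self, message: str, status: int | None = None):
        super().__init__(message)
        self.status = status


@dataclass
class Species:
    """A declared species with its initial concentration (molar)."""

    name: str
    initial: float = 0.0
    rail: str = "plain"  # "plain" | "plus" | "minus"
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise CRNError(f"negative initial concentration for {self.name}")
        if self.rail not in ("plain", "plus", "minus"):
            raise CRNError(f"bad rail {self.rail!r} for {self.name}")
        if self.rail == "plain" and self.partner is not None:
            raise CRNError(f"plain species {self.name} cannot have a partner")


@dataclass
class Reaction:
    """``reactants -> products`` with a mass-action rate constant.

    Rate units are /s for unimolecular and /M/s for bimolecular reactions.
    At most two reactant molecules (uni/bimolecular only).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.reactants = tuple(self.reactants)
        self.products = tuple(self.products)
        if len(self.reactants) > 2:
            raise CRNError(
                f"reaction {self.label or self.reactants}: more than two "
                "reactants (only uni/bimolecular reactions are DSD-compilable)"
            )
        if not self.rate > 0:
            raise CRNError(f"reaction {self.label or self.reactants}: rate must be > 0")


class CRN:
    """A chemical reaction network: species, reactions, conservation laws."""

    def __init__(self, eta: float = DEFAULT_ETA):
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []
        #: list of (coefficient map, total) pairs checked along trajectories
        self.conservation_laws: list[tuple[dict[str, float], float]] = []
        self.eta = eta

    # -- construction -----------------------------------------------------
    def add_species(self, name: str, initial: float = 0.0, rail: str = "plain",
                    partner: str | None = None) -> Species:
        if name in self.species:
            sp = self.species[name]
            if initial:
                sp.initial += initial
            return sp
        sp = Species(name, initial, rail, partner)
        self.species[name] = sp
        return sp

    def add_dual_pair(self, base: str, value: float = 0.0) -> tuple[str, str]:
        """Declare the rail pair for signal ``base`` (value may be signed)."""
        p, m = f"{base}_p", f"{base}_m"
        self.add_species(p, max(value, 0.0), "plus", m)
        self.add_species(m, max(-value, 0.0), "minus", p)
        return p, m

    def add_reaction(self, reactants: Iterable[str], products: Iterable[str],
                     rate: float, label: str = "") -> Reaction:
        rxn = Reaction(tuple(reactants), tuple(products), rate, label)
        self.reactions.append(rxn)
        return rxn

    def add_annihilation(self, base: str, eta: float | None = None) -> Reaction:
        """The dual-rail annihilation ``base_p + base_m -> 0``."""
        return self.add_reaction(
            (f"{base}_p", f"{base}_m"), (), self.eta if eta is None else eta,
            label=f"annihilation:{base}")

    def add_conservation(self, coeffs: Mapping[str, float], total: float) -> None:
        self.conservation_laws.append((dict(coeffs), float(total)))

    def merge(self, other: "CRN") -> "CRN":
        """Union of species and reactions (shared species keep the larger
        declared initial of the two)."""
        for sp in other.species.values():
            if sp.name in self.species:
                mine = self.species[sp.name]
                mine.initial = max(mine.initial, sp.initial)
            else:
                self.species[sp.name] = Species(sp.name, sp.initial, sp.rail, sp.partner)
        self.reactions.extend(other.reactions)
        self.conservation_laws.extend(other.conservation_laws)
        return self

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for rxn in self.reactions:
            for name in rxn.reactants + rxn.products:
                if name not in self.species:
                    raise CRNError(f"reaction {rxn.label or rxn.reactants}: "
                                   f"undeclared species {name!r}")
        for coeffs, total in self.conservation_laws:
            value = sum(c * self.species[n].initial for n, c in coeffs.items())
            if total and abs(value - total) > 1e-9 * max(abs(total), 1e-300):
                raise CRNError(
                    f"conservation law {coeffs} evaluates to {value}, "
                    f"declared total {total}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "species": [asdict(s) for s in self.species.values()],
            "reactions": [
                {"reactants": list(r.reactants), "products": list(r.products),
                 "rate": r.rate, "label": r.label}
                for r in self.reactions],
            "conservation": [
                {"coefficients": c, "total": t} for c, t in self.conservation_laws],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CRN":
        crn = cls(eta=data.get("eta", DEFAULT_ETA))
        for s in data["species"]:
            crn.species[s["name"]] = Species(**s)
        for r in data["reactions"]:
            crn.add_reaction(r["reactants"], r["products"], r["rate"],
                             r.get("label", ""))
        for law in data.get("conservation", []):
            crn.add_conservation(law["coefficients"], law["total"])
        return crn

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "CRN":
        try:
            with open(source) as fh:
                data = json.load(fh)
        except (OSError, ValueError):
            data = json.loads(source)
        return cls.from_dict(data)


@dataclass
class Trajectory:
    """Time grid, state matrix (species x time) and solver diagnostics."""

    t: np.ndarray
    y: np.ndarray
    species: list[str]
    status: int
    message: str
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.species)}

    def value(self, name: str) -> np.ndarray:
        return self.y[self.index[name]]

    def final(self, name: str) -> float:
        return float(self.y[self.index[name], -1])

    def dual(self, base: str) -> np.ndarray:
        return dual_value(self, base)


def _compiled(crn: CRN):
    names = list(crn.species)
    index = {n: i for i, n in enumerate(names)}
    n_sp, n_rx = len(names), len(crn.reactions)
    i1 = np.full(n_rx, -1, dtype=np.intp)
    i2 = np.full(n_rx, -1, dtype=np.intp)
    rates = np.empty(n_rx)
    stoich = np.zeros((n_sp, n_rx))
    for j, rxn in enumerate(crn.reactions):
        rates[j] = rxn.rate
        if len(rxn.reactants) >= 1:
            i1[j] = index[rxn.reactants[0]]
        if len(rxn.reactants) == 2:
            i2[j] = index[rxn.reactants[1]]
        for name in rxn.reactants:
            stoich[index[name], j] -= 1
        for name in rxn.products:
            stoich[index[name], j] += 1
    return names, index, i1, i2, rates, stoich


def mass_action_rhs(crn: CRN, state: Mapping[str, float]) -> dict[str, float]:
    """Mass-action time derivative of every species at ``state``.

    Each reaction contributes ``rate * prod(reactant concentrations)`` to its
    products (+) and reactants (-), with stoichiometric multiplicity.
    """
    crn.validate()
    for name in crn.species:
        if name not in state:
            raise CRNError(f"state missing declared species {name!r}")
    names, index, i1, i2, rates, stoich = _compiled(crn)
    y = np.array([state[n] for n in names])
    v = rates.copy()
    mask1 = i1 >= 0
    v[mask1] *= y[i1[mask1]]
    mask2 = i2 >= 0
    v[mask2] *= y[i2[mask2]]
    v[~mask1] = rates[~mask1]  # zeroth order (none in practice)
    dy = stoich @ v
    return {n: float(dy[index[n]]) for n in names}


def simulate(crn: CRN, t_final: float, t_eval: Sequence[float] | None = None,
             method: str = "LSODA", rtol: float = 1e-8, atol: float = 1e-12,
             state0: Mapping[str, float] | None = None,
             check: bool = True, **solver_opts) -> Trajectory:
    """Integrate the network from its declared initial state.

    A stiff-capable method is required: rate constants in the designs span
    roughly 5e-6 to 1.6e4 /s plus the fast annihilation.  LSODA switches
    automatically; "BDF" is also supported.  Post hoc the trajectory is
    checked for non-negativity and conservation (to 1e-6 relative).
    """
    if not t_final > 0:
        raise ValueError("t_final must be positive")
    crn.validate()
    names, index, i1, i2, rates, stoich = _compiled(crn)
    y0 = np.array([crn.species[n].initial for n in names])
    if state0 is not None:
        for n, v in state0.items():
            y0[index[n]] = v
    mask1, mask2 = i1 >= 0, i2 >= 0
    j1, j2 = i1[mask1], i2[mask2]

    def rhs(t, y):
        v = rates.copy()
        v[mask1] *= y[j1]
        v[mask2] *= y[j2]
        return stoich @ v

    n_sp = len(names)

    def jac(t, y):
        dv = np.zeros((len(rates), n_sp))
        v1 = rates.copy()
        v1[mask2] *= y[j2]
        dv[np.nonzero(mask1)[0], j1] += v1[mask1]
        v2 = rates.copy()
        v2[mask1] *= y[j1]
        dv[np.nonzero(mask2)[0], j2] += v2[mask2]
        return stoich @ dv

    kwargs = dict(method=method, rtol=rtol, atol=atol, **solver_opts)
    if method in ("BDF", "Radau"):
        kwargs["jac"] = jac
    if t_eval is None:
        t_eval = np.linspace(0.0, t_final, 500)
    sol = solve_ivp(rhs, (0.0, float(t_final)), y0, t_eval=np.asarray(t_eval),
                    **kwargs)
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}", sol.status)
    traj = Trajectory(sol.t, sol.y, names, sol.status, sol.message)
    if check:
        floor = traj.y.min()
        if floor < -1e-9:
            raise SimulationError(
                f"non-negativity violated: min concentration {floor:.3e}")
        for coeffs, total in crn.conservation_laws:
            series = sum(c * traj.value(n) for n, c in coeffs.items())
            scale = max(abs(total), 1e-300)
            drift = np.max(np.abs(series - total)) / scale
            if drift > 1e-6:
                raise SimulationError(
                    f"conservation law {coeffs} drifts by {drift:.2e} relative")
    return traj


def dual_value(traj: Trajectory, base: str) -> np.ndarray:
    """Signed value of a dual-rail signal: ``base_p - base_m``."""
    p, m = f"{base}_p", f"{base}_m"
    if p not in traj.index or m not in traj.index:
        raise CRNError(f"missing rail species for signal {base!r}")
    return traj.value(p) - traj.value(m)


def count_reactions(crn: CRN) -> int:
    """Number of reaction records (a ``x^± -> ...`` shorthand counts as 2)."""
    return len(crn.reactions)


def expand_bimolecular_dsd(rxn: Reaction, c_max: float, q_max: float,
                           tag: str = "dsd") -> tuple[list[Reaction], list[Species]]:
    """Two-step DNA-strand-displacement template for a bimolecular reaction.

    ``X1 + X2 -> P1 + P2`` (rate delta) becomes ``X1 + G -> O`` at the
    partial displacement rate ``q = delta / C_max`` followed by
    ``O + T -> P1 + P2`` at ``q_max``.  The auxiliary gate ``G`` and
    translator ``T`` start at the working concentration ``C_max``; the
    intermediate ``O`` starts empty.  The unimolecular template uses
    different auxiliary machinery and is not provided here.
    """
    if not (c_max > 0 and q_max > 0):
        raise ValueError("c_max and q_max must be positive")
    if len(rxn.reactants) != 2:
        raise CRNError(
            "only the bimolecular template is supported "
            "(unimolecular expansion uses a different, unavailable template)")
    g, o, t = (f"{tag}_G", f"{tag}_O", f"{tag}_T")
    q = rxn.rate / c_max
    aux = [Species(g, c_max), Species(o, 0.0), Species(t, c_max)]
    first = Reaction((rxn.reactants[0], g), (o,), q, label=f"{rxn.label}:dsd1")
    second = Reaction((o, t), tuple(rxn.products), q_max, label=f"{rxn.label}:dsd2")
    return [first, second], aux
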