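"""Elemental bookkeeping and thermodynamic primitives.

The model treats every reaction node as an ideal dilute mixture: the
dimensionless Gibbs free energy of a node is the mole-fraction weighted sum
of standard chemical potentials plus the ideal mixing entropy, and standard
reaction energies follow from tabulated formation energies by linear
stoichiometric combination.  Temperature enters through the integrated
Gibbs-Helmholtz correction of the standard terms.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np

from .constants import R_GAS, T0

__all__ = [
    "Species",
    "Reaction",
    "BalanceReport",
    "parse_formula",
    "check_balance",
    "reaction_delta",
    "gibbs_helmholtz",
    "mixture_gibbs",
    "total_gibbs",
]

#: Periodic symbols accepted in molecular formulas (one or two letters).
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba W Pt Au Hg Pb".split()
)

#: Pseudo-element used to fold the charge balance into the element balance,
#: so one stoichiometric matrix covers both conservation laws.
CHARGE = "charge"

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula such as ``"C10H18N3O6S"`` into an
    element -> count mapping.

    Counts default to 1 when omitted; repeated elements accumulate.
    Parenthesised groups are not supported (none occur in the model).
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"malformed formula {formula!r} at position {pos}")
        sym, num = m.groups()
        if sym not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


@dataclass(frozen=True)
class Species:
    """A chemical species in one compartment.

    Formation data are at the reference temperature ``T0`` (298 K);
    the same chemical in two compartments is two Species records sharing
    ``name`` and formation data, so transport between compartments carries
    zero standard reaction energy.
    """

    id: str
    name: str
    composition: Mapping[str, int]
    charge: int
    dGf0: float  # kJ/mol at T0
    dHf0: float  # kJ/mol at T0
    compartment: str
    #: buffered species (protons) are excluded from node objectives --
    #: their chemical potential is clamped by an external buffer and their
    #: amounts are restored by the engine's acid-base rebalance step
    buffered: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.composition.values()):
            raise ValueError(f"{self.id}: negative element count")
        if not (math.isfinite(self.dGf0) and math.isfinite(self.dHf0)):
            raise ValueError(f"{self.id}: formation data must be finite")
        object.__setattr__(self, "composition", dict(self.composition))

    @property
    def atoms(self) -> int:
        return sum(self.composition.values())


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction assigned to a network node.

    ``stoich`` maps species id to a signed real coefficient
    (products positive, reactants negative).  ``transport`` marks
    inter-compartment carrier edges whose extents form the outer-loop
    convergence vector of the equilibrium solver.
    """

    id: str
    enzyme: str
    stoich: Mapping[str, float]
    node: str
    irreversible: bool = False
    transport: bool = False
    #: optional per-hour extent cap (nmol/cell/h) at 37 C; None = uncapped
    max_rate: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich", dict(self.stoich))
        if not any(c < 0 for c in self.stoich.values()) or not any(
            c > 0 for c in self.stoich.values()
        ):
            raise ValueError(f"{self.id}: needs at least one reactant and one product")

    @property
    def reactants(self) -> Dict[str, float]:
        return {s: -c for s, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> Dict[str, float]:
        return {s: c for s, c in self.stoich.items() if c > 0}


@dataclass
class BalanceReport:
    """Per-element and charge residuals of a reaction (products minus
    reactants); all-zero for a valid reaction."""

    reaction_id: str
    residuals: Dict[str, float] = field(default_factory=dict)

    @property
    def balanced(self) -> bool:
        return all(abs(v) < 1e-9 for v in self.residuals.values())

    @property
    def flagged(self) -> Dict[str, float]:
        return {k: v for k, v in self.residuals.items() if abs(v) >= 1e-9}


def check_balance(reaction: Reaction, species_table: Mapping[str, Species]) -> BalanceReport:
    """Elemental and charge conservation check for one reaction.

    Charge is carried as the pseudo-element ``"charge"`` in the residual map.
    """
    residuals: Dict[str, float] = {}
    for sid, coeff in reaction.stoich.items():
        if sid not in species_table:
            raise KeyError(f"reaction {reaction.id}: unknown species {sid!r}")
        sp = species_table[sid]
        for el, cnt in sp.composition.items():
            residuals[el] = residuals.get(el, 0.0) + coeff * cnt
        residuals[CHARGE] = residuals.get(CHARGE, 0.0) + coeff * sp.charge
    return BalanceReport(reaction.id, residuals)


def reaction_delta(
    reaction: "Reaction | Mapping[str, float]",
    species_table: Mapping[str, Species],
    prop: str = "G",
) -> float:
    """Standard reaction energy (kJ/mol) from formation data:
    sum over products of Sk*Deltaf minus the same sum over reactants,
    i.e. the signed stoichiometric combination (0 for an empty sum).

    ``reaction`` may be a :class:`Reaction` or a bare signed stoichiometry
    map; ``prop`` selects Gibbs energy (``"G"``) or enthalpy (``"H"``).
    """
    if prop not in ("G", "H"):
        raise ValueError(f"prop must be 'G' or 'H', got {prop!r}")
    stoich = reaction.stoich if isinstance(reaction, Reaction) else reaction
    rid = reaction.id if isinstance(reaction, Reaction) else "<stoich>"
    total = 0.0
    for sid, coeff in stoich.items():
        sp = species_table.get(sid)
        if sp is None:
            raise KeyError(f"reaction {rid}: no formation data for species {sid!r}")
        total += coeff * (sp.dGf0 if prop == "G" else sp.dHf0)
    return total


def gibbs_helmholtz(dG0_at_T0: float, dH0_at_T0: float, T: float, T0_: float = T0) -> float:
    """Dimensionless standard energy DeltaG0(T)/RT at temperature ``T``.

    DeltaG0(T)/RT = DeltaG0(T0)/(R T0) + (DeltaH0(T0)/R) (T - T0)/(T T0),
    with energies in kJ/mol and temperatures in kelvin.  With this
    correction an exothermic transformation (DeltaH0 < 0) becomes more
    favorable below the reference temperature as T rises toward it, which
    is what drives the warming-policy trade-off downstream.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    R_kj = R_GAS / 1000.0  # kJ/(mol K)
    return dG0_at_T0 / (R_kj * T0_) + (dH0_at_T0 / R_kj) * (T - T0_) / (T * T0_)


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def mixture_gibbs(amounts: np.ndarray, dG0_over_RT: np.ndarray, T: float | None = None) -> float:
    """Intensive dimensionless Gibbs energy G/(n RT) of one node's ideal
    mixture: sum_i x_i (g_i + ln x_i) with x_i the amounts normalized
    within the node and g_i the dimensionless standard chemical potentials.

    Activities are ideal (mole fraction); x ln x -> 0 as x -> 0, so fully
    consumed species contribute nothing.
    """
    amounts = np.asarray(amounts, dtype=float)
    g = np.asarray(dG0_over_RT, dtype=float)
    if amounts.shape != g.shape:
        raise ValueError("amounts and dG0_over_RT must have the same shape")
    if np.any(amounts < 0):
        raise ValueError("amounts must be nonnegative")
    tot = amounts.sum()
    if tot <= 0:
        raise ValueError("all-zero amounts")
    x = amounts / tot
    return float(np.sum(x * g) + np.sum(_xlogx(x)))


def total_gibbs(amounts: np.ndarray, dG0_over_RT: np.ndarray) -> float:
    """Extensive dimensionless Gibbs energy G/RT = sum_i n_i (g_i + ln x_i).

    This is the objective the node solver minimizes: for reactions that
    change the total mole number only the extensive form reproduces the
    mass-action equilibrium of an ideal mixture.
    """
    amounts = np.asarray(amounts, dtype=float)
    tot = amounts.sum()
    if tot <= 0:
        raise ValueError("all-zero amounts")
    x = amounts / tot
    g = np.asarray(dG0_over_RT, dtype=float)
    return float(np.sum(amounts * g) + tot * np.sum(_xlogx(x)))


def species_mu0_over_RT(species: Iterable[Species], T: float) -> Dict[str, float]:
    """Dimensionless standard chemical potentials at ``T`` for a collection
    of species, via the Gibbs-Helmholtz correction of their formation data."""
    return {sp.id: gibbs_helmholtz(sp.dGf0, sp.dHf0, T) for sp in species}
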