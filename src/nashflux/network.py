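"""Metabolic network container, validation, and file I/O.

A :class:`MetabolicNetwork` holds compartments, a species table, reactions
partitioned into nodes (one node per enzyme "player"), and the transport /
feedback edges that couple the nodes.  Networks round-trip through a
canonical JSON document and a tabular TSV dialect whose reaction rows use
equation strings like ``"2 A + B = C + 2 D"``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

from .thermo import BalanceReport, Reaction, Species, check_balance

__all__ = [
    "MetabolicNetwork",
    "NetworkNode",
    "parse_equation",
    "format_equation",
    "load_network",
    "save_network",
]


@dataclass
class NetworkNode:
    """One Gibbs-minimizing player: the reactions it catalyzes and the
    species (components) whose amounts enter its objective."""

    id: str
    reactions: List[str] = field(default_factory=list)
    components: List[str] = field(default_factory=list)


def parse_equation(eq: str) -> Dict[str, float]:
    """Parse ``"2 A + B = C + 2 D"`` into a signed stoichiometry map
    (products positive, reactants negative).  Coefficients may be real."""
    if "=" not in eq:
        raise ValueError(f"equation {eq!r} lacks '='")
    lhs, rhs = eq.split("=", 1)
    stoich: Dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in equation {eq!r}")
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S+)$", term)
            if m:
                coeff, sid = float(m.group(1)), m.group(2)
            else:
                coeff, sid = 1.0, term
            stoich[sid] = stoich.get(sid, 0.0) + sign * coeff

    add(lhs, -1.0)
    add(rhs, +1.0)
    return {s: c for s, c in stoich.items() if c != 0.0}


def _fmt_coeff(c: float) -> str:
    return f"{c:g} " if c != 1.0 else ""


def format_equation(stoich: Mapping[str, float]) -> str:
    lhs = " + ".join(f"{_fmt_coeff(-c)}{s}" for s, c in stoich.items() if c < 0)
    rhs = " + ".join(f"{_fmt_coeff(c)}{s}" for s, c in stoich.items() if c > 0)
    return f"{lhs} = {rhs}"


@dataclass
class MetabolicNetwork:
    compartments: List[str]
    species: Dict[str, Species]
    reactions: Dict[str, Reaction]
    nodes: List[NetworkNode]

    # ------------------------------------------------------------------ access
    @property
    def transport_edges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.transport]

    def node(self, node_id: str) -> NetworkNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def species_ids(self) -> List[str]:
        return list(self.species)

    # -------------------------------------------------------------- validation
    def validate(self) -> List[BalanceReport]:
        """Structural + conservation validation.

        Raises ``ValueError`` on any violation; returns the per-reaction
        balance reports on success.
        """
        reports = []
        for sp in self.species.values():
            if sp.compartment not in self.compartments:
                raise ValueError(f"species {sp.id}: unknown compartment {sp.compartment!r}")
        node_of: Dict[str, str] = {}
        for n in self.nodes:
            for rid in n.reactions:
                if rid not in self.reactions:
                    raise ValueError(f"node {n.id}: unknown reaction {rid!r}")
                if rid in node_of:
                    raise ValueError(f"reaction {rid!r} assigned to two nodes")
                node_of[rid] = n.id
            missing = {
                sid
                for rid in n.reactions
                for sid in self.reactions[rid].stoich
                if sid not in n.components
            }
            if missing:
                raise ValueError(f"node {n.id}: components missing {sorted(missing)}")
        unassigned = set(self.reactions) - set(node_of)
        if unassigned:
            raise ValueError(f"reactions not assigned to any node: {sorted(unassigned)}")
        for rxn in self.reactions.values():
            rep = check_balance(rxn, self.species)
            if not rep.balanced:
                raise ValueError(f"reaction {rxn.id} unbalanced: {rep.flagged}")
            reports.append(rep)
            if rxn.transport:
                comps = {self.species[s].compartment for s in rxn.stoich}
                names = {self.species[s].name for s in rxn.stoich}
                if len(comps) != 2 or len(names) != 1:
                    raise ValueError(
                        f"transport edge {rxn.id} must move one chemical "
                        f"between two distinct compartments"
                    )
        return reports

    # --------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "species": [
                {
                    "id": sp.id,
                    "name": sp.name,
                    "composition": dict(sp.composition),
                    "charge": sp.charge,
                    "dGf0_kJ_mol": sp.dGf0,
                    "dHf0_kJ_mol": sp.dHf0,
                    "compartment": sp.compartment,
                    "buffered": sp.buffered,
                }
                for sp in self.species.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "enzyme": r.enzyme,
                    "equation": format_equation(r.stoich),
                    "node": r.node,
                    "irreversible": r.irreversible,
                    "transport": r.transport,
                    "max_rate": r.max_rate,
                }
                for r in self.reactions.values()
            ],
            "nodes": [
                {"id": n.id, "reactions": list(n.reactions), "components": list(n.components)}
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MetabolicNetwork":
        species = {
            rec["id"]: Species(
                id=rec["id"],
                name=rec["name"],
                composition=rec["composition"],
                charge=int(rec["charge"]),
                dGf0=float(rec["dGf0_kJ_mol"]),
                dHf0=float(rec["dHf0_kJ_mol"]),
                compartment=rec["compartment"],
                buffered=bool(rec.get("buffered", False)),
            )
            for rec in doc["species"]
        }
        reactions = {
            rec["id"]: Reaction(
                id=rec["id"],
                enzyme=rec["enzyme"],
                stoich=parse_equation(rec["equation"]),
                node=rec["node"],
                irreversible=bool(rec["irreversible"]),
                transport=bool(rec.get("transport", False)),
                max_rate=rec.get("max_rate"),
            )
            for rec in doc["reactions"]
        }
        nodes = [
            NetworkNode(id=n["id"], reactions=list(n["reactions"]), components=list(n["components"]))
            for n in doc["nodes"]
        ]
        return cls(list(doc["compartments"]), species, reactions, nodes)


def save_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the canonical JSON document (sorted keys, stable formatting)."""
    Path(path).write_text(json.dumps(network.to_dict(), indent=1, sort_keys=True))


def load_network(path: str | Path) -> MetabolicNetwork:
    net = MetabolicNetwork.from_dict(json.loads(Path(path).read_text()))
    net.validate()
    return net
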