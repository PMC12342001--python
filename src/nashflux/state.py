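"""Per-compartment system state: species amounts, temperature, clock."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .network import MetabolicNetwork

__all__ = ["SystemState"]


@dataclass
class SystemState:
    """Species amounts (nmol/cell, keyed by species id), temperature (K)
    and elapsed time (h).  Amounts are clipped to zero at machine noise
    level; genuinely negative amounts are a solver contract violation."""

    amounts: Dict[str, float]
    temperature: float  # K
    time: float = 0.0  # h

    def copy(self) -> "SystemState":
        return SystemState(dict(self.amounts), self.temperature, self.time)

    def get(self, species_id: str) -> float:
        return self.amounts.get(species_id, 0.0)

    def set(self, species_id: str, amount: float) -> None:
        if amount < -1e-9:
            raise ValueError(f"negative amount for {species_id}: {amount}")
        self.amounts[species_id] = max(amount, 0.0)

    def add(self, species_id: str, delta: float) -> None:
        self.set(species_id, self.get(species_id) + delta)

    def vector(self, species_ids) -> np.ndarray:
        return np.array([self.get(s) for s in species_ids], dtype=float)

    def update_from_vector(self, species_ids, values: np.ndarray) -> None:
        for sid, v in zip(species_ids, values):
            self.set(sid, float(v))

    def element_totals(self, network: MetabolicNetwork) -> Dict[str, float]:
        """System-wide elemental (and charge) inventory, for conservation
        checks across solver iterations."""
        totals: Dict[str, float] = {}
        for sid, n in self.amounts.items():
            sp = network.species[sid]
            for el, cnt in sp.composition.items():
                totals[el] = totals.get(el, 0.0) + n * cnt
            totals["charge"] = totals.get("charge", 0.0) + n * sp.charge
        return totals

    @classmethod
    def from_network(
        cls, network: MetabolicNetwork, amounts: Mapping[str, float], temperature: float
    ) -> "SystemState":
        unknown = set(amounts) - set(network.species)
        if unknown:
            raise KeyError(f"unknown species in initial amounts: {sorted(unknown)}")
        full = {sid: float(amounts.get(sid, 0.0)) for sid in network.species}
        return cls(full, temperature)
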