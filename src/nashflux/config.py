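"""Run configuration: a YAML (or JSON) document wiring networks, media,
protocol phases, solver and optimizer settings into one reproducible run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .liver import build_reduced_liver_network
from .media import Medium, load_medium_tsv, uw_solution, williams_medium_e
from .network import load_network
from .optimize import MCConfig
from .perfusion import SimConfig
from .pipeline import PerfusionModel
from .solver import SolverSettings

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field has a sensible
    default so ``RunConfig()`` reproduces the reference protocol."""

    network_path: Optional[str] = None  # None -> bundled reduced liver network
    uw_path: Optional[str] = None
    wme_path: Optional[str] = None
    scs_hours: float = 6.0
    mp_hours: float = 8.0
    mp_temp: float = 16.0
    seed: int = 0
    n_iter: int = 200
    perturbation: float = 0.0
    sim: SimConfig = field(default_factory=SimConfig)
    solver: SolverSettings = field(default_factory=SolverSettings)
    output_dir: str = "results"

    def model(self) -> PerfusionModel:
        network = (
            load_network(self.network_path) if self.network_path else build_reduced_liver_network()
        )
        self.solver.seed = self.seed
        return PerfusionModel(network=network, config=self.sim, settings=self.solver)

    def uw(self) -> Medium:
        return load_medium_tsv(self.uw_path) if self.uw_path else uw_solution()

    def wme(self) -> Medium:
        return load_medium_tsv(self.wme_path) if self.wme_path else williams_medium_e()

    def mc(self) -> MCConfig:
        return MCConfig(n_iter=self.n_iter, seed=self.seed, perturbation=self.perturbation)

    def digest(self) -> str:
        """Short stable hash of the configuration, embedded in outputs."""
        doc = {
            "network_path": self.network_path,
            "scs_hours": self.scs_hours,
            "mp_hours": self.mp_hours,
            "mp_temp": self.mp_temp,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "perturbation": self.perturbation,
            "sim": asdict(self.sim),
            "solver": asdict(self.solver),
        }
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML/JSON run configuration; missing keys keep defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    for key in ("network_path", "uw_path", "wme_path", "scs_hours", "mp_hours",
                "mp_temp", "seed", "n_iter", "perturbation", "output_dir"):
        if key in doc:
            setattr(cfg, key, doc[key])
    for key, val in (doc.get("sim") or {}).items():
        setattr(cfg.sim, key, val)
    for key, val in (doc.get("solver") or {}).items():
        setattr(cfg.solver, key, val)
    return cfg
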