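"""High-level protocol orchestration.

Wires the fixture network, media, solver and optimizers into the standard
study design: a University-of-Wisconsin cold flush, six hours of static
cold storage at 4 C, then eight hours of machine perfusion with Williams
Medium E under a (possibly optimized) warming schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .liver import build_initial_amounts, build_reduced_liver_network
from .media import Medium, uw_solution, williams_medium_e
from .network import MetabolicNetwork
from .optimize import (
    GSHMinimizationResult,
    MCConfig,
    TemperatureOptimizationResult,
    TemperaturePolicy,
    inflammation_sweep,
    minimize_gsh,
    normalized_weights,
    optimize_temperature,
    return_value,
)
from .perfusion import ProtocolPhase, SimConfig, SimulationResult, perturb_h2o2, simulate_phase
from .solver import SolverSettings
from .state import SystemState

__all__ = ["PerfusionModel", "SCS_HOURS", "SCS_TEMP_C", "MP_HOURS", "MP_TEMP_C"]

SCS_HOURS = 6.0
SCS_TEMP_C = 4.0
MP_HOURS = 8.0
MP_TEMP_C = 16.0


@dataclass
class PerfusionModel:
    """The liver model plus everything needed to run protocol studies."""

    network: MetabolicNetwork = field(default_factory=build_reduced_liver_network)
    config: SimConfig = field(default_factory=SimConfig)
    settings: SolverSettings = field(default_factory=SolverSettings)

    def initial_state(self) -> SystemState:
        return SystemState.from_network(
            self.network, build_initial_amounts(self.config.volume), temperature=310.15
        )

    # ------------------------------------------------------------- phases
    def run_scs(
        self, state: Optional[SystemState] = None, hours: float = SCS_HOURS
    ) -> SimulationResult:
        """UW flush followed by static cold storage at 4 C."""
        state = state or self.initial_state()
        phase = ProtocolPhase(
            kind="SCS", duration=hours, medium=uw_solution(), temperature=SCS_TEMP_C
        )
        return simulate_phase(self.network, state, phase, self.settings, self.config)

    def run_mp(
        self,
        state: SystemState,
        policy: Optional[TemperaturePolicy] = None,
        medium: Optional[Medium] = None,
        gsh_supplement: Optional[float] = None,
        perturbation: float = 0.0,
    ) -> SimulationResult:
        """Machine perfusion with WME from a post-storage state.

        ``gsh_supplement`` replaces the medium's total glutathione amount
        (nmol/cell); ``perturbation`` adds mitochondrial H2O2 at phase
        start to elicit an oxidative-stress response.
        """
        medium = medium or williams_medium_e()
        if gsh_supplement is not None:
            medium = medium.with_amount("glutathione", gsh_supplement)
        policy = policy or TemperaturePolicy.constant(MP_TEMP_C, int(MP_HOURS))
        start = perturb_h2o2(state, perturbation) if perturbation > 0 else state
        phase = ProtocolPhase(
            kind="MP",
            duration=policy.duration,
            medium=medium,
            temperature=list(policy.temps),
            n_steps=len(policy.temps),
        )
        return simulate_phase(self.network, start, phase, self.settings, self.config)

    def run_baseline(self) -> Tuple[SimulationResult, SimulationResult]:
        """The reference protocol: SCS then constant mid-thermic MP."""
        scs = self.run_scs()
        mp = self.run_mp(scs.final_state)
        return scs, mp

    # --------------------------------------------------------- optimizers
    def default_weights(self, post_scs: SystemState) -> Tuple[float, float, float, float]:
        baseline = self.run_mp(post_scs)
        return normalized_weights(return_value(baseline))

    def optimize_policy(
        self,
        post_scs: SystemState,
        mc: MCConfig,
        weights: Optional[Sequence[float]] = None,
        perturbation: float = 0.0,
    ) -> TemperatureOptimizationResult:
        weights = weights if weights is not None else self.default_weights(post_scs)
        initial = TemperaturePolicy.constant(MP_TEMP_C, int(MP_HOURS))
        return optimize_temperature(
            lambda pol: self.run_mp(post_scs, policy=pol, perturbation=perturbation),
            initial,
            weights,
            mc,
        )

    def minimize_gsh(
        self,
        post_scs: SystemState,
        policy: TemperaturePolicy,
        mc: MCConfig,
    ) -> GSHMinimizationResult:
        return minimize_gsh(
            lambda g: self.run_mp(
                post_scs, policy=policy, gsh_supplement=g, perturbation=mc.perturbation
            ),
            mc,
        )

    def inflammation_sweep(
        self,
        post_scs: SystemState,
        policy: TemperaturePolicy,
        perturbations: Sequence[float],
        gsh_amount: Optional[float] = None,
    ):
        gsh = gsh_amount if gsh_amount is not None else williams_medium_e().amount("glutathione")
        return inflammation_sweep(
            lambda p: self.run_mp(post_scs, policy=policy, gsh_supplement=gsh, perturbation=p),
            perturbations,
        )
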