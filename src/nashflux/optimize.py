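"""Monte Carlo optimizers for the perfusion protocol.

Two seeded, trace-recording searches:

* :func:`optimize_temperature` -- constrained Monte Carlo ascent of the
  scalar return R = w1*Glu + w2*ATP + w3*Mev + w4*EC over monotone
  (gradual-warming) temperature schedules, accepting a proposal only if R
  strictly increases, the schedule stays monotone, all six physiology
  criteria hold, and the clinical viability constraints
  (lactate <= 2.3 mM and pH > 7.3) are met at the end of perfusion;
* :func:`minimize_gsh` -- smallest glutathione supplement in the medium
  that keeps the final mitochondrial [H2O2] inside the normal band,
  searched by seeded uniform sampling with a shrinking envelope around
  the best feasible point.

The two optimizations are decoupled: the warming policy is fixed while
the supplement is searched (energetically, the heat turned over by
peroxide scavenging is orders of magnitude below the ATP-synthesis
budget, so supplementation does not move the optimal warming rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .perfusion import ROS_NORMAL, SimulationResult, physiology_check

__all__ = [
    "TemperaturePolicy",
    "ReturnValue",
    "MCConfig",
    "return_value",
    "check_viability",
    "optimize_temperature",
    "minimize_gsh",
    "inflammation_sweep",
]

LACTATE_MAX_MM = 2.3
PH_MIN = 7.3


@dataclass(frozen=True)
class TemperaturePolicy:
    """Discrete monotone warming schedule T1 <= T2 <= ... <= TN (deg C)."""

    temps: Tuple[float, ...]
    step_hours: float = 1.0
    t_min: float = 16.0
    t_max: float = 37.0

    def __post_init__(self) -> None:
        if any(b < a - 1e-12 for a, b in zip(self.temps, self.temps[1:])):
            raise ValueError("temperature policy must be non-decreasing")
        if any(t < self.t_min - 1e-12 or t > self.t_max + 1e-12 for t in self.temps):
            raise ValueError(f"temperatures must lie in [{self.t_min}, {self.t_max}]")

    @property
    def duration(self) -> float:
        return len(self.temps) * self.step_hours

    def monotone(self) -> bool:
        return all(b >= a for a, b in zip(self.temps, self.temps[1:]))

    @classmethod
    def constant(cls, temp: float, n_steps: int, step_hours: float = 1.0) -> "TemperaturePolicy":
        return cls(tuple([float(temp)] * n_steps), step_hours)


@dataclass
class ReturnValue:
    """The scalar return R = w1*Glu + w2*ATP + w3*Mev + w4*EC and its parts."""

    weights: Tuple[float, float, float, float]
    glucose_consumed: float
    net_atp: float
    mevalonate_produced: float
    energy_charge: float

    @property
    def value(self) -> float:
        w1, w2, w3, w4 = self.weights
        return (
            w1 * self.glucose_consumed
            + w2 * self.net_atp
            + w3 * self.mevalonate_produced
            + w4 * self.energy_charge
        )


@dataclass
class MCConfig:
    """Monte Carlo search settings (both optimizers)."""

    n_iter: int = 200
    seed: int = 0
    proposal_scale: float = 4.0  # deg C, half-normal increment scale
    gsh_bounds: Tuple[float, float] = (2.22e-5, 25.2e-5)  # nmol/cell
    h2o2_band: Tuple[float, float] = ROS_NORMAL  # molar
    perturbation: float = 0.0  # nmol/cell H2O2 at start of perfusion
    gsh_resolution: float = 1e-6  # nmol/cell

    def __post_init__(self) -> None:
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        lo, hi = self.gsh_bounds
        if not lo < hi:
            raise ValueError("gsh_bounds must satisfy L < U")
        blo, bhi = self.h2o2_band
        if not blo < bhi:
            raise ValueError("h2o2_band must satisfy lower < upper")


def return_value(
    result: SimulationResult, weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
) -> ReturnValue:
    """Evaluate the return on the phase-net metrics of a perfusion run."""
    return ReturnValue(
        weights=tuple(float(w) for w in weights),
        glucose_consumed=result.glucose_consumed,
        net_atp=result.net_atp,
        mevalonate_produced=result.mevalonate_produced,
        energy_charge=result.final_panel.energy_charge,
    )


def check_viability(result: SimulationResult) -> bool:
    """Clinical viability at end of perfusion: lactate <= 2.3 mM (inclusive)
    and pH > 7.3 (strict)."""
    panel = result.final_panel
    return panel.lactate <= LACTATE_MAX_MM and panel.ph > PH_MIN


def normalized_weights(baseline: ReturnValue) -> Tuple[float, float, float, float]:
    """Equal weights after normalizing each metric by its magnitude in a
    baseline perfusion, so no single term dominates R."""
    mags = (
        abs(baseline.glucose_consumed),
        abs(baseline.net_atp),
        abs(baseline.mevalonate_produced),
        abs(baseline.energy_charge),
    )
    return tuple(1.0 / m if m > 0 else 0.0 for m in mags)


@dataclass
class AcceptanceRecord:
    iteration: int
    proposal: Tuple[float, ...]
    R: float
    accepted: bool
    reason: str  # "accepted" or the first failed criterion


@dataclass
class TemperatureOptimizationResult:
    best_policy: TemperaturePolicy
    best_R: float
    best_result: SimulationResult
    trace: List[AcceptanceRecord] = field(default_factory=list)


def optimize_temperature(
    simulate: Callable[[TemperaturePolicy], SimulationResult],
    initial_policy: TemperaturePolicy,
    weights: Sequence[float],
    config: MCConfig,
) -> TemperatureOptimizationResult:
    """Constrained Monte Carlo ascent over monotone warming schedules.

    ``simulate`` runs machine perfusion from a fixed post-storage state
    under a candidate policy.  Each iteration perturbs the incumbent by
    adding a half-normal increment to a random suffix of the schedule
    (clamped to the policy's temperature window), which preserves
    monotonicity by construction; the proposal is accepted iff R strictly
    increases over the incumbent and every constraint holds.
    """
    rng = np.random.default_rng(config.seed)
    incumbent = initial_policy
    inc_result = simulate(incumbent)
    if not check_viability(inc_result) or not physiology_check(inc_result).passed:
        raise ValueError("initial temperature policy is infeasible")
    inc_R = return_value(inc_result, weights).value
    out = TemperatureOptimizationResult(incumbent, inc_R, inc_result)

    for it in range(config.n_iter):
        k = int(rng.integers(0, len(incumbent.temps)))
        delta = abs(rng.normal(0.0, config.proposal_scale))
        temps = list(incumbent.temps)
        for j in range(k, len(temps)):
            temps[j] = min(temps[j] + delta, incumbent.t_max)
        proposal = TemperaturePolicy(
            tuple(temps), incumbent.step_hours, incumbent.t_min, incumbent.t_max
        )
        res = simulate(proposal)
        R = return_value(res, weights).value
        if not proposal.monotone():
            verdict, ok = "monotonicity", False
        elif R <= inc_R:
            verdict, ok = "no R increase", False
        elif not physiology_check(res).passed:
            verdict, ok = "physiology", False
        elif not check_viability(res):
            verdict, ok = "viability", False
        else:
            verdict, ok = "accepted", True
        out.trace.append(AcceptanceRecord(it, proposal.temps, R, ok, verdict))
        if ok:
            incumbent, inc_R, inc_result = proposal, R, res
    out.best_policy, out.best_R, out.best_result = incumbent, inc_R, inc_result
    return out


@dataclass
class GSHMinimizationResult:
    supplement: float  # nmol/cell
    feasible: bool
    evaluations: List[Tuple[float, bool]] = field(default_factory=list)
    result: Optional[SimulationResult] = None


def minimize_gsh(
    simulate: Callable[[float], SimulationResult],
    config: MCConfig,
) -> GSHMinimizationResult:
    """Smallest medium GSH supplement keeping the final mitochondrial
    [H2O2] inside the band, by seeded Monte Carlo with a shrinking
    envelope.

    ``simulate`` runs the (fixed-policy) perfusion with a given total
    medium GSH amount.  The configured perturbation is applied by the
    caller inside ``simulate``.  Returns the best feasible supplement
    within the search resolution, or the upper bound with
    ``feasible=False`` when even that fails.
    """
    lo, hi = config.gsh_bounds
    band_lo, band_hi = config.h2o2_band
    rng = np.random.default_rng(config.seed)
    out = GSHMinimizationResult(hi, False)

    def feasible(g: float) -> tuple[bool, SimulationResult]:
        res = simulate(g)
        c = res.final_panel.h2o2_conc
        ok = band_lo <= c <= band_hi
        out.evaluations.append((g, ok))
        return ok, res

    ok, res = feasible(lo)
    if ok:
        out.supplement, out.feasible, out.result = lo, True, res
        return out
    # The feasible set can be an interior interval: too little GSH leaves
    # H2O2 above the band, too much scavenges it below, so sample inside
    # [L, best-so-far] (initially [L, U]) and shrink toward L.
    best: Optional[float] = None
    ok, res = feasible(hi)
    if ok:
        best, out.result = hi, res
    for _ in range(config.n_iter):
        if best is not None and best - lo <= config.gsh_resolution:
            break
        g = float(rng.uniform(lo, best if best is not None else hi))
        ok, res = feasible(g)
        if ok and (best is None or g < best):
            best, out.result = g, res
    if best is None:
        out.supplement, out.feasible = hi, False
    else:
        out.supplement, out.feasible = best, True
    return out


def inflammation_sweep(
    simulate: Callable[[float], SimulationResult],
    perturbations: Sequence[float],
) -> List[Dict[str, float]]:
    """One perfusion per H2O2 perturbation (ascending), medium GSH fixed;
    returns rows of the oxidative-stress readouts used for
    inflammation-regime plots."""
    if list(perturbations) != sorted(perturbations):
        raise ValueError("perturbations must be sorted ascending")
    rows: List[Dict[str, float]] = []
    for p in perturbations:
        res = simulate(p)
        panel = res.final_panel
        rows.append(
            {
                "perturbation": float(p),
                "h2o2_conc": panel.h2o2_conc,
                "o2_consumed": panel.o2_consumed,
                "o2_consumed_useful": panel.o2_consumed_useful,
                "gsh_gssg_ratio": panel.gsh_gssg_ratio if panel.gsh_gssg_ratio is not None else float("nan"),
                "etc_atp": 2.5 * res.net_extent("R_oxphos"),
                "energy_charge": panel.energy_charge,
            }
        )
    return rows
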