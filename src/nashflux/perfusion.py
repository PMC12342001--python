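"""Protocol engine: cold flush, static cold storage, machine perfusion.

A protocol phase advances the system in discrete time steps (hourly by
default).  Each step sets the temperature from the schedule, injects the
phase's superoxide source, relaxes the network to its Nash equilibrium
under the per-step rate budgets, and records a biomarker panel.

Superoxide sources follow the two classic ischemia/reperfusion routes:

* during hypoxic cold storage, purine breakdown -- a fixed per-step
  extent through the xanthine-oxidase steps (the oxidase form dominates
  in ischemia), sized by a calibration constant in the config;
* during oxygenated perfusion, electron leak from the respiratory chain
  -- a forced extent sized so that superoxide-forming O2 is exactly
  ``leak_fraction`` of all O2 consumed that step.

Sustained hydrogen peroxide above the oxidative-stress threshold degrades
cytochrome c oxidase; this is modeled as a smooth multiplicative
attenuation of the oxidative-phosphorylation rate capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

from .constants import celsius_to_kelvin
from .media import Medium
from .network import MetabolicNetwork
from .solver import ConvergenceReport, SolverSettings, ne_iterate
from .state import SystemState

__all__ = [
    "SimConfig",
    "ProtocolPhase",
    "BiomarkerPanel",
    "PhysiologyReport",
    "SimulationResult",
    "apply_flush",
    "perturb_h2o2",
    "simulate_phase",
    "energy_charge",
    "compute_ph",
    "classify_ros",
    "physiology_check",
]

#: mitochondrial [H2O2] bands (molar), bounds from the redox literature
ROS_NORMAL = (1e-9, 1e-8)
ROS_STRESS_THRESHOLD = 3e-8
ROS_DAMAGE_THRESHOLD = 1e-7


@dataclass
class SimConfig:
    """Physiological and calibration constants of the protocol engine."""

    #: intracellular amount<->concentration factor, nmol per (cell mM)
    volume: float = 1.0 / 9.0
    #: fraction of consumed O2 diverted to superoxide during perfusion
    leak_fraction: float = 0.02
    #: forced xanthine-oxidase extent during cold storage, nmol/cell/h
    #: (calibration constant for the hypoxic superoxide source)
    xo_scs_rate: float = 2e-7
    #: [H2O2] (M) above which cytochrome c oxidase capacity declines
    atten_threshold: float = ROS_STRESS_THRESHOLD
    #: concentration scale (M) of the capacity decline
    atten_scale: float = 5e-8
    #: apparent pK of the CO2/bicarbonate buffer (Henderson-Hasselbalch)
    ph_pk: float = 6.1
    #: chemicals re-equilibrated with the perfusate each MP step
    #: (continuous oxygenation / CO2 outgassing by the circuit)
    gas_refresh: tuple = ("oxygen", "co2")

    def conc_mM(self, amount: float) -> float:
        return amount / self.volume

    def conc_M(self, amount: float) -> float:
        return amount / self.volume * 1e-3

    def oxphos_attenuation(self, h2o2_M: float) -> float:
        """Multiplicative oxphos capacity in [0, 1]; 1 below the stress
        threshold, smoothly and monotonically decreasing above it."""
        excess = max(0.0, h2o2_M - self.atten_threshold)
        return 1.0 / (1.0 + excess / self.atten_scale)


@dataclass
class ProtocolPhase:
    kind: str  # "SCS" | "MP"
    duration: float  # hours
    medium: Optional[Medium] = None
    temperature: Union[float, List[float]] = 4.0  # deg C, scalar or schedule
    n_steps: Optional[int] = None  # default: hourly
    hypoxic: bool = False
    leak_fraction: Optional[float] = None  # default: config value (MP only)

    def __post_init__(self) -> None:
        if self.kind not in ("SCS", "MP"):
            raise ValueError(f"phase kind must be SCS or MP, got {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.n_steps is None:
            self.n_steps = max(int(round(self.duration)), 0)
        if self.kind == "SCS":
            self.hypoxic = True
        lf = self.leak_fraction
        if lf is not None and not (0.0 <= lf <= 0.05):
            raise ValueError("leak_fraction must lie in [0, 0.05]")

    def temperature_at(self, step: int) -> float:
        if isinstance(self.temperature, (int, float)):
            return float(self.temperature)
        sched = list(self.temperature)
        if len(sched) != self.n_steps:
            raise ValueError(
                f"temperature schedule length {len(sched)} != n_steps {self.n_steps}"
            )
        return float(sched[step])


@dataclass
class BiomarkerPanel:
    time: float
    temperature_C: float
    energy_charge: float
    ph: float
    lactate: float  # mM, cytosolic
    h2o2_conc: float  # M, mitochondrial
    superoxide_conc: float  # M
    gsh_conc: float  # mM, intracellular
    gsh_gssg_ratio: Optional[float]
    o2_consumed: float  # nmol/cell, cumulative over the phase (total)
    o2_consumed_useful: float  # excluding O2 diverted to superoxide
    gsh_consumed: float  # by the peroxidase channel, cumulative
    gssg_synthesized: float  # net, cumulative
    net_atp: float  # cumulative net change
    net_bile: float  # mevalonate proxy, cumulative


@dataclass
class PhysiologyReport:
    glycolysis_net_atp_positive: bool
    krebs_atp_per_glucose_in_0_2: bool
    oxphos_synthesizes_atp: bool
    malonyl_coa_forward_only: bool
    fa_synthesis_consumes_atp: bool
    net_gssg_produced: bool

    @property
    def passed(self) -> bool:
        return all(
            (
                self.glycolysis_net_atp_positive,
                self.krebs_atp_per_glucose_in_0_2,
                self.oxphos_synthesizes_atp,
                self.malonyl_coa_forward_only,
                self.fa_synthesis_consumes_atp,
                self.net_gssg_produced,
            )
        )


@dataclass
class SimulationResult:
    phase: ProtocolPhase
    initial_state: SystemState
    final_state: SystemState
    panels: List[BiomarkerPanel] = field(default_factory=list)
    step_fluxes: List[Dict[str, float]] = field(default_factory=list)
    net_fluxes: Dict[str, float] = field(default_factory=dict)
    reports: List[ConvergenceReport] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def final_panel(self) -> BiomarkerPanel:
        if not self.panels:
            raise ValueError("empty simulation result")
        return self.panels[-1]

    def net_extent(self, rid: str) -> float:
        return self.net_fluxes.get(rid, 0.0)

    @property
    def glucose_consumed(self) -> float:
        return self.net_extent("R_glyc")

    @property
    def net_atp(self) -> float:
        return self.panels[-1].net_atp if self.panels else 0.0

    @property
    def mevalonate_produced(self) -> float:
        return self.net_extent("R_mev")


def apply_flush(network: MetabolicNetwork, state: SystemState, medium: Medium) -> SystemState:
    """Replace the extracellular compartment by the medium composition.

    Intracellular amounts are untouched; the exchange is a boundary flux
    (total-system conservation intentionally does not hold across a
    flush).  Idempotent.  Medium components are resolved by chemical name
    against the network's extracellular species.
    """
    out = state.copy()
    by_name = {
        sp.name: sp.id
        for sp in network.species.values()
        if sp.compartment == "extracellular"
    }
    for sid, sp in network.species.items():
        if sp.compartment == "extracellular":
            out.amounts[sid] = 0.0
    for name, amount in medium.amounts().items():
        if name not in by_name:
            raise KeyError(f"medium component {name!r} has no extracellular species")
        out.amounts[by_name[name]] = amount
    return out


def perturb_h2o2(state: SystemState, amount: float) -> SystemState:
    """Add hydrogen peroxide to the mitochondrial pool (nmol/cell)."""
    if amount < 0:
        raise ValueError("perturbation must be nonnegative")
    out = state.copy()
    out.add("h2o2_m", amount)
    return out


def energy_charge(atp: float, adp: float, amp: float) -> float:
    """Adenylate energy charge (ATP + ADP/2) / (ATP + ADP + AMP)."""
    pool = atp + adp + amp
    if pool <= 0:
        raise ValueError("empty adenylate pool")
    return (atp + 0.5 * adp) / pool


def compute_ph(state: SystemState, config: SimConfig) -> float:
    """Cytosolic pH from the tracked proton amount."""
    h_conc = config.conc_M(state.get("h_c"))
    if h_conc <= 0:
        raise ValueError("nonpositive proton concentration")
    return -math.log10(h_conc)


def classify_ros(h2o2_conc: float) -> str:
    """Band classification of a mitochondrial [H2O2] in molar units."""
    if h2o2_conc < 0:
        raise ValueError("concentration must be nonnegative")
    lo, hi = ROS_NORMAL
    if h2o2_conc < lo:
        return "low"
    if h2o2_conc <= hi:
        return "normal"
    if h2o2_conc < ROS_STRESS_THRESHOLD:
        return "elevated"
    if h2o2_conc < ROS_DAMAGE_THRESHOLD:
        return "stress"
    return "damage"


def _rebalance_acid_base(state: SystemState, config: SimConfig) -> None:
    """Analytic carbonic-anhydrase step: protons are buffered, so after
    each equilibrium solve the acid load is absorbed into the
    CO2/bicarbonate pair and the tracked proton amounts are reset to the
    Henderson-Hasselbalch value.  Total hydrogen and charge are conserved
    (the exchange is the buffer reaction's own stoichiometry)."""
    h_tot = state.amounts.get("h_c", 0.0) + state.amounts.get("h_m", 0.0)
    for _ in range(2):
        hco3, co2 = state.get("hco3_c"), state.get("co2_m")
        if hco3 <= 0 or co2 <= 0:
            break
        ph = config.ph_pk + math.log10(hco3 / co2)
        h_ref = 10 ** (-ph) * 1e3 * config.volume  # molar -> mM -> nmol/cell
        excess = h_tot - 2.0 * h_ref
        if excess > 0:  # neutralize acid: HCO3- + H+ -> CO2 + H2O
            e = min(excess, 0.9 * hco3)
            state.set("hco3_c", hco3 - e)
            state.set("co2_m", co2 + e)
            state.add("h2o_m", e)
            h_tot -= e
        else:  # release acid: CO2 + H2O -> HCO3- + H+
            e = min(-excess, 0.9 * co2, state.get("h2o_m"))
            state.set("hco3_c", hco3 + e)
            state.set("co2_m", co2 - e)
            state.add("h2o_m", -e)
            h_tot += e
    state.amounts["h_c"] = h_tot / 2.0
    state.amounts["h_m"] = h_tot / 2.0


def _apply_forced(state: SystemState, network: MetabolicNetwork, rid: str, extent: float) -> float:
    """Apply a forced reaction extent, clipped to substrate availability;
    returns the extent actually applied."""
    rxn = network.reactions[rid]
    if extent <= 0:
        return 0.0
    for sid, coeff in rxn.stoich.items():
        if coeff < 0:
            extent = min(extent, state.get(sid) / (-coeff))
    extent = max(extent, 0.0)
    for sid, coeff in rxn.stoich.items():
        state.add(sid, coeff * extent)
    return extent


def _panel(
    state: SystemState,
    config: SimConfig,
    t: float,
    temp_C: float,
    tot: Dict[str, float],
) -> BiomarkerPanel:
    gssg = state.get("gssg_m")
    gsh = state.get("gsh_c") + state.get("gsh_m")
    return BiomarkerPanel(
        time=t,
        temperature_C=temp_C,
        energy_charge=energy_charge(state.get("atp_c"), state.get("adp_c"), state.get("amp_c")),
        ph=compute_ph(state, config),
        lactate=config.conc_mM(state.get("lac_c")),
        h2o2_conc=config.conc_M(state.get("h2o2_m")),
        superoxide_conc=config.conc_M(state.get("sox_c") + state.get("sox_m")),
        gsh_conc=config.conc_mM(gsh),
        gsh_gssg_ratio=(gsh / gssg) if gssg > 0 else None,
        o2_consumed=tot["o2_total"],
        o2_consumed_useful=tot["o2_useful"],
        gsh_consumed=tot["gsh_consumed"],
        gssg_synthesized=tot["gssg_net"],
        net_atp=tot["net_atp"],
        net_bile=tot["net_bile"],
    )


def _o2_consumed_by(network: MetabolicNetwork, fluxes: Dict[str, float]) -> float:
    """Gross O2 consumption implied by a set of reaction extents."""
    total = 0.0
    for rid, xi in fluxes.items():
        rxn = network.reactions[rid]
        if rxn.transport:
            continue
        for sid, coeff in rxn.stoich.items():
            if sid.startswith("o2_") and coeff < 0:
                total += -coeff * max(xi, 0.0)
    return total


def simulate_phase(
    network: MetabolicNetwork,
    state: SystemState,
    phase: ProtocolPhase,
    settings: Optional[SolverSettings] = None,
    config: Optional[SimConfig] = None,
) -> SimulationResult:
    """Run one protocol phase and return its time series.

    Per step: set temperature; (SCS) force the purine superoxide source;
    relax to equilibrium; (MP) apply the ETC leak sized from this step's
    useful O2 consumption, then let the scavenging nodes re-equilibrate;
    record biomarkers.  Amounts stay nonnegative throughout; a step whose
    outer loop does not converge is flagged and the run continues.
    """
    settings = settings or SolverSettings()
    config = config or SimConfig()
    if phase.medium is not None:
        state = apply_flush(network, state, phase.medium)
    result = SimulationResult(phase=phase, initial_state=state.copy(), final_state=state.copy())
    if phase.n_steps == 0 or phase.duration == 0:
        return result

    dt = phase.duration / phase.n_steps
    work = state.copy()
    tot = {k: 0.0 for k in ("o2_total", "o2_useful", "gsh_consumed", "gssg_net",
                            "net_atp", "net_bile")}
    net: Dict[str, float] = {}
    atp_stoich = {
        rid: rxn.stoich.get("atp_c", 0.0) for rid, rxn in network.reactions.items()
    }
    lf = phase.leak_fraction if phase.leak_fraction is not None else (
        config.leak_fraction if phase.kind == "MP" else 0.0
    )

    gas_ids = {}
    if phase.kind == "MP" and phase.medium is not None:
        by_name = {
            sp.name: sp.id
            for sp in network.species.values()
            if sp.compartment == "extracellular"
        }
        gas_ids = {
            by_name[name]: phase.medium.amount(name)
            for name in config.gas_refresh
            if name in by_name and phase.medium.amount(name) > 0
        }

    for step in range(phase.n_steps):
        temp_C = phase.temperature_at(step)
        T = celsius_to_kelvin(temp_C)
        work.temperature = T
        step_flux: Dict[str, float] = {}
        # continuous perfusion: the circuit holds perfusate gases at their
        # medium set-points (boundary flux, not counted in conservation)
        for sid, amount in gas_ids.items():
            work.amounts[sid] = amount

        if phase.kind == "SCS":
            for rid in ("R_xo1", "R_xo2"):
                applied = _apply_forced(work, network, rid, config.xo_scs_rate * dt)
                step_flux[rid] = step_flux.get(rid, 0.0) + applied

        atten = config.oxphos_attenuation(config.conc_M(work.get("h2o2_m")))
        overrides = {"R_oxphos": (network.reactions["R_oxphos"].max_rate or 0.0) * atten}

        work, fluxes, report = ne_iterate(
            network, work, T=T, dt=dt, settings=settings, rate_overrides=overrides
        )
        result.reports.append(report)
        if not report.converged:
            result.warnings.append(
                f"step {step}: outer loop not converged (norm={report.final_norm:.3g})"
            )
        for rid, xi in fluxes.items():
            step_flux[rid] = step_flux.get(rid, 0.0) + xi

        if phase.kind == "MP" and lf > 0:
            useful = _o2_consumed_by(network, fluxes)
            # superoxide-forming O2 D satisfies D = lf * (useful + D)
            leak_o2 = lf / (1.0 - lf) * useful
            applied = _apply_forced(work, network, "R_leak", leak_o2 / 2.0)
            step_flux["R_leak"] = step_flux.get("R_leak", 0.0) + applied
            if applied > 0:
                # let the scavenging nodes see the new superoxide
                scav = {rid: 0.0 for rid in network.reactions}
                for nid in ("ros", "glutathione"):
                    for rid in network.node(nid).reactions:
                        scav.pop(rid, None)
                work, fluxes2, _ = ne_iterate(
                    network, work, T=T, dt=dt, settings=settings, rate_overrides=scav
                )
                for rid, xi in fluxes2.items():
                    step_flux[rid] = step_flux.get(rid, 0.0) + xi

        _rebalance_acid_base(work, config)

        # ---------------- bookkeeping -----------------------------------
        leak_ext = step_flux.get("R_leak", 0.0)
        useful_o2 = _o2_consumed_by(
            network, {r: x for r, x in step_flux.items() if r != "R_leak"}
        )
        tot["o2_useful"] += useful_o2
        tot["o2_total"] += useful_o2 + 2.0 * leak_ext
        gpx = step_flux.get("R_gpx", 0.0)
        tot["gsh_consumed"] += 2.0 * gpx
        tot["gssg_net"] += gpx - step_flux.get("R_gr", 0.0)
        tot["net_atp"] += sum(atp_stoich.get(r, 0.0) * x for r, x in step_flux.items())
        tot["net_bile"] += step_flux.get("R_mev", 0.0)
        for rid, xi in step_flux.items():
            net[rid] = net.get(rid, 0.0) + xi

        work.time += dt
        result.step_fluxes.append(step_flux)
        result.panels.append(_panel(work, config, work.time, temp_C, dict(tot)))

    result.final_state = work
    result.net_fluxes = net
    return result


def physiology_check(result: SimulationResult) -> PhysiologyReport:
    """The six physiological-plausibility criteria, evaluated on net
    pathway fluxes over the phase."""
    glyc = result.net_extent("R_glyc")
    krebs_atp = result.net_extent("R_krebs")
    glucose = result.net_extent("R_glyc")
    ratio_ok = glucose > 0 and 0.0 <= krebs_atp / glucose <= 2.0
    return PhysiologyReport(
        glycolysis_net_atp_positive=2.0 * glyc > 0,
        krebs_atp_per_glucose_in_0_2=ratio_ok,
        oxphos_synthesizes_atp=2.5 * result.net_extent("R_oxphos") > 0,
        malonyl_coa_forward_only=result.net_extent("R_acc") >= 0,
        fa_synthesis_consumes_atp=4.0 * result.net_extent("R_fas") > 0,
        net_gssg_produced=result.net_extent("R_gpx") - result.net_extent("R_gr") > 0,
    )
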