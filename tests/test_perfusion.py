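"""Protocol engine: flushes, biomarkers, ROS bookkeeping, and the six
physiology criteria."""

import pytest

from nashflux.media import Medium, MediumComponent, uw_solution, williams_medium_e
from nashflux.perfusion import (
    ProtocolPhase,
    SimulationResult,
    apply_flush,
    classify_ros,
    energy_charge,
    perturb_h2o2,
    physiology_check,
    simulate_phase,
)


# ------------------------------------------------------------------ flush
def test_flush_with_empty_medium_zeroes_extracellular(model, network):
    state = model.initial_state()
    out = apply_flush(network, state, Medium("empty", []))
    for sp in network.species.values():
        if sp.compartment == "extracellular":
            assert out.get(sp.id) == 0.0
    assert out.get("atp_c") == state.get("atp_c")  # intracellular untouched


def test_uw_flush_sets_published_glutathione(model, network):
    out = apply_flush(network, model.initial_state(), uw_solution())
    assert out.get("gsh_e") == pytest.approx(3e-4)
    assert out.get("ado_e") == pytest.approx(5e-4)


def test_flush_is_idempotent(model, network):
    state = model.initial_state()
    once = apply_flush(network, state, williams_medium_e())
    twice = apply_flush(network, once, williams_medium_e())
    assert once.amounts == twice.amounts


def test_flush_unknown_component_raises(model, network):
    with pytest.raises(KeyError):
        apply_flush(network, model.initial_state(), Medium("x", [MediumComponent("kryptonite", 1.0)]))


# ----------------------------------------------------------- perturbation
def test_perturbation_zero_is_identity(model):
    state = model.initial_state()
    assert perturb_h2o2(state, 0.0).amounts == state.amounts


def test_perturbations_add(model):
    state = model.initial_state()
    a = perturb_h2o2(perturb_h2o2(state, 1e-7), 1.5e-7)
    b = perturb_h2o2(state, 2.5e-7)
    assert a.get("h2o2_m") == pytest.approx(b.get("h2o2_m"))
    assert b.get("h2o2_m") - state.get("h2o2_m") == pytest.approx(2.5e-7)


def test_negative_perturbation_rejected(model):
    with pytest.raises(ValueError):
        perturb_h2o2(model.initial_state(), -1e-9)


# ------------------------------------------------------------- biomarkers
@pytest.mark.parametrize(
    "atp,adp,amp,expected",
    [(1, 0, 0, 1.0), (0, 0, 1, 0.0), (1, 1, 1, 0.5), (2, 1, 0.5, 5.0 / 7.0)],
)
def test_energy_charge(atp, adp, amp, expected):
    assert energy_charge(atp, adp, amp) == pytest.approx(expected)


def test_energy_charge_empty_pool_raises():
    with pytest.raises(ValueError):
        energy_charge(0, 0, 0)


@pytest.mark.parametrize(
    "conc,band",
    [
        (5e-9, "normal"),
        (1e-9, "normal"),
        (1e-8, "normal"),
        (2e-8, "elevated"),
        (5e-8, "stress"),
        (3e-8, "stress"),
        (1e-7, "damage"),
        (5e-7, "damage"),
        (1e-10, "low"),
    ],
)
def test_ros_band_classification(conc, band):
    assert classify_ros(conc) == band


# --------------------------------------------------------------- protocol
def test_zero_duration_phase_is_identity(model):
    state = model.initial_state()
    phase = ProtocolPhase(kind="MP", duration=0.0, temperature=16.0)
    result = simulate_phase(model.network, state, phase, model.settings, model.config)
    assert result.panels == []
    assert result.final_state.amounts == state.amounts


def test_mp_without_leak_produces_no_etc_superoxide(model, post_scs):
    phase = ProtocolPhase(
        kind="MP", duration=2.0, medium=williams_medium_e(), temperature=16.0,
        leak_fraction=0.0,
    )
    result = simulate_phase(model.network, post_scs, phase, model.settings, model.config)
    assert all(f.get("R_leak", 0.0) == 0.0 for f in result.step_fluxes)


def test_leak_fraction_out_of_range_rejected():
    with pytest.raises(ValueError):
        ProtocolPhase(kind="MP", duration=1.0, leak_fraction=0.2)


def test_scs_depletes_atp_and_glutathione(scs_result):
    """Cold hypoxic storage runs the cell down: net ATP change and net
    total-glutathione change are both negative."""
    assert scs_result.final_panel.net_atp < 0
    gsh_ids = ("gsh_e", "gsh_c", "gsh_m")
    before = sum(scs_result.initial_state.get(s) for s in gsh_ids)
    after = sum(scs_result.final_state.get(s) for s in gsh_ids)
    assert after < before


def test_scs_superoxide_source_runs(scs_result):
    assert scs_result.net_extent("R_xo1") > 0
    assert scs_result.net_extent("R_xo2") > 0
    assert scs_result.final_state.get("ura_c") > scs_result.initial_state.get("ura_c")


def test_leak_identity_superoxide_is_two_percent_of_o2(model, baseline_mp):
    """Per step, superoxide-forming O2 equals leak_fraction x total O2
    consumed, exactly (bookkeeping identity)."""
    lf = model.config.leak_fraction
    for panel_prev, panel, flux in zip(
        [None] + baseline_mp.panels[:-1], baseline_mp.panels, baseline_mp.step_fluxes
    ):
        prev_tot = panel_prev.o2_consumed if panel_prev else 0.0
        prev_useful = panel_prev.o2_consumed_useful if panel_prev else 0.0
        step_total = panel.o2_consumed - prev_tot
        step_diverted = step_total - (panel.o2_consumed_useful - prev_useful)
        if step_total > 0:
            assert step_diverted / step_total == pytest.approx(lf, rel=1e-9)
        assert step_diverted == pytest.approx(2.0 * flux.get("R_leak", 0.0), rel=1e-12)


def test_peroxidase_channel_stoichiometric_identities(baseline_mp):
    """GSH consumed = 2 x H2O2 removed through the peroxidase channel and
    water produced = 2 x H2O2 removed (exact stoichiometry)."""
    gpx = baseline_mp.net_extent("R_gpx")
    assert gpx > 0
    assert baseline_mp.final_panel.gsh_consumed == pytest.approx(2.0 * gpx, rel=1e-12)
    # per mole of H2O2 removed: 2 GSH consumed, 2 H2O produced
    h2o2_removed = gpx  # 1 H2O2 per unit extent
    assert 2.0 * h2o2_removed == pytest.approx(baseline_mp.final_panel.gsh_consumed)


def test_biomarkers_physical(baseline_mp):
    for p in baseline_mp.panels:
        assert 0.0 <= p.energy_charge <= 1.0
        assert p.lactate >= 0 and p.h2o2_conc >= 0 and p.superoxide_conc >= 0
        assert 6.0 < p.ph < 9.0


def test_amounts_nonnegative_throughout(model, baseline_mp):
    for sid, amount in baseline_mp.final_state.amounts.items():
        assert amount >= 0.0, sid


# ------------------------------------------------------ physiology report
def _fake_result(**fluxes) -> SimulationResult:
    phase = ProtocolPhase(kind="MP", duration=0.0, temperature=16.0)
    from nashflux.state import SystemState

    empty = SystemState({}, 289.15)
    return SimulationResult(phase, empty, empty, net_fluxes=fluxes)


BASE = dict(R_glyc=0.1, R_krebs=0.08, R_oxphos=1e-3, R_acc=1e-4, R_fas=1e-4, R_gpx=1e-5, R_gr=0.0)


def test_physiology_baseline_passes_gate(baseline_mp):
    assert physiology_check(baseline_mp).passed


def test_physiology_all_criteria_on_synthetic_fluxes():
    assert physiology_check(_fake_result(**BASE)).passed


def test_krebs_ratio_above_two_fails():
    bad = dict(BASE, R_krebs=0.25)  # 2.5 ATP per glucose consumed
    report = physiology_check(_fake_result(**bad))
    assert not report.krebs_atp_per_glucose_in_0_2 and not report.passed


def test_reverse_malonyl_step_fails():
    report = physiology_check(_fake_result(**dict(BASE, R_acc=-1e-5)))
    assert not report.malonyl_coa_forward_only


def test_no_gssg_production_fails():
    report = physiology_check(_fake_result(**dict(BASE, R_gpx=0.0)))
    assert not report.net_gssg_produced
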