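"""Monte Carlo optimizers: return function, viability rule, policy
moves, and search contracts."""

import pytest

from nashflux.optimize import (
    MCConfig,
    TemperaturePolicy,
    check_viability,
    return_value,
)
from nashflux.perfusion import BiomarkerPanel, ProtocolPhase, SimulationResult
from nashflux.state import SystemState


def _result(lactate=1.0, ph=7.5, ec=0.7, glyc=0.0, mev=0.0, net_atp=0.0):
    phase = ProtocolPhase(kind="MP", duration=1.0, temperature=16.0)
    empty = SystemState({}, 289.15)
    panel = BiomarkerPanel(
        time=1.0, temperature_C=16.0, energy_charge=ec, ph=ph, lactate=lactate,
        h2o2_conc=2e-9, superoxide_conc=1e-12, gsh_conc=0.1, gsh_gssg_ratio=5.0,
        o2_consumed=0.1, o2_consumed_useful=0.098, gsh_consumed=1e-5,
        gssg_synthesized=5e-6, net_atp=net_atp, net_bile=mev,
    )
    return SimulationResult(
        phase, empty, empty, panels=[panel],
        net_fluxes={"R_glyc": glyc, "R_mev": mev},
    )


# ----------------------------------------------------------- return value
def test_return_zero_weights_is_zero():
    assert return_value(_result(glyc=1.0, net_atp=2.0), (0, 0, 0, 0)).value == 0.0


def test_return_single_metric_passthrough():
    rv = return_value(_result(net_atp=2.398), (0, 1, 0, 0))
    assert rv.value == pytest.approx(2.398)


def test_return_is_exact_weighted_sum():
    rv = return_value(_result(glyc=0.4, net_atp=1.5, mev=0.02, ec=0.61), (1, 1, 1, 1))
    assert rv.value == pytest.approx(0.4 + 1.5 + 0.02 + 0.61)


# -------------------------------------------------------------- viability
@pytest.mark.parametrize(
    "lactate,ph,expected",
    [
        (2.3, 7.31, True),   # lactate bound inclusive, pH strict
        (2.4, 7.5, False),
        (1.0, 7.3, False),   # pH exactly at bound fails (strict >)
        (2.31, 7.31, False),
        (0.0, 7.4, True),
    ],
)
def test_viability_rule(lactate, ph, expected):
    assert check_viability(_result(lactate=lactate, ph=ph)) is expected


# ---------------------------------------------------------------- policies
def test_policy_must_be_monotone():
    with pytest.raises(ValueError):
        TemperaturePolicy((20.0, 18.0, 22.0))


def test_policy_must_stay_in_window():
    with pytest.raises(ValueError):
        TemperaturePolicy((16.0, 40.0))


def test_constant_policy():
    pol = TemperaturePolicy.constant(16.0, 8)
    assert pol.temps == (16.0,) * 8
    assert pol.duration == 8.0
    assert pol.monotone()


# ------------------------------------------------------------ mc config
def test_mc_config_default_bounds_are_published_values():
    mc = MCConfig()
    assert mc.gsh_bounds == (2.22e-5, 25.2e-5)
    assert mc.h2o2_band == (1e-9, 1e-8)


def test_mc_config_rejects_inverted_bounds():
    with pytest.raises(ValueError):
        MCConfig(gsh_bounds=(1e-4, 1e-5))
    with pytest.raises(ValueError):
        MCConfig(h2o2_band=(1e-8, 1e-9))


# ---------------------------------------------- temperature optimization
def test_optimizer_zero_iterations_returns_initial(model, post_scs):
    mc = MCConfig(n_iter=0, seed=1)
    out = model.optimize_policy(post_scs, mc)
    assert out.best_policy.temps == (16.0,) * 8
    assert out.trace == []


def test_optimizer_trace_is_deterministic(model, post_scs):
    runs = []
    for _ in range(2):
        out = model.optimize_policy(post_scs, MCConfig(n_iter=4, seed=11))
        runs.append([(t.proposal, t.R, t.accepted, t.reason) for t in out.trace])
    assert runs[0] == runs[1]


def test_optimizer_accepted_policies_satisfy_all_constraints(model, post_scs):
    """Every accepted proposal is monotone and its simulation passes both
    the physiology gate and the viability rule; R is strictly increasing
    along the acceptance subsequence."""
    from nashflux.perfusion import physiology_check
    from nashflux.optimize import TemperaturePolicy

    out = model.optimize_policy(post_scs, MCConfig(n_iter=25, seed=5))
    accepted = [t for t in out.trace if t.accepted]
    last_R = None
    for rec in accepted:
        pol = TemperaturePolicy(rec.proposal)
        assert pol.monotone()
        res = model.run_mp(post_scs, policy=pol)
        assert check_viability(res)
        assert physiology_check(res).passed
        if last_R is not None:
            assert rec.R > last_R
        last_R = rec.R
    assert out.best_R >= return_value(
        model.run_mp(post_scs), model.default_weights(post_scs)
    ).value


# --------------------------------------------------------- gsh minimizer
def test_minimize_gsh_lower_bound_when_baseline_in_band(model, post_scs):
    """With no perturbation the unsupplemented baseline already ends in
    the normal band, so the search returns its lower bound."""
    from nashflux.optimize import TemperaturePolicy

    mc = MCConfig(n_iter=5, seed=2, perturbation=0.0)
    out = model.minimize_gsh(post_scs, TemperaturePolicy.constant(16.0, 8), mc)
    assert out.feasible
    assert out.supplement == pytest.approx(2.22e-5)
    assert len(out.evaluations) == 1  # L alone settles it


def test_minimize_gsh_respects_bounds_and_band(model, post_scs):
    from nashflux.optimize import TemperaturePolicy

    mc = MCConfig(n_iter=6, seed=9, perturbation=2.5e-5)
    out = model.minimize_gsh(post_scs, TemperaturePolicy.constant(16.0, 8), mc)
    lo, hi = mc.gsh_bounds
    assert lo <= out.supplement <= hi
    if out.feasible:
        c = out.result.final_panel.h2o2_conc
        assert mc.h2o2_band[0] <= c <= mc.h2o2_band[1]


def test_minimize_gsh_infeasible_when_perturbation_extreme(model, post_scs):
    from nashflux.optimize import TemperaturePolicy

    mc = MCConfig(n_iter=4, seed=2, perturbation=5e-3)
    out = model.minimize_gsh(post_scs, TemperaturePolicy.constant(16.0, 8), mc)
    assert not out.feasible
    assert out.supplement == mc.gsh_bounds[1]


def test_minimize_gsh_rejects_inverted_inputs():
    with pytest.raises(ValueError):
        MCConfig(gsh_bounds=(2e-4, 1e-4))


def test_policy_search_decoupled_from_gsh_supplementation(model, post_scs):
    """Supplementing glutathione does not change which warming policies
    the search accepts: the energy turned over by peroxide scavenging is
    orders of magnitude below the ATP budget that drives R."""
    from nashflux.optimize import optimize_temperature

    weights = model.default_weights(post_scs)
    initial = TemperaturePolicy.constant(16.0, 8)
    mc = MCConfig(n_iter=8, seed=13)
    plain = optimize_temperature(
        lambda pol: model.run_mp(post_scs, policy=pol), initial, weights, mc
    )
    boosted = optimize_temperature(
        lambda pol: model.run_mp(post_scs, policy=pol, gsh_supplement=2e-4),
        initial, weights, mc,
    )
    assert plain.best_policy.temps == boosted.best_policy.temps
    assert [t.accepted for t in plain.trace] == [t.accepted for t in boosted.trace]


# ------------------------------------------------------------- sweeps
def test_inflammation_sweep_empty_is_empty(model, post_scs):
    from nashflux.optimize import TemperaturePolicy

    rows = model.inflammation_sweep(post_scs, TemperaturePolicy.constant(16.0, 8), [])
    assert rows == []


def test_inflammation_sweep_requires_sorted_input(model, post_scs):
    from nashflux.optimize import TemperaturePolicy

    with pytest.raises(ValueError):
        model.inflammation_sweep(
            post_scs, TemperaturePolicy.constant(16.0, 8), [2e-5, 1e-5]
        )
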