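"""Equilibrium solver: closed-form and brute-force oracles on small
networks, conservation, determinism, and the outer-loop contract."""

import math

import numpy as np
import pytest

from nashflux.constants import R_GAS
from nashflux.network import MetabolicNetwork, NetworkNode
from nashflux.solver import SolverSettings, ne_iterate, solve_node_in_state
from nashflux.state import SystemState
from nashflux.thermo import Reaction, Species, parse_formula, total_gibbs

RT = R_GAS * 1e-3 * 298.0


def _one_compartment(species_defs, reactions, nodes):
    species = {
        sid: Species(sid, sid, parse_formula(f), q, dG, dH, "cytosol")
        for sid, (f, q, dG, dH) in species_defs.items()
    }
    net = MetabolicNetwork(["cytosol"], species, {r.id: r for r in reactions}, nodes)
    net.validate()
    return net


def _isomer_pair(dG_B):
    return _one_compartment(
        {"A": ("C6H12O6", 0, 0.0, 0.0), "B": ("C6H12O6", 0, dG_B, 0.0)},
        [Reaction("iso", "isomerase", {"A": -1, "B": 1}, "n1")],
        [NetworkNode("n1", ["iso"], ["A", "B"])],
    )


def _grid_minimize(objective, lo, hi, n=200001):
    xs = np.linspace(lo, hi, n)
    vals = np.array([objective(x) for x in xs])
    return xs[np.argmin(vals)]


def test_symmetric_isomerization_splits_evenly():
    net = _isomer_pair(0.0)
    out, _, rep = ne_iterate(net, SystemState({"A": 1.0, "B": 0.0}, 298.0))
    assert rep.converged
    assert out.get("A") == pytest.approx(0.5, abs=1e-6)
    assert out.get("B") == pytest.approx(0.5, abs=1e-6)


def test_isomerization_matches_equilibrium_constant():
    """x_B / x_A equals K = exp(-dG0/RT) to 3 significant figures, checked
    against a 1-D grid search over the reaction extent."""
    dG = -RT * math.log(3.0)
    net = _isomer_pair(dG)
    out, _, rep = ne_iterate(net, SystemState({"A": 1.0, "B": 0.0}, 298.0))
    ratio = out.get("B") / out.get("A")
    assert ratio == pytest.approx(3.0, rel=1e-3)

    g = np.array([0.0, dG / RT])
    xi_star = _grid_minimize(
        lambda xi: total_gibbs(np.array([1.0 - xi, xi]), g), 1e-9, 1 - 1e-9
    )
    assert out.get("B") == pytest.approx(xi_star, abs=1e-4)


def test_mole_changing_dimerization_matches_mass_action():
    """2 A = B: x_B / x_A^2 * x_tot... checked directly against the
    closed-form mass-action condition K = (x_B / x_A^2) at equilibrium of
    the total-Gibbs objective (grid-search oracle)."""
    K = 5.0
    dG_B = -RT * math.log(K) - 40.0  # -40*2 from the A anchors below
    net = _one_compartment(
        {"A": ("C2H4", 0, -20.0, 0.0), "B": ("C4H8", 0, dG_B, 0.0)},
        [Reaction("dim", "dimerase", {"A": -2, "B": 1}, "n1")],
        [NetworkNode("n1", ["dim"], ["A", "B"])],
    )
    out, _, _ = ne_iterate(net, SystemState({"A": 1.0, "B": 0.0}, 298.0))
    xA = out.get("A") / (out.get("A") + out.get("B"))
    xB = out.get("B") / (out.get("A") + out.get("B"))
    assert xB / xA**2 == pytest.approx(K, rel=2e-3)

    g = np.array([-20.0 / RT, dG_B / RT])
    xi_star = _grid_minimize(
        lambda xi: total_gibbs(np.array([1.0 - 2 * xi, xi]), g), 1e-9, 0.5 - 1e-9
    )
    assert out.get("B") == pytest.approx(xi_star, abs=1e-4)


def _two_node_chain():
    # A -> B at node 1, B -> C at node 2; all same formula so transport-free
    return _one_compartment(
        {
            "A": ("C3H6O3", 0, 0.0, 0.0),
            "B": ("C3H6O3", 0, -3.0, 0.0),
            "C": ("C3H6O3", 0, -5.0, 0.0),
        },
        [
            Reaction("r1", "e1", {"A": -1, "B": 1}, "n1"),
            Reaction("r2", "e2", {"B": -1, "C": 1}, "n2"),
        ],
        [NetworkNode("n1", ["r1"], ["A", "B"]), NetworkNode("n2", ["r2"], ["B", "C"])],
    )


def test_two_node_chain_matches_whole_network_minimum():
    """The per-node fixed point agrees with simultaneous whole-network
    Gibbs minimization over both extents (2-D brute-force oracle)."""
    net = _two_node_chain()
    start = {"A": 1.0, "B": 0.0, "C": 0.0}
    out, _, rep = ne_iterate(
        net, SystemState(dict(start), 298.0), settings=SolverSettings(max_steps=30)
    )
    assert rep.converged

    g = np.array([0.0, -3.0 / RT, -5.0 / RT])

    def search(lo1, hi1, lo2, hi2, n):
        best, best_val = None, np.inf
        for xi1 in np.linspace(lo1, hi1, n):
            for xi2 in np.linspace(lo2, hi2, n):
                amounts = np.array([1.0 - xi1, xi1 - xi2, xi2])
                if np.any(amounts < 0):
                    continue
                v = total_gibbs(np.maximum(amounts, 1e-300), g)
                if v < best_val:
                    best, best_val = (xi1, xi2), v
        return best

    # coarse scan then two local refinements around the incumbent
    x1, x2 = search(0, 1, 0, 1, 201)
    for span in (0.01, 0.0005):
        x1, x2 = search(x1 - span, x1 + span, x2 - span, x2 + span, 201)
    best = np.array([1.0 - x1, x1 - x2, x2])
    for sid, nb in zip(["A", "B", "C"], best):
        assert out.get(sid) == pytest.approx(nb, abs=1e-3)


def test_single_node_converges_immediately():
    net = _isomer_pair(-1.0)
    _, _, rep = ne_iterate(net, SystemState({"A": 1.0, "B": 0.0}, 298.0))
    assert rep.converged and rep.outer_iterations <= 2


def test_zero_step_budget_returns_state_unchanged():
    net = _isomer_pair(-1.0)
    state = SystemState({"A": 1.0, "B": 0.0}, 298.0)
    out, flux, rep = ne_iterate(net, state, settings=SolverSettings(max_steps=0))
    assert not rep.converged
    assert out.get("A") == 1.0 and out.get("B") == 0.0
    assert all(v == 0.0 for v in flux.values())


def test_irreversible_extent_clamped_at_zero():
    """An irreversible reaction whose thermodynamics favor the reverse
    direction stays at its zero bound."""
    net = _one_compartment(
        {"A": ("C6H12O6", 0, -50.0, 0.0), "B": ("C6H12O6", 0, 0.0, 0.0)},
        [Reaction("fwd", "e", {"A": -1, "B": 1}, "n1", irreversible=True)],
        [NetworkNode("n1", ["fwd"], ["A", "B"])],
    )
    out, flux, _ = ne_iterate(net, SystemState({"A": 0.5, "B": 0.5}, 298.0))
    assert flux["fwd"] == pytest.approx(0.0, abs=1e-12)
    assert out.get("B") == pytest.approx(0.5)


def test_rate_cap_limits_extent():
    net = _isomer_pair(-50.0)  # strongly forward
    net.reactions["iso"] = Reaction("iso", "isomerase", {"A": -1, "B": 1}, "n1", max_rate=0.1)
    out, flux, _ = ne_iterate(net, SystemState({"A": 1.0, "B": 0.0}, 310.15), dt=1.0)
    assert flux["iso"] == pytest.approx(0.1, rel=1e-6)


def test_solve_single_node_objective_never_increases():
    """A lone node solve reports a non-positive Gibbs change and leaves
    the input state untouched."""
    net = _isomer_pair(-RT * math.log(3.0))
    state = SystemState({"A": 1.0, "B": 0.0}, 298.0)
    sol = solve_node_in_state(net, "n1", state)
    assert sol.success
    assert sol.gibbs_change <= 0.0
    assert sol.extents["iso"] == pytest.approx(0.75, abs=1e-4)  # x_B = K/(1+K)
    assert state.get("A") == 1.0  # untouched


def test_element_and_charge_conservation(model, post_scs):
    """Whole-system elemental and charge totals are invariant under an
    equilibrium step (relative residual < 1e-9)."""
    before = post_scs.element_totals(model.network)
    out, _, _ = ne_iterate(model.network, post_scs, T=289.15, settings=model.settings)
    after = out.element_totals(model.network)
    for el, tot in before.items():
        scale = max(abs(tot), 1.0)
        assert abs(after[el] - tot) / scale < 1e-9, el


def test_deterministic_given_identical_inputs(model, post_scs):
    runs = []
    for _ in range(2):
        out, flux, _ = ne_iterate(model.network, post_scs, T=289.15, settings=model.settings)
        runs.append((dict(out.amounts), dict(flux)))
    assert runs[0] == runs[1]
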