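"""Unit tests for the mass-action engine: fluxes, ODE closed forms,
conserved moieties and steady states."""

import numpy as np
import pytest

from receptox import h1
from receptox.network import (
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
    SteadyStateConfig,
    SteadyStateError,
    conserved_moieties,
    find_steady_state,
    mass_action_flux,
    moiety_totals,
    reachable_species,
    simulate_ode,
)


def _net(species, reactions):
    return ReactionNetwork([Species(s) if isinstance(s, str) else s for s in species],
                           reactions)


# ---------------------------------------------------------------------------
# mass-action flux
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "reaction, amounts, expected",
    [
        # A + B -> C at k=1 with A=2, B=3: product rate 6
        (Reaction("r", {"A": 1, "B": 1}, {"C": 1}), {"A": 2, "B": 3}, 6.0),
        # catalytic conversion with zero catalyst gives zero flux
        (Reaction("r", {"S": 1}, {"P": 1}, ["E"]), {"S": 10, "E": 0}, 0.0),
        # dimerisation: ODE-mode flux is the plain power law A^2
        (Reaction("r", {"A": 2}, {"C": 1}), {"A": 3}, 9.0),
        # zero-order source fires at the bare rate constant
        (Reaction("r", {}, {"A": 1}, rate_constant=0.25), {}, 0.25),
    ],
)
def test_mass_action_flux_values(reaction, amounts, expected):
    ids = sorted({*reaction.reactants, *reaction.products, *reaction.modifiers,
                  *amounts})
    net = _net(ids, [reaction])
    assert mass_action_flux(net, net.state(amounts))[0] == pytest.approx(expected)


def test_all_zero_state_gives_zero_fluxes_on_h1():
    net = h1.build_h1_network()
    flux = mass_action_flux(net, net.state({}))
    # only the zero-order sources (PIP2 synthesis, basal transcription) fire
    nonzero = {net.reactions[j].id for j in np.nonzero(flux)[0]}
    assert nonzero == {"pip2_synthesis"} | {f"basal_{f}" for f in h1.FACTORS}


def test_flux_rejects_dimension_mismatch_and_negative_amounts():
    net = _net(["A"], [Reaction("r", {"A": 1}, {})])
    with pytest.raises(NetworkError):
        mass_action_flux(net, h1.default_state())
    bad = net.state({"A": -1.0})
    with pytest.raises(NetworkError):
        mass_action_flux(net, bad)


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------


def test_ode_clamped_source_chain_matches_closed_form():
    # source -> S -> 0 with clamped source = 1: S(t) = 1 - exp(-t)
    net = _net([Species("src", clamped=True), "S"],
               [Reaction("prod", {"src": 1}, {"src": 1, "S": 1}),
                Reaction("deg", {"S": 1}, {})])
    traj = simulate_ode(net, net.state({"src": 1.0}), 5.0)
    expected = 1.0 - np.exp(-traj.times)
    np.testing.assert_allclose(traj.series("S"), expected, atol=1e-7)
    assert np.all(traj.series("src") == 1.0)


def test_ode_isomerisation_conserves_and_equilibrates():
    net = _net(["A", "B"], [Reaction("f", {"A": 1}, {"B": 1}),
                            Reaction("b", {"B": 1}, {"A": 1})])
    traj = simulate_ode(net, net.state({"A": 2.0}), 30.0)
    np.testing.assert_allclose(traj.series("A") + traj.series("B"), 2.0, rtol=1e-8)
    assert traj.series("A")[-1] == pytest.approx(1.0, abs=1e-7)
    assert traj.series("B")[-1] == pytest.approx(1.0, abs=1e-7)


def test_ode_h1_trajectory_conserves_all_moieties():
    spec = h1.PathwaySpec(dose=2.0)
    net = h1.build_h1_network(spec)
    s0 = h1.default_state(spec, stimulated=True, network=net)
    mo = conserved_moieties(net)
    totals0 = moiety_totals(net, s0, mo)
    traj = simulate_ode(net, s0, 100.0)
    for row in traj.states:
        totals = moiety_totals(net, type(s0)(row), mo)
        np.testing.assert_allclose(totals, totals0, rtol=1e-6, atol=1e-9)


def test_ode_rejects_bad_inputs():
    net = _net(["A"], [Reaction("d", {"A": 1}, {})])
    with pytest.raises(NetworkError):
        simulate_ode(net, net.state({"A": 1.0}), -1.0)
    with pytest.raises(NetworkError):
        simulate_ode(net, net.state({"A": -0.5}), 1.0)


def test_ode_deterministic_repeatability():
    net = h1.build_h1_network()
    s0 = h1.default_state(stimulated=True, network=net)
    t1 = simulate_ode(net, s0, 20.0)
    t2 = simulate_ode(net, s0, 20.0)
    assert np.array_equal(t1.states, t2.states)


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------


def test_isomerisation_moiety():
    net = _net(["A", "B"], [Reaction("f", {"A": 1}, {"B": 1}),
                            Reaction("b", {"B": 1}, {"A": 1})])
    assert conserved_moieties(net) == [{"A": 1, "B": 1}]


def test_open_chain_has_no_moiety_with_s():
    net = _net([Species("src", clamped=True), "S"],
               [Reaction("prod", {"src": 1}, {"src": 1, "S": 1}),
                Reaction("deg", {"S": 1}, {})])
    assert all("S" not in m for m in conserved_moieties(net))


def test_h1_moieties_are_the_protein_cycles():
    """Every activation cycle shows up as a nonnegative conservation vector
    and each vector annihilates the stoichiometric matrix exactly."""
    net = h1.build_h1_network()
    mo = conserved_moieties(net)
    found = {frozenset(m.items()) for m in mo}
    assert frozenset({"NFAT_i": 1, "NFAT_act": 1}.items()) in found
    assert frozenset({"PKC_i": 1, "PKC_act": 1}.items()) in found
    assert frozenset({"Ca_ER": 1, "Ca_cyt": 1}.items()) in found
    assert frozenset({"BTK": 1, "BTK_PIP3": 1}.items()) in found
    # G-protein: trimer + Gaq forms, and trimer + Gbg, both weight-1
    assert frozenset({"Gabg": 1, "Gaq_act": 1, "Gaq_inact": 1}.items()) in found
    assert frozenset({"Gabg": 1, "Gbg_act": 1}.items()) in found
    # exact rational check v^T N = 0 via integer arithmetic
    N = net.stoichiometric_matrix
    for m in mo:
        v = np.zeros(net.n_species, dtype=object)
        for sp, w in m.items():
            v[net.species_index[sp]] = w
        assert all(int(x) == 0 for x in v @ N)
        assert all(w > 0 for w in m.values())


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


def test_steady_state_clamped_source_chain():
    net = _net([Species("src", clamped=True), "S"],
               [Reaction("prod", {"src": 1}, {"src": 1, "S": 1}),
                Reaction("deg", {"S": 1}, {})])
    ss = find_steady_state(net, net.state({"src": 1.0}))
    assert ss.amounts[net.species_index["S"]] == pytest.approx(1.0, abs=1e-9)


def test_steady_state_binding_equilibrium_quadratic_root():
    # A + B <-> C with totals 2, 2 and k_on = k_off = 1:
    # C* solves C^2 - 5C + 4 = 0 in [0, 2], i.e. C* = 1
    net = _net(["A", "B", "C"], [Reaction("on", {"A": 1, "B": 1}, {"C": 1}),
                                 Reaction("off", {"C": 1}, {"A": 1, "B": 1})])
    ss = find_steady_state(net, net.state({"A": 2.0, "B": 2.0}))
    assert ss.amounts[net.species_index["C"]] == pytest.approx(1.0, abs=1e-9)
    assert ss.amounts[net.species_index["A"]] == pytest.approx(1.0, abs=1e-9)


def test_steady_state_preserves_moiety_totals():
    spec = h1.PathwaySpec(moiety_totals={m: 0.5 + 0.1 * i for i, m in
                                         enumerate(h1.MOIETY_NAMES)}, dose=3.0)
    net = h1.build_h1_network(spec)
    s0 = h1.default_state(spec, stimulated=True, network=net)
    mo = conserved_moieties(net)
    ss = find_steady_state(net, s0)
    np.testing.assert_allclose(moiety_totals(net, ss, mo),
                               moiety_totals(net, s0, mo), rtol=1e-9)


def test_h1_zero_ligand_steady_state_is_the_basal_fixed_point():
    """With no ligand every activated species vanishes and each reporter
    settles at the basal/decay ratio."""
    spec = h1.PathwaySpec()
    net = h1.build_h1_network(spec)
    # start away from the fixed point to make the test non-trivial
    s0 = h1.default_state(spec, stimulated=False, network=net)
    s0.amounts = s0.amounts.copy()
    s0.amounts[net.species_index["Luc_NFAT"]] = 5.0
    ss = find_steady_state(net, s0)
    for sp in ("H1R_act", "Gaq_act", "Gbg_act", "PLCb_act", "IP3", "DAG",
               "Ca_cyt", "NFAT_act", "Mef2_act", "CREB_act", "PKC_act",
               "IKK_act", "NFkB_act", "AC_act", "cAMP", "PKA_act",
               "PI3K_act", "PIP3", "BTK_PIP3", "ATF2_act", "Akt_act"):
        assert abs(ss.amounts[net.species_index[sp]]) < 1e-9, sp
    for f in h1.FACTORS:
        luc = ss.amounts[net.species_index[f"Luc_{f}"]]
        assert luc == pytest.approx(spec.basal_rate, rel=1e-8)


def test_steady_state_reports_nonconvergence():
    # undamped oscillator-like open system: A -> A + B fed back is divergent
    net = _net(["A"], [Reaction("auto", {"A": 1}, {"A": 2})])
    with pytest.raises(SteadyStateError) as exc:
        find_steady_state(net, net.state({"A": 1.0}),
                          SteadyStateConfig(horizon=5.0))
    assert exc.value.residual is None or exc.value.residual > 0


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


def test_every_h1_species_reachable_from_stimulated_marking():
    spec = h1.PathwaySpec()
    net = h1.build_h1_network(spec)
    s0 = h1.default_state(spec, stimulated=True, network=net)
    assert reachable_species(net, s0) == {s.id for s in net.species}
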