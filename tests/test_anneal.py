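"""Simulated-annealing core refinement."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcore import (
    AnnealConfig,
    AnnealSchedule,
    CoreSet,
    ToyModelSpec,
    acceptance_probability,
    anneal_core,
    export_core_graph,
    generate_toy_model,
    is_connected_core,
    limit_flux_to_core,
    move_core,
    multi_seed_anneal,
    reaction_graph,
)


class ScriptedRNG:
    """Deterministic stand-in for a Generator: plays back scripted draws."""

    def __init__(self, uniforms, integers=()):
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def random(self):
        return self._uniforms.pop(0)

    def integers(self, n):
        return self._integers.pop(0) % n


# ---------------------------------------------------------------- probability


def test_acceptance_probability_branches():
    assert acceptance_probability(5.0, 3.0, 10.0) == 1.0
    assert acceptance_probability(2.0, 2.0, 1.0) == 1.0
    assert acceptance_probability(1.0, 2.0, 1.0) == pytest.approx(math.exp(-1))
    assert acceptance_probability(1.0, 2.0, 1e12) == pytest.approx(1.0, abs=1e-9)
    assert acceptance_probability(1.0, 2.0, 1e-12) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        acceptance_probability(1.0, 2.0, 0.0)
    with pytest.raises(ValueError):
        acceptance_probability(1.0, 2.0, -1.0)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    e_old=st.floats(0, 1e6),
    e_new=st.floats(0, 1e6),
    t=st.floats(1e-9, 1e9),
)
def test_acceptance_probability_is_a_probability(e_old, e_new, t):
    p = acceptance_probability(e_old, e_new, t)
    assert 0.0 <= p <= 1.0
    if e_old >= e_new:
        assert p == 1.0
    else:
        assert p < 1.0 or (e_new - e_old) / t < 1e-15  # underflow of exp(-x)


# ------------------------------------------------------------------- schedule


def test_schedule_endpoints_and_decay():
    schedule = AnnealSchedule(t_max=50000.0, t_min=0.01, steps=101)
    assert schedule.temperature(0) == pytest.approx(50000.0)
    assert schedule.temperature(100) == pytest.approx(0.01)
    # exponential decay: geometric mean at the midpoint
    assert schedule.temperature(50) == pytest.approx(
        math.sqrt(50000.0 * 0.01), rel=1e-9
    )
    with pytest.raises(ValueError):
        AnnealSchedule(t_max=1.0, t_min=2.0, steps=10)
    with pytest.raises(ValueError):
        AnnealSchedule(t_max=1.0, t_min=0.0, steps=10)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(step=st.integers(0, 99))
def test_schedule_monotone_within_bounds(step):
    schedule = AnnealSchedule(t_max=100.0, t_min=0.5, steps=100)
    t = schedule.temperature(step)
    assert 0.5 - 1e-12 <= t <= 100.0 + 1e-12
    if step > 0:
        assert t < schedule.temperature(step - 1)


# ---------------------------------------------------------------------- graph


def test_reaction_graph_currency_edges(backflow_fixture):
    graph = reaction_graph(backflow_fixture.model, backflow_fixture.currency)
    # shares only cur_atp with everything -> isolated
    assert graph.degree("NGAM") == 0
    # linear pathway sharing a real metabolite
    assert graph.has_edge("T_S", "PRE_1")
    assert graph.has_edge("PER_1", "BACK_1")  # share W_1
    assert not graph.has_edge("CF", "T_S")  # only cur_atp in common


def test_reaction_graph_hand_enumerated():
    fixture = generate_toy_model(
        ToyModelSpec(n_core_precursors=1, n_peripheral_branches=1, seed=2)
    )
    graph = reaction_graph(fixture.model, fixture.currency)
    expected = {
        frozenset(e)
        for e in [
            ("EX_S", "T_S"),       # S_e
            ("T_S", "PRE_1"),      # S_c
            ("T_S", "OV"),         # S_c
            ("PRE_1", "OV"),       # S_c
            ("PRE_1", "BIOMASS"),  # A_1
            ("PRE_1", "BR_1"),     # A_1
            ("BIOMASS", "BR_1"),   # A_1
            ("OV", "EX_O"),        # O_e
            ("BR_1", "EX_B_1"),    # B_1
            ("BR_1", "CF"),        # B_1
            ("EX_B_1", "CF"),      # B_1
        ]
    }
    assert {frozenset(e) for e in graph.edges} == expected


def test_connectivity_checks(backflow_fixture):
    model = backflow_fixture.model
    currency = backflow_fixture.currency
    assert is_connected_core(backflow_fixture.core, model, currency)
    assert is_connected_core(CoreSet(["T_S"]), model, currency)
    # EX_S and BIOMASS share no metabolite at all
    assert not is_connected_core(CoreSet(["EX_S", "BIOMASS"]), model, currency)
    # T_S is the articulation between uptake and the precursor fan
    assert not is_connected_core(
        backflow_fixture.core.without_reaction("T_S"), model, currency
    )
    with pytest.raises(ValueError):
        is_connected_core(CoreSet([]), model, currency)


# ----------------------------------------------------------------------- move


def test_move_forced_removal_at_maximum_size(backflow_fixture):
    config = AnnealConfig(minimum_overlap=0.5, maximum_size=len(backflow_fixture.core))
    # uniform 0.1 would choose addition, but the size cap forces removal
    rng = ScriptedRNG(uniforms=[0.1], integers=[3])
    moved = move_core(
        backflow_fixture.core,
        backflow_fixture.core,
        backflow_fixture.model,
        backflow_fixture.currency,
        config,
        rng,
    )
    assert len(moved) <= len(backflow_fixture.core)


def test_move_rejects_disconnecting_removal(backflow_fixture):
    config = AnnealConfig(minimum_overlap=0.0, maximum_size=100)
    members = sorted(backflow_fixture.core.reaction_ids)
    rng = ScriptedRNG(uniforms=[0.9], integers=[members.index("T_S")])
    moved = move_core(
        backflow_fixture.core,
        backflow_fixture.core,
        backflow_fixture.model,
        backflow_fixture.currency,
        config,
        rng,
    )
    assert moved is backflow_fixture.core


def test_move_rejects_overlap_violation(backflow_fixture):
    config = AnnealConfig(minimum_overlap=1.0, maximum_size=100)
    members = sorted(backflow_fixture.core.reaction_ids)
    # PRE_2's removal keeps the core connected, but overlap would drop
    rng = ScriptedRNG(uniforms=[0.9], integers=[members.index("PRE_2")])
    moved = move_core(
        backflow_fixture.core,
        backflow_fixture.core,
        backflow_fixture.model,
        backflow_fixture.currency,
        config,
        rng,
    )
    assert moved is backflow_fixture.core


def test_move_add_with_empty_boundary_returns_input(perfect_fixture):
    # perfect fixture has no boundary reactions at all
    config = AnnealConfig(minimum_overlap=0.0, maximum_size=100)
    rng = ScriptedRNG(uniforms=[0.1])
    moved = move_core(
        perfect_fixture.core,
        perfect_fixture.core,
        perfect_fixture.model,
        perfect_fixture.currency,
        config,
        rng,
    )
    assert moved is perfect_fixture.core


def test_move_addition_draws_from_boundary(backflow_fixture):
    config = AnnealConfig(minimum_overlap=0.0, maximum_size=100)
    rng = ScriptedRNG(uniforms=[0.1], integers=[0])
    moved = move_core(
        backflow_fixture.core,
        backflow_fixture.core,
        backflow_fixture.model,
        backflow_fixture.currency,
        config,
        rng,
    )
    added = moved.reaction_ids - backflow_fixture.core.reaction_ids
    assert added == {"BACK_1"}  # first of the sorted boundary {BACK_1, BR_2}


def test_move_config_validation(backflow_fixture):
    config = AnnealConfig(minimum_overlap=1.0, maximum_size=2)
    with pytest.raises(ValueError, match="maximum_size"):
        move_core(
            backflow_fixture.core,
            backflow_fixture.core,
            backflow_fixture.model,
            backflow_fixture.currency,
            config,
            np.random.default_rng(0),
        )
    with pytest.raises(ValueError):
        AnnealConfig(minimum_overlap=1.5)
    assert AnnealConfig(maximum_size=0.5).resolve_max_size(100) == 50


# --------------------------------------------------------------------- anneal


def _setup(backflow_fixture, steps=400, tmax=1.0):
    model = backflow_fixture.constrained_model()
    schedule = AnnealSchedule(t_max=tmax, t_min=1e-3, steps=steps)
    config = AnnealConfig(
        minimum_overlap=1.0, maximum_size=len(backflow_fixture.core) + 4
    )
    return model, schedule, config


def test_zero_steps_returns_initial_core(backflow_fixture):
    model, schedule, config = _setup(backflow_fixture)
    schedule = AnnealSchedule(t_max=1.0, t_min=1e-3, steps=0)
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency, schedule, config, 0
    )
    assert result.best_core.reaction_ids == backflow_fixture.core.reaction_ids
    assert result.best_energy == result.initial_energy
    assert len(result.trace) == 0


def test_trace_invariants_and_reproducibility(backflow_fixture):
    model, schedule, config = _setup(backflow_fixture)
    cache = {}
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, 42, energy_cache=cache,
    )
    trace = result.trace
    assert (trace["best_energy"].diff().dropna() <= 0).all()
    assert (trace["energy"] >= 0).all()
    assert (trace["core_size"] <= config.resolve_max_size(len(model.reactions))).all()
    assert trace["core_size"].diff().dropna().abs().max() <= 1
    assert (trace["temperature"].diff().dropna() < 0).all()
    again = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, 42,
    )
    assert result.trace.equals(again.trace)
    assert result.best_core.reaction_ids == again.best_core.reaction_ids


def test_quench_is_greedy(backflow_fixture):
    """At vanishing temperature no accepted move ever increases the energy."""
    model, _, config = _setup(backflow_fixture)
    schedule = AnnealSchedule(t_max=1e-12, t_min=1e-13, steps=200)
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency, schedule, config, 3
    )
    assert (result.trace["energy"].diff().dropna() <= 1e-12).all()


def test_best_energy_matches_independent_recompute(backflow_fixture):
    model, schedule, config = _setup(backflow_fixture)
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency, schedule, config, 5
    )
    recomputed = limit_flux_to_core(
        model, result.best_core, backflow_fixture.currency, tighten=False
    ).objective
    assert recomputed == pytest.approx(result.best_energy, abs=1e-9)
    assert is_connected_core(result.best_core, model, backflow_fixture.currency)


def test_annealer_finds_zero_energy_core(backflow_fixture):
    """Absorbing the backflow route (BACK_1 then PER_1) zeroes the inflow."""
    model, schedule, config = _setup(backflow_fixture, steps=500)
    cache = {}
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, 0, energy_cache=cache,
    )
    assert result.best_energy == pytest.approx(0.0, abs=1e-9)
    assert {"BACK_1", "PER_1"} <= result.best_core.reaction_ids


def test_faithful_pseudocode_variant_still_tracks_best(backflow_fixture):
    model, schedule, config = _setup(backflow_fixture, steps=300)
    result = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, 1, faithful_pseudocode=True,
    )
    assert result.best_energy <= result.initial_energy
    assert (result.trace["best_energy"].diff().dropna() <= 0).all()


def test_multi_seed_selects_best_and_is_nested_monotone(backflow_fixture):
    model, schedule, config = _setup(backflow_fixture, steps=150)
    cache = {}
    single = anneal_core(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, 0, energy_cache=cache,
    )
    best1, results1 = multi_seed_anneal(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, [0], energy_cache=cache,
    )
    assert best1.best_energy == single.best_energy
    assert best1.trace.equals(single.trace)
    best3, results3 = multi_seed_anneal(
        model, backflow_fixture.core, backflow_fixture.currency,
        schedule, config, [0, 1, 2], energy_cache=cache,
    )
    assert best3.best_energy <= best1.best_energy
    assert set(results3) == {0, 1, 2}
    with pytest.raises(ValueError):
        multi_seed_anneal(
            model, backflow_fixture.core, backflow_fixture.currency,
            schedule, config, [],
        )


def test_export_core_graph_categories(tmp_path, backflow_fixture):
    final = backflow_fixture.core.with_reaction("BACK_1")
    path = tmp_path / "core.graphml"
    graph = export_core_graph(
        backflow_fixture.model, backflow_fixture.currency,
        backflow_fixture.core, final, path,
    )
    assert graph.nodes["T_S"]["category"] == "initial"
    assert graph.nodes["BACK_1"]["category"] == "added"
    assert graph.nodes["PER_1"]["category"] == "peripheral"
    loaded = nx.read_graphml(path)
    assert loaded.nodes["BACK_1"]["category"] == "added"
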