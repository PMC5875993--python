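"""Simulated-annealing refinement of the core reaction set.

For a candidate core, the "energy" is the minimum total flux into the core
computed by :func:`fluxcore.fluxlimit.limit_flux_to_core` — zero for a perfect
bow tie.  The annealer explores neighbouring cores by adding a random current
boundary reaction or removing a random core reaction, accepting uphill moves
with probability exp((E_old − E_new)/t) under an exponentially decaying
temperature schedule, and returns the lowest-energy core encountered.

Moves are constrained so the search stays biologically meaningful: the core
must remain a single connected component of the reaction graph (two reactions
are adjacent iff they share a non-currency metabolite), must keep at least a
configured fraction of the initial core (so experimentally measured
metabolites stay in the model), and may not exceed a maximum size (so the
refined core stays tractable for 13C modeling).  Without these guards the
global optimum is degenerate — a single uptake reaction, or the whole model.

All randomness flows from one seed through a PCG64 generator; draws are
consumed in a fixed documented order (move type, element index, then an
acceptance uniform only for uphill proposals), so traces are reproducible
bit-for-bit across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import networkx as nx
import numpy as np
import pandas as pd

from .boundary import core_boundary
from .fluxlimit import limit_flux_to_core
from .model import CoreSet, CurrencySet

__all__ = [
    "AnnealSchedule",
    "AnnealConfig",
    "AnnealResult",
    "acceptance_probability",
    "reaction_graph",
    "is_connected_core",
    "move_core",
    "anneal_core",
    "multi_seed_anneal",
    "export_core_graph",
]


def acceptance_probability(e_old: float, e_new: float, t: float) -> float:
    """Metropolis acceptance probability at temperature *t*.

    Returns 1 when the proposal does not increase the energy (E_old >= E_new),
    otherwise exp((E_old − E_new)/t) in (0, 1).  Temperatures and energies are
    both in flux units (mmol·gDW⁻¹·h⁻¹).
    """
    if t <= 0:
        raise ValueError("temperature must be positive")
    if e_old >= e_new:
        return 1.0
    return math.exp((e_old - e_new) / t)


@dataclass(frozen=True)
class AnnealSchedule:
    """Exponentially decaying temperature schedule.

    Temperature at step k of ``steps`` is
    ``t_max * (t_min / t_max) ** (k / (steps - 1))``, i.e. it starts at
    ``t_max`` and ends exactly at ``t_min``.
    """

    t_max: float
    t_min: float
    steps: int

    def __post_init__(self):
        if not (self.t_max > self.t_min > 0):
            raise ValueError("schedule requires t_max > t_min > 0")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")

    def temperature(self, step: int) -> float:
        if self.steps <= 1:
            return self.t_max
        return self.t_max * (self.t_min / self.t_max) ** (step / (self.steps - 1))


@dataclass(frozen=True)
class AnnealConfig:
    """Move constraints for the core search.

    ``minimum_overlap`` is the fraction of the *initial* core that every
    visited core must retain (1.0 disables removals of initial-core members
    entirely).  ``maximum_size`` caps the core's reaction count; a float in
    (0, 1) is read as a fraction of the model's reactions and converted by
    floor.
    """

    minimum_overlap: float = 1.0
    maximum_size: float | int = 0.13

    def __post_init__(self):
        if not (0.0 <= self.minimum_overlap <= 1.0):
            raise ValueError("minimum_overlap must be in [0, 1]")
        if self.maximum_size <= 0:
            raise ValueError("maximum_size must be positive")

    def resolve_max_size(self, n_model_reactions: int) -> int:
        if isinstance(self.maximum_size, float) and self.maximum_size < 1.0:
            return math.floor(self.maximum_size * n_model_reactions)
        return int(self.maximum_size)


def reaction_graph(model: cobra.Model, currency: CurrencySet) -> nx.Graph:
    """Undirected graph over reactions; edge iff two reactions share at least
    one non-currency metabolite (as reactant or product of either)."""
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in model.reactions)
    for met in model.metabolites:
        if met.id in currency:
            continue
        rids = [r.id for r in met.reactions]
        for i, a in enumerate(rids):
            for b in rids[i + 1 :]:
                graph.add_edge(a, b)
    return graph


def is_connected_core(
    core: CoreSet,
    model: cobra.Model,
    currency: CurrencySet,
    graph: nx.Graph | None = None,
) -> bool:
    """True iff the core induces a single connected component of the
    reaction graph.  Raises on an empty core."""
    if len(core) == 0:
        raise ValueError("core set is empty")
    if graph is None:
        graph = reaction_graph(model, currency)
    return nx.is_connected(graph.subgraph(core.reaction_ids))


def move_core(
    core: CoreSet,
    initial_core: CoreSet,
    model: cobra.Model,
    currency: CurrencySet,
    config: AnnealConfig,
    rng: np.random.Generator,
    graph: nx.Graph | None = None,
) -> CoreSet:
    """Propose a neighbouring core differing by at most one reaction.

    A fair coin picks removal vs addition, except that a core at
    ``maximum_size`` is forced to attempt a removal.  A removal is rejected
    (input returned unchanged, the step still consumed) when it would
    disconnect the core or drop the overlap with the *initial* core below
    ``minimum_overlap``.  An addition draws uniformly from the current
    boundary reaction set; an empty boundary also returns the input
    unchanged.
    """
    max_size = config.resolve_max_size(len(model.reactions))
    if max_size < math.ceil(len(initial_core) * config.minimum_overlap):
        raise ValueError(
            "maximum_size is below the reactions minimum_overlap must retain"
        )
    if graph is None:
        graph = reaction_graph(model, currency)

    remove = rng.random() > 0.5 or len(core) >= max_size
    if remove:
        members = sorted(core.reaction_ids)
        victim = members[int(rng.integers(len(members)))]
        candidate = core.without_reaction(victim)
        if len(candidate) == 0:
            return core
        if not nx.is_connected(graph.subgraph(candidate.reaction_ids)):
            return core
        overlap = len(initial_core.reaction_ids & candidate.reaction_ids) / len(
            initial_core
        )
        if overlap < config.minimum_overlap:
            return core
        return candidate
    boundary = sorted(core_boundary(model, core, currency).reaction_ids)
    if not boundary:
        return core
    newcomer = boundary[int(rng.integers(len(boundary)))]
    return core.with_reaction(newcomer)


@dataclass
class AnnealResult:
    """Outcome of one annealing run."""

    best_core: CoreSet
    best_energy: float
    initial_energy: float
    seed: int
    trace: pd.DataFrame
    final_core: CoreSet

    def __str__(self) -> str:
        return (
            f"seed {self.seed}: energy {self.initial_energy:.6g} -> "
            f"{self.best_energy:.6g} mmol/gDW/h; best core "
            f"{len(self.best_core)} reactions"
        )


def _make_energy(model, currency, cache):
    def energy(core: CoreSet) -> float:
        key = core.reaction_ids
        if key not in cache:
            cache[key] = limit_flux_to_core(
                model, core, currency, tighten=False
            ).objective
        return cache[key]

    return energy


def anneal_core(
    model: cobra.Model,
    initial_core: CoreSet,
    currency: CurrencySet,
    schedule: AnnealSchedule,
    config: AnnealConfig,
    seed: int = 0,
    *,
    faithful_pseudocode: bool = False,
    energy_cache: dict | None = None,
) -> AnnealResult:
    """Anneal the core set, minimizing total flux into the core.

    *model* must already be measurement-constrained and feasible; the initial
    core must be connected.  Runs ``schedule.steps`` iterations of propose /
    evaluate / accept and returns the best core seen with a per-step trace
    (step, temperature, energy, core_size, accepted) suitable for plotting
    the annealing trajectory.  Rejected or invalid proposals still consume a
    step, so the temperature decays on a fixed clock.

    The reference energy for the Metropolis test is normally the energy of
    the *current* (last accepted) core.  ``faithful_pseudocode=True`` instead
    updates the reference energy to every proposal's energy regardless of
    acceptance — a quirk kept selectable for comparison; the best-so-far core
    is tracked and returned either way.

    Identical cores reuse cached LP energies (pass a shared ``energy_cache``
    dict across runs on the same model to pool them); caching cannot change
    results because the energy is a deterministic function of the core.
    """
    if not is_connected_core(initial_core, model, currency):
        raise ValueError("initial core is not connected")
    graph = reaction_graph(model, currency)
    cache = energy_cache if energy_cache is not None else {}
    energy = _make_energy(model, currency, cache)
    rng = np.random.default_rng(seed)

    current = initial_core
    current_e = energy(current)
    initial_e = current_e
    best, best_e = current, current_e
    records = []
    for step in range(schedule.steps):
        t = schedule.temperature(step)
        proposal = move_core(
            current, initial_core, model, currency, config, rng, graph
        )
        new_e = energy(proposal)
        if new_e <= current_e:
            accepted = True
        else:
            accepted = rng.random() < acceptance_probability(current_e, new_e, t)
        if accepted:
            current, current_e = proposal, new_e
            if current_e < best_e:
                best, best_e = current, current_e
        elif faithful_pseudocode:
            current_e = new_e
        records.append(
            {
                "step": step,
                "temperature": t,
                "energy": current_e,
                "core_size": len(current),
                "accepted": accepted,
                "best_energy": best_e,
            }
        )
    trace = pd.DataFrame(
        records,
        columns=[
            "step",
            "temperature",
            "energy",
            "core_size",
            "accepted",
            "best_energy",
        ],
    )
    return AnnealResult(
        best_core=best,
        best_energy=best_e,
        initial_energy=initial_e,
        seed=seed,
        trace=trace,
        final_core=current,
    )


def multi_seed_anneal(
    model: cobra.Model,
    initial_core: CoreSet,
    currency: CurrencySet,
    schedule: AnnealSchedule,
    config: AnnealConfig,
    seeds: list[int],
    **kwargs,
) -> tuple[AnnealResult, dict[int, AnnealResult]]:
    """Run :func:`anneal_core` once per seed and keep the best result.

    Runs share one energy cache (results are independent of execution order
    since each run's randomness depends only on its own seed).  Returns the
    minimum-energy result, ties broken by the earlier seed in ``seeds``, plus
    all per-seed results.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    cache: dict = kwargs.pop("energy_cache", None) or {}
    results = {
        seed: anneal_core(
            model,
            initial_core,
            currency,
            schedule,
            config,
            seed,
            energy_cache=cache,
            **kwargs,
        )
        for seed in seeds
    }
    best = min(results.values(), key=lambda r: (r.best_energy, seeds.index(r.seed)))
    return best, results


def export_core_graph(
    model: cobra.Model,
    currency: CurrencySet,
    initial_core: CoreSet,
    final_core: CoreSet | None = None,
    path: str | Path | None = None,
) -> nx.Graph:
    """Annotate the reaction graph with core membership and optionally write
    GraphML.

    Node attribute ``category`` is ``initial`` (in the starting core),
    ``added`` (in the refined core only) or ``peripheral``; layout/rendering
    is left to external tools.
    """
    graph = reaction_graph(model, currency)
    final = final_core.reaction_ids if final_core is not None else frozenset()
    for node in graph.nodes:
        if node in initial_core:
            category = "initial"
        elif node in final:
            category = "added"
        else:
            category = "peripheral"
        graph.nodes[node]["category"] = category
    if path is not None:
        nx.write_graphml(graph, str(path))
    return graph
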