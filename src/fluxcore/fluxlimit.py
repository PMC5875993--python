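"""Flux bounds into core metabolism.

Two procedures compute, for every boundary reaction, an upper bound on its
unidirectional flux component directed into the core:

* :func:`limit_flux_to_core` — a single linear program.  Every reaction is
  split into non-negative forward and reverse components; the objective
  minimizes the sum of the components that produce a non-currency core
  metabolite, subject to steady state (Sv = 0) and the measurement-constrained
  bounds.  The optimal objective is the smallest total flux from peripheral
  into core metabolism consistent with the observed growth and exchange
  fluxes — the quantitative degree to which the bow-tie approximation holds.

* :func:`legacy_limit_flux_to_core` — the sequential predecessor: each
  boundary reaction's core-directed bound is tried at quantized fractions of
  the carbon uptake rate (0, 0.05, 0.2 by default) and kept at the smallest
  level that leaves the constrained model feasible.  Kept for comparison; its
  totals are provably never below the LP optimum.

Because the LP can have alternate optima, per-reaction values at the optimum
are not unique even though the objective is.  The default output is made
deterministic by a second, FVA-style pass: with the total inflow pinned at
its optimum, each selected component is maximized individually, giving the
loosest per-reaction bound consistent with minimal total inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import cobra
import numpy as np
import pandas as pd
from optlang.symbolics import Zero
from scipy import sparse

from .boundary import BoundaryReactionSet, core_boundary
from .model import CoreSet, CurrencySet, InfeasibleModelError, is_feasible

__all__ = [
    "SplitProblem",
    "FluxLimitResult",
    "split_reversible",
    "limit_flux_to_core",
    "legacy_limit_flux_to_core",
    "compare_algorithms",
    "ZERO_TOLERANCE",
    "DEFAULT_BIG_BOUND",
]

#: a core-directed bound below this is reported as zero (solver noise floor)
ZERO_TOLERANCE = 1e-7

#: stand-in for infinite bounds, mmol·gDW⁻¹·h⁻¹ (COBRA convention)
DEFAULT_BIG_BOUND = 1000.0

#: default quantization levels of the legacy algorithm, as fractions of uptake
LEGACY_LEVELS = (0.0, 0.05, 0.2)


@dataclass
class SplitProblem:
    """Explicit unidirectional-flux LP data.

    Each reversible model reaction contributes a forward and a reverse
    non-negative component (ids ``<rid>__fwd`` / ``<rid>__rev``); irreversible
    reactions contribute one.  ``selection`` is the 0/1 vector c marking
    components whose products include a non-currency core metabolite; the LP
    minimizes ``selection @ v`` subject to ``stoichiometry @ v = 0`` and
    ``0 <= v <= upper``.
    """

    component_ids: list[str]
    metabolite_ids: list[str]
    stoichiometry: sparse.csr_matrix
    upper: np.ndarray
    selection: np.ndarray
    #: component index -> (reaction id, +1 forward / -1 reverse)
    component_map: list[tuple[str, int]]
    #: forced-direction minima (nonzero when a net bound forces flux)
    lower: np.ndarray | None = None
    boundary: BoundaryReactionSet | None = None

    def net_fluxes(self, assignment: np.ndarray) -> dict[str, float]:
        """Map a split assignment back to net reaction fluxes (fwd − rev)."""
        net: dict[str, float] = {}
        for value, (rid, sign) in zip(assignment, self.component_map):
            net[rid] = net.get(rid, 0.0) + sign * value
        return net


@dataclass
class FluxLimitResult:
    """Minimized flux bounds toward the core.

    ``objective`` is the optimal total unidirectional flux into the core
    (mmol·gDW⁻¹·h⁻¹).  ``raw_bound_toward_core`` holds one optimal solution's
    component values and sums to the objective; ``bound_toward_core`` holds
    the deterministic FVA-tightened per-reaction maxima (equal to the raw
    values when no tightening pass ran).  ``nonzero_ids`` are the reactions
    whose core-directed flux cannot be reported as zero.
    """

    objective: float
    bound_toward_core: dict[str, float]
    raw_bound_toward_core: dict[str, float]
    boundary: BoundaryReactionSet
    tightened: bool
    zero_tolerance: float = ZERO_TOLERANCE
    flagged_ids: frozenset[str] = frozenset()

    @property
    def nonzero_ids(self) -> frozenset[str]:
        return frozenset(
            rid
            for rid, b in self.bound_toward_core.items()
            if b > self.zero_tolerance
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction_id": rid, "bound_toward_core": self.bound_toward_core[rid]}
            for rid in sorted(self.bound_toward_core)
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "bound_toward_core"])


def _finite(bound: float, big: float) -> float:
    if np.isinf(bound):
        return big if bound > 0 else -big
    return bound


def split_reversible(
    model: cobra.Model,
    core: CoreSet | None = None,
    currency: CurrencySet | None = None,
    big_bound: float = DEFAULT_BIG_BOUND,
) -> SplitProblem:
    """Build the explicit split-flux LP data for *model*.

    A reaction with bounds [lb, ub] contributes a forward component on
    [max(lb, 0), max(ub, 0)] and, when lb < 0, a reverse component on
    [max(−ub, 0), −lb]; forced net fluxes (lb > 0, or ub < 0) thus become
    nonzero entries of ``lower``.  Any feasible net flux vector maps to a
    feasible split assignment and back (:meth:`SplitProblem.net_fluxes`).
    When ``core`` and ``currency`` are given, the selection vector marks the
    core-directed components of the boundary reactions.
    """
    met_ids = [m.id for m in model.metabolites]
    met_index = {mid: i for i, mid in enumerate(met_ids)}

    selection_dirs: dict[str, set[str]] = {}
    if core is not None and currency is not None:
        bset = core_boundary(model, core, currency)
        for rid in bset:
            selection_dirs[rid] = set(bset[rid].directions)
        boundary = bset
    else:
        boundary = BoundaryReactionSet()

    component_ids: list[str] = []
    component_map: list[tuple[str, int]] = []
    upper: list[float] = []
    lower: list[float] = []
    selection: list[float] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []

    for reaction in model.reactions:
        lb = _finite(reaction.lower_bound, big_bound)
        ub = _finite(reaction.upper_bound, big_bound)
        dirs = selection_dirs.get(reaction.id, set())
        col = len(component_ids)
        component_ids.append(f"{reaction.id}__fwd")
        component_map.append((reaction.id, +1))
        upper.append(max(ub, 0.0))
        lower.append(max(lb, 0.0))
        selection.append(1.0 if "forward" in dirs else 0.0)
        for met, coef in reaction.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(col)
            data.append(coef)
        if lb < 0:
            col = len(component_ids)
            component_ids.append(f"{reaction.id}__rev")
            component_map.append((reaction.id, -1))
            upper.append(-lb)
            lower.append(max(-ub, 0.0))
            selection.append(1.0 if "reverse" in dirs else 0.0)
            for met, coef in reaction.metabolites.items():
                rows.append(met_index[met.id])
                cols.append(col)
                data.append(-coef)

    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(component_ids))
    )
    return SplitProblem(
        component_ids=component_ids,
        metabolite_ids=met_ids,
        stoichiometry=S,
        upper=np.asarray(upper, dtype=float),
        selection=np.asarray(selection, dtype=float),
        component_map=component_map,
        lower=np.asarray(lower, dtype=float),
        boundary=boundary,
    )


def _selected_variables(
    model: cobra.Model, boundary: BoundaryReactionSet
) -> dict[str, list]:
    """optlang forward/reverse variables of each boundary reaction's
    core-directed direction(s)."""
    selected: dict[str, list] = {}
    for rid in boundary:
        reaction = model.reactions.get_by_id(rid)
        variables = []
        if "forward" in boundary[rid].directions:
            variables.append(reaction.forward_variable)
        if "reverse" in boundary[rid].directions:
            variables.append(reaction.reverse_variable)
        selected[rid] = variables
    return selected


def _solve_min_inflow(model: cobra.Model, selected: dict[str, list]) -> float:
    model.objective = model.problem.Objective(Zero, direction="min")
    coefficients = {}
    for variables in selected.values():
        for var in variables:
            coefficients[var] = coefficients.get(var, 0.0) + 1.0
    if coefficients:
        model.objective.set_linear_coefficients(coefficients)
    value = model.slim_optimize()
    if np.isnan(value):
        status = model.solver.status
        if status == "infeasible":
            raise InfeasibleModelError(
                "model infeasible under measurement constraints; "
                "no flux distribution meets the measured growth rate"
            )
        raise RuntimeError(
            f"flux minimization did not reach an optimum (solver status: "
            f"{status}); unbounded status indicates missing flux bounds"
        )
    return float(value)


def limit_flux_to_core(
    model: cobra.Model,
    core: CoreSet,
    currency: CurrencySet,
    *,
    tighten: bool = True,
    zero_tolerance: float = ZERO_TOLERANCE,
) -> FluxLimitResult:
    """Minimize total unidirectional flux into the core with one LP.

    *model* should already carry the measured-flux constraints
    (:func:`fluxcore.model.apply_measurements`).  Returns the optimal
    objective together with each boundary reaction's core-directed component
    value at the optimum.  With ``tighten=True`` (default) a second FVA-style
    pass pins the objective at its optimum and maximizes each selected
    component individually, making per-reaction bounds independent of solver
    arbitrariness among alternate optima; ``tighten=False`` returns the raw
    single-solution values.

    Raises :class:`InfeasibleModelError` when the constraints admit no
    solution (distinct from a merely positive objective) and ``RuntimeError``
    for an unbounded problem (missing bounds).
    """
    if len(core) == 0:
        raise ValueError("core set must be non-empty")
    boundary = core_boundary(model, core, currency)

    with model:
        selected = _selected_variables(model, boundary)
        objective = _solve_min_inflow(model, selected)
        raw = {
            rid: float(sum(var.primal for var in variables))
            for rid, variables in selected.items()
        }
        tightened = dict(raw)
        if tighten and boundary:
            constraint = model.problem.Constraint(
                Zero, lb=0.0, ub=objective + max(1e-9, 1e-9 * abs(objective))
            )
            model.add_cons_vars([constraint])
            model.solver.update()
            coefficients = {}
            for variables in selected.values():
                for var in variables:
                    coefficients[var] = coefficients.get(var, 0.0) + 1.0
            constraint.set_linear_coefficients(coefficients)
            for rid, variables in sorted(selected.items()):
                model.objective = model.problem.Objective(Zero, direction="max")
                model.objective.set_linear_coefficients(
                    {var: 1.0 for var in variables}
                )
                value = model.slim_optimize()
                tightened[rid] = 0.0 if np.isnan(value) else float(value)
            model.remove_cons_vars([constraint])

    clip = lambda b: 0.0 if b < zero_tolerance else b
    return FluxLimitResult(
        objective=objective,
        bound_toward_core={r: clip(b) for r, b in tightened.items()},
        raw_bound_toward_core=raw,
        boundary=boundary,
        tightened=tighten,
        zero_tolerance=zero_tolerance,
    )


def _clamp_toward_core(reaction: cobra.Reaction, direction: str, level: float):
    if direction == "forward":
        reaction.upper_bound = min(reaction.upper_bound, level)
        if reaction.lower_bound > level:
            reaction.lower_bound = level
    else:
        reaction.lower_bound = max(reaction.lower_bound, -level)
        if reaction.upper_bound < -level:
            reaction.upper_bound = -level


def legacy_limit_flux_to_core(
    model: cobra.Model,
    core: CoreSet,
    currency: CurrencySet,
    carbon_uptake_flux: float,
    limits: Sequence[float] | None = None,
    *,
    order: str = "lex",
    zero_tolerance: float = ZERO_TOLERANCE,
) -> FluxLimitResult:
    """Sequential quantized limiting of core-directed bounds.

    Boundary reactions are visited one at a time (lexicographic id order by
    default — the procedure is order-dependent, so the order is fixed for
    reproducibility; ``order="model"`` follows the model's reaction order).
    Each core-directed bound is set to the smallest of ``limits`` (default
    ``[0, 0.05, 0.2] * |carbon_uptake_flux|``) that keeps the
    measurement-constrained model feasible; constraints accumulate across
    reactions.  A reaction infeasible even at the largest level keeps its
    original bound and is reported in ``flagged_ids``.
    """
    if len(core) == 0:
        raise ValueError("core set must be non-empty")
    uptake = abs(carbon_uptake_flux)
    if limits is None:
        levels = [frac * uptake for frac in LEGACY_LEVELS]
    else:
        levels = sorted(float(l) for l in limits)
        if not levels or levels[0] != 0.0:
            raise ValueError("limits must be ascending and start at 0")

    boundary = core_boundary(model, core, currency)
    work = model.copy()
    if order == "lex":
        visit = sorted(boundary.reaction_ids)
    elif order == "model":
        visit = [r.id for r in model.reactions if r.id in boundary]
    else:
        raise ValueError(f"unknown order {order!r}")

    bounds: dict[str, float] = {}
    flagged: set[str] = set()
    for rid in visit:
        reaction = work.reactions.get_by_id(rid)
        original = reaction.bounds
        total = 0.0
        for direction in sorted(boundary[rid].directions):
            chosen = None
            for level in levels:
                saved = reaction.bounds
                _clamp_toward_core(reaction, direction, level)
                if is_feasible(work):
                    chosen = level
                    break
                reaction.bounds = saved
            if chosen is None:
                flagged.add(rid)
            else:
                total += chosen
        if rid in flagged:
            reaction.bounds = original
            # report the pre-existing core-directed capacity
            caps = []
            for direction in boundary[rid].directions:
                caps.append(
                    max(original[1], 0.0)
                    if direction == "forward"
                    else max(-original[0], 0.0)
                )
            bounds[rid] = float(sum(caps))
        else:
            bounds[rid] = total

    objective = float(
        sum(b for rid, b in bounds.items() if rid not in flagged)
    )
    clip = lambda b: 0.0 if b < zero_tolerance else b
    return FluxLimitResult(
        objective=objective,
        bound_toward_core={r: clip(b) for r, b in bounds.items()},
        raw_bound_toward_core=dict(bounds),
        boundary=boundary,
        tightened=False,
        zero_tolerance=zero_tolerance,
        flagged_ids=frozenset(flagged),
    )


@dataclass
class ComparisonReport:
    """Per-reaction legacy vs LP bounds and the two totals."""

    table: pd.DataFrame
    lp_total: float
    legacy_total: float

    def __str__(self) -> str:
        return (
            f"LP total inflow:     {self.lp_total:.6g} mmol/gDW/h\n"
            f"legacy total inflow: {self.legacy_total:.6g} mmol/gDW/h\n"
            f"{len(self.table)} boundary reactions"
        )


def compare_algorithms(
    model: cobra.Model,
    core: CoreSet,
    currency: CurrencySet,
    carbon_uptake_flux: float,
    limits: Sequence[float] | None = None,
) -> ComparisonReport:
    """Run both procedures and tabulate their bounds side by side.

    The LP total never exceeds the legacy total (it is the true minimum the
    legacy quantized search over-approximates); this is asserted.
    """
    lp = limit_flux_to_core(model, core, currency)
    legacy = legacy_limit_flux_to_core(
        model, core, currency, carbon_uptake_flux, limits
    )
    rids = sorted(set(lp.bound_toward_core) | set(legacy.bound_toward_core))
    table = pd.DataFrame(
        {
            "reaction_id": rids,
            "lp_bound": [lp.bound_toward_core.get(r, 0.0) for r in rids],
            "legacy_bound": [legacy.bound_toward_core.get(r, 0.0) for r in rids],
        }
    )
    assert lp.objective <= legacy.objective + 1e-6, (
        "LP optimum exceeded the legacy total; this indicates a solver failure"
    )
    return ComparisonReport(
        table=table, lp_total=lp.objective, legacy_total=legacy.objective
    )
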