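"""Model ingestion and measured-flux constraints.

The in-memory container for a genome-scale metabolic model is
:class:`cobra.Model`: its reactions carry the stoichiometry (``S_ij``), flux
bounds (``lb_j``, ``ub_j``) and reversibility, and its solver interface
represents every reaction as a pair of non-negative forward/reverse variables,
which is the split-flux form the rest of this package optimizes over.

Sign convention: exchange fluxes follow COBRA/BiGG, i.e. uptake is negative.
All fluxes are in mmol·gDW⁻¹·h⁻¹ and growth rates in h⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra
import pandas as pd

__all__ = [
    "CoreSet",
    "CurrencySet",
    "MeasuredFluxes",
    "InfeasibleModelError",
    "load_model",
    "find_biomass_reaction",
    "apply_measurements",
    "default_currency_set",
    "read_id_list",
    "read_fluxes_csv",
]


class InfeasibleModelError(RuntimeError):
    """The constrained model admits no steady-state flux distribution."""


@dataclass(frozen=True)
class CoreSet:
    """A set of reaction identifiers defining core (central carbon) metabolism."""

    reaction_ids: frozenset[str]

    def __init__(self, reaction_ids: Iterable[str]):
        object.__setattr__(self, "reaction_ids", frozenset(reaction_ids))

    def __len__(self) -> int:
        return len(self.reaction_ids)

    def __iter__(self):
        return iter(self.reaction_ids)

    def __contains__(self, rid: str) -> bool:
        return rid in self.reaction_ids

    def validate(self, model: cobra.Model) -> None:
        """Raise ``ValueError`` if any member is not a reaction of *model*."""
        known = {r.id for r in model.reactions}
        missing = sorted(self.reaction_ids - known)
        if missing:
            raise ValueError(
                f"core set contains {len(missing)} reaction id(s) absent from "
                f"the model: {missing[:10]}{'...' if len(missing) > 10 else ''}"
            )

    def with_reaction(self, rid: str) -> "CoreSet":
        return CoreSet(self.reaction_ids | {rid})

    def without_reaction(self, rid: str) -> "CoreSet":
        return CoreSet(self.reaction_ids - {rid})


@dataclass(frozen=True)
class CurrencySet:
    """Metabolite identifiers treated as carbon-free currency (ATP, NADH, ...).

    Currency metabolites participate in core reactions but cannot pass carbon
    to the metabolites whose labeling a 13C model simulates, so sharing one
    never makes a peripheral reaction a carbon route into the core.
    """

    metabolite_ids: frozenset[str]

    def __init__(self, metabolite_ids: Iterable[str]):
        object.__setattr__(self, "metabolite_ids", frozenset(metabolite_ids))

    def __len__(self) -> int:
        return len(self.metabolite_ids)

    def __iter__(self):
        return iter(self.metabolite_ids)

    def __contains__(self, mid: str) -> bool:
        return mid in self.metabolite_ids

    def validate(self, model: cobra.Model) -> "CurrencySet":
        """Drop ids unknown to *model*, warning with the rejected list."""
        known = {m.id for m in model.metabolites}
        unknown = sorted(self.metabolite_ids - known)
        if unknown:
            warnings.warn(
                f"ignoring {len(unknown)} currency metabolite id(s) not in the "
                f"model: {unknown}",
                stacklevel=2,
            )
        return CurrencySet(self.metabolite_ids & known)


@dataclass(frozen=True)
class MeasuredFluxes:
    """Measured exchange fluxes plus the growth rate.

    ``exchange_values`` maps exchange reaction id -> measured flux
    (mmol·gDW⁻¹·h⁻¹, uptake negative); ``growth_rate`` is in h⁻¹.
    ``tolerance_fraction`` widens each measurement v* into the interval
    [v*(1-tol), v*(1+tol)] (orientation fixed for negative v*); the default 0
    applies measurements as equalities.
    """

    exchange_values: Mapping[str, float]
    growth_rate: float
    tolerance_fraction: float = 0.0

    def __post_init__(self):
        if self.tolerance_fraction < 0:
            raise ValueError("tolerance_fraction must be >= 0")
        object.__setattr__(self, "exchange_values", dict(self.exchange_values))


# Base names of the shipped currency metabolites.  These are cofactors and
# ubiquitous small molecules that do not contribute carbon to the measured
# mass isotopomer distributions in a typical 13C experiment.
DEFAULT_CURRENCY_BASENAMES: tuple[str, ...] = (
    "atp", "adp", "amp",
    "nad", "nadh", "nadp", "nadph",
    "fad", "fadh2",
    "coa",
    "co2", "h2o", "h", "o2",
    "pi", "ppi",
    "q8", "q8h2",
)

# Compartment decorations seen across BiGG-style and legacy SBML identifiers.
_COMPARTMENT_PATTERNS: tuple[str, ...] = (
    "{base}_{c}", "{base}[{c}]", "{base}-{c}", "M_{base}_{c}", "{base}",
)
_COMPARTMENTS: tuple[str, ...] = ("c", "e", "p", "m", "x", "g", "r", "v", "n")


def load_model(path: str | Path, biomass_id: str | None = None) -> cobra.Model:
    """Read an SBML genome-scale model (Level 3 FBC preferred, Level 2 accepted).

    Exchange reactions are those cobra detects as single-metabolite boundary
    reactions.  The biomass reaction is resolved by ``biomass_id`` when given,
    otherwise by heuristic (see :func:`find_biomass_reaction`); the resolved id
    is stored on the returned model as ``model.biomass_id``.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If no biomass reaction can be resolved (the error names candidates),
        or bounds are inverted for some reaction.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"model file not found: {path}")
    model = cobra.io.read_sbml_model(str(path))
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"reaction {rxn.id} has lower bound {rxn.lower_bound} > upper "
                f"bound {rxn.upper_bound}"
            )
    model.biomass_id = find_biomass_reaction(model, biomass_id)
    return model


def find_biomass_reaction(model: cobra.Model, override: str | None = None) -> str:
    """Resolve the biomass reaction id.

    Priority: explicit ``override``; then the reaction carrying a nonzero
    objective coefficient; then a unique reaction whose id or name contains
    "biomass" (case-insensitive).  Anything else is a hard error listing the
    candidates considered.
    """
    if override is not None:
        if override not in {r.id for r in model.reactions}:
            raise ValueError(f"biomass reaction {override!r} not in model")
        return override
    objective = [r.id for r in model.reactions if r.objective_coefficient]
    if len(objective) == 1:
        return objective[0]
    named = [
        r.id
        for r in model.reactions
        if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower()
    ]
    if len(named) == 1:
        return named[0]
    candidates = sorted(set(objective) | set(named))
    raise ValueError(
        "cannot resolve a unique biomass reaction; pass biomass_id explicitly. "
        f"Candidates: {candidates or 'none found'}"
    )


def apply_measurements(
    model: cobra.Model,
    measured: MeasuredFluxes,
    biomass_id: str | None = None,
    *,
    growth_as_lower_bound: bool = False,
    check_feasible: bool = True,
) -> cobra.Model:
    """Return a copy of *model* constrained to the measurements.

    Each measured exchange flux v* becomes the bound interval
    [v*(1-tol), v*(1+tol)] (ends swapped when v* < 0 so lb <= ub).  The growth
    rate is fixed (lb = ub) by default: leaving growth as a lower bound only
    would let the flux-minimization LP trade growth slack against boundary
    inflow.  Set ``growth_as_lower_bound=True`` for the permissive convention.

    The input model is not modified.  Raises :class:`InfeasibleModelError` when
    the constrained model has no steady-state solution ("measurements
    inconsistent with model").
    """
    biomass_id = biomass_id or getattr(model, "biomass_id", None)
    if biomass_id is None:
        biomass_id = find_biomass_reaction(model)
    known = {r.id for r in model.reactions}
    missing = sorted(set(measured.exchange_values) - known)
    if missing:
        raise ValueError(f"measured reaction(s) not in model: {missing}")

    constrained = model.copy()
    constrained.biomass_id = biomass_id
    tol = measured.tolerance_fraction
    for rid, value in measured.exchange_values.items():
        lo, hi = value * (1 + tol), value * (1 - tol)
        if lo > hi:
            lo, hi = hi, lo
        constrained.reactions.get_by_id(rid).bounds = (lo, hi)
    mu = measured.growth_rate
    lo, hi = mu * (1 - tol), mu * (1 + tol)
    if lo > hi:
        lo, hi = hi, lo
    biomass = constrained.reactions.get_by_id(biomass_id)
    biomass.bounds = (lo, biomass.upper_bound if growth_as_lower_bound else hi)

    if check_feasible and not is_feasible(constrained):
        raise InfeasibleModelError("measurements inconsistent with model")
    return constrained


def is_feasible(model: cobra.Model) -> bool:
    """True iff the model admits any flux distribution within its bounds."""
    value = model.slim_optimize()
    return not math.isnan(value)


def default_currency_set(model: cobra.Model) -> CurrencySet:
    """Intersect the shipped currency-metabolite list with the model.

    The shipped list enumerates common cofactors (ATP/ADP/AMP, NAD(P)(H),
    FAD(H2), CoA, CO2, H2O, H+, phosphate, diphosphate, quinones) across the
    usual compartment suffix spellings.  Matching is by full metabolite
    identifier, compartment included.
    """
    candidates: set[str] = set()
    for base in DEFAULT_CURRENCY_BASENAMES:
        for comp in _COMPARTMENTS:
            for pattern in _COMPARTMENT_PATTERNS:
                candidates.add(pattern.format(base=base, c=comp))
    present = {m.id for m in model.metabolites} & candidates
    return CurrencySet(present)


def read_id_list(path: str | Path) -> list[str]:
    """Read one identifier per line; ``#`` starts a comment; blanks skipped."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.append(token)
    return ids


def read_fluxes_csv(
    path: str | Path,
    *,
    biomass_id: str | None = None,
    growth_rate: float | None = None,
    carbon_source: str | None = None,
    tolerance_fraction: float = 0.0,
) -> MeasuredFluxes:
    """Read measured fluxes from a CSV with columns ``reaction_id,flux``.

    The growth rate is taken from ``growth_rate`` if given, else from a row
    whose reaction_id equals ``biomass_id``.  When ``carbon_source`` names the
    labeled-substrate exchange reaction, a non-negative measured value for it
    triggers a warning (uptake should be negative under the COBRA convention).
    """
    df = pd.read_csv(path, comment="#")
    required = {"reaction_id", "flux"}
    if not required.issubset(df.columns):
        raise ValueError(f"fluxes CSV must have columns {sorted(required)}")
    values = dict(zip(df["reaction_id"].astype(str), df["flux"].astype(float)))

    if growth_rate is None:
        if biomass_id is not None and biomass_id in values:
            growth_rate = values.pop(biomass_id)
        else:
            raise ValueError(
                "growth rate not provided and no biomass row found in CSV"
            )
    elif biomass_id is not None:
        values.pop(biomass_id, None)

    if carbon_source is not None and carbon_source in values:
        if values[carbon_source] >= 0:
            warnings.warn(
                f"carbon source {carbon_source!r} has non-negative measured "
                f"flux {values[carbon_source]}; uptake should be negative "
                "(COBRA convention)",
                stacklevel=2,
            )
    return MeasuredFluxes(values, growth_rate, tolerance_fraction)
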