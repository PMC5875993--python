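"""Identification of core boundary reactions.

A *boundary reaction* is a non-core reaction that, in some direction allowed
by its current flux bounds, produces a non-currency metabolite participating
in a core reaction.  Such reactions are the carbon routes from peripheral into
core metabolism: under the bow-tie approximation their flux toward the core
should be zero or as small as the measured physiology allows.

Directionality is judged from the current bounds rather than the SBML
reversibility flag, so a model already constrained by measurements yields a
tighter boundary set.  Reactions that feed only currency metabolites (ATP,
NADH, ...) into the core are excluded: they exchange no carbon with the
simulated metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import cobra
import pandas as pd

from .model import CoreSet, CurrencySet

__all__ = ["BoundaryReaction", "BoundaryReactionSet", "core_boundary"]

#: bounds smaller than this (absolute) do not open a direction
_DIRECTION_EPS = 1e-12


@dataclass(frozen=True)
class BoundaryReaction:
    """Annotation for one boundary reaction.

    ``directions`` lists the allowed directions ("forward"/"reverse") in which
    the reaction produces at least one non-currency core participant, and
    ``core_metabolites`` maps each such direction to those metabolite ids.
    ``carbon_source`` marks exchange reactions (the labeled substrate uptake
    is typically expected inside the core instead).
    """

    reaction_id: str
    directions: frozenset[str]
    core_metabolites: dict[str, frozenset[str]]
    carbon_source: bool = False


@dataclass
class BoundaryReactionSet:
    """The boundary reactions of a (model, core, currency) triple."""

    reactions: dict[str, BoundaryReaction] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(sorted(self.reactions))

    def __contains__(self, rid: str) -> bool:
        return rid in self.reactions

    def __getitem__(self, rid: str) -> BoundaryReaction:
        return self.reactions[rid]

    def carbon_source_ids(self) -> frozenset[str]:
        return frozenset(
            rid for rid, ann in self.reactions.items() if ann.carbon_source
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as ``reaction_id,direction_into_core,core_metabolites_produced``."""
        rows = []
        for rid in sorted(self.reactions):
            ann = self.reactions[rid]
            for direction in sorted(ann.directions):
                rows.append(
                    {
                        "reaction_id": rid,
                        "direction_into_core": direction,
                        "core_metabolites_produced": ";".join(
                            sorted(ann.core_metabolites[direction])
                        ),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "reaction_id",
                "direction_into_core",
                "core_metabolites_produced",
            ],
        )


def _net_coefficients(reaction: cobra.Reaction) -> dict[str, float]:
    # summed so a metabolite on both sides with zero net coefficient drops out
    net: dict[str, float] = {}
    for met, coef in reaction.metabolites.items():
        net[met.id] = net.get(met.id, 0.0) + coef
    return {mid: c for mid, c in net.items() if abs(c) > _DIRECTION_EPS}


def core_metabolite_ids(
    model: cobra.Model, core: CoreSet, currency: CurrencySet
) -> frozenset[str]:
    """Non-currency metabolites participating in any core reaction.

    Participants on either side are treated symmetrically: a metabolite that a
    core reaction only produces still attracts boundary reactions, since a
    peripheral producer of it shares a carbon pool with the core.
    """
    mets: set[str] = set()
    for rid in core:
        mets.update(_net_coefficients(model.reactions.get_by_id(rid)))
    return frozenset(m for m in mets if m not in currency)


def core_boundary(
    model: cobra.Model, core: CoreSet, currency: CurrencySet
) -> BoundaryReactionSet:
    """Find every non-core reaction able to feed carbon into the core.

    For each non-core reaction, each direction open under the current bounds
    (forward when ub > 0, reverse when lb < 0) is inspected; the reaction is a
    boundary reaction if the metabolites it produces in that direction include
    a non-currency participant of a core reaction.

    Raises ``ValueError`` if the core is not a subset of the model's
    reactions.  An empty core yields an empty result with a warning.
    """
    core.validate(model)
    currency = currency.validate(model)
    result = BoundaryReactionSet()
    if len(core) == 0:
        warnings.warn("empty core set: no boundary reactions exist", stacklevel=2)
        return result

    core_mets = core_metabolite_ids(model, core, currency)
    exchange_ids = {r.id for r in model.boundary}

    for reaction in model.reactions:
        if reaction.id in core:
            continue
        net = _net_coefficients(reaction)
        directions: dict[str, frozenset[str]] = {}
        if reaction.upper_bound > _DIRECTION_EPS:
            produced = {m for m, c in net.items() if c > 0}
            hits = frozenset(produced & core_mets)
            if hits:
                directions["forward"] = hits
        if reaction.lower_bound < -_DIRECTION_EPS:
            produced = {m for m, c in net.items() if c < 0}
            hits = frozenset(produced & core_mets)
            if hits:
                directions["reverse"] = hits
        if directions:
            result.reactions[reaction.id] = BoundaryReaction(
                reaction_id=reaction.id,
                directions=frozenset(directions),
                core_metabolites=directions,
                carbon_source=reaction.id in exchange_ids,
            )
    return result
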