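"""Synthetic bow-tie models and an independent flux-minimization oracle.

:func:`generate_toy_model` builds a small metabolic network with an explicit
bow-tie architecture: a single carbon source funnels through a core of
precursor-producing reactions into biomass, peripheral branches drain core
precursors outward, and (optionally) *backflow* reactions re-enter the core
by producing a biomass precursor that nothing in the core can make.  Each
backflow with demand coefficient d forces a flux of d·μ into the core at
growth rate μ, so the minimum total inflow is known in closed form at
generation time: Σ d·μ, and exactly 0 for a perfect bow tie.

:func:`brute_force_min_inflow` recomputes that minimum along a path sharing
nothing with the main LP machinery: a dense split-flux formulation assembled
by direct iteration over the stoichiometry and solved with
``scipy.optimize.linprog`` (HiGHS).  It exists for testing only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import cobra
import numpy as np
from cobra import Metabolite, Reaction
from scipy.optimize import linprog

from .boundary import core_boundary
from .model import CoreSet, CurrencySet, MeasuredFluxes, apply_measurements

__all__ = ["ToyModelSpec", "ToyFixture", "generate_toy_model", "brute_force_min_inflow"]

_BIG = 1000.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of a synthetic bow-tie model.

    ``backflow_demands`` lists, per backflow route, the stoichiometric
    coefficient d with which biomass requires the peripherally-produced
    metabolite; each route contributes d·growth_rate to the analytic minimum
    inflow.  ``reversible_fraction`` makes that share of the peripheral
    branch reactions reversible, which enlarges the boundary set without
    changing the optimum.  Fluxes in mmol·gDW⁻¹·h⁻¹, growth in h⁻¹.
    """

    n_core_precursors: int = 3
    n_peripheral_branches: int = 2
    backflow_demands: tuple[float, ...] = ()
    reversible_fraction: float = 0.0
    seed: int = 0
    uptake_rate: float = 10.0
    growth_rate: float = 1.0
    atp_maintenance: float = 0.0

    def __post_init__(self):
        if self.n_core_precursors < 1:
            raise ValueError("need at least one core precursor")
        if not (0.0 <= self.reversible_fraction <= 1.0):
            raise ValueError("reversible_fraction must be in [0, 1]")
        if any(d <= 0 for d in self.backflow_demands):
            raise ValueError("backflow demands must be positive")

    @property
    def analytic_min_inflow(self) -> float:
        return float(sum(self.backflow_demands) * self.growth_rate)


@dataclass
class ToyFixture:
    """A generated model with its companion inputs and known optimum."""

    model: cobra.Model
    core: CoreSet
    currency: CurrencySet
    measured: MeasuredFluxes
    analytic_min_inflow: float
    spec: ToyModelSpec
    _constrained: cobra.Model | None = field(default=None, repr=False)

    def constrained_model(self) -> cobra.Model:
        """The model with measurements applied (cached)."""
        if self._constrained is None:
            self._constrained = apply_measurements(
                self.model, self.measured, biomass_id="BIOMASS"
            )
        return self._constrained

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write SBML + core.txt + currency.txt + fluxes.csv into *out_dir*."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": out / "model.xml",
            "core": out / "core.txt",
            "currency": out / "currency.txt",
            "fluxes": out / "fluxes.csv",
        }
        cobra.io.write_sbml_model(self.model, str(paths["model"]))
        paths["core"].write_text(
            "# core reaction set\n" + "\n".join(sorted(self.core)) + "\n"
        )
        paths["currency"].write_text(
            "# currency metabolites\n" + "\n".join(sorted(self.currency)) + "\n"
        )
        lines = ["reaction_id,flux"]
        for rid, value in sorted(self.measured.exchange_values.items()):
            lines.append(f"{rid},{value}")
        lines.append(f"BIOMASS,{self.measured.growth_rate}")
        paths["fluxes"].write_text("\n".join(lines) + "\n")
        return paths


def generate_toy_model(
    spec: ToyModelSpec, out_dir: str | Path | None = None
) -> ToyFixture:
    """Build a bow-tie toy model with a known minimum inflow.

    Network layout (core reactions marked *):

    *  ``EX_S``      substrate exchange (uptake, measured)
    *  ``T_S``       S_e → S_c + cur_atp (substrate funnel)
    *  ``PRE_i``     S_c → A_i (precursor synthesis, i = 1..n)
    *  ``BIOMASS``   Σ A_i + Σ d_k·X_k → ∅ (growth, measured)
    -  ``OV``/``EX_O``   overflow route draining surplus S_c
    -  ``NGAM``      cur_atp sink (maintenance; lower bound configurable)
    -  ``BR_j``/``EX_B_j``  peripheral branches off a precursor
    -  ``CF``        branch metabolite → cur_atp (currency-only feeder,
       present when branches exist; must never be a boundary reaction)
    -  ``PER_k``/``BACK_k``  backflow route k: A_1 → W_k → X_k, the only
       source of the biomass requirement X_k

    Deterministic for a fixed spec (the seed drives which branches are
    reversible); the same spec writes byte-identical SBML.  Raises
    ``ValueError`` at generation time when the demands are infeasible at the
    declared uptake and growth rates.
    """
    rng = np.random.default_rng(spec.seed)
    model = cobra.Model(f"bowtie_toy_{spec.seed}")
    model.id = f"bowtie_toy_{spec.seed}"

    def met(mid: str, compartment: str = "c") -> Metabolite:
        return Metabolite(mid, compartment=compartment)

    S_e = met("S_e", "e")
    S_c = met("S_c")
    atp = met("cur_atp")
    precursors = [met(f"A_{i}") for i in range(1, spec.n_core_precursors + 1)]
    reactions: list[Reaction] = []

    def rxn(rid: str, stoich: dict, lb: float, ub: float) -> Reaction:
        r = Reaction(rid)
        r.add_metabolites(stoich)
        r.bounds = (lb, ub)
        reactions.append(r)
        return r

    rxn("EX_S", {S_e: -1}, -_BIG, 0.0)
    rxn("T_S", {S_e: -1, S_c: 1, atp: 1}, 0.0, _BIG)
    for i, A in enumerate(precursors, start=1):
        stoich = {S_c: -1, A: 1}
        if rng.random() < 0.5:  # currency co-product on a random subset
            stoich[atp] = 1
        rxn(f"PRE_{i}", stoich, 0.0, _BIG)

    biomass_stoich: dict = {A: -1 for A in precursors}
    for k, demand in enumerate(spec.backflow_demands, start=1):
        W = met(f"W_{k}")
        X = met(f"X_{k}")
        rxn(f"PER_{k}", {precursors[0]: -1, W: 1}, 0.0, _BIG)
        rxn(f"BACK_{k}", {W: -1, X: 1}, 0.0, _BIG)
        biomass_stoich[X] = -demand
    rxn("BIOMASS", biomass_stoich, 0.0, _BIG)

    O_e = met("O_e", "e")
    rxn("OV", {S_c: -1, O_e: 1}, 0.0, _BIG)
    rxn("EX_O", {O_e: -1}, 0.0, _BIG)
    rxn("NGAM", {atp: -1}, spec.atp_maintenance, _BIG)

    branch_mets: list[Metabolite] = []
    for j in range(1, spec.n_peripheral_branches + 1):
        B = met(f"B_{j}")
        branch_mets.append(B)
        source = precursors[(j - 1) % len(precursors)]
        reversible = rng.random() < spec.reversible_fraction
        rxn(f"BR_{j}", {source: -1, B: 1}, -_BIG if reversible else 0.0, _BIG)
        rxn(f"EX_B_{j}", {B: -1}, 0.0, _BIG)
    if branch_mets:
        rxn("CF", {branch_mets[0]: -1, atp: 1}, 0.0, _BIG)

    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    model.biomass_id = "BIOMASS"

    core = CoreSet(
        ["EX_S", "T_S", "BIOMASS"]
        + [f"PRE_{i}" for i in range(1, spec.n_core_precursors + 1)]
    )
    currency = CurrencySet(["cur_atp"])
    measured = MeasuredFluxes(
        {"EX_S": -spec.uptake_rate}, spec.growth_rate, tolerance_fraction=0.0
    )

    required = spec.growth_rate * (
        spec.n_core_precursors + sum(spec.backflow_demands)
    )
    if required > spec.uptake_rate + 1e-9:
        raise ValueError(
            f"infeasible spec: growth needs {required:.4g} substrate but "
            f"uptake is {spec.uptake_rate:.4g}"
        )
    fixture = ToyFixture(
        model=model,
        core=core,
        currency=currency,
        measured=measured,
        analytic_min_inflow=spec.analytic_min_inflow,
        spec=spec,
    )
    fixture.constrained_model()  # raises InfeasibleModelError if inconsistent
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture


def brute_force_min_inflow(
    model: cobra.Model,
    core: CoreSet,
    currency: CurrencySet,
    max_reactions: int = 24,
) -> float:
    """Minimum total core-directed flux by an independent dense LP.

    Assembles the split-flux problem directly from the stoichiometry as dense
    arrays and solves with HiGHS via ``scipy.optimize.linprog`` — no shared
    code with :func:`fluxcore.fluxlimit.limit_flux_to_core` beyond the purely
    combinatorial boundary identification.  Guarded to small models; for
    testing only.
    """
    if len(model.reactions) > max_reactions:
        raise ValueError(
            f"model has {len(model.reactions)} reactions; oracle is guarded "
            f"to {max_reactions}"
        )
    bset = core_boundary(model, core, currency)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n_mets = len(met_index)

    columns: list[np.ndarray] = []
    bounds: list[tuple[float, float]] = []
    cost: list[float] = []
    for reaction in model.reactions:
        lb = max(reaction.lower_bound, -_BIG)
        ub = min(reaction.upper_bound, _BIG)
        dirs = bset[reaction.id].directions if reaction.id in bset else frozenset()
        col = np.zeros(n_mets)
        for m, coef in reaction.metabolites.items():
            col[met_index[m.id]] = coef
        columns.append(col)
        bounds.append((max(lb, 0.0), max(ub, 0.0)))
        cost.append(1.0 if "forward" in dirs else 0.0)
        if lb < 0:
            columns.append(-col)
            bounds.append((max(-ub, 0.0), -lb))
            cost.append(1.0 if "reverse" in dirs else 0.0)

    A_eq = np.column_stack(columns)
    result = linprog(
        c=np.asarray(cost),
        A_eq=A_eq,
        b_eq=np.zeros(n_mets),
        bounds=bounds,
        method="highs",
    )
    if not result.success:
        raise RuntimeError(f"oracle LP failed: {result.message}")
    return float(result.fun)
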