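"""Maximum theoretical carbon yields from stoichiometric metabolic models.

For a target metabolite, a demand (sink) reaction is added, its flux is
maximized by linear programming under the model's bounds (including any
non-growth-associated ATP maintenance the model ships with; growth is not
forced), and the carbon yield is the carbon flux into the product divided
by the total carbon influx over all uptaken carbon-bearing exchange
species (glucose and, where taken up, CO2).  The model is evaluated inside
a context so it is left unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra


class YieldError(ValueError):
    pass


@dataclass(frozen=True)
class YieldResult:
    """Maximum demand flux and theoretical carbon yield for one metabolite."""

    metabolite_id: str
    model_id: str
    demand_flux: float  # mmol / gDW / h
    carbon_yield: float  # dimensionless fraction
    carbon_influx: float  # mmol C / gDW / h


def _carbon_atoms(met: cobra.Metabolite) -> int:
    if not met.formula:
        raise YieldError(f"metabolite {met.id} has no elemental formula")
    return int(met.elements.get("C", 0))


def _total_carbon_influx(model: cobra.Model, solution) -> float:
    """Sum of carbon uptake over exchange reactions with net influx."""
    total = 0.0
    for rxn in model.boundary:
        flux = solution.fluxes[rxn.id]
        for met, coeff in rxn.metabolites.items():
            # boundary reactions are written as "met <->" (coeff -1); uptake
            # is flux < 0, adding coeff*flux = -flux of met to the system
            influx = coeff * flux
            if influx > 1e-9:
                total += influx * _carbon_atoms(met)
    return total


def max_theoretical_yield(model: cobra.Model, metabolite_id: str) -> YieldResult:
    """Maximize production of one metabolite and compute its carbon yield.

    Raises :class:`YieldError` if the metabolite is missing, has no formula,
    or the model is infeasible under its maintenance constraints.
    """
    if metabolite_id not in [m.id for m in model.metabolites]:
        raise YieldError(f"metabolite {metabolite_id!r} not in model {model.id}")
    met = model.metabolites.get_by_id(metabolite_id)
    n_carbon = _carbon_atoms(met)

    with model:
        demand = model.add_boundary(met, type="demand")
        model.objective = demand
        solution = model.optimize()
        if solution.status != "optimal":
            raise YieldError(
                f"model {model.id} infeasible when maximizing {metabolite_id}: "
                f"status {solution.status}"
            )
        flux = float(solution.objective_value)
        carbon_in = _total_carbon_influx(model, solution)

    if carbon_in <= 0:
        yield_frac = 0.0
    else:
        yield_frac = flux * n_carbon / carbon_in
    return YieldResult(
        metabolite_id=metabolite_id,
        model_id=model.id or "",
        demand_flux=flux,
        carbon_yield=yield_frac,
        carbon_influx=carbon_in,
    )


ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O"})


def filter_yield_targets(
    model: cobra.Model,
    yields: list[YieldResult],
    *,
    min_carbon: int = 2,
    max_mw: float = 300.0,
    min_yield: float = 0.10,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> list[str]:
    """Metabolites worth polymer consideration: CHNO only, at least two
    carbons, MW below 300 Da, carbon yield above 10%."""
    out = []
    for res in yields:
        met = model.metabolites.get_by_id(res.metabolite_id)
        if not met.formula:
            continue
        if set(met.elements) - set(allowed_elements):
            continue
        if met.elements.get("C", 0) < min_carbon:
            continue
        if met.formula_weight is None or met.formula_weight >= max_mw:
            continue
        if res.carbon_yield <= min_yield:
            continue
        out.append(res.metabolite_id)
    return out


def read_sbml(path: str) -> cobra.Model:
    """Load a genome-scale model from SBML."""
    return cobra.io.read_sbml_model(path)
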