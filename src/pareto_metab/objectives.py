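"""The four metabolic objectives and evaluation in objective space.

Cancer-cell metabolism is modelled as a trade-off between four demands:

1. biomass synthesis flux      (maximise)
2. ATP production, read as the flux of the ATP hydrolysis/maintenance
   reaction                    (maximise)
3. total metabolic enzyme abundance, proxied by the weighted sum of
   absolute fluxes through gene-associated reactions (a surrogate for
   the solvent-capacity/molecular-crowding limit)   (minimise)
4. total carbon uptake: carbon atoms imported per time through the
   uptake direction of exchange reactions           (minimise)

Objective units follow FBA conventions (mmol/gDW/h; carbon uptake in
mmol C/gDW/h; enzyme cost in flux units times the dimensionless weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError
from .formula import carbon_content
from .lp import FluxConfiguration, LinearFunctional
from .model import MetabolicNetwork

OBJECTIVE_NAMES = ("biomass", "atp", "enzyme_cost", "carbon_uptake")
#: orientation vector: +1 maximised, -1 minimised, in OBJECTIVE_NAMES order
OBJECTIVE_SENSES = np.array([1.0, 1.0, -1.0, -1.0])


@dataclass(frozen=True)
class ObjectiveVector:
    """A point in the 4-D objective space."""

    biomass: float
    atp: float
    enzyme_cost: float
    carbon_uptake: float

    def as_array(self) -> np.ndarray:
        return np.array([self.biomass, self.atp, self.enzyme_cost, self.carbon_uptake])

    @classmethod
    def from_array(cls, arr) -> "ObjectiveVector":
        b, a, e, c = (float(x) for x in arr)
        return cls(b, a, e, c)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Per-reaction enzyme-cost weights and per-exchange carbon coefficients."""

    enzyme_weight: Mapping[str, float] = field(default_factory=dict)
    carbon_coeff: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls, network: MetabolicNetwork) -> "ObjectiveWeights":
        """Unit weight on gene-associated reactions; carbons from formulas.

        Exchange and other non-gene-associated reactions carry no enzyme
        cost; the carbon coefficient of each exchange reaction is the
        carbon count of its exchanged metabolite (0 when the formula is
        absent, logged by the formula parser).
        """
        enzyme = {
            r.id: 1.0 for r in network.reactions if not r.gpr.is_empty
        }
        carbon = {}
        for r in network.exchange_reactions():
            met = network.exchanged_metabolite(r)
            carbon[r.id] = float(carbon_content(met.formula)) if met.formula else 0.0
        return cls(enzyme_weight=enzyme, carbon_coeff=carbon)


def build_objectives(
    network: MetabolicNetwork, weights: ObjectiveWeights | None = None
) -> dict[str, LinearFunctional]:
    """Construct the four functionals keyed by OBJECTIVE_NAMES."""
    if weights is None:
        weights = ObjectiveWeights.default(network)
    if network.biomass_reaction_id not in {r.id for r in network.reactions}:
        raise ConfigurationError("biomass reaction unresolved")
    return {
        "biomass": LinearFunctional(
            "biomass", "maximize", coefficients={network.biomass_reaction_id: 1.0}
        ),
        "atp": LinearFunctional(
            "atp", "maximize", coefficients={network.atp_hydrolysis_reaction_id: 1.0}
        ),
        "enzyme_cost": LinearFunctional(
            "enzyme_cost",
            "minimize",
            abs_coefficients={r: w for r, w in weights.enzyme_weight.items() if w > 0},
        ),
        "carbon_uptake": LinearFunctional(
            "carbon_uptake",
            "minimize",
            uptake_coefficients={r: c for r, c in weights.carbon_coeff.items() if c > 0},
        ),
    }


def evaluate_objectives(
    network: MetabolicNetwork,
    flux: FluxConfiguration | Mapping[str, float],
    weights: ObjectiveWeights | None = None,
) -> ObjectiveVector:
    """Map any flux configuration into 4-D objective space (exact, from v)."""
    if weights is None:
        weights = ObjectiveWeights.default(network)
    fx = flux.flux if isinstance(flux, FluxConfiguration) else flux
    biomass = fx[network.biomass_reaction_id]
    atp = fx[network.atp_hydrolysis_reaction_id]
    enzyme = sum(w * abs(fx[rid]) for rid, w in weights.enzyme_weight.items())
    carbon = sum(c * max(0.0, -fx[rid]) for rid, c in weights.carbon_coeff.items())
    return ObjectiveVector(float(biomass), float(atp), float(enzyme), float(carbon))


__all__ = [
    "OBJECTIVE_NAMES",
    "OBJECTIVE_SENSES",
    "ObjectiveVector",
    "ObjectiveWeights",
    "build_objectives",
    "evaluate_objectives",
]
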