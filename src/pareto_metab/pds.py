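"""Gene ablations and the Pareto deviation score (PDS).

A perturbation is simulated in three steps: (i) knock a gene down to a
fractional activity, propagate through the GPR rules and tighten the
bounds of the affected reactions; (ii) predict the perturbed flux by
MOMA from the cell line's representative flux; (iii) measure fitness
impact as the Euclidean distance from the perturbed objective point to
the sampled Pareto surface, in min-max normalised objective space
(PDS).  A flux configuration has PDS zero exactly when it sits on the
sampled surface, so genes whose ablation never moves any cell line off
the surface are called nonessential.

A raw-flux-space PDS variant is kept behind ``space="flux"`` for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cellline import CellLineModel
from .errors import GprLookupError
from .lp import FluxConfiguration, moma_solve
from .model import MetabolicNetwork
from .objectives import ObjectiveVector, ObjectiveWeights, evaluate_objectives
from .pareto import ParetoSet

_log = logging.getLogger(__name__)

TAU_PDS = 1e-6  # distances below this are clamped to zero (grid discreteness)


@dataclass
class PerturbedState:
    gene_ids: tuple[str, ...]
    knock_fraction: float
    perturbed_network: MetabolicNetwork
    perturbed_flux: FluxConfiguration
    objective_point: ObjectiveVector


@dataclass(frozen=True)
class PdsScore:
    gene_id: str
    cell_line_id: str
    pds: float


def apply_knockdown(
    network: MetabolicNetwork, gene_id: str, knock_fraction: float = 0.0
) -> MetabolicNetwork:
    """Tighten reaction bounds after one gene drops to ``knock_fraction``."""
    return apply_knockdowns(network, {gene_id: knock_fraction})


def apply_knockdowns(
    network: MetabolicNetwork, fractions: Mapping[str, float]
) -> MetabolicNetwork:
    """Joint knockdown: bounds of each GPR-carrying reaction scale by the
    rule's residual activity (AND = min, OR = max); reactions without a
    GPR are untouched, and bounds are only ever tightened."""
    known = set(network.genes)
    unknown = [g for g in fractions if g not in known]
    if unknown:
        raise GprLookupError(f"genes not in model: {unknown}")
    for g, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"knock_fraction for {g} must be in [0, 1], got {f}")
    new_bounds: dict[str, tuple[float, float]] = {}
    for rxn in network.reactions:
        if rxn.gpr.is_empty or not (rxn.gpr.genes & set(fractions)):
            continue
        activity = {g: fractions.get(g, 1.0) for g in rxn.gpr.genes}
        a = rxn.gpr.evaluate(activity)
        if a < 1.0:
            new_bounds[rxn.id] = (a * rxn.lower_bound, a * rxn.upper_bound)
    if not new_bounds:
        return network
    return network.with_bounds(new_bounds)


def pds_score(
    point: ObjectiveVector | np.ndarray,
    pareto: ParetoSet,
    tau_pds: float = TAU_PDS,
    space: str = "objective",
    flux: FluxConfiguration | None = None,
) -> float:
    """Distance from an objective point to the sampled Pareto surface.

    Default space: each objective min-max scaled to [0, 1] by the
    Pareto set's own normalisation (degenerate axes dropped with a
    warning); the surface is the discrete sampled solution set.
    """
    if space == "flux":
        if flux is None:
            raise ValueError("flux-space PDS needs the flux configuration")
        v = flux.as_array(pareto.reaction_ids)
        d = float(np.min(np.linalg.norm(pareto.flux_matrix() - v, axis=1)))
        return 0.0 if d < tau_pds else d
    p = point.as_array() if isinstance(point, ObjectiveVector) else np.asarray(point, float)
    scaled_front, keep = pareto.normalize(pareto.objectives)
    scaled_p, _ = pareto.normalize(p)
    d = float(np.min(np.linalg.norm(scaled_front - scaled_p, axis=1)))
    if _is_super_optimal(p, pareto):
        _log.info("PDS of a point dominating the whole sampled front (super-optimal)")
    return 0.0 if d < tau_pds else d


def _is_super_optimal(p: np.ndarray, pareto: ParetoSet) -> bool:
    from .objectives import OBJECTIVE_SENSES

    po = p * OBJECTIVE_SENSES
    fo = pareto.objectives * OBJECTIVE_SENSES
    return bool(np.all(po >= fo.max(axis=0)) and np.any(po > fo.max(axis=0)))


def perturb_and_score(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    reference_flux: FluxConfiguration,
    fractions: Mapping[str, float],
    weights: ObjectiveWeights | None = None,
    tau_pds: float = TAU_PDS,
) -> PerturbedState:
    """Knock down a gene set, re-predict flux by MOMA, evaluate objectives."""
    if weights is None:
        weights = ObjectiveWeights.default(network)
    perturbed = apply_knockdowns(network, fractions)
    if perturbed is network:  # bounds unchanged -> reference remains optimal
        flux = reference_flux
    else:
        flux = moma_solve(perturbed, reference_flux)
        if not flux.is_optimal:  # pragma: no cover - guarded by v=0 feasibility
            _log.warning("MOMA infeasible after knocking %s; scoring reference", fractions)
            flux = reference_flux
    point = evaluate_objectives(network, flux, weights)
    return PerturbedState(
        gene_ids=tuple(sorted(fractions)),
        knock_fraction=min(fractions.values(), default=1.0),
        perturbed_network=perturbed,
        perturbed_flux=flux,
        objective_point=point,
    )


def gene_essentiality_screen(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    cell_line_models: Sequence[CellLineModel],
    genes: Sequence[str] | None = None,
    knock_fraction: float = 0.0,
    weights: ObjectiveWeights | None = None,
    tau_pds: float = TAU_PDS,
) -> pd.DataFrame:
    """PDS per (gene, cell line) plus an ``essential`` flag.

    A gene is essential when its ablation yields a non-zero PDS in at
    least one cell line; genes with zero PDS everywhere are
    nonessential.
    """
    if genes is None:
        genes = network.genes
    if len(genes) == 0:
        raise ValueError("empty gene list")
    if weights is None:
        weights = ObjectiveWeights.default(network)
    rows = []
    for model in cell_line_models:
        ref = pareto.fluxes[model.representative_index]
        for gene in genes:
            state = perturb_and_score(
                network, pareto, ref, {gene: knock_fraction}, weights, tau_pds
            )
            rows.append(
                {
                    "gene": gene,
                    "cell_line": model.cell_line_id,
                    "pds": pds_score(state.objective_point, pareto, tau_pds),
                }
            )
    table = pd.DataFrame(rows)
    nonzero = table.groupby("gene")["pds"].transform(lambda s: (s > 0).any())
    table["essential"] = nonzero
    return table


def essentiality_summary(screen: pd.DataFrame) -> pd.DataFrame:
    """Per-gene count of cell lines with non-zero PDS (histogram data)."""
    out = (
        screen.assign(nonzero=screen["pds"] > 0)
        .groupby("gene")
        .agg(n_nonzero_lines=("nonzero", "sum"), essential=("essential", "first"))
        .reset_index()
    )
    return out


def combinatorial_perturbation(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    cell_line_model: CellLineModel,
    gene_sets: Sequence[Sequence[str]],
    knock_fraction: float = 0.0,
    weights: ObjectiveWeights | None = None,
    tau_pds: float = TAU_PDS,
) -> list[PdsScore]:
    """PDS of joint knockdowns, one score per gene set."""
    ref = pareto.fluxes[cell_line_model.representative_index]
    scores = []
    for gene_set in gene_sets:
        if len(gene_set) == 0:
            raise ValueError("empty gene set in combinatorial perturbation")
        state = perturb_and_score(
            network, pareto, ref, {g: knock_fraction for g in gene_set}, weights, tau_pds
        )
        scores.append(
            PdsScore(
                gene_id="+".join(sorted(gene_set)),
                cell_line_id=cell_line_model.cell_line_id,
                pds=pds_score(state.objective_point, pareto, tau_pds),
            )
        )
    return scores


__all__ = [
    "TAU_PDS",
    "PerturbedState",
    "PdsScore",
    "apply_knockdown",
    "apply_knockdowns",
    "pds_score",
    "perturb_and_score",
    "gene_essentiality_screen",
    "essentiality_summary",
    "combinatorial_perturbation",
]
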