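"""Cell-line-specific models from omics profiles.

A cell line is modelled by the subset of sampled Pareto solutions whose
fluxes look most like the line's measurements: per-gene flux engagement
(the model-side analogue of enzyme abundance, assuming pathway flux
tracks the abundance of its enzymes) is compared against proteomics,
and solution exchange fluxes against measured consumption-release
(CORE) rates.  The two component scores are blended with weight
``alpha`` and the top fraction of solutions forms the cell-line model;
its predicted phenotype is the mean objective vector of that subset.

Similarity kernels: proteomic abundances are in arbitrary relative
units, so their component uses Spearman rank correlation (invariant to
any monotone rescaling).  CORE exchange rates are absolute
(mmol/gDW/h, the same units as model fluxes), so their component
defaults to Lin's concordance correlation, which — unlike any pure
correlation — penalises solutions whose fluxes have the right pattern
at the wrong magnitude.  Both kernels are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientOverlapError
from .lp import FluxConfiguration
from .model import MetabolicNetwork
from .objectives import ObjectiveVector
from .pareto import ParetoSet

_log = logging.getLogger(__name__)

MIN_SHARED = 3


@dataclass(frozen=True)
class OmicsProfile:
    """Measured enzyme abundances and/or exchange fluxes for one cell line.

    ``exchange_flux`` uses the model's sign convention: negative =
    consumption (uptake), positive = release.
    """

    cell_line_id: str
    enzyme_abundance: Mapping[str, float] = field(default_factory=dict)
    exchange_flux: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.enzyme_abundance and not self.exchange_flux:
            raise ValueError(f"profile {self.cell_line_id}: both omics maps empty")
        neg = [g for g, a in self.enzyme_abundance.items() if a < 0]
        if neg:
            raise ValueError(f"profile {self.cell_line_id}: negative abundances {neg[:3]}")


@dataclass
class CellLineModel:
    cell_line_id: str
    selected_solutions: list[int]
    similarity: list[float]
    predicted_objectives: ObjectiveVector

    @property
    def representative_index(self) -> int:
        """Index of the top-similarity Pareto solution."""
        return self.selected_solutions[0]


def pathway_flux_features(
    network: MetabolicNetwork, flux: FluxConfiguration | Mapping[str, float]
) -> dict[str, float]:
    """Per-gene flux engagement: sum of |v| over reactions whose GPR
    references the gene (0 for genes absent from every GPR)."""
    fx = flux.flux if isinstance(flux, FluxConfiguration) else flux
    features = {g: 0.0 for g in network.genes}
    for rxn in network.reactions:
        if rxn.gpr.is_empty:
            continue
        v = abs(fx[rxn.id])
        for gene in rxn.gpr.genes:
            features[gene] += v
    return features


def solution_exchange_fluxes(
    network: MetabolicNetwork, flux: FluxConfiguration | Mapping[str, float]
) -> dict[str, float]:
    """Exchange flux per extracellular metabolite (negative = consumption).

    Boundary reactions of intracellular pseudo-species (e.g. a shared
    capacity pool) are skipped: a CORE profile can only see metabolites
    that appear in the medium.
    """
    fx = flux.flux if isinstance(flux, FluxConfiguration) else flux
    out = {}
    for r in network.exchange_reactions():
        met = network.exchanged_metabolite(r)
        if met.is_extracellular:
            out[met.id] = fx[r.id]
    return out


# ---------------------------------------------------------------------------
# similarity kernels
# ---------------------------------------------------------------------------

def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) and np.ptp(x) == np.ptp(y) == 0 else 0.0
    rho = stats.spearmanr(x, y).statistic
    return 0.0 if math.isnan(rho) else float(rho)


def _concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom < 1e-300:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(2.0 * cov / denom)


_KERNELS = {"spearman": _spearman, "ccc": _concordance}


def solution_similarity(
    profile: OmicsProfile,
    solution_features: Mapping[str, float],
    solution_exchange: Mapping[str, float],
    alpha: float = 0.5,
    abundance_kernel: str = "spearman",
    exchange_kernel: str = "ccc",
) -> float:
    """Blend of abundance-vs-engagement and measured-vs-solution exchange
    agreement; a component with fewer than 3 shared items drops out and
    the other is renormalised; both insufficient raises."""
    k_ab = _KERNELS[abundance_kernel]
    k_ex = _KERNELS[exchange_kernel]
    shared_genes = sorted(set(profile.enzyme_abundance) & set(solution_features))
    shared_mets = sorted(set(profile.exchange_flux) & set(solution_exchange))
    parts: list[tuple[float, float]] = []  # (weight, score)
    if len(shared_genes) >= MIN_SHARED:
        x = np.array([profile.enzyme_abundance[g] for g in shared_genes])
        y = np.array([solution_features[g] for g in shared_genes])
        parts.append((alpha, k_ab(x, y)))
    if len(shared_mets) >= MIN_SHARED:
        x = np.array([profile.exchange_flux[m] for m in shared_mets])
        y = np.array([solution_exchange[m] for m in shared_mets])
        parts.append((1.0 - alpha, k_ex(x, y)))
    if not parts:
        raise InsufficientOverlapError(
            f"profile {profile.cell_line_id}: {len(shared_genes)} shared genes and "
            f"{len(shared_mets)} shared metabolites (< {MIN_SHARED} in both components)"
        )
    total_w = sum(w for w, _ in parts)
    return sum(w * s for w, s in parts) / total_w


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _solution_omics(network: MetabolicNetwork, pareto: ParetoSet):
    """Per-solution gene features and exchange maps, cached on the set."""
    cache = getattr(pareto, "_omics_cache", None)
    if cache is not None and cache[0] is network:
        return cache[1], cache[2]
    feats = [pathway_flux_features(network, f) for f in pareto.fluxes]
    exch = [solution_exchange_fluxes(network, f) for f in pareto.fluxes]
    pareto._omics_cache = (network, feats, exch)
    return feats, exch


def score_solutions(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    profile: OmicsProfile,
    alpha: float = 0.5,
    abundance_kernel: str = "spearman",
    exchange_kernel: str = "ccc",
) -> np.ndarray:
    feats, exch = _solution_omics(network, pareto)
    scores = np.empty(len(pareto))
    for i in range(len(pareto)):
        scores[i] = solution_similarity(
            profile,
            feats[i],
            exch[i],
            alpha=alpha,
            abundance_kernel=abundance_kernel,
            exchange_kernel=exchange_kernel,
        )
    return scores


def fit_cell_line(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    profile: OmicsProfile,
    top_fraction: float = 0.01,
    alpha: float = 0.5,
    abundance_kernel: str = "spearman",
    exchange_kernel: str = "ccc",
    tie_tol: float = 1e-12,
) -> CellLineModel:
    """Select the top ``ceil(top_fraction * N)`` solutions by similarity.

    Solutions tied (within ``tie_tol``) with the cut-off score are all
    included, so identical solutions are never split by an arbitrary
    index order.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    scores = score_solutions(
        network, pareto, profile, alpha, abundance_kernel, exchange_kernel
    )
    k = math.ceil(top_fraction * len(pareto))
    order = np.argsort(-scores, kind="stable")
    cutoff = scores[order[k - 1]]
    selected = [int(i) for i in order if scores[i] >= cutoff - tie_tol]
    mean_obj = pareto.objectives[selected].mean(axis=0)
    return CellLineModel(
        cell_line_id=profile.cell_line_id,
        selected_solutions=selected,
        similarity=[float(scores[i]) for i in selected],
        predicted_objectives=ObjectiveVector.from_array(mean_obj),
    )


def predict_growth_panel(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    profiles: Sequence[OmicsProfile],
    measured_growth: Mapping[str, float] | None = None,
    top_fraction: float = 0.01,
    alpha: float = 0.5,
    n_permutations: int = 10000,
    seed: int = 0,
    **kernel_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Predicted biomass flux per line; optionally Spearman rho + permutation
    p-value against measured growth rates."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a panel")
    rows = []
    for profile in profiles:
        model = fit_cell_line(
            network, pareto, profile, top_fraction=top_fraction, alpha=alpha, **kernel_kwargs
        )
        rows.append(
            {
                "cell_line": profile.cell_line_id,
                "predicted_biomass": model.predicted_objectives.biomass,
                "n_selected": len(model.selected_solutions),
            }
        )
    table = pd.DataFrame(rows).set_index("cell_line")
    summary: dict = {}
    if measured_growth is not None:
        common = [cl for cl in table.index if cl in measured_growth]
        pred = table.loc[common, "predicted_biomass"].to_numpy()
        meas = np.array([measured_growth[cl] for cl in common])
        if np.ptp(pred) == 0 or np.ptp(meas) == 0:
            summary = {"spearman_rho": float("nan"), "p_value": float("nan"),
                       "note": "degenerate (constant) predictions or measurements"}
            _log.warning("growth-panel correlation undefined: %s", summary["note"])
        else:
            rho = float(stats.spearmanr(pred, meas).statistic)
            rng = np.random.default_rng(seed)
            null = np.empty(n_permutations)
            for b in range(n_permutations):
                null[b] = stats.spearmanr(pred, rng.permutation(meas)).statistic
            p = float((np.sum(null >= rho) + 1) / (n_permutations + 1))
            summary = {"spearman_rho": rho, "p_value": p, "n_lines": len(common)}
    return table, summary


__all__ = [
    "OmicsProfile",
    "CellLineModel",
    "pathway_flux_features",
    "solution_exchange_fluxes",
    "solution_similarity",
    "score_solutions",
    "fit_cell_line",
    "predict_growth_panel",
]
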