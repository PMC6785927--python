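"""Metabolic target identification from Pareto-surface geometry.

The sampled Pareto surface is projected onto planes spanned by a
phenotype (growth rate, or an in-silico Warburg magnitude) and the flux
engaging one enzyme.  Per phenotype bin the extreme fluxes define an
upper and a lower envelope.  An enzyme whose *upper* envelope falls
monotonically with the phenotype is suppressing: activating it pushes
high-phenotype configurations off the surface.  An enzyme whose *lower*
envelope rises monotonically is promoting: inhibiting it selectively
penalises high-phenotype configurations.  Monotonousness is scored as
the Spearman rank correlation between bin centres and envelope values,
and a call additionally requires that most cell-line models sit close
to the relevant boundary, since only then does the perturbation
actually displace them.

The Warburg magnitude is proxied by lactate secretion over O2 uptake,
the in-silico analogue of the experimental ECAR/OCR ratio (real
extracellular acidification also carries a CO2-derived component that
the proxy ignores).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cellline import CellLineModel, pathway_flux_features
from .errors import ConfigurationError, InsufficientDataError
from .lp import TAU_FEAS, FluxConfiguration
from .model import MetabolicNetwork
from .pareto import ParetoSet

_log = logging.getLogger(__name__)

PHENOTYPES = ("growth", "warburg")
WARBURG_CEILING = 1e3

_LACTATE_PAT = re.compile(r"lac", re.IGNORECASE)
_O2_PAT = re.compile(r"^o2|_o2|\bo2\b|oxygen", re.IGNORECASE)


@dataclass
class SurfaceProjection:
    phenotype: str
    target_id: str
    points: np.ndarray          # (n, 2): phenotype value, flux value
    bin_edges: np.ndarray       # (n_bins + 1,) phenotype partition
    bin_centers: np.ndarray
    upper_envelope: np.ndarray
    lower_envelope: np.ndarray

    def bin_of(self, phenotype_value: float) -> int:
        idx = int(np.searchsorted(self.bin_edges[1:-1], phenotype_value, side="right"))
        return min(max(idx, 0), len(self.bin_centers) - 1)


@dataclass(frozen=True)
class TargetCall:
    enzyme_id: str
    phenotype: str
    direction: str                      # promoting | suppressing | none
    monotonousness: float
    boundary_proximity_fraction: float
    reason: str = ""


def _find_exchange(network: MetabolicNetwork, pattern: re.Pattern, label: str) -> str:
    hits = [
        r.id
        for r in network.exchange_reactions()
        if pattern.search(network.exchanged_metabolite(r).id)
        or pattern.search(network.exchanged_metabolite(r).name or "")
    ]
    if not hits:
        raise ConfigurationError(f"no {label} exchange reaction found; pass its id explicitly")
    if len(hits) > 1:
        _log.warning("multiple %s exchanges %s; using %s", label, hits, hits[0])
    return hits[0]


def warburg_metric(
    network: MetabolicNetwork,
    flux: FluxConfiguration | Mapping[str, float],
    lactate_exchange: str | None = None,
    o2_exchange: str | None = None,
    ceiling: float = WARBURG_CEILING,
    tol: float = TAU_FEAS,
) -> float:
    """Lactate secretion / O2 uptake (in-silico ECAR/OCR proxy).

    With O2 uptake below tolerance the ratio is capped at ``ceiling``
    (flagged); with *both* fluxes below tolerance the metric is
    undefined and NaN is returned — a configuration doing nothing has
    no acidification phenotype at all.
    """
    fx = flux.flux if isinstance(flux, FluxConfiguration) else flux
    lac_id = lactate_exchange or _find_exchange(network, _LACTATE_PAT, "lactate")
    o2_id = o2_exchange or _find_exchange(network, _O2_PAT, "O2")
    secretion = max(0.0, fx[lac_id])
    uptake = max(0.0, -fx[o2_id])
    if uptake <= tol:
        if secretion <= tol:
            return float("nan")
        _log.debug("O2 uptake ~0 with lactate secretion %g: metric capped", secretion)
        return ceiling
    return min(secretion / uptake, ceiling)


def _phenotype_values(
    network: MetabolicNetwork, pareto: ParetoSet, phenotype: str, **warburg_kwargs
) -> np.ndarray:
    if phenotype == "growth":
        return pareto.objectives[:, 0].copy()
    if phenotype == "warburg":
        return np.array(
            [warburg_metric(network, f, **warburg_kwargs) for f in pareto.fluxes]
        )
    raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")


def _flux_values(
    network: MetabolicNetwork, pareto: ParetoSet, target_id: str
) -> np.ndarray:
    """|flux| through a reaction, or gene-level engagement for a gene id."""
    if target_id in set(pareto.reaction_ids):
        col = pareto.reaction_ids.index(target_id)
        return np.abs(pareto.flux_matrix()[:, col])
    if target_id in set(network.genes):
        return np.array(
            [pathway_flux_features(network, f)[target_id] for f in pareto.fluxes]
        )
    raise KeyError(f"{target_id!r} is neither a reaction nor a gene of the model")


def project(
    pareto: ParetoSet,
    network: MetabolicNetwork,
    phenotype: str,
    target_id: str,
    n_bins: int = 20,
    **warburg_kwargs,
) -> SurfaceProjection:
    """Project the Pareto surface onto the (phenotype, enzyme-flux) plane.

    Equal-count binning over the phenotype axis; per-bin max/min of the
    flux value give the upper/lower envelopes.  Solutions with an
    undefined phenotype (NaN Warburg metric) are excluded.
    """
    pheno = _phenotype_values(network, pareto, phenotype, **warburg_kwargs)
    fluxval = _flux_values(network, pareto, target_id)
    ok = ~np.isnan(pheno)
    pheno, fluxval = pheno[ok], fluxval[ok]
    if len(pheno) < 2 * n_bins:
        n_bins = max(len(pheno) // 2, 1)
    if len(pheno) < 6:
        raise InsufficientDataError(
            f"{target_id}/{phenotype}: only {len(pheno)} usable solutions"
        )
    # snap phenotype values to a grid coarse enough to absorb LP jitter
    # (~1e-6 relative) so near-duplicate solutions stay in one bin
    snap = 1e-5 * max(1.0, float(np.ptp(pheno)))
    pheno = np.round(pheno / snap) * snap
    # equal-count bins via phenotype quantiles; edges collapsed by ties
    # (duplicate solutions at grid values) are dropped, merging their bins
    edges = np.unique(np.quantile(pheno, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 4:
        raise InsufficientDataError(
            f"{target_id}/{phenotype}: fewer than 3 distinct phenotype bins"
        )
    assign = np.clip(
        np.searchsorted(edges[1:-1], pheno, side="right"), 0, len(edges) - 2
    )
    groups = [np.flatnonzero(assign == b) for b in range(len(edges) - 1)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 3:
        raise InsufficientDataError(
            f"{target_id}/{phenotype}: fewer than 3 non-empty phenotype bins"
        )
    centers = np.array([pheno[g].mean() for g in groups])
    upper = np.array([fluxval[g].max() for g in groups])
    lower = np.array([fluxval[g].min() for g in groups])
    # rebuild edges consistent with the surviving bins
    edges = np.empty(len(groups) + 1)
    edges[0], edges[-1] = pheno.min(), pheno.max()
    for i in range(1, len(groups)):
        edges[i] = 0.5 * (pheno[groups[i - 1]].max() + pheno[groups[i]].min())
    return SurfaceProjection(
        phenotype=phenotype,
        target_id=target_id,
        points=np.column_stack([pheno, fluxval]),
        bin_edges=edges,
        bin_centers=centers,
        upper_envelope=upper,
        lower_envelope=lower,
    )


def monotonousness(projection: SurfaceProjection, which: str) -> float:
    """Spearman correlation of the chosen envelope with the phenotype."""
    env = _envelope(projection, which)
    if len(env) < 3:
        raise InsufficientDataError("fewer than 3 envelope points")
    if np.ptp(env) == 0:
        _log.debug("constant %s envelope for %s: score 0", which, projection.target_id)
        return 0.0
    rho = stats.spearmanr(projection.bin_centers, env).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _envelope(projection: SurfaceProjection, which: str) -> np.ndarray:
    if which == "upper":
        return projection.upper_envelope
    if which == "lower":
        return projection.lower_envelope
    raise ValueError("which must be 'upper' or 'lower'")


def boundary_proximity(
    projection: SurfaceProjection,
    representative_points: np.ndarray,
    which: str,
    tol: float = 0.25,
) -> float:
    """Fraction of cell-line points within ``tol`` of the chosen envelope.

    The envelope is interpolated linearly between bin centres and the
    distance is taken relative to the local band width (upper minus
    lower, also interpolated); a band of zero width counts as
    on-envelope.
    """
    pts = np.atleast_2d(representative_points)
    whichs = ("upper", "lower") if which == "either" else (which,)
    envs = [_envelope(projection, w) for w in whichs]
    c = projection.bin_centers
    # distances below the envelope estimator's own resolution (global flux
    # range / number of bins) cannot be distinguished from zero
    flux_range = float(projection.upper_envelope.max() - projection.lower_envelope.min())
    resolution = flux_range / max(len(c), 1)
    close = 0
    for pheno_val, flux_val in pts:
        span = float(
            np.interp(pheno_val, c, projection.upper_envelope)
            - np.interp(pheno_val, c, projection.lower_envelope)
        )
        dist = min(
            abs(flux_val - float(np.interp(pheno_val, c, env))) for env in envs
        )
        if span <= TAU_FEAS or dist <= max(tol * span, resolution):
            close += 1
    return close / len(pts)


def representative_projection_points(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    cell_line_models: Sequence[CellLineModel],
    phenotype: str,
    target_id: str,
    **warburg_kwargs,
) -> np.ndarray:
    """(phenotype, flux) coordinates of each cell line's representative
    Pareto solution; lines with undefined phenotype are dropped."""
    pheno_all = _phenotype_values(network, pareto, phenotype, **warburg_kwargs)
    flux_all = _flux_values(network, pareto, target_id)
    pts = []
    for model in cell_line_models:
        i = model.representative_index
        if not np.isnan(pheno_all[i]):
            pts.append((pheno_all[i], flux_all[i]))
    return np.array(pts) if pts else np.empty((0, 2))


def classify_targets(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    cell_line_models: Sequence[CellLineModel],
    enzymes: Sequence[str] | None = None,
    phenotypes: Sequence[str] = PHENOTYPES,
    score_cutoff: float = 0.8,
    proximity_cutoff: float = 0.5,
    proximity_tol: float = 0.25,
    proximity_mode: str = "either",
    n_bins: int = 20,
    **warburg_kwargs,
) -> list[TargetCall]:
    """Call each enzyme promoting/suppressing/none per phenotype.

    suppressing: monotonousness(upper) <= -score_cutoff (activation is
    the intervention); promoting: monotonousness(lower) >= +score_cutoff
    (inhibition is the intervention).  Either call additionally requires
    that at least ``proximity_cutoff`` of the cell-line models sit close
    to the projection boundary — by default close to the upper *or*
    lower envelope (``proximity_mode='either'``); set ``proximity_mode``
    to ``'matched'`` to demand proximity to the specific envelope whose
    trend drives the call.  When both rules fire the stronger
    monotonousness wins.
    """
    if enzymes is None:
        enzymes = network.genes
    calls: list[TargetCall] = []
    for phenotype in phenotypes:
        for enzyme in enzymes:
            try:
                proj = project(
                    pareto, network, phenotype, enzyme, n_bins=n_bins, **warburg_kwargs
                )
            except InsufficientDataError as exc:
                calls.append(
                    TargetCall(enzyme, phenotype, "none", 0.0, 0.0, reason=str(exc))
                )
                continue
            reps = representative_projection_points(
                network, pareto, cell_line_models, phenotype, enzyme, **warburg_kwargs
            )
            mono_up = monotonousness(proj, "upper")
            mono_lo = monotonousness(proj, "lower")
            if len(reps) == 0:
                prox_up = prox_lo = 0.0
            elif proximity_mode == "either":
                prox_up = prox_lo = boundary_proximity(proj, reps, "either", proximity_tol)
            else:
                prox_up = boundary_proximity(proj, reps, "upper", proximity_tol)
                prox_lo = boundary_proximity(proj, reps, "lower", proximity_tol)
            suppressing = mono_up <= -score_cutoff and prox_up >= proximity_cutoff
            promoting = mono_lo >= score_cutoff and prox_lo >= proximity_cutoff
            if suppressing and promoting:
                if abs(mono_up) >= abs(mono_lo):
                    promoting = False
                else:
                    suppressing = False
            if suppressing:
                calls.append(TargetCall(enzyme, phenotype, "suppressing", mono_up, prox_up))
            elif promoting:
                calls.append(TargetCall(enzyme, phenotype, "promoting", mono_lo, prox_lo))
            else:
                calls.append(
                    TargetCall(
                        enzyme, phenotype, "none",
                        mono_up if abs(mono_up) >= abs(mono_lo) else mono_lo,
                        max(prox_up, prox_lo),
                    )
                )
    return calls


def calls_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": c.enzyme_id,
                "phenotype": c.phenotype,
                "direction": c.direction,
                "monotonousness": c.monotonousness,
                "boundary_proximity": c.boundary_proximity_fraction,
                "reason": c.reason,
            }
            for c in calls
        ]
    )


def category_overlap(calls: Sequence[TargetCall]) -> dict:
    """Counts per (phenotype, direction) category and all pairwise overlaps.

    An enzyme can fall into several categories at once — e.g. growth-
    promoting while Warburg-suppressing ('ambiguous' class).
    """
    sets: dict[str, set[str]] = {}
    for c in calls:
        if c.direction != "none":
            sets.setdefault(f"{c.phenotype}_{c.direction}", set()).add(c.enzyme_id)
    overlap = {}
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap[f"{a}&{b}"] = sorted(sets[a] & sets[b])
    return {
        "categories": {k: sorted(v) for k, v in sets.items()},
        "counts": {k: len(v) for k, v in sets.items()},
        "overlaps": overlap,
        "ambiguous": sorted(
            sets.get("growth_promoting", set()) & sets.get("warburg_suppressing", set())
        ),
    }


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


__all__ = [
    "PHENOTYPES",
    "WARBURG_CEILING",
    "SurfaceProjection",
    "TargetCall",
    "warburg_metric",
    "project",
    "monotonousness",
    "boundary_proximity",
    "representative_projection_points",
    "classify_targets",
    "calls_table",
    "category_overlap",
    "bh_adjust",
]
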