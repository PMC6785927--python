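"""End-to-end orchestration: sample -> fit -> pds -> targets.

Each stage writes plain-text outputs (TSV/JSON) plus a manifest
carrying the full config, the model hash and package version, so any
deterministic stage can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cellline import CellLineModel, OmicsProfile, fit_cell_line
from .config import RunConfig
from .errors import ConfigurationError
from .model import MetabolicNetwork, save_tabular
from .objectives import ObjectiveWeights
from .pareto import GridSpec, epsilon_constraint_sample
from .pds import essentiality_summary, gene_essentiality_screen
from .targets import calls_table, category_overlap, classify_targets

_log = logging.getLogger(__name__)


def _model_hash(network: MetabolicNetwork) -> str:
    h = hashlib.sha1()
    for r in network.reactions:
        h.update(
            f"{r.id}|{sorted(r.stoichiometry.items())}|{r.lower_bound}|{r.upper_bound}|{r.gpr}".encode()
        )
    return h.hexdigest()


def _manifest(out: Path, stage: str, config: RunConfig, network: MetabolicNetwork, **extra):
    from . import __version__

    data = {
        "stage": stage,
        "version": __version__,
        "model": network.name,
        "model_sha1": _model_hash(network),
        "config": config.to_dict(),
    }
    data.update(extra)
    (out / f"{stage}_manifest.json").write_text(json.dumps(data, indent=2, default=str))


def read_omics_tables(
    proteomics_path: str | Path | None, core_path: str | Path | None
) -> list[OmicsProfile]:
    """Build per-line profiles from gene x cell-line and metabolite x
    cell-line TSV tables (negative CORE values = consumption)."""
    if proteomics_path is None and core_path is None:
        raise ConfigurationError("need at least one of proteomics/CORE tables")
    prot = (
        pd.read_csv(proteomics_path, sep="\t", index_col=0)
        if proteomics_path is not None
        else pd.DataFrame()
    )
    core = (
        pd.read_csv(core_path, sep="\t", index_col=0) if core_path is not None else pd.DataFrame()
    )
    lines = list(dict.fromkeys(list(prot.columns) + list(core.columns)))
    profiles = []
    for cl in lines:
        profiles.append(
            OmicsProfile(
                cl,
                enzyme_abundance=prot[cl].dropna().to_dict() if cl in prot else {},
                exchange_flux=core[cl].dropna().to_dict() if cl in core else {},
            )
        )
    return profiles


def run_pipeline(
    network: MetabolicNetwork,
    config: RunConfig,
    out_dir: str | Path,
    profiles: Sequence[OmicsProfile] | None = None,
    genes: Sequence[str] | None = None,
) -> Path:
    """Execute the full workflow into ``out_dir``; returns the run directory.

    Without omics profiles the fit/pds/target stages fall back to
    treating every sampled solution as its own 'cell line' is not
    meaningful, so profiles are required for those stages; sampling
    alone always runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_tabular(network, out / "model.tsv")

    weights = ObjectiveWeights.default(network)
    pareto = epsilon_constraint_sample(
        network,
        weights,
        GridSpec(levels=config.grid_levels),
        primary=config.primary_objective,
        tol_obj=config.tau_obj,
    )
    pareto.to_dir(out / "pareto", manifest_extra={"model_sha1": _model_hash(network)})
    _manifest(out, "sample", config, network, n_solutions=len(pareto))

    if profiles is None:
        _log.info("no omics profiles supplied: stopping after sampling")
        return out

    models: list[CellLineModel] = []
    fit_rows = []
    for profile in profiles:
        m = fit_cell_line(
            network,
            pareto,
            profile,
            top_fraction=config.top_fraction,
            alpha=config.alpha,
            abundance_kernel=config.abundance_kernel,
            exchange_kernel=config.exchange_kernel,
        )
        models.append(m)
        fit_rows.append(
            {
                "cell_line": m.cell_line_id,
                "n_selected": len(m.selected_solutions),
                "top_similarity": m.similarity[0],
                "predicted_biomass": m.predicted_objectives.biomass,
                "predicted_atp": m.predicted_objectives.atp,
                "predicted_enzyme_cost": m.predicted_objectives.enzyme_cost,
                "predicted_carbon_uptake": m.predicted_objectives.carbon_uptake,
                "selected_indices": ",".join(map(str, m.selected_solutions)),
            }
        )
    pd.DataFrame(fit_rows).to_csv(out / "cell_line_models.tsv", sep="\t", index=False)
    _manifest(out, "fit", config, network, n_lines=len(models))

    screen = gene_essentiality_screen(
        network,
        pareto,
        models,
        genes=genes,
        knock_fraction=config.knock_fraction,
        weights=weights,
        tau_pds=config.tau_pds,
    )
    screen.to_csv(out / "pds_screen.tsv", sep="\t", index=False)
    essentiality_summary(screen).to_csv(out / "pds_summary.tsv", sep="\t", index=False)
    _manifest(out, "pds", config, network, n_genes=screen["gene"].nunique())

    phenotypes = ["growth"]
    try:
        from .targets import _LACTATE_PAT, _O2_PAT, _find_exchange

        _find_exchange(network, _LACTATE_PAT, "lactate")
        _find_exchange(network, _O2_PAT, "O2")
        phenotypes.append("warburg")
    except ConfigurationError:
        _log.info("model lacks lactate/O2 exchanges; Warburg phenotype skipped")
    calls = classify_targets(
        network,
        pareto,
        models,
        enzymes=genes,
        phenotypes=tuple(phenotypes),
        score_cutoff=config.score_cutoff,
        proximity_cutoff=config.proximity_cutoff,
        proximity_tol=config.proximity_tol,
        n_bins=config.n_bins,
    )
    calls_table(calls).to_csv(out / "target_calls.tsv", sep="\t", index=False)
    (out / "target_overlap.json").write_text(
        json.dumps(category_overlap(calls), indent=2)
    )
    _manifest(out, "targets", config, network, n_calls=len(calls))
    return out


__all__ = ["run_pipeline", "read_omics_tables"]
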