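"""Genome-scale metabolic network container, readers and writers.

The network is the substrate of every LP in the package: a stoichiometric
matrix S, per-reaction flux bounds, GPR rules, and two distinguished
reactions (biomass synthesis and ATP hydrolysis/maintenance) that anchor
the maximisation objectives.  Sign conventions follow constraint-based
modelling practice: steady state S.v = 0, exchange reactions are written
with the exchanged metabolite on the left so that uptake is a negative
flux and secretion a positive one.

Two on-disk formats are supported: SBML (through cobrapy) and a plain
two-file TSV dialect designed for readable fixtures (see
:func:`load_tabular` / :func:`save_tabular`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ModelFormatError, ModelValidationError
from .formula import carbon_content, parse_formula
from .gpr import Gpr

_log = logging.getLogger(__name__)

BIOMASS_PATTERN = re.compile(r"biomass", re.IGNORECASE)
ATP_PATTERN = re.compile(r"(^atpm$)|(dm_atp)|(atp[_ ]?maint)", re.IGNORECASE)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str = ""
    is_extracellular: bool = False


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Gpr = field(default_factory=Gpr)
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


class MetabolicNetwork:
    """Validated metabolic network with index structures for fast lookup."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        biomass_reaction_id: str,
        atp_hydrolysis_reaction_id: str,
        genes: Iterable[str] = (),
        name: str = "",
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self.atp_hydrolysis_reaction_id = atp_hydrolysis_reaction_id
        self.name = name
        gpr_genes = set()
        for rxn in self.reactions:
            gpr_genes |= rxn.gpr.genes
        self.genes = sorted(set(genes) | gpr_genes)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- lookup -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchanged_metabolite(self, rxn: Reaction) -> Metabolite:
        if not rxn.is_exchange:
            raise ValueError(f"{rxn.id} is not an exchange reaction")
        (met_id,) = rxn.stoichiometry
        return self.metabolite(met_id)

    def reactions_for_gene(self, gene_id: str) -> list[Reaction]:
        return [r for r in self.reactions if gene_id in r.gpr.genes]

    # -- numerics ---------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def with_bounds(self, new_bounds: Mapping[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Copy of the network with some reaction bounds replaced."""
        reactions = [
            replace(r, lower_bound=new_bounds[r.id][0], upper_bound=new_bounds[r.id][1])
            if r.id in new_bounds
            else r
            for r in self.reactions
        ]
        return MetabolicNetwork(
            self.metabolites,
            reactions,
            self.biomass_reaction_id,
            self.atp_hydrolysis_reaction_id,
            genes=self.genes,
            name=self.name,
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if len(self._met_index) != len(self.metabolites):
            problems.append("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            problems.append("duplicate reaction ids")
        for rxn in self.reactions:
            if not rxn.stoichiometry:
                problems.append(f"reaction {rxn.id}: empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(
                    f"reaction {rxn.id}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    problems.append(f"reaction {rxn.id}: unknown metabolite {met_id}")
        for met in self.metabolites:
            if met.formula:
                try:
                    parse_formula(met.formula)
                except Exception:
                    problems.append(f"metabolite {met.id}: malformed formula {met.formula!r}")
        if self.biomass_reaction_id not in self._rxn_index:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction_id!r} not found in model"
            )
        if self.atp_hydrolysis_reaction_id not in self._rxn_index:
            raise ConfigurationError(
                f"ATP hydrolysis reaction {self.atp_hydrolysis_reaction_id!r} not found in model"
            )
        if problems:
            raise ModelValidationError("; ".join(problems))

    def validation_report(self) -> str:
        lines = [
            f"model: {self.name or '<unnamed>'}",
            f"metabolites: {len(self.metabolites)}",
            f"reactions: {len(self.reactions)} "
            f"({sum(r.is_exchange for r in self.reactions)} exchange)",
            f"genes (GPR-referenced): {count_genes(self)}",
            f"biomass reaction: {self.biomass_reaction_id}",
            f"ATP hydrolysis reaction: {self.atp_hydrolysis_reaction_id}",
            "status: OK",
        ]
        return "\n".join(lines)


def count_genes(network: MetabolicNetwork) -> int:
    """Number of distinct gene ids referenced by at least one GPR rule."""
    genes: set[str] = set()
    for rxn in network.reactions:
        genes |= rxn.gpr.genes
    return len(genes)


# ---------------------------------------------------------------------------
# auto-detection of the anchor reactions
# ---------------------------------------------------------------------------

def _detect_reaction(reactions: Sequence[Reaction], pattern: re.Pattern, label: str) -> str:
    hits = [r.id for r in reactions if pattern.search(r.id) or pattern.search(r.name or "")]
    if not hits:
        raise ConfigurationError(
            f"could not auto-detect the {label} reaction; pass its id explicitly"
        )
    if len(hits) > 1:
        _log.warning("multiple %s candidates %s; using %s", label, hits, hits[0])
    return hits[0]


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------
#
# reactions file (TSV): reaction_id  equation  lower_bound  upper_bound  gpr
#   equation: "2 A + B -> C"; "<=>" marks a reversible arrow; an exchange
#   reaction leaves one side empty ("glc_e ->").
# metabolites file (TSV, optional): metabolite_id  name  compartment  formula
#   metabolites absent from it default to empty formula; ids ending in "_e"
#   are flagged extracellular.

_ARROWS = ("<=>", "<->", "-->", "->")


def _parse_equation(equation: str, rxn_id: str) -> tuple[dict[str, float], bool]:
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelFormatError(f"reaction {rxn_id}: no arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise ModelFormatError(
                        f"reaction {rxn_id}: bad coefficient in term {term!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ModelFormatError(f"reaction {rxn_id}: cannot parse term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelFormatError(f"reaction {rxn_id}: equation {equation!r} cancels out")
    return stoich, arrow in ("<=>", "<->")


def _format_equation(rxn: Reaction) -> str:
    def side(items):
        return " + ".join(
            met if coeff == 1.0 else f"{coeff:g} {met}" for met, coeff in items
        )

    left = [(m, -c) for m, c in sorted(rxn.stoichiometry.items()) if c < 0]
    right = [(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(left)} {arrow} {side(right)}".strip()


def load_tabular(
    path: str | Path,
    metabolites_path: str | Path | None = None,
    biomass_id: str | None = None,
    atp_id: str | None = None,
    name: str = "",
) -> MetabolicNetwork:
    """Load the TSV dialect; ``<stem>_metabolites.tsv`` is picked up if present."""
    path = Path(path)
    if metabolites_path is None:
        candidate = path.with_name(path.stem + "_metabolites.tsv")
        metabolites_path = candidate if candidate.exists() else None

    met_info: dict[str, Metabolite] = {}
    if metabolites_path is not None:
        for lineno, row in _read_tsv(Path(metabolites_path)):
            if len(row) < 1:
                continue
            met_id = row[0]
            met_info[met_id] = Metabolite(
                id=met_id,
                name=row[1] if len(row) > 1 else "",
                compartment=row[2] if len(row) > 2 else "",
                formula=row[3] if len(row) > 3 else "",
                is_extracellular=(row[2] == "e") if len(row) > 2 else met_id.endswith("_e"),
            )

    reactions: list[Reaction] = []
    met_ids_seen: dict[str, None] = {}
    for lineno, row in _read_tsv(path):
        if len(row) < 4:
            raise ModelFormatError(
                f"{path}:{lineno}: expected at least 4 columns "
                "(reaction_id, equation, lb, ub[, gpr])"
            )
        rxn_id, equation = row[0], row[1]
        try:
            lb, ub = float(row[2]), float(row[3])
        except ValueError as exc:
            raise ModelFormatError(f"{path}:{lineno}: bad bounds for {rxn_id}") from exc
        gpr = Gpr.from_string(row[4] if len(row) > 4 else "")
        stoich, reversible = _parse_equation(equation, rxn_id)
        if reversible and lb >= 0:
            _log.debug("reaction %s written reversible but lb=%g", rxn_id, lb)
        # enforce uptake-negative convention on medium exchanges (boundary
        # reactions of intracellular pseudo-species are left as written)
        if len(stoich) == 1:
            ((met, coeff),) = stoich.items()
            extracellular = (
                met_info[met].is_extracellular if met in met_info else met.endswith("_e")
            )
            if coeff > 0 and extracellular:
                stoich = {met: -coeff}
                lb, ub = -ub, -lb
                _log.info("exchange %s flipped to uptake-negative convention", rxn_id)
        reactions.append(Reaction(rxn_id, stoich, lb, ub, gpr))
        for met in stoich:
            met_ids_seen.setdefault(met, None)

    metabolites = [
        met_info.get(
            met_id,
            Metabolite(id=met_id, is_extracellular=met_id.endswith("_e")),
        )
        for met_id in met_ids_seen
    ]
    biomass = biomass_id or _detect_reaction(reactions, BIOMASS_PATTERN, "biomass")
    atp = atp_id or _detect_reaction(reactions, ATP_PATTERN, "ATP hydrolysis")
    return MetabolicNetwork(metabolites, reactions, biomass, atp, name=name or path.stem)


def _read_tsv(path: Path):
    if not path.exists():
        raise ModelFormatError(f"file not found: {path}")
    with path.open() as fh:
        header_skipped = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            row = [cell.strip() for cell in line.split("\t")]
            if not header_skipped:
                header_skipped = True
                if row[0].lower() in ("reaction_id", "metabolite_id", "id"):
                    continue
            yield lineno, row


def save_tabular(network: MetabolicNetwork, path: str | Path) -> Path:
    """Write reactions + sibling metabolites TSV; returns the reactions path."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("reaction_id\tequation\tlower_bound\tupper_bound\tgpr\n")
        for rxn in network.reactions:
            fh.write(
                f"{rxn.id}\t{_format_equation(rxn)}\t{rxn.lower_bound:.10g}"
                f"\t{rxn.upper_bound:.10g}\t{rxn.gpr}\n"
            )
    met_path = path.with_name(path.stem + "_metabolites.tsv")
    with met_path.open("w") as fh:
        fh.write("metabolite_id\tname\tcompartment\tformula\n")
        for met in network.metabolites:
            comp = met.compartment or ("e" if met.is_extracellular else "c")
            fh.write(f"{met.id}\t{met.name}\t{comp}\t{met.formula}\n")
    return path


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def load_sbml(
    path: str | Path,
    biomass_id: str | None = None,
    atp_id: str | None = None,
) -> MetabolicNetwork:
    try:
        from cobra.io import read_sbml_model
    except ImportError as exc:  # pragma: no cover
        raise ModelFormatError("cobrapy is required to read SBML models") from exc
    try:
        cobra_model = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"failed to parse SBML file {path}: {exc}") from exc

    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "",
            formula=m.formula or "",
            is_extracellular=(m.compartment or "").lower().startswith("e"),
        )
        for m in cobra_model.metabolites
    ]
    reactions = []
    for r in cobra_model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        lb, ub = float(r.lower_bound), float(r.upper_bound)
        if len(stoich) == 1:
            ((met_id, coeff),) = stoich.items()
            comp = (r.metabolites and list(r.metabolites)[0].compartment) or ""
            if coeff > 0 and comp.lower().startswith("e"):
                stoich, lb, ub = {met_id: -coeff}, -ub, -lb
        reactions.append(
            Reaction(r.id, stoich, lb, ub, Gpr.from_string(r.gene_reaction_rule), name=r.name or "")
        )
    biomass = biomass_id or _detect_reaction(reactions, BIOMASS_PATTERN, "biomass")
    atp = atp_id or _detect_reaction(reactions, ATP_PATTERN, "ATP hydrolysis")
    return MetabolicNetwork(
        metabolites, reactions, biomass, atp, name=cobra_model.id or Path(path).stem
    )


def load_model(
    path: str | Path,
    format: str | None = None,
    biomass_id: str | None = None,
    atp_id: str | None = None,
) -> MetabolicNetwork:
    """Load a model in ``sbml`` or ``tabular`` format (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular"
    if format == "sbml":
        return load_sbml(path, biomass_id=biomass_id, atp_id=atp_id)
    if format == "tabular":
        return load_tabular(path, biomass_id=biomass_id, atp_id=atp_id)
    raise ModelFormatError(f"unknown model format {format!r}")


__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "load_model",
    "load_tabular",
    "load_sbml",
    "save_tabular",
    "count_genes",
    "carbon_content",
]
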