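"""pareto-metab: multi-objective flux balance analysis of cancer metabolism.

Samples Pareto-optimal flux configurations of a genome-scale metabolic
model under four objectives (maximise biomass and ATP production,
minimise enzyme cost and carbon uptake) via the epsilon-constraint
method; fits cell-line-specific models from proteomic and exometabolic
(CORE) profiles; scores gene ablations by the Pareto deviation score
(PDS, MOMA-predicted flux vs. the sampled surface); and classifies
enzymes as proliferation/Warburg promoting or suppressing from the
geometry of Pareto-surface projections.
"""

from .errors import (
    ConfigurationError,
    EmptyParetoSetError,
    FormulaError,
    GprLookupError,
    InsufficientDataError,
    InsufficientOverlapError,
    ModelFormatError,
    ModelValidationError,
    ParetoMetabError,
    SolverError,
)
from .formula import carbon_content, parse_formula
from .gpr import Gpr
from .model import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    count_genes,
    load_model,
    load_tabular,
    save_tabular,
)
from .lp import (
    AffineConstraint,
    FluxConfiguration,
    FluxProblem,
    LinearFunctional,
    fba_solve,
    is_feasible_flux,
    moma_solve,
)
from .objectives import (
    OBJECTIVE_NAMES,
    ObjectiveVector,
    ObjectiveWeights,
    build_objectives,
    evaluate_objectives,
)
from .pareto import (
    GridSpec,
    ParetoSet,
    dominates,
    epsilon_constraint_sample,
    lexicographic_cleanup,
    pareto_filter,
)
from .cellline import (
    CellLineModel,
    OmicsProfile,
    fit_cell_line,
    pathway_flux_features,
    predict_growth_panel,
    solution_similarity,
)
from .pds import (
    apply_knockdown,
    apply_knockdowns,
    combinatorial_perturbation,
    gene_essentiality_screen,
    pds_score,
)
from .targets import (
    bh_adjust,
    boundary_proximity,
    category_overlap,
    classify_targets,
    monotonousness,
    project,
    warburg_metric,
)
from .synthetic import (
    FixtureSpec,
    brute_force_pareto,
    make_fixture,
    make_synthetic_panel,
    sample_feasible_fluxes,
)


def evaluate_gpr(gpr: Gpr, gene_activity) -> float:
    """Evaluate a GPR rule on fractional gene activities (AND=min, OR=max)."""
    return gpr.evaluate(gene_activity)


__version__ = "0.1.0"
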