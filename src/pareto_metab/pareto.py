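"""Pareto-front sampling by the epsilon-constraint method.

The four-objective problem is scalarised into a collection of LPs: one
*primary* objective (biomass by default) is optimised while the other
three are held at grid levels (>= eps for maximised, <= eps for
minimised objectives).  Grid ranges come from the four single-objective
extreme solutions.  Because the epsilon-constraint method can emit
weakly-optimal points, each cell is finished with a lexicographic
clean-up (secondary minimisation of enzyme cost, then carbon uptake)
and the pooled solutions pass a final dominance filter.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyParetoSetError
from .lp import (
    OPTIMAL,
    TAU_OBJ,
    AffineConstraint,
    FluxConfiguration,
    FluxProblem,
    LinearFunctional,
    pin_constraint,
)
from .model import MetabolicNetwork
from .objectives import (
    OBJECTIVE_NAMES,
    OBJECTIVE_SENSES,
    ObjectiveVector,
    ObjectiveWeights,
    build_objectives,
    evaluate_objectives,
)

_log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

def _oriented(points: np.ndarray) -> np.ndarray:
    """Flip minimised objectives so 'larger is better' everywhere."""
    return np.asarray(points, dtype=float) * OBJECTIVE_SENSES


def dominates(a: ObjectiveVector | np.ndarray, b: ObjectiveVector | np.ndarray,
              tol: float = 0.0) -> bool:
    """True iff ``a`` is at least as good as ``b`` everywhere and strictly
    better (by more than ``tol``) in at least one objective."""
    av = a.as_array() if isinstance(a, ObjectiveVector) else np.asarray(a, dtype=float)
    bv = b.as_array() if isinstance(b, ObjectiveVector) else np.asarray(b, dtype=float)
    ao, bo = av * OBJECTIVE_SENSES, bv * OBJECTIVE_SENSES
    return bool(np.all(ao >= bo - tol) and np.any(ao > bo + tol))


def pareto_filter(points: Sequence[ObjectiveVector] | np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Indices of non-dominated points (duplicates of survivors retained)."""
    if len(points) == 0:
        return np.array([], dtype=int)
    if isinstance(points[0], ObjectiveVector):
        arr = np.array([p.as_array() for p in points])
    else:
        arr = np.asarray(points, dtype=float)
    P = _oriented(arr)
    n = len(P)
    alive = np.ones(n, dtype=bool)
    # scan in order of decreasing oriented sum: dominators come early
    order = np.argsort(-P.sum(axis=1), kind="stable")
    Ps = P[order]
    for k in range(n):
        if not alive[order[k]]:
            continue
        p = Ps[k]
        ge = np.all(Ps >= p - tol, axis=1)
        gt = np.any(Ps > p + tol, axis=1)
        if np.any(ge & gt & alive[order]):
            alive[order[k]] = False
    return np.flatnonzero(alive)


# ---------------------------------------------------------------------------
# grid + Pareto set containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Epsilon-grid: number of levels per constrained objective.

    ``levels`` is a single int applied to every constrained objective or
    a mapping objective-name -> levels; ranges default to the span of
    the four single-objective extreme solutions, overridable per
    objective via ``ranges``.
    """

    levels: int | Mapping[str, int] = 10
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def levels_for(self, name: str) -> int:
        lv = self.levels[name] if isinstance(self.levels, Mapping) else self.levels
        if lv < 2:
            raise ValueError(f"grid levels for {name} must be >= 2, got {lv}")
        return int(lv)


class ParetoSet:
    """Sampled Pareto-optimal flux configurations with their objectives."""

    def __init__(
        self,
        fluxes: Sequence[FluxConfiguration],
        objectives: np.ndarray,
        grid: GridSpec | None = None,
        n_infeasible_cells: int = 0,
        reaction_ids: Sequence[str] | None = None,
    ):
        if len(fluxes) == 0:
            raise EmptyParetoSetError("Pareto set is empty")
        self.fluxes = list(fluxes)
        self.objectives = np.asarray(objectives, dtype=float)
        assert self.objectives.shape == (len(self.fluxes), 4)
        self.grid = grid
        self.n_infeasible_cells = n_infeasible_cells
        self.reaction_ids = list(reaction_ids) if reaction_ids else sorted(self.fluxes[0].flux)

    def __len__(self) -> int:
        return len(self.fluxes)

    def objective_vector(self, i: int) -> ObjectiveVector:
        return ObjectiveVector.from_array(self.objectives[i])

    @property
    def normalization(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-objective (min, max) over the set."""
        return self.objectives.min(axis=0), self.objectives.max(axis=0)

    def normalize(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Min-max scale points; returns (scaled, mask of non-degenerate axes)."""
        lo, hi = self.normalization
        span = hi - lo
        keep = span > TAU_OBJ
        if not np.all(keep):
            _log.warning(
                "objectives %s are constant over the Pareto set and are "
                "dropped from normalised distances",
                [OBJECTIVE_NAMES[i] for i in np.flatnonzero(~keep)],
            )
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        scaled = (pts[:, keep] - lo[keep]) / span[keep]
        return scaled, keep

    def flux_matrix(self) -> np.ndarray:
        return np.array([[f.flux[rid] for rid in self.reaction_ids] for f in self.fluxes])

    # -- persistence (two TSVs + manifest) --------------------------------
    def to_dir(self, out_dir: str | Path, manifest_extra: dict | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        obj = pd.DataFrame(self.objectives, columns=list(OBJECTIVE_NAMES))
        obj.index.name = "solution"
        obj.to_csv(out / "objectives.tsv", sep="\t", float_format="%.10g")
        flux = pd.DataFrame(self.flux_matrix(), columns=self.reaction_ids)
        flux.index.name = "solution"
        flux.to_csv(out / "fluxes.tsv", sep="\t", float_format="%.10g")
        manifest = {
            "n_solutions": len(self),
            "n_infeasible_cells": self.n_infeasible_cells,
            "grid_levels": None
            if self.grid is None
            else (self.grid.levels if isinstance(self.grid.levels, int) else dict(self.grid.levels)),
            "objectives": list(OBJECTIVE_NAMES),
            "flux_table_sha1": hashlib.sha1(
                (out / "fluxes.tsv").read_bytes()
            ).hexdigest(),
        }
        manifest.update(manifest_extra or {})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "ParetoSet":
        in_dir = Path(in_dir)
        obj = pd.read_csv(in_dir / "objectives.tsv", sep="\t", index_col="solution")
        flux = pd.read_csv(in_dir / "fluxes.tsv", sep="\t", index_col="solution")
        fluxes = [
            FluxConfiguration(dict(zip(flux.columns, row)), OPTIMAL)
            for row in flux.to_numpy()
        ]
        return cls(fluxes, obj.to_numpy(), reaction_ids=list(flux.columns))


# ---------------------------------------------------------------------------
# lexicographic clean-up
# ---------------------------------------------------------------------------

def lexicographic_cleanup(
    network: MetabolicNetwork,
    objective_order: Sequence[LinearFunctional],
    epsilon_constraints: Sequence[AffineConstraint] = (),
    problem: FluxProblem | None = None,
    tol_obj: float = TAU_OBJ,
) -> FluxConfiguration:
    """Optimise objectives in sequence, pinning each attained optimum.

    Resolves alternate optima (e.g. futile cycles at the biomass
    optimum) so stored fluxes are reproducible; returns the final flux
    carrying the *first* objective's value/status.
    """
    if problem is None:
        abs_ids, upt_ids = set(), set()
        for fn in objective_order:
            abs_ids |= set(fn.abs_coefficients)
            upt_ids |= set(fn.uptake_coefficients)
        for con in epsilon_constraints:
            abs_ids |= set(con.functional.abs_coefficients)
            upt_ids |= set(con.functional.uptake_coefficients)
        problem = FluxProblem(network, abs_ids, upt_ids)
    constraints = list(epsilon_constraints)
    result: FluxConfiguration | None = None
    primary_value = None
    for k, fn in enumerate(objective_order):
        sol = problem.solve(fn, constraints)
        if not sol.is_optimal:
            return sol
        if k == 0:
            primary_value = sol.objective_value
        result = sol
        if k < len(objective_order) - 1:
            # pin an order of magnitude tighter than the dominance tolerance
            # so stored solutions stay within tol_obj of the true front
            constraints.append(pin_constraint(fn, sol.objective_value, tol_obj / 10.0))
    result.objective_name = objective_order[0].name
    result.objective_value = primary_value
    return result


# ---------------------------------------------------------------------------
# epsilon-constraint sampling
# ---------------------------------------------------------------------------

def epsilon_constraint_sample(
    network: MetabolicNetwork,
    weights: ObjectiveWeights | None = None,
    grid: GridSpec | None = None,
    primary: str = "biomass",
    tol_obj: float = TAU_OBJ,
) -> ParetoSet:
    """Sample the 4-objective Pareto front of a network.

    Steps: (i) solve the four single-objective extreme LPs to bound the
    epsilon ranges; (ii) for every grid cell solve the primary LP under
    epsilon constraints on the other three objectives, with
    lexicographic clean-up; (iii) pool with the extremes and keep the
    non-dominated points.  Deterministic for a fixed grid.
    """
    if weights is None:
        weights = ObjectiveWeights.default(network)
    if grid is None:
        grid = GridSpec()
    objectives = build_objectives(network, weights)
    if primary not in objectives:
        raise ValueError(f"unknown primary objective {primary!r}")
    problem = FluxProblem(
        network,
        abs_reactions=objectives["enzyme_cost"].abs_coefficients,
        uptake_reactions=objectives["carbon_uptake"].uptake_coefficients,
    )

    cleanup_tail = [
        objectives[name]
        for name in ("enzyme_cost", "carbon_uptake")
        if name != primary
    ]

    def solve_cell(first: str, eps_cons: list[AffineConstraint]) -> FluxConfiguration:
        order = [objectives[first]] + [fn for fn in cleanup_tail if fn.name != first]
        return lexicographic_cleanup(
            network, order, eps_cons, problem=problem, tol_obj=tol_obj
        )

    # (i) extremes
    solutions: list[FluxConfiguration] = []
    points: list[np.ndarray] = []
    extreme_points: dict[str, ObjectiveVector] = {}
    for name in OBJECTIVE_NAMES:
        sol = solve_cell(name, [])
        if not sol.is_optimal:
            raise EmptyParetoSetError(
                f"extreme problem for {name} is {sol.status}; network infeasible?"
            )
        vec = evaluate_objectives(network, sol, weights)
        extreme_points[name] = vec
        solutions.append(sol)
        points.append(vec.as_array())

    # (ii) grid
    constrained = [n for n in OBJECTIVE_NAMES if n != primary]
    axes: list[np.ndarray] = []
    for name in constrained:
        if name in grid.ranges:
            lo, hi = grid.ranges[name]
        else:
            idx = OBJECTIVE_NAMES.index(name)
            vals = [extreme_points[n].as_array()[idx] for n in OBJECTIVE_NAMES]
            lo, hi = min(vals), max(vals)
        if hi - lo <= tol_obj:
            axes.append(np.array([lo]))
        else:
            axes.append(np.linspace(lo, hi, grid.levels_for(name)))

    n_infeasible = 0
    for eps in itertools.product(*axes):
        cons = []
        for name, level in zip(constrained, eps):
            fn = objectives[name]
            op = ">=" if fn.sense == "maximize" else "<="
            cons.append(AffineConstraint(fn, op, float(level)))
        sol = solve_cell(primary, cons)
        if not sol.is_optimal:
            n_infeasible += 1
            continue
        solutions.append(sol)
        points.append(evaluate_objectives(network, sol, weights).as_array())

    arr = np.array(points)
    keep = pareto_filter(arr, tol=tol_obj)
    if len(keep) == 0:
        raise EmptyParetoSetError("no non-dominated solutions survived")
    _log.info(
        "epsilon-constraint sampling: %d LP cells (%d infeasible), %d Pareto solutions",
        int(np.prod([len(a) for a in axes])),
        n_infeasible,
        len(keep),
    )
    return ParetoSet(
        [solutions[i] for i in keep],
        arr[keep],
        grid=grid,
        n_infeasible_cells=n_infeasible,
        reaction_ids=network.reaction_ids,
    )


__all__ = [
    "dominates",
    "pareto_filter",
    "GridSpec",
    "ParetoSet",
    "lexicographic_cleanup",
    "epsilon_constraint_sample",
]
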