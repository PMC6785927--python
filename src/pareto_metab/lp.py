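"""Linear and quadratic programming core for FBA and MOMA.

All linear programs share one structure: steady-state mass balance
S.v = 0, box bounds lb <= v <= ub, plus affine side constraints.  Two
non-smooth constructs appearing in the four-objective model are realised
with auxiliary variables so everything stays linear:

* total enzyme cost  sum_i w_i |v_i|   -> slack s_i >= |v_i|
* total carbon uptake sum_j c_j max(0, -v_j) over exchanges
                                       -> slack u_j >= max(0, -v_j)

Both constructs are convex, hence valid only in *minimised* objectives
or upper-bounded constraints; that is exactly where the model uses them.

LPs are solved with scipy's HiGHS interface (deterministic); the MOMA
quadratic program (nearest feasible flux in Euclidean norm) is solved
with SLSQP, falling back to trust-constr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .errors import SolverError
from .model import MetabolicNetwork

_log = logging.getLogger(__name__)

TAU_FEAS = 1e-9   # feasibility tolerance for S.v = 0 and bounds
TAU_OBJ = 1e-6    # tolerance on objective values / dominance ties

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class FluxConfiguration:
    """A solved flux distribution over all reactions of a network."""

    flux: dict[str, float]
    status: str
    objective_value: float | None = None
    objective_name: str | None = None

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL

    def as_array(self, reaction_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.flux[rid] for rid in reaction_ids])


@dataclass(frozen=True)
class LinearFunctional:
    """Objective over fluxes: linear part + optional |v| and uptake parts."""

    name: str
    sense: str  # "maximize" | "minimize"
    coefficients: Mapping[str, float] = field(default_factory=dict)
    abs_coefficients: Mapping[str, float] = field(default_factory=dict)
    uptake_coefficients: Mapping[str, float] = field(default_factory=dict)

    def value(self, flux: Mapping[str, float]) -> float:
        """Evaluate the functional exactly on a flux dictionary."""
        total = sum(c * flux[rid] for rid, c in self.coefficients.items())
        total += sum(w * abs(flux[rid]) for rid, w in self.abs_coefficients.items())
        total += sum(c * max(0.0, -flux[rid]) for rid, c in self.uptake_coefficients.items())
        return total


@dataclass(frozen=True)
class AffineConstraint:
    """``functional <op> rhs`` with op in {"<=", ">=", "=="}."""

    functional: LinearFunctional
    op: str
    rhs: float

    def satisfied_by(self, flux: Mapping[str, float], tol: float = TAU_FEAS) -> bool:
        val = self.functional.value(flux)
        if self.op == "<=":
            return val <= self.rhs + tol
        if self.op == ">=":
            return val >= self.rhs - tol
        return abs(val - self.rhs) <= tol


def pin_constraint(functional: LinearFunctional, value: float, tol: float) -> AffineConstraint:
    """Constrain a functional to stay at an attained optimum (within tol)."""
    slack = tol * max(1.0, abs(value))
    if functional.sense == "maximize":
        return AffineConstraint(functional, ">=", value - slack)
    return AffineConstraint(functional, "<=", value + slack)


class FluxProblem:
    """Reusable LP scaffold over one network (variables v, s, u)."""

    def __init__(
        self,
        network: MetabolicNetwork,
        abs_reactions: Iterable[str] = (),
        uptake_reactions: Iterable[str] = (),
    ):
        self.network = network
        self.reaction_ids = network.reaction_ids
        self._rxn_pos = {rid: i for i, rid in enumerate(self.reaction_ids)}
        self.n = len(self.reaction_ids)
        self.abs_ids = [rid for rid in self.reaction_ids if rid in set(abs_reactions)]
        self.uptake_ids = [rid for rid in self.reaction_ids if rid in set(uptake_reactions)]
        self._abs_pos = {rid: self.n + k for k, rid in enumerate(self.abs_ids)}
        base = self.n + len(self.abs_ids)
        self._upt_pos = {rid: base + k for k, rid in enumerate(self.uptake_ids)}
        self.n_total = base + len(self.uptake_ids)

        S = network.stoichiometric_matrix()
        self.A_eq = np.hstack([S, np.zeros((S.shape[0], self.n_total - self.n))])
        self.b_eq = np.zeros(S.shape[0])

        lb, ub = network.bounds_arrays()
        big = np.maximum(np.abs(lb), np.abs(ub))
        lo = np.concatenate([lb, np.zeros(self.n_total - self.n)])
        hi = np.concatenate(
            [
                ub,
                np.array([big[self._rxn_pos[r]] for r in self.abs_ids]),
                np.array([max(0.0, -lb[self._rxn_pos[r]]) for r in self.uptake_ids]),
            ]
        )
        self.var_bounds = list(zip(lo, hi))

        rows = []
        # s_r >= v_r  and  s_r >= -v_r   (as A_ub x <= 0)
        for rid in self.abs_ids:
            for sign in (+1.0, -1.0):
                row = np.zeros(self.n_total)
                row[self._rxn_pos[rid]] = sign
                row[self._abs_pos[rid]] = -1.0
                rows.append((row, 0.0))
        # u_r >= -v_r
        for rid in self.uptake_ids:
            row = np.zeros(self.n_total)
            row[self._rxn_pos[rid]] = -1.0
            row[self._upt_pos[rid]] = -1.0
            rows.append((row, 0.0))
        self._link_rows = rows

    # -- assembling -------------------------------------------------------
    def _functional_vector(self, fn: LinearFunctional) -> np.ndarray:
        c = np.zeros(self.n_total)
        for rid, coeff in fn.coefficients.items():
            c[self._rxn_pos[rid]] += coeff
        for rid, coeff in fn.abs_coefficients.items():
            if rid not in self._abs_pos:
                raise SolverError(
                    f"|v| term on {rid} but problem built without that slack variable"
                )
            c[self._abs_pos[rid]] += coeff
        for rid, coeff in fn.uptake_coefficients.items():
            if rid not in self._upt_pos:
                raise SolverError(
                    f"uptake term on {rid} but problem built without that slack variable"
                )
            c[self._upt_pos[rid]] += coeff
        return c

    def solve(
        self,
        objective: LinearFunctional,
        constraints: Sequence[AffineConstraint] = (),
    ) -> FluxConfiguration:
        if objective.sense == "maximize" and (
            objective.abs_coefficients or objective.uptake_coefficients
        ):
            raise SolverError(
                f"objective {objective.name!r}: maximising |v|/uptake terms is non-convex"
            )
        c = self._functional_vector(objective)
        sign = -1.0 if objective.sense == "maximize" else 1.0

        A_ub_rows = [row for row, _ in self._link_rows]
        b_ub_vals = [rhs for _, rhs in self._link_rows]
        A_eq_rows, b_eq_vals = [], []
        for con in constraints:
            vec = self._functional_vector(con.functional)
            if con.op == "<=":
                A_ub_rows.append(vec)
                b_ub_vals.append(con.rhs)
            elif con.op == ">=":
                A_ub_rows.append(-vec)
                b_ub_vals.append(-con.rhs)
            elif con.op == "==":
                A_eq_rows.append(vec)
                b_eq_vals.append(con.rhs)
            else:
                raise ValueError(f"unknown constraint op {con.op!r}")

        A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
        b_ub = np.array(b_ub_vals) if b_ub_vals else None
        A_eq = self.A_eq
        b_eq = self.b_eq
        if A_eq_rows:
            A_eq = np.vstack([A_eq, np.vstack(A_eq_rows)])
            b_eq = np.concatenate([b_eq, np.array(b_eq_vals)])

        res = linprog(
            sign * c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=self.var_bounds,
            method="highs",
        )
        if res.status == 2:
            return FluxConfiguration({}, INFEASIBLE, objective_name=objective.name)
        if res.status == 3:
            return FluxConfiguration({}, UNBOUNDED, objective_name=objective.name)
        if res.status != 0:  # pragma: no cover - solver internal failures
            raise SolverError(f"LP solver failed with status {res.status}: {res.message}")
        flux = {rid: float(res.x[self._rxn_pos[rid]]) for rid in self.reaction_ids}
        return FluxConfiguration(
            flux, OPTIMAL, objective_value=objective.value(flux), objective_name=objective.name
        )


def fba_solve(
    network: MetabolicNetwork,
    objective: LinearFunctional,
    extra_constraints: Sequence[AffineConstraint] = (),
    problem: FluxProblem | None = None,
) -> FluxConfiguration:
    """Flux balance analysis: optimise one functional over the flux polytope."""
    if problem is None:
        abs_ids: set[str] = set(objective.abs_coefficients)
        upt_ids: set[str] = set(objective.uptake_coefficients)
        for con in extra_constraints:
            abs_ids |= set(con.functional.abs_coefficients)
            upt_ids |= set(con.functional.uptake_coefficients)
        problem = FluxProblem(network, abs_reactions=abs_ids, uptake_reactions=upt_ids)
    return problem.solve(objective, extra_constraints)


# ---------------------------------------------------------------------------
# MOMA
# ---------------------------------------------------------------------------

def is_feasible_flux(
    network: MetabolicNetwork, flux: Mapping[str, float], tol: float = TAU_FEAS
) -> bool:
    rids = network.reaction_ids
    v = np.array([flux[rid] for rid in rids])
    lb, ub = network.bounds_arrays()
    if np.any(v < lb - tol) or np.any(v > ub + tol):
        return False
    S = network.stoichiometric_matrix()
    return bool(np.max(np.abs(S @ v), initial=0.0) <= tol)


def moma_solve(
    network: MetabolicNetwork,
    reference_flux: FluxConfiguration | Mapping[str, float],
    tol: float = 1e-9,
) -> FluxConfiguration:
    """Minimisation of metabolic adjustment.

    Returns the feasible flux minimising the Euclidean distance
    ``sqrt(sum_i (v_i - v_i_ref)^2)`` subject to S.v = 0 and the current
    bounds; ``objective_value`` carries that distance.
    """
    ref_map = reference_flux.flux if isinstance(reference_flux, FluxConfiguration) else reference_flux
    rids = network.reaction_ids
    missing = [rid for rid in rids if rid not in ref_map]
    if missing:
        raise ValueError(f"reference flux missing reactions: {missing[:5]}")
    r = np.array([ref_map[rid] for rid in rids])
    lb, ub = network.bounds_arrays()
    S = network.stoichiometric_matrix()

    # fast exact path: a feasible reference is its own projection
    if is_feasible_flux(network, ref_map):
        return FluxConfiguration(
            {rid: float(val) for rid, val in zip(rids, r)},
            OPTIMAL,
            objective_value=0.0,
            objective_name="moma_distance",
        )

    # feasibility probe (zero objective LP)
    probe = linprog(
        np.zeros(len(rids)), A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if probe.status == 2:
        return FluxConfiguration({}, INFEASIBLE, objective_name="moma_distance")

    def fun(x):
        d = x - r
        return 0.5 * float(d @ d)

    def jac(x):
        return x - r

    x0 = np.clip(r, lb, ub)
    res = minimize(
        fun,
        x0,
        jac=jac,
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda x: S @ x, "jac": lambda x: S}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    x = res.x
    if (not res.success) or np.max(np.abs(S @ x), initial=0.0) > 1e-6:
        res2 = minimize(
            fun,
            np.asarray(probe.x),
            jac=jac,
            hess=lambda x: np.eye(len(rids)),
            bounds=Bounds(lb, ub),
            constraints=[LinearConstraint(S, 0.0, 0.0)],
            method="trust-constr",
            options={"gtol": 1e-12, "xtol": 1e-12, "maxiter": 3000},
        )
        if np.max(np.abs(S @ res2.x), initial=0.0) <= 1e-6:
            x = res2.x
        else:  # pragma: no cover
            raise SolverError("MOMA QP failed to converge to a feasible point")
    x = np.clip(x, lb, ub)
    distance = float(np.linalg.norm(x - r))
    return FluxConfiguration(
        {rid: float(val) for rid, val in zip(rids, x)},
        OPTIMAL,
        objective_value=distance,
        objective_name="moma_distance",
    )


__all__ = [
    "FluxConfiguration",
    "LinearFunctional",
    "AffineConstraint",
    "FluxProblem",
    "fba_solve",
    "moma_solve",
    "is_feasible_flux",
    "pin_constraint",
    "TAU_FEAS",
    "TAU_OBJ",
    "OPTIMAL",
    "INFEASIBLE",
    "UNBOUNDED",
]
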