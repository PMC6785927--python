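"""Synthetic fixtures: toy metabolic networks with enumerable Pareto
fronts and synthetic omics panels with known generating solutions.

Every pipeline stage can be exercised against these fixtures without
any external data.  The five named networks:

``chain-net``
    glucose -> biomass, a single path; one flux degree of freedom, so
    there is no trade-off and the front is the efficient ray.
``Y-net``
    glucose splits between a biomass path (yield 1 biomass per glucose)
    and an ATP path (yield 2 ATP per glucose); the classic two-way
    trade-off of the four-objective model.
``parallel-net``
    Y-net plus a redundant isozyme-like duplicate of the ATP path and a
    low-yield salvage route (0.25 ATP per glucose instead of 2); single
    knockouts reroute between the twin efficient paths at no fitness
    cost, while the double knockout forces flux through the wasteful
    salvage route, leaving a configuration no longer on the Pareto
    surface.
``ferm-resp-net``
    glucose fermented to lactate (cheap in catalytic capacity, poor ATP
    yield per glucose) versus respired with O2 to CO2 (capacity-hungry,
    high yield), under a shared capacity budget; biomass consumes
    glucose and ATP.  Respiration is the glucose- and carbon-efficient
    route, fermentation the capacity-efficient one, which guarantees a
    growth/Warburg trade-off: maximal growth is respiratory (glucose
    limited) while maximal ATP throughput is fermentative (capacity
    limited).
``random-net``
    seeded random sparse linear pathway network, mass-balance checked.

Substrate formulas are real (glucose C6H12O6 etc.) so the carbon-uptake
objective is non-trivial.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass


import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .cellline import (
    OmicsProfile,
    pathway_flux_features,
    solution_exchange_fluxes,
)
from .errors import ModelValidationError
from .gpr import Gpr
from .lp import OPTIMAL, TAU_OBJ, FluxConfiguration
from .model import MetabolicNetwork, Metabolite, Reaction
from .objectives import ObjectiveVector, ObjectiveWeights, evaluate_objectives
from .pareto import ParetoSet, pareto_filter

_log = logging.getLogger(__name__)

FIXTURE_NAMES = ("chain-net", "Y-net", "parallel-net", "ferm-resp-net", "random-net")

_GLC = "C6H12O6"
_LAC = "C3H6O3"


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    n_metabolites: int = 6      # random-net only
    n_reactions: int = 10       # random-net only
    bound_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}; pick one of {FIXTURE_NAMES}")


def _rxn(rid, stoich, lb, ub, gpr=""):
    return Reaction(rid, stoich, float(lb), float(ub), Gpr.from_string(gpr))


def _mets(*specs) -> list[Metabolite]:
    return [
        Metabolite(id=mid, formula=formula, compartment=comp,
                   is_extracellular=(comp == "e"))
        for mid, formula, comp in specs
    ]


def make_fixture(spec: FixtureSpec | str) -> MetabolicNetwork:
    if isinstance(spec, str):
        spec = FixtureSpec(spec)
    u = spec.bound_scale
    if spec.name == "chain-net":
        mets = _mets(("glc_e", _GLC, "e"), ("glc_c", _GLC, "c"), ("atp_c", "C10H16N5O13P3", "c"))
        rxns = [
            _rxn("EX_glc", {"glc_e": -1}, -u, 0),
            _rxn("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 100 * u, "g_tglc"),
            _rxn("BIOMASS", {"glc_c": -1}, 0, 100 * u, "g_bio"),
            _rxn("ATPM", {"atp_c": -1}, 0, 100 * u),
        ]
        return MetabolicNetwork(mets, rxns, "BIOMASS", "ATPM", name="chain-net")

    if spec.name in ("Y-net", "parallel-net"):
        mets = _mets(("glc_e", _GLC, "e"), ("glc_c", _GLC, "c"), ("atp_c", "C10H16N5O13P3", "c"))
        rxns = [
            _rxn("EX_glc", {"glc_e": -1}, -u, 0),
            _rxn("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 100 * u, "g_tglc"),
            _rxn("BIOMASS", {"glc_c": -1}, 0, 100 * u, "g_bio"),
            _rxn("ATP_SYN", {"glc_c": -1, "atp_c": 2}, 0, 100 * u, "g_atp"),
            _rxn("ATPM", {"atp_c": -1}, 0, 100 * u),
        ]
        if spec.name == "parallel-net":
            rxns.insert(
                4, _rxn("ATP_SYN2", {"glc_c": -1, "atp_c": 2}, 0, 100 * u, "g_atp2")
            )
            rxns.insert(
                5, _rxn("ATP_SALV", {"glc_c": -4, "atp_c": 1}, 0, 100 * u, "g_salv")
            )
        return MetabolicNetwork(mets, rxns, "BIOMASS", "ATPM", name=spec.name)

    if spec.name == "ferm-resp-net":
        return _ferm_resp_net(u)

    return _random_net(spec)


def _ferm_resp_net(u: float) -> MetabolicNetwork:
    """Fermentation/respiration trade-off under a capacity budget.

    Stoichiometry (per unit flux):
      FERM:  glc + 1 cap  -> 2 lac + 2 atp     (capacity-cheap, low yield)
      RESP:  glc + 6 o2 + 20 cap -> 6 co2 + 30 atp  (capacity-hungry, high yield)
      BIOMASS: 3 glc + 4 atp + 1 cap -> .
      ATPM:  1 atp + 0.5 cap -> .
    The capacity source is bounded at 1.2*u (12 by default), glucose
    uptake at u; O2 is effectively unlimited so the trade-off is set by
    the capacity budget, not by an arbitrary O2 cap.  Maintenance ATP
    hydrolysis also competes for catalytic capacity (no sink is free),
    so high-respiration states coincide with high-growth states rather
    than with idle ATP-burning ones.  The fermentation reaction has its
    own finite capacity (ub 0.2*u, a Vmax in effect), so fast growth
    cannot be powered by fermentation alone and respiratory flux must
    rise with growth rate.
    """
    mets = _mets(
        ("glc_e", _GLC, "e"), ("glc_c", _GLC, "c"),
        ("o2_e", "O2", "e"), ("o2_c", "O2", "c"),
        ("lac_e", _LAC, "e"), ("lac_c", _LAC, "c"),
        ("co2_e", "CO2", "e"), ("co2_c", "CO2", "c"),
        ("atp_c", "C10H16N5O13P3", "c"), ("cap_c", "", "c"),
    )
    rxns = [
        _rxn("EX_glc", {"glc_e": -1}, -u, 0),
        _rxn("EX_o2", {"o2_e": -1}, -100 * u, 0),
        _rxn("EX_lac", {"lac_e": -1}, 0, 100 * u),
        _rxn("EX_co2", {"co2_e": -1}, 0, 100 * u),
        _rxn("CAP_SRC", {"cap_c": 1}, 0, 1.2 * u),
        _rxn("T_glc", {"glc_e": -1, "glc_c": 1}, 0, 100 * u, "g_tglc"),
        _rxn("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 100 * u, "g_to2"),
        _rxn("T_lac", {"lac_c": -1, "lac_e": 1}, 0, 100 * u, "g_tlac"),
        _rxn("T_co2", {"co2_c": -1, "co2_e": 1}, 0, 100 * u),
        _rxn("FERM", {"glc_c": -1, "cap_c": -1, "lac_c": 2, "atp_c": 2}, 0, 0.2 * u, "g_ferm"),
        _rxn("RESP", {"glc_c": -1, "o2_c": -6, "cap_c": -20, "co2_c": 6, "atp_c": 30},
             0, 100 * u, "g_resp"),
        _rxn("BIOMASS", {"glc_c": -3, "atp_c": -4, "cap_c": -1}, 0, 100 * u, "g_bio"),
        _rxn("ATPM", {"atp_c": -1, "cap_c": -0.5}, 0, 100 * u),
    ]
    return MetabolicNetwork(mets, rxns, "BIOMASS", "ATPM", name="ferm-resp-net")


def _random_net(spec: FixtureSpec, max_retries: int = 20) -> MetabolicNetwork:
    """Random sparse pathway net: substrate -> chain of conversions with
    random branching -> biomass/ATP drains; coefficients chosen so each
    internal reaction conserves the count of carbon skeletons."""
    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        n_int = max(3, spec.n_metabolites)
        mets = [Metabolite("sub_e", formula=_GLC, is_extracellular=True, compartment="e")]
        mets += [Metabolite(f"m{i}_c", formula=_GLC, compartment="c") for i in range(n_int)]
        mets.append(Metabolite("atp_c", compartment="c"))
        rxns = [
            _rxn("EX_sub", {"sub_e": -1}, -spec.bound_scale, 0),
            _rxn("T_sub", {"sub_e": -1, "m0_c": 1}, 0, 100 * spec.bound_scale, "g_t"),
        ]
        n_conv = max(2, spec.n_reactions - 4)
        for k in range(n_conv):
            src = int(rng.integers(0, n_int - 1))
            dst = int(rng.integers(src + 1, n_int))
            make_atp = bool(rng.random() < 0.4)
            stoich = {f"m{src}_c": -1.0, f"m{dst}_c": 1.0}
            if make_atp:
                stoich["atp_c"] = float(rng.integers(1, 3))
            rxns.append(
                _rxn(f"R{k}", stoich, 0, 100 * spec.bound_scale, f"g_r{k}")
            )
        sink = int(rng.integers(1, n_int))
        rxns.append(_rxn("BIOMASS", {f"m{sink}_c": -1}, 0, 100 * spec.bound_scale, "g_bio"))
        rxns.append(_rxn("ATPM", {"atp_c": -1}, 0, 100 * spec.bound_scale))
        try:
            net = MetabolicNetwork(mets, rxns, "BIOMASS", "ATPM", name=f"random-net-{spec.seed}")
        except ModelValidationError:
            continue
        # feasible with nonzero biomass?
        S = net.stoichiometric_matrix()
        lb, ub = net.bounds_arrays()
        c = np.zeros(len(rxns))
        c[net.reaction_ids.index("BIOMASS")] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)),
                      method="highs")
        if res.status == 0 and -res.fun > TAU_OBJ:
            return net
    raise RuntimeError(f"random-net: no feasible draw in {max_retries} retries")


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _nullspace_box(network: MetabolicNetwork, tol: float = 1e-10):
    """Nullspace basis of S and a bounding box for its coordinates."""
    S = network.stoichiometric_matrix()
    N = null_space(S)
    if N.shape[1] == 0:
        raise ValueError("network admits only the zero flux")
    lb, ub = network.bounds_arrays()
    box = []
    for k in range(N.shape[1]):
        c = np.zeros(N.shape[1])
        c[k] = 1.0
        lo = linprog(c, A_ub=np.vstack([N, -N]), b_ub=np.concatenate([ub, -lb]),
                     bounds=[(None, None)] * N.shape[1], method="highs")
        hi = linprog(-c, A_ub=np.vstack([N, -N]), b_ub=np.concatenate([ub, -lb]),
                     bounds=[(None, None)] * N.shape[1], method="highs")
        if lo.status != 0 or hi.status != 0:
            raise ValueError("flux polytope empty or unbounded in nullspace coordinates")
        box.append((float(lo.fun), float(-hi.fun)))
    return N, np.array(box), lb, ub


def enumerate_feasible_fluxes(
    network: MetabolicNetwork, points_per_axis: int = 21, tol: float = 1e-9
) -> np.ndarray:
    """Grid-enumerate feasible fluxes (rows = reactions order of the network)."""
    N, box, lb, ub = _nullspace_box(network)
    k = N.shape[1]
    if k > 4:
        raise ValueError(f"{k} flux degrees of freedom; enumeration oracle refuses > 4")
    axes = [np.linspace(lo, hi, points_per_axis) for lo, hi in box]
    T = np.array(list(itertools.product(*axes)))
    V = T @ N.T
    ok = np.all(V >= lb - tol, axis=1) & np.all(V <= ub + tol, axis=1)
    return np.clip(V[ok], lb, ub)


def brute_force_pareto(
    network: MetabolicNetwork,
    points_per_axis: int = 21,
    weights: ObjectiveWeights | None = None,
    tol_obj: float = TAU_OBJ,
) -> ParetoSet:
    """Oracle front: enumerate the flux polytope on a grid, evaluate the four
    objectives and keep the non-dominated points.  Exponential in the
    degrees of freedom; refuses networks with more than 4."""
    if weights is None:
        weights = ObjectiveWeights.default(network)
    V = enumerate_feasible_fluxes(network, points_per_axis)
    rids = network.reaction_ids
    points = np.array(
        [evaluate_objectives(network, dict(zip(rids, v)), weights).as_array() for v in V]
    )
    keep = pareto_filter(points, tol=tol_obj)
    fluxes = [
        FluxConfiguration(dict(zip(rids, V[i])), OPTIMAL) for i in keep
    ]
    return ParetoSet(fluxes, points[keep], grid=None, reaction_ids=rids)


def front_equivalence(
    network: MetabolicNetwork,
    sampled: ParetoSet,
    points_per_axis: int = 15,
    weights: ObjectiveWeights | None = None,
    tol_obj: float = TAU_OBJ,
) -> dict:
    """Compare an epsilon-constraint front against the enumeration oracle.

    Two checks: (1) *optimality* — no enumerated feasible flux dominates
    any sampled solution beyond a relative tolerance ``tol_obj`` (every
    sampled point is Pareto-optimal); (2) *coverage at matched
    resolution* — every oracle-front point lies within a normalised
    objective-space distance of the sampled front commensurate with the
    two grid resolutions (2*(1/(levels-1) + 1/(points_per_axis-1))).
    Returns the measured numbers; callers assert on them.
    """
    if weights is None:
        weights = ObjectiveWeights.default(network)
    V = enumerate_feasible_fluxes(network, points_per_axis)
    rids = network.reaction_ids
    feas_pts = np.array(
        [evaluate_objectives(network, dict(zip(rids, v)), weights).as_array() for v in V]
    )
    from .objectives import OBJECTIVE_SENSES

    F = feas_pts * OBJECTIVE_SENSES
    n_dominated = 0
    for p in sampled.objectives * OBJECTIVE_SENSES:
        m = tol_obj * np.maximum(1.0, np.maximum(np.abs(p), np.abs(F)))
        if np.any(np.all(F >= p - m, axis=1) & np.any(F > p + m, axis=1)):
            n_dominated += 1

    keep = pareto_filter(feas_pts, tol=tol_obj)
    lo = feas_pts[keep].min(axis=0)
    hi = feas_pts[keep].max(axis=0)
    span = np.where(hi - lo > 1e-9, hi - lo, 1.0)
    O = (feas_pts[keep] - lo) / span
    E = (sampled.objectives - lo) / span
    cover = np.sqrt(((O[:, None, :] - E[None, :, :]) ** 2).sum(-1)).min(axis=1)
    levels = 10
    if sampled.grid is not None and isinstance(sampled.grid.levels, int):
        levels = sampled.grid.levels
    bound = 2.0 * (1.0 / (levels - 1) + 1.0 / (points_per_axis - 1))
    return {
        "n_sampled_dominated": n_dominated,
        "coverage_max": float(cover.max()),
        "coverage_bound": float(bound),
        "oracle_front_size": int(len(keep)),
    }


def sample_feasible_fluxes(
    network: MetabolicNetwork, n: int, seed: int = 0, max_draws: int = 200000
) -> list[dict[str, float]]:
    """Rejection-sample random feasible flux configurations (seeded)."""
    N, box, lb, ub = _nullspace_box(network)
    rng = np.random.default_rng(seed)
    rids = network.reaction_ids
    out: list[dict[str, float]] = []
    draws = 0
    while len(out) < n and draws < max_draws:
        batch = rng.uniform(box[:, 0], box[:, 1], size=(512, N.shape[1]))
        draws += 512
        V = batch @ N.T
        ok = np.all(V >= lb - 1e-9, axis=1) & np.all(V <= ub + 1e-9, axis=1)
        for v in np.clip(V[ok], lb, ub):
            out.append(dict(zip(rids, v)))
            if len(out) == n:
                break
    if len(out) < n:
        raise RuntimeError(f"only {len(out)}/{n} feasible samples in {draws} draws")
    return out


# ---------------------------------------------------------------------------
# synthetic omics panels
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    profiles: list[OmicsProfile]
    ground_truth: dict[str, dict]
    noise_sigma: float
    seed: int


def make_synthetic_panel(
    network: MetabolicNetwork,
    pareto: ParetoSet,
    n_lines: int,
    noise_sigma: float = 0.05,
    seed: int = 1,
    min_growth_fraction: float = 0.2,
    min_warburg: float | None = 0.0,
) -> SyntheticPanel:
    """Emulated proteomics + CORE panel with known generating solutions.

    Per line: draw a Pareto solution, emit enzyme abundances as that
    solution's gene-level flux engagement under multiplicative lognormal
    noise (non-negative by construction) and exchange fluxes under
    additive Gaussian noise scaled per metabolite by the flux spread
    across the front.  Regeneration with the same seed is bit-identical.

    The panel emulates a cancer cell-line collection, i.e. actively
    proliferating states: generating solutions are drawn uniformly from
    the part of the front whose biomass flux is at least
    ``min_growth_fraction`` of the front's maximum.  The default 0.2
    mirrors the roughly fivefold spread of doubling times across a
    cancer cell-line panel such as NCI-60; 0 reproduces a uniform draw
    over the whole front, including idle low-flux states no growing
    cell line occupies.  When the model carries lactate and O2
    exchanges, generating states are additionally required to show
    aerobic glycolysis (Warburg ratio strictly above ``min_warburg``) —
    cultured cancer lines universally secrete lactate under aerobic
    conditions; pass ``min_warburg=None`` to disable.
    """
    rng = np.random.default_rng(seed)
    biomass = pareto.objectives[:, 0]
    mask = biomass >= min_growth_fraction * biomass.max()
    if min_warburg is not None:
        from .errors import ConfigurationError
        from .targets import warburg_metric

        try:
            w = np.array([warburg_metric(network, f) for f in pareto.fluxes])
            mask &= w > min_warburg
        except ConfigurationError:
            pass  # model has no fermentation/respiration boundary fluxes
    candidates = np.flatnonzero(mask)
    if len(candidates) == 0:
        candidates = np.flatnonzero(biomass >= min_growth_fraction * biomass.max())
    if len(candidates) == 0:
        candidates = np.arange(len(pareto))
    genes = network.genes
    measurable = [
        r for r in network.exchange_reactions()
        if network.exchanged_metabolite(r).is_extracellular
    ]
    exch_mets = [network.exchanged_metabolite(r).id for r in measurable]
    exch_scale = {}
    flux_mat = pareto.flux_matrix()
    for r in measurable:
        col = pareto.reaction_ids.index(r.id)
        exch_scale[network.exchanged_metabolite(r).id] = max(
            float(np.max(np.abs(flux_mat[:, col]))), 1.0
        )
    profiles: list[OmicsProfile] = []
    truth: dict[str, dict] = {}
    for i in range(n_lines):
        idx = int(candidates[rng.integers(0, len(candidates))])
        flux = pareto.fluxes[idx]
        feats = pathway_flux_features(network, flux)
        abundance = {
            g: feats[g] * float(np.exp(rng.normal(0.0, noise_sigma))) for g in genes
        }
        exch = solution_exchange_fluxes(network, flux)
        # sd relative to each measurement's own magnitude (measurement CV),
        # floored at 2% of the metabolite's front-wide scale so zero fluxes
        # still carry noise
        exchange = {
            m: exch[m]
            + float(
                rng.normal(
                    0.0,
                    noise_sigma * max(abs(exch[m]), 0.02 * exch_scale[m]),
                )
            )
            for m in exch_mets
        }
        cl = f"line_{i:03d}"
        profiles.append(OmicsProfile(cl, abundance, exchange))
        truth[cl] = {
            "solution_index": idx,
            "objectives": ObjectiveVector.from_array(pareto.objectives[idx]),
        }
    return SyntheticPanel(profiles, truth, noise_sigma, seed)


__all__ = [
    "FIXTURE_NAMES",
    "FixtureSpec",
    "make_fixture",
    "brute_force_pareto",
    "enumerate_feasible_fluxes",
    "sample_feasible_fluxes",
    "SyntheticPanel",
    "make_synthetic_panel",
]
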