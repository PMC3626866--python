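"""Chance-constrained strain-design MILP and its variants.

The design problem selects up to ``L`` reactions for up- or down-regulation
(binary decisions ``y_j^u``, ``y_j^d``) so as to maximize the target flux
minus a small per-intervention penalty ``alpha``:

    max  v_target - alpha * sum_j (y_j^u + y_j^d)
    s.t. S v = 0
         v_biomass >= biomass_fraction * v_biomass^max        (if present)
         v_j <= SSU_j + y_j^u (Q_j^u - SSU_j) + y_j^d (Q_j^d - SSU_j)
         v_j >= SSL_j (1 - y_j^d)
         sum_j (y_j^u + y_j^d) <= L
         y_j^u + y_j^d <= 1
         no split pair both-up or both-down
         y binary, v >= 0

The flux capacity of a modified reaction is a random variable; requiring the
capacity constraint to hold with probability >= 1 - eps and inverting the
capacity CDF turns the chance constraint into the deterministic bound above
with ``Q_j = F_j^{-1}(eps)`` (CCOpt).  ``eps = 0`` uses the worst case of
every capacity distribution (DetOpt).  MCOpt instead solves the MILP
repeatedly with capacities drawn from the distributions, yielding a
frequency table of intervention sets.

Down-regulation quantiles and draws are capped at ``SSU_j``: lowering an
enzyme level must not raise the capacity above the unmodified state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from ._linprog import solve_flux_lp
from .capacity import DOWN, UP, CapacityTable, ReferenceState
from .exceptions import ConfigurationError, InfeasibleError, ValidationError
from .model import MetabolicModel

INTEGRALITY_TOL = 1e-6

__all__ = [
    "OptimizationSettings", "InterventionSet", "OptimizationResult",
    "CapacitySample", "capacity_bound", "ccopt_solve", "detopt_solve",
    "mcopt_run", "wild_type_optimum", "default_alpha",
]


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizationSettings:
    """Knobs of the design MILP.

    eps : confidence parameter in [0, 1]; probability mass the capacity
        constraint may leave uncovered (0 = worst case).
    L : maximum number of interventions.
    alpha : per-intervention penalty in flux units; ``None`` selects
        1e-4 x the wild-type target optimum (or 1 if that is 0).  Keep
        ``alpha * L`` below the smallest flux improvement of interest.
    biomass_fraction : minimal biomass flux as a fraction of the wild-type
        theoretical maximum (ignored when the model has no biomass reaction).
    eligible_reactions : optional subset of reactions allowed to carry
        intervention variables; ``None`` means every reaction that has a
        capacity distribution for the relevant direction.
    allow_target_biomass_down : let the target/biomass reactions be
        down-regulated (off by default).
    """

    eps: float = 0.0
    L: int = 1
    alpha: float | None = None
    biomass_fraction: float = 0.01
    eligible_reactions: frozenset[str] | None = None
    allow_target_biomass_down: bool = False

    def __post_init__(self):
        if not 0.0 <= self.eps <= 1.0:
            raise ValidationError(f"eps must be in [0, 1], got {self.eps}")
        if self.L < 0:
            raise ValidationError("L must be nonnegative")
        if self.alpha is not None and self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if not 0.0 <= self.biomass_fraction <= 1.0:
            raise ValidationError("biomass_fraction must be in [0, 1]")
        if self.eligible_reactions is not None:
            object.__setattr__(self, "eligible_reactions",
                               frozenset(self.eligible_reactions))


@dataclass(frozen=True)
class InterventionSet:
    """Chosen up-/down-regulations (disjoint sets of reaction ids)."""

    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValidationError(
                f"reactions both up- and down-regulated: {sorted(self.up & self.down)}")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def key(self) -> str:
        """Canonical string key (sorted ids per direction)."""
        return "up:{}|down:{}".format(",".join(sorted(self.up)),
                                      ",".join(sorted(self.down)))

    def __str__(self) -> str:
        parts = [f"up {{{', '.join(sorted(self.up))}}}" if self.up else "",
                 f"down {{{', '.join(sorted(self.down))}}}" if self.down else ""]
        return "; ".join(p for p in parts if p) or "{}"


@dataclass
class OptimizationResult:
    """Solution of one design MILP."""

    interventions: InterventionSet
    v_target: float
    fluxes: pd.Series | None
    objective: float
    status: str  # optimal | infeasible | iteration-limit
    settings: OptimizationSettings
    alpha: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def summary(self) -> str:
        lines = [
            "Strain-design MILP result",
            "=" * 34,
            f"status            : {self.status}",
            f"interventions     : {self.interventions}",
            f"v_target          : {self.v_target:.6g}",
            f"objective         : {self.objective:.6g}",
            f"eps               : {self.settings.eps}",
            f"L (max interv.)   : {self.settings.L}",
            f"alpha             : {self.alpha:.6g}",
        ]
        return "\n".join(lines)


CapacitySample = dict  # (reaction_id, direction) -> drawn capacity value


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def capacity_bound(SSU_j: float, q_u: float, q_d: float,
                   y_u: int, y_d: int) -> float:
    """Upper flux bound of one reaction given its modification state:
    ``SSU + y_u (q_u - SSU) + y_d (q_d - SSU)``."""
    if y_u and y_d:
        raise ValueError("a reaction cannot be both up- and down-regulated")
    return SSU_j + y_u * (q_u - SSU_j) + y_d * (q_d - SSU_j)


def wild_type_optimum(model: MetabolicModel, ref: ReferenceState,
                      biomass_fraction: float = 0.01) -> tuple[float, np.ndarray]:
    """FBA optimum of the target flux over the unmodified reference bounds."""
    if model.target_id is None:
        raise ConfigurationError("model has no target reaction")
    m = model.n_reactions
    c = np.zeros(m)
    c[model.index(model.target_id)] = 1.0
    lb, ub = ref.SSL.copy(), ref.SSU.copy()
    if model.biomass_id is not None and ref.vbiomass_max is not None:
        jb = model.index(model.biomass_id)
        lb[jb] = max(lb[jb], biomass_fraction * ref.vbiomass_max)
    return solve_flux_lp(c, model.S, lb, ub, sense="max",
                         context="wild-type target optimum")


def default_alpha(model: MetabolicModel, ref: ReferenceState,
                  biomass_fraction: float = 0.01) -> float:
    wt, _ = wild_type_optimum(model, ref, biomass_fraction)
    return 1e-4 * (wt if wt > 0 else 1.0)


def _eligibility(model: MetabolicModel, caps: CapacityTable,
                 settings: OptimizationSettings) -> tuple[list[str], list[str]]:
    """Reactions allowed to carry y^u / y^d variables (sorted for determinism)."""
    has_up = caps.reactions(UP)
    has_down = caps.reactions(DOWN)
    if settings.eligible_reactions is not None:
        missing = settings.eligible_reactions - (has_up | has_down)
        if missing:
            raise ConfigurationError(
                f"eligible reactions without any capacity distribution: {sorted(missing)}")
        has_up &= settings.eligible_reactions
        has_down &= settings.eligible_reactions
    unknown = (has_up | has_down) - set(model.reaction_ids)
    if unknown:
        raise ConfigurationError(
            f"capacity distributions for unknown reactions: {sorted(unknown)}")
    if not settings.allow_target_biomass_down:
        has_down -= {model.target_id, model.biomass_id}
    return sorted(has_up), sorted(has_down)


def _check_inputs(model: MetabolicModel, ref: ReferenceState) -> None:
    if not model.is_split:
        raise ConfigurationError("the optimizer requires a split (irreversible) model")
    if list(ref.reaction_ids) != list(model.reaction_ids):
        raise ConfigurationError("reference state is not aligned with the model")
    if model.target_id is None:
        raise ConfigurationError("model has no target reaction")


def _fixed_bounds(model, ref, up_q, down_q, interventions, biomass_fraction):
    """Flux bounds for a *fixed* intervention set (LP re-solve / oracle)."""
    lb, ub = ref.SSL.copy(), ref.SSU.copy()
    for rid in interventions.up:
        j = model.index(rid)
        ub[j] = up_q[rid]
    for rid in interventions.down:
        j = model.index(rid)
        ub[j] = down_q[rid]
        lb[j] = 0.0
    if model.biomass_id is not None and ref.vbiomass_max is not None:
        jb = model.index(model.biomass_id)
        lb[jb] = max(lb[jb], biomass_fraction * ref.vbiomass_max)
        ub[jb] = max(ub[jb], lb[jb])
    return lb, ub


def _solve_fixed(model, ref, up_q, down_q, interventions, settings, alpha):
    """LP value of a fixed intervention set; None when infeasible."""
    lb, ub = _fixed_bounds(model, ref, up_q, down_q, interventions,
                           settings.biomass_fraction)
    if (lb > ub + 1e-9).any():
        return None
    c = np.zeros(model.n_reactions)
    c[model.index(model.target_id)] = 1.0
    try:
        v_target, v = solve_flux_lp(c, model.S, lb, ub, sense="max")
    except InfeasibleError:
        return None
    fluxes = pd.Series(v, index=model.reaction_ids, name="flux")
    return OptimizationResult(
        interventions=interventions, v_target=v_target, fluxes=fluxes,
        objective=v_target - alpha * len(interventions),
        status="optimal", settings=settings, alpha=alpha)


# ---------------------------------------------------------------------------
# MILP
# ---------------------------------------------------------------------------

def _solve_design_milp(model, ref, up_q, down_q, settings, alpha,
                       up_eligible, down_eligible):
    """Assemble and solve the MILP for given per-reaction capacity bounds
    ``up_q``/``down_q`` (dicts reaction_id -> value)."""
    m = model.n_reactions
    nu, nd = len(up_eligible), len(down_eligible)
    n_var = m + nu + nd
    iu = {rid: m + k for k, rid in enumerate(up_eligible)}
    idn = {rid: m + nu + k for k, rid in enumerate(down_eligible)}

    c = np.zeros(n_var)
    c[model.index(model.target_id)] = -1.0  # milp minimizes
    c[m:] = alpha

    lb_v = ref.SSL.copy()
    ub_v = ref.SSU.copy()
    for rid in down_eligible:
        lb_v[model.index(rid)] = 0.0  # Eq-10 handled by an explicit row
    for rid in up_eligible:
        j = model.index(rid)
        ub_v[j] = max(ub_v[j], up_q[rid])
    lower = np.concatenate([lb_v, np.zeros(nu + nd)])
    upper = np.concatenate([ub_v, np.ones(nu + nd)])

    rows, row_lb, row_ub = [], [], []

    def add_row(idx_val, lo, hi):
        r = np.zeros(n_var)
        for idx, val in idx_val:
            r[idx] += val
        rows.append(r)
        row_lb.append(lo)
        row_ub.append(hi)

    # steady state
    for i in range(model.n_metabolites):
        r = np.zeros(n_var)
        r[:m] = model.S[i]
        rows.append(r)
        row_lb.append(0.0)
        row_ub.append(0.0)

    # minimal biomass
    if model.biomass_id is not None and ref.vbiomass_max is not None:
        add_row([(model.index(model.biomass_id), 1.0)],
                settings.biomass_fraction * ref.vbiomass_max, np.inf)

    # capacity bounds: v_j - y_u (q_u - SSU) - y_d (q_d - SSU) <= SSU
    for rid in set(up_eligible) | set(down_eligible):
        j = model.index(rid)
        terms = [(j, 1.0)]
        if rid in iu:
            terms.append((iu[rid], -(up_q[rid] - ref.SSU[j])))
        if rid in idn:
            terms.append((idn[rid], -(down_q[rid] - ref.SSU[j])))
        add_row(terms, -np.inf, ref.SSU[j])

    # lower bounds: v_j + SSL_j y_d >= SSL_j
    for rid in down_eligible:
        j = model.index(rid)
        if ref.SSL[j] > 0:
            add_row([(j, 1.0), (idn[rid], ref.SSL[j])], ref.SSL[j], np.inf)

    # cardinality
    if nu + nd:
        add_row([(k, 1.0) for k in range(m, n_var)], -np.inf, float(settings.L))

    # exclusivity up/down on one reaction
    for rid in up_eligible:
        if rid in idn:
            add_row([(iu[rid], 1.0), (idn[rid], 1.0)], -np.inf, 1.0)

    # split pairs: not both-up, not both-down
    for fwd, bwd in model.split_pairs.items():
        if fwd in iu and bwd in iu:
            add_row([(iu[fwd], 1.0), (iu[bwd], 1.0)], -np.inf, 1.0)
        if fwd in idn and bwd in idn:
            add_row([(idn[fwd], 1.0), (idn[bwd], 1.0)], -np.inf, 1.0)

    integrality = np.zeros(n_var)
    integrality[m:] = 1
    res = milp(c=c,
               constraints=LinearConstraint(np.array(rows), row_lb, row_ub),
               integrality=integrality,
               bounds=Bounds(lower, upper))
    if res.status == 2:
        return None, "infeasible"
    if res.status != 0 or res.x is None:
        return None, "iteration-limit"

    y = np.round(res.x[m:]).astype(int)
    if np.abs(res.x[m:] - y).max(initial=0.0) > INTEGRALITY_TOL:
        return None, "iteration-limit"
    up = frozenset(rid for rid in up_eligible if y[iu[rid] - m])
    down = frozenset(rid for rid in down_eligible if y[idn[rid] - m])
    return InterventionSet(up=up, down=down), "optimal"


def _solve_with_bounds(model, ref, up_q, down_q, settings, alpha,
                       up_eligible, down_eligible):
    interventions, status = _solve_design_milp(
        model, ref, up_q, down_q, settings, alpha, up_eligible, down_eligible)
    if interventions is None:
        return OptimizationResult(
            interventions=InterventionSet(), v_target=math.nan, fluxes=None,
            objective=math.nan, status=status, settings=settings, alpha=alpha)
    # post-solve verification: rounded binaries must still satisfy the
    # combinatorial constraints, and the LP re-solve with y fixed yields
    # clean fluxes.
    if len(interventions) > settings.L:
        raise ValidationError("solver returned more interventions than L")
    for fwd, bwd in model.split_pairs.items():
        if {fwd, bwd} <= interventions.up or {fwd, bwd} <= interventions.down:
            raise ValidationError(
                f"solver selected both directions of split pair ({fwd}, {bwd})")
    result = _solve_fixed(model, ref, up_q, down_q, interventions, settings, alpha)
    if result is None:  # cannot happen for a feasible MILP; belt and braces
        return OptimizationResult(
            interventions=interventions, v_target=math.nan, fluxes=None,
            objective=math.nan, status="infeasible", settings=settings, alpha=alpha)
    return result


def _quantile_bounds(model, ref, caps, eps, up_eligible, down_eligible):
    up_q, down_q = {}, {}
    for rid in up_eligible:
        up_q[rid] = caps[(rid, UP)].quantile(eps)
    for rid in down_eligible:
        # cap at SSU: down-regulation must not raise the bound
        down_q[rid] = min(caps[(rid, DOWN)].quantile(eps), ref.ssu(rid))
    return up_q, down_q


# ---------------------------------------------------------------------------
# public solvers
# ---------------------------------------------------------------------------

def ccopt_solve(model: MetabolicModel, ref: ReferenceState,
                caps: CapacityTable,
                settings: OptimizationSettings) -> OptimizationResult:
    """Chance-constrained design: capacity bounds at the eps-quantile."""
    _check_inputs(model, ref)
    up_eligible, down_eligible = _eligibility(model, caps, settings)
    alpha = settings.alpha
    if alpha is None:
        alpha = default_alpha(model, ref, settings.biomass_fraction)
    up_q, down_q = _quantile_bounds(model, ref, caps, settings.eps,
                                    up_eligible, down_eligible)
    return _solve_with_bounds(model, ref, up_q, down_q, settings, alpha,
                              up_eligible, down_eligible)


def detopt_solve(model: MetabolicModel, ref: ReferenceState,
                 caps: CapacityTable,
                 settings: OptimizationSettings) -> OptimizationResult:
    """Deterministic worst-case design: CCOpt with eps forced to 0."""
    return ccopt_solve(model, ref, caps, replace(settings, eps=0.0))


def mcopt_run(model: MetabolicModel, ref: ReferenceState,
              caps: CapacityTable, settings: OptimizationSettings,
              n_samples: int, seed: int):
    """Monte-Carlo design: solve the MILP once per drawn capacity sample.

    Returns ``(runs, frequencies)`` where ``runs`` is a list of
    ``(CapacitySample, OptimizationResult)`` and ``frequencies`` maps each
    canonical intervention set (or the ``"infeasible"`` sentinel) to its
    fraction of the pool.

    One master seed spawns independent per-sample substreams; within a
    sample, draws are ordered by (reaction id, direction) so results do not
    depend on iteration order of the eligible set.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    _check_inputs(model, ref)
    up_eligible, down_eligible = _eligibility(model, caps, settings)
    alpha = settings.alpha
    if alpha is None:
        alpha = default_alpha(model, ref, settings.biomass_fraction)

    keys = sorted([(rid, UP) for rid in up_eligible] +
                  [(rid, DOWN) for rid in down_eligible])
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    runs = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        sample: CapacitySample = {}
        up_x, down_x = {}, {}
        for rid, d in keys:
            x = float(caps[(rid, d)].sample(1, rng)[0])
            if d == DOWN:
                x = min(x, ref.ssu(rid))
                down_x[rid] = x
            else:
                up_x[rid] = x
            sample[(rid, d)] = x
        result = _solve_with_bounds(model, ref, up_x, down_x, settings, alpha,
                                    up_eligible, down_eligible)
        runs.append((sample, result))

    from .evaluate import intervention_frequencies
    frequencies = intervention_frequencies([r for _, r in runs])
    return runs, frequencies
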