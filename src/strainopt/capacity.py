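"""Flux-capacity distributions and reference-state estimation.

Uncertain engineering outcomes are modelled as fold-change distributions on
enzyme activity: up-regulation multiplies the enzyme level by a factor drawn
from a normal with mean ``mu`` and spread ``delta`` (defined as 6 standard
deviations), truncated to ``[mu - delta/2, mu + delta/2]`` and renormalized.
The defaults — up: mu=6, delta=8; down: mu=0.5, delta=1 — reflect
over-expression fold-changes reported for mammalian cells; the up-spread is
constrained so that ``mu - delta/2 > 1``, guaranteeing that up-regulation
always raises the capacity above the unmodified state.

For kinetic models the capacity of a modified reaction is the fold-change
distribution scaled by the reaction's maximal velocity v_max (a fold-change
in enzyme level translates one-to-one into a fold-change in v_max, which has
flux units).  Reference-state flux bounds (SSU/SSL) and missing v_max values
are estimated by flux-variability-style LPs over the measured state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linprog import ZERO_TOL, solve_flux_lp
from .exceptions import (ConfigurationError, InfeasibleError,
                         UnboundedError, ValidationError)
from .model import MetabolicModel

UP = "up"
DOWN = "down"


# ---------------------------------------------------------------------------
# fold-change distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldChangeDistribution:
    """Truncated-normal fold-change in enzyme activity.

    ``delta`` is the spread, defined as 6 sigma; the support is the closed
    interval ``[mu - delta/2, mu + delta/2]`` (i.e. +/- 3 sigma).  A zero
    ``delta`` degenerates to a point mass at ``mu``.
    """

    direction: str
    mu: float
    delta: float

    def __post_init__(self):
        if self.direction not in (UP, DOWN):
            raise ValidationError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.delta < 0:
            raise ValidationError("delta must be nonnegative")
        if self.direction == UP and not self.mu - self.delta / 2 > 1:
            raise ValidationError(
                "up-regulation requires mu - delta/2 > 1 so the modified "
                f"capacity exceeds the unmodified state (mu={self.mu}, delta={self.delta})")
        if self.direction == DOWN and self.mu - self.delta / 2 < 0:
            raise ValidationError("down-regulation fold-change support must be nonnegative")

    @property
    def sigma(self) -> float:
        return self.delta / 6.0

    @property
    def support(self) -> tuple[float, float]:
        return (self.mu - self.delta / 2, self.mu + self.delta / 2)


UP_DEFAULT = FoldChangeDistribution(UP, mu=6.0, delta=8.0)
DOWN_DEFAULT = FoldChangeDistribution(DOWN, mu=0.5, delta=1.0)


# ---------------------------------------------------------------------------
# capacity distributions
# ---------------------------------------------------------------------------

MIN_EMPIRICAL_SAMPLE = 100


@dataclass
class CapacityDistribution:
    """Random flux capacity of a reaction after up-/down-regulation.

    Two representations:

    * parametric — truncated normal with ``loc``, ``scale`` and bounded
      support ``[lower, upper]`` (all in flux units);
    * empirical — a finite sample of capacity values (flux units), with
      quantiles by linear interpolation of the order statistics and the
      endpoints pinned to the sample min/max so the 0-quantile (worst case)
      is well defined.
    """

    reaction_id: str
    direction: str
    loc: float | None = None
    scale: float | None = None
    lower: float | None = None
    upper: float | None = None
    sample_values: np.ndarray | None = None
    min_empirical: int = MIN_EMPIRICAL_SAMPLE

    def __post_init__(self):
        if self.direction not in (UP, DOWN):
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.sample_values is not None:
            self.sample_values = np.sort(np.asarray(self.sample_values, dtype=float))
            if self.sample_values.size < self.min_empirical:
                raise ValidationError(
                    f"empirical capacity for {self.reaction_id!r} has "
                    f"{self.sample_values.size} values; floor is {self.min_empirical}")
            if (self.sample_values < 0).any():
                raise ValidationError("capacity values must be nonnegative")
        else:
            if None in (self.loc, self.scale, self.lower, self.upper):
                raise ValidationError("parametric capacity needs loc, scale, lower, upper")
            if self.lower < 0:
                raise ValidationError("capacity support must be nonnegative")
            if not self.lower <= self.loc <= self.upper:
                raise ValidationError("capacity loc must lie within [lower, upper]")
            if self.scale < 0 or not np.isfinite(self.upper):
                raise ValidationError("capacity needs nonnegative scale and bounded support")

    # -- representation -------------------------------------------------

    @property
    def is_empirical(self) -> bool:
        return self.sample_values is not None

    @property
    def is_point_mass(self) -> bool:
        if self.is_empirical:
            return bool(self.sample_values[0] == self.sample_values[-1])
        return self.scale == 0 or self.upper == self.lower

    def _truncnorm(self):
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return stats.truncnorm(a, b, loc=self.loc, scale=self.scale)

    # -- contract -------------------------------------------------------

    def quantile(self, eps: float) -> float:
        """eps-quantile (inverse CDF); monotone, maps [0, 1] onto the support."""
        if not 0.0 <= eps <= 1.0:
            raise ValueError(f"eps must be in [0, 1], got {eps}")
        if self.is_empirical:
            return float(np.quantile(self.sample_values, eps))
        if self.is_point_mass:
            return float(self.loc)
        if eps == 0.0:
            return float(self.lower)
        if eps == 1.0:
            return float(self.upper)
        return float(self._truncnorm().ppf(eps))

    def sample(self, n: int, seed=None) -> np.ndarray:
        """n independent draws; reproducible given a seed (or Generator)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        if self.is_empirical:
            return rng.choice(self.sample_values, size=n, replace=True)
        if self.is_point_mass:
            return np.full(n, float(self.loc))
        # inverse-CDF transform of seeded uniforms
        return np.asarray(self._truncnorm().ppf(rng.uniform(size=n)), dtype=float)

    def mean(self) -> float:
        if self.is_empirical:
            return float(self.sample_values.mean())
        if self.is_point_mass:
            return float(self.loc)
        return float(self._truncnorm().mean())

    @property
    def support(self) -> tuple[float, float]:
        if self.is_empirical:
            return float(self.sample_values[0]), float(self.sample_values[-1])
        return float(self.lower), float(self.upper)


def kinetic_capacity(reaction_id: str, vmax_j: float,
                     fc: FoldChangeDistribution) -> CapacityDistribution:
    """Capacity distribution of a kinetic-model reaction: v_max times the
    enzyme fold-change distribution (pure linear scaling)."""
    if not vmax_j > 0:
        raise ValueError(f"vmax must be positive, got {vmax_j}")
    lo, hi = fc.support
    return CapacityDistribution(
        reaction_id=reaction_id, direction=fc.direction,
        loc=vmax_j * fc.mu, scale=vmax_j * fc.sigma,
        lower=vmax_j * lo, upper=vmax_j * hi)


def quantile(dist: CapacityDistribution, eps: float) -> float:
    """Functional alias for :meth:`CapacityDistribution.quantile`."""
    return dist.quantile(eps)


def sample_capacity(dist: CapacityDistribution, n: int, seed=None) -> np.ndarray:
    """Functional alias for :meth:`CapacityDistribution.sample`."""
    return dist.sample(n, seed)


# ---------------------------------------------------------------------------
# capacity tables (per-reaction, per-direction)
# ---------------------------------------------------------------------------

class CapacityTable(dict):
    """Mapping (reaction_id, direction) -> CapacityDistribution."""

    def add(self, dist: CapacityDistribution) -> "CapacityTable":
        self[(dist.reaction_id, dist.direction)] = dist
        return self

    def reactions(self, direction: str | None = None) -> set[str]:
        return {rid for rid, d in self if direction is None or d == direction}

    def to_json_obj(self) -> list[dict]:
        out = []
        for (rid, d), dist in sorted(self.items()):
            rec = {"reaction_id": rid, "direction": d}
            if dist.is_empirical:
                rec["kind"] = "empirical"
                rec["sample"] = [float(x) for x in dist.sample_values]
            else:
                rec["kind"] = "truncated-normal"
                rec.update(loc=dist.loc, scale=dist.scale,
                           lower=dist.lower, upper=dist.upper)
            out.append(rec)
        return out

    @classmethod
    def from_json_obj(cls, obj: list[dict]) -> "CapacityTable":
        table = cls()
        for rec in obj:
            if rec["kind"] == "empirical":
                dist = CapacityDistribution(rec["reaction_id"], rec["direction"],
                                            sample_values=np.asarray(rec["sample"]))
            else:
                dist = CapacityDistribution(rec["reaction_id"], rec["direction"],
                                            loc=rec["loc"], scale=rec["scale"],
                                            lower=rec["lower"], upper=rec["upper"])
            table.add(dist)
        return table


# ---------------------------------------------------------------------------
# v_max vectors and reference state
# ---------------------------------------------------------------------------

@dataclass
class VmaxVector:
    """Per-reaction maximal velocities with provenance (given vs completed)."""

    values: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rid, v in self.values.items():
            if not v > 0:
                raise ValidationError(f"vmax for {rid!r} must be positive, got {v}")
        for rid in self.values:
            self.provenance.setdefault(rid, "given")

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.values


@dataclass
class ReferenceState:
    """Reference (unmodified) steady-state flux bounds.

    ``SSU``/``SSL`` are per-reaction upper/lower bounds (flux units) aligned
    with ``reaction_ids``; ``measured`` records the exchange fluxes the
    bounds were conditioned on; ``vbiomass_max`` is the wild-type theoretical
    maximal biomass flux (None when the model has no biomass reaction).
    """

    reaction_ids: list[str]
    SSU: np.ndarray
    SSL: np.ndarray
    measured: dict[str, float] = field(default_factory=dict)
    vbiomass_max: float | None = None

    def __post_init__(self):
        self.SSU = np.asarray(self.SSU, dtype=float)
        self.SSL = np.asarray(self.SSL, dtype=float)
        m = len(self.reaction_ids)
        if self.SSU.shape != (m,) or self.SSL.shape != (m,):
            raise ValidationError("SSU/SSL length does not match reaction_ids")
        if (self.SSL < -ZERO_TOL).any():
            raise ValidationError("SSL must be nonnegative in a split model")
        if (self.SSL > self.SSU + 1e-7).any():
            bad = [self.reaction_ids[j] for j in
                   np.flatnonzero(self.SSL > self.SSU + 1e-7)]
            raise ValidationError(f"SSL > SSU for {bad}")
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    def ssu(self, rid: str) -> float:
        return float(self.SSU[self._index[rid]])

    def ssl(self, rid: str) -> float:
        return float(self.SSL[self._index[rid]])


def _measured_bounds(model, measured, measurement_tol, base_lb, base_ub):
    lb, ub = base_lb.copy(), base_ub.copy()
    for rid, m in measured.items():
        j = model.index(rid)
        slack = measurement_tol * abs(m)
        lb[j] = max(lb[j], m - slack)
        ub[j] = min(ub[j], m + slack)
    return lb, ub


def estimate_reference_state(model: MetabolicModel, vmax: VmaxVector,
                             measured: dict[str, float] | None = None,
                             measurement_tol: float = 0.0) -> ReferenceState:
    """Estimate SSU/SSL by maximizing/minimizing each flux over the measured
    reference state.

    The feasible set is ``{S v = 0, 0 <= v_j <= vmax_j, v_k = measured_k}``
    (the measured equality relaxed to a relative band when
    ``measurement_tol > 0``).  The wild-type maximal biomass flux is computed
    over the same set *without* the measurement constraints — it is the
    theoretical maximum of the unmodified network, which the viability
    constraint of the optimizers is expressed against.
    """
    if not model.is_split:
        raise ConfigurationError("estimate_reference_state requires a split model")
    measured = dict(measured or {})
    for rid in measured:
        if rid not in model._index:
            raise ConfigurationError(f"measured flux for unknown reaction {rid!r}")
    missing = [rid for rid in model.reaction_ids if rid not in vmax]
    if missing:
        raise ConfigurationError(
            f"vmax must cover all reactions; missing {missing} "
            "(run complete_vmax first)")

    m = model.n_reactions
    base_lb = np.zeros(m)
    base_ub = np.array([vmax[rid] for rid in model.reaction_ids])
    lb, ub = _measured_bounds(model, measured, measurement_tol, base_lb, base_ub)
    if (lb > ub + ZERO_TOL).any():
        bad = [model.reaction_ids[j] for j in np.flatnonzero(lb > ub + ZERO_TOL)]
        raise InfeasibleError(
            "measured fluxes conflict with vmax bounds", diagnostics=bad)

    SSU = np.empty(m)
    SSL = np.empty(m)
    c = np.zeros(m)
    for j, rid in enumerate(model.reaction_ids):
        c[:] = 0.0
        c[j] = 1.0
        try:
            SSU[j], _ = solve_flux_lp(c, model.S, lb, ub, sense="max",
                                      context=f"SSU of {rid}")
            SSL[j], _ = solve_flux_lp(c, model.S, lb, ub, sense="min",
                                      context=f"SSL of {rid}")
        except InfeasibleError as err:
            raise InfeasibleError(
                f"reference state infeasible while bounding {rid!r}; "
                f"measured constraints: {sorted(measured)}",
                diagnostics=sorted(measured)) from err
    SSL = np.minimum(SSL, SSU)  # guard numerical slack

    vb_max = None
    if model.biomass_id is not None:
        c[:] = 0.0
        c[model.index(model.biomass_id)] = 1.0
        vb_max, _ = solve_flux_lp(c, model.S, base_lb, base_ub, sense="max",
                                  context="wild-type biomass maximum")
    return ReferenceState(list(model.reaction_ids), SSU, SSL,
                          measured=measured, vbiomass_max=vb_max)


def complete_vmax(model: MetabolicModel, known: VmaxVector | dict[str, float]) -> VmaxVector:
    """Fill in missing maximal velocities by flux maximization.

    For each reaction lacking a v_max, its completed value is the LP maximum
    of its flux subject to steady state and ``0 <= v_k <= known_k`` for the
    reactions with pre-defined v_max (all other fluxes only nonnegative).
    Known entries pass through unchanged.
    """
    if not model.is_split:
        raise ConfigurationError("complete_vmax requires a split model")
    if isinstance(known, dict):
        known = VmaxVector(dict(known))
    if not known.values:
        raise ConfigurationError("complete_vmax needs at least one known vmax")
    for rid in known.values:
        if rid not in model._index:
            raise ConfigurationError(f"known vmax names unknown reaction {rid!r}")

    m = model.n_reactions
    lb = np.zeros(m)
    ub = np.full(m, np.inf)
    for rid, v in known.values.items():
        ub[model.index(rid)] = v

    values = dict(known.values)
    provenance = dict(known.provenance)
    c = np.zeros(m)
    for j, rid in enumerate(model.reaction_ids):
        if rid in values:
            continue
        c[:] = 0.0
        c[j] = 1.0
        try:
            vj, _ = solve_flux_lp(c, model.S, lb, ub, sense="max",
                                  context=f"vmax completion of {rid}")
        except UnboundedError as err:
            raise UnboundedError(
                f"flux of {rid!r} is unbounded given the known vmax set; "
                "cannot complete its vmax") from err
        if vj <= 0:
            raise ConfigurationError(
                f"completed vmax for {rid!r} is {vj}; the reaction carries no "
                "flux under the known caps")
        values[rid] = vj
        provenance[rid] = "completed"
    return VmaxVector(values, provenance)
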