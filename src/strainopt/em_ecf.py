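"""Elementary flux modes and enzyme-control-flux (ECF) capacity estimation.

For a purely stoichiometric model (no kinetic v_max data), the flux capacity
of a modified reaction is estimated from the network's elementary modes: the
support-minimal nonnegative steady-state flux vectors, of which every
steady-state flux is a nonnegative combination ``v = E lambda``.

The ECF procedure implemented here:

1. enumerate all elementary modes of the split network (double description
   on the irreversible flux cone, futile forward/backward two-cycles
   removed);
2. constrain the elementary-mode coefficients ``lambda`` to reproduce the
   measured reference state (the coefficients are generally underdetermined,
   so the constraints describe a polytope, not a point);
3. model an enzyme modification as a power-law scaling ``lambda_k' =
   lambda_k * f^h`` of every mode whose support contains the modified
   reaction, where ``f`` is the fold-change and ``h`` the power-law exponent
   (default 1);
4. the modified capacity of the reaction is the LP *maximum* of its
   reconstructed flux over the polytope; repeating over fold-changes drawn
   from the fold-change distribution yields an empirical capacity
   distribution.

The coefficient-estimation step is deliberately formulated as an LP over the
EMC polytope rather than any particular iterative update: the ECF problem is
underdetermined and its solution is a range of minimal and maximal flux, and
the LP computes that range exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .capacity import CapacityDistribution, FoldChangeDistribution, ReferenceState
from .exceptions import ConfigurationError, InfeasibleError, ResourceError
from .model import MetabolicModel

EM_TOL = 1e-9

__all__ = ["ElementaryModeSet", "EMCPolytope", "enumerate_ems",
           "reference_emc_polytope", "ecf_adjusted_max_flux",
           "ecf_capacity_distribution"]


@dataclass
class ElementaryModeSet:
    """All elementary modes of an irreversible network.

    ``modes`` is M x K with column k an elementary mode normalized to max
    entry 1; ``supports[k]`` is the set of reaction ids the mode uses.
    """

    reaction_ids: list[str]
    modes: np.ndarray
    supports: list[frozenset[str]]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.modes, index=self.reaction_ids,
                            columns=[f"EM{k + 1}" for k in range(self.n_modes)])


def _double_description(S: np.ndarray, max_modes: int) -> np.ndarray:
    """Extreme rays of {v >= 0, S v = 0} via iterative double description.

    Rays are kept as rows, normalized to max entry 1.  The adjacency test is
    the standard one: a positive/negative pair is combined only if no third
    ray's zero set contains the intersection of their zero sets.
    """
    m = S.shape[1]
    rays = np.eye(m)
    for s in S:
        d = rays @ s
        zero = np.abs(d) < EM_TOL
        keep = rays[zero]
        pos_idx = np.flatnonzero(~zero & (d > 0))
        neg_idx = np.flatnonzero(~zero & (d < 0))
        support = [frozenset(np.flatnonzero(r > EM_TOL)) for r in rays]
        new_rays = []
        for p in pos_idx:
            for q in neg_idx:
                sup = support[p] | support[q]
                # adjacency: no other ray's support is contained in sup
                adjacent = True
                for t, zs in enumerate(support):
                    if t != p and t != q and zs <= sup:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                r = d[p] * rays[q] - d[q] * rays[p]
                r[np.abs(r) < EM_TOL] = 0.0
                mx = r.max()
                if mx > 0:
                    new_rays.append(r / mx)
        rays = np.vstack([keep] + [np.asarray(new_rays)]) if new_rays else keep
        if rays.shape[0] > max_modes:
            raise ResourceError(
                f"elementary-mode count exceeded the cap ({max_modes}) "
                "during enumeration")
    return rays


def enumerate_ems(model: MetabolicModel, max_modes: int = 10 ** 6) -> ElementaryModeSet:
    """Enumerate all elementary modes of a split (irreversible) model.

    Futile two-cycles supported exactly on a forward/backward split pair are
    removed; modes are normalized (max entry 1), deduplicated, and ordered
    lexicographically by support.
    """
    if not model.is_split:
        raise ConfigurationError("enumerate_ems requires a split model")
    rays = _double_description(model.S, max_modes)

    futile = {frozenset((model.index(f), model.index(b)))
              for f, b in model.split_pairs.items()}
    modes, supports, seen = [], [], set()
    for r in rays:
        sup_idx = frozenset(np.flatnonzero(r > EM_TOL))
        if not sup_idx or sup_idx in futile:
            continue
        key = (sup_idx, tuple(np.round(r, 9)))
        if key in seen:
            continue
        seen.add(key)
        modes.append(r)
        supports.append(sup_idx)

    order = sorted(range(len(modes)), key=lambda k: tuple(sorted(supports[k])))
    matrix = (np.array([modes[k] for k in order]).T
              if modes else np.zeros((model.n_reactions, 0)))
    sup_ids = [frozenset(model.reaction_ids[j] for j in supports[k])
               for k in order]
    return ElementaryModeSet(list(model.reaction_ids), matrix, sup_ids)


@dataclass
class EMCPolytope:
    """Feasible elementary-mode coefficients for a reference state.

    {lambda >= 0;  SSL <= E lambda <= SSU;  (E lambda)_k = measured_k}.
    """

    ems: ElementaryModeSet
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray | None
    b_eq: np.ndarray | None

    def max_weighted(self, c: np.ndarray) -> tuple[float, np.ndarray]:
        """max c . lambda over the polytope; returns (value, lambda)."""
        k = self.ems.n_modes
        res = linprog(-c, A_ub=self.A_ub, b_ub=self.b_ub,
                      A_eq=self.A_eq, b_eq=self.b_eq,
                      bounds=[(0, None)] * k, method="highs")
        if res.status == 2:
            raise InfeasibleError("EMC polytope query infeasible")
        if res.status != 0:
            raise InfeasibleError(f"EMC LP failed (status {res.status})")
        return float(-res.fun), res.x


def reference_emc_polytope(ems: ElementaryModeSet,
                           ref: ReferenceState) -> EMCPolytope:
    """Constrain mode coefficients to the measured reference state.

    Raises :class:`InfeasibleError` when no nonnegative coefficient vector
    reproduces the reference bounds and measurements.
    """
    if ems.n_modes == 0:
        raise ConfigurationError("elementary mode set is empty")
    if list(ems.reaction_ids) != list(ref.reaction_ids):
        raise ConfigurationError("mode set and reference state are misaligned")
    E = ems.modes
    # SSU rows:  E lambda <= SSU ; SSL rows: -E lambda <= -SSL
    A_ub = np.vstack([E, -E])
    b_ub = np.concatenate([ref.SSU, -ref.SSL])
    A_eq = b_eq = None
    if ref.measured:
        rows, vals = [], []
        index = {rid: j for j, rid in enumerate(ems.reaction_ids)}
        for rid, v in sorted(ref.measured.items()):
            rows.append(E[index[rid]])
            vals.append(v)
        A_eq, b_eq = np.array(rows), np.array(vals)
    poly = EMCPolytope(ems, A_ub, b_ub, A_eq, b_eq)
    try:
        poly.max_weighted(np.zeros(ems.n_modes))
    except InfeasibleError as err:
        raise InfeasibleError(
            "no elementary-mode coefficients reproduce the reference state "
            f"(measured: {sorted(ref.measured)})") from err
    return poly


def ecf_adjusted_max_flux(ems: ElementaryModeSet, polytope: EMCPolytope,
                          modified_reaction: str, fold_change: float,
                          query_reaction: str, h: float = 1.0) -> float:
    """Maximal flux of ``query_reaction`` after scaling the coefficients of
    every mode using ``modified_reaction`` by ``fold_change ** h``."""
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if h <= 0:
        raise ValueError("power-law exponent h must be positive")
    index = {rid: j for j, rid in enumerate(ems.reaction_ids)}
    for rid in (modified_reaction, query_reaction):
        if rid not in index:
            raise ConfigurationError(f"unknown reaction {rid!r}")
    g = np.array([fold_change ** h if modified_reaction in sup else 1.0
                  for sup in ems.supports])
    c = ems.modes[index[query_reaction]] * g
    value, _ = polytope.max_weighted(c)
    return value


def ecf_capacity_distribution(ems: ElementaryModeSet, polytope: EMCPolytope,
                              reaction: str, fc: FoldChangeDistribution,
                              n: int, seed: int,
                              h: float = 1.0) -> CapacityDistribution:
    """Empirical capacity distribution of ``reaction`` under ECF analysis.

    Draws ``n`` fold-changes from ``fc`` and maps each through
    :func:`ecf_adjusted_max_flux` with the modified reaction as its own
    query.  Reproducible given ``seed``.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for a usable empirical distribution")
    rng = np.random.default_rng(seed)
    lo, hi = fc.support
    if fc.delta == 0:
        draws = np.full(n, fc.mu)
    else:
        from scipy import stats
        a = (lo - fc.mu) / fc.sigma
        b = (hi - fc.mu) / fc.sigma
        draws = stats.truncnorm(a, b, loc=fc.mu, scale=fc.sigma).ppf(
            rng.uniform(size=n))
    values = np.array([
        ecf_adjusted_max_flux(ems, polytope, reaction, float(f), reaction, h=h)
        for f in draws])
    values[np.abs(values) < EM_TOL] = 0.0
    return CapacityDistribution(reaction_id=reaction, direction=fc.direction,
                                sample_values=values)
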