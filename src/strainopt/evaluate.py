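"""Monte-Carlo evaluation (MCEval) of a fixed intervention set.

An intervention set predicted by any optimizer is evaluated by repeatedly
solving the plain FBA problem with the capacities of the *intervened*
reactions drawn from their distributions (unmodified reactions keep their
reference bounds SSL/SSU; down-regulated reactions get lower bound 0).  The
resulting distribution of optimal target fluxes is summarized by its 5th and
95th percentiles — the "probable range" the design should fall into.

Percentiles follow the operational below/above-count definition: the lower
percentile at level p is the smallest sample value with at least a fraction
p of the data at or below it; the upper percentile at level p is the largest
value with at least 1 - p of the data at or above it.  No interpolation —
a degenerate sample yields identical 5th and 95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linprog import solve_flux_lp
from .capacity import DOWN, UP, CapacityTable, ReferenceState
from .exceptions import ConfigurationError, InfeasibleError
from .model import MetabolicModel

INFEASIBLE = "infeasible"

__all__ = ["EvalDistribution", "mceval_run", "percentile_summary",
           "intervention_frequencies", "INFEASIBLE"]


@dataclass
class EvalDistribution:
    """Monte-Carlo distribution of optimal target fluxes for one design."""

    samples: np.ndarray
    n_infeasible: int
    p05: float
    p95: float
    seed: int

    def summary(self) -> str:
        n = self.samples.size
        lines = [
            "MCEval distribution",
            "=" * 34,
            f"feasible samples  : {n}",
            f"infeasible        : {self.n_infeasible}",
            f"mean v_target     : {self.samples.mean():.6g}",
            f"probable range    : [{self.p05:.6g}, {self.p95:.6g}]  (5th-95th pct)",
            f"seed              : {self.seed}",
        ]
        return "\n".join(lines)


def percentile_summary(samples, levels) -> list[float]:
    """Order-statistic percentiles under the below/above-count definition.

    For level ``p <= 0.5``: the smallest value with >= p of the data at or
    below it.  For ``p > 0.5``: the largest value with >= 1 - p of the data
    at or above it.  A constant sample returns that constant at every level.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("samples must be nonempty")
    out = []
    for p in levels:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"percentile level must be in [0, 1], got {p}")
        if p <= 0.5:
            # smallest x[k] with (k+1)/n >= p
            k = max(int(np.ceil(p * n)) - 1, 0)
        else:
            # largest x[k] with (n-k)/n >= 1-p
            k = min(int(np.floor(p * n)), n - 1)
        out.append(float(x[k]))
    return out


def intervention_frequencies(results) -> dict:
    """Tabulate canonical intervention sets as fractions of the pool.

    Non-optimal results are counted under the ``"infeasible"`` sentinel key.
    Fractions sum to 1.
    """
    if not results:
        raise ValueError("results must be nonempty")
    counts: dict = {}
    for res in results:
        key = res.interventions if res.ok else INFEASIBLE
        counts[key] = counts.get(key, 0) + 1
    total = len(results)
    return {k: v / total for k, v in counts.items()}


def mceval_run(model: MetabolicModel, ref: ReferenceState,
               caps: CapacityTable, interventions, n_samples: int,
               seed: int, biomass_fraction: float = 0.01) -> EvalDistribution:
    """Evaluate a fixed intervention set by repeated FBA under sampled
    capacities.

    Per sample: upper bounds are drawn capacities for intervened reactions
    (down-draws capped at SSU) and SSU otherwise; lower bounds are 0 for
    down-regulated reactions and SSL otherwise; biomass must reach
    ``biomass_fraction`` of its wild-type maximum; the LP maximizes the
    target flux.  Infeasible samples are counted and excluded from the
    percentiles.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not model.is_split:
        raise ConfigurationError("mceval_run requires a split model")
    if model.target_id is None:
        raise ConfigurationError("model has no target reaction")
    for rid in interventions.up:
        if (rid, UP) not in caps:
            raise ConfigurationError(f"no up-capacity distribution for {rid!r}")
    for rid in interventions.down:
        if (rid, DOWN) not in caps:
            raise ConfigurationError(f"no down-capacity distribution for {rid!r}")

    m = model.n_reactions
    c = np.zeros(m)
    c[model.index(model.target_id)] = 1.0

    base_lb, base_ub = ref.SSL.copy(), ref.SSU.copy()
    for rid in interventions.down:
        base_lb[model.index(rid)] = 0.0
    if model.biomass_id is not None and ref.vbiomass_max is not None:
        jb = model.index(model.biomass_id)
        base_lb[jb] = max(base_lb[jb], biomass_fraction * ref.vbiomass_max)

    keys = sorted([(rid, UP) for rid in interventions.up] +
                  [(rid, DOWN) for rid in interventions.down])
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    samples = []
    n_infeasible = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        lb, ub = base_lb.copy(), base_ub.copy()
        for rid, d in keys:
            x = float(caps[(rid, d)].sample(1, rng)[0])
            j = model.index(rid)
            if d == DOWN:
                x = min(x, ref.SSU[j])
            ub[j] = x
        if (lb > ub + 1e-9).any():
            n_infeasible += 1
            continue
        try:
            v_target, _ = solve_flux_lp(c, model.S, lb, ub, sense="max")
        except InfeasibleError:
            n_infeasible += 1
            continue
        samples.append(v_target)

    if not samples:
        raise InfeasibleError(
            "every MCEval sample was infeasible; the intervention set is "
            "incompatible with the viability constraint")
    samples = np.asarray(samples)
    p05, p95 = percentile_summary(samples, [0.05, 0.95])
    return EvalDistribution(samples=samples, n_infeasible=n_infeasible,
                            p05=p05, p95=p95, seed=seed)
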