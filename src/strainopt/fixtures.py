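"""Synthetic test networks with planted capacity bottlenecks.

These fixtures are algebraic test objects, not biology: small irreversible
networks whose optimal intervention sets are known by construction and
verifiable by exhaustive enumeration (:func:`brute_force_optimum`), which is
the package's independent oracle for the design MILP.

The canonical 3-reaction linear fixture ("TL3"): an uptake -> conversion ->
export chain with reference upper bounds (30, 5, 30) and a kinetic capacity
distribution on the middle reaction (vmax 5).  Up-regulating the middle
reaction at the median fold-change (6) lifts its capacity to 30, the chain
ceiling; at the worst case (fold-change 2) only to 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import NamedTuple

import numpy as np

from ._linprog import solve_flux_lp
from .capacity import (DOWN, DOWN_DEFAULT, UP, UP_DEFAULT, CapacityTable,
                       ReferenceState, kinetic_capacity)
from .exceptions import InfeasibleError, ResourceError
from .model import MetabolicModel
from .optimize import InterventionSet, capacity_bound, default_alpha

__all__ = ["Fixture", "make_linear_fixture", "make_branched_fixture",
           "make_random_fixture", "brute_force_optimum", "write_fixture"]

CAP_WIDE = 30.0       # non-bottleneck reference upper bound
CAP_BOTTLENECK = 5.0  # planted bottleneck upper bound


@dataclass
class Fixture:
    """A model + reference state + capacity table bundle for testing."""

    model: MetabolicModel
    ref: ReferenceState
    caps: CapacityTable
    eligible: frozenset[str]
    expected: dict = field(default_factory=dict)


def _chain_model(k: int, units: str = "") -> MetabolicModel:
    mets = [f"A{i}" for i in range(1, k)]
    rids = [f"R{i}" for i in range(1, k + 1)]
    S = np.zeros((k - 1, k))
    S[0, 0] = 1.0                      # uptake
    for i in range(1, k - 1):          # conversions
        S[i - 1, i] = -1.0
        S[i, i] = 1.0
    S[k - 2, k - 1] = -1.0             # export (target)
    return MetabolicModel(mets, rids, S, np.zeros(k, dtype=bool),
                          target_id=rids[-1], units=units)


def _attach_kinetic_caps(caps: CapacityTable, rid: str, vmax: float) -> None:
    caps.add(kinetic_capacity(rid, vmax, UP_DEFAULT))
    caps.add(kinetic_capacity(rid, vmax, DOWN_DEFAULT))


def make_linear_fixture(k: int = 3, bottleneck_position: int | None = None,
                        seed: int = 0) -> Fixture:
    """Uptake -> (k-2 conversions) -> export chain with one planted
    bottleneck whose reference upper bound is the unique binding constraint.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with :func:`make_random_fixture` and recorded in ``expected``.
    """
    if k < 3:
        raise ValueError("chain length must be >= 3")
    if bottleneck_position is None:
        bottleneck_position = 1
    if not 1 <= bottleneck_position <= k - 2:
        raise ValueError("bottleneck must be an interior reaction")
    model = _chain_model(k)
    SSU = np.full(k, CAP_WIDE)
    SSU[bottleneck_position] = CAP_BOTTLENECK
    ref = ReferenceState(list(model.reaction_ids), SSU, np.zeros(k))
    caps = CapacityTable()
    interior = model.reaction_ids[1:-1]
    for j, rid in enumerate(model.reaction_ids):
        if rid in interior:
            _attach_kinetic_caps(caps, rid, SSU[j])
    return Fixture(model, ref, caps, frozenset(interior),
                   expected={"seed": seed,
                             "bottleneck": model.reaction_ids[bottleneck_position]})


def make_branched_fixture(branches: int = 2, seed: int = 0) -> Fixture:
    """One uptake feeding ``branches`` competing pathways; the target branch
    has two bottleneck reactions in series, so no single intervention can
    raise the target flux — both serial reactions must be up-regulated.

    The competing branches get down-capacity distributions but reference
    lower bounds of zero, so down-regulating them can never help (the flux
    is already free to vanish).
    """
    if branches < 2:
        raise ValueError("need at least 2 branches")
    mets = ["A", "B", "C"]
    rids = ["U", "T1", "T2", "Texp"]
    cols = {
        "U": {"A": 1.0},
        "T1": {"A": -1.0, "B": 1.0},
        "T2": {"B": -1.0, "C": 1.0},
        "Texp": {"C": -1.0},
    }
    for b in range(1, branches):
        rid = f"S{b}"
        rids.append(rid)
        cols[rid] = {"A": -1.0}
    S = np.zeros((len(mets), len(rids)))
    mindex = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(rids):
        for met, coef in cols[rid].items():
            S[mindex[met], j] = coef
    model = MetabolicModel(mets, rids, S, np.zeros(len(rids), dtype=bool),
                           target_id="Texp")

    SSU = np.full(len(rids), CAP_WIDE)
    SSU[rids.index("T1")] = CAP_BOTTLENECK
    SSU[rids.index("T2")] = CAP_BOTTLENECK
    ref = ReferenceState(rids, SSU, np.zeros(len(rids)))
    caps = CapacityTable()
    _attach_kinetic_caps(caps, "T1", CAP_BOTTLENECK)
    _attach_kinetic_caps(caps, "T2", CAP_BOTTLENECK)
    eligible = {"T1", "T2"}
    for b in range(1, branches):
        _attach_kinetic_caps(caps, f"S{b}", CAP_WIDE)
        eligible.add(f"S{b}")
    return Fixture(model, ref, caps, frozenset(eligible),
                   expected={"seed": seed, "serial": ("T1", "T2")})


def make_random_fixture(seed: int) -> Fixture:
    """Randomized linear or branched fixture (topology and magnitudes drawn
    from ``seed``) for property tests against the brute-force oracle."""
    rng = np.random.default_rng(seed)
    kind = rng.choice(["linear", "branched"])
    if kind == "linear":
        k = int(rng.integers(3, 7))
        pos = int(rng.integers(1, k - 1))
        fixture = make_linear_fixture(k, pos, seed)
    else:
        fixture = make_branched_fixture(int(rng.integers(2, 4)), seed)
    # jitter the planted magnitudes while preserving the bottleneck structure
    model, ref = fixture.model, fixture.ref
    scale_wide = float(rng.uniform(20.0, 40.0))
    scale_narrow = float(rng.uniform(2.0, 8.0))
    SSU = np.where(ref.SSU == CAP_BOTTLENECK, scale_narrow, scale_wide)
    new_ref = ReferenceState(list(ref.reaction_ids), SSU,
                             np.zeros(len(ref.reaction_ids)))
    caps = CapacityTable()
    for (rid, d) in fixture.caps:
        if d == UP:  # one kinetic pair per eligible reaction
            vmax = new_ref.ssu(rid)
            _attach_kinetic_caps(caps, rid, vmax)
    fixture.ref = new_ref
    fixture.caps = caps
    fixture.expected["kind"] = str(kind)
    return fixture


class BruteForceOptimum(NamedTuple):
    interventions: InterventionSet
    v_target: float
    objective: float


def _candidate_options(fixture: Fixture, allow_target_biomass_down=False):
    model, caps = fixture.model, fixture.caps
    protected = set() if allow_target_biomass_down else \
        {model.target_id, model.biomass_id}
    options = []
    for rid in sorted(fixture.eligible):
        if (rid, UP) in caps:
            options.append((rid, UP))
        if (rid, DOWN) in caps and rid not in protected:
            options.append((rid, DOWN))
    return options


def _valid_combo(combo, split_pairs):
    rids = [rid for rid, _ in combo]
    if len(set(rids)) != len(rids):
        return False
    chosen = set(combo)
    for fwd, bwd in split_pairs.items():
        for d in (UP, DOWN):
            if (fwd, d) in chosen and (bwd, d) in chosen:
                return False
    return True


def brute_force_optimum(fixture: Fixture, eps: float, L: int,
                        alpha: float | None = None,
                        biomass_fraction: float = 0.01) -> BruteForceOptimum:
    """Exhaustive oracle for the design problem.

    Enumerates every valid intervention set of size <= L, fixes the flux
    bounds via :func:`capacity_bound` with capacity quantiles at ``eps``,
    solves each resulting LP, and returns the best penalized objective.
    Entirely independent of the MILP code path.
    """
    model, ref, caps = fixture.model, fixture.ref, fixture.caps
    options = _candidate_options(fixture)
    n_eligible = len({rid for rid, _ in options})
    if n_eligible > 12 or L > 3:
        raise ResourceError(
            f"oracle guard: {n_eligible} eligible reactions, L={L} "
            "(limits: 12 and 3)")
    if alpha is None:
        alpha = default_alpha(model, ref, biomass_fraction)

    q = {(rid, d): (caps[(rid, d)].quantile(eps) if d == UP
                    else min(caps[(rid, d)].quantile(eps), ref.ssu(rid)))
         for rid, d in options}
    c = np.zeros(model.n_reactions)
    c[model.index(model.target_id)] = 1.0

    best = None
    for size in range(min(L, len(options)) + 1):
        for combo in combinations(options, size):
            if not _valid_combo(combo, model.split_pairs):
                continue
            lb, ub = ref.SSL.copy(), ref.SSU.copy()
            for rid, d in combo:
                j = model.index(rid)
                ub[j] = capacity_bound(ref.SSU[j], q.get((rid, UP), 0.0),
                                       q.get((rid, DOWN), 0.0),
                                       int(d == UP), int(d == DOWN))
                if d == DOWN:
                    lb[j] = 0.0
            if model.biomass_id is not None and ref.vbiomass_max is not None:
                jb = model.index(model.biomass_id)
                lb[jb] = max(lb[jb], biomass_fraction * ref.vbiomass_max)
            if (lb > ub + 1e-9).any():
                continue
            try:
                v_target, _ = solve_flux_lp(c, model.S, lb, ub, sense="max")
            except InfeasibleError:
                continue
            objective = v_target - alpha * size
            ivs = InterventionSet(
                up=frozenset(r for r, d in combo if d == UP),
                down=frozenset(r for r, d in combo if d == DOWN))
            cand = BruteForceOptimum(ivs, v_target, objective)
            if best is None or cand.objective > best.objective + 1e-12 or (
                    abs(cand.objective - best.objective) <= 1e-12
                    and len(cand.interventions) < len(best.interventions)):
                best = cand
    if best is None:
        raise InfeasibleError("no valid intervention set is feasible")
    return best


def write_fixture(fixture: Fixture, out_dir) -> None:
    """Serialize a fixture (model.json, refstate.tsv, capacities.json)."""
    from .io import write_capacities, write_model, write_reference_state
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_model(fixture.model, out / "model.json")
    write_reference_state(fixture.ref, out / "refstate.tsv")
    write_capacities(fixture.caps, out / "capacities.json")
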