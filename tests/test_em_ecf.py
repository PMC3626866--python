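from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import linprog

from strainopt.capacity import DOWN_DEFAULT, UP_DEFAULT, FoldChangeDistribution, ReferenceState
from strainopt.em_ecf import (ecf_adjusted_max_flux, ecf_capacity_distribution,
                              enumerate_ems, reference_emc_polytope)
from strainopt.exceptions import ConfigurationError, InfeasibleError
from strainopt.model import MetabolicModel, split_reversible


def brute_force_minimal_supports(S, split_pairs=None, tol=1e-9):
    """Oracle: all support-minimal nonnegative steady-state supports, by
    checking every reaction subset with an LP (flux >= 1 on the support)."""
    m = S.shape[1]
    feasible = []
    for size in range(1, m + 1):
        for sub in combinations(range(m), size):
            sup = set(sub)
            if any(set(f) < sup or set(f) == sup for f in feasible):
                continue  # already dominated by a smaller support
            cols = list(sub)
            A_eq = S[:, cols]
            res = linprog(np.zeros(len(cols)), A_eq=A_eq,
                          b_eq=np.zeros(S.shape[0]),
                          bounds=[(1, None)] * len(cols), method="highs")
            if res.status == 0:
                feasible.append(frozenset(sub))
    minimal = [f for f in feasible
               if not any(g < f for g in feasible)]
    if split_pairs:
        minimal = [f for f in minimal if f not in split_pairs]
    return set(minimal)


def _ids_to_idx(model, supports):
    return {frozenset(model.index(r) for r in s) for s in supports}


class TestEnumeration:
    def test_single_pathway_chain(self, chain_model):
        ems = enumerate_ems(chain_model)
        assert ems.n_modes == 1
        np.testing.assert_allclose(ems.modes[:, 0], [1.0, 1.0, 1.0])

    def test_two_branch_split(self):
        model = MetabolicModel(["A"], ["R1", "R2", "R3"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool))
        ems = enumerate_ems(model)
        assert {frozenset(s) for s in ems.supports} == {
            frozenset({"R1", "R2"}), frozenset({"R1", "R3"})}

    def test_futile_split_cycle_excluded(self, chain_model):
        model = MetabolicModel(
            chain_model.metabolite_ids, chain_model.reaction_ids,
            chain_model.S, np.array([False, True, False]),
            target_id="R3")
        split = split_reversible(model)
        ems = enumerate_ems(split)
        assert ems.n_modes == 1
        assert ems.supports[0] == frozenset({"R1", "R2", "R3"})

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_networks(self, seed):
        """Mode supports on <= 6-reaction random networks equal the
        exhaustive support-minimal enumeration."""
        rng = np.random.default_rng(seed)
        n_mets = int(rng.integers(2, 4))
        n_rxns = int(rng.integers(4, 7))
        while True:
            S = rng.choice([-1.0, 0.0, 1.0], size=(n_mets, n_rxns),
                           p=[0.3, 0.4, 0.3])
            if (np.abs(S).sum(axis=0) > 0).all():
                break
        model = MetabolicModel([f"M{i}" for i in range(n_mets)],
                               [f"R{j}" for j in range(n_rxns)], S,
                               np.zeros(n_rxns, dtype=bool))
        ems = enumerate_ems(model)
        expected = brute_force_minimal_supports(S)
        assert _ids_to_idx(model, ems.supports) == expected

    def test_modes_satisfy_steady_state_and_minimality(self):
        model = MetabolicModel(
            ["A", "B"], ["R1", "R2", "R3", "R4"],
            np.array([[1.0, -1.0, -1.0, 0.0], [0.0, 1.0, 0.0, -1.0]]),
            np.zeros(4, dtype=bool))
        ems = enumerate_ems(model)
        assert (ems.modes >= -1e-12).all()
        np.testing.assert_allclose(model.S @ ems.modes, 0.0, atol=1e-9)
        sups = [frozenset(s) for s in ems.supports]
        for a in sups:
            assert not any(b < a for b in sups)
        # normalized and deduplicated
        assert np.allclose(ems.modes.max(axis=0), 1.0)
        assert len(set(sups)) == len(sups)


class TestEMCPolytope:
    def test_single_mode_unique_coefficient(self, chain_model):
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 10.0})
        poly = reference_emc_polytope(ems, ref)
        val, lam = poly.max_weighted(np.ones(1))
        assert lam[0] == pytest.approx(10.0)

    def test_branch_segment_endpoints(self):
        """2 modes, measured uptake only: the feasible coefficients form a
        segment whose endpoints are computable by hand."""
        model = MetabolicModel(["A"], ["U", "B1", "B2"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool))
        ems = enumerate_ems(model)
        ref = ReferenceState(["U", "B1", "B2"], np.array([10.0, 6.0, 5.0]),
                             np.zeros(3), measured={"U": 8.0})
        poly = reference_emc_polytope(ems, ref)
        # lambda1 + lambda2 = 8, lambda1 <= 6, lambda2 <= 5
        j = ems.reaction_ids.index("B1")
        c = ems.modes[j]
        hi, _ = poly.max_weighted(c)
        lo, _ = poly.max_weighted(-c)
        assert hi == pytest.approx(6.0)
        assert -lo == pytest.approx(3.0)

    def test_measured_violating_ssu_infeasible(self, chain_model):
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 20.0})
        with pytest.raises(InfeasibleError):
            reference_emc_polytope(ems, ref)


class TestECF:
    def _chain_setup(self, chain_model):
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 10.0})
        return ems, reference_emc_polytope(ems, ref)

    def test_identity_fold_change(self, chain_model):
        ems, poly = self._chain_setup(chain_model)
        assert ecf_adjusted_max_flux(ems, poly, "R2", 1.0, "R3") == pytest.approx(10.0)

    def test_single_mode_scales_linearly(self, chain_model):
        ems, poly = self._chain_setup(chain_model)
        for a in [0.5, 2.0, 6.0]:
            assert ecf_adjusted_max_flux(ems, poly, "R2", a, "R2") == \
                pytest.approx(a * 10.0)

    def test_two_mode_branch_hand_solution(self):
        """Doubling one branch's enzyme doubles only the modes through it;
        the 1-D interval LP optimum is computable by hand."""
        model = MetabolicModel(["A"], ["U", "B1", "B2"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool))
        ems = enumerate_ems(model)
        ref = ReferenceState(["U", "B1", "B2"], np.array([10.0, 6.0, 5.0]),
                             np.zeros(3), measured={"U": 8.0})
        poly = reference_emc_polytope(ems, ref)
        # objective max 2*lambda_B1 over {l1 + l2 = 8, l1 <= 6, l2 <= 5}
        assert ecf_adjusted_max_flux(ems, poly, "B1", 2.0, "B1") == \
            pytest.approx(12.0)

    def test_monotone_in_fold_change(self, chain_model):
        ems, poly = self._chain_setup(chain_model)
        vals = [ecf_adjusted_max_flux(ems, poly, "R2", f, "R2")
                for f in [0.5, 1.0, 2.0, 4.0, 8.0]]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments(self, chain_model):
        ems, poly = self._chain_setup(chain_model)
        with pytest.raises(ValueError):
            ecf_adjusted_max_flux(ems, poly, "R2", -1.0, "R2")
        with pytest.raises(ValueError):
            ecf_adjusted_max_flux(ems, poly, "R2", 2.0, "R2", h=0.0)
        with pytest.raises(ConfigurationError):
            ecf_adjusted_max_flux(ems, poly, "nope", 2.0, "R2")


class TestECFCapacityDistribution:
    def test_point_mass_reproduces_reference_max(self, chain_model):
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 10.0})
        poly = reference_emc_polytope(ems, ref)
        fc = FoldChangeDistribution("up", mu=1.5, delta=0.0)
        dist = ecf_capacity_distribution(ems, poly, "R2", fc, 100, seed=0)
        assert dist.support == (pytest.approx(15.0), pytest.approx(15.0))

    def test_single_mode_composes_with_fold_change_sample(self, chain_model):
        """On a single-mode chain the capacity sample is exactly the
        reference flux times the fold-change sample."""
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 10.0})
        poly = reference_emc_polytope(ems, ref)
        dist = ecf_capacity_distribution(ems, poly, "R2", UP_DEFAULT, 150, seed=7)
        lo, hi = dist.support
        assert lo >= 10 * 2 - 1e-9 and hi <= 10 * 10 + 1e-9
        assert np.mean(dist.sample_values) == pytest.approx(10 * 6, rel=0.1)

    def test_reproducible(self, chain_model):
        ems = enumerate_ems(chain_model)
        ref = ReferenceState(["R1", "R2", "R3"], np.full(3, 10.0),
                             np.zeros(3), measured={"R1": 10.0})
        poly = reference_emc_polytope(ems, ref)
        d1 = ecf_capacity_distribution(ems, poly, "R2", DOWN_DEFAULT, 120, seed=11)
        d2 = ecf_capacity_distribution(ems, poly, "R2", DOWN_DEFAULT, 120, seed=11)
        np.testing.assert_array_equal(d1.sample_values, d2.sample_values)
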