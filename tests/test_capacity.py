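import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from strainopt.capacity import (DOWN, DOWN_DEFAULT, UP, UP_DEFAULT,
                                CapacityDistribution, FoldChangeDistribution,
                                ReferenceState, VmaxVector, complete_vmax,
                                estimate_reference_state, kinetic_capacity)
from strainopt.exceptions import (ConfigurationError, InfeasibleError,
                                  UnboundedError, ValidationError)
from strainopt.model import MetabolicModel


# --------------------------------------------------------------------------
# fold-change distributions
# --------------------------------------------------------------------------

class TestFoldChange:
    def test_defaults(self):
        assert UP_DEFAULT.mu == 6 and UP_DEFAULT.delta == 8
        assert UP_DEFAULT.sigma == pytest.approx(8 / 6)
        assert UP_DEFAULT.support == (2.0, 10.0)
        assert DOWN_DEFAULT.support == (0.0, 1.0)

    def test_up_spread_must_exceed_unmodified(self):
        # support minimum must exceed 1: up-regulation always raises capacity
        with pytest.raises(ValidationError):
            FoldChangeDistribution(UP, mu=2.0, delta=4.0)

    def test_down_support_nonnegative(self):
        with pytest.raises(ValidationError):
            FoldChangeDistribution(DOWN, mu=0.2, delta=1.0)


# --------------------------------------------------------------------------
# kinetic capacity scaling
# --------------------------------------------------------------------------

class TestKineticCapacity:
    def test_up_scaling(self):
        cap = kinetic_capacity("R", 100.0, UP_DEFAULT)
        assert cap.loc == 600.0
        assert cap.support == (200.0, 1000.0)

    def test_down_scaling(self):
        cap = kinetic_capacity("R", 100.0, DOWN_DEFAULT)
        assert cap.loc == 50.0
        assert cap.support == (0.0, 100.0)

    def test_zero_delta_is_point_mass(self):
        fc = FoldChangeDistribution(UP, mu=6.0, delta=0.0)
        cap = kinetic_capacity("R", 10.0, fc)
        assert cap.is_point_mass
        assert cap.quantile(0.0) == cap.quantile(1.0) == 60.0
        assert (cap.sample(5, seed=0) == 60.0).all()

    def test_nonpositive_vmax_rejected(self):
        with pytest.raises(ValueError):
            kinetic_capacity("R", 0.0, UP_DEFAULT)

    def test_scaling_commutes_quantile_by_quantile(self):
        base = kinetic_capacity("R", 7.0, UP_DEFAULT)
        scaled = kinetic_capacity("R", 3.0 * 7.0, UP_DEFAULT)
        for eps in [0.0, 0.1, 0.37, 0.5, 0.9, 1.0]:
            assert scaled.quantile(eps) == pytest.approx(3.0 * base.quantile(eps))


# --------------------------------------------------------------------------
# quantiles
# --------------------------------------------------------------------------

def _numeric_quantile(cap, eps, tol=1e-10):
    """Independent inverse CDF: bisection on the trapezoid-integrated
    truncated-normal density."""
    lo, hi = cap.support
    grid = np.linspace(lo, hi, 20001)
    pdf = stats.norm.pdf(grid, cap.loc, cap.scale)
    cdf = np.concatenate([[0.0], np.cumsum(
        (pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]

    def cdf_at(x):
        return float(np.interp(x, grid, cdf))

    a, b = lo, hi
    while b - a > tol:
        mid = (a + b) / 2
        if cdf_at(mid) < eps:
            a = mid
        else:
            b = mid
    return (a + b) / 2


class TestQuantile:
    def setup_method(self):
        self.cap = kinetic_capacity("R", 1.0, UP_DEFAULT)  # TN(6, 8/6) on [2,10]

    def test_median_by_symmetry(self):
        assert self.cap.quantile(0.5) == pytest.approx(6.0, abs=1e-12)

    def test_endpoints(self):
        assert self.cap.quantile(0.0) == 2.0
        assert self.cap.quantile(1.0) == 10.0

    @pytest.mark.parametrize("eps", [0.01, 0.1, 0.25, 0.75, 0.99])
    def test_matches_numerically_integrated_cdf(self, eps):
        assert self.cap.quantile(eps) == pytest.approx(
            _numeric_quantile(self.cap, eps), abs=1e-6)

    def test_monotone_and_onto_support(self):
        grid = np.linspace(0, 1, 101)
        q = [self.cap.quantile(e) for e in grid]
        assert all(b >= a for a, b in zip(q, q[1:]))
        assert q[0] == 2.0 and q[-1] == 10.0

    def test_empirical_min_rule(self):
        cap = CapacityDistribution("R", UP, sample_values=np.tile(
            [2.0, 4.0, 6.0, 8.0, 10.0], 20))
        assert cap.quantile(0.0) == 2.0
        assert cap.quantile(1.0) == 10.0
        assert cap.quantile(0.5) == 6.0

    def test_eps_out_of_range(self):
        with pytest.raises(ValueError):
            self.cap.quantile(1.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(vmax=st.floats(0.1, 100.0),
           mu=st.floats(3.0, 10.0),
           delta=st.floats(0.5, 3.0),
           e1=st.floats(0.0, 1.0), e2=st.floats(0.0, 1.0))
    def test_quantile_monotone_within_support(self, vmax, mu, delta, e1, e2):
        cap = kinetic_capacity("R", vmax, FoldChangeDistribution(UP, mu, delta))
        lo, hi = sorted([e1, e2])
        qlo, qhi = cap.quantile(lo), cap.quantile(hi)
        assert qlo <= qhi + 1e-12
        assert cap.lower - 1e-9 <= qlo and qhi <= cap.upper + 1e-9


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

class TestSampling:
    def test_reproducible(self):
        cap = kinetic_capacity("R", 5.0, UP_DEFAULT)
        np.testing.assert_array_equal(cap.sample(10, seed=3), cap.sample(10, seed=3))

    def test_sample_mean_matches_truncnorm_moment(self):
        cap = kinetic_capacity("R", 5.0, UP_DEFAULT)
        n = 100_000
        x = cap.sample(n, seed=0)
        a = (cap.lower - cap.loc) / cap.scale
        b = (cap.upper - cap.loc) / cap.scale
        dist = stats.truncnorm(a, b, loc=cap.loc, scale=cap.scale)
        se = dist.std() / np.sqrt(n)
        assert abs(x.mean() - dist.mean()) < 3 * se

    def test_empirical_cdf_close_to_analytic(self):
        cap = kinetic_capacity("R", 5.0, UP_DEFAULT)
        x = np.sort(cap.sample(100_000, seed=1))
        a = (cap.lower - cap.loc) / cap.scale
        b = (cap.upper - cap.loc) / cap.scale
        F = stats.truncnorm(a, b, loc=cap.loc, scale=cap.scale).cdf(x)
        ecdf_hi = np.arange(1, x.size + 1) / x.size
        ecdf_lo = np.arange(0, x.size) / x.size
        ks = max(np.abs(ecdf_hi - F).max(), np.abs(F - ecdf_lo).max())
        assert ks < 0.01

    def test_empirical_resampling_support(self):
        cap = CapacityDistribution("R", DOWN,
                                   sample_values=np.linspace(1, 2, 150))
        draws = cap.sample(500, seed=2)
        assert set(np.round(draws, 12)) <= set(np.round(cap.sample_values, 12))


# --------------------------------------------------------------------------
# reference state estimation
# --------------------------------------------------------------------------

def _chain_ref(chain_model, vmax, measured=None):
    return estimate_reference_state(
        chain_model, VmaxVector(vmax), measured or {})


class TestReferenceState:
    def test_measured_uptake_pins_chain(self, chain_model):
        ref = _chain_ref(chain_model, {"R1": 10.0, "R2": 10.0, "R3": 10.0},
                         {"R1": 10.0})
        np.testing.assert_allclose(ref.SSU, [10, 10, 10])
        np.testing.assert_allclose(ref.SSL, [10, 10, 10])

    def test_unmeasured_chain(self, chain_model):
        ref = _chain_ref(chain_model, {"R1": 10.0, "R2": 10.0, "R3": 10.0})
        np.testing.assert_allclose(ref.SSL, 0.0)
        np.testing.assert_allclose(ref.SSU, [10, 10, 10])

    def test_branched_matches_vertex_enumeration(self):
        """1 uptake feeding 2 competing branches; measured uptake u.  The
        feasible set is the segment {vB1 + vB2 = u, 0 <= vBi <= ci}; its
        vertices give SSU/SSL exactly."""
        model = MetabolicModel(["A"], ["U", "B1", "B2"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool))
        u, c1, c2 = 8.0, 6.0, 5.0
        ref = estimate_reference_state(
            model, VmaxVector({"U": 10.0, "B1": c1, "B2": c2}), {"U": u})
        # vertex-enumeration oracle on the 1-D segment
        ssu_b1 = min(c1, u)           # push everything through B1 ...
        ssl_b1 = max(0.0, u - c2)     # ... or as little as B2 allows
        assert ref.ssu("B1") == pytest.approx(ssu_b1)
        assert ref.ssl("B1") == pytest.approx(ssl_b1)
        assert ref.ssu("B2") == pytest.approx(min(c2, u))
        assert ref.ssl("B2") == pytest.approx(max(0.0, u - c1))
        assert ref.ssu("U") == ref.ssl("U") == pytest.approx(u)

    def test_inconsistent_measurement_raises(self, chain_model):
        with pytest.raises(InfeasibleError):
            _chain_ref(chain_model, {"R1": 10.0, "R2": 5.0, "R3": 10.0},
                       {"R1": 10.0})

    def test_measurement_tol_relaxes(self, chain_model):
        ref = estimate_reference_state(
            chain_model, VmaxVector({"R1": 10.0, "R2": 10.0, "R3": 10.0}),
            {"R1": 8.0}, measurement_tol=0.25)
        assert ref.ssl("R1") == pytest.approx(6.0)
        assert ref.ssu("R1") == pytest.approx(10.0)

    def test_ssl_never_exceeds_ssu(self, chain_model):
        ref = _chain_ref(chain_model, {"R1": 3.0, "R2": 9.0, "R3": 7.0})
        assert (ref.SSL <= ref.SSU).all()

    def test_biomass_max_ignores_measurements(self):
        # biomass branch capped at 4; measured uptake of 2 would otherwise
        # limit it, but the wild-type maximum is measurement-free
        model = MetabolicModel(["A"], ["U", "Bio", "E"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool),
                               target_id="E", biomass_id="Bio")
        ref = estimate_reference_state(
            model, VmaxVector({"U": 10.0, "Bio": 4.0, "E": 10.0}), {"U": 2.0})
        assert ref.vbiomass_max == pytest.approx(4.0)
        assert ref.ssu("Bio") == pytest.approx(2.0)


class TestCompleteVmax:
    def test_chain_propagates_bound(self, chain_model):
        vmax = complete_vmax(chain_model, {"R1": 10.0})
        assert vmax["R2"] == pytest.approx(10.0)
        assert vmax["R3"] == pytest.approx(10.0)
        assert vmax.provenance == {"R1": "given", "R2": "completed",
                                   "R3": "completed"}

    def test_unbounded_reaction_detected(self):
        # B is produced/consumed by an R2/R3 loop never limited by R1's cap
        model = MetabolicModel(
            ["A", "B"], ["R1", "R2", "R3"],
            np.array([[1.0, -1.0, 1.0], [0.0, 1.0, -1.0]]),
            np.zeros(3, dtype=bool))
        with pytest.raises(UnboundedError, match="R2"):
            complete_vmax(model, {"R1": 10.0})

    def test_branched_matches_hand_lp(self):
        model = MetabolicModel(["A"], ["U", "B1", "B2"],
                               np.array([[1.0, -1.0, -1.0]]),
                               np.zeros(3, dtype=bool))
        vmax = complete_vmax(model, {"B1": 6.0, "B2": 5.0})
        assert vmax["U"] == pytest.approx(11.0)  # both branches saturated

    def test_empty_known_rejected(self, chain_model):
        with pytest.raises(ConfigurationError):
            complete_vmax(chain_model, {})
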