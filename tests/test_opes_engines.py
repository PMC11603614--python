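import numpy as np
import pytest
from scipy import integrate
from scipy.special import logsumexp

from oneopes.opes_engines import (
    BiasSettings,
    MultiThermalState,
    OPESExploreState,
    OPESKernel,
    multithermal_temperature_grid,
    total_bias,
)
from oneopes.oneopes_ladder import ReplicaSpec
from oneopes.units import KB

T = 298.0
KBT = KB * T


def make_state(barrier=50.0, sigma=0.1, pace=10, **kw):
    return OPESExploreState(sigma=[sigma], barrier=barrier, temperature=T, pace=pace, **kw)


class TestOPESKernel:
    def test_validation(self):
        with pytest.raises(ValueError):
            OPESKernel(np.zeros(1), np.array([-0.1]))
        with pytest.raises(ValueError):
            OPESKernel(np.zeros(1), np.array([0.1]), weight=0.0)


class TestOPESExploreBasics:
    def test_empty_state_bias_is_zero_everywhere(self):
        st = make_state()
        for s in (-5.0, 0.0, 3.2):
            assert st.bias(np.array([s])) == 0.0

    def test_single_deposit_peak_and_decay(self):
        st = make_state()
        st.deposit(np.array([0.3]))
        grid = np.linspace(-1.5, 2.0, 301)
        vals = np.array([st.bias(np.array([g])) for g in grid])
        peak = grid[np.argmax(vals)]
        assert peak == pytest.approx(0.3, abs=0.02)
        right = vals[grid >= 0.3]
        assert np.all(np.diff(right) <= 1e-12)
        left = vals[grid <= 0.3]
        assert np.all(np.diff(left) >= -1e-12)

    def test_identical_density_identical_bias(self):
        st = make_state()
        st.deposit(np.array([1.0]))
        # symmetric points around the kernel have identical density
        assert st.bias(np.array([0.6])) == pytest.approx(st.bias(np.array([1.4])), rel=1e-12)

    def test_far_field_reaches_epsilon_floor(self):
        st = make_state(barrier=20.0)
        st.deposit(np.array([0.0]))
        floor = st.prefactor * np.log(st.epsilon)
        assert floor == pytest.approx(-20.0)
        assert st.bias(np.array([50.0])) == pytest.approx(floor, abs=1e-9)
        assert st.bias(np.array([-50.0])) == pytest.approx(floor, abs=1e-9)

    def test_gamma_default_and_epsilon_convention(self):
        st = make_state(barrier=30.0)
        assert st.gamma == pytest.approx(30.0 / KBT)
        assert st.epsilon == pytest.approx(np.exp(-30.0 / ((st.gamma - 1) * KBT)))

    def test_barrier_must_exceed_kbt_unless_null(self):
        with pytest.raises(ValueError):
            make_state(barrier=1.0)  # gamma < 1
        null = make_state(barrier=0.0)
        null.deposit(np.array([0.0]))
        assert null.deposit_count == 0
        assert null.bias(np.array([0.0])) == 0.0

    def test_deposit_respects_pace(self):
        st = make_state(pace=5)
        st.deposit(np.array([0.0]), step=3)
        assert st.deposit_count == 0
        st.deposit(np.array([0.0]), step=5)
        assert st.deposit_count == 1

    def test_nonfinite_cv_aborts_with_step(self):
        st = make_state()
        with pytest.raises(FloatingPointError, match="step 7"):
            st.deposit(np.array([np.nan]), step=7)

    def test_gradient_matches_finite_difference(self, rng):
        st = make_state()
        for _ in range(5):
            st.deposit(rng.normal(0, 0.5, 1))
        for s in rng.normal(0, 1.0, 10):
            _, g = st.bias_and_grad(np.array([s]))
            h = 1e-6
            fd = (st.bias(np.array([s + h])) - st.bias(np.array([s - h]))) / (2 * h)
            assert g[0] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestBarrierContract:
    @pytest.mark.parametrize("barrier", [3.0, 20.0, 100.0])
    def test_range_never_exceeds_barrier(self, barrier, rng):
        # the BARRIER contract is algebraic: holds at every deposition count
        st = OPESExploreState(sigma=[0.08], barrier=barrier, temperature=T, pace=1)
        grid = np.linspace(-3, 3, 601)
        for i in range(60):
            st.deposit(rng.normal(0, 0.8, 1))
            if i % 10 == 0:
                assert st.bias_range(grid) <= barrier * (1 + 1e-6)
        assert st.bias_range(grid) <= barrier * (1 + 1e-6)

    def test_weak_multicv_barrier_three(self, rng):
        st = OPESExploreState(sigma=[0.1], barrier=3.0, temperature=T, pace=1)
        for _ in range(200):
            st.deposit(rng.normal(0, 0.5, 1))
        assert st.bias_range(np.linspace(-4, 4, 2001)) <= 3.0 * (1 + 1e-6)


class TestPeriodicKernels:
    def test_wrapped_distance(self):
        st = OPESExploreState(
            sigma=[0.3], barrier=20.0, temperature=T, pace=1,
            periodic=[True], periods=[2 * np.pi],
        )
        st.deposit(np.array([np.pi - 0.1]))
        # -pi+0.1 is 0.2 away through the boundary
        near = st.bias(np.array([-np.pi + 0.1]))
        far = st.bias(np.array([0.0]))
        assert near > far
        assert st.bias(np.array([np.pi - 0.1 + 2 * np.pi])) == pytest.approx(
            st.bias(np.array([np.pi - 0.1])), rel=1e-12
        )


class TestSerialization:
    def test_round_trip(self, rng):
        st = make_state()
        for _ in range(7):
            st.deposit(rng.normal(0, 0.4, 1))
        clone = OPESExploreState.from_dict(st.to_dict())
        for s in rng.normal(0, 1, 20):
            assert clone.bias(np.array([s])) == pytest.approx(st.bias(np.array([s])), rel=1e-12)

    def test_kernels_table_header(self):
        st = make_state()
        st.deposit(np.array([0.5]))
        table = st.kernels_table()
        assert table.startswith("#! FIELDS kernel_id center_0 sigma_0")
        assert len(table.strip().splitlines()) == 2


class TestMultiThermal:
    def test_temperature_grid_geometric(self):
        g = multithermal_temperature_grid(298.0, 370.0, 8)
        assert len(g) == 8
        assert g[0] == pytest.approx(298.0)
        assert g[-1] == pytest.approx(370.0)
        ratios = g[1:] / g[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_single_temperature_bias_zero(self):
        mt = MultiThermalState(298.0, 298.0)
        assert mt.n_temps == 1
        assert mt.bias(123.4) == 0.0

    def test_constant_energy_warns_and_stays_zero(self):
        mt = MultiThermalState(298.0, 370.0, pace=2)
        with pytest.warns(RuntimeWarning, match="constant potential energy"):
            for step in range(1, 5):
                mt.update(5.0, step)
        assert mt.bias(5.0) == pytest.approx(0.0, abs=1e-12)

    def test_offsets_match_harmonic_closed_form(self):
        # 3-D harmonic oscillator: p(U) ~ U^(1/2) exp(-beta0*U), so
        # <exp(-(b_l-b0)U)>_{b0} = (b0/b_l)^(3/2)  =>  f_l = 1.5*ln(b_l/b0)
        mt = MultiThermalState(298.0, 370.0, n_temps=6)
        beta0 = mt.beta0
        # deterministic quadrature "samples": U grid weighted by the exact
        # beta0 density
        u = np.linspace(1e-8, 80.0, 400001)
        logw = 0.5 * np.log(u) - beta0 * u
        f = MultiThermalState.offsets_from_samples(u, logw, mt.betas)
        expected = 1.5 * np.log(mt.betas / beta0)
        np.testing.assert_allclose(f, expected, atol=1e-6)
        # bias from these offsets matches an independent logsumexp evaluation
        mt.f = f
        for u0 in (0.5, 2.0, 10.0):
            expo = -(mt.betas - beta0) * u0 + f
            ref = -(logsumexp(expo) - np.log(mt.n_temps)) / beta0
            assert mt.bias(u0) == pytest.approx(ref, abs=1e-3)
            assert mt.bias(u0) == pytest.approx(ref, rel=1e-12)

    def test_gauge_invariance_under_energy_shift(self):
        mt = MultiThermalState(298.0, 370.0, n_temps=5)
        rng = np.random.default_rng(0)
        u = rng.exponential(2.0, size=5000)
        logw = np.zeros_like(u)
        f1 = MultiThermalState.offsets_from_samples(u, logw, mt.betas)
        f2 = MultiThermalState.offsets_from_samples(u + 17.0, logw, mt.betas)
        mt.f = f1
        v1 = mt.bias(3.0)
        mt.f = f2
        v2 = mt.bias(3.0 + 17.0)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_dvdu_matches_finite_difference(self):
        mt = MultiThermalState(298.0, 370.0, n_temps=6)
        mt.f = 0.5 * np.log(mt.betas / mt.beta0)
        for u0 in (1.0, 5.0, 20.0):
            _, dvdu = mt.bias_and_dvdu(u0)
            h = 1e-5
            fd = (mt.bias(u0 + h) - mt.bias(u0 - h)) / (2 * h)
            assert dvdu == pytest.approx(fd, rel=1e-6)

    def test_deltaf_gauge_zero_at_tmin(self):
        mt = MultiThermalState(298.0, 370.0)
        rng = np.random.default_rng(1)
        for step in range(1, 400):
            mt.update(rng.exponential(2.0), step)
        assert mt.deltaf_estimates[0] == 0.0


class TestTotalBias:
    def test_replica_zero_is_main_only(self):
        spec = ReplicaSpec(0, main_cvs=("z",))
        st = make_state()
        st.deposit(np.array([0.2]))
        v = total_bias(spec, [st], None, {"z": 0.2}, None)
        assert v == pytest.approx(st.bias(np.array([0.2])))

    def test_sum_matches_term_by_term(self, rng):
        spec = ReplicaSpec(
            4, main_cvs=("z",), aux_biases=(("w",), ("w",)), multithermal_tmax=350.0
        )
        states = [make_state() for _ in range(3)]
        for st in states:
            for _ in range(4):
                st.deposit(rng.normal(0, 0.3, 1))
        mt = MultiThermalState(298.0, 350.0)
        mt.f = 0.5 * np.log(mt.betas / mt.beta0)
        cvs = {"z": 0.1, "w": -0.4}
        v = total_bias(spec, states, mt, cvs, 2.5)
        manual = (
            states[0].bias(np.array([0.1]))
            + states[1].bias(np.array([-0.4]))
            + states[2].bias(np.array([-0.4]))
            + mt.bias(2.5)
        )
        assert v == pytest.approx(manual, rel=1e-12)

    def test_all_biases_empty_gives_zero(self):
        spec = ReplicaSpec(1, main_cvs=("z",), aux_biases=(("w",),))
        assert total_bias(spec, [make_state(), make_state()], None, {"z": 0, "w": 0}, None) == 0.0

    def test_roster_mismatch_raises(self):
        spec = ReplicaSpec(1, main_cvs=("z",), aux_biases=(("w",),))
        with pytest.raises(ValueError, match="bias states"):
            total_bias(spec, [make_state()], None, {"z": 0, "w": 0}, None)
        with pytest.raises(ValueError, match="MultiThermal"):
            total_bias(
                spec, [make_state(), make_state()],
                MultiThermalState(298.0, 350.0), {"z": 0, "w": 0}, 1.0,
            )


class TestMultiThermalReweighting:
    def test_reweighted_mean_energy_matches_canonical(self):
        # harmonic oscillator sampled under the MultiThermal bias; the
        # exp(+V/kBT)-reweighted mean energy must recover kB*T/2 (3 SE)
        k, dt = 50.0, 0.002
        kbt = KBT
        mt = MultiThermalState(T, 370.0, pace=50, n_temps=6)
        rng = np.random.default_rng(8)
        x = 0.0
        prev = rng.standard_normal()
        us, vs = [], []
        for step in range(1, 80001):
            u = 0.5 * k * x * x
            v, dvdu = mt.bias_and_dvdu(u)
            mt.update(u, step, log_weight=v / kbt)
            f = -k * x * (1.0 + dvdu)
            noise = rng.standard_normal()
            x += f * dt + np.sqrt(2 * kbt * dt) * 0.5 * (noise + prev)
            prev = noise
            if step > 20000 and step % 4 == 0:
                us.append(u)
                vs.append(v)
        us, vs = np.array(us), np.array(vs)
        w = np.exp((vs - vs.max()) / kbt)
        mean_u = float(np.sum(w * us) / np.sum(w))
        # crude SE: correlation time ~ 1/(k*dt) steps, thinned by 4
        n_eff = len(us) / (2 * (1.0 / (k * dt)) / 4)
        se = (kbt / 2) * np.sqrt(2.0 / n_eff)
        assert abs(mean_u - kbt / 2) < 3 * se


class TestBiasSettings:
    def test_published_defaults(self):
        s = BiasSettings()
        assert (s.main_barrier, s.main_pace) == (100.0, 10000)
        assert (s.aux_barrier, s.aux_pace) == (3.0, 20000)
        assert s.mt_pace == 100

    def test_toy_preset_keeps_pace_ordering(self):
        s = BiasSettings.toy_preset(50000)
        assert s.aux_pace == s.main_pace
        assert s.mt_pace <= s.main_pace


@pytest.fixture(scope="module")
def converged_double_well_run():
    """Shared biased run on a small double well for the distribution and
    flatness oracles (kept short; tolerances are set accordingly)."""
    from oneopes.oneopes_ladder import build_toy_ladder, run_oneopes
    from oneopes.toy_systems import DoubleWellSystem

    barrier = 6.0 * KBT
    sys_ = DoubleWellSystem(barrier_height=barrier, minima_sep=2.0)
    steps = 250000
    ladder = build_toy_ladder(
        ("x",), None, n_replicas=1, steps=steps, seed=11, exchange_stride=10**9
    )
    settings = BiasSettings.toy_preset(steps, main_barrier=barrier + 15.0)
    run = run_oneopes(sys_, ladder, settings, dt=0.001, record_stride=4)
    return sys_, run, settings


class TestExploreConvergence:
    def test_sampled_distribution_near_well_tempered_target(self, converged_double_well_run):
        # TV distance between the sampled x histogram and [P(x)]^(1/gamma)
        sys_, run, settings = converged_double_well_run
        gamma = settings.main_barrier / KBT
        x = run.trajectories[0].cv_values["x"]
        x = x[len(x) // 2 :]
        grid = np.linspace(-1.6, 1.6, 33)
        hist, _ = np.histogram(x, bins=grid, density=True)
        centers = 0.5 * (grid[:-1] + grid[1:])
        f = sys_.free_energy_profile(centers, T)
        target = np.exp(-f / (gamma * KBT))
        target /= np.trapezoid(target, centers)
        width = grid[1] - grid[0]
        tv = 0.5 * np.sum(np.abs(hist - target)) * width
        assert tv < 0.1

    def test_bias_plus_free_energy_flat_on_sampled_region(self, converged_double_well_run):
        sys_, run, settings = converged_double_well_run
        st = run.explore_states[0][0]
        grid = np.linspace(-1.2, 1.2, 49)
        f = sys_.free_energy_profile(grid, T)
        v = np.array([st.bias(np.array([g])) for g in grid])
        resid = v + (1 - 1 / st.gamma) * f
        # flatness up to the (1-1/gamma)-scaled convergence tolerance
        assert np.max(resid) - np.min(resid) < (1 - 1 / st.gamma) * 3.5


class TestDeterminism:
    def test_same_seed_identical_kernels_and_bias(self):
        from oneopes.oneopes_ladder import build_toy_ladder, run_oneopes
        from oneopes.toy_systems import DoubleWellSystem

        def go():
            sys_ = DoubleWellSystem(barrier_height=8.0, minima_sep=1.5)
            ladder = build_toy_ladder(
                ("x",), None, n_replicas=2, steps=2000, seed=77, exchange_stride=500
            )
            return run_oneopes(sys_, ladder, BiasSettings.toy_preset(2000), dt=0.001)

        a, b = go(), go()
        np.testing.assert_array_equal(
            a.explore_states[0][0].centers, b.explore_states[0][0].centers
        )
        np.testing.assert_array_equal(
            a.trajectories[1].cv_values["x"], b.trajectories[1].cv_values["x"]
        )
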