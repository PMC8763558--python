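import numpy as np
import pytest

from swarmfs.chaos import Bounds
from swarmfs.sailfish import (
    SFOConfig,
    SwarmState,
    capture_and_replace,
    compute_atk,
    compute_mu,
    compute_pd,
    optimize,
    update_sailfish,
    update_sardines,
)


def sphere(x):
    return float(np.sum(x * x))


class _FixedRng:
    """Stub generator returning a constant for every uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        return self.value if size is None else np.full(size, self.value)


def _state_1d(sailfish, sardines, elite, injured):
    sf = np.asarray(sailfish, dtype=float)[:, None]
    sd = np.asarray(sardines, dtype=float)[:, None]
    return SwarmState(
        sailfish_pos=sf.copy(),
        sailfish_fit=np.array([sphere(x) for x in sf]),
        sardine_pos=sd.copy(),
        sardine_fit=np.array([sphere(x) for x in sd]),
        elite_pos=np.array([float(elite)]),
        elite_fit=sphere(np.array([elite])),
        injured_pos=np.array([float(injured)]),
        injured_fit=sphere(np.array([injured])),
    )


class TestCoefficients:
    def test_prey_density_values(self):
        assert compute_pd(30, 100) == pytest.approx(100 / 130)
        assert compute_pd(17, 17) == 0.5
        assert compute_pd(9, 0) == 0.0
        with pytest.raises(ValueError):
            compute_pd(0, 0)

    def test_mu_range_and_extremes(self):
        assert compute_mu(0.8, 0.5) == pytest.approx(0.0)
        assert compute_mu(0.8, 1.0) == pytest.approx(0.8)
        assert compute_mu(0.8, 0.0) == pytest.approx(-0.8)

    def test_attack_power_schedule(self):
        assert compute_atk(0, 4.0, 0.001) == 4.0
        assert compute_atk(250, 4.0, 0.001) == pytest.approx(2.0)
        assert compute_atk(500, 4.0, 0.001) == pytest.approx(0.0)


class TestSailfishUpdate:
    def test_midpoint_position_collapses_to_elite(self):
        st = _state_1d(sailfish=[1.0], sardines=[0.0], elite=2.0, injured=0.0)
        new = update_sailfish(st, mu=0.7, rng=_FixedRng(0.3), bounds=Bounds.cube(-10, 10, 1))
        assert new[0, 0] == pytest.approx(2.0)

    def test_zero_mu_sends_everyone_to_elite(self):
        st = _state_1d(sailfish=[5.0, -3.0], sardines=[0.0], elite=2.0, injured=0.0)
        new = update_sailfish(st, mu=0.0, rng=_FixedRng(0.9), bounds=Bounds.cube(-10, 10, 1))
        assert np.allclose(new, 2.0)

    def test_hand_evaluated_step(self):
        # elite 2, injured 0, sailfish 3, mu*r = 0.5 -> 2 - 0.5*(1 - 3) = 3
        st = _state_1d(sailfish=[3.0], sardines=[0.0], elite=2.0, injured=0.0)
        new = update_sailfish(st, mu=0.5, rng=_FixedRng(1.0), bounds=Bounds.cube(-10, 10, 1))
        assert new[0, 0] == pytest.approx(3.0)


class TestSardineUpdate:
    def test_full_update_hand_value(self):
        # r = 1: new = elite - x + atk = 5 - 2 + 0.6
        st = _state_1d(sailfish=[0.0], sardines=[2.0], elite=5.0, injured=2.0)
        new = update_sardines(st, atk=0.6, rng=_FixedRng(1.0), bounds=Bounds.cube(-10, 10, 1))
        assert new[0, 0] == pytest.approx(3.6)

    def test_zero_r_zeroes_updated_entries(self):
        st = _state_1d(sailfish=[0.0], sardines=[2.0, -4.0], elite=5.0, injured=2.0)
        new = update_sardines(st, atk=0.9, rng=_FixedRng(0.0), bounds=Bounds.cube(-10, 10, 1))
        assert np.allclose(new, 0.0)

    def test_partial_update_counts(self):
        # atk = 0.4 with 50 sardines and 13 dims: 20 sardines, 5 dims each
        rng = np.random.default_rng(3)
        sd = rng.normal(size=(50, 13))
        st = SwarmState(
            sailfish_pos=np.zeros((1, 13)),
            sailfish_fit=np.zeros(1),
            sardine_pos=sd.copy(),
            sardine_fit=np.zeros(50),
            elite_pos=np.full(13, 5.0),
            elite_fit=0.0,
            injured_pos=np.zeros(13),
            injured_fit=0.0,
        )
        new = update_sardines(st, atk=0.4, rng=np.random.default_rng(7), bounds=Bounds.cube(-100, 100, 13))
        changed_rows = np.flatnonzero(np.any(new != sd, axis=1))
        assert changed_rows.size == 20
        per_row = np.sum(new[changed_rows] != sd[changed_rows], axis=1)
        assert np.all(per_row == 5)

    def test_no_update_at_zero_attack(self):
        st = _state_1d(sailfish=[0.0], sardines=[2.0], elite=5.0, injured=2.0)
        new = update_sardines(st, atk=0.0, rng=_FixedRng(0.5), bounds=Bounds.cube(-10, 10, 1))
        assert np.array_equal(new, st.sardine_pos)


class TestCapture:
    def test_better_sardine_is_captured_and_removed(self):
        st = _state_1d(sailfish=[np.sqrt(2.0)], sardines=[1.0], elite=np.sqrt(2.0), injured=1.0)
        capture_and_replace(st)
        assert st.sardine_fit.size == 0
        assert st.sailfish_fit[0] == pytest.approx(1.0)

    def test_equal_fitness_is_not_captured(self):
        st = _state_1d(sailfish=[2.0], sardines=[-2.0], elite=2.0, injured=-2.0)
        capture_and_replace(st)
        assert st.sardine_fit.size == 1
        assert st.sailfish_pos[0, 0] == pytest.approx(2.0)

    def test_single_sardine_goes_to_the_worse_sailfish(self):
        st = _state_1d(sailfish=[3.0, 2.0], sardines=[1.0], elite=2.0, injured=1.0)
        capture_and_replace(st)
        # sailfish 0 (fitness 9) is served first and captures; sailfish 1 unchanged
        assert st.sailfish_pos[0, 0] == pytest.approx(1.0)
        assert st.sailfish_pos[1, 0] == pytest.approx(2.0)
        assert st.sardine_fit.size == 0

    def test_empty_sardines_is_a_noop(self):
        st = _state_1d(sailfish=[3.0], sardines=[], elite=3.0, injured=0.0)
        before = st.sailfish_pos.copy()
        capture_and_replace(st)
        assert np.array_equal(st.sailfish_pos, before)


class TestOptimize:
    def test_constant_objective_flat_history(self):
        cfg = SFOConfig(num_sardines=10, max_iter=20, seed=1, bounds=Bounds.cube(-1, 1, 3))
        res = optimize(lambda x: 7.5, cfg)
        assert res.best_fit == 7.5
        assert np.all(res.history == 7.5)

    def test_determinism(self):
        cfg = SFOConfig(num_sardines=20, max_iter=30, seed=5, bounds=Bounds.cube(-5, 5, 4))
        a, b = optimize(sphere, cfg), optimize(sphere, cfg)
        assert a.best_fit == b.best_fit
        assert np.array_equal(a.best_pos, b.best_pos)
        assert np.array_equal(a.history, b.history)
        assert a.evaluations == b.evaluations

    @pytest.mark.parametrize("chaos", [True, False])
    def test_history_monotone_and_bounds_respected(self, chaos):
        bounds = Bounds.cube(-5, 5, 4)
        cfg = SFOConfig(num_sardines=20, max_iter=40, seed=2, bounds=bounds, chaos_init=chaos)
        seen = []
        res = optimize(lambda x: (seen.append(x.copy()), sphere(x))[1], cfg)
        assert np.all(np.diff(res.history) <= 1e-15)
        pts = np.array(seen)
        assert np.all(pts >= bounds.lower - 1e-12) and np.all(pts <= bounds.upper + 1e-12)
        assert np.all(np.abs(res.best_pos) <= 5 + 1e-12)

    def test_evaluation_counter_audits_objective_calls(self):
        calls = [0]

        def counting(x):
            calls[0] += 1
            return sphere(x)

        cfg = SFOConfig(num_sardines=15, max_iter=25, seed=9, bounds=Bounds.cube(-3, 3, 2))
        res = optimize(counting, cfg)
        assert res.evaluations == calls[0]

    def test_non_finite_objective_becomes_inf(self):
        def nasty(x):
            return np.nan if x[0] > 0 else sphere(x)

        cfg = SFOConfig(num_sardines=10, max_iter=5, seed=3, bounds=Bounds.cube(-1, 1, 2))
        res = optimize(nasty, cfg)
        assert np.isfinite(res.best_fit)
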