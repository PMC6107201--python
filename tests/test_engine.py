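"""Single-night dynamics: kinematics, mating resolution, event accounting."""

import math

import numpy as np
import pytest

from chorusim import (
    SimulationConfig,
    Strategy,
    move_toward,
    outcomes_to_frame,
    run_simulation,
)


class TestMoveToward:
    def test_straight_step(self):
        new, delta = move_toward((0, 0), (0, 100), 10)
        np.testing.assert_allclose(new, [0, 10])
        assert delta == 10

    def test_never_overshoots(self):
        new, delta = move_toward((0, 97), (0, 100), 10)
        np.testing.assert_allclose(new, [0, 100])
        assert delta == pytest.approx(3)

    def test_converges_in_ceil_d_over_speed_cycles(self):
        pos = np.array([3.0, 4.0])  # distance 5 from origin target
        steps = 0
        while not np.allclose(pos, 0):
            pos, _ = move_toward(pos, (0, 0), 2)
            steps += 1
        assert steps == math.ceil(5 / 2)

    def test_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError):
            move_toward((0, 0), (1, 1), 0)


class TestSingleFemaleKinematics:
    @pytest.mark.parametrize("kind,param", [
        ("best_of_n", 1), ("min_threshold", 1), ("random", None)])
    def test_mates_at_predicted_cycle_and_distance(self, kind, param):
        """With one female and no competition, arrival time and travel
        distance follow directly from start-to-mate geometry."""
        cfg = SimulationConfig(strategy=Strategy(kind, param), n_females=1,
                               n_males=25, pop_mean=12.0, seed=31)
        res = run_simulation(cfg, record_events=True)
        (o,) = res.outcomes
        assert o.mated
        mate = res.events[-1].new_target
        d0 = float(np.hypot(*(res.male_positions[mate]
                              - res.female_start_positions[0])))
        expected_cycles = max(1, math.ceil((d0 - cfg.contact_radius)
                                           / cfg.speed))
        assert o.cycles_active == expected_cycles
        assert o.distance_cm == pytest.approx(
            min(d0, expected_cycles * cfg.speed))
        assert o.n_targets == 1  # nobody stole the target


class TestThresholdRemoval:
    def test_unreachable_threshold_removes_all_after_one_step(self):
        """θ far above the population mean: no acceptable male ever exists,
        every female walks one cycle and leaves unmated."""
        for seed in range(8):
            cfg = SimulationConfig(strategy=Strategy("min_threshold", 24),
                                   n_females=10, pop_mean=6.0, seed=seed)
            res = run_simulation(cfg)
            if (res.male_pulsenumbers >= 24).any():  # astronomically rare
                continue
            assert res.cycles == 1
            for o in res.outcomes:
                assert not o.mated
                assert o.mate_pulsenumber is None
                assert o.distance_cm == pytest.approx(cfg.speed)
                assert o.cycles_active == 1
                assert o.n_targets == 0

    def test_low_threshold_everyone_mates(self):
        cfg = SimulationConfig(strategy=Strategy("min_threshold", 6),
                               n_females=10, pop_mean=18.0, seed=3)
        res = run_simulation(cfg)
        assert all(o.mated for o in res.outcomes)


class TestDeterminismAndConservation:
    @pytest.mark.parametrize("kind,param", [
        ("best_of_n", 3), ("best_of_n_no_switch", 3),
        ("min_threshold", 12), ("random", None)])
    def test_same_seed_same_outcomes(self, kind, param, make_config):
        cfg = make_config(kind, param, n_females=15, seed=99)
        a = run_simulation(cfg, record_events=True)
        b = run_simulation(cfg, record_events=True)
        assert a.outcomes == b.outcomes
        assert a.events == b.events
        assert a.cycles == b.cycles

    @pytest.mark.parametrize("kind,param", [
        ("best_of_n", 5), ("min_threshold", 12), ("random", None)])
    def test_each_male_mates_at_most_once(self, kind, param, make_config):
        for seed in range(5):
            res = run_simulation(make_config(kind, param, n_females=20,
                                             seed=seed), record_events=True)
            mates = [_final_target(res, o.female_id)
                     for o in res.outcomes if o.mated]
            assert len(mates) == len(set(mates))
            assert sum(o.mated for o in res.outcomes) <= min(20, 25)

    def test_statuses_resolve_exactly_once(self, make_config):
        res = run_simulation(make_config("best_of_n", 2, n_females=20))
        assert len(res.outcomes) == 20
        for o in res.outcomes:
            assert o.mated == (o.mate_pulsenumber is not None)
            assert o.cycles_active >= 1


def _final_target(res, female_id):
    evs = [e for e in res.events if e.female_id == female_id]
    return evs[-1].new_target if evs else None


class TestEventAccounting:
    def test_best_of_n_switches_only_trade_up(self, make_config):
        """A target change not caused by the old target mating must strictly
        increase target quality."""
        for seed in range(6):
            res = run_simulation(make_config("best_of_n", 5, n_females=20,
                                             seed=seed), record_events=True)
            for e in res.events:
                if e.reason == "better_male":
                    assert e.new_pulsenumber > e.old_pulsenumber
            n_ev = {o.female_id: 0 for o in res.outcomes}
            for e in res.events:
                n_ev[e.female_id] += 1
            for o in res.outcomes:
                assert o.n_targets == n_ev[o.female_id]

    @pytest.mark.parametrize("kind,param", [
        ("min_threshold", 12), ("random", None),
        ("best_of_n_no_switch", 3)])
    def test_event_driven_rules_retarget_only_on_mating(self, kind, param,
                                                        make_config):
        """For threshold/random/no-switch females the number of distinct
        targets is 1 + (times their target mated with another female)."""
        res = run_simulation(make_config(kind, param, n_females=20, seed=5),
                             record_events=True)
        stolen = {o.female_id: 0 for o in res.outcomes}
        for e in res.events:
            assert e.reason in ("init", "target_mated")
            if e.reason == "target_mated":
                stolen[e.female_id] += 1
        for o in res.outcomes:
            if o.n_targets:
                assert o.n_targets == 1 + stolen[o.female_id]

    def test_mated_distance_bounded_below_by_geometry(self, make_config):
        """Travel of a mated female is at least the straight-line distance
        from her start to her mate minus the contact radius."""
        res = run_simulation(make_config("best_of_n", 3, n_females=15,
                                         seed=13), record_events=True)
        for o in res.outcomes:
            if not o.mated:
                continue
            mate = _final_target(res, o.female_id)
            straight = np.hypot(*(res.male_positions[mate]
                                  - res.female_start_positions[o.female_id]))
            assert o.distance_cm >= straight - res.config.contact_radius - 1e-9


class TestSpeedInvariance:
    @pytest.mark.parametrize("kind,param", [
        ("min_threshold", 12), ("random", None), ("best_of_n", 3)])
    def test_halving_speed_preserves_single_female_outcome(self, kind, param):
        """The movement rate must not hide dynamics: with no competition the
        mate is unchanged and travel differs by less than one step."""
        for seed in range(5):
            outs = {}
            for speed in (2.0, 1.0):
                cfg = SimulationConfig(strategy=Strategy(kind, param),
                                       n_females=1, pop_mean=12.0,
                                       speed=speed, seed=seed)
                res = run_simulation(cfg)
                outs[speed] = res.outcomes[0]
            assert outs[2.0].mate_pulsenumber == outs[1.0].mate_pulsenumber
            assert abs(outs[2.0].distance_cm
                       - outs[1.0].distance_cm) <= 2.0 + 1e-9


class TestRunBookkeeping:
    def test_cycle_cap_reported_not_raised(self, make_config):
        res = run_simulation(make_config("random", None, n_females=5,
                                         max_cycles=3, seed=0))
        assert res.hit_time_limit
        assert all(not o.mated for o in res.outcomes)

    def test_outcomes_frame_carries_condition_labels(self, make_config):
        res = run_simulation(make_config("best_of_n", 2, seed=1))
        df = outcomes_to_frame(res)
        assert set(df.columns) >= {
            "strategy_class", "param", "strategy", "pop_mean", "n_females",
            "distribution", "seed", "mated", "mate_pulsenumber",
            "distance_cm", "n_targets"}
        assert (df["strategy"] == "best_of_n:2").all()

    def test_full_mating_for_nonthreshold_strategies(self, make_config):
        for kind, param in (("best_of_n", 4), ("random", None)):
            res = run_simulation(make_config(kind, param, n_females=20,
                                             seed=2))
            assert all(o.mated for o in res.outcomes)
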