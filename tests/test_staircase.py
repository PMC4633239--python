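"""Staircase update rules, interleaved scheduling, and run constraint."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfmotion.staircase import (
    BlockDesign,
    BlockScheduler,
    Response,
    StaircaseConfig,
    StaircaseError,
    init_staircase,
    run_block,
    update,
)

R, L, N = Response.RIGHT, Response.LEFT, Response.NONE


def drive(state, responses):
    for r in responses:
        state = update(state, r)
    return state


class TestUpdateRules:
    def test_initial_state_at_maximum_with_step_four(self):
        s = init_staircase(StaircaseConfig())
        assert s.current_magnitude == 10.0
        assert s.current_step == 4.0
        assert s.history == ()

    def test_first_rightward_response_moves_ten_to_six(self):
        s = update(init_staircase(StaircaseConfig()), R)
        assert s.current_magnitude == 6.0

    def test_reversal_halves_step(self):
        s = drive(init_staircase(StaircaseConfig()), [R, L])
        assert s.current_step == 2.0

    def test_step_never_below_minimum(self):
        s = init_staircase(StaircaseConfig())
        # alternate responses until the step pins at the minimum
        s = drive(s, [R, L, R, L, R, L, R, L])
        assert s.current_step == 0.25
        s = drive(s, [R, L])
        assert s.current_step == 0.25

    def test_three_in_a_row_doubles_and_retriggers_to_maximum(self):
        cfg = StaircaseConfig(initial_step=1.0)
        s = init_staircase(cfg)
        steps = []
        for _ in range(5):
            s = update(s, R)
            steps.append(s.current_step)
        assert steps == [1.0, 1.0, 2.0, 4.0, 4.0]

    def test_always_right_trace_matches_hand_simulation(self):
        # independent oracle: the update rules executed by hand for 10 trials
        expected = [10.0, 6.0, 2.0, -2.0, -6.0, -10.0, -10.0, -10.0, -10.0, -10.0]
        s = init_staircase(StaircaseConfig())
        trace = []
        for _ in range(10):
            trace.append(s.current_magnitude)
            s = update(s, R)
        assert trace == expected

    def test_none_response_is_logged_but_not_counted(self):
        s = init_staircase(StaircaseConfig())
        s2 = update(s, N)
        assert s2.current_magnitude == s.current_magnitude
        assert s2.current_step == s.current_step
        assert s2.history == ()
        assert len(s2.events) == 1

    def test_single_step_staircase_completes(self):
        s = update(init_staircase(StaircaseConfig(n_steps=1)), L)
        assert s.completed
        with pytest.raises(StaircaseError):
            update(s, R)

    def test_invalid_step_ordering_rejected(self):
        with pytest.raises(ValueError):
            StaircaseConfig(min_step=5.0, initial_step=4.0)
        with pytest.raises(ValueError):
            StaircaseConfig(n_steps=0)
        with pytest.raises(ValueError):
            StaircaseConfig(initial_magnitude=12.0, magnitude_limit=10.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([R, L, N]), min_size=1, max_size=40))
def test_state_invariants_under_arbitrary_responses(responses):
    cfg = StaircaseConfig()
    s = init_staircase(cfg)
    for r in responses:
        if s.completed:
            break
        s = update(s, r)
        assert cfg.min_step <= s.current_step <= cfg.max_step
        assert abs(s.current_magnitude) <= cfg.magnitude_limit
    assert s.completed == (len(s.history) == cfg.n_steps)


def _design(n_staircases, n_steps=25, max_run=5):
    if n_staircases == 1:
        conditions = {"control": "control"}
        configs = {"control": StaircaseConfig(n_steps=n_steps)}
    else:
        conditions = {"star_left": "star_left", "star_right": "star_right"}
        configs = {
            "star_left": StaircaseConfig(initial_magnitude=-10.0, n_steps=n_steps),
            "star_right": StaircaseConfig(initial_magnitude=10.0, n_steps=n_steps),
        }
    return BlockDesign(
        block_label="blk", block_type="star_sway", axis="sway",
        conditions=conditions, configs=configs, max_run=max_run,
    )


def random_responder(rng, p_right=0.5):
    return lambda condition, v: R if rng.random() < p_right else L


class TestBlockScheduling:
    def test_control_block_yields_25_counted_trials(self):
        rng = np.random.default_rng(0)
        trials = list(run_block(_design(1), random_responder(rng), rng))
        assert sum(t.counted for t, _ in trials) == 25

    def test_experimental_block_yields_50_counted_trials(self):
        rng = np.random.default_rng(0)
        trials = list(run_block(_design(2), random_responder(rng), rng))
        assert sum(t.counted for t, _ in trials) == 50

    def test_schedule_is_deterministic_under_fixed_seed(self):
        def go():
            rng = np.random.default_rng(1234)
            resp = random_responder(np.random.default_rng(77))
            return [(t.staircase_id, t.magnitude) for t, _ in run_block(_design(2), resp, rng)]

        assert go() == go()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_run_constraint_violations_are_flagged(self, seed):
        """No more than max_run consecutive same-direction stimuli unless the
        trial is explicitly flagged unresolvable."""
        rng = np.random.default_rng(seed)
        resp = random_responder(np.random.default_rng(seed + 100), p_right=0.8)
        run_dir, run_len = 0, 0
        for trial, _ in run_block(_design(2), resp, rng):
            d = np.sign(trial.magnitude)
            run_len = run_len + 1 if (d == run_dir and d != 0) else 1
            run_dir = d
            if run_len > 5:
                assert trial.run_violation
                run_len = 1  # restart accounting after a flagged violation

    def test_interleaved_staircases_evolve_independently(self):
        """Each staircase's magnitude trace depends only on its own responses."""
        script = {"star_left": [R, L] * 13, "star_right": [L, L, R] * 9}
        seen = {"star_left": [], "star_right": []}

        def respond_for(cond_trace):
            def respond(condition, v):
                i = len(seen[condition])
                seen[condition].append(v)
                return script[condition][i]
            return respond

        rng = np.random.default_rng(5)
        for trial, _ in run_block(_design(2), respond_for(script), rng):
            pass

        for sid in ("star_left", "star_right"):
            cfg = StaircaseConfig(initial_magnitude=-10.0 if sid.endswith("left") else 10.0)
            s = init_staircase(cfg)
            solo = []
            for r in script[sid][:25]:
                solo.append(2.0 * s.current_magnitude)
                s = update(s, r)
            assert seen[sid] == solo

    def test_record_must_follow_next_trial(self):
        rng = np.random.default_rng(0)
        sched = BlockScheduler(_design(2), rng)
        with pytest.raises(StaircaseError):
            sched.record("star_left", R)

    def test_none_responses_do_not_consume_steps(self):
        rng = np.random.default_rng(3)
        resp_rng = np.random.default_rng(4)

        def respond(condition, v):
            r = resp_rng.random()
            if r < 0.2:
                return N
            return R if r < 0.6 else L

        trials = list(run_block(_design(2), respond, rng))
        counted = [t for t, _ in trials if t.counted]
        uncounted = [t for t, _ in trials if not t.counted]
        assert len(counted) == 50
        assert len(uncounted) > 0


def test_block_design_requires_one_or_two_staircases():
    with pytest.raises(ValueError):
        BlockDesign(
            block_label="b", block_type="star_sway", axis="sway",
            conditions={}, configs={},
        )
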