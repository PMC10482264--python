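"""Task schedulers, agents, and task execution."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from tracemem import (
    AgentContractError,
    Agent,
    FaithfulAgent,
    RandomAgent,
    TraceAgent,
    TraceParams,
    TrialLog,
    run_task,
    schedule_delayed_mts,
    schedule_mts,
    schedule_probe_phase,
    schedule_sequence_task,
    windowed_criterion,
)


class TestMTSScheduler:
    def test_colour_and_side_balance_per_window(self):
        specs = schedule_mts("simultaneous_mts", 50, seed=7)
        for w in range(5):
            window = specs[w * 10:(w + 1) * 10]
            colours = Counter(s.rewarded_option for s in window)
            sides = Counter(
                "left" if s.options[0] == s.rewarded_option else "right"
                for s in window)
            assert colours == {"A": 5, "B": 5}
            assert sides == {"left": 5, "right": 5}

    def test_determinism(self):
        a = schedule_mts("zero_delay_mts", 30, seed=3)
        b = schedule_mts("zero_delay_mts", 30, seed=3)
        assert a == b
        c = schedule_mts("zero_delay_mts", 30, seed=4)
        assert a != c

    def test_partial_window_warns(self):
        with pytest.warns(UserWarning, match="not a multiple of 10"):
            schedule_mts("simultaneous_mts", 13, seed=0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            schedule_mts("simultaneous_mts", 0, seed=0)
        with pytest.raises(ValueError):
            schedule_mts("sequence_disc", 10, seed=0)


class TestDelayedMTSScheduler:
    def test_every_second_trial_is_zero_delay(self):
        specs = schedule_delayed_mts(8, (0, 2, 5, 10), seed=1)
        assert [s.delay for s in specs[::2]] == [0.0] * 4
        assert all(s.delay in (2.0, 5.0, 10.0) for s in specs[1::2])

    def test_balanced_nonzero_delays(self):
        specs = schedule_delayed_mts(1200, (0, 2, 5, 10), seed=2)
        nonzero = Counter(s.delay for s in specs[1::2])
        assert nonzero == {2.0: 200, 5.0: 200, 10.0: 200}

    def test_zero_only_delay_set(self):
        specs = schedule_delayed_mts(10, (0,), seed=0)
        assert all(s.delay == 0.0 for s in specs)

    def test_invalid_delay_sets(self):
        with pytest.raises(ValueError):
            schedule_delayed_mts(10, (), seed=0)
        with pytest.raises(ValueError):
            schedule_delayed_mts(10, (2, 5), seed=0)  # must contain 0


class TestSequenceScheduler:
    def test_block_composition(self):
        specs = schedule_sequence_task(5, seed=9)
        for b in range(5):
            block = specs[b * 18:(b + 1) * 18]
            assert Counter(s.trial_type for s in block) == {
                "AB": 9, "AA": 3, "BA": 3, "BB": 3}

    def test_reward_sides(self):
        for s in schedule_sequence_task(2, seed=0):
            assert s.rewarded_option == ("left" if s.trial_type == "AB"
                                         else "right")

    def test_timing(self):
        s = schedule_sequence_task(1, seed=0)[0]
        e1, e2 = s.sample_events
        assert e1.duration == pytest.approx(1.0)
        assert e2.duration == pytest.approx(1.0)
        assert e2.onset - e1.offset == pytest.approx(0.3)

    def test_seeds_change_order_not_composition(self):
        a = schedule_sequence_task(3, seed=1)
        b = schedule_sequence_task(3, seed=2)
        assert a != b
        for blk in range(3):
            assert (Counter(s.trial_type for s in a[blk * 18:(blk + 1) * 18])
                    == Counter(s.trial_type for s in b[blk * 18:(blk + 1) * 18]))

    def test_counterbalanced_assignment_relabels_stimuli(self):
        specs = schedule_sequence_task(
            1, seed=0, assignment={"A": "yellow", "B": "blue"})
        ids = {e.stimulus_id for s in specs for e in s.sample_events}
        assert ids == {"yellow", "blue"}

    def test_invalid_blocks(self):
        with pytest.raises(ValueError):
            schedule_sequence_task(0, seed=0)


class TestProbeScheduler:
    def test_default_design_counts(self):
        specs = schedule_probe_phase(seed=5)
        probes = [s for s in specs if s.is_probe]
        assert len(probes) == 120          # 20 reps x 6 conditions
        assert len(specs) == 1200          # one probe per 10-trial block

    def test_one_probe_per_block_and_probe_structure(self):
        specs = schedule_probe_phase(reps_per_condition=2, seed=6)
        by_block = {}
        for s in specs:
            by_block.setdefault(s.block_index, []).append(s)
        for block in by_block.values():
            probes = [s for s in block if s.is_probe]
            assert len(probes) == 1
            probe = probes[0]
            assert probe.rewarded_option is None
            first, second = probe.sample_ids
            assert first != second
            assert set(probe.sample_ids) <= set(probe.options)
            assert len(probe.options) == 4

    def test_probe_position_uniform(self):
        # positions of the probe within blocks should be uniform on 1..10
        specs = schedule_probe_phase(
            conditions=[(1.0, 1.0)], reps_per_condition=2000, seed=8)
        positions = Counter()
        for s in specs:
            if s.is_probe:
                positions[(s.trial_index - 1) % 10] += 1
        counts = [positions[i] for i in range(10)]
        stat, p = sps.chisquare(counts)
        assert p > 0.01

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            schedule_probe_phase(pool_size=3, seed=0)


class TestRunTask:
    def test_random_agent_near_chance_on_four_options(self):
        specs = schedule_probe_phase(reps_per_condition=10, seed=1)
        log = run_task(RandomAgent(), specs, seed=2)
        baseline = [r for r in log if not r.spec.is_probe]
        acc = np.mean([r.correct for r in baseline])
        assert abs(acc - 0.25) < 0.05

    def test_always_correct_agent_has_no_corrections(self):
        class Oracle(Agent):
            def act(self, spec, rng):
                return spec.rewarded_option

        log = run_task(Oracle(), schedule_sequence_task(3, seed=1),
                       correction=True, seed=2)
        assert sum(r.spec.is_correction for r in log) == 0
        assert len(log) == 54

    def test_correction_bookkeeping(self):
        # corrections immediately follow the error, repeat its type, and
        # their count equals the number of incorrect responses
        log = run_task(RandomAgent(), schedule_sequence_task(4, seed=3),
                       correction=True, seed=4)
        results = log.results
        n_wrong = sum(not r.correct for r in results)
        n_corr = sum(r.spec.is_correction for r in results)
        assert n_corr == n_wrong
        for i, r in enumerate(results[:-1]):
            if not r.correct:
                nxt = results[i + 1].spec
                assert nxt.is_correction
                assert nxt.trial_type == r.spec.trial_type

    def test_probe_trials_never_rewarded(self):
        specs = schedule_probe_phase(reps_per_condition=2, seed=5)
        log = run_task(RandomAgent(), specs, seed=6)
        assert all(not r.rewarded for r in log if r.spec.is_probe)

    def test_offscreen_response_raises(self):
        class Broken(Agent):
            def act(self, spec, rng):
                return "nonsense"

        with pytest.raises(AgentContractError):
            run_task(Broken(), schedule_sequence_task(1, seed=0), seed=0)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            run_task(RandomAgent(), [], seed=0)

    def test_determinism(self):
        a = run_task(TraceAgent(TraceParams()),
                     schedule_sequence_task(2, seed=7), correction=True, seed=8)
        b = run_task(TraceAgent(TraceParams()),
                     schedule_sequence_task(2, seed=7), correction=True, seed=8)
        assert a.to_frame().equals(b.to_frame())

    def test_session_cap_splits_sessions(self):
        log = run_task(RandomAgent(), schedule_sequence_task(2, seed=1),
                       seed=2, session_cap=20)
        sessions = [r.session for r in log]
        assert sessions[0] == 1 and sessions[20] == 2
        assert max(Counter(sessions).values()) <= 20


class TestTraceAgent:
    def test_order_blind_without_decay(self):
        # with no decay, AB and BA leave identical trace intensities
        agent = TraceAgent(TraceParams(decay=0.0, noise_sd=0.0))
        specs = schedule_sequence_task(1, seed=0)
        ab = next(s for s in specs if s.trial_type == "AB")
        ba = next(s for s in specs if s.trial_type == "BA")
        assert agent._sequence_intensities(ab) == pytest.approx(
            agent._sequence_intensities(ba))

    def test_order_sensitive_with_decay(self):
        agent = TraceAgent(TraceParams(decay=0.8, noise_sd=0.0))
        specs = schedule_sequence_task(1, seed=0)
        ab = next(s for s in specs if s.trial_type == "AB")
        m_a, m_b = agent._sequence_intensities(ab)
        assert m_b > m_a  # second stimulus decayed less

    def test_huge_noise_means_chance(self):
        agent = TraceAgent(TraceParams(decay=0.5, noise_sd=100.0))
        log = run_task(agent, schedule_sequence_task(20, seed=1), seed=2)
        acc = np.mean([r.correct for r in log])
        assert abs(acc - 0.5) < 0.1

    def test_repetition_contrast_more_discriminable_than_order(self):
        # in the perceived trace space, AA vs BB are far apart while AB vs
        # BA differ only through decay-induced asymmetry — so the repeated
        # pairs are discriminable long before (and with zero decay, instead
        # of) the order pair
        specs = {s.trial_type: s for s in schedule_sequence_task(1, seed=0)}

        def separation(agent, t1, t2):
            m1 = np.array(agent._sequence_intensities(specs[t1]))
            m2 = np.array(agent._sequence_intensities(specs[t2]))
            return float(np.linalg.norm(m1 - m2))

        moderate = TraceAgent(TraceParams(decay=0.3, noise_sd=0.1))
        assert separation(moderate, "AA", "BB") > 3 * separation(
            moderate, "AB", "BA")
        order_blind = TraceAgent(TraceParams(decay=0.0, noise_sd=0.1))
        assert separation(order_blind, "AB", "BA") == pytest.approx(0.0,
                                                                    abs=1e-12)
        assert separation(order_blind, "AA", "BB") > 0.5


class TestFaithfulAgent:
    def test_ordered_keys_distinguish_ab_from_ba(self):
        specs = schedule_sequence_task(1, seed=0)
        ab = next(s for s in specs if s.trial_type == "AB")
        ba = next(s for s in specs if s.trial_type == "BA")
        assert ab.sample_ids != ba.sample_ids

    def test_one_shot_learning_without_exploration(self):
        # learning rate 1, no exploration: at most one error per sequence key
        agent = FaithfulAgent(alpha=1.0, epsilon=0.0)
        log = run_task(agent, schedule_sequence_task(10, seed=1), seed=2)
        errors = Counter(r.spec.trial_type for r in log if not r.correct)
        assert all(v <= 1 for v in errors.values())

    def test_criterion_trial_regression(self):
        # frozen seeded run: criterion reached at a reproducible trial
        agent = FaithfulAgent(alpha=1.0, epsilon=0.1)
        log = run_task(agent, schedule_sequence_task(8, seed=11),
                       correction=True, seed=12)
        assert windowed_criterion(log) == 20


class TestTrialLogCSV:
    def test_round_trip_full_equality(self, tmp_path):
        log = run_task(TraceAgent(TraceParams()),
                       schedule_probe_phase(reps_per_condition=2, seed=3),
                       seed=4, subject_id="rt")
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = TrialLog.from_csv(path)
        assert back.to_frame().equals(log.to_frame())
        assert back.subject_id == "rt"

    def test_round_trip_sequence_log(self, tmp_path):
        log = run_task(RandomAgent(), schedule_sequence_task(2, seed=5),
                       correction=True, seed=6)
        path = tmp_path / "seq.csv"
        log.to_csv(path)
        assert TrialLog.from_csv(path).to_frame().equals(log.to_frame())
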