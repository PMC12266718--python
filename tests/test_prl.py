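"""PRL task logic: contingency recovery, block structure, trial timeline."""

import numpy as np
import pytest
from scipy import stats

from rigflow.fixtures import scripted_session
from rigflow.nodes.prl import (
    ControllerParams,
    GeneratorConfig,
    PRLConfigError,
    TrialDefinition,
    make_generator_state,
    trial_controller_run_trial,
    trial_generator_step,
)


def run_trials(n, cfg, seed=42, all_correct=False):
    """Drive the generator n trials; feed back a scripted result each time."""
    from rigflow.nodes.prl import TrialResult

    state = make_generator_state(seed)
    prev = None
    trials = []
    for _ in range(n):
        state, d = trial_generator_step(state, prev, cfg)
        trials.append(d)
        prev = TrialResult(
            stim_type=d.stim_type,
            licked=all_correct,
            correct_port_licked=all_correct,
            rewarded=all_correct and d.reward_available,
            phase_timestamps_ns=(0, 0, 0, 0, 0),
        )
    return trials, state


class TestGenerator:
    def test_probability_one_cell_always_rewards(self):
        cfg = GeneratorConfig(contingencies=((1.0, 1.0, 1.0, 1.0), (1.0, 1.0, 1.0, 1.0)))
        trials, _ = run_trials(200, cfg)
        assert all(t.reward_available for t in trials)

    def test_probability_zero_cell_never_rewards(self):
        cfg = GeneratorConfig(contingencies=((0.0,) * 4, (0.0,) * 4))
        trials, _ = run_trials(200, cfg)
        assert not any(t.reward_available for t in trials)

    def test_reference_config_recovers_contingencies_within_99pct_ci(self):
        """10^4 trials: per-cell reward frequency inside the binomial 99% CI,
        all four stim types appear, block lengths stay within range."""
        cfg = GeneratorConfig(block_length_range=(5, 10))
        trials, _ = run_trials(10_000, cfg, seed=42)
        m = np.asarray(cfg.contingencies)
        assert {t.stim_type for t in trials} == {0, 1, 2, 3}
        z = stats.norm.ppf(0.995)
        for block in range(2):
            for stim in range(4):
                cell = [t.reward_available for t in trials if t.block_index == block and t.stim_type == stim]
                n = len(cell)
                assert n > 0
                p = m[block, stim]
                half = z * np.sqrt(p * (1 - p) / n)
                assert abs(np.mean(cell) - p) <= max(half, 1.5 / n)
        # block lengths from the block_index switch points
        lengths = []
        run = 1
        for a, b in zip(trials, trials[1:]):
            if a.block_index == b.block_index:
                run += 1
            else:
                lengths.append(run)
                run = 1
        assert lengths and all(5 <= L <= 10 for L in lengths)

    def test_blocks_strictly_alternate_between_two(self):
        cfg = GeneratorConfig(block_length_range=(3, 5))
        trials, _ = run_trials(500, cfg, seed=7)
        seen = [t.block_index for t in trials]
        changes = [(a, b) for a, b in zip(seen, seen[1:]) if a != b]
        assert changes and all({a, b} == {0, 1} for a, b in changes)

    def test_block_lengths_uniform_on_range_chi_square(self):
        """10^3 blocks: chi-square GOF does not reject uniformity at alpha=0.01."""
        cfg = GeneratorConfig(block_length_range=(5, 10))
        trials, _ = run_trials(9_000, cfg, seed=123)
        lengths = []
        run = 1
        for a, b in zip(trials, trials[1:]):
            if a.block_index == b.block_index:
                run += 1
            else:
                lengths.append(run)
                run = 1
        assert len(lengths) >= 1000
        lengths = lengths[:1000]
        counts = [lengths.count(v) for v in range(5, 11)]
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_correct_licks_accumulate_per_port(self):
        cfg = GeneratorConfig()
        _, state = run_trials(100, cfg, all_correct=True)
        assert state.correct_lick_tallies.sum() == 99  # first trial has no prev
        assert (state.correct_lick_tallies >= 0).all()

    def test_bad_contingencies_rejected(self):
        with pytest.raises(PRLConfigError):
            GeneratorConfig(contingencies=((1.5, 0, 0, 0), (0, 0, 0, 0))).validate()
        with pytest.raises(PRLConfigError):
            GeneratorConfig(block_length_range=(0, 5)).validate()

    def test_performance_rule_extension_switches_early(self):
        cfg = GeneratorConfig(block_length_range=(50, 50), performance_rule=(5, 5))
        trials, _ = run_trials(30, cfg, all_correct=True)
        assert len({t.block_index for t in trials}) == 2  # switched before 50 trials


def _definition(stim=0, reward=True):
    return TrialDefinition(stim_type=stim, reward_available=reward, block_index=0, trial_number=0)


class TestController:
    def test_degenerate_zero_windows_unrewarded_zero_duration(self):
        p = ControllerParams(0.0, 0.0, 0.0, 0.0, reward_only_after_lick=True)
        result, _ = trial_controller_run_trial(_definition(), p, scripted_session([]))
        assert not result.rewarded and not result.licked
        t = result.phase_timestamps_ns
        assert t[-1] - t[0] == 0

    def test_lick_mid_response_window_earns_reward(self):
        """Hand-traced timeline: odour 0.5 s, delay 0.25 s, response 1 s.

        The response window spans [0.75 s, 1.75 s); a correct-port lick at
        1.25 s, with reward available and the lick gate on, must reward.
        """
        p = ControllerParams(0.5, 0.25, 1.0, 0.5, reward_only_after_lick=True, stim_to_port=(0, 0, 1, 1))
        rig = scripted_session([(1_250_000_000, "lick", {"port": 0})])
        result, history = trial_controller_run_trial(_definition(stim=0), p, rig)
        assert result.licked and result.correct_port_licked and result.rewarded
        assert history["rewarded"] is True

    def test_no_lick_means_no_reward_under_the_gate(self):
        p = ControllerParams(0.5, 0.25, 1.0, 0.5, reward_only_after_lick=True)
        result, _ = trial_controller_run_trial(_definition(reward=True), p, scripted_session([]))
        assert result.rewarded is False

    def test_wrong_port_lick_does_not_reward(self):
        p = ControllerParams(0.0, 0.0, 1.0, 0.0, reward_only_after_lick=True, stim_to_port=(0, 0, 1, 1))
        rig = scripted_session([(500_000_000, "lick", {"port": 1})])
        result, _ = trial_controller_run_trial(_definition(stim=0), p, rig)
        assert result.licked and not result.correct_port_licked and not result.rewarded

    def test_lick_outside_response_window_ignored(self):
        p = ControllerParams(0.5, 0.25, 1.0, 0.5, reward_only_after_lick=True)
        rig = scripted_session([(100_000_000, "lick", {"port": 0})])  # during odour
        result, _ = trial_controller_run_trial(_definition(), p, rig)
        assert not result.licked

    def test_without_gate_reward_follows_availability(self):
        p = ControllerParams(0.1, 0.1, 0.1, 0.1, reward_only_after_lick=False)
        r1, _ = trial_controller_run_trial(_definition(reward=True), p, scripted_session([]))
        r2, _ = trial_controller_run_trial(_definition(reward=False), p, scripted_session([]))
        assert r1.rewarded and not r2.rewarded

    def test_rewarded_implies_reward_available_and_lick_under_gate(self):
        """Invariant sweep over random rigs and definitions."""
        rng = np.random.default_rng(5)
        p = ControllerParams(0.1, 0.1, 0.5, 0.1, reward_only_after_lick=True)
        for _ in range(200):
            reward = bool(rng.random() < 0.5)
            events = []
            if rng.random() < 0.7:
                t = int(rng.integers(0, 800_000_000))
                events.append((t, "lick", {"port": int(rng.integers(0, 2))}))
            result, _ = trial_controller_run_trial(
                _definition(stim=int(rng.integers(0, 4)), reward=reward), p, scripted_session(events)
            )
            if result.rewarded:
                assert reward and result.correct_port_licked

    def test_phase_timestamps_non_decreasing_in_order(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            durations = rng.uniform(0, 0.4, size=4)
            p = ControllerParams(*durations, reward_only_after_lick=True)
            result, _ = trial_controller_run_trial(_definition(), p, scripted_session([]))
            t = result.phase_timestamps_ns
            assert all(a <= b for a, b in zip(t, t[1:]))

    def test_negative_duration_rejected(self):
        with pytest.raises(PRLConfigError):
            ControllerParams(odour_window_s=-1.0).validate()

    def test_scripted_replay_gives_identical_results(self):
        p = ControllerParams(0.2, 0.1, 0.6, 0.2, reward_only_after_lick=True)
        rig = scripted_session([(500_000_000, "lick", {"port": 0})])
        r1, h1 = trial_controller_run_trial(_definition(), p, rig)
        r2, h2 = trial_controller_run_trial(_definition(), p, rig)
        assert r1 == r2 and h1 == h2
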