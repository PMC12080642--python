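import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cptspect.simulate import (
    ConfigurationError,
    GroupSpec,
    ParticipantSim,
    TaskSpec,
    generate_cohort,
    generate_trial_sequence,
    simulate_session,
)


def count_ak_bigrams(letters):
    """Independent oracle: exhaustive scan for A-followed-by-K."""
    return sum(
        1 for a, b in zip(letters[:-1], letters[1:]) if a == "A" and b == "K"
    )


class TestSequence:
    def test_default_spec_places_25_targets_per_block(self, default_sequence, default_spec):
        letters, is_target = default_sequence
        for b in range(default_spec.n_placement_blocks):
            lo, hi = b * 120, (b + 1) * 120
            assert is_target[lo:hi].sum() == 25

    def test_bigram_scan_matches_flags(self, default_sequence):
        letters, is_target = default_sequence
        assert count_ak_bigrams(letters) == 100
        assert is_target.sum() == 100
        # every flagged K is genuinely preceded by an A
        for i in np.flatnonzero(is_target):
            assert letters[i] == "K" and letters[i - 1] == "A"

    def test_no_targets_means_no_ak_bigrams(self):
        spec = TaskSpec(n_targets=0)
        letters, is_target = generate_trial_sequence(spec, seed=5)
        assert count_ak_bigrams(letters) == 0
        assert is_target.sum() == 0

    def test_same_seed_identical(self, default_spec):
        a = generate_trial_sequence(default_spec, seed=1)
        b = generate_trial_sequence(default_spec, seed=1)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])

    def test_different_seeds_differ(self, default_spec):
        a = generate_trial_sequence(default_spec, seed=1)
        b = generate_trial_sequence(default_spec, seed=2)
        assert a[0] != b[0]

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_target_count_conserved_any_seed(self, seed):
        spec = TaskSpec()
        letters, is_target = generate_trial_sequence(spec, seed)
        assert count_ak_bigrams(letters) == spec.n_targets

    @settings(max_examples=20, deadline=None)
    @given(
        n_blocks=st.integers(1, 6),
        per_block=st.integers(0, 20),
        block_len=st.integers(40, 120),
        seed=st.integers(0, 1000),
    )
    def test_block_balance_varied_geometry(self, n_blocks, per_block, block_len, seed):
        spec = TaskSpec(
            n_trials=n_blocks * block_len,
            n_targets=n_blocks * per_block,
            n_placement_blocks=n_blocks,
        )
        letters, is_target = generate_trial_sequence(spec, seed)
        assert count_ak_bigrams(letters) == spec.n_targets
        for b in range(n_blocks):
            assert is_target[b * block_len : (b + 1) * block_len].sum() == per_block

    def test_infeasible_placement_rejected(self):
        spec = TaskSpec(n_trials=80, n_targets=60, n_placement_blocks=4)
        with pytest.raises(ConfigurationError):
            generate_trial_sequence(spec, seed=0)

    def test_nondivisible_targets_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_trial_sequence(TaskSpec(n_targets=101), seed=0)


class TestTaskSpec:
    def test_soa_derived(self):
        spec = TaskSpec()
        assert spec.soa == 985.0
        assert spec.default_response_window == 1135.0

    def test_onset_spacing(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC")
        df = simulate_session(default_sequence, sim, default_spec)
        dt = np.diff(df["onset_time_s"].to_numpy())
        assert np.allclose(dt, 0.985)


class TestSession:
    def test_noiseless_rt_equals_mu(self, default_sequence, default_spec):
        sim = ParticipantSim(
            "p", "HC", rt_mu=450.0, rt_sigma=0.0, rt_tau=0.0,
            trend_slope=0.0, osc_amplitude=0.0, p_miss=0.0,
        )
        df = simulate_session(default_sequence, sim, default_spec)
        hits = df.loc[df["is_target"], "rt_ms"]
        assert len(hits) == 100
        assert np.allclose(hits, 450.0)

    def test_sinusoid_reproduced_pointwise(self, default_sequence, default_spec):
        phase = 0.7
        sim = ParticipantSim(
            "p", "HC", rt_mu=450.0, rt_sigma=0.0, rt_tau=0.0, p_miss=0.0,
            osc_amplitude=100.0, osc_freq=0.063, osc_phase=phase,
        )
        df = simulate_session(default_sequence, sim, default_spec)
        tgt = df[df["is_target"]]
        expected = 450.0 + 100.0 * np.sin(
            2 * math.pi * 0.063 * tgt["onset_time_s"].to_numpy() + phase
        )
        assert np.allclose(tgt["rt_ms"].to_numpy(), expected)

    def test_all_miss(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC", p_miss=1.0)
        df = simulate_session(default_sequence, sim, default_spec)
        assert df.loc[df["is_target"], "rt_ms"].isna().all()

    def test_rt_bounds_respected(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC", rt_mu=200.0, rt_sigma=150.0, rt_tau=100.0, seed=4)
        df = simulate_session(default_sequence, sim, default_spec)
        rt = df["rt_ms"].dropna()
        assert (rt >= 100.0).all()
        assert (rt <= default_spec.default_response_window).all()

    def test_session_determinism(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC", rt_sigma=40.0, p_miss=0.1, p_commission=0.02, seed=9)
        a = simulate_session(default_sequence, sim, default_spec)
        b = simulate_session(default_sequence, sim, default_spec)
        pd.testing.assert_frame_equal(a, b)

    def test_oscillation_variance_ground_truth(self, default_spec):
        # noise off, >=10 oscillation periods: var(rt) ~= amplitude^2 / 2
        seq = generate_trial_sequence(default_spec, seed=3)
        sim = ParticipantSim(
            "p", "HC", rt_mu=500.0, rt_sigma=0.0, rt_tau=0.0, p_miss=0.0,
            osc_amplitude=80.0, osc_freq=0.05, osc_phase=1.1,
        )
        df = simulate_session(seq, sim, default_spec)
        rt = df.loc[df["is_target"], "rt_ms"].to_numpy()
        span = df["onset_time_s"].iloc[-1]
        assert span * 0.05 >= 10
        assert np.var(rt) == pytest.approx(80.0**2 / 2, rel=0.05)

    def test_invalid_probability_rejected(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC", p_miss=1.5)
        with pytest.raises(ConfigurationError):
            simulate_session(default_sequence, sim, default_spec)

    def test_osc_freq_above_nyquist_rejected(self, default_sequence, default_spec):
        sim = ParticipantSim("p", "HC", osc_freq=0.6)
        with pytest.raises(ConfigurationError):
            simulate_session(default_sequence, sim, default_spec)


class TestCohort:
    def test_bookkeeping(self):
        groups = [GroupSpec("A", 3), GroupSpec("B", 3)]
        trials, cov = generate_cohort(groups, seed=1)
        assert len(cov) == 6
        assert len(trials) == 6 * 480
        assert set(cov["group"]) == {"A", "B"}
        assert trials.groupby("participant_id").size().eq(480).all()

    def test_master_seed_reproducibility(self):
        groups = [
            GroupSpec("A", 2, params={"rt_sigma": {"mean": 50, "sd": 10, "min": 5}}),
            GroupSpec("B", 2),
        ]
        t1, c1 = generate_cohort(groups, seed=77)
        t2, c2 = generate_cohort(groups, seed=77)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_master_seed_differs(self):
        groups = [GroupSpec("A", 2, params={"rt_sigma": 40.0})]
        t1, _ = generate_cohort(groups, seed=1)
        t2, _ = generate_cohort(groups, seed=2)
        assert not t1["rt_ms"].equals(t2["rt_ms"])

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort([GroupSpec("A", 0)], seed=1)

    def test_covariate_ranges(self):
        groups = [GroupSpec("A", 30)]
        _, cov = generate_cohort(groups, seed=5)
        assert cov["age"].between(18, 65).all()
        assert set(cov["sex"]) <= {"F", "M"}
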