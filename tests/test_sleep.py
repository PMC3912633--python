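"""Sleep bout detection, architecture summaries, profiles and deprivation."""

import numpy as np
import pytest

from flysleep.sleep import (
    activity_index,
    deprivation_metrics,
    detect_sleep_bouts,
    sleep_mask,
    sleep_profile,
    summarize_sleep,
)
from flysleep.simulate import (
    SHORT_SLEEP_MUTANT,
    ActivitySimConfig,
    simulate_activity,
    simulate_deprivation_pair,
)

from conftest import brute_force_bouts, make_trace


class TestBoutDetection:
    def test_all_zero_day_is_one_bout(self):
        tr = make_trace(np.zeros(1440))
        bouts = detect_sleep_bouts(tr)
        assert len(bouts) == 1
        assert bouts[0].duration_min == 1440
        assert bouts[0].phase == "daytime"

    def test_alternating_counts_no_bouts(self):
        tr = make_trace(np.tile([1, 0], 720))
        assert detect_sleep_bouts(tr) == []

    def test_short_run_below_threshold_ignored(self):
        counts = np.ones(1440, dtype=int)
        counts[10:17] = 0  # 7-min run: a bout
        counts[100:104] = 0  # 4-min run: not a bout
        bouts = detect_sleep_bouts(make_trace(counts), min_inactive_min=5)
        assert [(b.start_min, b.duration_min) for b in bouts] == [(10, 7)]

    def test_matches_brute_force_on_random_traces(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            counts = (rng.random(1440) < 0.45).astype(int)
            tr = make_trace(counts)
            got = [(b.start_min, b.duration_min) for b in detect_sleep_bouts(tr)]
            assert got == brute_force_bouts(counts, 5)

    def test_maximality(self):
        rng = np.random.default_rng(5)
        counts = (rng.random(1440) < 0.4).astype(int)
        tr = make_trace(counts)
        for b in detect_sleep_bouts(tr):
            if b.start_min > 0:
                assert counts[b.start_min - 1] != 0
            if b.end_min < 1440:
                assert counts[b.end_min] != 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        counts = (rng.random(1440) < 0.4).astype(int)
        tr = make_trace(counts)
        prev_sleep, prev_n = 1441, 10**6
        for thr in (1, 3, 5, 10, 30):
            bouts = detect_sleep_bouts(tr, thr)
            total = sum(b.duration_min for b in bouts)
            assert total <= prev_sleep
            assert len(bouts) <= prev_n
            prev_sleep, prev_n = total, len(bouts)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            detect_sleep_bouts(make_trace(np.zeros(1440)), 0)


class TestSummaries:
    def test_full_day_asleep(self):
        tr = make_trace(np.zeros(1440))
        s = summarize_sleep(tr, detect_sleep_bouts(tr), exclude_dead=False)
        row = s.iloc[0]
        assert row.total_sleep_min == 1440
        assert row.day_sleep_min == 720
        assert row.night_sleep_min == 720
        assert row.n_episodes_day == 1 and row.n_episodes_night == 0

    def test_no_bouts_all_zero_metrics(self):
        tr = make_trace(np.ones(1440))
        s = summarize_sleep(tr, [])
        row = s.iloc[0]
        assert row.total_sleep_min == 0
        assert np.isnan(row.mean_episode_min_day)
        assert np.isnan(row.mean_episode_min_night)

    def test_planted_architecture(self):
        # 3 daytime bouts of 30 min, 5 night bouts of 60 min
        counts = np.ones(1440, dtype=int)
        for s in (60, 180, 300):
            counts[s : s + 30] = 0
        for s in (760, 860, 960, 1060, 1160):
            counts[s : s + 60] = 0
        tr = make_trace(counts)
        s = summarize_sleep(tr, detect_sleep_bouts(tr)).iloc[0]
        assert s.total_sleep_min == 390
        assert s.day_sleep_min == 90
        assert s.night_sleep_min == 300
        assert (s.n_episodes_day, s.n_episodes_night) == (3, 5)
        assert s.mean_episode_min_day == 30 and s.mean_episode_min_night == 60

    def test_boundary_crossing_bout_split_but_counted_once(self):
        # bout from ZT11:40 to ZT12:20 — 20 min day, 20 min night, 1 day episode
        counts = np.ones(1440, dtype=int)
        counts[700:740] = 0
        tr = make_trace(counts)
        s = summarize_sleep(tr, detect_sleep_bouts(tr)).iloc[0]
        assert s.day_sleep_min == 20 and s.night_sleep_min == 20
        assert s.n_episodes_day == 1 and s.n_episodes_night == 0

    def test_phase_conservation(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts = (rng.random(2880) < 0.5).astype(int)
            tr = make_trace(counts)
            bouts = detect_sleep_bouts(tr)
            s = summarize_sleep(tr, bouts, exclude_dead=False)
            assert (
                s.total_sleep_min == s.day_sleep_min + s.night_sleep_min
            ).all()
            assert s.total_sleep_min.sum() == sleep_mask(tr, bouts).sum()

    def test_mismatched_bouts_rejected(self):
        tr = make_trace(np.ones(1440))
        other = make_trace(np.zeros(1440))
        with pytest.raises(ValueError):
            summarize_sleep(tr, detect_sleep_bouts(other))


class TestActivityIndex:
    def test_ten_waking_minutes(self):
        counts = np.zeros(1440, dtype=int)
        counts[0:10] = 2
        tr = make_trace(counts)
        assert activity_index(tr, detect_sleep_bouts(tr)) == 2.0

    def test_all_waking_ones(self):
        tr = make_trace(np.ones(1440))
        assert activity_index(tr, []) == 1.0

    def test_always_asleep_undefined(self):
        tr = make_trace(np.zeros(1440))
        assert np.isnan(activity_index(tr, detect_sleep_bouts(tr)))

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            counts = rng.poisson(0.8, 1440)
            tr = make_trace(counts)
            bouts = detect_sleep_bouts(tr)
            mask = sleep_mask(tr, bouts)
            if (~mask).sum() == 0:
                continue
            expected = counts[~mask].mean()
            assert activity_index(tr, bouts) == pytest.approx(expected)


class TestProfile:
    def test_always_asleep_profile_is_one(self):
        trs = [make_trace(np.zeros(1440), fly_id=f"f{i}") for i in range(2)]
        prof = sleep_profile(trs, exclude_dead=False)
        assert (prof["mean"] == 1.0).all()
        assert (prof["sem"] == 0.0).all()

    def test_half_asleep_two_point_sem(self):
        trs = [make_trace(np.zeros(1440)), make_trace(np.ones(1440))]
        prof = sleep_profile(trs, exclude_dead=False)
        assert (prof["mean"] == 0.5).all()
        assert prof["sem"].iloc[0] == pytest.approx(0.5)

    def test_bimodal_architecture_peaks_inside_windows(self):
        cfg = ActivitySimConfig(n_ld_days=3)
        trs = [simulate_activity(cfg, s, fly_id=f"f{s}")[0] for s in range(8)]
        prof = sleep_profile(trs)
        day = prof[prof.zt_bin_min < 720]
        night = prof[prof.zt_bin_min >= 720]
        # generator places siesta in ZT5-12 and night sleep after ZT12
        assert day.loc[day["mean"].idxmax(), "zt_bin_min"] >= 300
        assert night["mean"].max() > day["mean"].max() * 0.8
        assert prof.loc[prof["mean"].idxmax(), "zt_bin_min"] >= 300

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sleep_profile([])


class TestMutantArchitecture:
    def test_short_sleep_pattern_recovered(self):
        """Mutant cohort: >50% less sleep but *more* night episodes."""
        import pandas as pd

        wt_cfg = ActivitySimConfig(n_ld_days=2)
        mut_cfg = ActivitySimConfig(n_ld_days=2, **SHORT_SLEEP_MUTANT)

        def cohort_summary(cfg, seed0):
            rows = []
            for s in range(10):
                tr, _ = simulate_activity(cfg, seed0 + s)
                rows.append(summarize_sleep(tr, detect_sleep_bouts(tr)))
            return pd.concat(rows)

        wt = cohort_summary(wt_cfg, 0)
        mut = cohort_summary(mut_cfg, 100)
        assert mut.total_sleep_min.mean() < 0.5 * wt.total_sleep_min.mean()
        assert mut.n_episodes_night.mean() > wt.n_episodes_night.mean()

    def test_partial_dominance_intermediate(self):
        import pandas as pd

        base = ActivitySimConfig(n_ld_days=2, **SHORT_SLEEP_MUTANT)

        def mean_sleep(cfg, seed0):
            vals = []
            for s in range(10):
                tr, _ = simulate_activity(cfg, seed0 + s)
                vals.append(
                    summarize_sleep(tr, detect_sleep_bouts(tr)).total_sleep_min.mean()
                )
            return np.mean(vals)

        wt = mean_sleep(base.for_genotype("wt"), 0)
        het = mean_sleep(base.for_genotype("het"), 50)
        mut = mean_sleep(base.for_genotype("mut"), 100)
        assert mut < het < wt


class TestDeprivation:
    def _trace_with_window_sleep(self, night_sleep_start, night_len, morning_len=0):
        counts = np.ones(2880, dtype=int)
        counts[night_sleep_start : night_sleep_start + night_len] = 0
        if morning_len:
            counts[1440 + 60 : 1440 + 60 + morning_len] = 0
        return make_trace(counts)

    def test_complete_deprivation(self):
        # baseline sleeps 300 min inside ZT18-24; deprived fly sleeps 0 there
        counts = np.ones(1440, dtype=int)
        counts[1100:1400] = 0
        baseline = make_trace(counts)
        deprived = make_trace(np.ones(2880, dtype=int))
        res = deprivation_metrics(baseline, deprived, sd_day=0)
        assert res.sleep_lost_min == 300
        assert res.deprivation_efficacy == pytest.approx(1.0)

    def test_sd_equal_to_baseline_is_null(self):
        tr = self._trace_with_window_sleep(1100, 300)
        tr2 = self._trace_with_window_sleep(1100 + 1440, 300)
        # deprived day reproduces the baseline day exactly: nothing lost
        counts = np.concatenate([tr.counts[:1440], tr.counts[:1440]])
        both = make_trace(counts)
        res = deprivation_metrics(both, both, sd_day=0)
        assert res.sleep_lost_min == 0
        assert res.rebound_gain_min == 0

    def test_zero_baseline_window_flagged(self):
        baseline = make_trace(np.ones(2880, dtype=int))
        res = deprivation_metrics(baseline, baseline, sd_day=0)
        assert res.deprivation_efficacy is None

    def test_simulated_rebound_matches_boost(self):
        """Mean rebound gain over replicate flies ≈ planted boost."""
        cfg = ActivitySimConfig(n_ld_days=4)
        boost = 60
        gains = []
        for s in range(60):
            base, dep, sd_day = simulate_deprivation_pair(cfg, boost, s)
            res = deprivation_metrics(base, dep, sd_day)
            gains.append(res.rebound_gain_min)
            assert res.sleep_lost_min > 0 or res.deprivation_efficacy is None
        assert np.mean(gains) == pytest.approx(boost, abs=5)
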