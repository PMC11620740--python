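"""Normalizations, outlier fences, the event-count exclusion loop, and
the orchestrated pipeline."""

import numpy as np
import pytest

from varicount import (
    EstimationError,
    FlowSample,
    FrequencySeries,
    PipelineConfig,
    SimulationConfig,
    derive_confetti_fractions,
    derive_pairwise_ratio,
    fixed_n_cohort,
    min_event_exclusion,
    normalize_blood_subsets,
    normalize_chimerism,
    run_pipeline,
    tukey_filter,
)


def sample(**kw):
    defaults = dict(sample_id="s1", recorded_events=10_000,
                    rfp_pct=2.0, yfp_pct=2.0, cfp_pct=1.0)
    defaults.update(kw)
    return FlowSample(**defaults)


class TestNormalizations:
    @pytest.mark.parametrize("m,t,b,expected", [
        ((40, 30, 30), None, None, (40, 30, 30)),
        ((20, 15, 15), None, None, (40, 30, 30)),
    ])
    def test_subset_normalization(self, m, t, b, expected):
        s = sample(myeloid_pct=m[0], t_pct=m[1], b_pct=m[2])
        out = normalize_blood_subsets(s)
        assert (out.myeloid_pct, out.t_pct, out.b_pct) == pytest.approx(expected)
        # idempotent
        again = normalize_blood_subsets(out)
        assert (again.myeloid_pct, again.t_pct, again.b_pct) == pytest.approx(expected)

    def test_zero_subset_total_flagged(self):
        s = sample(myeloid_pct=0.0, t_pct=0.0, b_pct=0.0)
        assert "zero-subset-total" in normalize_blood_subsets(s).flags

    @pytest.mark.parametrize("c1,c2,expected", [
        ((60, 40), None, (60, 40)),
        ((45, 45), None, (50, 50)),
        ((0, 80), None, (0, 100)),
    ])
    def test_chimerism_normalization(self, c1, c2, expected):
        s = sample(cd45_1_pct=c1[0], cd45_2_pct=c1[1])
        out = normalize_chimerism(s)
        assert (out.cd45_1_pct, out.cd45_2_pct) == pytest.approx(expected)
        again = normalize_chimerism(out)
        assert (again.cd45_1_pct, again.cd45_2_pct) == pytest.approx(expected)

    def test_zero_chimerism_flagged(self):
        s = sample(cd45_1_pct=0.0, cd45_2_pct=0.0)
        assert "zero-chimerism-total" in normalize_chimerism(s).flags


class TestDerivedFractions:
    def test_confetti_fractions(self):
        out = derive_confetti_fractions(sample(rfp_pct=2, yfp_pct=2, cfp_pct=1))
        assert out.derived["confetti_pct"] == pytest.approx(5.0)
        assert out.derived["rfp_conf"] == pytest.approx(0.40)
        assert out.derived["cfp_conf"] == pytest.approx(0.20)

    def test_single_channel(self):
        out = derive_confetti_fractions(sample(rfp_pct=3, yfp_pct=0, cfp_pct=0))
        assert out.derived["rfp_conf"] == pytest.approx(1.0)

    def test_unlabeled_flagged(self):
        out = derive_confetti_fractions(sample(rfp_pct=0, yfp_pct=0, cfp_pct=0))
        assert "no-labeled-cells" in out.flags

    @pytest.mark.parametrize("rfp,yfp,expected", [
        (3.0, 1.0, 0.75),
        (2.0, 2.0, 0.5),
        (0.0, 2.0, 0.0),
    ])
    def test_pairwise_ratio(self, rfp, yfp, expected):
        s = sample(rfp_pct=rfp, yfp_pct=yfp)
        assert derive_pairwise_ratio(s) == pytest.approx(expected)

    def test_pairwise_ratio_zero_pair(self):
        assert derive_pairwise_ratio(sample(rfp_pct=0, yfp_pct=0)) is None


class TestTukeyFilter:
    def test_tight_cluster_untouched(self):
        s = FrequencySeries([0.48, 0.50, 0.52, 0.49, 0.51],
                            percent_autoscale=False)
        kept, removed = tukey_filter(s, 1.5)
        assert removed == [] and len(kept) == 5

    def test_removes_low_outlier(self):
        values = [0.10, 0.50, 0.51, 0.52, 0.53, 0.54]
        s = FrequencySeries(values, percent_autoscale=False)
        kept, removed = tukey_filter(s, 1.5)
        # independent fence oracle via interpolated quartiles
        q1, q3 = np.percentile(values, [25, 75])
        lo = q1 - 1.5 * (q3 - q1)
        assert 0.10 < lo  # the fence indeed excludes 0.10
        assert removed == ["s0"]
        assert kept.values.min() > lo

    def test_huge_k_is_identity(self):
        s = FrequencySeries([0.1, 0.5, 0.6, 0.9], percent_autoscale=False)
        kept, removed = tukey_filter(s, 1e9)
        assert removed == [] and kept.values.tolist() == s.values.tolist()

    def test_small_series_passthrough(self):
        s = FrequencySeries([0.1, 0.9], percent_autoscale=False)
        kept, removed = tukey_filter(s, 1.5)
        assert removed == [] and len(kept) == 2


class TestMinEventExclusion:
    def test_no_exclusion_when_events_abundant(self):
        fracs = 0.5 + 0.0112 * np.array([-1.5, -1, -0.5, 0.5, 1, 1.5, 0.0])
        s = FrequencySeries(fracs, percent_autoscale=False)
        res = min_event_exclusion(s, [10**6] * 7)
        assert res.exclusions == () and not res.flagged
        assert res.n_hat < 10**6

    def test_single_exclusion_matches_hand_stepped_loop(self):
        """One low-event sample forces exactly one exclusion; the final
        estimate equals re-estimating on the remaining six by hand."""
        d = 0.008183
        fracs = 0.5 + d * np.array([-3, -2, -1, 0, 1, 2, 3])
        ids = [f"m{i}" for i in range(7)]
        events = {f"m{i}": 10**6 for i in range(7)}
        events["m0"] = 500  # lowest-count sample
        s = FrequencySeries(fracs, ids, percent_autoscale=False)
        # hand-stepped oracle
        p0, sd0 = fracs.mean(), fracs.std(ddof=1)
        n0 = p0 * (1 - p0) / sd0**2
        assert n0 > 500  # triggers one exclusion
        rest = fracs[1:]
        p1, sd1 = rest.mean(), rest.std(ddof=1)
        n1 = p1 * (1 - p1) / sd1**2
        assert n1 < 10**6  # loop terminates after one drop

        res = min_event_exclusion(s, events)
        assert res.exclusions == (("m0", "insufficient-events"),)
        assert res.n_hat == pytest.approx(n1, rel=1e-12)
        assert res.n_samples_used == 6

    def test_size_guard_flags_no_valid_estimate(self):
        fracs = [0.48, 0.49, 0.50, 0.51, 0.52]
        s = FrequencySeries(fracs, percent_autoscale=False)
        res = min_event_exclusion(s, [10] * 5)  # n_hat ~ 1200 >> 10 events
        assert "no-valid-estimate" in res.flags
        assert res.n_hat is None
        assert res.n_samples_used == 5

    def test_insufficient_samples_is_error(self):
        s = FrequencySeries([0.4, 0.5, 0.6], percent_autoscale=False)
        with pytest.raises(EstimationError, match="insufficient-samples"):
            min_event_exclusion(s, [100] * 3)


class TestRunPipeline:
    def test_recovers_generating_n(self, small_cohort):
        res = run_pipeline(small_cohort)
        assert len(res) == 1
        r = res[0]
        assert not r.flagged
        assert abs(r.n_hat / 1000 - 1) < 0.30
        assert r.marker == "rfp_conf"

    def test_all_samples_accounted_for(self, small_cohort):
        r = run_pipeline(small_cohort)[0]
        assert r.n_samples_used + len(r.exclusions) == len(small_cohort)
        reasons = [reason for _, reason in r.exclusions]
        assert all(isinstance(x, str) and x for x in reasons)

    def test_outlier_excluded_and_recovery_restored(self, small_cohort):
        t = small_cohort.copy()
        # inject a gross outlier: one animal reads almost pure RFP
        t.loc[3, "rfp_pct"], t.loc[3, "yfp_pct"] = 99.0, 1.0
        r = run_pipeline(t)[0]
        excluded = {sid for sid, reason in r.exclusions
                    if reason.startswith("tukey")}
        assert t.loc[3, "sample_id"] in excluded
        assert abs(r.n_hat / 1000 - 1) < 0.30
        # with fences effectively disabled the outlier inflates sigma
        # and crushes the estimate
        r_off = run_pipeline(t, PipelineConfig(tukey_k=1e9))[0]
        assert r_off.n_hat < 0.2 * r.n_hat

    def test_row_order_invariance(self, small_cohort, rng):
        shuffled = small_cohort.sample(frac=1, random_state=42).reset_index(drop=True)
        a = run_pipeline(small_cohort)[0]
        b = run_pipeline(shuffled)[0]
        assert a.n_hat == b.n_hat
        assert a.exclusions == b.exclusions

    def test_group_below_min_size_flagged_not_dropped(self):
        t = fixed_n_cohort(SimulationConfig(n=100, n_animals=3, seed=1))
        res = run_pipeline(t)
        assert len(res) == 1
        assert "insufficient-samples" in res[0].flags
        assert res[0].n_hat is None

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            run_pipeline(pd.DataFrame())

    def test_ratio_mode_and_labeling_normalization(self):
        cfg = SimulationConfig(
            n=500, n_animals=20,
            p_channels={"rfp": 0.4, "yfp": 0.4, "cfp": 0.2},
            labeling_efficiency=0.5, seed=3,
        )
        t = fixed_n_cohort(cfg)
        pc = PipelineConfig(marker_mode="rfp_over_rfp_plus_yfp",
                            labeling_normalization=True)
        r = run_pipeline(t, pc)[0]
        assert r.marker == "rfp_over_rfp_plus_yfp"
        # the ratio restricts to the RFP+YFP compartment:
        # ~ 500 * 0.5 * 0.8 = 200 precursors measured
        assert r.n_hat == pytest.approx(200, rel=0.5)
        assert r.labeling_fraction == pytest.approx(0.5 * 0.8, rel=0.1)
        assert r.n_hat_total == pytest.approx(r.n_hat / r.labeling_fraction)
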