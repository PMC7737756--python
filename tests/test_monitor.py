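"""Progression calling: ratio normalization, sustained-elevation rule, lead time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdnamon.monitor import (
    TimelineError,
    call_cea_pd,
    call_ctdna_pd,
    cea_log2_index,
    compute_lead_time,
    detect_emerging_alterations,
    first_sustained_run,
    relative_fold_series,
    summarize_lead_times,
)

from conftest import make_variants


def timeline(dates, erbb2=1.0, tcl=0, tmb=0.0, cea=2.0, patient="P1"):
    n = len(dates)
    as_list = lambda x: list(x) if hasattr(x, "__len__") else [x] * n
    return pd.DataFrame(
        {
            "patient_id": [patient] * n,
            "date": pd.to_datetime(dates),
            "erbb2_fold": as_list(erbb2),
            "tcl": as_list(tcl),
            "tmb": as_list(tmb),
            "cea_ng_ml": as_list(cea),
        }
    )


DATES = ["2020-01-01", "2020-02-12", "2020-03-25", "2020-05-06"]


class TestRelativeFold:
    def test_cutoff_identity_and_arithmetic(self):
        assert relative_fold_series([8.5], 8.5)[0] == pytest.approx(1.0)
        assert relative_fold_series([4], 2)[0] == pytest.approx(2.0)
        assert relative_fold_series([0.7], 1.4)[0] == pytest.approx(0.5)

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            relative_fold_series([1.0], 0.0)


class TestCtdnaPD:
    def test_run_of_two_starts_call(self):
        # TMB/cutoff ratios [0.5, 0.4, 1.2, 1.6] -> PD at the third draw
        tl = timeline(DATES, tmb=[x * 8.5 for x in (0.5, 0.4, 1.2, 1.6)])
        call = call_ctdna_pd(tl)
        assert call is not None
        assert call.date == pd.Timestamp("2020-03-25")
        assert call.trigger == "tmb"

    def test_all_below_cutoff_no_call(self):
        assert call_ctdna_pd(timeline(DATES)) is None

    def test_isolated_spike_is_not_progression(self):
        tl = timeline(DATES, tmb=[x * 8.5 for x in (0.9, 1.3, 0.8, 0.9)])
        assert call_ctdna_pd(tl) is None

    def test_exactly_at_cutoff_is_not_beyond(self):
        # "elevated beyond" is strict: a ratio pinned at 1.0 never triggers
        tl = timeline(DATES, tmb=8.5, tcl=2, erbb2=1.4)
        assert call_ctdna_pd(tl) is None

    def test_baseline_never_calls(self):
        # above cutoff from BL: the call lands on the first post-baseline draw
        tl = timeline(DATES, erbb2=2.0)
        assert call_ctdna_pd(tl).date == pd.Timestamp(DATES[1])

    def test_tie_broken_by_feature_priority(self):
        tl = timeline(DATES, erbb2=[1.0, 2.0, 2.0, 2.0], tmb=[0, 17, 17, 17])
        assert call_ctdna_pd(tl).trigger == "erbb2_cnv"

    def test_earliest_feature_wins_over_priority(self):
        tl = timeline(DATES, erbb2=[1.0, 1.0, 2.0, 2.0], tmb=[0, 17, 17, 0])
        assert call_ctdna_pd(tl).trigger == "tmb"

    def test_fewer_than_three_samples_excluded(self):
        with pytest.raises(TimelineError):
            call_ctdna_pd(timeline(DATES[:2]))

    def test_duplicate_dates_rejected(self):
        with pytest.raises(TimelineError):
            call_ctdna_pd(timeline(["2020-01-01", "2020-01-01", "2020-03-01"]))

    def test_nonconsecutive_flag(self):
        tl = timeline(DATES, tmb=[x * 8.5 for x in (0.5, 1.3, 0.8, 1.2)])
        assert call_ctdna_pd(tl) is None
        call = call_ctdna_pd(tl, consecutive=False)
        assert call.date == pd.Timestamp(DATES[1])


class TestRunRuleProperties:
    @given(st.lists(st.booleans(), min_size=1, max_size=25))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_run_scan(self, above):
        def oracle(flags):
            for i in range(len(flags) - 1):
                if flags[i] and flags[i + 1]:
                    return i
            return None

        assert first_sustained_run(np.array(above)) == oracle(above)

    @given(st.lists(st.booleans(), min_size=2, max_size=20), st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_prepending_false_and_appending_never_moves_call_earlier(self, above, pad):
        base = first_sustained_run(np.array(above))
        prefixed = first_sustained_run(np.array([False] * pad + above))
        if base is not None:
            assert prefixed == base + pad
        extended = first_sustained_run(np.array(above + [True] * pad))
        if base is not None:
            assert extended == base


class TestCeaPD:
    def test_constant_below_cutoff(self):
        assert call_cea_pd(timeline(DATES[:3], cea=2.0)) is None

    def test_two_points_above(self):
        call = call_cea_pd(timeline(DATES[:3], cea=[3, 6, 8]))
        assert call.date == pd.Timestamp(DATES[1])
        assert call.trigger == "cea"

    def test_log2_index(self):
        assert cea_log2_index([10.0])[0] == pytest.approx(1.0)

    def test_nonpositive_cea_rejected(self):
        with pytest.raises(TimelineError):
            call_cea_pd(timeline(DATES[:3], cea=[3, 0, 8]))


class TestLeadTime:
    def test_identical_dates_not_ahead(self):
        assert compute_lead_time("2018-01-01", "2018-01-01") == 0

    def test_calendar_arithmetic(self):
        assert compute_lead_time("2018-01-01", "2018-02-08") == 38

    def test_negative_lead(self):
        assert compute_lead_time("2018-03-01", "2018-02-08") == -21

    def test_summary_counts_strictly_positive_leads(self):
        s = summarize_lead_times([42, 0, -7, 84, 0])
        assert s["n_evaluable"] == 5 and s["n_ahead"] == 2
        assert s["ahead_fraction"] == pytest.approx(0.4)
        assert s["mean_advancement_days"] == pytest.approx(63.0)


class TestEmergingAlterations:
    def test_identical_sets_empty(self):
        v = make_variants([("chr17", 100, "G", "A", "TP53", "missense", 0.1)])
        out = detect_emerging_alterations(v, v.copy())
        assert len(out["variants"]) == 0

    def test_set_difference(self):
        bl = make_variants([("chr17", 100, "G", "A", "TP53", "missense", 0.1)])
        pd_ = make_variants(
            [
                ("chr17", 100, "G", "A", "TP53", "missense", 0.2),
                ("chr17", 200, "T", "C", "ERBB2", "missense", 0.05),
            ]
        )
        out = detect_emerging_alterations(bl, pd_)
        assert out["variants"]["pos"].tolist() == [200]

    def test_multiple_new_kinase_domain_mutations_reported(self):
        # resistance pattern: three ERBB2 point mutations absent at baseline
        bl = make_variants([("chr17", 100, "G", "A", "TP53", "missense", 0.1)])
        new = [
            ("chr17", 1976, "T", "A", "ERBB2", "missense", 0.04),  # p.V659D
            ("chr17", 2264, "T", "C", "ERBB2", "missense", 0.06),  # p.L755S
            ("chr17", 2305, "G", "T", "ERBB2", "missense", 0.03),  # p.D769Y
        ]
        pd_ = pd.concat([bl, make_variants(new)], ignore_index=True)
        out = detect_emerging_alterations(bl, pd_)
        assert sorted(out["variants"]["pos"]) == [1976, 2264, 2305]
        assert set(out["variants"]["gene"]) == {"ERBB2"}

    def test_cnv_changes_reported_separately(self):
        bl_cnv = pd.DataFrame({"gene": ["ERBB2", "MYC"], "call": ["gain", "neutral"]})
        pd_cnv = pd.DataFrame({"gene": ["ERBB2", "MYC"], "call": ["gain", "gain"]})
        empty = make_variants([])
        out = detect_emerging_alterations(empty, empty, bl_cnv, pd_cnv)
        assert out["cnv"]["gene"].tolist() == ["MYC"]


class TestZeroNoiseRecovery:
    def test_called_dates_equal_truth_on_grid(self, zero_noise_cohort):
        """Noise-free cohort: every ctDNA-PD equals the latent molecular
        progression date on the sampling grid, and leads are non-negative
        whenever imaging detection comes after the feature-cutoff crossing."""
        from ctdnamon.denoise import WBCDatabase, build_background_model, denoise_sample
        from ctdnamon.features import extract_sample_features

        c = zero_noise_cohort
        model = build_background_model(c.healthy_pool)
        db = WBCDatabase.from_table(c.wbc_table, c.wbc_total)
        for truth in c.truths:
            rows = []
            for s in [x for x in c.samples if x["patient_id"] == truth.patient_id]:
                kept, _ = denoise_sample(s["variants"], db, model)
                folds = pd.DataFrame(
                    {"gene": list(s["folds"]), "fold": list(s["folds"].values())}
                )
                f = extract_sample_features(s["sample_id"], kept, folds, c.panel)
                rows.append(
                    {
                        "patient_id": truth.patient_id, "date": pd.Timestamp(s["date"]),
                        "erbb2_fold": f.erbb2_fold, "tcl": f.tcl, "tmb": f.tmb,
                    }
                )
            call = call_ctdna_pd(pd.DataFrame(rows))
            if truth.molecular_pd_date is None:
                assert call is None
            else:
                assert call is not None
                assert call.date == pd.Timestamp(truth.molecular_pd_date)
                if truth.radiologic_pd_date is not None and pd.Timestamp(
                    truth.radiologic_pd_date
                ) >= pd.Timestamp(truth.molecular_pd_date):
                    lead = compute_lead_time(call.date, truth.radiologic_pd_date)
                    assert lead >= 0
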