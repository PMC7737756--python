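"""Two-stage artifact elimination: WBC recurrence filter and 3-SD rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctdnamon.denoise import (
    BackgroundErrorModel,
    WBCDatabase,
    background_denoise,
    build_background_model,
    denoise_sample,
    wbc_artifact_filter,
)

from conftest import make_variants

SITE = ("chr1", 1000137, "A", "C")


def pool_of_afs(afs):
    """One single-site healthy table per AF value."""
    return [make_variants([(*SITE, "ERBB2", "missense", af)]) for af in afs]


class TestBackgroundModel:
    def test_hand_computed_mean_sd_threshold(self):
        # {0.001, 0.002, 0.003}: mean 0.002, sample SD 0.001 -> threshold 0.005
        model = build_background_model(pool_of_afs([0.001, 0.002, 0.003]))
        mean, sd, n = model.sites[SITE]
        assert mean == pytest.approx(0.002)
        assert sd == pytest.approx(0.001)
        assert n == 3
        assert model.threshold(SITE) == pytest.approx(0.005)

    def test_all_zero_site(self):
        model = build_background_model(pool_of_afs([0.0, 0.0, 0.0]))
        assert model.sites[SITE][:2] == (0.0, 0.0)

    def test_single_sample_pool_has_zero_sd(self):
        model = build_background_model(pool_of_afs([0.004]))
        assert model.sites[SITE][1] == 0.0

    def test_absent_observations_imputed_as_zero(self):
        # site seen in only one of three samples: mean over the full pool
        tables = pool_of_afs([0.003])
        other = ("chr2", 2000137, "C", "T")
        tables.append(make_variants([(*other, "TP53", "missense", 0.006)]))
        tables.append(make_variants([(*other, "TP53", "missense", 0.0)]))
        model = build_background_model(tables)
        mean, sd, n = model.sites[SITE]
        assert n == 3
        assert mean == pytest.approx(0.001)

    def test_fallback_used_for_unseen_site(self):
        model = build_background_model(pool_of_afs([0.001, 0.003]))
        unseen = ("chrX", 999, "G", "A")
        assert model.threshold(unseen) == pytest.approx(
            model.fallback[0] + 3 * model.fallback[1]
        )

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            build_background_model([])


class TestWBCFilter:
    def db(self, count, total=400):
        return WBCDatabase(total_samples=total, occurrence={SITE: count})

    def variants(self):
        return make_variants([(*SITE, "ERBB2", "missense", 0.02)])

    def test_recurrence_just_above_cutoff_removed(self):
        kept, log = wbc_artifact_filter(self.variants(), self.db(41))  # 10.25%
        assert len(kept) == 0
        assert log["reason"].tolist() == ["wbc_recurrent"]

    def test_recurrence_exactly_ten_percent_retained(self):
        kept, log = wbc_artifact_filter(self.variants(), self.db(40))
        assert len(kept) == 1 and len(log) == 0

    def test_unknown_variants_pass_empty_db(self):
        db = WBCDatabase(total_samples=400, occurrence={})
        kept, _ = wbc_artifact_filter(self.variants(), db)
        assert len(kept) == 1

    def test_occurrence_above_total_rejected(self):
        with pytest.raises(ValueError):
            WBCDatabase(total_samples=10, occurrence={SITE: 11})


class TestBackgroundDenoise:
    def model(self, mean=0.002, sd=0.001):
        return BackgroundErrorModel(sites={SITE: (mean, sd, 50)}, fallback=(mean, sd), pool_size=50)

    @pytest.mark.parametrize(
        "af,kept",
        [(0.0051, True), (0.0050, False), (0.0, False)],
    )
    def test_strict_three_sd_boundary(self, af, kept):
        variants = make_variants([(*SITE, "ERBB2", "missense", af)])
        retained, _ = background_denoise(variants, self.model())
        assert (len(retained) == 1) is kept

    def test_zero_background_keeps_tiny_af(self):
        variants = make_variants([(*SITE, "ERBB2", "missense", 0.0001)])
        retained, _ = background_denoise(variants, self.model(0.0, 0.0))
        assert len(retained) == 1

    def test_negative_af_rejected(self):
        bad = make_variants([(*SITE, "ERBB2", "missense", 0.1)]).assign(af=-0.1)
        with pytest.raises(ValueError):
            background_denoise(bad, self.model())

    def test_read_support_check_optional(self):
        # af above 3-SD but unimpressive read support at alpha 1e-12
        variants = make_variants([(*SITE, "ERBB2", "missense", 0.006)])
        retained, _ = background_denoise(variants, self.model(), read_support_alpha=1e-12)
        assert len(retained) == 0
        retained, _ = background_denoise(variants, self.model())
        assert len(retained) == 1

    @given(
        afs=st.lists(st.floats(0, 0.05, allow_nan=False), min_size=1, max_size=20),
        mean=st.floats(0, 0.01),
        sd=st.floats(0, 0.005),
    )
    @settings(max_examples=200, deadline=None)
    def test_retention_monotone_in_af(self, afs, mean, sd):
        """If a variant at AF a survives, any higher-AF variant at the site does."""
        model = BackgroundErrorModel(sites={SITE: (mean, sd, 10)}, fallback=(mean, sd), pool_size=10)
        variants = make_variants([(*SITE, "ERBB2", "missense", af) for af in afs])
        retained, _ = background_denoise(variants, model)
        kept_afs = set(retained["af"])
        if kept_afs:
            floor = min(kept_afs)
            assert all(af in kept_afs for af in afs if af > floor)


def _random_instance(rng):
    n_sites = rng.integers(3, 12)
    sites = [(f"chr{i%5+1}", 1000 + 7 * i, "A", "C") for i in range(n_sites)]
    total = int(rng.integers(10, 400))
    occurrence = {
        s: int(rng.integers(0, total + 1)) for s in sites if rng.random() < 0.6
    }
    model_sites = {
        s: (float(rng.uniform(0, 0.01)), float(rng.uniform(0, 0.004)), 10)
        for s in sites
        if rng.random() < 0.8
    }
    fallback = (float(rng.uniform(0, 0.01)), float(rng.uniform(0, 0.004)))
    picks = [sites[i] for i in rng.integers(0, n_sites, size=rng.integers(1, 30))]
    variants = make_variants(
        [(*s, "G", "missense", float(rng.uniform(0, 0.05))) for s in picks]
    )
    db = WBCDatabase(total_samples=total, occurrence=occurrence)
    model = BackgroundErrorModel(sites=model_sites, fallback=fallback, pool_size=10)
    return variants, db, model


def _brute_force_survivors(variants, db, model):
    """Straight-line reimplementation of both rules, row by row."""
    out = []
    for _, row in variants.iterrows():
        key = (row["chrom"], row["pos"], row["ref"], row["alt"])
        if db.occurrence.get(key, 0) / db.total_samples > 0.10:
            continue
        mean, sd, _ = model.sites.get(key, (*model.fallback, 0))
        if row["af"] > mean + 3 * sd:
            out.append((key, row["af"]))
    return sorted(out)


def test_denoise_matches_brute_force_oracle():
    """Vectorized survivors equal row-by-row rule application, many instances."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        variants, db, model = _random_instance(rng)
        kept, _ = denoise_sample(variants, db, model)
        got = sorted(
            ((r["chrom"], r["pos"], r["ref"], r["alt"]), r["af"])
            for _, r in kept.iterrows()
        )
        assert got == _brute_force_survivors(variants, db, model)


def test_filter_order_invariance():
    """WBC filter then denoise equals denoise then WBC filter (survivor sets)."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        variants, db, model = _random_instance(rng)
        a, _ = wbc_artifact_filter(variants, db)
        a, _ = background_denoise(a, model)
        b, _ = background_denoise(variants, model)
        b, _ = wbc_artifact_filter(b, db)
        key = lambda df: sorted(zip(df["chrom"], df["pos"], df["alt"], df["af"]))
        assert key(a) == key(b)


def test_planted_artifacts_removed_and_somatic_kept(small_cohort):
    """Synthetic samples: planted WBC artifacts never leak; strong somatic
    variants (AF >= 10x the noise mean) always survive."""
    from ctdnamon.denoise import build_background_model
    from ctdnamon.io import add_variant_keys

    model = build_background_model(small_cohort.healthy_pool)
    db = WBCDatabase.from_table(small_cohort.wbc_table, small_cohort.wbc_total)
    noise_mean = small_cohort.config.noise_mean_sd()[0]
    checked = 0
    for sample in small_cohort.samples[:40]:
        kept, _ = denoise_sample(sample["variants"], db, model)
        kept_keys = set(add_variant_keys(kept)["key"]) if len(kept) else set()
        assert not (kept_keys & small_cohort.artifact_keys)
        truth = next(
            t for t in small_cohort.truths if t.patient_id == sample["patient_id"]
        )
        f_now = truth.f_trajectory[truth.sample_days.index(sample["day"])]
        strong = {
            tuple(v["key"])
            for v in truth.clonal_variants
            if v["c"] * f_now / 2 >= 10 * noise_mean
        }
        assert strong <= kept_keys
        checked += 1
    assert checked == 40
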