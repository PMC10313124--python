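"""Complexity scoring, track summaries, accumulation, bootstrap, histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mgm.damage_metrics import (
    TrackDamageSummary,
    accumulate_tracks,
    bootstrap_yields,
    complexity_histogram,
    complexity_score,
    distribution_rmse,
    summarize_tracks,
)


class TestComplexityScore:
    def test_simple_dsb_scores_two(self, record_factory):
        """One strand break on each strand and nothing else: the minimum."""
        assert complexity_score(record_factory(sb1=1, sb2=1, bd=0)) == 2

    def test_score_is_total_lesion_count_when_dsb_present(self, record_factory):
        assert complexity_score(record_factory(sb1=2, sb2=1, bd=2)) == 5

    def test_no_dsb_means_no_score(self, record_factory):
        rec = record_factory(sb1=2, sb2=0, bd=1)
        assert rec.has_dsb is False
        assert complexity_score(rec) is None

    @given(sb1=st.integers(0, 6), sb2=st.integers(0, 6), bd=st.integers(0, 6))
    @settings(max_examples=100, deadline=None)
    def test_score_is_none_iff_no_dsb(self, sb1, sb2, bd):
        from conftest import make_record
        if sb1 + sb2 + bd == 0:
            bd = 1
        rec = make_record(sb1=sb1, sb2=sb2, bd=bd)
        score = complexity_score(rec)
        if rec.has_dsb:
            assert score == sb1 + sb2 + bd >= 2
        else:
            assert score is None


class TestSummarizeTracks:
    def test_counts_sites_and_dsb_sites(self, record_factory):
        recs = [
            record_factory(track_id=1, position=0),
            record_factory(track_id=1, position=100, sb1=0, sb2=0, bd=2),
            record_factory(track_id=1, position=200, sb1=2, sb2=2, bd=1),
        ]
        (s,) = summarize_tracks(recs)
        assert s.n_ds_total == 3
        assert s.n_ds_with_dsb == 2
        assert sorted(s.complexities) == [2, 5]

    def test_all_direct_lesions_give_zero_indirect(self, record_factory):
        recs = [record_factory(track_id=0, sb1=2, sb2=1, bd=3, direct=6)]
        (s,) = summarize_tracks(recs)
        assert s.n_sb_indirect == 0 and s.n_bd_indirect == 0
        assert s.n_sb_direct == 3 and s.n_bd_direct == 3

    def test_hand_tallied_fixture(self, record_factory):
        recs = [
            record_factory(track_id=0, sb1=1, sb2=1, bd=0, direct=2),
            record_factory(track_id=0, position=500, sb1=0, sb2=2, bd=3,
                           direct=0),
            record_factory(track_id=1, sb1=1, sb2=0, bd=0, direct=1),
        ]
        s0, s1 = summarize_tracks(recs)
        assert (s0.n_sb, s0.n_bd) == (4, 3)
        assert s0.n_sb_direct + s0.n_sb_indirect == 4
        assert s0.n_bd_direct + s0.n_bd_indirect == 3
        assert s0.n_sb_direct + s0.n_bd_direct == 2  # total direct lesions
        assert (s1.n_sb, s1.n_bd, s1.n_ds_with_dsb) == (1, 0, 0)

    def test_missing_cause_info_flags_split_unavailable(self, record_factory):
        recs = [record_factory(track_id=0, direct=0, indirect=0)]
        (s,) = summarize_tracks(recs)
        assert s.cause_split_available is False
        assert s.n_sb == 2  # totals still computed


class TestAccumulateTracks:
    def test_opposite_strand_breaks_merge_into_dsb(self, record_factory):
        a = record_factory(track_id=1, position=100, sb1=1, sb2=0, bd=0)
        b = record_factory(track_id=2, position=100, sb1=0, sb2=1, bd=0)
        (merged,) = accumulate_tracks([a, b])
        assert merged.has_dsb is True
        assert complexity_score(merged) == 2

    def test_different_chromosomes_never_merge(self, record_factory):
        a = record_factory(chromosome_id=1, position=100)
        b = record_factory(chromosome_id=2, position=100)
        assert len(accumulate_tracks([a, b])) == 2

    def test_non_overlapping_windows_do_not_merge(self, record_factory):
        a = record_factory(position=100)
        b = record_factory(position=110)
        assert len(accumulate_tracks([a, b])) == 2

    def test_transitive_chain_merges_once(self, record_factory):
        recs = [record_factory(position=p) for p in (100, 105, 112)]
        merged = accumulate_tracks(recs)
        assert len(merged) == 1
        assert merged[0].genomic_position_bp == 100

    def test_lesion_counts_conserved_on_random_fixture(self, rng, record_factory):
        recs = []
        for _ in range(400):
            sb1, sb2, bd = rng.integers(0, 3, size=3)
            if sb1 + sb2 + bd == 0:
                sb1 = 1
            recs.append(record_factory(
                track_id=int(rng.integers(0, 20)),
                chromosome_id=int(rng.integers(1, 4)),
                position=int(rng.integers(0, 2000)),
                sb1=int(sb1), sb2=int(sb2), bd=int(bd),
                direct=int(rng.integers(0, sb1 + sb2 + bd + 1)),
            ))
        merged = accumulate_tracks(recs)
        assert len(merged) <= len(recs)
        for attr in ("n_sb_strand1", "n_sb_strand2", "n_bd",
                     "cause_direct", "cause_indirect"):
            assert sum(getattr(r, attr) for r in merged) == \
                sum(getattr(r, attr) for r in recs), attr


class TestBootstrapYields:
    @staticmethod
    def _summary(track_id, n=10):
        return TrackDamageSummary(
            track_id=track_id, n_sb=n, n_bd=n, n_sb_direct=n, n_bd_direct=n,
            n_ds_total=n, n_ds_with_dsb=n // 2,
        )

    def test_identical_tracks_have_zero_variance(self):
        summaries = [self._summary(i) for i in range(20)]
        est = bootstrap_yields(summaries, dose_Gy=2.0, tracks_per_dose=10,
                               rng=0)
        assert est["sb"].variance == 0.0
        assert est["sb"].mean == pytest.approx(10 * 10 / 2.0)

    def test_single_bootstrap_equals_its_resample(self):
        summaries = [self._summary(i, n=i + 1) for i in range(5)]
        est = bootstrap_yields(summaries, dose_Gy=1.0, tracks_per_dose=3,
                               n_bootstrap=1, rng=42)
        rng = np.random.default_rng(42)
        idx = rng.integers(0, 5, size=(1, 3))
        expected = sum(summaries[i].n_sb for i in idx[0])
        assert est["sb"].mean == pytest.approx(expected)

    def test_seeded_runs_are_bit_reproducible(self):
        summaries = [self._summary(i, n=i % 4 + 1) for i in range(30)]
        a = bootstrap_yields(summaries, 2.0, 15, rng=7)
        b = bootstrap_yields(summaries, 2.0, 15, rng=7)
        assert a == b

    def test_bootstrap_mean_near_plugin_estimate(self, rng):
        summaries = [self._summary(i, n=int(rng.poisson(20))) for i in range(200)]
        tracks_per_dose = 50
        est = bootstrap_yields(summaries, 2.0, tracks_per_dose,
                               n_bootstrap=40, rng=3)
        plugin = np.mean([s.n_sb for s in summaries]) * tracks_per_dose / 2.0
        se = np.sqrt(est["sb"].variance / est["sb"].n_bootstrap)
        assert abs(est["sb"].mean - plugin) < 3 * se

    def test_empty_summaries_error(self):
        with pytest.raises(ValueError):
            bootstrap_yields([], 1.0, 1)


class TestHistograms:
    def test_small_example_masses(self):
        h = complexity_histogram([2, 2, 3])
        assert h[2] == pytest.approx(2 / 3)
        assert h[3] == pytest.approx(1 / 3)
        assert h.sum() == pytest.approx(1.0)

    def test_single_value_single_bin(self):
        h = complexity_histogram([5, 5, 5])
        assert list(h.index) == [5] and h.iloc[0] == 1.0

    def test_histogram_mean_matches_sample_mean(self, rng):
        c = np.maximum(np.rint(rng.gamma(4.0, 1.5, size=50_000)), 2).astype(int)
        h = complexity_histogram(c)
        hist_mean = float((h.index.to_numpy() * h.to_numpy()).sum())
        assert hist_mean == pytest.approx(c.mean(), rel=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            complexity_histogram([])

    def test_scores_below_two_rejected(self):
        with pytest.raises(ValueError):
            complexity_histogram([1, 2, 3])


class TestDistributionRmse:
    def test_identical_histograms_have_zero_rmse(self):
        h = complexity_histogram([2, 3, 3, 4])
        assert distribution_rmse(h, h) == 0.0

    def test_disjoint_point_masses_closed_form(self):
        a = pd.Series({2: 1.0})
        b = pd.Series({3: 1.0})
        assert distribution_rmse(a, b) == pytest.approx(1.0)

    @given(st.lists(st.integers(2, 10), min_size=1, max_size=50),
           st.lists(st.integers(2, 10), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, xs, ys):
        a = complexity_histogram(xs)
        b = complexity_histogram(ys)
        assert distribution_rmse(a, b) == pytest.approx(distribution_rmse(b, a))
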