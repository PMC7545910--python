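import numpy as np
import pandas as pd
import pytest

from bsamap.io import GenomeLayout
from bsamap.scan import (
    NullCiTable,
    attach_ci,
    call_regions,
    simulate_null_ci,
    slide_windows,
)


def _index_df(positions, deltas, chrom="chr1", depth=30):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "depthA": depth,
            "depthB": depth,
            "indexA": np.asarray(deltas) + 0.3,
            "indexB": 0.3,
            "delta": deltas,
        }
    )


class TestSlideWindows:
    def test_singleton_snp_mean(self):
        genome = GenomeLayout([("chr1", 2_000_000)])
        df = _index_df([1_500_000], [0.4])
        win = slide_windows(df, genome)
        hits = win[win["n_snps"] > 0]
        assert (hits["mean_delta"] == 0.4).all()
        assert (hits["n_snps"] == 1).all()
        # window containing the SNP must span it
        assert ((hits["start"] <= 1_500_000) & (hits["end"] >= 1_500_000)).all()

    def test_constant_signal_gives_constant_means(self):
        genome = GenomeLayout([("chr1", 3_000_000)])
        df = _index_df(np.arange(50_000, 3_000_001, 50_000), 0.25)
        win = slide_windows(df, genome)
        hits = win[win["n_snps"] > 0]
        assert np.allclose(hits["mean_delta"], 0.25)

    def test_three_snps_hand_mean(self):
        genome = GenomeLayout([("chr1", 1_000_000)])
        df = _index_df([100, 200, 300], [0.2, 0.4, 0.9])
        win = slide_windows(df, genome)
        first = win.iloc[0]
        assert first["start"] == 1 and first["n_snps"] == 3
        assert first["mean_delta"] == pytest.approx(0.5)

    def test_window_phase_anchored_at_one(self):
        genome = GenomeLayout([("chr1", 5_000_000)])
        win = slide_windows(_index_df([10], [0.1]), genome)
        starts = win["start"].to_numpy()
        assert starts[0] == 1
        assert np.all(np.diff(starts) == 10_000)
        # 1 Mb span, truncated at the chromosome end
        assert (win["end"] - win["start"] + 1).max() == 1_000_000
        assert win["end"].max() == 5_000_000

    def test_empty_windows_reported_with_zero_snps(self):
        genome = GenomeLayout([("chr1", 2_000_000)])
        win = slide_windows(_index_df([100], [0.1]), genome)
        empty = win[win["n_snps"] == 0]
        assert len(empty) > 0
        assert empty["mean_delta"].isna().all()

    def test_unknown_chromosome_errors(self):
        genome = GenomeLayout([("chr1", 1_000_000)])
        with pytest.raises(ValueError, match="chr9"):
            slide_windows(_index_df([10], [0.1], chrom="chr9"), genome)

    def test_window_must_cover_step(self):
        genome = GenomeLayout([("chr1", 1_000_000)])
        with pytest.raises(ValueError):
            slide_windows(_index_df([10], [0.1]), genome, window_bp=5_000, step_bp=10_000)


class TestNullCi:
    def test_minimal_design_bounds_are_plus_minus_one(self):
        # bulk of 1, depth 1, F2: Delta in {-1, 0, +1} w.p. {1/4, 1/2, 1/4};
        # the central 95% interval of that law is the full support
        t = simulate_null_ci("F2", 1, [1], n_replicates=10_000, seed=0)
        lo95, hi95, lo99, hi99 = t.for_depth(1)
        assert (lo95, hi95) == (-1.0, 1.0)
        assert (lo99, hi99) == (-1.0, 1.0)

    def test_minimal_design_matches_enumeration(self):
        t = NullCiTable("F2", 1, n_replicates=10_000, seed=0)
        d = t.null_draws(1, 10_000)
        for value, prob in [(-1, 0.25), (0, 0.5), (1, 0.25)]:
            frac = float(np.mean(d == value))
            sigma = np.sqrt(prob * (1 - prob) / len(d))
            assert abs(frac - prob) < 4 * sigma

    def test_median_of_null_is_zero(self):
        t = NullCiTable("F2", 21, seed=1)
        d = t.null_draws(30, 10_000)
        assert abs(np.median(d)) <= 1 / 30 + 1e-12

    def test_ci_width_shrinks_with_design_size(self):
        widths = []
        for bulk, depth in [(1, 5), (5, 20), (21, 50), (50, 200)]:
            t = simulate_null_ci("F2", bulk, [depth], n_replicates=5_000, seed=2)
            lo, hi, _, _ = t.for_depth(depth)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_99_interval_contains_95_interval(self):
        t = simulate_null_ci("F2", 21, [30], seed=3)
        lo95, hi95, lo99, hi99 = t.for_depth(30)
        assert lo99 <= lo95 < hi95 <= hi99

    def test_reproducible_under_seed(self):
        a = simulate_null_ci("F2", 21, [10, 30], seed=7).bounds
        b = simulate_null_ci("F2", 21, [30, 10], seed=7).bounds
        assert a == b


class TestAttachCi:
    def test_min_depth_keying(self):
        t = simulate_null_ci("F2", 21, [12], seed=0)
        df = _index_df([100], [0.0])
        df["depthA"], df["depthB"] = 12, 30
        out = attach_ci(df, t)
        assert tuple(out.iloc[0][["ci95_lo", "ci95_hi", "ci99_lo", "ci99_hi"]]) == t.bounds[12]

    def test_same_depth_same_bounds(self):
        t = simulate_null_ci("F2", 21, [], seed=0)
        df = _index_df([100, 200], [0.0, 0.1])
        out = attach_ci(df, t)
        assert out.iloc[0]["ci95_hi"] == out.iloc[1]["ci95_hi"]

    def test_missing_depth_computed_on_demand(self):
        t = simulate_null_ci("F2", 21, [], seed=0)
        assert t.bounds == {}
        df = _index_df([100], [0.0], depth=17)
        attach_ci(df, t)
        assert 17 in t.bounds


class TestCallRegions:
    def _windows(self, deltas, hi=0.3, n_snps=1):
        n = len(deltas)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 10_000 + 1,
                "end": np.arange(n) * 10_000 + 1_000_000,
                "n_snps": n_snps,
                "mean_delta": deltas,
                "mean_ci95_lo": -hi, "mean_ci95_hi": hi,
                "mean_ci99_lo": -hi - 0.1, "mean_ci99_hi": hi + 0.1,
            }
        )

    def test_nothing_significant_gives_empty_list(self):
        regions = call_regions(self._windows([0.1, 0.2, 0.0]), level=95)
        assert len(regions) == 0

    def test_single_significant_window_is_its_own_region(self):
        win = self._windows([0.0, 0.9, 0.0])
        regions = call_regions(win, level=95)
        assert len(regions) == 1
        row = regions.iloc[0]
        assert row["start"] == win.iloc[1]["start"] and row["end"] == win.iloc[1]["end"]
        assert row["peak_delta"] == pytest.approx(0.9)

    def test_overlapping_windows_merge(self):
        regions = call_regions(self._windows([0.9, 0.8, 0.95, 0.0]), level=95)
        assert len(regions) == 1
        assert regions.iloc[0]["peak_delta"] == pytest.approx(0.95)

    def test_peak_exceeds_bound_in_every_region(self):
        win = self._windows([0.9, 0.0, 0.0, 0.85])
        regions = call_regions(win, level=95)
        assert (regions["peak_delta"] > 0.3).all()

    def test_empty_windows_never_significant(self):
        win = self._windows([0.9], n_snps=0)
        assert len(call_regions(win, level=95)) == 0

    def test_two_sided_mode_catches_negative_peaks(self):
        win = self._windows([-0.9, 0.0])
        assert len(call_regions(win, level=95)) == 0
        assert len(call_regions(win, level=95, two_sided=True)) == 1

    def test_missing_ci_columns_instructs_user(self):
        win = self._windows([0.9]).drop(columns=["mean_ci99_hi", "mean_ci99_lo"])
        with pytest.raises(ValueError, match="simulate_null_ci"):
            call_regions(win, level=99)
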