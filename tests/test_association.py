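import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutscape import association as assoc


def table_from_bins(bin_events, cpgs_per_bin=100, timing=50.0):
    """Table with ``cpgs_per_bin`` CpGs at each bin midpoint and given events.

    Events are placed on the first site of each bin, which leaves the binned
    totals exact.
    """
    rows = []
    i = 0
    for b, ev in enumerate(bin_events):
        mid = b / 10 + 0.05
        for j in range(cpgs_per_bin):
            rows.append(("chr1", i * 10, mid, timing, "ACG", ev if j == 0 else 0))
            i += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "M", "R", "context", "events"])
    df["mutated"] = df["events"] >= 1
    return df


class TestBinnedRate:
    def test_rate_arithmetic(self):
        t = table_from_bins([6, 0, 3])
        a = assoc.binned_rate(t)
        # 6 events over 100 CpGs = 6 / 200 bp * 1e6 per Mb
        assert a.bins.loc[0, "rate"] == pytest.approx(30_000)
        assert a.bins.loc[1, "rate"] == 0.0

    def test_perfectly_linear_rates_give_r2_one(self):
        t = table_from_bins([2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
        a = assoc.binned_rate(t)
        assert a.r_squared == pytest.approx(1.0)
        # rate_b = (2b+2) * 5000, midpoints step 0.1 -> slope 10000/0.1
        assert a.slope == pytest.approx(100_000, rel=1e-9)

    def test_event_conservation(self):
        t = table_from_bins([5, 3, 0, 7])
        assert assoc.binned_rate(t).total_events == t["events"].sum() == 15

    def test_topmost_bin_closed(self):
        t = table_from_bins([1] * 10)
        t.loc[len(t) - 1, "M"] = 1.0
        a = assoc.binned_rate(t)
        assert a.bins["n_cpg"].sum() == len(t)

    def test_too_few_bins_refused(self):
        t = table_from_bins([5, 5])
        with pytest.raises(ValueError, match="non-empty"):
            assoc.binned_rate(t)

    def test_empty_table_refused(self):
        with pytest.raises(ValueError):
            assoc.binned_rate(table_from_bins([]))


class TestCompareSlopes:
    def test_identical_groups_zero_difference(self):
        a = assoc.binned_rate(table_from_bins([3, 9, 4, 12, 8, 20, 11, 30, 16, 40]))
        cmp = assoc.compare_slopes({"A": a, "B": a}, reference="A")
        assert cmp.differences["A"] == 0.0 and cmp.p_values["A"] == 1.0
        assert cmp.differences["B"] == pytest.approx(0.0, abs=1e-9)
        assert cmp.p_values["B"] == pytest.approx(1.0)

    def test_noiseless_slope_difference_closed_form(self):
        # rates exactly linear: group A slope 100 /unit, group B slope 300 /unit
        a = assoc.BinnedAssociation(
            bins=_linear_bins(slope=100), slope=100, intercept=0, r_squared=1, p_value=0
        )
        b = assoc.BinnedAssociation(
            bins=_linear_bins(slope=300), slope=300, intercept=0, r_squared=1, p_value=0
        )
        cmp = assoc.compare_slopes({"A": a, "B": b}, reference="A")
        assert cmp.differences["B"] == pytest.approx(200, rel=1e-9)
        assert cmp.slopes["A"] == pytest.approx(100, rel=1e-9)

    def test_reference_swap_reparameterization(self):
        t1 = table_from_bins([3, 9, 4, 12, 8, 20, 11, 30, 16, 40])
        t2 = table_from_bins([1, 5, 9, 2, 14, 11, 19, 22, 30, 28])
        t3 = table_from_bins([2, 2, 6, 9, 9, 15, 14, 21, 25, 31])
        assocs = {k: assoc.binned_rate(t) for k, t in {"A": t1, "B": t2, "C": t3}.items()}
        ca = assoc.compare_slopes(assocs, reference="A")
        cb = assoc.compare_slopes(assocs, reference="B")
        for g in "ABC":
            assert ca.slopes[g] == pytest.approx(cb.slopes[g], rel=1e-9)
        assert cb.differences["A"] == pytest.approx(-ca.differences["B"], rel=1e-9)

    def test_unknown_reference_rejected(self):
        a = assoc.binned_rate(table_from_bins([3, 9, 4, 12]))
        with pytest.raises(KeyError):
            assoc.compare_slopes({"A": a}, reference="Z")


def _linear_bins(slope, intercept=0.0):
    mids = np.arange(0.05, 1.0, 0.1)
    return pd.DataFrame(
        {
            "lo": mids - 0.05,
            "hi": mids + 0.05,
            "midpoint": mids,
            "n_cpg": 100,
            "events": 1,
            "rate": intercept + slope * mids,
        }
    )


class TestStratifyByTiming:
    def test_tertiles_split_evenly(self):
        t = pd.concat([table_from_bins([1] * 10, cpgs_per_bin=1, timing=v)
                       for v in range(1, 31)], ignore_index=True)
        strata = assoc.stratify_by_timing(t)
        assert {k: int(v.bins["n_cpg"].sum()) for k, v in strata.items()} == {
            "early": 100, "mid": 100, "late": 100
        }

    def test_highest_timing_is_early(self):
        t = pd.concat([table_from_bins([1] * 10, cpgs_per_bin=1, timing=v)
                       for v in (10.0, 50.0, 90.0)], ignore_index=True)
        strata = assoc.stratify_by_timing(t)
        # reconstruct which timing went where via per-stratum totals
        assert strata["early"].bins["n_cpg"].sum() == 10
        # early stratum must hold the sites with timing 90
        t_early = t[t["R"] == 90.0]
        assert len(t_early) == 10

    def test_degenerate_timing_refused(self):
        t = table_from_bins([1] * 10, timing=42.0)
        with pytest.raises(ValueError, match="degenerate"):
            assoc.stratify_by_timing(t)

    def test_planted_slope_ordering_recovered(self, rng):
        # later-replicating sites get a steeper methylation slope
        frames = []
        for timing, slope in [(80.0, 2.0), (50.0, 6.0), (20.0, 12.0)]:
            events = [int(slope * (b + 0.5)) for b in range(10)]
            frames.append(table_from_bins(events, timing=timing))
        t = pd.concat(frames, ignore_index=True)
        strata = assoc.stratify_by_timing(t)
        cmp = assoc.compare_slopes(strata, reference="early")
        assert cmp.differences["late"] > 0 and cmp.differences["mid"] > 0
        assert cmp.slopes["late"] > cmp.slopes["mid"] > cmp.slopes["early"]


class TestPerSampleSlopes:
    def _hits(self, spec):
        rows = [("chr1", pos, s, n) for s, items in spec.items() for pos, n in items]
        return pd.DataFrame(rows, columns=["chrom", "pos", "sample", "count"])

    def test_doubled_events_double_slope(self):
        t = table_from_bins([0] * 10)
        base = [(b * 1000, b + 1) for b in range(10)]  # first site of each bin
        hits = self._hits({"s1": base, "s2": [(p, 2 * n) for p, n in base]})
        df, r2, _ = assoc.per_sample_slopes(t, hits)
        s = df.set_index("sample")["slope"]
        assert s["s2"] == pytest.approx(2 * s["s1"], rel=1e-9)

    def test_collinear_slopes_and_totals(self):
        t = table_from_bins([0] * 10)
        base = [(b * 1000, b + 1) for b in range(10)]
        hits = self._hits(
            {"s1": base, "s2": [(p, 2 * n) for p, n in base], "s3": [(p, 3 * n) for p, n in base]}
        )
        df, r2, p = assoc.per_sample_slopes(t, hits)
        assert r2 == pytest.approx(1.0)

    def test_single_sample_rejected(self):
        t = table_from_bins([0] * 10)
        with pytest.raises(ValueError):
            assoc.per_sample_slopes(t, self._hits({"s1": [(0, 1)]}))


class TestCandidateFraction:
    def _table(self):
        rows = []
        for i in range(10):  # low-methylation TCG candidates
            rows.append(("chr1", i * 100, 0.1, 50.0, "TCG", 0))
        for i in range(10):  # high-methylation TCG candidates
            rows.append(("chr1", 5000 + i * 100, 0.9, 50.0, "TCG", 0))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "M", "R", "context", "events"])
        df["mutated"] = False
        return df

    def test_percentages(self):
        t = self._table()
        hits = pd.DataFrame(
            {"chrom": "chr1", "pos": [0, 100, 5000], "sample": "s1", "count": 1}
        )
        hits2 = hits.assign(sample="s2")
        df, _ = assoc.candidate_fraction(t, pd.concat([hits, hits2]))
        assert df.set_index("sample").loc["s1", "low_pct"] == 20.0
        assert df.set_index("sample").loc["s1", "high_pct"] == 10.0

    def test_zero_difference_degenerate(self):
        t = self._table()
        hits = pd.DataFrame(
            {"chrom": "chr1", "pos": [0, 5000, 0, 5000], "sample": ["s1", "s1", "s2", "s2"],
             "count": 1}
        )
        _, tests = assoc.candidate_fraction(t, hits)
        assert tests["paired"] == (0.0, 1.0)

    def test_planted_offset_detected_by_paired_test(self, rng):
        # 8 samples, high% = low% + 5 + noise(sigma=1): paired t must flag it
        low = 20 + rng.normal(0, 3, size=8)
        high = low + 5 + rng.normal(0, 1, size=8)
        diff = high - low
        t_stat = diff.mean() / (diff.std(ddof=1) / np.sqrt(8))
        p_oracle = 2 * stats.t.sf(abs(t_stat), df=7)
        t_sp, p_sp = stats.ttest_rel(high, low)
        assert p_sp == pytest.approx(p_oracle, rel=1e-9)
        assert p_sp < 0.01


class TestOneSampleTTest:
    def test_all_equal_to_mu(self):
        assert assoc.one_sample_ttest(np.array([0.5, 0.5, 0.5]), 0.5) == (0.0, 1.0)

    def test_symmetric_values(self):
        t, p = assoc.one_sample_ttest(np.array([0.1, 0.2, 0.3]), 0.2)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_distant_mu_strongly_rejected(self, rng):
        vals = rng.normal(0.5, 0.1, size=100)
        t, p = assoc.one_sample_ttest(vals, 0.97)
        # analytic scale: |t| approx 0.47 / (0.1/10) = 47
        assert abs(t) > 30 and p < 1e-10

    def test_zero_variance_sign_convention(self):
        t, p = assoc.one_sample_ttest(np.array([0.4, 0.4]), 0.9)
        assert p == 0.0 and t < 0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            assoc.one_sample_ttest(np.array([0.4]), 0.5)


class TestWindowedCorrelation:
    def _timing(self, values):
        from mutscape.io import TimingTrack

        return TimingTrack(
            pd.DataFrame(
                {"chrom": "chr1", "start": np.arange(len(values)) * 10**6,
                 "end": (np.arange(len(values)) + 1) * 10**6, "timing": values}
            )
        )

    def test_identical_signal(self):
        t = self._timing([10.0, 20.0, 30.0, 40.0])
        sig = t.windows[["chrom", "start"]].assign(value=t.windows["timing"])
        r, r2, p = assoc.windowed_signal_correlation(sig, t)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_negated_signal_carries_sign(self):
        t = self._timing([10.0, 20.0, 30.0, 40.0])
        sig = t.windows[["chrom", "start"]].assign(value=-t.windows["timing"])
        r, r2, _ = assoc.windowed_signal_correlation(sig, t)
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        vals = rng.normal(50, 10, size=10_000)
        t = self._timing(vals)
        sig = t.windows[["chrom", "start"]].assign(value=rng.normal(0, 1, size=10_000))
        _, r2, _ = assoc.windowed_signal_correlation(sig, t)
        assert r2 < 0.001  # ~chi2_1/n envelope

    def test_too_few_windows(self):
        t = self._timing([10.0, 20.0])
        sig = t.windows[["chrom", "start"]].assign(value=[1.0, 2.0])
        with pytest.raises(ValueError):
            assoc.windowed_signal_correlation(sig, t)
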