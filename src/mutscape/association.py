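"""Binned association statistics between CpG mutation rate and methylation.

The core quantity is the mutation rate per megabase of CpG dinucleotide
sequence within methylation bins of width 0.1: with ``n`` CpGs and ``k``
mutation events in a bin, rate = k / (2 n bp) x 1e6. A Pearson (ordinary
least squares) regression of rate on bin midpoint gives the slope of the
mutation-methylation association; slopes are compared between cohorts or
replication-timing strata via a stacked linear model with a group x midpoint
interaction against a named reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("mutscape")

BP_PER_CPG = 2  # a CpG dinucleotide covers 2 bp of sequence


@dataclass
class BinnedAssociation:
    """Mutation rate per methylation bin with its linear fit.

    ``bins`` columns: lo, hi, midpoint, n_cpg, events, rate (per Mb of CpG
    sequence). Empty bins are retained in the table but excluded from the
    fit. slope/intercept/r_squared/p_value come from OLS of rate on midpoint
    (two-sided p on the slope).
    """

    bins: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    @property
    def total_events(self) -> int:
        return int(self.bins["events"].sum())


def _bin_edges(bin_width: float) -> np.ndarray:
    n = int(round(1.0 / bin_width))
    return np.linspace(0.0, 1.0, n + 1)


def binned_rate(table: pd.DataFrame, bin_width: float = 0.1) -> BinnedAssociation:
    """Bin the CpG table by methylation and regress rate on bin midpoint.

    The topmost bin is closed ([1 - w, 1.0]); all others are half-open.
    Requires at least 3 non-empty bins for the fit.
    """
    if table.empty:
        raise ValueError("empty CpG table")
    edges = _bin_edges(bin_width)
    m = table["M"].to_numpy(dtype=float)
    idx = np.clip(np.digitize(m, edges[1:-1]), 0, len(edges) - 2)
    n_cpg = np.bincount(idx, minlength=len(edges) - 1)
    events = np.bincount(idx, weights=table["events"].to_numpy(dtype=float),
                         minlength=len(edges) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(n_cpg > 0, events / (n_cpg * BP_PER_CPG) * 1e6, 0.0)
    bins = pd.DataFrame(
        {
            "lo": edges[:-1],
            "hi": edges[1:],
            "midpoint": (edges[:-1] + edges[1:]) / 2,
            "n_cpg": n_cpg,
            "events": events.astype(int),
            "rate": rate,
        }
    )
    nonempty = bins[bins["n_cpg"] > 0]
    if len(nonempty) < 3:
        raise ValueError(f"only {len(nonempty)} non-empty methylation bins; need >=3 to fit")
    fit = stats.linregress(nonempty["midpoint"], nonempty["rate"])
    return BinnedAssociation(
        bins=bins,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
    )


@dataclass
class SlopeComparison:
    """Per-group slopes and their differences against a reference group."""

    reference: str
    slopes: dict[str, float]
    differences: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


def compare_slopes(assocs: dict[str, BinnedAssociation], reference: str) -> SlopeComparison:
    """Test slope differences between groups on stacked binned data.

    Fits one OLS model rate ~ midpoint + group + group:midpoint over the
    non-empty bins of all groups; the interaction coefficients are the slope
    differences relative to ``reference`` with their t-test p-values.
    """
    if reference not in assocs:
        raise KeyError(f"reference group {reference!r} not among {sorted(assocs)}")
    ref_edges = assocs[reference].bins[["lo", "hi"]].to_numpy()
    for name, a in assocs.items():
        if not np.array_equal(a.bins[["lo", "hi"]].to_numpy(), ref_edges):
            raise ValueError(f"group {name!r} uses different bin edges")

    groups = [reference] + sorted(g for g in assocs if g != reference)
    frames = []
    for g in groups:
        b = assocs[g].bins
        b = b[b["n_cpg"] > 0]
        frames.append(pd.DataFrame({"midpoint": b["midpoint"], "rate": b["rate"], "group": g}))
    data = pd.concat(frames, ignore_index=True)

    x = data["midpoint"].to_numpy()
    cols = [np.ones(len(data)), x]
    names = ["intercept", "midpoint"]
    for g in groups[1:]:
        ind = (data["group"] == g).to_numpy(dtype=float)
        cols += [ind, ind * x]
        names += [f"group[{g}]", f"slope_diff[{g}]"]
    X = np.column_stack(cols)
    res = sm.OLS(data["rate"].to_numpy(), X).fit()
    params = dict(zip(names, res.params))
    pvals = dict(zip(names, res.pvalues))

    slopes = {reference: params["midpoint"]}
    differences = {reference: 0.0}
    p_values = {reference: 1.0}
    for g in groups[1:]:
        differences[g] = float(params[f"slope_diff[{g}]"])
        slopes[g] = slopes[reference] + differences[g]
        p_values[g] = float(pvals[f"slope_diff[{g}]"])
    return SlopeComparison(reference=reference, slopes=slopes,
                           differences=differences, p_values=p_values)


def stratify_by_timing(
    table: pd.DataFrame, n_strata: int = 3, bin_width: float = 0.1
) -> dict[str, BinnedAssociation]:
    """Split the table by replication-timing quantiles and bin each stratum.

    Strata are genome-wide quantiles (tertiles by default) of the per-site
    timing values, with higher timing treated as earlier replication; with
    three strata the keys are "early", "mid" and "late" (else "stratum_i",
    earliest first). Ties spanning a boundary are assigned deterministically
    to the lower stratum, with a warning.
    """
    r = table["R"].to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("timing missing on some sites; drop them before stratifying")
    qs = np.quantile(r, np.linspace(0, 1, n_strata + 1))
    if np.unique(qs).size != n_strata + 1:
        raise ValueError("degenerate timing distribution: quantile boundaries coincide")
    inner = qs[1:-1]
    if any(np.sum(r == b) > 1 for b in inner):
        logger.warning("stratify_by_timing: ties at a stratum boundary assigned to lower stratum")
    # stratum 0 = lowest timing = latest replication; flip so index 0 = earliest
    idx = np.digitize(r, inner, right=True)
    order = n_strata - 1 - idx
    if n_strata == 3:
        names = ["early", "mid", "late"]
    else:
        names = [f"stratum_{i}" for i in range(n_strata)]
    out = {}
    for i, name in enumerate(names):
        sub = table[order == i]
        out[name] = binned_rate(sub, bin_width=bin_width)
    return out


def per_sample_slopes(
    table: pd.DataFrame,
    hits: pd.DataFrame,
    bin_width: float = 0.1,
) -> tuple[pd.DataFrame, float, float]:
    """Slope of the binned mutation-methylation fit for each sample separately.

    ``hits`` is the long per-(CpG, sample) count table. Each sample's own
    events are re-binned over the full CpG table. Returns (per-sample frame
    with slope and total mutation count, Pearson r^2 of slope vs total,
    p-value). Samples with zero events are excluded with a warning.
    """
    samples = sorted(hits["sample"].unique())
    if len(samples) < 2:
        raise ValueError("need >=2 samples")
    key = pd.MultiIndex.from_frame(table[["chrom", "pos"]])
    rows = []
    for s in samples:
        sub = hits[hits["sample"] == s]
        if sub["count"].sum() == 0:
            logger.warning("per_sample_slopes: sample %s has zero events; excluded", s)
            continue
        ev = sub.set_index(["chrom", "pos"])["count"].reindex(key, fill_value=0).to_numpy()
        t = table.assign(events=ev)
        assoc = binned_rate(t, bin_width=bin_width)
        rows.append((s, assoc.slope, int(ev.sum())))
    df = pd.DataFrame(rows, columns=["sample", "slope", "total_mutations"])
    if len(df) < 2:
        raise ValueError("fewer than 2 samples with events")
    if df["slope"].std() == 0 or df["total_mutations"].std() == 0:
        logger.warning("per_sample_slopes: zero variance; correlation undefined")
        return df, float("nan"), float("nan")
    r, p = stats.pearsonr(df["slope"], df["total_mutations"])
    return df, float(r) ** 2, float(p)


def candidate_fraction(
    table: pd.DataFrame,
    hits: pd.DataFrame,
    context: str = "TCG",
    low: float = 0.25,
    high: float = 0.75,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-sample percentage of low- vs high-methylation candidate CpGs mutated.

    Candidates are CpGs whose forward-strand trinucleotide context matches
    ``context``; the low stratum is methylation < ``low``, the high stratum
    > ``high``. For each sample the percentage of candidates in each stratum
    carrying a (deamination-class) mutation is reported, followed by paired
    and unpaired two-sided t-tests of high vs low across samples.
    """
    cand = table[table["context"] == context]
    low_set = cand[cand["M"] < low]
    high_set = cand[cand["M"] > high]
    rows = []
    for s in sorted(hits["sample"].unique()):
        sub = hits[hits["sample"] == s]
        hit_keys = set(zip(sub["chrom"], sub["pos"]))
        res = []
        skip = False
        for strat in (low_set, high_set):
            if strat.empty:
                logger.warning("candidate_fraction: empty stratum; sample %s excluded", s)
                skip = True
                break
            n_hit = sum((c, p) in hit_keys for c, p in zip(strat["chrom"], strat["pos"]))
            res.append(100.0 * n_hit / len(strat))
        if not skip:
            rows.append((s, res[0], res[1]))
    df = pd.DataFrame(rows, columns=["sample", "low_pct", "high_pct"])
    tests: dict[str, tuple[float, float]] = {}
    if len(df) >= 2:
        diff = df["high_pct"] - df["low_pct"]
        if diff.std() == 0:
            logger.warning("candidate_fraction: zero-variance differences; paired test degenerate")
            tests["paired"] = (0.0, 1.0) if (diff == 0).all() else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_rel(df["high_pct"], df["low_pct"])
            tests["paired"] = (float(t), float(p))
        t, p = stats.ttest_ind(df["high_pct"], df["low_pct"])
        tests["unpaired"] = (float(t), float(p))
    return df, tests


def one_sample_ttest(values: np.ndarray, mu: float) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``values`` against the constant ``mu``.

    With zero-variance values the statistic is degenerate: p = 1 when the
    common value equals mu, else p = 0 (flagged by a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >=2 values")
    if values.std(ddof=1) == 0:
        logger.warning("one_sample_ttest: zero variance; p by sign convention")
        if np.isclose(values.mean(), mu):
            return 0.0, 1.0
        return float(np.sign(values.mean() - mu)) * float("inf"), 0.0
    t, p = stats.ttest_1samp(values, mu)
    return float(t), float(p)


def windowed_signal_correlation(
    signal: pd.DataFrame, timing
) -> tuple[float, float, float]:
    """Pearson correlation of a per-window signal with replication timing.

    ``signal`` has chrom/start/value columns on the same windows as the
    timing track. Returns (r, r^2, two-sided p). Requires >=3 shared windows.
    """
    tw = timing.windows.dropna(subset=["timing"])
    merged = signal.merge(tw, on=["chrom", "start"], how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared windows")
    r, p = stats.pearsonr(merged["value"], merged["timing"])
    return float(r), float(r) ** 2, float(p)
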