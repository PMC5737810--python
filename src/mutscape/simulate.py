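"""Synthetic genomes, tracks and mutation cohorts with planted structure.

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes:

* a random genome whose only CpG dinucleotides are planted at a chosen
  density (the background sequence is sampled so that no CpG arises by
  chance, making the CpG count exact and scans cheap to verify);
* a bimodal per-CpG methylation fraction, mixing a high and a low Beta
  component the way whole-genome bisulfite data from somatic tissue does;
* a smooth replication-timing signal — a low-frequency sinusoid per
  chromosome scaled to a Repli-seq-like range, higher values = earlier;
* per-sample mutations drawn independently per CpG from the logistic model
  logit(P) = b0 + b1*M + b2*M^2 + b3*R + b4*M*R, realised as C>T on the C or
  G>A on the G of the dinucleotide with equal probability;
* optional strand-asymmetric mutation classes around declared origins, and
  toy coding sequences with known TCG stop-gain sites.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for configs)

from .cpg_table import TABLE_COLUMNS
from .io import GeneModel, MethylationTrack, TimingTrack, revcomp


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the study design.

    ``coefficients`` are (b0, b1, b2, b3, b4) of the generative logistic
    model; the default timing range (25, 75) mimics the wavelet-smoothed
    Repli-seq scale on which timing coefficients of order 0.01 are
    meaningful. ``meth_timing_correlation`` optionally couples methylation
    to timing to stress-test the model's ability to separate the two.
    """

    seed: int
    genome_length: int = 10_000_000
    n_chroms: int = 4
    cpg_density: float = 0.02  # CpGs per bp
    meth_high_ab: tuple[float, float] = (6.0, 1.5)
    meth_low_ab: tuple[float, float] = (1.5, 6.0)
    meth_high_weight: float = 0.75
    timing_range: tuple[float, float] = (25.0, 75.0)
    timing_period_bp: float = 5e6
    window_size: int = 1_000_000
    coefficients: tuple[float, float, float, float, float] = (-8.0, 3.0, -1.0, 0.01, 0.005)
    n_samples: int = 10
    sample_multipliers: tuple[float, ...] | None = None  # per-sample odds multipliers
    meth_timing_correlation: float = 0.0
    origins: tuple[tuple[str, int, str], ...] = ()
    origin_bias: float = 0.9
    origin_flank: int = 25_000

    def __post_init__(self) -> None:
        if not 0 <= self.meth_high_weight <= 1:
            raise ValueError("mixture weight outside [0, 1]")
        if self.cpg_density > 0.25:
            raise ValueError("CpG density too high to place non-overlapping CpGs")
        if self.sample_multipliers is not None and len(self.sample_multipliers) != self.n_samples:
            raise ValueError("one multiplier per sample required")


@dataclass
class SyntheticTracks:
    """Everything :func:`simulate_genome` produces, in memory."""

    genome: dict[str, str]
    methylation: MethylationTrack
    timing: TimingTrack
    genes: list[GeneModel] = field(default_factory=list)


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_genome(config: SimulationConfig) -> SyntheticTracks:
    """Generate the genome, methylation and timing tracks of one synthetic study.

    The background sequence never contains a C directly followed by a G, so
    the genome's CpGs are exactly the planted ones; planting draws one CpG
    per non-overlapping 1/density window jittered uniformly, keeping the
    realised count within a few percent of density x length.
    """
    rng = np.random.default_rng(config.seed)
    names = _chrom_names(config.n_chroms)
    chrom_len = config.genome_length // config.n_chroms
    genome: dict[str, str] = {}
    meth_rows = []
    timing_rows = []
    for ci, chrom in enumerate(names):
        seq = _background_sequence(rng, chrom_len)
        spacing = int(round(1.0 / config.cpg_density))  # one CpG per spacing bp
        starts = np.arange(0, chrom_len - spacing, spacing)
        jitter = rng.integers(1, spacing - 2, size=starts.size)
        pos = starts + jitter
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        # planting may separate a background C from a following G it never had,
        # but cannot create a new CpG other than the planted ones: guard anyway
        genome[chrom] = seq.tobytes().decode()

        # timing: one smooth sinusoid per chromosome over megabase windows
        lo, hi = config.timing_range
        mid, amp = (lo + hi) / 2, (hi - lo) / 2
        n_win = (chrom_len + config.window_size - 1) // config.window_size
        phase = 2 * np.pi * ci / max(config.n_chroms, 1)
        for w in range(n_win):
            centre = (w + 0.5) * config.window_size
            t = mid + amp * np.sin(2 * np.pi * centre / config.timing_period_bp + phase)
            timing_rows.append((chrom, w * config.window_size,
                                min((w + 1) * config.window_size, chrom_len), t))

        meth = _bimodal_methylation(rng, pos.size, config)
        if config.meth_timing_correlation != 0.0:
            t_at = np.interp(
                pos,
                [r[1] for r in timing_rows if r[0] == chrom],
                [r[3] for r in timing_rows if r[0] == chrom],
            )
            z = (t_at - np.mean(config.timing_range)) / (np.ptp(config.timing_range) / 2)
            meth = np.clip(meth + config.meth_timing_correlation * 0.2 * z, 0.0, 1.0)
        meth_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth,
                                       "coverage": -1}))

    methylation = MethylationTrack(pd.concat(meth_rows, ignore_index=True))
    timing = TimingTrack(
        pd.DataFrame(timing_rows, columns=["chrom", "start", "end", "timing"]),
        window_size=config.window_size,
    )
    return SyntheticTracks(genome=genome, methylation=methylation, timing=timing)


def _background_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sequence with no CpG: after a C, G is never drawn."""
    draws = rng.integers(0, 4, size=length)
    bases = np.frombuffer(b"ACGT", dtype="S1")[draws].copy()
    # rewrite any G following a C with a non-G base (deterministic from draws)
    cg = np.flatnonzero((bases[:-1] == b"C") & (bases[1:] == b"G"))
    while cg.size:
        repl = np.frombuffer(b"ACT", dtype="S1")[rng.integers(0, 3, size=cg.size)]
        bases[cg + 1] = repl
        cg = np.flatnonzero((bases[:-1] == b"C") & (bases[1:] == b"G"))
    return bases


def _bimodal_methylation(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    hi = rng.random(n) < config.meth_high_weight
    a1, b1 = config.meth_high_ab
    a0, b0 = config.meth_low_ab
    out = np.empty(n)
    out[hi] = rng.beta(a1, b1, size=int(hi.sum()))
    out[~hi] = rng.beta(a0, b0, size=int((~hi).sum()))
    return out


def build_synthetic_table(tracks: SyntheticTracks) -> pd.DataFrame:
    """Per-CpG table (no mutations yet) straight from in-memory tracks."""
    rows = []
    for chrom, sub in tracks.methylation.records.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        seq = tracks.genome[chrom]
        padded = "N" + seq + "N"
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "M": sub["meth"].to_numpy(),
                    "R": tracks.timing.lookup(chrom, pos),
                    "context": [padded[p : p + 3] for p in pos],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["mutated"] = False
    table["events"] = 0
    return table[TABLE_COLUMNS]


def simulate_mutations(
    table: pd.DataFrame,
    coefficients: tuple[float, float, float, float, float],
    n_samples: int,
    seed: int,
    sample_multipliers: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Draw per-sample mutations from the logistic model over a CpG table.

    Each CpG is mutated independently in each sample with probability
    expit(b0 + b1*M + b2*M^2 + b3*R + b4*M*R) (per-sample odds multipliers
    shift b0 by log(multiplier)); a mutated CpG carries C>T at the C or G>A
    at the G with equal probability. Returns the standard mutation table
    with samples "s000"..; all records are PASS.
    """
    b0, b1, b2, b3, b4 = (float(c) for c in coefficients)
    if not all(np.isfinite([b0, b1, b2, b3, b4])):
        raise ValueError("non-finite coefficients")
    m = table["M"].to_numpy(dtype=float)
    r = table["R"].to_numpy(dtype=float)
    lp = b0 + b1 * m + b2 * m * m + b3 * r + b4 * m * r
    rng = np.random.default_rng(seed)
    if sample_multipliers is None:
        sample_multipliers = (1.0,) * n_samples
    frames = []
    chrom = table["chrom"].to_numpy()
    pos = table["pos"].to_numpy()
    for i in range(n_samples):
        p = expit(lp + np.log(sample_multipliers[i]))
        if np.any(p >= 1.0):
            raise ValueError("mutation probability reached 1: implausible coefficients")
        hit = rng.random(m.size) < p
        if not hit.any():
            continue
        on_c = rng.random(int(hit.sum())) < 0.5
        hpos = pos[hit] + np.where(on_c, 0, 1)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom[hit],
                    "pos": hpos,
                    "ref": np.where(on_c, "C", "G"),
                    "alt": np.where(on_c, "T", "A"),
                    "sample": f"s{i:03d}",
                    "filter": "PASS",
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "sample", "filter"])
    return pd.concat(frames, ignore_index=True)


def plant_asymmetry(
    mutations: pd.DataFrame,
    origin: tuple[str, int, str],
    ratio: float,
    seed: int,
    flank: int = 25_000,
) -> pd.DataFrame:
    """Reassign mutation strand labels around an origin at a given bias ratio.

    Mutations 5' of the origin (within ``flank``) are placed with the
    pyrimidine on the plus strand with probability ``ratio``; 3' mutations
    with probability 1 - ``ratio`` — mimicking the leading/lagging flip a
    replication-coupled mutation class shows across an origin. Only ref/alt
    (and the within-dinucleotide base) change; positions of the affected
    CpGs and total counts are conserved.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    chrom, opos, _ = origin
    rng = np.random.default_rng(seed)
    out = mutations.copy()
    in_flank = (
        (out["chrom"] == chrom)
        & (out["pos"] >= opos - flank)
        & (out["pos"] < opos + flank)
    )
    if not in_flank.any():
        raise ValueError("no mutations within the origin flank")
    idx = out.index[in_flank]
    five_prime = out.loc[idx, "pos"].to_numpy() < opos
    p_plus = np.where(five_prime, ratio, 1.0 - ratio)
    on_plus = rng.random(idx.size) < p_plus
    # current pyrimidine strand: plus iff ref is a pyrimidine
    cur_plus = out.loc[idx, "ref"].isin(["C", "T"]).to_numpy()
    flip = on_plus != cur_plus
    for i, do_flip in zip(idx, flip):
        if not do_flip:
            continue
        ref, alt = out.at[i, "ref"], out.at[i, "alt"]
        # move the record to the complementary base of the dinucleotide
        out.at[i, "pos"] += 1 if ref in "CT" else -1
        out.at[i, "ref"] = revcomp(ref)
        out.at[i, "alt"] = revcomp(alt)
    return out


def make_toy_cds(
    n_codons: int, seed: int, plant_stop_gain: bool = True
) -> tuple[str, list[int]]:
    """Random in-frame CDS with optionally planted TCG stop-gain codons.

    Returns (cds, planted_codon_indices). A planted site is an ACT CGA codon
    pair: the CGA codon's C sits in a TCG context and C>T yields TGA. The
    CDS starts with ATG and ends with a TAA stop.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    non_stop = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS_TUPLE
    ]
    for _ in range(max(n_codons - 2, 0)):
        codons.append(non_stop[rng.integers(0, len(non_stop))])
    codons.append("TAA")
    planted = []
    if plant_stop_gain and n_codons >= 4:
        k = int(rng.integers(2, n_codons - 1))
        codons[k - 1], codons[k] = "ACT", "CGA"
        planted.append(k + 1)  # 1-based codon index of the CGA
    return "".join(codons), planted


STOP_CODONS_TUPLE = ("TAA", "TAG", "TGA")


def simulate_cohort(config: SimulationConfig) -> tuple[SyntheticTracks, pd.DataFrame, pd.DataFrame]:
    """End-to-end synthetic study: tracks, per-CpG table and mutation table.

    The returned table carries the pooled binary outcome over the simulated
    cohort (events counted with the default deamination classes).
    """
    tracks = simulate_genome(config)
    table = build_synthetic_table(tracks)
    mutations = simulate_mutations(
        table,
        config.coefficients,
        config.n_samples,
        seed=config.seed + 1,
        sample_multipliers=config.sample_multipliers,
    )
    from .cpg_table import assign_mutations

    hits = assign_mutations(mutations, table)
    if len(hits):
        events = hits.groupby(["chrom", "pos"])["count"].sum()
        key = pd.MultiIndex.from_frame(table[["chrom", "pos"]])
        table["events"] = events.reindex(key, fill_value=0).to_numpy()
    table["mutated"] = table["events"] >= 1
    return tracks, table, mutations


def cohort_with_vertex(
    vertex: float,
    config: SimulationConfig,
    curvature: float = -2.0,
    base_log_odds: float = -4.5,
) -> SimulationConfig:
    """Config whose generative log-odds parabola peaks at ``vertex`` (b4 = 0).

    With b4 = 0 the planted vertex is -b1 / (2*b2) regardless of the timing
    reference, so the recovery target is exact by construction.
    """
    b2 = curvature
    b1 = -2.0 * b2 * vertex
    b0 = base_log_odds + b2 * vertex**2  # same log-odds at the peak for any vertex
    return replace(config, coefficients=(b0, b1, b2, 0.01, 0.0))
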