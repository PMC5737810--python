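"""Genome-wide per-CpG annotation table and TSS profiles.

The table is the central data structure of the analysis: one row per genomic
CpG dinucleotide with methylation data, carrying the methylation fraction M,
the replication timing R of the enclosing megabase window, the trinucleotide
context centred on the cytosine, and the pooled binary mutation outcome
(mutated in at least one sample of the cohort vs never mutated) together
with the total event count. It is a plain pandas DataFrame with columns

    chrom, pos, M, R, context, mutated, events

Per-sample hit counts are kept in a separate long-format DataFrame
(chrom, pos, sample, count) produced by :func:`assign_mutations`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AUTOSOMES, MethylationTrack, TimingTrack, cpg_positions

logger = logging.getLogger("mutscape")

TABLE_COLUMNS = ["chrom", "pos", "M", "R", "context", "mutated", "events"]

#: mutation classes: which substitutions at a CpG count as "a mutation at the CpG"
DEAMINATION = "deamination"  # C>T at the C, or G>A at the G (strand-symmetric 5mC>T)
ALL_SNVS = "all"  # any single-base substitution on either base of the dinucleotide


def assign_mutations(
    mutations: pd.DataFrame,
    cpg_index: pd.DataFrame,
    mutation_classes: str = DEAMINATION,
) -> pd.DataFrame:
    """Map mutation records onto CpG dinucleotides.

    ``cpg_index`` needs chrom/pos columns giving the C of each CpG. A record
    is assigned to a CpG if it falls on either base of the dinucleotide and
    matches the class rule. Returns per-(CpG, sample) counts with the CpG
    addressed by its C position. Mutations outside any CpG are ignored here.
    """
    if mutation_classes not in (DEAMINATION, ALL_SNVS):
        raise ValueError(f"unknown mutation_classes: {mutation_classes!r}")
    hits = []
    for chrom, sub in mutations.groupby("chrom", sort=False):
        cpgs = cpg_index.loc[cpg_index["chrom"] == chrom, "pos"].to_numpy()
        if cpgs.size == 0:
            continue
        cset = set(cpgs.tolist())
        pos = sub["pos"].to_numpy()
        ref = sub["ref"].to_numpy()
        alt = sub["alt"].to_numpy()
        on_c = np.fromiter((p in cset for p in pos), bool, len(pos))
        on_g = np.fromiter((p - 1 in cset for p in pos), bool, len(pos))
        if mutation_classes == DEAMINATION:
            on_c &= (ref == "C") & (alt == "T")
            on_g &= (ref == "G") & (alt == "A")
        keep = on_c | on_g
        if not keep.any():
            continue
        cpos = np.where(on_c, pos, pos - 1)[keep]
        hits.append(
            pd.DataFrame({"chrom": chrom, "pos": cpos, "sample": sub["sample"].to_numpy()[keep]})
        )
    if not hits:
        return pd.DataFrame(columns=["chrom", "pos", "sample", "count"])
    out = (
        pd.concat(hits, ignore_index=True)
        .groupby(["chrom", "pos", "sample"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def build_cpg_table(
    genome: dict[str, str],
    methylation: MethylationTrack,
    timing: TimingTrack,
    mutations: pd.DataFrame,
    mutation_classes: str = DEAMINATION,
    chroms: tuple[str, ...] = AUTOSOMES,
) -> pd.DataFrame:
    """Build the per-CpG annotation table for one cohort.

    Only contigs in ``chroms`` (default: autosomes) enter the table, and only
    CpGs with methylation data are kept. The binary ``mutated`` flag follows
    the pooled rule: true iff at least one sample of the supplied cohort
    carries a class-matching mutation on either base of the dinucleotide.
    """
    rows = []
    for chrom, seq in genome.items():
        if chrom not in chroms:
            continue
        pos = cpg_positions(seq)
        if pos.size == 0:
            continue
        meth = methylation.records[methylation.records["chrom"] == chrom]
        meth_map = dict(zip(meth["pos"].to_numpy(), meth["meth"].to_numpy()))
        keep = np.fromiter((p in meth_map for p in pos), bool, len(pos))
        pos = pos[keep]
        if pos.size == 0:
            continue
        m = np.fromiter((meth_map[p] for p in pos), float, len(pos))
        r = timing.lookup(chrom, pos)
        padded = "N" + seq + "N"
        ctx = [padded[p : p + 3] for p in pos]  # padded index p == seq index p-1
        rows.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "M": m, "R": r, "context": ctx})
        )
    if not rows:
        raise ValueError("no CpG of the genome has methylation data on the kept contigs")
    table = pd.concat(rows, ignore_index=True)

    muts = mutations[mutations["chrom"].isin(chroms)]
    hits = assign_mutations(muts, table, mutation_classes)
    events = hits.groupby(["chrom", "pos"])["count"].sum()
    key = pd.MultiIndex.from_frame(table[["chrom", "pos"]])
    table["events"] = events.reindex(key, fill_value=0).to_numpy()
    table["mutated"] = table["events"] >= 1
    return table[TABLE_COLUMNS].sort_values(["chrom", "pos"], ignore_index=True)


def write_table(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"pos": "pos"})
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["mutated"] = df["mutated"].astype(bool)
    return df[TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# TSS profiles


@dataclass
class ProfileTrack:
    """Pooled mutation counts and mean methylation around anchor points.

    ``positions`` are transcription-oriented offsets (downstream positive);
    ``counts`` is the per-bp pooled mutation count, ``binned`` sums counts in
    fixed-width bins (indexed by bin start offset) and ``mean_meth`` averages
    the methylation of CpGs observed at each offset (NaN where none).
    """

    positions: np.ndarray
    counts: np.ndarray
    bin_width: int
    binned: pd.DataFrame
    mean_meth: np.ndarray

    def __post_init__(self) -> None:
        assert int(self.counts.sum()) == int(self.binned["count"].sum())


def tss_profile(
    mutations: pd.DataFrame,
    methylation: MethylationTrack,
    tss_anchors: list[tuple[str, int, str]],
    flank: int = 2000,
    bin_width: int = 25,
    chrom_sizes: dict[str, int] | None = None,
) -> ProfileTrack:
    """Mutation and methylation profile around transcription start sites.

    Offsets for minus-strand anchors are reflected so that positive offsets
    are always downstream of transcription. Anchors whose window extends past
    a known chromosome end are skipped with a warning.
    """
    if not tss_anchors:
        raise ValueError("no TSS anchors supplied")
    if flank <= 0:
        raise ValueError("flank must be positive")
    offsets = np.arange(-flank, flank + 1)
    counts = np.zeros(offsets.size, dtype=np.int64)
    meth_sum = np.zeros(offsets.size)
    meth_n = np.zeros(offsets.size, dtype=np.int64)

    mut_by_chrom = {c: s["pos"].to_numpy() for c, s in mutations.groupby("chrom", sort=False)}
    meth_by_chrom = {
        c: (s["pos"].to_numpy(), s["meth"].to_numpy())
        for c, s in methylation.records.groupby("chrom", sort=False)
    }
    for chrom, tss, strand in tss_anchors:
        if chrom_sizes is not None:
            size = chrom_sizes.get(chrom, 0)
            if tss - flank < 0 or tss + flank >= size:
                logger.warning("tss_profile: anchor %s:%d outside bounds; skipped", chrom, tss)
                continue
        sign = -1 if strand == "-" else 1
        mpos = mut_by_chrom.get(chrom)
        if mpos is not None:
            rel = (mpos - tss) * sign
            sel = rel[(rel >= -flank) & (rel <= flank)]
            np.add.at(counts, sel + flank, 1)
        if chrom in meth_by_chrom:
            cpos, cval = meth_by_chrom[chrom]
            rel = (cpos - tss) * sign
            inside = (rel >= -flank) & (rel <= flank)
            np.add.at(meth_sum, rel[inside] + flank, cval[inside])
            np.add.at(meth_n, rel[inside] + flank, 1)

    bin_start = (offsets + flank) // bin_width * bin_width - flank
    binned = (
        pd.DataFrame({"bin_start": bin_start, "count": counts})
        .groupby("bin_start")["count"]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore"):
        mean_meth = np.where(meth_n > 0, meth_sum / np.maximum(meth_n, 1), np.nan)
    return ProfileTrack(
        positions=offsets, counts=counts, bin_width=bin_width, binned=binned, mean_meth=mean_meth
    )
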