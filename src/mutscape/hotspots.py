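"""Truncating-mutation candidates at TCG trinucleotides, and origin asymmetry.

Methylated TCG sites are the most mutated CpG context in POLE-mutant tumours,
and a C>T there can convert a sense codon directly into a stop codon (e.g.
CGA -> TGA at TP53 R213). This module enumerates every coding-sequence
position where a single C>T in a 5'-TCG-3' context — on either the coding or
the template strand — immediately truncates the protein, annotates candidates
with their CpG methylation, and provides the Fisher exact tests used for
hotspot contingency and replication-origin strand asymmetry.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import one_sample_ttest
from .io import GeneModel, MethylationTrack, revcomp

logger = logging.getLogger("mutscape")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class CandidateStopSite:
    """A CDS position where C>T in TCG context creates an immediate stop.

    ``cds_pos`` is the 0-based position of the mutated base in the spliced
    CDS (on the coding strand); ``strand`` records where the mutated
    pyrimidine sits: "coding" for a coding-strand C>T, "template" for a
    template-strand C>T (seen as G>A on the coding strand).
    """

    gene: str
    codon_index: int  # 1-based
    cds_pos: int
    strand: str
    ref_codon: str
    mut_codon: str

    def __post_init__(self) -> None:
        assert self.mut_codon in STOP_CODONS and self.ref_codon not in STOP_CODONS


def enumerate_stop_gain_tcg(
    cds: str, gene: str = "", flank5: str = "N", flank3: str = "N"
) -> list[CandidateStopSite]:
    """Scan an in-frame CDS for C>T stop-gain candidates in TCG context.

    ``flank5``/``flank3`` are the single genomic bases immediately before and
    after the CDS, needed to resolve the context of edge positions. Both
    strands are scanned: a coding-strand site needs 5'-TCG-3' read on the
    coding strand around a C; a template-strand site needs 5'-TCG-3' on the
    template, i.e. 5'-CGA-3' on the coding strand around the central G whose
    G>A (template C>T) is tested. Sites whose context contains an ambiguous
    base are skipped with a warning. Results are sorted by codon index.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    padded = flank5.upper() + cds + flank3.upper()
    sites = []
    for i, base in enumerate(cds):
        ctx = padded[i : i + 3]  # padded[i] = cds[i-1]
        if "N" in ctx:
            if (base == "C" and ctx[1:] == "CG") or (base == "G" and ctx[:2] == "CG"):
                logger.warning("%s: ambiguous context at CDS pos %d; skipped", gene, i)
            continue
        codon_idx = i // 3
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        offset = i % 3
        if base == "C" and ctx == "TCG":
            mut = codon[:offset] + "T" + codon[offset + 1 :]
            strand = "coding"
        elif base == "G" and revcomp(ctx) == "TCG":  # coding CGA centred on the G
            mut = codon[:offset] + "A" + codon[offset + 1 :]
            strand = "template"
        else:
            continue
        if mut in STOP_CODONS and codon not in STOP_CODONS:
            sites.append(
                CandidateStopSite(
                    gene=gene,
                    codon_index=codon_idx + 1,
                    cds_pos=i,
                    strand=strand,
                    ref_codon=codon,
                    mut_codon=mut,
                )
            )
    return sorted(sites, key=lambda s: (s.codon_index, s.cds_pos))


def enumerate_stop_gain_for_gene(
    gene: GeneModel, genome: dict[str, str]
) -> list[CandidateStopSite]:
    """Run the TCG stop-gain scan on a gene model against its genome."""
    cds = gene.cds_sequence(genome)
    chrom = genome[gene.chrom]
    first, last = gene.exons[0][0], gene.exons[-1][1]
    if gene.strand == "-":
        f5 = revcomp(chrom[last]) if last < len(chrom) else "N"
        f3 = revcomp(chrom[first - 1]) if first > 0 else "N"
    else:
        f5 = chrom[first - 1] if first > 0 else "N"
        f3 = chrom[last] if last < len(chrom) else "N"
    return enumerate_stop_gain_tcg(cds, gene=gene.name, flank5=f5, flank3=f3)


def candidate_genomic_position(site: CandidateStopSite, gene: GeneModel) -> int:
    """Genomic coordinate of the mutated C (the pyrimidine) of a candidate."""
    return gene.cds_to_genomic(site.cds_pos)


def candidate_cpg_position(site: CandidateStopSite, gene: GeneModel) -> int:
    """Genomic coordinate of the forward-strand C of the candidate's CpG.

    A coding-strand TCG on a plus-strand gene has its CpG C at the mutated
    base itself; template-strand sites and minus-strand genes are resolved
    through the CG dinucleotide the context guarantees.
    """
    gpos = gene.cds_to_genomic(site.cds_pos)
    plus_coding = gene.strand != "-"
    on_coding_c = site.strand == "coding"
    # the mutated base is a C on its own strand; the forward-strand C of the
    # CpG is at gpos when that strand is '+', else at the paired position
    mutated_on_plus = plus_coding == on_coding_c
    return gpos if mutated_on_plus else gpos - 1


def rank_hotspot_methylation(
    sites: list[CandidateStopSite],
    gene: GeneModel,
    methylation: MethylationTrack,
    background: np.ndarray,
) -> pd.DataFrame:
    """Annotate candidates with CpG methylation and test against background.

    ``background`` holds the methylation of all CpGs in the gene's coding
    exons; each candidate's methylation becomes the ``mu`` of a one-sample
    t-test of the background against it. Candidates absent from the
    methylation track are flagged missing.
    """
    rows = []
    for s in sites:
        cpos = candidate_cpg_position(s, gene)
        meth = methylation.lookup(gene.chrom, cpos)
        if meth is None:
            rows.append((s.gene, s.codon_index, cpos, np.nan, True, np.nan, np.nan))
            continue
        t, p = one_sample_ttest(background, meth)
        rows.append((s.gene, s.codon_index, cpos, meth, False, t, p))
    return pd.DataFrame(
        rows,
        columns=["gene", "codon_index", "cpg_pos", "methylation", "missing", "t", "p"],
    )


# ---------------------------------------------------------------------------
# Fisher exact tests


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


@dataclass
class AsymmetryResult:
    """Mutation strand counts 5' and 3' of a replication origin."""

    origin: str
    flank: int
    counts: pd.DataFrame  # index 5prime/3prime, columns plus/minus
    p_value: float


_CLASS_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def parse_context_class(context_class: str) -> tuple[str, str, str]:
    """Split e.g. "T[C>T]G" into (5'-flank + ref + 3'-flank, ref, alt)."""
    m = _CLASS_RE.match(context_class)
    if not m:
        raise ValueError(f"malformed context class: {context_class!r}")
    f5, ref, alt, f3 = m.groups()
    if ref not in "CT":
        raise ValueError("context class must be written on the pyrimidine strand")
    return f5 + ref + f3, ref, alt


def strand_asymmetry(
    mutations: pd.DataFrame,
    genome: dict[str, str],
    origin: tuple[str, int, str],
    flank: int = 25_000,
    context_class: str = "T[C>T]G",
) -> AsymmetryResult:
    """Test strand asymmetry of one mutation class across a replication origin.

    Each matching mutation within ``flank`` bp of the origin is assigned to
    (5' vs 3' of the origin) x (strand carrying the mutated pyrimidine: plus
    when the reference base is the pyrimidine itself, minus when the record
    shows the purine complement). Leading/lagging strand roles flip across an
    origin, so a replication-coupled mutation class flips strand there;
    significance is a two-sided Fisher exact test on the 2x2 table.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    chrom, opos, name = origin
    ctx, ref, alt = parse_context_class(context_class)
    seq = genome[chrom]
    sub = mutations[
        (mutations["chrom"] == chrom)
        & (mutations["pos"] >= opos - flank)
        & (mutations["pos"] < opos + flank)
    ]
    counts = np.zeros((2, 2), dtype=int)  # rows: 5'/3'; cols: plus/minus
    for row in sub.itertuples(index=False):
        p = row.pos
        if not 1 <= p < len(seq) - 1:
            continue
        fwd = seq[p - 1 : p + 2]
        side = 0 if p < opos else 1
        if row.ref == ref and row.alt == alt and fwd == ctx:
            counts[side, 0] += 1
        elif row.ref == revcomp(ref) and row.alt == revcomp(alt) and revcomp(fwd) == ctx:
            counts[side, 1] += 1
    if counts.sum() == 0:
        raise ValueError(f"no {context_class} mutations within {flank} bp of {name}")
    df = pd.DataFrame(counts, index=["5prime", "3prime"], columns=["plus", "minus"])
    return AsymmetryResult(origin=name, flank=flank, counts=df, p_value=fisher_exact(counts))


def hotspot_contingency(
    labels: pd.DataFrame,
    site_mutated: dict[str, bool],
    groups: tuple[str, str] = ("POLE-mutant", "MSS"),
) -> tuple[pd.DataFrame, float]:
    """Group x mutated 2x2 contingency for one hotspot site.

    ``labels`` is the classification frame (sample, label); ``site_mutated``
    maps sample id to whether it carries the hotspot mutation. Returns the
    table (rows = groups, columns mutant/wild-type) and the two-sided Fisher
    exact p-value.
    """
    counts = np.zeros((2, 2), dtype=int)
    for i, g in enumerate(groups):
        members = labels.loc[labels["label"] == g, "sample"]
        if members.empty:
            raise ValueError(f"group {g!r} has no samples")
        for s in members:
            counts[i, 0 if site_mutated.get(s, False) else 1] += 1
    df = pd.DataFrame(counts, index=list(groups), columns=["mutant", "wild-type"])
    return df, fisher_exact(counts)
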