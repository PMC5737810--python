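"""Cancer-sample classification: MSS / MSI / POLE-mutant, via 96-channel spectra.

A sample is called POLE-mutant when it carries a somatic mutation in the POLE
exonuclease domain (amino acids 268-471) AND its trinucleotide mutation
spectrum has Pearson correlation > 0.85 with mutational signature 10 (the
POLE-ultramutator signature, dominated by T[C>A]T and T[C>T]G). Samples
failing the POLE rule fall back to an external MSI-H annotation (MSI) or MSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: canonical 96-channel order: substitution class major, 5' then 3' flank lexicographic
CHANNELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _FLANKS for f3 in _FLANKS
)

POLE_EXONUCLEASE_DOMAIN = (268, 471)  # amino-acid range, inclusive
SIG10_CORRELATION_THRESHOLD = 0.85


def channel_of(ref: str, alt: str, context: str) -> str | None:
    """96-channel label for a substitution with its ±1 bp context.

    ``context`` is the 3-mer centred on the mutated base on the reference
    forward strand. Purine-reference mutations are folded onto the pyrimidine
    strand by reverse complement. Returns None when the context contains an
    ambiguous base.
    """
    if ref in "GA":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return label if label in _CHANNEL_SET else None


_CHANNEL_SET = frozenset(CHANNELS)


def trinucleotide_spectrum(mutations: pd.DataFrame, genome: dict[str, str]) -> pd.Series:
    """96-channel count spectrum of one sample's single-base substitutions.

    Mutations whose ±1 bp context contains N (or that sit at a contig edge)
    are excluded. Counts are conserved otherwise: the spectrum sums to the
    number of classifiable mutations.
    """
    counts = pd.Series(0, index=list(CHANNELS), dtype=int)
    for row in mutations.itertuples(index=False):
        seq = genome.get(row.chrom)
        if seq is None or not 1 <= row.pos < len(seq) - 1:
            continue
        ch = channel_of(row.ref, row.alt, seq[row.pos - 1 : row.pos + 2])
        if ch is not None:
            counts[ch] += 1
    return counts


def normalize_spectrum(spectrum: pd.Series) -> pd.Series:
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("empty spectrum cannot be normalized")
    return spectrum / total


def load_signature10() -> pd.Series:
    """Packaged signature-10 reference vector (synthetic stand-in).

    A constructed 96-channel vector with the defining features of signature
    10 — dominated by T[C>A]T and T[C>T]G — shipped as
    ``data/signature10_synthetic.tsv``; replaceable by any user-supplied
    96-channel vector in the same two-column format.
    """
    path = resources.files("mutscape.data").joinpath("signature10_synthetic.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    s = pd.Series(df["proportion"].to_numpy(), index=df["channel"].tolist())
    return s.reindex(list(CHANNELS)).fillna(0.0)


@dataclass
class SampleLabel:
    """Classification of one cancer sample."""

    sample_id: str
    msi_status: bool
    pole_exonuclease_mutation: bool
    sig10_correlation: float
    label: str  # MSS | MSI | POLE-mutant | unclassified
    reason: str = ""


def classify_pole(
    sample_id: str,
    protein_mutations: list[tuple[str, int]],
    spectrum: pd.Series,
    signature10: pd.Series | None = None,
    msi_status: bool = False,
) -> SampleLabel:
    """Label one sample as POLE-mutant / MSI / MSS.

    ``protein_mutations`` are (gene, amino-acid position) pairs from somatic
    coding annotation. POLE-mutant requires a POLE mutation inside the
    exonuclease domain and spectrum correlation with signature 10 strictly
    above the threshold; the MSI-H annotation takes effect only when the
    POLE criteria fail. A zero-variance spectrum leaves the correlation
    undefined and the sample unclassified.
    """
    if signature10 is None:
        signature10 = load_signature10()
    lo, hi = POLE_EXONUCLEASE_DOMAIN
    has_pole = any(g == "POLE" and lo <= aa <= hi for g, aa in protein_mutations)

    spec = spectrum.reindex(list(CHANNELS)).fillna(0.0).to_numpy(dtype=float)
    sig = signature10.reindex(list(CHANNELS)).fillna(0.0).to_numpy(dtype=float)
    if spec.std() == 0 or sig.std() == 0:
        return SampleLabel(
            sample_id, msi_status, has_pole, float("nan"), "unclassified",
            reason="zero-variance spectrum: correlation undefined",
        )
    spec = spec / spec.sum()
    sig = sig / sig.sum()
    r = float(np.corrcoef(spec, sig)[0, 1])

    if has_pole and r > SIG10_CORRELATION_THRESHOLD:
        label = "POLE-mutant"
    elif msi_status:
        label = "MSI"
    else:
        label = "MSS"
    return SampleLabel(sample_id, msi_status, has_pole, r, label)


def classify_cohort(
    mutations: pd.DataFrame,
    genome: dict[str, str],
    protein_mutations: pd.DataFrame,
    msi_annotations: dict[str, bool] | None = None,
    signature10: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every sample in a mutation table.

    ``protein_mutations`` has columns sample, gene, aa_pos. Returns one row
    per sample with the correlation and final label.
    """
    msi_annotations = msi_annotations or {}
    rows = []
    for sample, sub in mutations.groupby("sample", sort=True):
        spec = trinucleotide_spectrum(sub, genome)
        pm = protein_mutations[protein_mutations["sample"] == sample]
        lab = classify_pole(
            sample,
            list(zip(pm["gene"], pm["aa_pos"])),
            spec,
            signature10=signature10,
            msi_status=msi_annotations.get(sample, False),
        )
        rows.append(
            (lab.sample_id, lab.msi_status, lab.pole_exonuclease_mutation,
             lab.sig10_correlation, lab.label)
        )
    return pd.DataFrame(
        rows, columns=["sample", "msi_status", "pole_exonuclease_mutation",
                       "sig10_correlation", "label"]
    )
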