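"""Readers and writers for the genomic tracks the analysis consumes.

All coordinates are 0-based half-open internally. BED/bedGraph input is taken
as 0-based; VCF-like and tab-delimited mutation tables are 1-based and
converted on read. Tracks are held as pandas DataFrames inside light wrapper
classes that enforce the invariants the downstream analysis relies on:
methylation values live on the cytosine of a forward-strand CpG, replication
timing is averaged across cell types within fixed-size (default 1 Mb)
windows, and mutation records are single-base substitutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger("mutscape")

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + tuple(str(i) for i in range(1, 23))

BASES = ("A", "C", "G", "T")


class ParseError(ValueError):
    """A malformed line in an input file; carries the file and line number."""


class ValidationError(ValueError):
    """A well-formed record violating a track invariant."""


# ---------------------------------------------------------------------------
# genome


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an uppercase in-memory dict keyed by contig name."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every forward-strand CpG in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G")).astype(np.int64)


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationTrack:
    """Per-CpG methylation fractions, one record per CpG cytosine.

    ``records`` columns: chrom, pos (0-based C of the forward-strand CpG),
    meth (fraction in [0, 1]) and optional coverage. ``dropped`` counts input
    records that did not map onto a genomic CpG.
    """

    records: pd.DataFrame
    dropped: int = 0

    def __post_init__(self) -> None:
        m = self.records["meth"].to_numpy(dtype=float)
        if m.size and ((m < 0) | (m > 1)).any():
            raise ValidationError("methylation fraction outside [0, 1]")
        dup = self.records.duplicated(["chrom", "pos"])
        if dup.any():
            raise ValidationError("duplicate methylation positions")

    def lookup(self, chrom: str, pos: int) -> float | None:
        sel = self.records[(self.records["chrom"] == chrom) & (self.records["pos"] == pos)]
        return None if sel.empty else float(sel["meth"].iloc[0])


def read_methylation(
    path: str | Path,
    genome: dict[str, str],
    min_coverage: int = 0,
) -> MethylationTrack:
    """Read a bedGraph/BED methylation file and merge values onto CpG cytosines.

    Input rows cover single bases (start, start+1). A row on the C of a
    forward-strand CpG is kept as-is; a row on the G of a CpG is folded back
    onto the C at ``pos - 1`` and used only when no C-strand row exists there
    (the cytosine's own value takes precedence). Rows on neither base of a
    CpG are dropped and counted. No coverage filter is applied unless
    ``min_coverage`` > 0.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            try:
                chrom, start = parts[0], int(parts[1])
                # bedGraph puts the value in col 4; BED5+ carries it as the score
                if len(parts) >= 5 and _is_number(parts[4]) and not _is_number(parts[3]):
                    value = float(parts[4])
                else:
                    value = float(parts[3])
                coverage = int(float(parts[5])) if len(parts) >= 6 and _is_number(parts[5]) else -1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: methylation {value} outside [0, 1]"
                )
            rows.append((chrom, start, value, coverage))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "coverage"])
    if min_coverage > 0:
        df = df[(df["coverage"] < 0) | (df["coverage"] >= min_coverage)]

    kept, dropped = [], 0
    for chrom, sub in df.groupby("chrom", sort=False):
        seq = genome.get(chrom)
        if seq is None:
            dropped += len(sub)
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        base = np.array([seq[p] if 0 <= p < len(seq) else "N" for p in pos])
        nxt = np.array([seq[p + 1] if p + 1 < len(seq) else "N" for p in pos])
        prv = np.array([seq[p - 1] if p > 0 else "N" for p in pos])
        on_c = (base == "C") & (nxt == "G")
        on_g = (base == "G") & (prv == "C")
        dropped += int((~on_c & ~on_g).sum())
        c_rows = sub[on_c].assign(cpos=pos[on_c])
        g_rows = sub[on_g].assign(cpos=pos[on_g] - 1)
        have_c = set(c_rows["cpos"])
        g_fallback = g_rows[~g_rows["cpos"].isin(have_c)]
        if len(g_fallback):
            logger.info(
                "%s: %d CpGs covered only on the G strand; using G-strand values",
                chrom,
                len(g_fallback),
            )
        merged = pd.concat([c_rows, g_fallback]).drop_duplicates("cpos")
        kept.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": merged["cpos"].to_numpy(),
                    "meth": merged["meth"].to_numpy(),
                    "coverage": merged["coverage"].to_numpy(),
                }
            )
        )
    out = (
        pd.concat(kept, ignore_index=True)
        if kept
        else pd.DataFrame(columns=["chrom", "pos", "meth", "coverage"])
    )
    out = out.sort_values(["chrom", "pos"], ignore_index=True)
    if dropped:
        logger.info("read_methylation: dropped %d records not on a CpG", dropped)
    return MethylationTrack(out, dropped=dropped)


def write_methylation(track: MethylationTrack, path: str | Path) -> None:
    """Write as 4-column bedGraph (chrom, start, end, fraction)."""
    with open(path, "w") as fh:
        for r in track.records.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.meth:.6g}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# replication timing


@dataclass
class TimingTrack:
    """Replication timing per fixed-size genomic window (higher = earlier).

    ``windows`` columns: chrom, start, end, timing (NaN where no track had
    data). Windows are sorted and non-overlapping; trailing windows shorter
    than the nominal size are kept and flagged in ``short``.
    """

    windows: pd.DataFrame
    window_size: int = 1_000_000

    def __post_init__(self) -> None:
        w = self.windows
        for chrom, sub in w.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping timing windows on {chrom}")

    def lookup(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Timing of the window containing each position (NaN outside/missing)."""
        out = np.full(len(pos), np.nan)
        sub = self.windows[self.windows["chrom"] == chrom]
        if sub.empty:
            return out
        idx = np.asarray(pos) // self.window_size
        by_win = dict(zip(sub["start"] // self.window_size, sub["timing"]))
        for i, w in enumerate(idx):
            out[i] = by_win.get(w, np.nan)
        return out


def _parse_wig(path: str | Path):
    """Yield (chrom, start0, end0, value) intervals from a WIG or bedGraph file."""
    chrom, start, step, span, mode = None, 0, 1, 1, None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1  # WIG is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                mode = "variable"
                continue
            parts = line.split()
            if len(parts) >= 4:  # bedGraph line
                yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            elif mode == "fixed" and len(parts) == 1:
                yield chrom, start, start + span, float(parts[0])
                start += step
            elif mode == "variable" and len(parts) == 2:
                p = int(parts[0]) - 1
                yield chrom, p, p + span, float(parts[1])
            else:
                raise ParseError(f"{path}:{lineno}: unrecognised WIG/bedGraph line")


def read_timing(
    paths: list[str | Path] | str | Path,
    chrom_sizes: dict[str, int],
    window_size: int = 1_000_000,
) -> TimingTrack:
    """Average one or more replication-timing tracks into fixed windows.

    Each genome window receives the mean across tracks of each track's
    within-window mean (bp-weighted), so no single densely sampled cell type
    dominates. Windows with no data in any track carry NaN timing.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("at least one timing track required")
    per_track_means: list[dict[tuple[str, int], float]] = []
    for path in paths:
        sums: dict[tuple[str, int], float] = {}
        lens: dict[tuple[str, int], float] = {}
        any_value = False
        for chrom, start, end, value in _parse_wig(path):
            if not np.isfinite(value):
                continue
            any_value = True
            w0, w1 = start // window_size, (end - 1) // window_size
            for w in range(w0, w1 + 1):
                ov = min(end, (w + 1) * window_size) - max(start, w * window_size)
                key = (chrom, w)
                sums[key] = sums.get(key, 0.0) + value * ov
                lens[key] = lens.get(key, 0.0) + ov
        if not any_value:
            raise ValidationError(f"{path}: no usable timing values genome-wide")
        per_track_means.append({k: sums[k] / lens[k] for k in sums})

    rows = []
    for chrom, size in chrom_sizes.items():
        n_win = (size + window_size - 1) // window_size
        for w in range(n_win):
            vals = [m[(chrom, w)] for m in per_track_means if (chrom, w) in m]
            rows.append(
                (
                    chrom,
                    w * window_size,
                    min((w + 1) * window_size, size),
                    float(np.mean(vals)) if vals else np.nan,
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "timing"])
    n_missing = int(df["timing"].isna().sum())
    if n_missing:
        logger.info("read_timing: %d windows with no data flagged missing", n_missing)
    return TimingTrack(df, window_size=window_size)


def write_timing(track: TimingTrack, path: str | Path) -> None:
    """Write as bedGraph; windows with missing timing are omitted."""
    with open(path, "w") as fh:
        for r in track.windows.itertuples(index=False):
            if np.isfinite(r.timing):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.timing:.6g}\n")


# ---------------------------------------------------------------------------
# somatic mutations

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "filter"]


def read_mutations(path: str | Path, pass_only: bool = False) -> pd.DataFrame:
    """Read somatic single-base substitutions into a mutation table.

    Accepts a tab-delimited file with header columns chrom, pos, ref, alt,
    sample (and optional filter) or a VCF 4.x text file (sample id taken from
    an INFO SAMPLE= tag, else the file stem). Positions are 1-based on disk
    and converted to 0-based. Indels and multi-nucleotide variants are
    skipped with a warning; with ``pass_only`` records whose filter is not
    PASS are excluded.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        rows = _read_vcf(path)
    else:
        rows = _read_mutation_tsv(path, first)
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    n_raw = len(df)
    snv = df["ref"].isin(BASES) & df["alt"].isin(BASES) & (df["ref"] != df["alt"])
    if (~snv).any():
        logger.warning("read_mutations: skipped %d non-SNV records", int((~snv).sum()))
    df = df[snv]
    if pass_only:
        df = df[df["filter"] == "PASS"]
    logger.info("read_mutations: kept %d of %d records", len(df), n_raw)
    return df.reset_index(drop=True)


def _read_mutation_tsv(path: Path, first: str) -> list[tuple]:
    header = [h.strip().lower() for h in first.rstrip("\n").split("\t")]
    required = ["chrom", "pos", "ref", "alt", "sample"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    col = {name: header.index(name) for name in header}
    rows = []
    with open(path) as fh:
        next(fh)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rows.append(
                    (
                        parts[col["chrom"]],
                        int(parts[col["pos"]]) - 1,
                        parts[col["ref"]].upper(),
                        parts[col["alt"]].upper(),
                        parts[col["sample"]],
                        parts[col["filter"]] if "filter" in col else "PASS",
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def _read_vcf(path: Path) -> list[tuple]:
    rows = []
    default_sample = path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, _, ref, alts, _, filt = parts[:7]
            info = parts[7] if len(parts) > 7 else ""
            sample = default_sample
            for kv in info.split(";"):
                if kv.startswith("SAMPLE="):
                    sample = kv.split("=", 1)[1]
            for alt in alts.split(","):
                rows.append((chrom, int(pos) - 1, ref.upper(), alt.upper(), sample, filt))
    return rows


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    """Write the 1-based tab-delimited mutation table the reader accepts."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False, columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS exons on one strand.

    Exons are 0-based half-open genomic intervals in ascending genomic order;
    the concatenated CDS (reverse-complemented for minus-strand genes) must
    be a whole number of codons.
    """

    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        if any(b[0] < a[1] for a, b in zip(ex, ex[1:])):
            raise ValidationError(f"{self.name}: overlapping CDS exons")
        if self.cds_length % 3 != 0:
            raise ValidationError(f"{self.name}: CDS length {self.cds_length} not divisible by 3")
        self.exons = ex

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic coordinate of a 0-based position in the spliced CDS."""
        if not 0 <= cds_pos < self.cds_length:
            raise IndexError(cds_pos)
        if self.strand == "-":
            cds_pos = self.cds_length - 1 - cds_pos
        for s, e in self.exons:
            if cds_pos < e - s:
                return s + cds_pos
            cds_pos -= e - s
        raise AssertionError("unreachable")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd ignored; blocks = CDS exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start, name, strand = p[0], int(p[1]), p[3], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name=name, chrom=chrom, strand=strand, exons=exons))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.exons[0][0]
            end = g.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.name}\t0\t{g.strand}\t{start}\t{end}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{offsets}\n"
            )
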