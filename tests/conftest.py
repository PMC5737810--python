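import numpy as np
import pandas as pd
import pytest

from mutscape.io import MethylationTrack, TimingTrack


@pytest.fixture
def tiny_genome():
    """Two short contigs with hand-placed CpGs.

    chr1: CpGs with C at positions 2, 8, 14 (contexts ACG, TCG, TCG).
    chr2: CpG with C at position 4.
    """
    return {
        #       0123456789012345678
        "chr1": "AACGAATTCGAATTCGTTA",
        "chr2": "ATTACGTTTTA",
    }


@pytest.fixture
def tiny_methylation(tiny_genome):
    rec = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [2, 8, 14, 4],
            "meth": [0.1, 0.5, 0.9, 0.7],
            "coverage": [-1, -1, -1, -1],
        }
    )
    return MethylationTrack(rec)


@pytest.fixture
def tiny_timing(tiny_genome):
    win = pd.DataFrame(
        {
            "chrom": ["chr1", "chr2"],
            "start": [0, 0],
            "end": [len(tiny_genome["chr1"]), len(tiny_genome["chr2"])],
            "timing": [50.0, 30.0],
        }
    )
    return TimingTrack(win, window_size=1_000_000)


def mutation_frame(rows):
    """rows: (chrom, pos, ref, alt, sample[, filter])."""
    out = []
    for r in rows:
        r = tuple(r) + ("PASS",) * (6 - len(r))
        out.append(r)
    return pd.DataFrame(out, columns=["chrom", "pos", "ref", "alt", "sample", "filter"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
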