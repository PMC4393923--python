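import numpy as np
import pytest

from strandcheck.annotation import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_transcript(acc, chrom, strand, exons, gene=None):
    starts = tuple(s for s, _ in exons)
    ends = tuple(e for _, e in exons)
    return TranscriptModel(
        accession=acc,
        gene=gene or acc,
        chrom=chrom,
        strand=strand,
        tx_start=starts[0],
        tx_end=ends[-1],
        exon_starts=starts,
        exon_ends=ends,
    )


def random_small_annotation(rng, n_transcripts=20, span=2000):
    """Random compact annotation used for oracle-equivalence checks."""
    models = []
    for i in range(n_transcripts):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        pos = int(rng.integers(0, span // 2))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(10, 120))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(5, 80))
        models.append(make_transcript(f"T{i:03d}", "chr1", strand, exons))
    return models
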