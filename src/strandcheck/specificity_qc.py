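"""Library-performance and strand-specificity QC.

Covers four diagnostics: per-position base-quality profiles from FASTQ,
gene-body coverage along length-normalized transcripts, mappable rates
under sense / antisense / strand-blind alignment modes (including the
sense-to-antisense mappable-rate ratio, which is near 1 for a
non-strand-specific library and far above 1 for a strand-specific one),
and per-transcript sense/antisense read-count ratios for nonoverlapped
transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from strandcheck.annotation import TranscriptModel
from strandcheck.quantification import ReadAlignment

N_COVERAGE_BINS = 100
_MAX_PHRED = 94


def quality_profile(fastq_path, phred_offset: int = 33) -> pd.DataFrame:
    """Per-position quality summary of a FASTQ file.

    Returns a DataFrame indexed by 1-based read position with columns
    ``count``, ``mean``, ``q1``, ``median``, ``q3``.  Variable-length
    reads are supported; position counts then differ.  An empty file
    yields an empty profile.
    """
    # histogram[pos, q] avoids holding every quality in memory
    hists: list[np.ndarray] = []
    with open(fastq_path) as fh:
        for idx, (_title, _seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(qual) > len(hists):
                for _ in range(len(qual) - len(hists)):
                    hists.append(np.zeros(_MAX_PHRED, dtype=np.int64))
            for pos, ch in enumerate(qual):
                q = ord(ch) - phred_offset
                if q < 0 or q >= _MAX_PHRED:
                    raise ValueError(
                        f"record {idx}: quality character {ch!r} outside Phred+{phred_offset} range"
                    )
                hists[pos][q] += 1
    rows = []
    qs = np.arange(_MAX_PHRED)
    for pos, hist in enumerate(hists, start=1):
        n = int(hist.sum())
        cum = np.cumsum(hist)
        def _quantile(p: float) -> float:
            # nearest-rank quantile on the histogram
            k = max(1, math.ceil(p * n))
            return float(qs[np.searchsorted(cum, k)])
        rows.append(
            {
                "position": pos,
                "count": n,
                "mean": float((hist * qs).sum() / n),
                "q1": _quantile(0.25),
                "median": _quantile(0.5),
                "q3": _quantile(0.75),
            }
        )
    df = pd.DataFrame(rows, columns=["position", "count", "mean", "q1", "median", "q3"])
    return df.set_index("position") if len(df) else df


def coverage_profile(
    alignments: Iterable[ReadAlignment],
    models: Sequence[TranscriptModel],
) -> np.ndarray:
    """Gene-body coverage over 100 length-normalized positional bins.

    Each aligned base of each transcript-space alignment falls into bin
    floor(100 * pos / transcript_length), counted 5'->3' in transcript
    orientation; the summed histogram is normalized by the total number
    of mapped bases (across all alignments), so the bins sum to the
    fraction of mapped bases landing inside annotated transcripts.
    """
    lengths = {m.accession: m.exonic_length for m in models}
    bins = np.zeros(N_COVERAGE_BINS)
    total_bases = 0
    for aln in alignments:
        total_bases += aln.aligned_length
        length = lengths.get(aln.reference)
        if length is None:
            continue
        pos = np.arange(aln.start, aln.start + aln.aligned_length)
        pos = pos[(pos >= 0) & (pos < length)]
        idx = (N_COVERAGE_BINS * pos) // length
        np.add.at(bins, idx, 1)
    if total_bases > 0:
        bins /= total_bases
    return bins


@dataclass
class MappableRates:
    rate_any: float
    rate_sense: float
    rate_antisense: float
    sense_to_antisense_ratio: float  # inf when no antisense reads
    antisense_fraction: float  # antisense reads / all mappable reads
    infinite_ratio: bool = False


def mappable_rates(
    total_reads: int,
    mapped_sense: int,
    mapped_antisense: int,
    mapped_any: int,
) -> MappableRates:
    """Mappable-rate summary from read tallies.

    Rates are fractions of all sequenced reads; the ratio divides the
    sense mappable rate by the antisense one (about 1 for NSS libraries,
    large for SS ones); ``antisense_fraction`` is the share of mappable
    reads located on the antisense strand.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    for name, v in (
        ("mapped_sense", mapped_sense),
        ("mapped_antisense", mapped_antisense),
        ("mapped_any", mapped_any),
    ):
        if v < 0 or v > total_reads:
            raise ValueError(f"{name}={v} outside [0, total_reads]")
    rate_sense = mapped_sense / total_reads
    rate_antisense = mapped_antisense / total_reads
    infinite = mapped_antisense == 0
    return MappableRates(
        rate_any=mapped_any / total_reads,
        rate_sense=rate_sense,
        rate_antisense=rate_antisense,
        sense_to_antisense_ratio=float("inf") if infinite else rate_sense / rate_antisense,
        antisense_fraction=(mapped_antisense / mapped_any) if mapped_any else 0.0,
        infinite_ratio=infinite,
    )


@dataclass
class StrandRatioRecord:
    accession: str
    sense_count: float
    antisense_count: float
    log2_ratio: float  # log2(sense / antisense)


@dataclass
class StrandRatioSummary:
    records: list[StrandRatioRecord]
    fraction_below: float  # fraction of records with log2_ratio <= threshold
    antisense_excess: list[str]  # accessions with more antisense than sense reads


def strand_ratio_table(
    sense_counts: Mapping[str, float],
    antisense_counts: Mapping[str, float],
    min_count: float = 10,
    low_ratio_threshold: float = 0.0,
) -> StrandRatioSummary:
    """Per-transcript sense/antisense read-count ratios.

    Only transcripts with at least ``min_count`` reads on both strands
    are reported (guards against wild ratios from tiny counts).  The
    summary reports the fraction of transcripts with log2 ratio at or
    below ``low_ratio_threshold`` and the list with antisense excess
    (log2 ratio < 0) — candidates for hidden antisense transcription.
    """
    records: list[StrandRatioRecord] = []
    for acc in sorted(set(sense_counts) | set(antisense_counts)):
        s = sense_counts.get(acc, 0.0)
        a = antisense_counts.get(acc, 0.0)
        if s < min_count or a < min_count:
            continue
        records.append(StrandRatioRecord(acc, s, a, math.log2(s / a)))
    n = len(records)
    below = sum(1 for r in records if r.log2_ratio <= low_ratio_threshold)
    return StrandRatioSummary(
        records=records,
        fraction_below=below / n if n else 0.0,
        antisense_excess=[r.accession for r in records if r.log2_ratio < 0],
    )
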