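"""Overlap-stratified SS/NSS expression concordance with a resampling control.

Transcripts are partitioned by their maximum antisense-overlap percentage;
within each bin the Pearson correlation of log2 RPKM between the
strand-specific and non-strand-specific libraries is computed.  Because
bins differ in size, a "mimic" control resamples equally sized sets from
the nonoverlapped (O=0) pool: if the correlation decline across overlap
bins were a set-size artefact, the mimic curve would show it too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from strandcheck.annotation import OverlapPair, TranscriptModel, max_overlap_percentages


@dataclass
class OverlapBinSet:
    """One overlap-percentage stratum: label, (lower, upper] bounds, members."""

    label: str
    lower: float
    upper: float
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CorrelationResult:
    r: float  # NaN when undefined
    n: int
    ok: bool


def bin_by_overlap(
    pairs: Sequence[OverlapPair],
    models: Sequence[TranscriptModel],
    edges: Sequence[float],
) -> list[OverlapBinSet]:
    """Partition transcripts into overlap-percentage bins.

    Each overlapped transcript goes into exactly one (lower, upper] bin by
    its maximum overlap percentage over all its antisense partners; the
    nonoverlapped transcripts form the O=0 set (returned first, with
    lower == upper == 0).
    """
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    edges = list(edges)
    if edges[0] != 0:
        raise ValueError("bin edges must start at 0")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")

    max_pct = max_overlap_percentages(pairs)
    bins = [OverlapBinSet(label="O=0", lower=0.0, upper=0.0, members=[])]
    for lo, hi in zip(edges, edges[1:]):
        bins.append(OverlapBinSet(label=f"({lo:g},{hi:g}]", lower=lo, upper=hi, members=[]))

    for m in models:
        pct = max_pct.get(m.accession)
        if pct is None:
            bins[0].members.append(m.accession)
            continue
        placed = False
        for b in bins[1:]:
            if b.lower < pct <= b.upper:
                b.members.append(m.accession)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"{m.accession}: overlap {pct:.4g}% falls outside the bin edges"
            )
    return bins


def correlation_in_set(
    rpkm_ss: Mapping[str, float],
    rpkm_nss: Mapping[str, float],
    members: Sequence[str],
    min_count: float = 0.0001,
    counts_ss: Mapping[str, float] | None = None,
    counts_nss: Mapping[str, float] | None = None,
) -> CorrelationResult:
    """Pearson correlation of log2 expression between the two libraries.

    Members with read count (or, when counts are not supplied, RPKM) not
    larger than ``min_count`` in either library are excluded before the
    log transform; with fewer than 3 members left the result is flagged
    with r undefined.
    """
    fs = counts_ss if counts_ss is not None else rpkm_ss
    fn = counts_nss if counts_nss is not None else rpkm_nss
    xs, ys = [], []
    for acc in members:
        if fs.get(acc, 0.0) > min_count and fn.get(acc, 0.0) > min_count:
            xs.append(np.log2(rpkm_ss[acc]))
            ys.append(np.log2(rpkm_nss[acc]))
    n = len(xs)
    if n < 3:
        return CorrelationResult(r=float("nan"), n=n, ok=False)
    r = stats.pearsonr(xs, ys).statistic
    return CorrelationResult(r=float(r), n=n, ok=True)


def mimic_resample(
    o_zero_members: Sequence[str],
    bin_sizes: Sequence[int],
    rpkm_ss: Mapping[str, float],
    rpkm_nss: Mapping[str, float],
    reps: int = 100,
    seed: int | None = None,
    min_count: float = 0.0001,
    counts_ss: Mapping[str, float] | None = None,
    counts_nss: Mapping[str, float] | None = None,
) -> list[tuple[int, float, float]]:
    """Size-matched resampling control from the nonoverlapped pool.

    For each requested bin size, draws that many distinct transcripts from
    the O=0 set, computes the in-set correlation, and repeats ``reps``
    times.  Returns (bin_size, mean r, sd of r) per bin size; the draws
    are seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(o_zero_members, dtype=object)
    out: list[tuple[int, float, float]] = []
    for size in bin_sizes:
        if size > len(pool):
            raise ValueError(
                f"bin size {size} exceeds O=0 pool of {len(pool)} transcripts"
            )
        rs = []
        for _ in range(reps):
            draw = rng.choice(pool, size=size, replace=False)
            res = correlation_in_set(
                rpkm_ss, rpkm_nss, list(draw), min_count, counts_ss, counts_nss
            )
            if res.ok:
                rs.append(res.r)
        if not rs:
            out.append((size, float("nan"), float("nan")))
        else:
            out.append((size, float(np.mean(rs)), float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0))
    return out
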