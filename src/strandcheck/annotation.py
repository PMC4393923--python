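"""Gene-model annotation: refFlat parsing and antisense-overlap detection.

Transcript models follow the UCSC refFlat convention: 0-based half-open
genomic coordinates, tab-separated 11-column records with comma-terminated
exon coordinate lists.  Two transcripts are "mutually overlapped at the
antisense strand" when they sit on the same chromosome, on opposite
strands, and their exons share at least one genomic base.  The per-side
overlap percentage relates the shared exonic bases to each transcript's
exonic (mRNA) length, so the same pair generally has two different
overlap values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


class RefFlatParseError(ValueError):
    """Raised for a malformed refFlat record; the message names the line."""


@dataclass(frozen=True)
class TranscriptModel:
    """One refFlat record: a transcript and its exon structure.

    Coordinates are 0-based half-open.  ``exon_starts``/``exon_ends`` are
    parallel, sorted ascending and pairwise disjoint.
    """

    accession: str
    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    cds_start: int = -1
    cds_end: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(
                f"{self.accession}: exon start/end lists must be parallel and non-empty"
            )
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if e <= s:
                raise ValueError(f"{self.accession}: empty or inverted exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.accession}: exons not sorted/disjoint")
            prev_end = e
        if self.tx_start != self.exon_starts[0] or self.tx_end != self.exon_ends[-1]:
            raise ValueError(
                f"{self.accession}: tx bounds do not match first/last exon"
            )

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))


@dataclass(frozen=True)
class OverlapPair:
    """Two antisense-overlapped transcripts and their overlap percentages.

    ``overlap_pct_a`` is 100 * shared_exonic_bases / exonic_length(a), and
    likewise for b, so overlap_pct_a * len_a == overlap_pct_b * len_b.
    """

    acc_a: str
    acc_b: str
    shared_exonic_bases: int
    overlap_pct_a: float
    overlap_pct_b: float


def _parse_exon_list(text: str, lineno: int, what: str) -> tuple[int, ...]:
    items = [t for t in text.strip().split(",") if t.strip() != ""]
    try:
        return tuple(int(t) for t in items)
    except ValueError as exc:
        raise RefFlatParseError(
            f"line {lineno}: non-integer {what} coordinate in {text!r}"
        ) from exc


def parse_refflat(path) -> list[TranscriptModel]:
    """Parse a UCSC refFlat table into transcript models.

    Expects the 11-column dialect (geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds); trailing
    commas in the exon lists are tolerated.  Raises
    :class:`RefFlatParseError` naming the offending line for malformed
    records.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise RefFlatParseError(
                    f"line {lineno}: expected 11 tab-separated fields, got {len(fields)}"
                )
            gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
                cds_start, cds_end = int(fields[6]), int(fields[7])
                exon_count = int(fields[8])
            except ValueError as exc:
                raise RefFlatParseError(
                    f"line {lineno}: non-integer coordinate field"
                ) from exc
            starts = _parse_exon_list(fields[9], lineno, "exonStarts")
            ends = _parse_exon_list(fields[10], lineno, "exonEnds")
            if len(starts) != exon_count or len(ends) != exon_count:
                raise RefFlatParseError(
                    f"line {lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            try:
                model = TranscriptModel(
                    accession=name,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exon_starts=starts,
                    exon_ends=ends,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            except ValueError as exc:
                raise RefFlatParseError(f"line {lineno}: {exc}") from exc
            models.append(model)
    return models


def write_refflat(models: Iterable[TranscriptModel], path) -> None:
    """Write models as an 11-column refFlat table (comma-terminated exon lists)."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            cds_start = m.cds_start if m.cds_start >= 0 else m.tx_start
            cds_end = m.cds_end if m.cds_end >= 0 else m.tx_start
            fh.write(
                "\t".join(
                    [
                        m.gene,
                        m.accession,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(cds_start),
                        str(cds_end),
                        str(len(m.exon_starts)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


def filter_single_locus(models: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Keep only transcripts whose accession maps to a single genomic locus.

    A transcript accession appearing in more than one record is taken to
    have multiple genomic loci, and all of its records are removed.  Input
    order is preserved.
    """
    counts: dict[str, int] = {}
    for m in models:
        counts[m.accession] = counts.get(m.accession, 0) + 1
    return [m for m in models if counts[m.accession] == 1]


def exonic_length(model: TranscriptModel) -> int:
    """Total exonic (mRNA) length of a transcript in bases."""
    return model.exonic_length


def shared_exonic_bases(a: TranscriptModel, b: TranscriptModel) -> int:
    """Count genomic bases exonic in both transcripts (two-pointer sweep)."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        s = max(ea[i][0], eb[j][0])
        e = min(ea[i][1], eb[j][1])
        if e > s:
            total += e - s
        if ea[i][1] <= eb[j][1]:
            i += 1
        else:
            j += 1
    return total


def find_antisense_overlaps(
    models: Sequence[TranscriptModel],
) -> list[OverlapPair]:
    """Detect mutually antisense-overlapped transcript pairs.

    Emits one :class:`OverlapPair` per unordered pair of transcripts on
    the same chromosome and opposite strands whose exons share at least
    one genomic base.  A transcript may participate in several pairs.
    Span-only (intron-level) antisense overlap is not reported: the read
    allocation ambiguity the analysis cares about only arises at shared
    exonic bases.
    """
    pairs: list[OverlapPair] = []
    by_chrom: dict[str, dict[str, list[TranscriptModel]]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, {"+": [], "-": []})[m.strand].append(m)
    for chrom, strands in by_chrom.items():
        plus = sorted(strands["+"], key=lambda m: m.tx_start)
        minus = sorted(strands["-"], key=lambda m: m.tx_start)
        j_lo = 0
        for a in plus:
            # advance past minus transcripts that end before a starts
            while j_lo < len(minus) and minus[j_lo].tx_end <= a.tx_start:
                j_lo += 1
            for b in minus[j_lo:]:
                if b.tx_start >= a.tx_end:
                    break
                shared = shared_exonic_bases(a, b)
                if shared > 0:
                    pairs.append(
                        OverlapPair(
                            acc_a=a.accession,
                            acc_b=b.accession,
                            shared_exonic_bases=shared,
                            overlap_pct_a=100.0 * shared / a.exonic_length,
                            overlap_pct_b=100.0 * shared / b.exonic_length,
                        )
                    )
    return pairs


def max_overlap_percentages(pairs: Iterable[OverlapPair]) -> dict[str, float]:
    """Per-transcript maximum overlap percentage across all its pairs.

    This is the per-transcript "overlap value" used for binning: a
    transcript overlapped by several partners is characterised by its
    largest overlap fraction.
    """
    best: dict[str, float] = {}
    for p in pairs:
        for acc, pct in ((p.acc_a, p.overlap_pct_a), (p.acc_b, p.overlap_pct_b)):
            if pct > best.get(acc, 0.0):
                best[acc] = pct
    return best


def write_overlap_report(pairs: Iterable[OverlapPair], path) -> None:
    """Write the overlap pairs as a TSV report."""
    with open(path, "w") as fh:
        fh.write("acc_a\tacc_b\tshared_exonic_bases\toverlap_pct_a\toverlap_pct_b\n")
        for p in pairs:
            fh.write(
                f"{p.acc_a}\t{p.acc_b}\t{p.shared_exonic_bases}\t"
                f"{p.overlap_pct_a:.6g}\t{p.overlap_pct_b:.6g}\n"
            )


def read_overlap_report(path) -> list[OverlapPair]:
    pairs: list[OverlapPair] = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pairs.append(
                OverlapPair(f[0], f[1], int(f[2]), float(f[3]), float(f[4]))
            )
    return pairs
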