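"""Strand-aware read counting with equal-split allocation, and RPKM.

Reads are counted in either transcript space (the alignment reference is
a transcript accession, the default, mirroring alignment of reads
directly against the transcript set) or genome space (the reference is a
chromosome and reads are projected onto exons).  A read aligning to k
transcripts under the chosen strand mode contributes weight 1/k to each
("equal-split" allocation), which is exactly the convention that biases
non-strand-specific quantification of antisense-overlapped genes toward
equal abundance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pysam

from strandcheck.annotation import TranscriptModel

logger = logging.getLogger(__name__)


class ReadAlignment(NamedTuple):
    """One alignment of a read against a transcript or chromosome.

    ``ref_strand`` is the orientation of the alignment relative to the
    reference ('+' = forward).  ``blocks`` carries gapped genomic blocks
    for genome-space alignments; transcript-space alignments leave it None.
    """

    read_id: str
    reference: str
    ref_strand: str
    start: int
    aligned_length: int
    mismatches: int = 0
    blocks: tuple[tuple[int, int], ...] | None = None


@dataclass(frozen=True)
class ExpressionRecord:
    accession: str
    read_count: float
    exonic_length: int
    rpkm: float


@dataclass
class CountResult:
    """Weighted per-transcript counts plus library bookkeeping."""

    counts: dict[str, float]
    library_mapped_reads: int
    skipped_unknown_reference: int = 0


def _alignment_blocks_overlap_exons(
    blocks: Sequence[tuple[int, int]], model: TranscriptModel
) -> bool:
    i = j = 0
    exons = model.exons
    while i < len(blocks) and j < len(exons):
        s = max(blocks[i][0], exons[j][0])
        e = min(blocks[i][1], exons[j][1])
        if e > s:
            return True
        if blocks[i][1] <= exons[j][1]:
            i += 1
        else:
            j += 1
    return False


def count_reads(
    alignments: Iterable[ReadAlignment],
    models: Sequence[TranscriptModel],
    strand_mode: str = "both",
    max_mismatches: int = 3,
    space: str = "transcript",
) -> CountResult:
    """Count reads per transcript with equal-split allocation.

    Parameters
    ----------
    alignments : iterable of ReadAlignment
        All alignments, including secondary ones (a read may appear with
        several alignments; they are grouped by ``read_id``).
    models : sequence of TranscriptModel
        The transcript set being quantified.
    strand_mode : {"sense_only", "antisense_only", "both"}
        Which alignment orientations count.  In transcript space a '+'
        alignment is sense; in genome space sense means the alignment
        strand equals the transcript strand.  ``sense_only`` corresponds
        to strand-specific counting, ``both`` to strand-blind counting.
    max_mismatches : int
        Alignments with more mismatches are discarded (mirrors an
        aligner-side mismatch cap of 3).
    space : {"transcript", "genome"}
        Coordinate space of the alignment references.

    Returns
    -------
    CountResult
        Weighted counts (each surviving read contributes total weight 1,
        split 1/k over the k transcripts it is assigned to), the number
        of distinct reads assigned, and the number of alignments skipped
        because their reference was unknown.
    """
    if strand_mode not in ("sense_only", "antisense_only", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if space not in ("transcript", "genome"):
        raise ValueError(f"unknown space {space!r}")

    by_accession = {m.accession: m for m in models}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    if space == "genome":
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)

    # read_id -> set of assigned accessions
    assigned: dict[str, set[str]] = {}
    skipped_unknown = 0

    for aln in alignments:
        if aln.mismatches > max_mismatches:
            continue
        if space == "transcript":
            model = by_accession.get(aln.reference)
            if model is None:
                skipped_unknown += 1
                continue
            is_sense = aln.ref_strand == "+"
            if strand_mode == "sense_only" and not is_sense:
                continue
            if strand_mode == "antisense_only" and is_sense:
                continue
            assigned.setdefault(aln.read_id, set()).add(model.accession)
        else:
            candidates = by_chrom.get(aln.reference)
            if candidates is None:
                skipped_unknown += 1
                continue
            blocks = aln.blocks or (
                (aln.start, aln.start + aln.aligned_length),
            )
            for model in candidates:
                if blocks[-1][1] <= model.tx_start or blocks[0][0] >= model.tx_end:
                    continue
                if not _alignment_blocks_overlap_exons(blocks, model):
                    continue
                is_sense = aln.ref_strand == model.strand
                if strand_mode == "sense_only" and not is_sense:
                    continue
                if strand_mode == "antisense_only" and is_sense:
                    continue
                assigned.setdefault(aln.read_id, set()).add(model.accession)

    if skipped_unknown:
        logger.warning(
            "%d alignments referenced unknown %s(s) and were skipped",
            skipped_unknown,
            "transcript" if space == "transcript" else "chromosome",
        )

    counts: dict[str, float] = {m.accession: 0.0 for m in models}
    for accs in assigned.values():
        w = 1.0 / len(accs)
        for acc in accs:
            counts[acc] += w

    return CountResult(
        counts=counts,
        library_mapped_reads=len(assigned),
        skipped_unknown_reference=skipped_unknown,
    )


def compute_rpkm(
    counts: Mapping[str, float],
    lengths: Mapping[str, int],
    library_mapped_reads: int,
) -> list[ExpressionRecord]:
    """Reads-per-kilobase-per-million-mapped-reads for every transcript.

    Records are emitted for every accession in ``lengths``; transcripts
    with zero counts get rpkm 0.
    """
    if library_mapped_reads <= 0:
        raise ValueError("library_mapped_reads must be positive")
    records: list[ExpressionRecord] = []
    millions = library_mapped_reads / 1e6
    for acc, length in lengths.items():
        if length <= 0:
            raise ValueError(f"{acc}: non-positive exonic length")
        c = counts.get(acc, 0.0)
        records.append(
            ExpressionRecord(
                accession=acc,
                read_count=c,
                exonic_length=length,
                rpkm=c / (length / 1000.0) / millions,
            )
        )
    return records


_CIGAR_ALIGNED_OPS = {0, 7, 8}  # M, =, X consume both query and reference


def sam_to_alignments(path, space: str = "transcript") -> list[ReadAlignment]:
    """Read a SAM file into :class:`ReadAlignment` records.

    Unmapped records are skipped; secondary alignments are retained, as
    equal-split allocation needs every alignment of a read.  Mismatch
    counts come from the NM tag (or a substitution count from MD when NM
    is absent); with neither tag, mismatches default to 0 with a warning.
    """
    alignments: list[ReadAlignment] = []
    warned_no_tag = False
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for idx, rec in enumerate(sam):
            try:
                if rec.is_unmapped:
                    continue
                strand = "-" if rec.is_reverse else "+"
                aligned = sum(
                    length
                    for op, length in (rec.cigartuples or [])
                    if op in _CIGAR_ALIGNED_OPS
                )
                if rec.has_tag("NM"):
                    mism = int(rec.get_tag("NM"))
                elif rec.has_tag("MD"):
                    mism = _md_substitutions(str(rec.get_tag("MD")))
                else:
                    if not warned_no_tag:
                        warnings.warn(
                            "SAM records lack NM/MD tags; mismatches set to 0"
                        )
                        warned_no_tag = True
                    mism = 0
                blocks = None
                if space == "genome":
                    blocks = tuple(rec.get_blocks())
                alignments.append(
                    ReadAlignment(
                        read_id=rec.query_name,
                        reference=rec.reference_name,
                        ref_strand=strand,
                        start=rec.reference_start,
                        aligned_length=aligned,
                        mismatches=mism,
                        blocks=blocks,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unparseable SAM record at index {idx}: {exc}")
    return alignments


def _md_substitutions(md: str) -> int:
    """Count substitution positions in an MD tag (deleted bases excluded)."""
    count = 0
    i = 0
    while i < len(md):
        ch = md[i]
        if ch == "^":  # deletion run: skip the deleted reference bases
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        elif ch.isalpha():
            count += 1
            i += 1
        else:
            i += 1
    return count


def write_expression_tsv(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tlength\tcount\trpkm\n")
        for r in records:
            fh.write(f"{r.accession}\t{r.exonic_length}\t{r.read_count:.6g}\t{r.rpkm:.6g}\n")


def read_expression_tsv(path) -> list[ExpressionRecord]:
    records: list[ExpressionRecord] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                ExpressionRecord(f[0], float(f[2]), int(f[1]), float(f[3]))
            )
    return records
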