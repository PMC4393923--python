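"""Novel antisense gene discovery from assembled-contig genome alignments.

Assembled transcript contigs ("isotigs") aligned back to the genome (blat
PSL format) are filtered by alignment identity (>= 95% by default, best
locus per isotig), multi-exon alignments must satisfy the canonical GT-AG
splice rule on their transcribed strand, alignments are kept only when
they exonically overlap a known gene on the opposite strand (sense
matches to known exons are fragments of known genes, not novel antisense
transcripts), and surviving transcripts are grouped into novel antisense
gene (NAG) loci by transitive exon overlap.  Finally, RPKM fold changes
between NAG pairs sharing a host gene (FCsame) and pairs with different
hosts (FCdiff) are compared with a one-sided t-test: same-host NAG pairs
having systematically smaller fold changes suggests they are fragments of
a single gene split by assembly gaps.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from strandcheck.annotation import (
    TranscriptModel,
    find_antisense_overlaps,
    shared_exonic_bases,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsotigAlignment:
    """One contig-to-genome alignment with block structure (PSL semantics).

    ``blocks`` are genomic plus-strand coordinates, 0-based half-open,
    sorted and disjoint; ``strand`` is the query (transcribed) strand.
    Identity follows the standard PSL mRNA convention:
    matches / (matches + mismatches + query-insert count).
    """

    isotig_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    matches: int
    mismatches: int
    q_num_insert: int
    query_size: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev = None
        for s, e in self.blocks:
            if e <= s or (prev is not None and s < prev):
                raise ValueError(f"{self.isotig_id}: blocks not sorted/disjoint")
            prev = e

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches + self.q_num_insert
        return self.matches / denom if denom else 0.0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def to_model(self, accession: str | None = None, gene: str = "") -> TranscriptModel:
        return TranscriptModel(
            accession=accession or self.isotig_id,
            gene=gene or (accession or self.isotig_id),
            chrom=self.chrom,
            strand=self.strand,
            tx_start=self.start,
            tx_end=self.end,
            exon_starts=tuple(s for s, _ in self.blocks),
            exon_ends=tuple(e for _, e in self.blocks),
        )


def parse_psl(path) -> list[IsotigAlignment]:
    """Parse a 21-column blat PSL file (psLayout headers tolerated)."""
    out: list[IsotigAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            first = line.split("\t", 1)[0]
            if not first or not first[0].isdigit():
                continue  # psLayout header / separator lines
            f = line.split("\t")
            if len(f) < 21:
                raise ValueError(f"line {lineno}: expected 21 PSL fields, got {len(f)}")
            matches, mismatches = int(f[0]), int(f[1])
            q_num_insert = int(f[4])
            strand = f[8]
            q_name, q_size = f[9], int(f[10])
            t_name = f[13]
            block_sizes = [int(x) for x in f[18].rstrip(",").split(",") if x]
            t_starts = [int(x) for x in f[20].rstrip(",").split(",") if x]
            if len(block_sizes) != len(t_starts):
                raise ValueError(f"line {lineno}: blockSizes/tStarts length mismatch")
            blocks = tuple((s, s + sz) for s, sz in zip(t_starts, block_sizes))
            out.append(
                IsotigAlignment(
                    isotig_id=q_name,
                    chrom=t_name,
                    strand=strand[-1],  # un-translated blat: single query strand char
                    blocks=blocks,
                    matches=matches,
                    mismatches=mismatches,
                    q_num_insert=q_num_insert,
                    query_size=q_size,
                )
            )
    return out


def write_psl(alignments: Iterable[IsotigAlignment], path) -> None:
    """Write alignments as 21-column PSL (headerless)."""
    with open(path, "w") as fh:
        for a in alignments:
            sizes = ",".join(str(e - s) for s, e in a.blocks) + ","
            t_starts = ",".join(str(s) for s, _ in a.blocks) + ","
            aligned = sum(e - s for s, e in a.blocks)
            q_starts = []
            pos = 0
            for s, e in a.blocks:
                q_starts.append(pos)
                pos += e - s
            fields = [
                a.matches, a.mismatches, 0, 0,  # matches misMatches repMatches nCount
                a.q_num_insert, 0, len(a.blocks) - 1,  # qNumInsert qBaseInsert tNumInsert
                a.end - a.start - aligned,  # tBaseInsert
                a.strand, a.isotig_id, a.query_size, 0, aligned,
                a.chrom, 0, a.start, a.end, len(a.blocks),
                sizes, ",".join(str(q) for q in q_starts) + ",", t_starts,
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def filter_alignments(
    alignments: Sequence[IsotigAlignment], min_identity: float = 0.95
) -> list[IsotigAlignment]:
    """Identity filter plus best-locus selection per isotig.

    Alignments below ``min_identity`` (boundary inclusive: "no less
    than") are dropped.  An isotig with several passing loci keeps only
    the highest-identity one; an exact identity tie makes the isotig
    ambiguous and it is dropped entirely.
    """
    passing: dict[str, list[IsotigAlignment]] = {}
    for a in alignments:
        if a.identity >= min_identity:
            passing.setdefault(a.isotig_id, []).append(a)
    out: list[IsotigAlignment] = []
    for isotig, alns in passing.items():
        if len(alns) == 1:
            out.append(alns[0])
            continue
        alns = sorted(alns, key=lambda a: a.identity, reverse=True)
        if alns[0].identity == alns[1].identity:
            logger.warning("isotig %s dropped: ambiguous best locus", isotig)
            continue
        out.append(alns[0])
    return out


def check_gt_ag(alignment: IsotigAlignment, genome: Mapping[str, str]) -> bool:
    """Canonical splice-site check for a multi-exon alignment.

    True iff every intron (gap between consecutive blocks) starts with GT
    and ends with AG on the transcribed strand.  On the minus strand the
    genomic plus-strand intron must therefore read CT...AC (its reverse
    complement is GT...AG).  Single-block alignments are vacuously true.
    """
    if alignment.chrom not in genome:
        raise KeyError(f"chromosome {alignment.chrom} absent from genome")
    seq = genome[alignment.chrom]
    for (s1, e1), (s2, e2) in zip(alignment.blocks, alignment.blocks[1:]):
        if e1 >= s2:
            continue  # abutting blocks: no intron
        if s2 > len(seq) or e1 < 0:
            raise ValueError(
                f"{alignment.isotig_id}: intron ({e1},{s2}) outside {alignment.chrom}"
            )
        donor2 = str(seq[e1 : e1 + 2]).upper()
        acceptor2 = str(seq[s2 - 2 : s2]).upper()
        if alignment.strand == "+":
            if donor2 != "GT" or acceptor2 != "AG":
                return False
        else:
            if donor2 != "CT" or acceptor2 != "AC":
                return False
    return True


def assign_antisense_hosts(
    alignments: Sequence[IsotigAlignment],
    known: Sequence[TranscriptModel],
    nonoverlapped_only: bool = True,
) -> list[tuple[IsotigAlignment, str]]:
    """Keep alignments antisense to a known gene and name the host.

    An alignment whose blocks share exonic bases with a known transcript
    on the *same* strand is discarded — it is a fragment of a known gene.
    Remaining alignments must exonically overlap a known transcript on
    the opposite strand; that transcript (the one with the most shared
    bases, if several) becomes the host.  With ``nonoverlapped_only``
    the host pool is restricted to known genes that are not themselves
    antisense-overlapped by another known gene.
    """
    hosts_pool = list(known)
    if nonoverlapped_only:
        overlapped = set()
        for p in find_antisense_overlaps(known):
            overlapped.add(p.acc_a)
            overlapped.add(p.acc_b)
        hosts_pool = [m for m in known if m.accession not in overlapped]

    by_chrom_known: dict[str, list[TranscriptModel]] = {}
    for m in known:
        by_chrom_known.setdefault(m.chrom, []).append(m)
    by_chrom_hosts: dict[str, list[TranscriptModel]] = {}
    for m in hosts_pool:
        by_chrom_hosts.setdefault(m.chrom, []).append(m)

    out: list[tuple[IsotigAlignment, str]] = []
    for aln in alignments:
        model = aln.to_model()
        sense_hit = any(
            m.strand == aln.strand and shared_exonic_bases(model, m) > 0
            for m in by_chrom_known.get(aln.chrom, [])
        )
        if sense_hit:
            continue
        best_host, best_shared = None, 0
        for m in by_chrom_hosts.get(aln.chrom, []):
            if m.strand == aln.strand:
                continue
            shared = shared_exonic_bases(model, m)
            if shared > best_shared:
                best_host, best_shared = m.accession, shared
        if best_host is not None:
            out.append((aln, best_host))
    return out


@dataclass
class NovelGene:
    """A grouped novel antisense gene locus (NAG)."""

    nag_id: str
    chrom: str
    strand: str
    members: list[TranscriptModel]
    host_gene: str
    read_count: float = 0.0
    rpkm: float = 0.0

    @property
    def start(self) -> int:
        return min(m.tx_start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.tx_end for m in self.members)


def group_into_genes(
    transcripts: Sequence[TranscriptModel],
    hosts: Mapping[str, str] | None = None,
    read_counts: Mapping[str, float] | None = None,
) -> list[NovelGene]:
    """Merge novel transcripts into gene loci by transitive exon overlap.

    Transcripts on the same chromosome and strand belong to one gene iff
    their exons overlap, closed transitively.  Transcripts without exon
    overlap stay separate genes even when only a few hundred bases apart.
    NAG identifiers are assigned in genomic order (chromosome, start).
    """
    n = len(transcripts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    order = sorted(range(n), key=lambda i: (transcripts[i].chrom, transcripts[i].strand, transcripts[i].tx_start))
    for a_pos in range(len(order)):
        i = order[a_pos]
        ti = transcripts[i]
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            tj = transcripts[j]
            if (tj.chrom, tj.strand) != (ti.chrom, ti.strand) or tj.tx_start >= ti.tx_end:
                break
            if shared_exonic_bases(ti, tj) > 0:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    genes: list[NovelGene] = []
    for members_idx in groups.values():
        members = sorted(
            (transcripts[i] for i in members_idx),
            key=lambda m: (m.tx_start, m.tx_end, m.accession),
        )
        host = ""
        if hosts:
            for m in members:
                if m.accession in hosts:
                    host = hosts[m.accession]
                    break
        count = 0.0
        if read_counts:
            count = sum(read_counts.get(m.accession, 0.0) for m in members)
        genes.append(
            NovelGene(
                nag_id="",
                chrom=members[0].chrom,
                strand=members[0].strand,
                members=members,
                host_gene=host,
                read_count=count,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    for k, g in enumerate(genes, start=1):
        g.nag_id = f"NAG{k:04d}"
    return genes


@dataclass
class FcPairSets:
    """Within-host vs cross-host RPKM fold-change comparison."""

    fc_same: list[float] = field(default_factory=list)
    fc_diff: list[float] = field(default_factory=list)
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def fc_same_diff(genes: Sequence[NovelGene]) -> FcPairSets:
    """FCsame / FCdiff fold-change sets and their one-sided comparison.

    For every pair of novel genes sharing a host, the fold change
    max(rpkm)/min(rpkm) enters FCsame; pairs with different hosts enter
    FCdiff.  A one-sided Welch t-test on log2 fold changes asks whether
    FCsame values are smaller than FCdiff values.  Pairs involving a
    zero RPKM are skipped with a warning.
    """
    result = FcPairSets()
    for a, b in combinations(genes, 2):
        if a.rpkm == 0 or b.rpkm == 0:
            logger.warning("pair (%s, %s) skipped: zero RPKM", a.nag_id, b.nag_id)
            continue
        fc = max(a.rpkm, b.rpkm) / min(a.rpkm, b.rpkm)
        if a.host_gene == b.host_gene and a.host_gene:
            result.fc_same.append(fc)
        else:
            result.fc_diff.append(fc)
    if len(result.fc_same) >= 2 and len(result.fc_diff) >= 2:
        t = stats.ttest_ind(
            np.log2(result.fc_same),
            np.log2(result.fc_diff),
            equal_var=False,
            alternative="less",
        )
        result.t_statistic = float(t.statistic)
        result.p_value = float(t.pvalue)
    return result


def load_novel_transcript_table(path) -> tuple[list[TranscriptModel], dict[str, float]]:
    """Read a novel-transcript TSV (refFlat-style layout plus read_count)."""
    models: list[TranscriptModel] = []
    counts: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            f = line.rstrip("\n").split("\t")
            starts = tuple(int(x) for x in f[5].rstrip(",").split(",") if x)
            ends = tuple(int(x) for x in f[6].rstrip(",").split(",") if x)
            models.append(
                TranscriptModel(
                    accession=f[0],
                    gene=f[0],
                    chrom=f[1],
                    strand=f[2],
                    tx_start=int(f[3]),
                    tx_end=int(f[4]),
                    exon_starts=starts,
                    exon_ends=ends,
                )
            )
            counts[f[0]] = float(f[7])
    return models, counts


def load_packaged_novel_transcripts() -> tuple[list[TranscriptModel], dict[str, float]]:
    """Load the packaged nine-transcript novel-antisense fixture."""
    ref = importlib.resources.files("strandcheck.data") / "novel_antisense_transcripts.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_novel_transcript_table(path)


def write_novel_genes(genes: Sequence[NovelGene], path) -> None:
    """Write grouped novel genes in the refFlat-style layout with read counts."""
    with open(path, "w") as fh:
        fh.write("transcript\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tread_count\tnag_id\thost_gene\n")
        for g in genes:
            for m in g.members:
                starts = ",".join(str(s) for s in m.exon_starts) + ","
                ends = ",".join(str(e) for e in m.exon_ends) + ","
                fh.write(
                    f"{m.accession}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t{m.tx_end}\t"
                    f"{starts}\t{ends}\t{g.read_count:.6g}\t{g.nag_id}\t{g.host_gene}\n"
                )
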