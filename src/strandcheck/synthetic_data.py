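"""Ground-truth simulation of every input the pipeline consumes.

The generator emulates the data-generating structure the analyses assume:
a random genome carrying (a) singleton multi-exon genes, (b) antisense
gene pairs overlapping at a controllable fraction of their exonic length,
and (c) planted novel antisense transcripts (with canonical GT-AG splice
sites written into the genome) hidden inside the exons of singleton host
genes.  Single-end reads are drawn per transcript in proportion to
abundance x length, with a Beta-distributed 5'-biased start position,
and either strand-specific labelling with a per-read leakage probability
or non-strand-specific labelling with a uniformly random strand.  Reads
falling entirely inside a pair's shared exonic region are emitted with a
secondary alignment to the antisense partner, which is exactly the
ambiguity that equal-split counting resolves by halving.  qPCR cycle
thresholds are generated as Ct = baseline - log2(abundance) + noise.

Because the simulator knows the truth, all alignments are emitted
directly (SAM or in-memory records); no external aligner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from strandcheck.annotation import TranscriptModel
from strandcheck.antisense_discovery import IsotigAlignment
from strandcheck.qpcr_concordance import QpcrTable
from strandcheck.quantification import ReadAlignment


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with defaults matching the study
    conditions the analyses were designed around.

    ``read_length`` 101 mirrors the sequenced libraries; ``leakage_p``
    0.13 mirrors the observed ~13% antisense noise of a real SS library;
    ``ct_noise_sd`` 0.1 cycles is a typical replicate spread for a
    well-behaved qPCR assay; ``positional_bias`` Beta(1, 2) yields the
    5'-biased gene-body coverage seen in oligo-dT-primed libraries;
    ``log2_abundance_sd`` 2 gives the several-orders-of-magnitude
    dynamic range of real transcriptomes.
    """

    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 500_000
    n_genes: int = 40
    fraction_antisense_pairs: float = 0.4
    overlap_range: tuple[float, float] = (0.1, 0.9)
    exon_count_range: tuple[int, int] = (1, 6)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (60, 300)
    pair_exon_length_range: tuple[int, int] = (600, 2000)
    intergenic_gap_range: tuple[int, int] = (200, 800)
    log2_abundance_sd: float = 2.0
    n_reads: int = 100_000
    read_length: int = 101
    protocol: str = "SS"  # {"SS", "NSS"}
    leakage_p: float = 0.13
    positional_bias: tuple[float, float] = (1.0, 2.0)
    error_rate: float = 0.0
    quality_start: float = 40.0
    quality_slope: float = -0.2
    quality_noise_sd: float = 2.0
    ct_baseline: float = 30.0
    ct_noise_sd: float = 0.1
    n_replicates: int = 3
    n_planted_nags: int = 0
    nag_isoforms_per_gene: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.leakage_p <= 0.5):
            raise ValueError("leakage_p must lie in [0, 0.5]")
        lo, hi = self.overlap_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("overlap_range must lie in (0, 1]")
        if self.protocol not in ("SS", "NSS"):
            raise ValueError("protocol must be 'SS' or 'NSS'")


class PairTruth(NamedTuple):
    """An antisense pair of equal-length single-exon transcripts sharing
    ``shared`` exonic bases; both sides have overlap shared/length."""

    acc_a: str
    acc_b: str
    length: int
    shared: int

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.shared / self.length


class NagLink(NamedTuple):
    """Maps reads of a planted novel antisense transcript onto its host.

    ``exons`` holds (a, b, c) per novel-transcript exon enclosed by a
    host exon: a read starting at novel-transcript coordinate s in
    [a, b) with length rl aligns to the host transcript starting at
    c - (s - a) - rl, on the strand opposite the read's.
    """

    nag_acc: str
    host_acc: str
    exons: tuple[tuple[int, int, int], ...]


class ReadTruth(NamedTuple):
    read_id: str
    origin: str
    tx_start: int
    flipped: bool
    mismatches: int


@dataclass
class ReadSet:
    """In-memory simulated library: transcript-space alignments plus truth."""

    alignments: list[ReadAlignment]
    truth: list[ReadTruth]
    n_reads: int


@dataclass
class Annotation:
    """Simulated annotation with full ground truth."""

    models: list[TranscriptModel]  # the "known" transcript set
    pairs: list[PairTruth]
    nag_models: list[TranscriptModel]  # planted novel antisense transcripts
    nag_links: list[NagLink]
    nag_groups: dict[str, list[str]]  # planted gene id -> member accessions
    nag_hosts: dict[str, str]  # nag accession -> host accession


# ---------------------------------------------------------------------------
# genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """I.i.d. uniform ACGT chromosomes; bit-reproducible per seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        arr = _BASES[rng.integers(0, 4, size=config.chrom_length)]
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation

def _patch(seq: bytearray, pos: int, text: str) -> None:
    seq[pos : pos + len(text)] = text.encode("ascii")


def simulate_annotation(
    config: SimulationConfig,
    genome: Mapping[str, str],
    rng: np.random.Generator | None = None,
    noncanonical_nags: int = 0,
) -> tuple[Annotation, dict[str, str]]:
    """Construct an annotation hitting the configured overlap targets.

    Antisense pairs are built as equal-length single-exon transcripts
    sharing exactly round(o * L) bases, so the realized overlap
    percentage matches the drawn target to within one base.  Singleton
    genes are multi-exon.  Planted novel antisense transcripts sit
    inside a long exon of a singleton host on the opposite strand, with
    GT-AG dinucleotides written into the genome at every planted intron
    (the first ``noncanonical_nags`` planted transcripts get a GC-AG
    first intron instead, for splice-filter testing).  Returns the
    annotation plus the (possibly patched) genome.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    chroms = list(genome)
    seqs = {c: bytearray(genome[c], "ascii") for c in chroms}

    n_pair_genes = 2 * int(round(config.n_genes * config.fraction_antisense_pairs / 2))
    n_singletons = config.n_genes - n_pair_genes

    models: list[TranscriptModel] = []
    pairs: list[PairTruth] = []
    nag_models: list[TranscriptModel] = []
    nag_links: list[NagLink] = []
    nag_groups: dict[str, list[str]] = {}
    nag_hosts: dict[str, str] = {}

    cursors = {c: 100 for c in chroms}
    chrom_cycle = 0

    def next_chrom() -> str:
        nonlocal chrom_cycle
        c = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        return c

    def gap() -> int:
        return int(rng.integers(*config.intergenic_gap_range))

    # singleton multi-exon genes; remember candidates able to host a NAG
    host_candidates: list[int] = []  # indices into models
    for i in range(n_singletons):
        chrom = next_chrom()
        cur = cursors[chrom] + gap()
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        starts, ends = [], []
        pos = cur
        host_exon_needed = 600  # room for a planted two-exon novel transcript
        for e in range(n_exons):
            length = int(rng.integers(*config.exon_length_range))
            if i < config.n_planted_nags and e == 0:
                length = max(length, host_exon_needed + 100)
            starts.append(pos)
            ends.append(pos + length)
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(*config.intron_length_range))
        if pos >= len(seqs[chrom]):
            raise ValueError(
                "genes do not fit on the simulated chromosomes; increase chrom_length"
            )
        model = TranscriptModel(
            accession=f"SNG{i + 1:04d}",
            gene=f"sgene{i + 1}",
            chrom=chrom,
            strand=strand,
            tx_start=starts[0],
            tx_end=ends[-1],
            exon_starts=tuple(starts),
            exon_ends=tuple(ends),
        )
        models.append(model)
        host_candidates.append(len(models) - 1)
        cursors[chrom] = pos

    # antisense pairs: single-exon, equal length, exact shared bases
    for p in range(n_pair_genes // 2):
        chrom = next_chrom()
        cur = cursors[chrom] + gap()
        length = int(rng.integers(*config.pair_exon_length_range))
        o = rng.uniform(*config.overlap_range)
        shared = max(1, int(round(o * length)))
        a_start = cur
        b_start = a_start + length - shared
        end = b_start + length
        if end >= len(seqs[chrom]):
            raise ValueError(
                "genes do not fit on the simulated chromosomes; increase chrom_length"
            )
        acc_a, acc_b = f"PRA{p + 1:04d}", f"PRB{p + 1:04d}"
        models.append(
            TranscriptModel(
                accession=acc_a, gene=f"pgeneA{p + 1}", chrom=chrom, strand="+",
                tx_start=a_start, tx_end=a_start + length,
                exon_starts=(a_start,), exon_ends=(a_start + length,),
            )
        )
        models.append(
            TranscriptModel(
                accession=acc_b, gene=f"pgeneB{p + 1}", chrom=chrom, strand="-",
                tx_start=b_start, tx_end=end,
                exon_starts=(b_start,), exon_ends=(end,),
            )
        )
        pairs.append(PairTruth(acc_a, acc_b, length, shared))
        cursors[chrom] = end

    # planted novel antisense transcripts inside singleton host exons
    if config.n_planted_nags > len(host_candidates):
        raise ValueError(
            "n_planted_nags exceeds the number of singleton host genes; "
            "increase n_genes or lower fraction_antisense_pairs"
        )
    for k in range(config.n_planted_nags):
        host = models[host_candidates[k]]
        he_start, he_end = host.exon_starts[0], host.exon_ends[0]
        nag_strand = "-" if host.strand == "+" else "+"
        gene_id = f"PLANT{k + 1:03d}"
        nag_groups[gene_id] = []
        base = he_start + 30 + 5 * k
        members: list[TranscriptModel] = []
        for iso in range(config.nag_isoforms_per_gene):
            # two exons of 150 b separated by an 80 b intron; isoforms are
            # shifted but keep exon overlap so they group into one gene
            shift = 40 * iso
            e1 = (base + shift, base + shift + 150)
            e2 = (base + shift + 230, base + shift + 380)
            if e2[1] > he_end:
                raise ValueError("host exon too short for planted transcript")
            acc = f"{gene_id}-{iso + 1}"
            m = TranscriptModel(
                accession=acc, gene=gene_id, chrom=host.chrom, strand=nag_strand,
                tx_start=e1[0], tx_end=e2[1],
                exon_starts=(e1[0], e2[0]), exon_ends=(e1[1], e2[1]),
            )
            # splice sites on the transcribed strand
            seq = seqs[host.chrom]
            noncanonical = k < noncanonical_nags and iso == 0
            if nag_strand == "+":
                _patch(seq, e1[1], "GC" if noncanonical else "GT")
                _patch(seq, e2[0] - 2, "AG")
            else:
                # plus-strand genomic must read CT...AC (GC-AG becomes CT...GC)
                _patch(seq, e1[1], "CT")
                _patch(seq, e2[0] - 2, "GC" if noncanonical else "AC")
            nag_models.append(m)
            members.append(m)
            nag_groups[gene_id].append(acc)
            nag_hosts[acc] = host.accession
            # read-projection link onto the host transcript: both planted
            # exons sit inside the host's genomically-first exon, whose
            # offset in host transcript coordinates depends on host strand
            if host.strand == "+":
                hoff = 0
            else:
                hoff = host.exonic_length - (he_end - he_start)
            link_exons = []
            tx_off = 0
            exon_iter = m.exons if nag_strand == "+" else list(reversed(m.exons))
            for gs, ge in exon_iter:
                if host.strand == "+":
                    c_const = hoff + ge - he_start
                else:
                    c_const = hoff + he_end - gs
                link_exons.append((tx_off, tx_off + (ge - gs), c_const))
                tx_off += ge - gs
            nag_links.append(NagLink(acc, host.accession, tuple(link_exons)))

    annotation = Annotation(
        models=models,
        pairs=pairs,
        nag_models=nag_models,
        nag_links=nag_links,
        nag_groups=nag_groups,
        nag_hosts=nag_hosts,
    )
    patched = {c: seqs[c].decode("ascii") for c in chroms}
    return annotation, patched


# ---------------------------------------------------------------------------
# abundances and reads

def simulate_abundances(
    accessions: Iterable[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Log-normal relative abundances: 2**N(0, log2_abundance_sd)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    accs = list(accessions)
    return {a: float(2.0 ** rng.normal(0.0, config.log2_abundance_sd)) for a in accs}


def simulate_reads(
    config: SimulationConfig,
    origin_models: Sequence[TranscriptModel],
    abundances: Mapping[str, float],
    rng: np.random.Generator | None = None,
    reference_models: Sequence[TranscriptModel] | None = None,
    pair_truths: Sequence[PairTruth] = (),
    nag_links: Sequence[NagLink] = (),
) -> ReadSet:
    """Draw a read library and emit its transcript-space alignments.

    Reads are sampled Multinomial(n_reads) with weights abundance x
    exonic length over ``origin_models`` (transcripts shorter than the
    read length are excluded with a warning).  Start positions follow
    the Beta positional-bias law scaled to the transcript.  Strand: SS
    reads are sense with probability 1 - leakage_p, NSS reads uniform.
    Alignments are emitted against ``reference_models`` (default: the
    origin set): a sense-of-origin read aligns '+' to its origin, and
    additionally '-' to the antisense partner when it falls entirely
    inside the pair's shared region; reads from planted novel antisense
    transcripts align (antisense) to their host where a single planted
    exon is enclosed by a host exon.
    """
    import warnings

    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    reference_models = origin_models if reference_models is None else reference_models
    ref_accs = {m.accession for m in reference_models}

    rl = config.read_length
    usable = [m for m in origin_models if m.exonic_length >= rl]
    dropped = len(origin_models) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} transcript(s) shorter than the read length excluded")
    if not usable:
        raise ValueError("no transcript is long enough for the configured read length")

    weights = np.array([abundances[m.accession] * m.exonic_length for m in usable])
    if weights.sum() <= 0:
        raise ValueError("total abundance must be positive")
    counts = rng.multinomial(config.n_reads, weights / weights.sum())

    pair_map: dict[str, tuple[str, int, int]] = {}
    for p in pair_truths:
        pair_map[p.acc_a] = (p.acc_b, p.length, p.shared)
        pair_map[p.acc_b] = (p.acc_a, p.length, p.shared)
    link_map = {l.nag_acc: l for l in nag_links}

    a_beta, b_beta = config.positional_bias
    alignments: list[ReadAlignment] = []
    truth: list[ReadTruth] = []
    read_no = 0
    for m, c in zip(usable, counts):
        if c == 0:
            continue
        L = m.exonic_length
        u = rng.beta(a_beta, b_beta, size=c)
        starts = np.minimum((u * (L - rl + 1)).astype(np.int64), L - rl)
        if config.protocol == "SS":
            flipped = rng.random(c) < config.leakage_p
        else:
            flipped = rng.random(c) < 0.5
        mism = (
            rng.binomial(rl, config.error_rate, size=c)
            if config.error_rate > 0
            else np.zeros(c, dtype=np.int64)
        )
        rids = [f"r{j:08d}" for j in range(read_no, read_no + c)]
        read_no += c
        starts_l = starts.tolist()
        flipped_l = flipped.tolist()
        mism_l = mism.tolist()
        strands_l = ["-" if f else "+" for f in flipped_l]
        truth.extend(
            ReadTruth(rid, m.accession, s, f, nm)
            for rid, s, f, nm in zip(rids, starts_l, flipped_l, mism_l)
        )
        if m.accession in ref_accs:
            alignments.extend(
                ReadAlignment(rid, m.accession, st, s, rl, nm)
                for rid, st, s, nm in zip(rids, strands_l, starts_l, mism_l)
            )
        partner = pair_map.get(m.accession)
        if partner is not None and partner[0] in ref_accs:
            pacc, pl, ps = partner
            hit = np.nonzero((starts >= pl - ps) & (starts + rl <= pl))[0]
            p_starts = (2 * pl - ps - rl - starts[hit]).tolist()
            alignments.extend(
                ReadAlignment(
                    rids[i], pacc, "+" if flipped_l[i] else "-", p_start, rl, mism_l[i]
                )
                for i, p_start in zip(hit.tolist(), p_starts)
            )
        link = link_map.get(m.accession)
        if link is not None and link.host_acc in ref_accs:
            for a, b, c_const in link.exons:
                hit = np.nonzero((starts >= a) & (starts + rl <= b))[0]
                h_starts = (c_const - (starts[hit] - a) - rl).tolist()
                alignments.extend(
                    ReadAlignment(
                        rids[i], link.host_acc, "+" if flipped_l[i] else "-",
                        h_start, rl, mism_l[i],
                    )
                    for i, h_start in zip(hit.tolist(), h_starts)
                )
    return ReadSet(alignments=alignments, truth=truth, n_reads=config.n_reads)


def simulate_pair_alignments(
    ratio: float,
    overlap: float,
    n_reads: int,
    protocol: str,
    rng: np.random.Generator,
    length: int = 1000,
    read_length: int = 101,
    leakage_p: float = 0.0,
) -> tuple[list[TranscriptModel], ReadSet]:
    """Convenience generator: one antisense pair with abundance ratio
    ``ratio`` (first over second) overlapping at fraction ``overlap``.

    Used to demonstrate the equal-split estimation bias: strand-blind
    counting of a non-strand-specific library pulls the estimated ratio
    toward 1, while sense-only counting of a strand-specific library
    recovers it.
    """
    shared = max(1, int(round(overlap * length)))
    a = TranscriptModel(
        accession="PAIR_A", gene="pairA", chrom="chrS", strand="+",
        tx_start=0, tx_end=length, exon_starts=(0,), exon_ends=(length,),
    )
    b = TranscriptModel(
        accession="PAIR_B", gene="pairB", chrom="chrS", strand="-",
        tx_start=length - shared, tx_end=2 * length - shared,
        exon_starts=(length - shared,), exon_ends=(2 * length - shared,),
    )
    config = SimulationConfig(
        n_reads=n_reads,
        read_length=read_length,
        protocol=protocol,
        leakage_p=leakage_p,
        positional_bias=(1.0, 1.0),  # uniform starts: the bias under test is allocation
    )
    readset = simulate_reads(
        config,
        [a, b],
        {"PAIR_A": ratio, "PAIR_B": 1.0},
        rng=rng,
        pair_truths=[PairTruth("PAIR_A", "PAIR_B", length, shared)],
    )
    return [a, b], readset


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr(
    abundances: Mapping[str, float],
    targets: Sequence[str],
    controls: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> QpcrTable:
    """Replicate Ct values consistent with the true abundances.

    Ct = ct_baseline - log2(abundance) + N(0, ct_noise_sd^2), replicates
    independent.  Lower Ct means higher abundance, and a noise-free run
    recovers fold changes exactly through 2^(Ct_control - Ct_target).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    genes = list(targets) + list(controls)
    for g in genes:
        if abundances[g] <= 0:
            raise ValueError(f"{g}: abundance must be positive")
    data = {}
    for rep in range(1, config.n_replicates + 1):
        data[f"Ct{rep}"] = [
            config.ct_baseline - np.log2(abundances[g]) + rng.normal(0.0, config.ct_noise_sd)
            for g in genes
        ]
    ct = pd.DataFrame(data, index=genes)
    roles = {g: ("target" if g in set(targets) else "internal_control") for g in genes}
    return QpcrTable(ct=ct, roles=roles)


# ---------------------------------------------------------------------------
# serialisation: SAM / FASTQ / PSL

def project_to_genome(model: TranscriptModel, tx_start: int, length: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic blocks.

    Transcript coordinates run 5'->3'; for minus-strand models the
    genomic blocks therefore come from the 3' end of the exon chain.
    Returned blocks are genomic plus-strand, sorted ascending.
    """
    exons = model.exons if model.strand == "+" else [
        (s, e) for s, e in reversed(model.exons)
    ]
    blocks: list[tuple[int, int]] = []
    off = 0
    for gs, ge in exons:
        exon_len = ge - gs
        lo = max(tx_start, off)
        hi = min(tx_start + length, off + exon_len)
        if hi > lo:
            if model.strand == "+":
                blocks.append((gs + (lo - off), gs + (hi - off)))
            else:
                blocks.append((ge - (hi - off), ge - (lo - off)))
        off += exon_len
    blocks.sort()
    return blocks


def write_sam_transcript(
    readset: ReadSet, reference_models: Sequence[TranscriptModel], path
) -> None:
    """Write transcript-space alignments as SAM (references = transcripts)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for m in reference_models:
            fh.write(f"@SQ\tSN:{m.accession}\tLN:{m.exonic_length}\n")
        for aln in readset.alignments:
            flag = 16 if aln.ref_strand == "-" else 0
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.reference}\t{aln.start + 1}\t255\t"
                f"{aln.aligned_length}M\t*\t0\t0\t*\t*\tNM:i:{aln.mismatches}\n"
            )


def write_sam_genome(
    readset: ReadSet,
    origin_models: Sequence[TranscriptModel],
    genome_lengths: Mapping[str, int],
    path,
    read_length: int,
) -> None:
    """Write genome-space alignments (spliced CIGARs) derived from truth."""
    by_acc = {m.accession: m for m in origin_models}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, ln in genome_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for t in readset.truth:
            m = by_acc[t.origin]
            blocks = project_to_genome(m, t.tx_start, read_length)
            genomic_strand = m.strand if not t.flipped else ("-" if m.strand == "+" else "+")
            flag = 16 if genomic_strand == "-" else 0
            cigar = ""
            for i, (s, e) in enumerate(blocks):
                if i:
                    cigar += f"{s - blocks[i - 1][1]}N"
                cigar += f"{e - s}M"
            fh.write(
                f"{t.read_id}\t{flag}\t{m.chrom}\t{blocks[0][0] + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t*\t*\tNM:i:{t.mismatches}\n"
            )


def write_fastq(
    readset: ReadSet,
    config: SimulationConfig,
    path,
    rng: np.random.Generator | None = None,
) -> None:
    """Random-sequence FASTQ with linearly decaying Phred+33 qualities."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    rl = config.read_length
    positions = np.arange(rl)
    with open(path, "w") as fh:
        for t in readset.truth:
            seq = _BASES[rng.integers(0, 4, size=rl)].tobytes().decode("ascii")
            q = (
                config.quality_start
                + config.quality_slope * positions
                + rng.normal(0.0, config.quality_noise_sd, size=rl)
            )
            q = np.clip(np.rint(q), 2, 40).astype(int)
            qual = "".join(chr(33 + v) for v in q)
            fh.write(f"@{t.read_id}\n{seq}\n+\n{qual}\n")


def exact_psl(models: Sequence[TranscriptModel]) -> list[IsotigAlignment]:
    """Perfect-identity contig alignments for planted transcripts."""
    return [
        IsotigAlignment(
            isotig_id=m.accession,
            chrom=m.chrom,
            strand=m.strand,
            blocks=tuple(m.exons),
            matches=m.exonic_length,
            mismatches=0,
            q_num_insert=0,
            query_size=m.exonic_length,
        )
        for m in models
    ]


# ---------------------------------------------------------------------------
# study designs

def simulate_overlap_study(
    seed: int,
    n_pairs_per_bin: int = 40,
    n_singletons: int = 300,
    pair_length: int = 1000,
    n_reads: int = 200_000,
    n_bins: int = 10,
) -> tuple[list[TranscriptModel], list[PairTruth], dict[str, float], dict[str, float], dict[str, float], dict[str, float]]:
    """Paired SS/NSS libraries over an annotation spanning all overlap bins.

    Builds ``n_pairs_per_bin`` equal-length single-exon antisense pairs
    per overlap decile plus a pool of nonoverlapped singletons, draws one
    abundance vector, and sequences it twice: once strand-specifically
    (no leakage, counted sense-only) and once strand-blind (counted on
    both strands with equal-split allocation).  Returns the models, pair
    truths, and per-transcript RPKM and count maps for both libraries —
    the inputs needed to correlate expression by overlap bin and run the
    size-matched mimic control.
    """
    from strandcheck.quantification import compute_rpkm, count_reads

    rng = np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    pair_truths: list[PairTruth] = []
    for decile in range(n_bins):
        lo = decile / n_bins if decile else 2.0 / pair_length
        hi = (decile + 1) / n_bins
        for p in range(n_pairs_per_bin):
            shared = max(1, int(round(rng.uniform(lo, hi) * pair_length)))
            acc_a, acc_b = f"A{decile}_{p}", f"B{decile}_{p}"
            chrom = f"pair{decile}_{p}"
            models.append(
                TranscriptModel(
                    accession=acc_a, gene=acc_a, chrom=chrom, strand="+",
                    tx_start=0, tx_end=pair_length,
                    exon_starts=(0,), exon_ends=(pair_length,),
                )
            )
            b_start = pair_length - shared
            models.append(
                TranscriptModel(
                    accession=acc_b, gene=acc_b, chrom=chrom, strand="-",
                    tx_start=b_start, tx_end=b_start + pair_length,
                    exon_starts=(b_start,), exon_ends=(b_start + pair_length,),
                )
            )
            pair_truths.append(PairTruth(acc_a, acc_b, pair_length, shared))
    for s in range(n_singletons):
        models.append(
            TranscriptModel(
                accession=f"S{s}", gene=f"S{s}", chrom=f"sng{s}", strand="+",
                tx_start=0, tx_end=pair_length,
                exon_starts=(0,), exon_ends=(pair_length,),
            )
        )

    abundance = simulate_abundances([m.accession for m in models], SimulationConfig(), rng)
    lengths = {m.accession: m.exonic_length for m in models}
    ss_cfg = SimulationConfig(
        n_reads=n_reads, protocol="SS", leakage_p=0.0, positional_bias=(1.0, 1.0)
    )
    nss_cfg = SimulationConfig(
        n_reads=n_reads, protocol="NSS", positional_bias=(1.0, 1.0)
    )
    ss = simulate_reads(ss_cfg, models, abundance, rng, pair_truths=pair_truths)
    nss = simulate_reads(nss_cfg, models, abundance, rng, pair_truths=pair_truths)
    ss_res = count_reads(ss.alignments, models, "sense_only")
    nss_res = count_reads(nss.alignments, models, "both")
    rpkm_ss = {
        r.accession: r.rpkm
        for r in compute_rpkm(ss_res.counts, lengths, ss_res.library_mapped_reads)
    }
    rpkm_nss = {
        r.accession: r.rpkm
        for r in compute_rpkm(nss_res.counts, lengths, nss_res.library_mapped_reads)
    }
    return models, pair_truths, rpkm_ss, rpkm_nss, ss_res.counts, nss_res.counts
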