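"""The ground-truth generator: genome, annotation, reads, qPCR, round trips."""

import numpy as np
import pytest

from strandcheck.annotation import find_antisense_overlaps
from strandcheck.antisense_discovery import check_gt_ag
from strandcheck.qpcr_concordance import ct_fold_changes
from strandcheck.quantification import compute_rpkm, count_reads, sam_to_alignments
from strandcheck.synthetic_data import (
    SimulationConfig,
    exact_psl,
    project_to_genome,
    simulate_abundances,
    simulate_annotation,
    simulate_genome,
    simulate_qpcr,
    simulate_reads,
    write_fasta,
    write_sam_genome,
)

from conftest import make_transcript


class TestSimulateGenome:
    def test_reproducible_per_seed(self):
        cfg = SimulationConfig(seed=7, chrom_length=5000)
        assert simulate_genome(cfg) == simulate_genome(cfg)

    def test_requested_length(self):
        cfg = SimulationConfig(chrom_length=12_345, n_chromosomes=2)
        genome = simulate_genome(cfg)
        assert set(genome) == {"chr1", "chr2"}
        assert all(len(s) == 12_345 for s in genome.values())

    def test_base_composition_uniform(self):
        cfg = SimulationConfig(seed=3, chrom_length=1_000_000)
        seq = simulate_genome(cfg)["chr1"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.01)

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        cfg = SimulationConfig(seed=1, chrom_length=777)
        genome = simulate_genome(cfg)
        write_fasta(genome, tmp_path / "g.fa")
        parsed = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "g.fa"), "fasta")}
        assert parsed == genome


class TestSimulateAnnotation:
    def _build(self, **kw):
        cfg = SimulationConfig(seed=11, n_genes=24, chrom_length=400_000, **kw)
        rng = np.random.default_rng(cfg.seed)
        genome = simulate_genome(cfg, rng)
        annot, genome = simulate_annotation(cfg, genome, rng)
        return cfg, annot, genome

    def test_no_pairs_when_fraction_zero(self):
        _, annot, _ = self._build(fraction_antisense_pairs=0.0)
        assert annot.pairs == []
        assert find_antisense_overlaps(annot.models) == []

    def test_realized_overlap_matches_target(self):
        _, annot, _ = self._build(overlap_range=(0.68, 0.72))
        pairs = find_antisense_overlaps(annot.models)
        assert len(pairs) == len(annot.pairs)
        for p in pairs:
            assert 68.0 - 2 <= p.overlap_pct_a <= 72.0 + 2
            assert p.overlap_pct_a == pytest.approx(p.overlap_pct_b)

    def test_planted_transcripts_pass_splice_rule(self):
        _, annot, genome = self._build(n_planted_nags=4)
        for aln in exact_psl(annot.nag_models):
            assert check_gt_ag(aln, genome)

    def test_too_many_planted_genes_rejected(self):
        with pytest.raises(ValueError, match="n_planted_nags"):
            self._build(n_planted_nags=100)


class TestSimulateReads:
    def test_no_leakage_means_no_antisense(self, rng):
        models = [make_transcript("T", "c1", "+", [(0, 2000)])]
        cfg = SimulationConfig(n_reads=5000, protocol="SS", leakage_p=0.0)
        rs = simulate_reads(cfg, models, {"T": 1.0}, rng)
        anti = count_reads(rs.alignments, models, "antisense_only")
        assert anti.library_mapped_reads == 0

    def test_truth_table_accounts_for_every_read(self, rng):
        models = [make_transcript(f"T{i}", f"c{i}", "+", [(0, 1500)]) for i in range(5)]
        cfg = SimulationConfig(n_reads=3000, protocol="NSS")
        ab = {m.accession: float(i + 1) for i, m in enumerate(models)}
        rs = simulate_reads(cfg, models, ab, rng)
        assert len(rs.truth) == 3000
        assert len({t.read_id for t in rs.truth}) == 3000

    def test_short_transcripts_excluded_with_warning(self, rng):
        models = [
            make_transcript("SHORT", "c1", "+", [(0, 50)]),
            make_transcript("OK", "c2", "+", [(0, 1500)]),
        ]
        cfg = SimulationConfig(n_reads=100, read_length=101)
        with pytest.warns(UserWarning, match="shorter"):
            rs = simulate_reads(cfg, models, {"SHORT": 1.0, "OK": 1.0}, rng)
        assert all(t.origin == "OK" for t in rs.truth)

    def test_abundance_ratio_recovered_without_overlap(self, rng):
        """Two nonoverlapping genes at 4:1 abundance: sense-only RPKM on
        an SS library recovers the ratio within multinomial error."""
        models = [
            make_transcript("HI", "c1", "+", [(0, 1000)]),
            make_transcript("LO", "c2", "+", [(0, 1000)]),
        ]
        cfg = SimulationConfig(n_reads=100_000, protocol="SS", leakage_p=0.0)
        rs = simulate_reads(cfg, models, {"HI": 4.0, "LO": 1.0}, rng)
        res = count_reads(rs.alignments, models, "sense_only")
        recs = {
            r.accession: r.rpkm
            for r in compute_rpkm(
                res.counts, {m.accession: 1000 for m in models}, res.library_mapped_reads
            )
        }
        assert recs["HI"] / recs["LO"] == pytest.approx(4.0, rel=0.1)

    def test_bit_reproducible_given_seed(self):
        models = [make_transcript("T", "c1", "+", [(0, 1500)])]
        cfg = SimulationConfig(n_reads=500, protocol="NSS")
        a = simulate_reads(cfg, models, {"T": 1.0}, np.random.default_rng(5))
        b = simulate_reads(cfg, models, {"T": 1.0}, np.random.default_rng(5))
        assert a.alignments == b.alignments
        assert a.truth == b.truth


class TestGenomeProjection:
    def test_spliced_projection_blocks(self):
        m = make_transcript("T", "c1", "+", [(100, 200), (300, 400)])
        assert project_to_genome(m, 50, 100) == [(150, 200), (300, 350)]

    def test_minus_strand_projection_counts_from_three_prime(self):
        m = make_transcript("T", "c1", "-", [(100, 200), (300, 400)])
        # transcript position 0 is the genomic end of the last exon
        assert project_to_genome(m, 0, 50) == [(350, 400)]
        # tx 80..100 sits in the last genomic exon, tx 100..120 in the first
        assert project_to_genome(m, 80, 40) == [(180, 200), (300, 320)]

    def test_genome_sam_counts_match_transcript_counts(self, tmp_path, rng):
        """Quantifying the genome-space SAM (exon projection) of a simple
        SS library agrees with transcript-space counting."""
        models = [
            make_transcript("T1", "chr1", "+", [(100, 700), (900, 1600)]),
            make_transcript("T2", "chr1", "-", [(3000, 4500)]),
        ]
        cfg = SimulationConfig(n_reads=2000, protocol="SS", leakage_p=0.05)
        ab = {"T1": 2.0, "T2": 1.0}
        rs = simulate_reads(cfg, models, ab, rng)
        sam = tmp_path / "g.sam"
        write_sam_genome(rs, models, {"chr1": 10_000}, sam, cfg.read_length)
        genome_alns = sam_to_alignments(sam, space="genome")
        res_g = count_reads(genome_alns, models, "sense_only", space="genome")
        res_t = count_reads(rs.alignments, models, "sense_only")
        assert res_g.counts == pytest.approx(res_t.counts)


class TestSimulateQpcr:
    def test_noise_free_fold_change_exact(self):
        cfg = SimulationConfig(ct_noise_sd=0.0)
        table = simulate_qpcr({"t": 8.0, "c": 1.0}, ["t"], ["c"], cfg, np.random.default_rng(0))
        fcs = ct_fold_changes(table)
        assert all(v.fc == pytest.approx(8.0) for v in fcs.values)

    def test_equal_abundance_equal_expected_ct(self):
        cfg = SimulationConfig(ct_noise_sd=0.0)
        table = simulate_qpcr({"a": 2.0, "b": 2.0, "c": 1.0}, ["a", "b"], ["c"], cfg, np.random.default_rng(0))
        assert table.ct.loc["a", "Ct1"] == pytest.approx(table.ct.loc["b", "Ct1"])

    def test_fold_change_recovery_unbiased_across_seeds(self):
        """Replicate-averaged delta-Ct fold changes are unbiased: over 100
        seeds the mean recovered fold change is within 3 SE of truth."""
        cfg = SimulationConfig(ct_noise_sd=0.1)
        truth = 5.0
        ests = []
        for seed in range(100):
            table = simulate_qpcr(
                {"t": truth, "c": 1.0}, ["t"], ["c"], cfg, np.random.default_rng(seed)
            )
            fcs = [v.fc for v in ct_fold_changes(table).values]
            ests.append(np.mean(fcs))
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(truth, abs=3 * se + 0.02)


class TestFullLoopRecovery:
    def test_relative_abundance_correlation(self, rng):
        """Fifty nonoverlapped transcripts, 100k SS reads: estimated log
        RPKM correlates >= 0.99 with true log abundance."""
        models = [make_transcript(f"T{i}", f"c{i}", "+", [(0, 1200)]) for i in range(50)]
        cfg = SimulationConfig(n_reads=100_000, protocol="SS", leakage_p=0.0)
        ab = simulate_abundances([m.accession for m in models], cfg, rng)
        rs = simulate_reads(cfg, models, ab, rng)
        res = count_reads(rs.alignments, models, "sense_only")
        recs = compute_rpkm(
            res.counts, {m.accession: 1200 for m in models}, res.library_mapped_reads
        )
        est = {r.accession: r.rpkm for r in recs}
        keep = [m.accession for m in models if est[m.accession] > 0]
        r = np.corrcoef(
            [np.log(ab[a]) for a in keep], [np.log(est[a]) for a in keep]
        )[0, 1]
        assert r >= 0.99
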