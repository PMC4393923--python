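"""PSL filtering, GT-AG validation, host assignment, NAG grouping, FCsame/FCdiff."""

import pytest

from strandcheck.antisense_discovery import (
    IsotigAlignment,
    NovelGene,
    assign_antisense_hosts,
    check_gt_ag,
    fc_same_diff,
    filter_alignments,
    group_into_genes,
    load_packaged_novel_transcripts,
    parse_psl,
    write_psl,
)

from conftest import make_transcript


def iso(name, blocks, matches=None, mismatches=0, q_ins=0, chrom="chr1", strand="+"):
    aligned = sum(e - s for s, e in blocks)
    return IsotigAlignment(
        isotig_id=name, chrom=chrom, strand=strand, blocks=tuple(blocks),
        matches=matches if matches is not None else aligned,
        mismatches=mismatches, q_num_insert=q_ins, query_size=aligned + mismatches,
    )


class TestFilterAlignments:
    def test_boundary_identity_kept(self):
        a = iso("i1", [(0, 95)], matches=95, mismatches=5)  # identity exactly 0.95
        assert a.identity == pytest.approx(0.95)
        assert filter_alignments([a]) == [a]

    def test_just_below_boundary_dropped(self):
        a = iso("i1", [(0, 9499)], matches=9499, mismatches=501)
        assert a.identity < 0.95
        assert filter_alignments([a]) == []

    def test_best_locus_kept_among_multiple(self):
        good = iso("i1", [(0, 99)], matches=99, mismatches=1)
        worse = iso("i1", [(500, 596)], matches=96, mismatches=4)
        kept = filter_alignments([worse, good])
        assert kept == [good]

    def test_identity_tie_drops_isotig(self):
        a = iso("i1", [(0, 98)], matches=98, mismatches=2)
        b = iso("i1", [(500, 598)], matches=98, mismatches=2)
        assert filter_alignments([a, b]) == []


class TestCheckGtAg:
    def _genome(self, intron, flank=20):
        seq = "A" * flank + intron + "C" * flank
        return {"chr1": seq}, flank, flank + len(intron)

    def test_plus_strand_canonical_intron(self):
        genome, s, e = self._genome("GT" + "N" * 30 + "AG")
        aln = iso("i1", [(0, s), (e, e + 10)])
        assert check_gt_ag(aln, genome)

    def test_minus_strand_reads_reverse_complement(self):
        # genomic plus strand CT...AC is GT...AG after reverse complement
        genome, s, e = self._genome("CT" + "N" * 30 + "AC")
        aln = iso("i1", [(0, s), (e, e + 10)], strand="-")
        assert check_gt_ag(aln, genome)

    def test_gc_ag_minor_class_rejected(self):
        genome, s, e = self._genome("GC" + "N" * 30 + "AG")
        aln = iso("i1", [(0, s), (e, e + 10)])
        assert not check_gt_ag(aln, genome)

    def test_single_block_vacuously_true(self):
        assert check_gt_ag(iso("i1", [(0, 50)]), {"chr1": "A" * 60})

    def test_strand_consistency_with_reverse_complement(self, rng):
        """A minus-strand alignment over a genome equals the plus-strand
        check on the reverse-complemented construction."""
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(20):
            bases = "".join(rng.choice(list("ACGT"), size=120))
            donor = "CT" if rng.random() < 0.5 else "TT"
            acceptor = "AC" if rng.random() < 0.5 else "AA"
            seq = bases[:30] + donor + bases[30:60] + acceptor + bases[60:]
            L = len(seq)
            minus = iso("m", [(10, 30), (64, 80)], strand="-")
            plus_seq = seq.translate(comp)[::-1]
            plus = iso("p", [(L - 80, L - 64), (L - 30, L - 10)], strand="+")
            assert check_gt_ag(minus, {"chr1": seq}) == check_gt_ag(plus, {"chr1": plus_seq})

    def test_out_of_range_intron_rejected(self):
        aln = iso("i1", [(0, 10), (500, 510)])
        with pytest.raises(ValueError):
            check_gt_ag(aln, {"chr1": "A" * 100})
        with pytest.raises(KeyError):
            check_gt_ag(aln, {"chr2": "A" * 1000})


class TestAssignAntisenseHosts:
    def _known(self):
        return [
            make_transcript("HOST", "chr1", "+", [(1000, 2000), (3000, 4000)]),
            make_transcript("OTHER", "chr2", "+", [(0, 500)]),
        ]

    def test_antisense_overlap_assigns_host(self):
        aln = iso("n1", [(1200, 1500)], strand="-")
        assigned = assign_antisense_hosts([aln], self._known())
        assert assigned == [(aln, "HOST")]

    def test_sense_concordant_alignment_discarded(self):
        aln = iso("n1", [(1200, 1500)], strand="+")
        assert assign_antisense_hosts([aln], self._known()) == []

    def test_intergenic_alignment_excluded(self):
        aln = iso("n1", [(2200, 2600)], strand="-")  # intronic only
        assert assign_antisense_hosts([aln], self._known()) == []

    def test_overlapped_known_genes_excluded_as_hosts_by_default(self):
        known = self._known() + [
            make_transcript("ANTI", "chr1", "-", [(1500, 2500)])
        ]
        aln = iso("n1", [(1200, 1400)], strand="-")
        # HOST is itself antisense-overlapped by ANTI, so no host remains
        assert assign_antisense_hosts([aln], known, nonoverlapped_only=True) == []
        assigned = assign_antisense_hosts([aln], known, nonoverlapped_only=False)
        assert assigned[0][1] == "HOST"


class TestGroupIntoGenes:
    def test_packaged_table_groups_into_expected_loci(self):
        """The packaged nine-transcript table groups into five loci; on
        chr19 the four transcripts form exactly two genes despite the two
        loci being fewer than 500 bases apart."""
        models, counts = load_packaged_novel_transcripts()
        genes = group_into_genes(models, read_counts=counts)
        chr19 = [g for g in genes if g.chrom == "chr19"]
        assert len(genes) == 5
        assert len(chr19) == 2
        memberships = sorted(
            tuple(sorted(m.accession for m in g.members)) for g in chr19
        )
        assert memberships == [("NAG0001-1", "NAG0001-2"), ("NAG0002-1", "NAG0002-2")]
        # the gap between the two chr19 loci is under 500 bases, yet they
        # stay separate because no exonic base is shared
        assert 50362914 - 50362420 < 500

    def test_single_transcript_single_gene(self):
        m = make_transcript("n1", "chr1", "-", [(0, 100)])
        (gene,) = group_into_genes([m])
        assert gene.members == [m]
        assert gene.nag_id == "NAG0001"

    def test_transitive_chain_merges(self):
        a = make_transcript("a", "chr1", "-", [(0, 100)])
        b = make_transcript("b", "chr1", "-", [(80, 180)])
        c = make_transcript("c", "chr1", "-", [(160, 260)])
        (gene,) = group_into_genes([a, b, c])
        assert sorted(m.accession for m in gene.members) == ["a", "b", "c"]

    def test_grouping_is_partition_and_order_independent(self, rng):
        models = []
        for i in range(12):
            start = int(rng.integers(0, 3000))
            models.append(
                make_transcript(f"n{i}", "chr1", "-", [(start, start + int(rng.integers(50, 400)))])
            )
        genes_fwd = group_into_genes(models)
        perm = list(rng.permutation(len(models)))
        genes_perm = group_into_genes([models[i] for i in perm])
        assert sum(len(g.members) for g in genes_fwd) == len(models)
        sets_fwd = sorted(tuple(sorted(m.accession for m in g.members)) for g in genes_fwd)
        sets_perm = sorted(tuple(sorted(m.accession for m in g.members)) for g in genes_perm)
        assert sets_fwd == sets_perm

    def test_read_counts_summed_per_gene(self):
        models, counts = load_packaged_novel_transcripts()
        genes = {g.nag_id: g for g in group_into_genes(models, read_counts=counts)}
        chr19 = sorted(
            (g for g in genes.values() if g.chrom == "chr19"), key=lambda g: g.start
        )
        assert chr19[0].read_count == pytest.approx(180 + 34)
        assert chr19[1].read_count == pytest.approx(121 + 125.5)


class TestFcSameDiff:
    def _gene(self, nag_id, host, rpkm):
        m = make_transcript(nag_id, "chr1", "-", [(0, 100)])
        return NovelGene(nag_id, "chr1", "-", [m], host, rpkm=rpkm)

    def test_equal_rpkm_unit_fold_change(self):
        genes = [self._gene("NAG0001", "H1", 10.0), self._gene("NAG0002", "H1", 10.0),
                 self._gene("NAG0003", "H2", 3.0), self._gene("NAG0004", "H2", 3.0)]
        res = fc_same_diff(genes)
        assert all(fc == 1.0 for fc in res.fc_same)

    def test_pair_counts_match_combinatorics(self):
        # hosts A: 3 genes, B: 2 genes -> C(3,2)+C(2,2)=4 same, 3*2=6 diff
        genes = [self._gene(f"NAGA{i}", "A", 5.0 + i) for i in range(3)]
        genes += [self._gene(f"NAGB{i}", "B", 7.0 + i) for i in range(2)]
        res = fc_same_diff(genes)
        assert len(res.fc_same) == 4
        assert len(res.fc_diff) == 6
        assert all(fc >= 1.0 for fc in res.fc_same + res.fc_diff)

    def test_zero_rpkm_pairs_skipped(self):
        genes = [self._gene("NAG0001", "A", 0.0), self._gene("NAG0002", "A", 5.0),
                 self._gene("NAG0003", "B", 2.0), self._gene("NAG0004", "B", 4.0)]
        res = fc_same_diff(genes)
        assert len(res.fc_same) == 1  # only the B-host pair survives

    def test_similar_same_host_abundances_detected(self, rng):
        """Same-host genes share abundance within 10% while hosts span
        orders of magnitude: the one-sided test is decisive."""
        genes = []
        for h in range(8):
            base = float(10 ** rng.uniform(0, 2))
            for i in range(3):
                genes.append(
                    self._gene(f"NAG{h}_{i}", f"H{h}", base * float(rng.uniform(0.9, 1.1)))
                )
        res = fc_same_diff(genes)
        assert res.p_value < 0.001


class TestPslRoundTrip:
    def test_written_psl_parses_back(self, tmp_path):
        alns = [
            iso("i1", [(100, 200), (300, 450)], matches=240, mismatches=10),
            iso("i2", [(50, 80)], strand="-"),
        ]
        path = tmp_path / "a.psl"
        write_psl(alns, path)
        parsed = parse_psl(path)
        assert [(a.isotig_id, a.blocks, a.strand) for a in parsed] == [
            ("i1", ((100, 200), (300, 450)), "+"),
            ("i2", ((50, 80),), "-"),
        ]
        assert parsed[0].identity == pytest.approx(240 / 250)

    def test_header_lines_skipped(self, tmp_path):
        path = tmp_path / "h.psl"
        path.write_text(
            "psLayout version 3\n\nmatch\tmis-\n---------\n"
            "30\t0\t0\t0\t0\t0\t0\t0\t+\tq1\t30\t0\t30\tchr1\t1000\t10\t40\t1\t30,\t0,\t10,\n"
        )
        (a,) = parse_psl(path)
        assert a.blocks == ((10, 40),)
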