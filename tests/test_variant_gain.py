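"""VCF ingest and gain/loss-of-function candidacy decisions."""

import pytest

from gasfunnel.motif_model import build_gas_classes, iupac_matches
from gasfunnel.sequence_scan import MotifHit, scan_fasta
from gasfunnel.variant_gain import (VCFReader, VariantRecord, candidate_gof,
                                    candidate_lof, evidence_filter,
                                    read_candidates_tsv, read_vcf,
                                    write_candidates_tsv)

from conftest import oracle_scan_plus

CLASSES = build_gas_classes()

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=FREQ,Number=.,Type=String,Description="Frequency studies">\n'
    "##contig=<ID=chr1,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def write_vcf(path, rows):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))


def t1_hit(start=100, kmer="GTCAAAGAA", chrom="chr1"):
    return MotifHit(chrom, start, start + 9, "T1", kmer,
                    deviant_pos=start, restore_allele_plus="T")


def gas_hit(start=100, kmer="TTCAAAGAA", chrom="chr1"):
    return MotifHit(chrom, start, start + 9, "GAS", kmer)


class TestReadVcf:

    def test_single_snv(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t101\trs1\tG\tT\t.\t.\t."])
        recs = read_vcf(vcf)
        assert len(recs) == 1
        assert (recs[0].pos, recs[0].ref, recs[0].alts) == (101, "G", ("T",))
        assert recs[0].pos0 == 100

    def test_multiallelic_expansion(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t101\trs1\tG\tT,C\t.\t.\t."])
        recs = read_vcf(vcf)
        assert [r.alt for r in recs] == ["T", "C"]
        assert all(r.rsid == "rs1" for r in recs)

    def test_indel_excluded_and_tallied(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, ["chr1\t101\trs1\tGA\tG\t.\t.\t.",
                        "chr1\t201\trs2\tG\tT\t.\t.\t."])
        reader = VCFReader(vcf)
        recs = list(reader)
        assert [r.rsid for r in recs] == ["rs2"]
        assert reader.n_skipped_non_snv == 1

    def test_freq_evidence_counts_studies(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        write_vcf(vcf, [
            "chr1\t101\trs1\tG\tT\t.\t.\tFREQ=KG:0.9,0.1",
            "chr1\t201\trs2\tG\tT\t.\t.\tFREQ=KG:0.9,0.1|TOPMED:0.8,0.2|X:0.5,0.5",
            "chr1\t301\trs3\tG\tT\t.\t.\t.",
        ])
        counts = {r.rsid: r.evidence_count for r in read_vcf(vcf)}
        assert counts == {"rs1": 1, "rs2": 3, "rs3": 0}

    def test_alternate_integer_evidence_key(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=NSUB,Number=1,Type=Integer,Description="subjects">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\trs1\tG\tT\t.\t.\tNSUB=4\n")
        recs = read_vcf(vcf, evidence_key="NSUB")
        assert recs[0].evidence_count == 4


class TestCandidateGof:

    def test_restoring_alt_completes_motif(self):
        var = VariantRecord("chr1", 101, "rs1", "G", ("T",), 2)
        cands = candidate_gof([t1_hit()], [var])
        assert len(cands) == 1
        assert cands[0].completed_kmer == "TTCAAAGAA"
        assert iupac_matches("TTCNNNGAA", cands[0].completed_kmer)

    def test_non_restoring_alt_ignored(self):
        var = VariantRecord("chr1", 101, "rs1", "G", ("C",), 2)
        assert candidate_gof([t1_hit()], [var]) == []

    def test_variant_off_deviant_position_ignored(self):
        var = VariantRecord("chr1", 105, "rs1", "A", ("T",), 2)
        assert candidate_gof([t1_hit()], [var]) == []

    def test_ref_mismatch_warns_and_skips(self):
        var = VariantRecord("chr1", 101, "rs1", "A", ("T",), 2)
        with pytest.warns(UserWarning, match="build mismatch"):
            cands = candidate_gof([t1_hit()], [var])
        assert cands == []

    def test_scenario_matches_apply_and_rescan_oracle(self, scenario):
        """Planted restorable SNPs, and only those, become candidates."""
        from Bio import SeqIO

        bundle, truth = scenario
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(bundle["genome_fasta"],
                                                      "fasta")}
        _, hits = scan_fasta(bundle["genome_fasta"], CLASSES)
        nc = [h for h in hits if h.class_name != "GAS"]
        cands = candidate_gof(nc, read_vcf(bundle["vcf"]))

        # oracle: apply every catalogued alt, diff intact-motif window sets
        expected = set()
        for var in read_vcf(bundle["vcf"]):
            seq = seqs[var.chrom]
            mutated = seq[:var.pos0] + var.alt + seq[var.pos0 + 1:]
            before = {s for s, n in oracle_scan_plus(seq) if n == "GAS"}
            after = {s for s, n in oracle_scan_plus(mutated) if n == "GAS"}
            if after - before:
                expected.add((var.chrom, var.rsid))
        assert {(c.chrom, c.variant.rsid) for c in cands} == expected
        assert expected == {(s.chrom, s.rsid) for s in truth.sites
                            if s.failure != "decoy"}

    def test_self_consistency_of_emitted_candidates(self, scenario):
        bundle, _ = scenario
        _, hits = scan_fasta(bundle["genome_fasta"], CLASSES)
        nc = [h for h in hits if h.class_name != "GAS"]
        for c in candidate_gof(nc, read_vcf(bundle["vcf"])):
            off = c.hit.deviant_pos - c.hit.start
            substituted = c.hit.kmer[:off] + c.variant.alt + c.hit.kmer[off + 1:]
            assert iupac_matches("TTCNNNGAA", substituted)
            assert c.variant.pos0 == c.hit.deviant_pos
            assert c.variant.alt == c.hit.restore_allele_plus


class TestCandidateLof:

    def test_fixed_position_break(self):
        var = VariantRecord("chr1", 103, "rs1", "C", ("A",), 2)
        lofs = candidate_lof([gas_hit()], [var])
        assert len(lofs) == 1
        assert lofs[0].broken_kmer == "TTAAAAGAA"

    def test_free_middle_position_never_breaks(self):
        var = VariantRecord("chr1", 105, "rs1", "A", ("G",), 2)
        assert candidate_lof([gas_hit()], [var]) == []

    def test_broken_kmer_never_rescans_as_gas(self, rng):
        """Rescan oracle: every reported LOF substitution kills the motif."""
        hit = gas_hit()
        variants = []
        for off in range(9):
            ref = hit.kmer[off]
            for alt in set("ACGT") - {ref}:
                variants.append(VariantRecord("chr1", 101 + off,
                                              f"rs{off}{alt}", ref, (alt,), 2))
        lofs = candidate_lof([hit], variants)
        assert len(lofs) == 18  # 6 fixed positions x 3 alts
        for c in lofs:
            assert not iupac_matches("TTCNNNGAA", c.broken_kmer)


class TestEvidenceFilter:

    def _cand(self, evidence):
        var = VariantRecord("chr1", 101, "rs1", "G", ("T",), evidence)
        return candidate_gof([t1_hit()], [var])[0]

    @pytest.mark.parametrize("evidence,threshold,kept", [
        (2, 2, True),   # two independent subjects pass the default rule
        (1, 2, False),
        (0, 0, True),   # threshold 0 is the identity filter
    ])
    def test_threshold(self, evidence, threshold, kept):
        cands = [self._cand(evidence)]
        assert (evidence_filter(cands, threshold) == cands) is kept

    def test_monotonicity(self):
        cands = [self._cand(e) for e in (0, 1, 2, 3, 5)]
        sizes = [len(evidence_filter(list(cands), t)) for t in range(7)]
        assert sizes == sorted(sizes, reverse=True)
        for t in range(7):
            assert set(map(id, evidence_filter(list(cands), t))) <= \
                set(map(id, cands))


def test_candidate_tsv_round_trip(tmp_path, scenario):
    bundle, _ = scenario
    _, hits = scan_fasta(bundle["genome_fasta"], CLASSES)
    nc = [h for h in hits if h.class_name != "GAS"]
    cands = candidate_gof(nc, read_vcf(bundle["vcf"]))
    cands[0].nearest_gene = "G1"
    cands[0].distance_to_tss = 1234
    cands[0].conserved = True
    path = tmp_path / "c.tsv"
    write_candidates_tsv(cands, path)
    back = read_candidates_tsv(path)
    assert len(back) == len(cands)
    for a, b in zip(cands, back):
        assert a.variant == b.variant
        assert a.hit == b.hit
        assert a.completed_kmer == b.completed_kmer
        assert a.nearest_gene == b.nearest_gene
        assert a.distance_to_tss == b.distance_to_tss
        assert a.conserved == b.conserved
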