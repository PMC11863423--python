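"""Interval funnel stages versus quadratic brute-force oracles."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from gasfunnel._util import BadInputError
from gasfunnel.region_filters import (GeneModel, GenomicInterval,
                                      neighbor_gene_filter, read_gtf,
                                      read_tss_bed, set_immune_flags,
                                      spacing_filter, threshold_signal,
                                      upstream_tss_filter, upstream_window,
                                      window_join)


@dataclass
class Item:
    """Minimal interval-bearing stand-in for a candidate."""

    chrom: str
    motif_start: int
    motif_end: int
    provenance: list = field(default_factory=list)
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None
    upstream_gene: str | None = None
    distance_to_tss: int | None = None

    @property
    def snp_pos0(self):
        return self.motif_start

    @property
    def start(self):
        return self.motif_start

    @property
    def end(self):
        return self.motif_end


def gap(a_start, a_end, b_start, b_end):
    """Bases strictly between two half-open intervals (0 when they touch/overlap)."""
    return max(b_start - a_end, a_start - b_end, 0)


class TestThresholdSignal:

    def _bedgraph(self, tmp_path, rows):
        path = tmp_path / "s.bedGraph"
        path.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in rows))
        return path

    def test_boundary_inclusive(self, tmp_path):
        path = self._bedgraph(tmp_path, [("chr1", 0, 10, 20.0),
                                         ("chr1", 10, 20, 19.9)])
        regions = threshold_signal(path, 20)
        assert [(r.start, r.end) for r in regions] == [(0, 10)]

    def test_strict_comparator(self, tmp_path):
        path = self._bedgraph(tmp_path, [("chr1", 0, 10, 20.0)])
        assert threshold_signal(path, 20, comparator="gt") == []

    def test_bookended_merge(self, tmp_path):
        path = self._bedgraph(tmp_path, [("chr1", 0, 10, 25),
                                         ("chr1", 10, 20, 30)])
        regions = threshold_signal(path, 20)
        assert [(r.start, r.end) for r in regions] == [(0, 20)]

    def test_non_numeric_value_errors(self, tmp_path):
        path = tmp_path / "bad.bedGraph"
        path.write_text("chr1\t0\t10\thigh\n")
        with pytest.raises(BadInputError):
            threshold_signal(path, 20)

    def test_matches_per_base_oracle(self, tmp_path, rng):
        """Merged passing intervals equal per-base thresholding + run-length."""
        rows, pos = [], 0
        for _ in range(200):
            width = int(rng.integers(1, 30))
            rows.append(("chr1", pos, pos + width, float(rng.integers(0, 40))))
            pos += width
        regions = threshold_signal(self._bedgraph(tmp_path, rows), 20)

        base = np.zeros(pos)
        for _c, s, e, v in rows:
            base[s:e] = v
        mask = base >= 20
        runs, i = [], 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j < len(mask) and mask[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        assert [(r.start, r.end) for r in regions] == runs


class TestWindowJoin:

    def test_gap_within_window_kept(self):
        item = Item("chr1", 1000, 1009)
        region = GenomicInterval("chr1", 1150, 1200)
        assert window_join([item], [region], 200) == [item]  # gap 141

    def test_gap_beyond_window_dropped(self):
        item = Item("chr1", 1000, 1009)
        region = GenomicInterval("chr1", 1300, 1350)
        assert window_join([item], [region], 200) == []  # gap 291

    def test_gap_exactly_w_kept(self):
        item = Item("chr1", 1000, 1009)
        for region in (GenomicInterval("chr1", 1209, 1300),
                       GenomicInterval("chr1", 700, 800)):
            assert window_join([item], [region], 200) == [item]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(5)
        items = [Item("chr1", s, s + 9)
                 for s in rng.integers(0, 50_000, size=1500)]
        regions = [GenomicInterval("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 50_000, size=400),
                                   rng.integers(1, 500, size=400))]
        kept = window_join(items, regions, 200)
        expected = [it for it in items
                    if any(gap(it.start, it.end, r.start, r.end) <= 200
                           for r in regions)]
        assert kept == expected


class TestNeighborGeneFilter:

    def test_immune_flank_kept_and_annotated(self):
        genes = [GeneModel("gL", "L", "chr1", "+", 45_000, immune=True),
                 GeneModel("gR", "R", "chr1", "+", 60_000, immune=False)]
        cand = Item("chr1", 50_000, 50_009)
        kept = neighbor_gene_filter([cand], genes)
        assert kept == [cand]
        assert cand.nearest_gene == "gL"
        assert cand.nearest_gene_distance == 5000

    def test_both_flanks_non_immune_dropped(self):
        genes = [GeneModel("gL", "L", "chr1", "+", 45_000),
                 GeneModel("gR", "R", "chr1", "+", 60_000)]
        assert neighbor_gene_filter([Item("chr1", 50_000, 50_009)], genes) == []

    def test_immune_gene_two_away_does_not_count(self):
        """Only the two flanking genes matter, not any immune gene nearby."""
        genes = [GeneModel("far", "F", "chr1", "+", 44_000, immune=True),
                 GeneModel("gL", "L", "chr1", "+", 45_000),
                 GeneModel("gR", "R", "chr1", "+", 60_000)]
        assert neighbor_gene_filter([Item("chr1", 50_000, 50_009)], genes) == []

    def test_chromosome_without_genes_drops(self):
        genes = [GeneModel("g", "G", "chr2", "+", 100, immune=True)]
        assert neighbor_gene_filter([Item("chr1", 500, 509)], genes) == []

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        genes = [GeneModel(f"g{i}", f"g{i}", "chr1", "+", int(t),
                           immune=bool(rng.random() < 0.5))
                 for i, t in enumerate(sorted(rng.choice(
                     200_000, size=50, replace=False)))]
        cands = [Item("chr1", int(p), int(p) + 9)
                 for p in rng.integers(0, 200_000, size=1000)]
        kept = neighbor_gene_filter(list(cands), genes)

        expected = []
        for c in cands:
            left = [g for g in genes if g.tss <= c.snp_pos0]
            right = [g for g in genes if g.tss > c.snp_pos0]
            flanks = []
            if left:
                flanks.append(max(left, key=lambda g: g.tss))
            if right:
                flanks.append(min(right, key=lambda g: g.tss))
            if any(g.immune for g in flanks):
                expected.append(c)
        assert kept == expected


class TestUpstreamTssFilter:

    def test_plus_strand_upstream_kept(self):
        gene = GeneModel("g", "G", "chr1", "+", 20_000, immune=True)
        cand = Item("chr1", 15_000, 15_009)
        kept = upstream_tss_filter([cand], [gene], 10_000)
        assert kept == [cand]
        assert cand.distance_to_tss == 5000
        assert cand.upstream_gene == "g"

    def test_plus_strand_downstream_dropped(self):
        gene = GeneModel("g", "G", "chr1", "+", 20_000, immune=True)
        assert upstream_tss_filter([Item("chr1", 20_500, 20_509)],
                                   [gene], 10_000) == []

    def test_minus_strand_upstream_kept(self):
        gene = GeneModel("g", "G", "chr1", "-", 20_000, immune=True)
        cand = Item("chr1", 25_000, 25_009)
        assert upstream_tss_filter([cand], [gene], 10_000) == [cand]
        assert cand.distance_to_tss == 5000

    def test_non_immune_gene_window_ignored(self):
        gene = GeneModel("g", "G", "chr1", "+", 20_000, immune=False)
        assert upstream_tss_filter([Item("chr1", 15_000, 15_009)],
                                   [gene], 10_000) == []

    def test_span_must_be_positive(self):
        with pytest.raises(BadInputError):
            upstream_tss_filter([], [], 0)

    def test_strand_reflection(self):
        """Mirroring the chromosome and flipping strands preserves the result."""
        rng = np.random.default_rng(11)
        N = 100_000
        genes = [GeneModel(f"g{i}", f"g{i}", "chr1",
                           "+" if rng.random() < 0.5 else "-",
                           int(t), immune=True)
                 for i, t in enumerate(rng.integers(100, N - 100, size=30))]
        cands = [Item("chr1", int(p), int(p) + 1)
                 for p in rng.integers(0, N, size=500)]
        kept = upstream_tss_filter(list(cands), genes, 10_000)

        flip = {"+": "-", "-": "+"}
        genes_m = [GeneModel(g.gene_id, g.symbol, "chr1", flip[g.strand],
                             N - 1 - g.tss, immune=True) for g in genes]
        cands_m = [Item("chr1", N - 1 - c.snp_pos0, N - c.snp_pos0)
                   for c in cands]
        kept_m = upstream_tss_filter(list(cands_m), genes_m, 10_000)
        assert {c.snp_pos0 for c in kept} == \
            {N - 1 - c.snp_pos0 for c in kept_m}


class TestSpacingFilter:

    def _gas(self, start, chrom="chr1"):
        from gasfunnel.sequence_scan import MotifHit
        return MotifHit(chrom, start, start + 9, "GAS", "TTCAAAGAA")

    def test_near_canonical_hit_removed(self):
        cand = Item("chr1", 5100, 5109)
        assert spacing_filter([cand], [self._gas(5000)], 200) == []  # gap 91

    def test_distant_canonical_hit_kept(self):
        cand = Item("chr1", 5300, 5309)
        assert spacing_filter([cand], [self._gas(5000)], 200) == [cand]

    def test_clustered_candidates_both_removed(self):
        a, b = Item("chr1", 5000, 5009), Item("chr1", 5059, 5068)
        assert spacing_filter([a, b], [], 200, drop_clustered=True) == []

    def test_cluster_drop_toggle(self):
        a, b = Item("chr1", 5000, 5009), Item("chr1", 5059, 5068)
        assert spacing_filter([a, b], [], 200, drop_clustered=False) == [a, b]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)
        cands = [Item("chr1", int(s), int(s) + 9)
                 for s in rng.integers(0, 300_000, size=800)]
        gas = [self._gas(int(s)) for s in rng.integers(0, 300_000, size=300)]
        kept = spacing_filter(list(cands), gas, 200, drop_clustered=True)

        expected = []
        for c in cands:
            if any(gap(c.start, c.end, g.start, g.end) <= 200 for g in gas):
                continue
            if any(o is not c and gap(c.start, c.end, o.start, o.end) <= 200
                   for o in cands):
                continue
            expected.append(c)
        assert kept == expected


class TestFilterAlgebra:

    def test_filters_return_subsets(self, rng):
        items = [Item("chr1", int(s), int(s) + 9)
                 for s in rng.integers(0, 10_000, size=100)]
        regions = [GenomicInterval("chr1", 4000, 4200)]
        genes = [GeneModel("g", "G", "chr1", "+", 5000, immune=True)]
        for result in (window_join(list(items), regions, 200),
                       neighbor_gene_filter(list(items), genes),
                       upstream_tss_filter(list(items), genes, 10_000),
                       spacing_filter(list(items), [], 200)):
            assert set(map(id, result)) <= set(map(id, items))


class TestGeneIngest:

    def test_gtf_transcript_tss_most_five_prime(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\tgene\t1001\t5000\t.\t+\t.\tgene_id "g1"; gene_name "A";\n'
            'chr1\tx\ttranscript\t1201\t5000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tx\ttranscript\t1101\t4000\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tx\tgene\t8001\t9000\t.\t-\t.\tgene_id "g2"; gene_name "B";\n')
        genes = {g.gene_id: g for g in read_gtf(gtf)}
        # transcripts take precedence; most 5' start on + is the smallest
        assert genes["g1"].tss == 1100
        assert genes["g1"].symbol == "A"
        # minus strand: TSS is the end coordinate (0-based)
        assert genes["g2"].tss == 8999

    def test_tss_bed(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t100\t101\tg1\t0\t+\nchr1\t200\t201\tg2\t0\t-\n")
        genes = {g.gene_id: g for g in read_tss_bed(bed)}
        assert genes["g1"].tss == 100
        assert genes["g2"].tss == 200

    def test_set_immune_flags_by_symbol_or_id(self):
        genes = [GeneModel("g1", "IRF3", "chr1", "+", 0),
                 GeneModel("g2", "OTHER", "chr1", "+", 10)]
        set_immune_flags(genes, {"IRF3", "g2"})
        assert [g.immune for g in genes] == [True, True]


def test_upstream_window_arithmetic():
    assert upstream_window(20_000, "+", 10_000) == (10_000, 20_000)
    assert upstream_window(20_000, "-", 10_000) == (20_001, 30_001)
    assert upstream_window(5_000, "+", 10_000) == (0, 5_000)
    assert upstream_window(20_000, "-", 10_000, chrom_len=25_000) == \
        (20_001, 25_000)
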