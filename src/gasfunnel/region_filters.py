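"""Interval-based funnel stages.

Four filters narrow the candidate pool using genomic context:

* ``threshold_signal`` / ``window_join`` — keep candidates whose motif lies
  in or near (gap <= w, default 200 bp) an open-chromatin region, where
  regions are H3K27ac bedGraph intervals with signal >= 20 (or pre-called
  peaks).  The 200 bp window reflects the peak-valley-peak geometry of
  acetylation around a bound transcription factor.
* ``neighbor_gene_filter`` — keep candidates whose nearest flanking gene
  (by TSS distance, either side, strand-agnostic) is an immune gene.
* ``upstream_tss_filter`` — keep candidates whose SNP lies in the
  strand-aware 10 kb window upstream of an immune gene's TSS, the
  promoter/enhancer-proximal search space.
* ``spacing_filter`` — drop candidates within 200 bp of an existing intact
  GAS motif (a second STAT dimer could not bind there) and, optionally,
  whole clusters of mutually close candidates.

All filters return subsets of their input and annotate in place.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import BadInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval with an optional numeric signal value."""

    chrom: str
    start: int
    end: int
    value: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise BadInputError(
                f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class GeneModel:
    """One gene with a single deterministic TSS.

    For multi-transcript genes the TSS is the most 5' transcript start on
    the gene's strand.  ``tss`` is a 0-based position of the first
    transcribed base.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    immune: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise BadInputError(f"gene {self.gene_id}: bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# ingest


def threshold_signal(bedgraph_path, min_signal: float = 20,
                     comparator: str = "ge") -> list[GenomicInterval]:
    """Open-chromatin regions: bedGraph intervals passing the signal cutoff.

    Adjacent (bookended or overlapping) passing intervals on the same
    chromosome are merged.  ``comparator`` "ge" keeps value >= cutoff (the
    default, "a signal of 20 or higher"); "gt" keeps strictly greater.
    """
    df = pd.read_csv(bedgraph_path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    try:
        values = df["value"].astype(float)
    except ValueError as exc:
        raise BadInputError(f"non-numeric value column in {bedgraph_path}: "
                            f"{exc}") from exc
    if comparator == "ge":
        keep = df[values >= min_signal]
    elif comparator == "gt":
        keep = df[values > min_signal]
    else:
        raise BadInputError(f"unknown comparator {comparator!r}")
    keep = keep.sort_values(["chrom", "start"])

    merged: list[GenomicInterval] = []
    for row in keep.itertuples(index=False):
        if merged and merged[-1].chrom == row.chrom and row.start <= merged[-1].end:
            prev = merged.pop()
            merged.append(GenomicInterval(prev.chrom, prev.start,
                                          max(prev.end, int(row.end))))
        else:
            merged.append(GenomicInterval(row.chrom, int(row.start),
                                          int(row.end), float(row.value)))
    return merged


def read_peaks_bed(path) -> list[GenomicInterval]:
    """Pre-called peak BED (>=3 columns) as open-chromatin regions."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BadInputError(f"{path}:{ln}: expected >=3 BED columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


_GTF_ATTR = re.compile(r'(\w+)[ =]+"?([^";]+)"?')


def read_gtf(path, id_attr: str = "gene_id",
             name_attr: str = "gene_name") -> list[GeneModel]:
    """Gene models from GTF/GFF3, one TSS per gene.

    Transcript features are preferred for TSS derivation when present,
    falling back to gene features; the TSS is the most 5' transcript start
    on the gene's strand.
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise BadInputError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "transcript", "mRNA"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gid = attr.get(id_attr)
            if gid is None:
                raise BadInputError(f"{path}:{ln}: missing attribute {id_attr!r}")
            entry = per_gene.setdefault(gid, {
                "chrom": chrom, "strand": strand,
                "symbol": attr.get(name_attr, gid),
                "gene_starts": [], "tx_starts": []})
            if name_attr in attr:
                entry["symbol"] = attr[name_attr]
            five_prime = int(start) - 1 if strand == "+" else int(end) - 1
            key = "gene_starts" if feature == "gene" else "tx_starts"
            entry[key].append(five_prime)

    genes = []
    for gid, entry in per_gene.items():
        starts = entry["tx_starts"] or entry["gene_starts"]
        tss = min(starts) if entry["strand"] == "+" else max(starts)
        genes.append(GeneModel(gid, entry["symbol"], entry["chrom"],
                               entry["strand"], tss))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def read_tss_bed(path) -> list[GeneModel]:
    """6-column TSS BED: chrom, start, end, gene_id, score, strand."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise BadInputError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            tss = int(start) if strand == "+" else int(end) - 1
            genes.append(GeneModel(name, name, chrom, strand, tss))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def set_immune_flags(genes: Iterable[GeneModel],
                     immune_names: set[str]) -> None:
    """Mark genes whose symbol or id is in the immune gene set."""
    for g in genes:
        g.immune = g.symbol in immune_names or g.gene_id in immune_names


# ---------------------------------------------------------------------------
# filters

_DefaultInterval = Callable[[object], tuple[str, int, int]]


def _default_interval(item) -> tuple[str, int, int]:
    if hasattr(item, "motif_start"):
        return item.chrom, item.motif_start, item.motif_end
    return item.chrom, item.start, item.end


def _region_trees(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def window_join(items: Sequence, regions: Iterable[GenomicInterval],
                w: int = 200,
                interval: _DefaultInterval = _default_interval) -> list:
    """Keep items whose interval is within ``w`` bp of some region.

    Symmetric gap rule: an item is kept iff the gap between its interval and
    the nearest region is <= w (overlap counts as gap 0); this is the
    item-extended-by-w overlap test of ``bedtools window -w``.
    """
    trees = _region_trees(regions)
    kept = []
    for item in items:
        chrom, start, end = interval(item)
        tree = trees.get(chrom)
        # query [start-w-1, end+w+1) so that regions with gap exactly w,
        # on either side, still register as overlaps
        if tree is not None and tree.overlap(start - w - 1, end + w + 1):
            kept.append(item)
    return kept


def neighbor_gene_filter(candidates: Sequence, genes: Sequence[GeneModel],
                         annotate: bool = True) -> list:
    """Keep candidates whose nearest flanking gene on either side is immune.

    For each candidate the nearest gene by TSS distance is found on each
    side (strand-agnostic); the candidate survives iff at least one of the
    two is an immune gene, and is annotated with that gene and the signed
    distance (SNP position minus TSS).  Candidates on chromosomes without
    any gene are dropped and logged.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
    tss_by_chrom = {c: [g.tss for g in glist] for c, glist in by_chrom.items()}

    kept = []
    n_no_genes = 0
    for cand in candidates:
        glist = by_chrom.get(cand.chrom)
        if not glist:
            n_no_genes += 1
            continue
        pos = cand.snp_pos0
        tss_list = tss_by_chrom[cand.chrom]
        i = bisect.bisect_right(tss_list, pos)
        left = glist[i - 1] if i > 0 else None
        right = glist[i] if i < len(glist) else None
        flanks = [g for g in (left, right) if g is not None]
        immune_flanks = [g for g in flanks if g.immune]
        if not immune_flanks:
            continue
        best = min(immune_flanks, key=lambda g: abs(pos - g.tss))
        if annotate:
            cand.nearest_gene = best.gene_id
            cand.nearest_gene_distance = pos - best.tss
            cand.provenance.append("immune_neighbor")
        kept.append(cand)
    if n_no_genes:
        logger.warning("neighbor_gene_filter: dropped %d candidates on "
                       "chromosomes with no genes", n_no_genes)
    return kept


def upstream_window(tss: int, strand: str, span: int,
                    chrom_len: int | None = None) -> tuple[int, int]:
    """Half-open strand-aware upstream window of a TSS.

    Plus strand: [tss - span, tss); minus strand: [tss + 1, tss + span + 1).
    Clipped to [0, chrom_len) when a chromosome length is given.  This is
    the single window-arithmetic code path shared by the 10 kb upstream
    filter and the cross-species conservation check.
    """
    if span <= 0:
        raise BadInputError(f"span must be positive, got {span}")
    if strand == "+":
        lo, hi = tss - span, tss
    else:
        lo, hi = tss + 1, tss + span + 1
    lo = max(lo, 0)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return lo, hi


def upstream_tss_filter(candidates: Sequence, genes: Sequence[GeneModel],
                        span: int = 10000, annotate: bool = True) -> list:
    """Keep candidates whose SNP lies <= ``span`` bp upstream of an immune TSS.

    Annotates the closest qualifying gene and the (positive) distance from
    SNP to TSS.
    """
    if span <= 0:
        raise BadInputError(f"span must be positive, got {span}")
    immune = [g for g in genes if g.immune]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in immune:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))

    kept = []
    for cand in candidates:
        pos = cand.snp_pos0
        best_gene, best_dist = None, None
        for g in by_chrom.get(cand.chrom, ()):
            if abs(g.tss - pos) > span + 1:
                continue
            lo, hi = upstream_window(g.tss, g.strand, span)
            if lo <= pos < hi:
                dist = (g.tss - pos) if g.strand == "+" else (pos - g.tss)
                if best_dist is None or dist < best_dist:
                    best_gene, best_dist = g, dist
        if best_gene is None:
            continue
        if annotate:
            cand.upstream_gene = best_gene.gene_id
            cand.distance_to_tss = best_dist
            cand.provenance.append(f"upstream_{span}")
        kept.append(cand)
    return kept


def spacing_filter(candidates: Sequence, gas_hits: Sequence,
                   w: int = 200, drop_clustered: bool = True,
                   annotate: bool = True) -> list:
    """Drop candidates too close to intact GAS motifs or to each other.

    A candidate is removed when the gap between its motif interval and any
    canonical GAS hit is <= ``w``.  With ``drop_clustered``, every member of
    a group of candidate motifs mutually within ``w`` bp is also removed —
    no ranking rule exists to prefer one member over another.
    """
    gas_trees = _region_trees(
        GenomicInterval(h.chrom, h.start, h.end) for h in gas_hits)

    by_chrom: dict[str, list] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chrom, []).append(cand)

    kept = []
    for cand in candidates:
        tree = gas_trees.get(cand.chrom)
        if tree is not None and tree.overlap(cand.motif_start - w - 1,
                                             cand.motif_end + w + 1):
            continue
        if drop_clustered:
            clustered = any(
                other is not cand
                and other.motif_start <= cand.motif_end + w
                and other.motif_end >= cand.motif_start - w
                for other in by_chrom[cand.chrom])
            if clustered:
                continue
        if annotate:
            cand.provenance.append(f"spacing_{w}")
        kept.append(cand)
    return kept
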