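"""Joining catalogued SNPs to motif hits: gain- and loss-of-function calls.

A gain-of-function (GOF) candidate is a catalogued single-nucleotide variant
whose alternate allele sits exactly at the deviant position of a
near-complete GAS hit and equals the plus-strand restoring allele — i.e. the
variant completes an intact TTCnnnGAA motif.  A loss-of-function (LOF)
candidate breaks one of the six fixed bases of an intact motif.

VCF input is 1-based; all library coordinates are 0-based half-open, and the
conversion happens only here and in the writers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam

from ._util import BadInputError, normalize_chrom
from .motif_model import CANONICAL_BASE, FIXED_OFFSETS
from .sequence_scan import MotifHit

logger = logging.getLogger(__name__)

_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One catalogued SNP (multi-allelic records arrive pre-expanded).

    ``pos`` is the 1-based VCF position; ``evidence_count`` is the number of
    independent supporting sources (for dbSNP, the number of frequency
    studies listed in the INFO FREQ field) used as a proxy for the number of
    human subjects the allele was observed in.
    """

    chrom: str
    pos: int
    rsid: str
    ref: str
    alts: tuple[str, ...]
    evidence_count: int = 0

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def pos0(self) -> int:
        """0-based genomic position."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return self.ref in _SNV_BASES and all(a in _SNV_BASES for a in self.alts)


@dataclass
class GofCandidate:
    """A (motif hit, variant) pair where the alt completes a GAS motif."""

    hit: MotifHit
    variant: VariantRecord
    completed_kmer: str
    provenance: list[str] = field(default_factory=lambda: ["snp_gof"])
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None
    upstream_gene: str | None = None
    distance_to_tss: int | None = None
    conserved: bool | None = None
    known: bool | None = None

    @property
    def chrom(self) -> str:
        return self.hit.chrom

    @property
    def snp_pos0(self) -> int:
        return self.variant.pos0

    @property
    def motif_start(self) -> int:
        return self.hit.start

    @property
    def motif_end(self) -> int:
        return self.hit.end

    @property
    def class_name(self) -> str:
        return self.hit.class_name


@dataclass
class LofCandidate:
    """A variant breaking a fixed position of an intact GAS motif."""

    hit: MotifHit
    variant: VariantRecord
    broken_kmer: str


class VCFReader:
    """Stream SNV VariantRecords from a VCF, expanding multi-allelic sites.

    Non-SNV alleles (indels, MNVs, symbolic or missing alts) are excluded
    from candidacy and tallied in ``n_skipped_non_snv``.  Evidence counts
    come from ``evidence_key``: for the dbSNP-style ``FREQ`` field the count
    is the number of '|'-separated frequency studies; any other key is read
    as an integer.  Chromosome names are normalized on ingest.
    """

    def __init__(self, path, evidence_key: str = "FREQ",
                 chrom_style: str | None = None,
                 chrom_aliases: dict[str, str] | None = None):
        self.path = str(path)
        self.evidence_key = evidence_key
        self.chrom_style = chrom_style
        self.chrom_aliases = chrom_aliases
        self.n_skipped_non_snv = 0
        self.n_records = 0

    def _evidence(self, rec) -> int:
        try:
            value = rec.info.get(self.evidence_key)
        except (KeyError, ValueError):
            # evidence key not declared in this VCF's header
            return 0
        if value is None:
            return 0
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        value = str(value)
        if self.evidence_key == "FREQ":
            return value.count("|") + 1 if value else 0
        try:
            return int(value)
        except ValueError as exc:
            raise BadInputError(
                f"INFO/{self.evidence_key} is not an integer: {value!r}") from exc

    def __iter__(self) -> Iterator[VariantRecord]:
        try:
            vcf = pysam.VariantFile(self.path)
        except (OSError, ValueError) as exc:
            raise BadInputError(f"cannot read VCF {self.path}: {exc}") from exc
        with vcf:
            for rec in vcf:
                self.n_records += 1
                chrom = rec.chrom
                if self.chrom_style or self.chrom_aliases:
                    chrom = normalize_chrom(chrom, self.chrom_style or "chr",
                                            self.chrom_aliases)
                evidence = self._evidence(rec)
                rsid = rec.id or f"{chrom}:{rec.pos}"
                for alt in rec.alts or ():
                    record = VariantRecord(chrom, rec.pos, rsid, rec.ref,
                                           (alt,), evidence)
                    if not record.is_snv:
                        self.n_skipped_non_snv += 1
                        continue
                    yield record


def read_vcf(path, evidence_key: str = "FREQ", **kwargs) -> list[VariantRecord]:
    """Read a whole VCF into a list of expanded SNV records."""
    return list(VCFReader(path, evidence_key=evidence_key, **kwargs))


def candidate_gof(hits: Iterable[MotifHit],
                  variants: Iterable[VariantRecord]) -> list[GofCandidate]:
    """Emit one candidate per (hit, variant, alt) triple completing a motif.

    A variant whose REF disagrees with the genome base at the deviant
    position signals a genome/catalogue build mismatch: it is skipped with a
    warning rather than silently matched.
    """
    index: dict[tuple[str, int], list[MotifHit]] = {}
    for hit in hits:
        if hit.deviant_pos is None:
            continue  # canonical hits cannot gain function
        index.setdefault((hit.chrom, hit.deviant_pos), []).append(hit)

    candidates: list[GofCandidate] = []
    for var in variants:
        for hit in index.get((var.chrom, var.pos0), ()):
            offset = hit.deviant_pos - hit.start
            genome_base = hit.kmer[offset]
            if var.ref != genome_base:
                warnings.warn(
                    f"{var.rsid} at {var.chrom}:{var.pos}: REF {var.ref!r} "
                    f"disagrees with genome base {genome_base!r}; skipping "
                    "(genome/catalogue build mismatch?)", stacklevel=2)
                continue
            for alt in var.alts:
                if alt != hit.restore_allele_plus:
                    continue
                completed = hit.kmer[:offset] + alt + hit.kmer[offset + 1:]
                candidates.append(GofCandidate(hit, var, completed))
    candidates.sort(key=lambda c: (c.chrom, c.motif_start, c.variant.pos,
                                   c.variant.alt))
    return candidates


def candidate_lof(gas_hits: Iterable[MotifHit],
                  variants: Iterable[VariantRecord]) -> list[LofCandidate]:
    """Emit variants whose alt breaks a fixed position of a canonical hit.

    Variants falling on the three free middle bases never qualify; at a
    fixed position every alt different from the canonical base destroys the
    motif (each fixed position admits exactly one base).
    """
    index: dict[tuple[str, int], list[tuple[MotifHit, int]]] = {}
    for hit in gas_hits:
        if hit.class_name != "GAS":
            raise BadInputError("candidate_lof expects canonical GAS hits only")
        for off in FIXED_OFFSETS:
            index.setdefault((hit.chrom, hit.start + off), []).append((hit, off))

    out: list[LofCandidate] = []
    for var in variants:
        for hit, off in index.get((var.chrom, var.pos0), ()):
            if var.ref != hit.kmer[off]:
                warnings.warn(
                    f"{var.rsid} at {var.chrom}:{var.pos}: REF {var.ref!r} "
                    f"disagrees with genome base {hit.kmer[off]!r}; skipping",
                    stacklevel=2)
                continue
            for alt in var.alts:
                if alt == CANONICAL_BASE[off]:
                    continue
                broken = hit.kmer[:off] + alt + hit.kmer[off + 1:]
                out.append(LofCandidate(hit, var, broken))
    out.sort(key=lambda c: (c.hit.chrom, c.hit.start, c.variant.pos,
                            c.variant.alt))
    return out


def evidence_filter(candidates: list[GofCandidate],
                    min_subjects: int = 2) -> list[GofCandidate]:
    """Keep candidates supported by at least ``min_subjects`` sources."""
    kept = [c for c in candidates if c.variant.evidence_count >= min_subjects]
    for c in kept:
        c.provenance.append(f"evidence_ge{min_subjects}")
    return kept


_TSV_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "class", "motif_start",
                "motif_end", "completed_kmer", "evidence_count",
                "nearest_gene", "nearest_gene_distance", "upstream_gene",
                "distance_to_tss", "conserved", "known", "provenance"]


def candidates_to_frame(candidates: list[GofCandidate]) -> pd.DataFrame:
    """Flatten candidates to a DataFrame with the canonical column order."""
    rows = []
    for c in candidates:
        rows.append({
            "rsid": c.variant.rsid,
            "chrom": c.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "class": c.class_name,
            "motif_start": c.motif_start,
            "motif_end": c.motif_end,
            "completed_kmer": c.completed_kmer,
            "evidence_count": c.variant.evidence_count,
            "nearest_gene": c.nearest_gene,
            "nearest_gene_distance": c.nearest_gene_distance,
            "upstream_gene": c.upstream_gene,
            "distance_to_tss": c.distance_to_tss,
            "conserved": c.conserved,
            "known": c.known,
            "provenance": ",".join(c.provenance),
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_candidates_tsv(candidates: list[GofCandidate], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False,
                                           na_rep=".")


def write_candidates_bed(candidates: list[GofCandidate], path) -> None:
    """Motif intervals of candidates as BED4 (name = rsid) for interval tools."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.motif_start}\t{c.motif_end}\t{c.variant.rsid}\n")


def _opt(value, conv):
    if value is None or (isinstance(value, float) and pd.isna(value)) \
            or value in (".", ""):
        return None
    return conv(value)


def read_candidates_tsv(path) -> list[GofCandidate]:
    """Reconstruct candidates from a stage TSV (for resuming / CLI stages)."""
    from .motif_model import build_gas_classes

    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False,
                     dtype=str)
    by_name = {c.name: c for c in build_gas_classes()}
    out = []
    for row in df.to_dict("records"):
        cls = by_name[row["class"]]
        start, end = int(row["motif_start"]), int(row["motif_end"])
        kmer = row["completed_kmer"]
        if not cls.is_canonical:
            off = cls.deviant_offset
            kmer = kmer[:off] + row["ref"] + kmer[off + 1:]
        hit = MotifHit(row["chrom"], start, end, cls.name, kmer,
                       deviant_pos=None if cls.is_canonical else start + cls.deviant_offset,
                       restore_allele_plus=cls.restore_base)
        var = VariantRecord(row["chrom"], int(row["pos"]), row["rsid"],
                            row["ref"], (row["alt"],),
                            int(row["evidence_count"]))
        cand = GofCandidate(hit, var, row["completed_kmer"],
                            provenance=str(row["provenance"]).split(","))
        cand.nearest_gene = _opt(row["nearest_gene"], str)
        cand.nearest_gene_distance = _opt(row["nearest_gene_distance"],
                                          lambda v: int(float(v)))
        cand.upstream_gene = _opt(row["upstream_gene"], str)
        cand.distance_to_tss = _opt(row["distance_to_tss"],
                                    lambda v: int(float(v)))
        cand.conserved = _opt(row["conserved"], lambda v: str(v) == "True")
        cand.known = _opt(row["known"], lambda v: str(v) == "True")
        out.append(cand)
    return out
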