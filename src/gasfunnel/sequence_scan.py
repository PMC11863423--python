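"""Genome scanning for canonical and near-complete GAS motif occurrences.

The scanner slides a 9-bp window over the plus strand of each sequence and
reports every window matching one of the seven motif classes.  Because the
class set is closed under reverse complement, plus-strand scanning with all
seven classes captures minus-strand occurrences as the partner class at the
same interval, and each genomic interval is reported exactly once.

Matching is vectorized: the sequence is encoded as small integers and each
class pattern is applied as a stack of per-offset boolean lookups, so the
inner loop never touches Python-level string comparison.  Independent
regex-based oracles in the test suite cross-check the results.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._util import BadInputError
from .motif_model import MotifClass, build_gas_classes

MOTIF_WIDTH = 9

# Base encoding: A,C,G,T -> 0..3 (case-insensitive, soft-masked bases are
# treated as their uppercase equivalents); everything else, including the
# assembly-gap 'N', -> 4, which no pattern position accepts.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    """A single motif occurrence on the plus strand of a sequence.

    Coordinates are 0-based half-open; ``end - start == 9`` always and
    ``kmer`` equals the (uppercased) plus-strand slice.  For non-canonical
    hits, ``deviant_pos`` is the absolute genomic position of the deviant
    base and ``restore_allele_plus`` the plus-strand base that would
    complete the canonical motif there.
    """

    chrom: str
    start: int
    end: int
    class_name: str
    kmer: str
    deviant_pos: int | None = None
    restore_allele_plus: str | None = None


def _class_lut(cls: MotifClass) -> np.ndarray:
    """(9, 5) boolean lookup: lut[offset, code] == base allowed at offset."""
    lut = np.zeros((MOTIF_WIDTH, 5), dtype=bool)
    for off, allowed in enumerate(cls.allowed):
        for base in allowed:
            lut[off, _CODE[ord(base)]] = True
    return lut


def scan_sequence(seq: str, chrom: str,
                  classes: list[MotifClass] | None = None) -> list[MotifHit]:
    """Report all class occurrences in ``seq``, sorted by start position.

    Overlapping hits (necessarily of different classes, at different starts)
    are all reported.  Sequences shorter than 9 bp yield no hits.
    """
    classes = classes if classes is not None else build_gas_classes()
    n = len(seq)
    if n < MOTIF_WIDTH:
        return []
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = n - MOTIF_WIDTH + 1
    upper = None  # uppercased lazily, only if there are hits
    hits: list[MotifHit] = []
    for cls in classes:
        lut = _class_lut(cls)
        valid = lut[0][codes[:n_win]]
        for off in range(1, MOTIF_WIDTH):
            valid &= lut[off][codes[off:off + n_win]]
        starts = np.nonzero(valid)[0]
        if starts.size and upper is None:
            upper = seq.upper()
        for i in starts.tolist():
            if cls.is_canonical:
                hits.append(MotifHit(chrom, i, i + MOTIF_WIDTH, cls.name,
                                     upper[i:i + MOTIF_WIDTH]))
            else:
                hits.append(MotifHit(chrom, i, i + MOTIF_WIDTH, cls.name,
                                     upper[i:i + MOTIF_WIDTH],
                                     deviant_pos=i + cls.deviant_offset,
                                     restore_allele_plus=cls.restore_base))
    hits.sort(key=lambda h: h.start)
    return hits


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a plain or gzip-compressed FASTA."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fasta"):
            yield record.id, str(record.seq)


def scan_fasta(fasta_path, classes: list[MotifClass] | None = None,
               out_bed_path=None, collect: bool = True):
    """Scan every sequence of a FASTA file, one sequence in memory at a time.

    Returns ``(tallies, hits)`` where ``tallies`` maps sequence name to a
    per-class hit Counter, and ``hits`` is the coordinate-sorted list of all
    hits (or ``None`` when ``collect`` is False, for genome-scale runs where
    only the BED output is wanted).  Duplicate sequence names are rejected.
    """
    classes = classes if classes is not None else build_gas_classes()
    tallies: dict[str, Counter] = {}
    all_hits: list[MotifHit] | None = [] if collect else None
    bed = open(out_bed_path, "w") if out_bed_path is not None else None
    try:
        for name, seq in iter_fasta(fasta_path):
            if name in tallies:
                raise BadInputError(f"duplicate sequence name in FASTA: {name!r}")
            hits = scan_sequence(seq, name, classes)
            tallies[name] = Counter(h.class_name for h in hits)
            if bed is not None:
                for h in hits:
                    bed.write(format_bed_line(h))
            if all_hits is not None:
                all_hits.extend(hits)
    finally:
        if bed is not None:
            bed.close()
    if not tallies:
        raise BadInputError(f"no sequences found in FASTA: {fasta_path}")
    return tallies, all_hits


def format_bed_line(hit: MotifHit) -> str:
    """BED6+3: chrom, start, end, class, score 0, strand +, kmer, deviant_pos, restore allele."""
    dev = "." if hit.deviant_pos is None else str(hit.deviant_pos)
    res = hit.restore_allele_plus or "."
    return (f"{hit.chrom}\t{hit.start}\t{hit.end}\t{hit.class_name}\t0\t+\t"
            f"{hit.kmer}\t{dev}\t{res}\n")


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(format_bed_line(h))


def read_hits_bed(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise BadInputError(f"{path}:{ln}: expected BED6+3, got "
                                    f"{len(fields)} columns")
            chrom, start, end, name, _score, _strand, kmer, dev, res = fields[:9]
            hits.append(MotifHit(
                chrom, int(start), int(end), name, kmer,
                deviant_pos=None if dev == "." else int(dev),
                restore_allele_plus=None if res == "." else res))
    return hits
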