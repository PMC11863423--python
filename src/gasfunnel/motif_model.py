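"""The GAS motif and its six single-deviation (near-complete) classes.

STAT transcription-factor dimers bind the palindromic gamma-interferon
activated site (GAS) consensus TTCnnnGAA: six fixed bases flanking three
unconstrained ones.  A near-complete GAS (ncGAS) motif deviates from the
consensus at exactly one of the six fixed positions, so a single nucleotide
substitution — the "restoring" substitution — converts it into an intact
GAS motif.  The six deviation families are named for the fixed base that is
wrong: T1, T2 (the two 5' thymines), C, G, A1, A2 (the two 3' adenines).

Patterns are degenerate IUPAC strings; each non-canonical class replaces one
fixed base with the IUPAC code for the three *other* nucleotides, which makes
the seven classes pairwise disjoint over 9-mers by construction.

Matching is implemented on explicit per-position allowed-base sets rather
than regular expressions, so that regex-based scanners can serve as
independent cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import BadInputError

#: IUPAC nucleotide codes mapped to the set of bases they allow.  A genome
#: 'N' is deliberately absent from every set: an ambiguous base never
#: supports a motif call, not even at an unconstrained pattern position.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAS_PATTERN = "TTCNNNGAA"

#: Offsets within the 9-mer that are constrained by the consensus.
FIXED_OFFSETS = (0, 1, 2, 6, 7, 8)

#: Canonical base at each fixed offset.
CANONICAL_BASE = {0: "T", 1: "T", 2: "C", 6: "G", 7: "A", 8: "A"}


@dataclass(frozen=True)
class MotifClass:
    """One of the seven motif families: canonical GAS or a deviation class.

    Parameters
    ----------
    name
        ``GAS`` or one of ``T1, T2, C, G, A1, A2``.
    pattern
        9-character IUPAC consensus.
    deviant_offset
        Offset (0-8) of the deviant fixed position; ``None`` for GAS.
    restore_base
        The base whose substitution at ``deviant_offset`` restores the
        canonical motif; ``None`` for GAS.
    """

    name: str
    pattern: str
    deviant_offset: int | None = None
    restore_base: str | None = None

    @property
    def is_canonical(self) -> bool:
        return self.deviant_offset is None

    @property
    def allowed(self) -> tuple[frozenset[str], ...]:
        """Per-position allowed-base sets derived from the IUPAC pattern."""
        return tuple(IUPAC_SETS[sym] for sym in self.pattern)

    def matches(self, kmer: str) -> bool:
        return iupac_matches(self.pattern, kmer)


def build_gas_classes() -> list[MotifClass]:
    """Return the canonical GAS class followed by the six deviation classes.

    The deviation patterns substitute, at one fixed offset, the IUPAC code
    for the complement set of the canonical base (V excludes T, D excludes C,
    H excludes G, B excludes A), so each class is disjoint from GAS and from
    every other class.
    """
    spec = [
        ("GAS", GAS_PATTERN, None, None),
        ("T1", "VTCNNNGAA", 0, "T"),
        ("T2", "TVCNNNGAA", 1, "T"),
        ("C", "TTDNNNGAA", 2, "C"),
        ("G", "TTCNNNHAA", 6, "G"),
        ("A1", "TTCNNNGBA", 7, "A"),
        ("A2", "TTCNNNGAB", 8, "A"),
    ]
    return [MotifClass(*row) for row in spec]


def iupac_matches(pattern: str, kmer: str) -> bool:
    """True iff every base of ``kmer`` is allowed at its pattern position.

    ``kmer`` must be uppercase A/C/G/T/N.  An 'N' (or any other non-ACGT
    symbol) in the kmer matches nothing, including pattern 'N'.
    """
    if len(pattern) != len(kmer):
        raise BadInputError(
            f"pattern length {len(pattern)} != kmer length {len(kmer)}")
    for sym, base in zip(pattern, kmer):
        if base not in IUPAC_SETS[sym]:
            return False
    return True


_REVCOMP_PARTNER = {
    "GAS": "GAS",
    "T1": "A2", "A2": "T1",
    "T2": "A1", "A1": "T2",
    "C": "G", "G": "C",
}


def revcomp_partner(class_name: str) -> str:
    """The class whose pattern is the reverse complement of the input's.

    The canonical motif is self-reverse-complementary, so a minus-strand
    occurrence of class X appears on the plus strand as its partner class at
    the same interval.  This closure is what lets the scanner work on the
    plus strand only.
    """
    try:
        return _REVCOMP_PARTNER[class_name]
    except KeyError:
        raise BadInputError(f"unknown motif class: {class_name!r}") from None


def restoring_substitution(kmer: str, motif_class: MotifClass) -> tuple[int, str]:
    """Return ``(offset, base)`` converting a class-matching 9-mer into GAS.

    Raises if the class is canonical (nothing to restore) or the kmer does
    not actually match the class pattern.
    """
    if motif_class.is_canonical:
        raise BadInputError("canonical GAS motif needs no restoration")
    if not iupac_matches(motif_class.pattern, kmer):
        raise BadInputError(
            f"kmer {kmer!r} does not match class {motif_class.name}")
    return motif_class.deviant_offset, motif_class.restore_base


def classify_kmer(kmer: str, classes: list[MotifClass] | None = None) -> MotifClass | None:
    """Return the unique class matching ``kmer``, or None.

    Uniqueness follows from pairwise disjointness of the class patterns.
    """
    for cls in classes or build_gas_classes():
        if iupac_matches(cls.pattern, kmer):
            return cls
    return None


def classes_to_tsv(classes: list[MotifClass], path) -> None:
    """Write the class table as TSV (name, pattern, deviant_offset, restore_base)."""
    with open(path, "w") as fh:
        fh.write("name\tpattern\tdeviant_offset\trestore_base\n")
        for cls in classes:
            off = "." if cls.deviant_offset is None else str(cls.deviant_offset)
            base = cls.restore_base or "."
            fh.write(f"{cls.name}\t{cls.pattern}\t{off}\t{base}\n")


def classes_to_meme(classes: list[MotifClass], path) -> None:
    """Export the classes as a MEME motif file.

    Each class becomes a letter-probability matrix with uniform probability
    over its allowed bases per position, suitable for consensus-style
    scanning with MEME-suite tools.
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for cls in classes:
            fh.write(f"MOTIF {cls.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(cls.pattern)} "
                     f"nsites= 20 E= 0\n")
            for allowed in cls.allowed:
                p = 1.0 / len(allowed)
                row = " ".join(f"{p if b in allowed else 0.0:.6f}" for b in "ACGT")
                fh.write(f" {row}\n")
            fh.write("\n")
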