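"""Shared helpers: errors, DNA utilities, chromosome-name normalization."""

from __future__ import annotations


class GasFunnelError(Exception):
    """Base class for all package errors."""


class BadInputError(GasFunnelError):
    """A user-supplied file or parameter is malformed or inconsistent."""


class InfeasibleConfigError(GasFunnelError):
    """A scenario or pipeline configuration cannot be satisfied."""


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_chrom(name: str, style: str = "chr", aliases: dict[str, str] | None = None) -> str:
    """Normalize a chromosome name to a consistent style.

    style "chr" prefixes bare names ("1" -> "chr1"); style "bare" strips the
    prefix. An explicit alias map takes precedence over the style rule.
    """
    if aliases and name in aliases:
        return aliases[name]
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "bare":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome-name style: {style!r}")
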