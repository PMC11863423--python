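"""Shared fixtures and independent oracles.

The oracles here are deliberately naive and regex/loop-based so they share
no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import re

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# Independent IUPAC table for oracle regexes (hand-written, not imported).
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "V": "ACG", "D": "AGT", "H": "ACT", "B": "CGT", "N": "ACGT",
}

ORACLE_PATTERNS = {
    "GAS": "TTCNNNGAA",
    "T1": "VTCNNNGAA",
    "T2": "TVCNNNGAA",
    "C": "TTDNNNGAA",
    "G": "TTCNNNHAA",
    "A1": "TTCNNNGBA",
    "A2": "TTCNNNGAB",
}

ORACLE_PARTNER = {"GAS": "GAS", "T1": "A2", "A2": "T1", "T2": "A1",
                  "A1": "T2", "C": "G", "G": "C"}

_ORACLE_RE = {
    name: re.compile(
        "(?=" + "".join(f"[{ORACLE_IUPAC[s]}]" for s in pat) + ")")
    for name, pat in ORACLE_PATTERNS.items()
}

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_scan_plus(seq: str) -> set[tuple[int, str]]:
    """Plus-strand occurrences of all seven classes, by lookahead regex."""
    seq = seq.upper()
    out = set()
    for name, pattern in _ORACLE_RE.items():
        out.update((m.start(), name) for m in pattern.finditer(seq))
    return out


def oracle_scan_both_strands(seq: str) -> set[tuple[int, str]]:
    """Both-strand regex scan, minus-strand hits mapped back to plus.

    A minus-strand occurrence of class X at reverse-complement offset j
    corresponds to the plus-strand interval starting at len(seq) - 9 - j
    and reads, on the plus strand, as the reverse-complement partner of X.
    """
    seq = seq.upper()
    n = len(seq)
    out = set(oracle_scan_plus(seq))
    rc = oracle_revcomp(seq)
    for name, pattern in _ORACLE_RE.items():
        for m in pattern.finditer(rc):
            out.add((n - 9 - m.start(), ORACLE_PARTNER[name]))
    return out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def scenario(tmp_path):
    """A default synthetic scenario bundle (seed 42) plus its truth table."""
    from gasfunnel.fixtures import ScenarioConfig, generate_scenario

    bundle, truth = generate_scenario(ScenarioConfig(), seed=42,
                                      outdir=tmp_path / "scn")
    return bundle, truth


def funnel_config_for(bundle, **overrides):
    """FunnelConfig wired to a scenario bundle's files."""
    from gasfunnel.funnel import FunnelConfig

    kwargs = dict(
        genome_fasta=bundle["genome_fasta"], vcf=bundle["vcf"],
        signal_bedgraph=bundle["signal_bedgraph"],
        genes_gtf=bundle["genes_gtf"], gene_list=bundle["gene_list"],
        orthologs=bundle["orthologs"],
        genome2_fasta=bundle["genome2_fasta"],
        genome2_gtf=bundle["genome2_gtf"])
    kwargs.update(overrides)
    return FunnelConfig(**kwargs)
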