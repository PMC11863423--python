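"""Cross-species motif conservation in orthologous upstream regions.

A candidate passes when the upstream window (default 10 kb, strand-aware)
of an ortholog's TSS in the second genome contains a qualifying motif hit.
What "qualifying" means is configurable because the biological reading is
genuinely ambiguous:

* ``same_class`` (default) — a hit of the identical near-GAS class;
* ``any_ncgas``  — any non-canonical class hit (superset of same_class);
* ``canonical``  — an intact GAS motif.

Window arithmetic is shared with the primary-genome upstream filter
(:func:`gasfunnel.region_filters.upstream_window`), and extracted windows
are scanned on the plus strand only — the class set is closed under reverse
complement, so minus-strand occurrences need no special casing.
"""

from __future__ import annotations

import logging
from typing import Sequence

from pyfaidx import Fasta

from ._util import BadInputError
from .motif_model import MotifClass, build_gas_classes
from .region_filters import GeneModel, upstream_window
from .sequence_scan import scan_sequence

logger = logging.getLogger(__name__)

MATCH_MODES = ("same_class", "any_ncgas", "canonical")


def read_orthologs(path) -> dict[str, list[str]]:
    """2-column TSV (gene_id_1, gene_id_2); one-to-many maps allowed."""
    pairs: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise BadInputError(f"{path}:{ln}: expected 2 columns")
            pairs.setdefault(fields[0], []).append(fields[1])
    return pairs


def _qualifies(hits, candidate_class: str, match_mode: str) -> bool:
    if match_mode == "same_class":
        return any(h.class_name == candidate_class for h in hits)
    if match_mode == "any_ncgas":
        return any(h.class_name != "GAS" for h in hits)
    if match_mode == "canonical":
        return any(h.class_name == "GAS" for h in hits)
    raise BadInputError(f"unknown match_mode {match_mode!r}; "
                        f"expected one of {MATCH_MODES}")


def conservation_filter(candidates: Sequence, ortholog_map: dict[str, list[str]],
                        genome2_fasta, genes2: Sequence[GeneModel],
                        span: int = 10000, match_mode: str = "same_class",
                        classes: list[MotifClass] | None = None,
                        annotate: bool = True) -> list:
    """Keep candidates whose ortholog upstream window holds a qualifying hit.

    A candidate with several orthologs is conserved if ANY ortholog window
    qualifies.  Candidates without an ortholog are dropped and counted
    separately from "ortholog present but motif absent".
    """
    if match_mode not in MATCH_MODES:
        raise BadInputError(f"unknown match_mode {match_mode!r}; "
                            f"expected one of {MATCH_MODES}")
    classes = classes if classes is not None else build_gas_classes()
    fasta = Fasta(str(genome2_fasta))
    genes2_by_id = {g.gene_id: g for g in genes2}

    kept = []
    n_no_ortholog = 0
    n_not_conserved = 0
    for cand in candidates:
        target_gene = cand.upstream_gene or cand.nearest_gene
        if target_gene is None:
            raise BadInputError(
                f"candidate {cand.variant.rsid} has no target gene annotation; "
                "run the gene-proximity stages first")
        orthologs = ortholog_map.get(target_gene, [])
        if not orthologs:
            n_no_ortholog += 1
            if annotate:
                cand.conserved = False
            continue
        conserved = False
        for orth_id in orthologs:
            gene2 = genes2_by_id.get(orth_id)
            if gene2 is None:
                raise BadInputError(
                    f"ortholog {orth_id} missing from second-genome gene models")
            chrom_len = len(fasta[gene2.chrom])
            lo, hi = upstream_window(gene2.tss, gene2.strand, span, chrom_len)
            if lo >= hi:
                continue
            window_seq = str(fasta[gene2.chrom][lo:hi])
            hits = scan_sequence(window_seq, gene2.chrom, classes)
            if _qualifies(hits, cand.class_name, match_mode):
                conserved = True
                break
        if annotate:
            cand.conserved = conserved
        if conserved:
            if annotate:
                cand.provenance.append("conserved")
            kept.append(cand)
        else:
            n_not_conserved += 1
    if n_no_ortholog:
        logger.info("conservation_filter: %d candidates dropped for lack of "
                    "an ortholog", n_no_ortholog)
    if n_not_conserved:
        logger.info("conservation_filter: %d candidates had orthologs but no "
                    "qualifying motif", n_not_conserved)
    return kept
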