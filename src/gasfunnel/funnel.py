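"""Eight-stage prioritization funnel orchestration.

Stage order is fixed: genome scan, SNP gain-of-function join, open
chromatin, immune-gene neighborhood, 10 kb upstream of TSS, >=2-subject
evidence, 200 bp spacing from intact GAS motifs, and cross-species
conservation.  Each stage writes its output before the next runs, the
machine-readable report embeds the effective configuration, and identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._util import BadInputError
from .conservation import conservation_filter, read_orthologs
from .gene_sets import DEFAULT_GO_ROOTS, immune_gene_set
from .motif_model import build_gas_classes
from .region_filters import (read_gtf, read_peaks_bed, read_tss_bed,
                             neighbor_gene_filter, set_immune_flags,
                             spacing_filter, threshold_signal,
                             upstream_tss_filter, window_join)
from .sequence_scan import scan_fasta
from .variant_gain import (VCFReader, candidate_gof, evidence_filter,
                           write_candidates_tsv)

logger = logging.getLogger(__name__)

STAGE_LABELS = ("scan", "snp_gof", "open_chromatin", "immune_neighbor",
                "upstream_10kb", "evidence_ge2", "spacing_200", "conservation")


@dataclass
class FunnelConfig:
    """All inputs and stage parameters of one funnel run."""

    genome_fasta: str
    vcf: str
    signal_bedgraph: str | None = None
    peaks_bed: str | None = None
    genes_gtf: str | None = None
    tss_bed: str | None = None
    gene_list: str | None = None
    obo: str | None = None
    gaf: str | None = None
    go_roots: tuple[str, ...] = DEFAULT_GO_ROOTS
    orthologs: str | None = None
    genome2_fasta: str | None = None
    genome2_gtf: str | None = None
    genome2_tss_bed: str | None = None
    known_rsids: str | None = None
    window: int = 200
    span: int = 10000
    min_subjects: int = 2
    min_signal: float = 20
    signal_comparator: str = "ge"
    match_mode: str = "same_class"
    drop_clustered: bool = True
    evidence_key: str = "FREQ"
    skip: tuple[str, ...] = ()

    @classmethod
    def from_dict(cls, d: dict) -> "FunnelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise BadInputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.go_roots = tuple(cfg.go_roots)
        cfg.skip = tuple(cfg.skip)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise BadInputError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    label: str
    n_in: int
    n_out: int
    path: str | None
    params: dict = field(default_factory=dict)
    skipped: bool = False


@dataclass
class FunnelReport:
    stages: list[StageResult]
    config_digest: str
    version: str
    final_path: str | None = None

    @property
    def final_count(self) -> int:
        return self.stages[-1].n_out

    def counts(self) -> dict[str, int]:
        return {s.label: s.n_out for s in self.stages}

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "config_digest": self.config_digest,
            "final_path": self.final_path,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_out\toutput\tskipped\n")
            for s in self.stages:
                fh.write(f"{s.label}\t{s.n_in}\t{s.n_out}\t"
                         f"{s.path or '.'}\t{s.skipped}\n")


def _check_inputs(config: FunnelConfig) -> None:
    """Fail before any stage runs if a named input file is missing."""
    for name in ("genome_fasta", "vcf", "signal_bedgraph", "peaks_bed",
                 "genes_gtf", "tss_bed", "gene_list", "obo", "gaf",
                 "orthologs", "genome2_fasta", "genome2_gtf",
                 "genome2_tss_bed", "known_rsids"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise BadInputError(f"input file for {name!r} not found: {path}")
    if config.signal_bedgraph is None and config.peaks_bed is None:
        raise BadInputError("need signal_bedgraph or peaks_bed")
    if config.genes_gtf is None and config.tss_bed is None:
        raise BadInputError("need genes_gtf or tss_bed")
    if config.gene_list is None and (config.obo is None or config.gaf is None):
        raise BadInputError("need gene_list or obo+gaf")
    for name in ("orthologs", "genome2_fasta"):
        if getattr(config, name) is None and "conservation" not in config.skip:
            raise BadInputError(f"need {name} (or skip the conservation stage)")


def _load_genes(gtf, tss_bed):
    return read_gtf(gtf) if gtf is not None else read_tss_bed(tss_bed)


def annotate_known(candidates, rsid_list_path) -> None:
    """Flag candidates whose rsID appears in a ClinVar-style list (no filtering)."""
    known: set[str] = set()
    if rsid_list_path is not None:
        with open(rsid_list_path) as fh:
            known = {line.strip() for line in fh if line.strip()}
    for c in candidates:
        c.known = c.variant.rsid in known


def run_pipeline(config: FunnelConfig, outdir) -> FunnelReport:
    """Execute all eight stages, writing each stage's output as it completes.

    Returns the funnel report; also writes ``funnel_report.json``/``.tsv``
    and the final candidate table sorted by chromosome and position.
    Stages named in ``config.skip`` pass candidates through unchanged.
    """
    _check_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classes = build_gas_classes()
    stages: list[StageResult] = []

    def run_stage(idx, label, current, fn, params=None):
        t0 = time.monotonic()
        if label in config.skip:
            stages.append(StageResult(label, len(current), len(current),
                                      None, params or {}, skipped=True))
            logger.info("stage %d %s: skipped", idx, label)
            return current
        result, path = fn()
        stages.append(StageResult(label, len(current), len(result),
                                  str(Path(path).name), params or {}))
        logger.info("stage %d %s: %d -> %d (%.2fs)", idx, label,
                    len(current), len(result), time.monotonic() - t0)
        return result

    # stage 1: scan
    scan_bed = outdir / "stage_1_scan.bed"
    tallies, hits = scan_fasta(config.genome_fasta, classes, scan_bed)
    gas_hits = [h for h in hits if h.class_name == "GAS"]
    nc_hits = [h for h in hits if h.class_name != "GAS"]
    stages.append(StageResult("scan", len(tallies), len(hits), scan_bed.name))
    logger.info("stage 1 scan: %d sequences -> %d hits", len(tallies), len(hits))

    # stage 2: SNP gain-of-function join
    reader = VCFReader(config.vcf, evidence_key=config.evidence_key)
    candidates = candidate_gof(nc_hits, reader)
    path2 = outdir / "stage_2_snp_gof.tsv"
    write_candidates_tsv(candidates, path2)
    stages.append(StageResult("snp_gof", len(nc_hits), len(candidates),
                              path2.name,
                              {"skipped_non_snv": reader.n_skipped_non_snv}))
    logger.info("stage 2 snp_gof: %d nc hits, %d variants -> %d candidates",
                len(nc_hits), reader.n_records, len(candidates))

    # stage 3: open chromatin
    def _stage3():
        if config.peaks_bed is not None:
            regions = read_peaks_bed(config.peaks_bed)
        else:
            regions = threshold_signal(config.signal_bedgraph,
                                       config.min_signal,
                                       config.signal_comparator)
        kept = window_join(candidates, regions, config.window)
        for c in kept:
            c.provenance.append("open_chromatin")
        path = outdir / "stage_3_open_chromatin.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(3, "open_chromatin", candidates, _stage3,
                           {"min_signal": config.min_signal,
                            "window": config.window})

    # gene models + immune set (used by stages 4 and 5)
    genes = _load_genes(config.genes_gtf, config.tss_bed)
    immune = immune_gene_set(config.gene_list, config.obo, config.gaf,
                             roots=tuple(config.go_roots))
    set_immune_flags(genes, immune)

    # stage 4: immune-gene neighborhood
    def _stage4():
        kept = neighbor_gene_filter(candidates, genes)
        path = outdir / "stage_4_immune_neighbor.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(4, "immune_neighbor", candidates, _stage4)

    # stage 5: 10 kb upstream of TSS
    def _stage5():
        kept = upstream_tss_filter(candidates, genes, config.span)
        path = outdir / "stage_5_upstream_10kb.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(5, "upstream_10kb", candidates, _stage5,
                           {"span": config.span})

    # stage 6: evidence
    def _stage6():
        kept = evidence_filter(candidates, config.min_subjects)
        path = outdir / "stage_6_evidence_ge2.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(6, "evidence_ge2", candidates, _stage6,
                           {"min_subjects": config.min_subjects})

    # stage 7: spacing from intact GAS motifs
    def _stage7():
        kept = spacing_filter(candidates, gas_hits, config.window,
                              config.drop_clustered)
        path = outdir / "stage_7_spacing_200.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(7, "spacing_200", candidates, _stage7,
                           {"window": config.window,
                            "drop_clustered": config.drop_clustered})

    # stage 8: conservation
    def _stage8():
        orth = read_orthologs(config.orthologs)
        genes2 = _load_genes(config.genome2_gtf, config.genome2_tss_bed)
        kept = conservation_filter(candidates, orth, config.genome2_fasta,
                                   genes2, config.span, config.match_mode,
                                   classes)
        path = outdir / "stage_8_conservation.tsv"
        write_candidates_tsv(kept, path)
        return kept, path

    candidates = run_stage(8, "conservation", candidates, _stage8,
                           {"span": config.span,
                            "match_mode": config.match_mode})

    # final table
    annotate_known(candidates, config.known_rsids)
    candidates.sort(key=lambda c: (c.chrom, c.variant.pos, c.variant.alt))
    final_path = outdir / "final_candidates.tsv"
    write_candidates_tsv(candidates, final_path)

    report = FunnelReport(stages=stages, config_digest=config.digest(),
                          version=__version__, final_path=final_path.name)
    report.to_json(outdir / "funnel_report.json")
    report.to_tsv(outdir / "funnel_report.tsv")
    return report
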