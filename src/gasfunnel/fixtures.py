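"""Synthetic, ground-truthed scenario generation for the whole funnel.

Each scenario plants candidate sites — a near-complete GAS motif, a
catalogued SNP, a gene neighborhood, an acetylation peak, and an
orthologous second-genome window — on its own small chromosome, so sites
cannot interfere with one another.  Every site carries a *designed failure
stage*: either it qualifies end-to-end or it is constructed to fail at
exactly one funnel stage (non-restoring decoy SNP, closed chromatin,
non-immune neighborhood, SNP downstream of the TSS, single-subject
evidence, an intact GAS motif planted within 200 bp, or a missing/empty
ortholog window).

Background sequence is sampled at human-like GC content and then patched
until it contains **no** motif-class occurrence other than the planted
ones, so per-stage survivor sets are exact.  The expected survivors are
recomputed from the emitted files by the generator's own brute-force logic
(regex scanning, per-base signal thresholding, quadratic interval checks) —
deliberately independent from the pipeline modules under test — and the
generator refuses to emit a bundle whose brute-force truth disagrees with
the design.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._util import InfeasibleConfigError
from .motif_model import IUPAC_SETS, build_gas_classes

STAGES = ("scan", "snp_gof", "open_chromatin", "immune_neighbor",
          "upstream_10kb", "evidence_ge2", "spacing_200", "conservation")

#: designed failure kind -> funnel stage at which the site must disappear
FAILURE_STAGE = {
    "decoy": "snp_gof",
    "open_chromatin": "open_chromatin",
    "immune_neighbor": "immune_neighbor",
    "upstream_tss": "upstream_10kb",
    "evidence": "evidence_ge2",
    "spacing": "spacing_200",
    "conservation": "conservation",
    "no_ortholog": "conservation",
}

_CLASSES = build_gas_classes()
_NONCANON = [c for c in _CLASSES if not c.is_canonical]
_CLASS_BY_NAME = {c.name: c for c in _CLASSES}

# Independent regex machinery for truth computation: one lookahead regex per
# class, built directly from the IUPAC table, never touching the scanner.
_CLASS_RE = {
    c.name: re.compile("(?=" + "".join(
        "[" + "".join(sorted(IUPAC_SETS[sym])) + "]" for sym in c.pattern) + ")")
    for c in _CLASSES
}
_GAS_RE = _CLASS_RE["GAS"]


@dataclass
class ScenarioConfig:
    """Counts of planted sites per designed outcome, plus geometry.

    Defaults give a scenario with ten fully qualifying candidates and two
    negative controls per funnel stage, on 2.5 kb chromosomes with
    human-like 41% GC background.
    """

    n_qualifying: int = 10
    n_decoy: int = 2
    n_fail_open_chromatin: int = 2
    n_fail_immune: int = 2
    n_fail_upstream: int = 2
    n_fail_evidence: int = 2
    n_fail_spacing: int = 2
    n_fail_conservation: int = 2
    n_fail_no_ortholog: int = 0
    chrom_length: int = 2500
    genome2_chrom_length: int = 1600
    gc: float = 0.41
    span: int = 10000
    window: int = 200
    min_signal: float = 20
    min_subjects: int = 2
    emit_ontology: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InfeasibleConfigError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def site_plan(self) -> list[str | None]:
        plan: list[str | None] = [None] * self.n_qualifying
        plan += ["decoy"] * self.n_decoy
        plan += ["open_chromatin"] * self.n_fail_open_chromatin
        plan += ["immune_neighbor"] * self.n_fail_immune
        plan += ["upstream_tss"] * self.n_fail_upstream
        plan += ["evidence"] * self.n_fail_evidence
        plan += ["spacing"] * self.n_fail_spacing
        plan += ["conservation"] * self.n_fail_conservation
        plan += ["no_ortholog"] * self.n_fail_no_ortholog
        return plan


@dataclass
class PlantedSite:
    idx: int
    failure: str | None
    chrom: str
    class_name: str
    motif_start: int
    kmer: str
    snp_pos0: int
    ref: str
    alt: str
    rsid: str
    evidence: int
    gene_id: str
    gene_symbol: str
    gene_tss: int
    gene_strand: str
    immune: bool
    gas_start: int | None = None
    ortholog_id: str | None = None


@dataclass
class TruthTable:
    """Planted ground truth plus independently recomputed survivor sets."""

    sites: list[PlantedSite]
    scan_hit_count: int
    scan_hits: list[tuple[str, int, str]]
    stage_survivors: dict[str, list[str]]
    stage_counts: dict[str, int]

    def to_json(self, path) -> None:
        payload = {
            "scan_hit_count": self.scan_hit_count,
            "stage_counts": self.stage_counts,
            "stage_survivors": self.stage_survivors,
            "sites": [dataclasses.asdict(s) for s in self.sites],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def sites_to_tsv(self, path) -> None:
        cols = [f.name for f in dataclasses.fields(PlantedSite)]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for s in self.sites:
                row = [str(getattr(s, c)) for c in cols]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=length, p=p))


def _sample_kmer(rng: np.random.Generator, class_name: str) -> str:
    cls = _CLASS_BY_NAME[class_name]
    bases = []
    for off, allowed in enumerate(cls.allowed):
        bases.append(str(rng.choice(sorted(allowed))))
    return "".join(bases)


def _regex_hits(seq: str) -> list[tuple[int, str]]:
    """All (start, class_name) occurrences, via the independent regexes."""
    hits = []
    for name, pattern in _CLASS_RE.items():
        hits.extend((m.start(), name) for m in pattern.finditer(seq))
    hits.sort()
    return hits


def _clean_background(rng: np.random.Generator, chars: list[str],
                      protected: list[tuple[int, int]],
                      max_rounds: int = 400) -> None:
    """Patch random unprotected bases until no unplanned class hit remains.

    A hit is "planned" iff its interval exactly equals a protected interval.
    Patching may create new hits; the loop re-scans to a fixpoint.
    """
    protected_set = set(protected)
    protected_pos = set()
    for lo, hi in protected:
        protected_pos.update(range(lo, hi))
    for _ in range(max_rounds):
        seq = "".join(chars)
        unwanted = [(start, name) for start, name in _regex_hits(seq)
                    if (start, start + 9) not in protected_set]
        if not unwanted:
            return
        for start, _name in unwanted:
            free = [p for p in range(start, start + 9) if p not in protected_pos]
            if not free:  # cannot happen with >=10 bp between plants
                raise InfeasibleConfigError(
                    "planted items too dense to clean background")
            pos = int(rng.choice(free))
            current = chars[pos]
            chars[pos] = str(rng.choice([b for b in "ACGT" if b != current]))
    raise InfeasibleConfigError("background cleaning did not converge")


# ---------------------------------------------------------------------------
# generation


def generate_scenario(config: ScenarioConfig, seed: int, outdir) -> tuple[dict, TruthTable]:
    """Emit a complete input bundle plus its truth table.

    Returns ``(bundle, truth)`` where ``bundle`` maps logical names
    (genome_fasta, vcf, signal_bedgraph, genes_gtf, gene_list, orthologs,
    genome2_fasta, genome2_gtf, truth_json, ...) to file paths.
    Deterministic given ``(config, seed)``.
    """
    L = config.chrom_length
    L2 = config.genome2_chrom_length
    if L < 1600:
        raise InfeasibleConfigError(
            f"chrom_length {L} too short to lay out a site (need >= 1600)")
    if L2 < 600:
        raise InfeasibleConfigError(
            f"genome2_chrom_length {L2} too short (need >= 600)")

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # mix the designed-outcome kinds along the genome, deterministically
    plan = config.site_plan()
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    sites: list[PlantedSite] = []
    chrom_seqs: dict[str, str] = {}
    genome2_seqs: dict[str, str] = {}
    genes: list[dict] = []
    genes2: list[dict] = []
    bedgraph_rows: list[tuple[str, int, int, float]] = []
    ortholog_rows: list[tuple[str, str]] = []

    for idx, failure in enumerate(plan, start=1):
        chrom = f"chr{idx}"
        chars = _random_seq(rng, L, config.gc)
        m = int(rng.integers(700, 900))
        class_name = str(rng.choice([c.name for c in _NONCANON]))
        cls = _CLASS_BY_NAME[class_name]
        kmer = _sample_kmer(rng, class_name)
        chars[m:m + 9] = list(kmer)
        protected = [(m, m + 9)]

        # SNP
        dev_off = cls.deviant_offset
        if failure == "decoy":
            if rng.random() < 0.5:  # non-restoring allele at the deviant base
                snp_pos0 = m + dev_off
                ref = kmer[dev_off]
                others = sorted(IUPAC_SETS[cls.pattern[dev_off]] - {ref})
                alt = str(rng.choice(others))
            else:  # SNP at a free middle base: never creates a GAS motif
                off = int(rng.integers(3, 6))
                snp_pos0 = m + off
                ref = kmer[off]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        else:
            snp_pos0 = m + dev_off
            ref = kmer[dev_off]
            alt = cls.restore_base
        evidence = 1 if failure == "evidence" else int(rng.integers(2, 5))

        # gene neighborhood
        gene_id, symbol = f"G{idx}", f"GENE{idx}"
        immune = failure != "immune_neighbor"
        if failure == "upstream_tss":
            # immune gene stays the nearest neighbor, but the SNP sits on
            # the downstream side of its TSS
            if rng.random() < 0.5:
                strand, tss = "+", m - int(rng.integers(300, m - 220))
            else:
                strand, tss = "-", m + int(rng.integers(300, L - m - 220))
        else:
            if rng.random() < 0.5:
                strand, tss = "+", m + int(rng.integers(400, L - m - 220))
            else:
                strand, tss = "-", m - int(rng.integers(400, m - 220))
        genes.append({"gene_id": gene_id, "symbol": symbol, "chrom": chrom,
                      "strand": strand, "tss": tss, "immune": immune})

        # open chromatin
        if failure == "open_chromatin":
            bedgraph_rows.append((chrom, 0, L, 2.0))
        else:
            ps, pe = m - 60, m + 70
            value = float(rng.integers(25, 60))
            bedgraph_rows.append((chrom, 0, ps, 2.0))
            bedgraph_rows.append((chrom, ps, pe, value))
            bedgraph_rows.append((chrom, pe, L, 2.0))

        # spacing: plant an intact GAS motif within the 200 bp window
        gas_start = None
        if failure == "spacing":
            gas_start = m + 9 + int(rng.integers(30, 150))
            gas_kmer = "TTC" + "".join(rng.choice(list("ACGT"), 3)) + "GAA"
            chars[gas_start:gas_start + 9] = list(gas_kmer)
            protected.append((gas_start, gas_start + 9))

        _clean_background(rng, chars, protected)
        chrom_seqs[chrom] = "".join(chars)

        # second genome / ortholog
        ortholog_id = None
        if failure != "no_ortholog":
            ortholog_id = f"M{idx}"
            chrom2 = f"chr{idx}_m2"
            chars2 = _random_seq(rng, L2, config.gc)
            tss2 = L2 - 200
            protected2: list[tuple[int, int]] = []
            if failure != "conservation":
                m2 = int(rng.integers(100, tss2 - 150))
                chars2[m2:m2 + 9] = list(_sample_kmer(rng, class_name))
                protected2.append((m2, m2 + 9))
            _clean_background(rng, chars2, protected2)
            genome2_seqs[chrom2] = "".join(chars2)
            genes2.append({"gene_id": ortholog_id, "symbol": ortholog_id,
                           "chrom": chrom2, "strand": "+", "tss": tss2})
            ortholog_rows.append((gene_id, ortholog_id))

        sites.append(PlantedSite(
            idx=idx, failure=failure, chrom=chrom, class_name=class_name,
            motif_start=m, kmer="".join(chrom_seqs[chrom][m:m + 9]),
            snp_pos0=snp_pos0, ref=ref, alt=alt, rsid=f"rs{1000 + idx}",
            evidence=evidence, gene_id=gene_id, gene_symbol=symbol,
            gene_tss=tss, gene_strand=strand, immune=immune,
            gas_start=gas_start, ortholog_id=ortholog_id))

    if not chrom_seqs:  # degenerate scenario: background only
        chars = _random_seq(rng, L, config.gc)
        _clean_background(rng, chars, [])
        chrom_seqs["chr1"] = "".join(chars)
    if not genome2_seqs:
        chars2 = _random_seq(rng, L2, config.gc)
        _clean_background(rng, chars2, [])
        genome2_seqs["chr1_m2"] = "".join(chars2)

    bundle = _write_bundle(outdir, config, chrom_seqs, genome2_seqs, sites,
                           genes, genes2, bedgraph_rows, ortholog_rows)
    truth = _brute_force_truth(config, chrom_seqs, genome2_seqs, sites,
                               genes, genes2, bedgraph_rows, ortholog_rows)
    _check_design(truth, sites)
    truth.to_json(bundle["truth_json"])
    truth.sites_to_tsv(bundle["truth_sites_tsv"])
    return bundle, truth


def _write_fasta(path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_bundle(outdir: Path, config: ScenarioConfig,
                  chrom_seqs, genome2_seqs, sites, genes, genes2,
                  bedgraph_rows, ortholog_rows) -> dict:
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "vcf": outdir / "variants.vcf",
        "signal_bedgraph": outdir / "signal.bedGraph",
        "genes_gtf": outdir / "genes.gtf",
        "gene_list": outdir / "immune_genes.txt",
        "orthologs": outdir / "orthologs.tsv",
        "genome2_fasta": outdir / "genome2.fa",
        "genome2_gtf": outdir / "genes2.gtf",
        "truth_json": outdir / "truth.json",
        "truth_sites_tsv": outdir / "truth_sites.tsv",
        "config_yaml": outdir / "scenario.yaml",
    }
    _write_fasta(paths["genome_fasta"], chrom_seqs)
    _write_fasta(paths["genome2_fasta"], genome2_seqs)

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=FREQ,Number=.,Type=String,'
                 'Description="Frequency studies">\n')
        for chrom, seq in chrom_seqs.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        chrom_order = {c: i for i, c in enumerate(chrom_seqs)}
        for site in sorted(sites, key=lambda s: (chrom_order[s.chrom],
                                                 s.snp_pos0)):
            freq = "|".join(f"Study{j + 1}:0.99,0.01"
                            for j in range(site.evidence))
            fh.write(f"{site.chrom}\t{site.snp_pos0 + 1}\t{site.rsid}\t"
                     f"{site.ref}\t{site.alt}\t.\t.\tFREQ={freq}\n")

    with open(paths["signal_bedgraph"], "w") as fh:
        for chrom, start, end, value in bedgraph_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")

    def _gtf_line(g: dict) -> str:
        if g["strand"] == "+":
            start1, end1 = g["tss"] + 1, g["tss"] + 150
        else:
            start1, end1 = max(1, g["tss"] + 1 - 150), g["tss"] + 1
        attrs = f'gene_id "{g["gene_id"]}"; gene_name "{g["symbol"]}";'
        return (f'{g["chrom"]}\tfixture\tgene\t{start1}\t{end1}\t.\t'
                f'{g["strand"]}\t.\t{attrs}\n')

    with open(paths["genes_gtf"], "w") as fh:
        for g in genes:
            fh.write(_gtf_line(g))
    with open(paths["genome2_gtf"], "w") as fh:
        for g in genes2:
            fh.write(_gtf_line(g))

    with open(paths["gene_list"], "w") as fh:
        for g in genes:
            if g["immune"]:
                fh.write(g["symbol"] + "\n")

    with open(paths["orthologs"], "w") as fh:
        for a, b in ortholog_rows:
            fh.write(f"{a}\t{b}\n")

    if config.emit_ontology:
        paths["obo"] = outdir / "ontology.obo"
        paths["gaf"] = outdir / "annotations.gaf"
        _write_ontology(paths["obo"], paths["gaf"], genes)

    with open(paths["config_yaml"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    return {k: str(v) for k, v in paths.items()}


def _write_ontology(obo_path, gaf_path, genes) -> None:
    """Toy immune-branch ontology whose closure reproduces the gene list."""
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        fh.write("[Term]\nid: GO:0002376\nname: immune system process\n\n")
        fh.write("[Term]\nid: GO:0000101\nname: leukocyte activation\n"
                 "is_a: GO:0002376 ! immune system process\n\n")
        fh.write("[Term]\nid: GO:9999999\nname: unrelated process\n")
    with open(gaf_path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for g in genes:
            term = "GO:0000101" if g["immune"] else "GO:9999999"
            fh.write(f'FX\t{g["gene_id"]}\t{g["symbol"]}\t\t{term}\t'
                     f"FX:0001\tIEA\t\tP\t\t\tgene\ttaxon:9606\t"
                     f"20200101\tFX\n")


# ---------------------------------------------------------------------------
# brute-force truth (independent of the pipeline modules)


def _gas_windows(seq: str) -> set[int]:
    return {m.start() for m in _GAS_RE.finditer(seq)}


def _brute_force_truth(config: ScenarioConfig, chrom_seqs, genome2_seqs,
                       sites, genes, genes2, bedgraph_rows,
                       ortholog_rows) -> TruthTable:
    w, span = config.window, config.span

    scan_hits = []
    for chrom, seq in chrom_seqs.items():
        scan_hits.extend((chrom, start, name)
                         for start, name in _regex_hits(seq))

    site_by_rsid = {s.rsid: s for s in sites}

    # stage 2: apply each alt genome-wide, diff the intact-GAS window sets
    gof: list[str] = []
    gof_motif: dict[str, tuple[int, int]] = {}
    for s in sites:
        seq = chrom_seqs[s.chrom]
        mutated = seq[:s.snp_pos0] + s.alt + seq[s.snp_pos0 + 1:]
        gained = _gas_windows(mutated) - _gas_windows(seq)
        if gained:
            gof.append(s.rsid)
            start = min(gained)
            gof_motif[s.rsid] = (start, start + 9)

    # stage 3: per-base thresholding, then quadratic gap test
    passing: dict[str, list[tuple[int, int]]] = {}
    values: dict[str, np.ndarray] = {}
    for chrom, seq in chrom_seqs.items():
        values[chrom] = np.zeros(len(seq))
    for chrom, start, end, value in bedgraph_rows:
        values[chrom][start:end] = value
    for chrom, arr in values.items():
        mask = arr >= config.min_signal
        runs = []
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j < len(mask) and mask[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        passing[chrom] = runs

    def _near_region(chrom, lo, hi):
        return any(r_lo <= hi + w and r_hi >= lo - w
                   for r_lo, r_hi in passing.get(chrom, ()))

    open_chrom = [r for r in gof
                  if _near_region(site_by_rsid[r].chrom, *gof_motif[r])]

    # stage 4: nearest flanking gene on each side must include an immune gene
    genes_by_chrom: dict[str, list[dict]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g["chrom"], []).append(g)

    def _immune_flank(chrom, pos):
        glist = genes_by_chrom.get(chrom, [])
        left = [g for g in glist if g["tss"] <= pos]
        right = [g for g in glist if g["tss"] > pos]
        flanks = []
        if left:
            flanks.append(max(left, key=lambda g: g["tss"]))
        if right:
            flanks.append(min(right, key=lambda g: g["tss"]))
        return any(g["immune"] for g in flanks)

    neighbor = [r for r in open_chrom
                if _immune_flank(site_by_rsid[r].chrom,
                                 site_by_rsid[r].snp_pos0)]

    # stage 5: strand-aware 10 kb upstream window of any immune gene
    def _in_upstream(chrom, pos):
        for g in genes_by_chrom.get(chrom, []):
            if not g["immune"]:
                continue
            if g["strand"] == "+":
                lo, hi = g["tss"] - span, g["tss"]
            else:
                lo, hi = g["tss"] + 1, g["tss"] + span + 1
            if lo <= pos < hi:
                return True
        return False

    upstream = [r for r in neighbor
                if _in_upstream(site_by_rsid[r].chrom,
                                site_by_rsid[r].snp_pos0)]

    # stage 6
    evidence = [r for r in upstream
                if site_by_rsid[r].evidence >= config.min_subjects]

    # stage 7: quadratic gap to canonical hits, plus mutual clustering
    canonical = [(chrom, start) for chrom, start, name in scan_hits
                 if name == "GAS"]

    def _near_gas(chrom, lo, hi):
        return any(c == chrom and s <= hi + w and s + 9 >= lo - w
                   for c, s in canonical)

    spaced = []
    for r in evidence:
        chrom = site_by_rsid[r].chrom
        lo, hi = gof_motif[r]
        if _near_gas(chrom, lo, hi):
            continue
        clustered = any(
            o != r and site_by_rsid[o].chrom == chrom
            and gof_motif[o][0] <= hi + w and gof_motif[o][1] >= lo - w
            for o in evidence)
        if not clustered:
            spaced.append(r)

    # stage 8: same-class motif in the ortholog's upstream window
    orth_map: dict[str, list[str]] = {}
    for a, b in ortholog_rows:
        orth_map.setdefault(a, []).append(b)
    genes2_by_id = {g["gene_id"]: g for g in genes2}

    conserved = []
    for r in spaced:
        s = site_by_rsid[r]
        ok = False
        for orth in orth_map.get(s.gene_id, []):
            g2 = genes2_by_id[orth]
            seq2 = genome2_seqs[g2["chrom"]]
            if g2["strand"] == "+":
                lo, hi = max(0, g2["tss"] - span), g2["tss"]
            else:
                lo, hi = g2["tss"] + 1, min(len(seq2), g2["tss"] + span + 1)
            window_seq = seq2[lo:hi]
            if _CLASS_RE[s.class_name].search(window_seq):
                ok = True
                break
        if ok:
            conserved.append(r)

    survivors = {
        "snp_gof": sorted(gof),
        "open_chromatin": sorted(open_chrom),
        "immune_neighbor": sorted(neighbor),
        "upstream_10kb": sorted(upstream),
        "evidence_ge2": sorted(evidence),
        "spacing_200": sorted(spaced),
        "conservation": sorted(conserved),
    }
    counts = {"scan": len(scan_hits)}
    counts.update({stage: len(rsids) for stage, rsids in survivors.items()})
    return TruthTable(sites=sites, scan_hit_count=len(scan_hits),
                      scan_hits=scan_hits, stage_survivors=survivors,
                      stage_counts=counts)


def _check_design(truth: TruthTable, sites: list[PlantedSite]) -> None:
    """Verify the brute-force truth matches each site's designed fate."""
    for stage in STAGES[1:]:
        stage_idx = STAGES.index(stage)
        expected = sorted(
            s.rsid for s in sites
            if s.failure is None
            or STAGES.index(FAILURE_STAGE[s.failure]) > stage_idx)
        actual = truth.stage_survivors[stage]
        if actual != expected:
            raise RuntimeError(
                f"generator invariant violated at stage {stage}: designed "
                f"{expected} != brute-force {actual}")
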