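# gasfunnel

Find single-nucleotide variants that **create** STAT transcription-factor
binding sites, and prioritize them down to an experimentally reviewable list.

## The problem

Phosphorylated STAT dimers of the JAK-STAT cytokine-signaling pathway bind
gamma-interferon activated site (GAS) motifs — the palindromic consensus
`TTCnnnGAA`, six fixed bases around three free ones — in promoters and
enhancers of immune genes. A genome is littered with *near-complete* GAS
(ncGAS) motifs: 9-mers that deviate from the consensus at exactly one fixed
position. A catalogued SNP whose alternate allele sits at that deviant
position and supplies the missing base converts an ncGAS into an intact GAS
motif, potentially creating a de novo STAT binding site and a
gain-of-function change in nearby immune-gene regulation (the symmetric
event — a SNP breaking an intact motif — is a loss-of-function candidate).

Because the genome holds millions of ncGAS occurrences, raw motif gain is
far too permissive a criterion. `gasfunnel` implements the full
prioritization funnel around it, in fixed order:

1. **scan** — find every GAS/ncGAS occurrence (exact degenerate IUPAC
   matching; the seven classes are closed under reverse complement, so a
   plus-strand scan covers both strands and reports each interval once);
2. **snp_gof** — join variants whose alternate allele completes a motif;
3. **open_chromatin** — keep candidates within 200 bp of an active region
   (H3K27ac bedGraph signal ≥ 20, or pre-called peaks);
4. **immune_neighbor** — keep candidates whose nearest flanking gene is an
   immune gene (GO immune-branch closure, or a plain gene list);
5. **upstream_10kb** — keep SNPs in the strand-aware 10 kb window upstream
   of an immune gene's TSS;
6. **evidence_ge2** — require support from ≥ 2 independent sources
   (dbSNP `FREQ` study count as the subject-count proxy);
7. **spacing_200** — drop candidates within 200 bp of an existing intact
   GAS motif (no room for a second STAT dimer) or of each other;
8. **conservation** — require the same motif class in the 10 kb upstream
   window of the orthologous gene in a second genome (e.g. mouse).

The motif classes (deviant fixed base → IUPAC pattern → restoring allele):

| class | pattern     | deviant offset | restoring base |
|-------|-------------|----------------|----------------|
| GAS   | `TTCNNNGAA` | —              | —              |
| T1    | `VTCNNNGAA` | 0              | T              |
| T2    | `TVCNNNGAA` | 1              | T              |
| C     | `TTDNNNGAA` | 2              | C              |
| G     | `TTCNNNHAA` | 6              | G              |
| A1    | `TTCNNNGBA` | 7              | A              |
| A2    | `TTCNNNGAB` | 8              | A              |

(`V`=ACG, `D`=AGT, `H`=ACT, `B`=CGT.) Exactly 64 of the 262,144 9-mers match
GAS and 192 match each deviation class; the classes are pairwise disjoint.

## Worked example

The package ships a synthetic-scenario generator that plants ground-truthed
candidate sites — each either fully qualifying or designed to fail at exactly
one funnel stage — so the whole protocol runs without any downloads:

```sh
gasfunnel simulate --seed 42 --outdir demo/scenario
gasfunnel run-all --config demo/funnel.yaml --outdir demo/run
```

with `demo/funnel.yaml` pointing at the generated files:

```yaml
genome_fasta: demo/scenario/genome.fa
vcf: demo/scenario/variants.vcf
signal_bedgraph: demo/scenario/signal.bedGraph
genes_gtf: demo/scenario/genes.gtf
gene_list: demo/scenario/immune_genes.txt
orthologs: demo/scenario/orthologs.tsv
genome2_fasta: demo/scenario/genome2.fa
genome2_gtf: demo/scenario/genes2.gtf
```

prints the funnel (input count → output count per stage):

```
scan	24	26
snp_gof	24	22
open_chromatin	22	20
immune_neighbor	20	18
upstream_10kb	18	16
evidence_ge2	16	14
spacing_200	14	12
conservation	12	10
final candidates: 10
```

Seed 42 plants 24 candidate sites (plus two decoy intact motifs), of which
ten qualify end-to-end and two are designed to drop at each stage — and the
funnel recovers exactly that: 26 scanned motif occurrences, 22
gain-of-function SNPs, then 20 → 18 → 16 → 14 → 12 → 10 survivors. The final
table lists, per SNP, the motif class, the completed 9-mer, the target gene,
the distance to its TSS and the conservation call:

```
rsid	chrom	pos	ref	alt	class	motif_start	motif_end	completed_kmer	evidence_count
rs1011	chr11	764	T	C	C	761	770	TTCACCGAA	2
rs1012	chr12	813	A	C	C	810	819	TTCGCGGAA	2
```

Every stage's output is written before the next runs
(`stage_1_scan.bed` … `stage_8_conservation.tsv`, then
`final_candidates.tsv` and `funnel_report.json`/`.tsv`), and identical
configuration reproduces byte-identical outputs. Subcommands `scan`, `gof`,
`lof`, `filter`, `conserve` and `report` expose the individual steps; the
same functionality is available as a library (`gasfunnel.run_pipeline`,
`gasfunnel.scan_sequence`, `gasfunnel.candidate_gof`, …).

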