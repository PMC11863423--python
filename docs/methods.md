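# Methods

## Motif model

The canonical gamma-interferon activated site (GAS) element is modeled as
the degenerate 9-mer `TTCNNNGAA`: six fixed positions (offsets 0,1,2,6,7,8)
and three unconstrained middle positions. A *near-complete* GAS (ncGAS)
class is derived by replacing exactly one fixed base with the IUPAC code for
the other three nucleotides (`V`=ACG, `D`=AGT, `H`=ACT, `B`=CGT). This
construction has three consequences the rest of the package leans on, each
verified exhaustively over all 4^9 = 262,144 9-mers in the test suite:

* **Counting.** 4^3 = 64 9-mers match GAS; 3 x 64 = 192 match each of the
  six deviation classes (1,152 in total).
* **Disjointness.** Each deviation class excludes the canonical base at its
  deviant position and demands canonical bases everywhere else, so the seven
  classes are pairwise disjoint and every 9-mer has at most one class.
* **Reverse-complement closure.** `TTCNNNGAA` is self-reverse-complementary,
  and the deviation classes pair up (T1<->A2, T2<->A1, C<->G). A
  minus-strand occurrence of class X therefore *is* a plus-strand occurrence
  of its partner class at the same interval.

Matching is exact consensus matching on per-position allowed-base sets —
deliberately not a position-weight-matrix score. There is no p-value or
score threshold to tune; a window either matches a class or it does not.
A PWM scanner run at a permissive threshold on these same consensus
matrices can report additional sub-consensus windows, so occurrence counts
from score-based tools are not expected to be bit-identical. The class
table can be exported as a MEME-format motif file for that comparison.

Two normalization rules: soft-masked (lowercase) genome bases are
uppercased before matching, because repeats are part of the search space;
an `N` (or any non-ACGT symbol) matches nothing, *including* the three free
middle positions — a motif call through an assembly gap is meaningless.

## Scanner

`scan_sequence` encodes the sequence as small integers once and applies each
class as nine per-offset boolean table lookups over numpy slices, so cost is
O(9 x 7 x L) vectorized operations per sequence. By reverse-complement
closure, scanning the plus strand with all seven classes is complete for
both strands, and each genomic interval is reported exactly once — no
plus/minus duplicates, which also avoids double-counting the palindromic
canonical motif. Overlapping hits at different offsets are all kept; the
spacing stage resolves clustering later. FASTA input is streamed one
sequence at a time (gzip supported); coordinates are 0-based half-open
everywhere inside the library and converted only at I/O boundaries (VCF,
GTF are 1-based).

The scanner's independent check is a naive both-strand lookahead-regex
oracle whose minus-strand hits are mapped through the partner classes; the
two agree exactly on random 100 kb sequences (50 fixed seeds in the
acceptance suite).

## Gain- and loss-of-function candidacy

A gain-of-function candidate is a (hit, variant, allele) triple where the
variant's 1-based position minus one equals the hit's deviant position, the
VCF REF equals the genome base there (a mismatch signals a genome/catalogue
build mismatch and is skipped with a warning), and an ALT equals the
plus-strand restoring allele. Multi-allelic records are expanded first;
indels and other non-SNV alleles are excluded and tallied. This local rule
is provably equivalent to the global definition "applying the allele
creates a new intact-GAS window somewhere": if a substitution at position p
turns window w into a GAS match, then w matched GAS at every other position
before, i.e. w was the deviation class keyed by p's offset. The acceptance
suite still checks the equivalence empirically against an
apply-every-allele-and-rescan oracle.

Loss-of-function candidacy is the mirror image: any SNV allele at one of
the six fixed positions of an intact motif destroys it (each fixed position
admits exactly one base), while middle-position variants never qualify.

**Evidence counting.** The requirement that a variant be seen in at least
two independent subjects (to exclude sequencing artifacts) is proxied by
the number of `|`-separated studies in the dbSNP-style `FREQ` INFO field;
no dbSNP field records subject counts directly. The INFO key is
configurable, and any other key is read as a plain integer. Default
threshold: 2.

## Interval filters

* **Open chromatin** (default signal ≥ 20, window w = 200 bp). bedGraph
  intervals passing the cutoff are merged when bookended or overlapping; a
  candidate survives when the gap between its motif interval and the
  nearest passing region is ≤ w. The 200 bp window reflects the
  peak–valley–peak geometry of acetylation flanking a bound factor. The
  threshold is inclusive ("20 or higher"); a strict comparator is
  available. Pre-called peak BEDs are accepted in place of thresholding.
* **Immune neighborhood.** For each candidate the nearest gene by TSS
  distance is found on each side, strand-agnostic; the candidate survives
  iff at least one of these two flanking genes is an immune gene. Only the
  two flanking genes are consulted — an immune gene two genes away does not
  count. Genes get one deterministic TSS each: the most 5' transcript start
  on the gene's strand (transcript features preferred over gene features
  when a GTF has both).
* **Upstream 10 kb** (span = 10,000). Strand-aware window: `[tss-span,
  tss)` for plus-strand genes, `[tss+1, tss+span+1)` for minus-strand
  genes, applied to immune genes only (this stage follows the immune
  filter). The closest qualifying gene and the SNP→TSS distance are
  annotated. The same window arithmetic (one shared function) is used by
  the conservation stage.
* **Spacing** (w = 200). A candidate within w bp of an intact GAS motif is
  removed — a second STAT dimer could not bind there. With
  `drop_clustered` (default on), every member of a group of candidate
  motifs mutually within w bp is also removed; no principled ranking
  exists to prefer one member, so none is kept. Toggleable.

The gap convention throughout is symmetric and inclusive: an item and a
region with exactly w intervening bases still count as neighbors (this is
the item-extended-by-w overlap reading of a `bedtools window -w` join; at
the exact boundary, half-open overlap arithmetic would differ by one base).

## Immune gene set

Either a plain newline-delimited gene list, or Gene Ontology closure: all
terms at or below a configurable set of roots (default: immune system
process GO:0002376, immune response GO:0006955, cytokine signaling
GO:0019221, interferon-gamma signaling GO:0060333, interleukin signaling
GO:0070102, JAK-STAT cascade GO:0007259), following `is_a` edges only by
default (`part_of` optional), then every gene annotated to any term in the
closure. The resulting gene count is GO-release-dependent, so no specific
count is asserted anywhere.

## Conservation

A candidate's target gene (the gene whose upstream window it sits in) is
mapped through a 2-column ortholog table (one-to-many allowed; any
qualifying ortholog suffices). The ortholog's strand-aware 10 kb upstream
window is extracted from the second genome and scanned; the candidate
survives according to `match_mode`:

* `same_class` (default) — a hit of the identical ncGAS class must be
  present. "The same type of motif" is read as the same deviation class;
  this is a judgment call, so
* `any_ncgas` — any deviation-class hit, and
* `canonical` — an intact GAS motif,

are exposed as alternatives. Candidates without an ortholog are dropped and
logged separately from "ortholog present, motif absent". Windows are
scanned on the extracted plus-strand slice only; class closure makes
minus-strand special-casing unnecessary.

## Synthetic scenarios and what they do (not) show

The generator plants each candidate site on its own small chromosome
(default 2.5 kb, 41% GC, human-like): an ncGAS motif of a random class, a
SNP, one gene (body 150 bp, TSS 0.3–1.8 kb from the motif on a random
side/strand), an acetylation peak (value 25–60 over ~130 bp on background
2), an ortholog with its own second-genome chromosome (1.6 kb, TSS near the
3' end), and dbSNP-style `FREQ` evidence. Each site either qualifies
end-to-end or is built to fail at exactly one stage: a non-restoring decoy
allele, a peak-free chromosome, a non-immune flanking gene, a TSS placed so
the SNP is downstream, single-study evidence, an intact GAS motif planted
30–150 bp away, an empty ortholog window, or a missing ortholog. The
one-site-per-chromosome layout guarantees designed failures cannot interact
through shared windows.

Background sequence is random and then *patched to zero unplanned motif
occurrences* (re-scan and mutate free positions to a fixpoint), so the
truth table's per-stage survivor sets are exact. Expected survivors are
recomputed from the emitted files by brute force — lookahead-regex
scanning, per-base signal thresholding, quadratic all-pairs interval checks
and flanking-gene scans, all independent of the pipeline implementations —
and generation fails rather than emit a bundle whose brute-force truth
disagrees with the design.

Consequences for interpretation: passing scenarios demonstrates the
*logic* of every stage and their composition, under clean separability.
Real genomes have overlapping ncGAS occurrences, gene-dense and gene-empty
stretches, signal noise, build mismatches and multi-mapped orthologs; the
scenario generator deliberately does not emulate read-level ChIP-seq noise
or population-genetic allele-frequency structure. Absolute survivor counts
on real data are additionally sensitive to the motif-matching convention
(exact consensus here versus thresholded PWM scores) and to database
releases, and are not reproduced by the synthetic tests.

## Numerical and engineering choices

* Problem sizes in the shipped checks: exhaustive 262,144-9-mer
  enumeration; 50 x 100 kb scanner-oracle sequences; 20 scenarios of 100 kb
  (40 sites) for candidacy; 20 end-to-end scenarios; quadratic-oracle
  comparisons at 1–2 k items (the oracles are O(n²); these sizes already
  exercise every branch).
* Determinism: a single `numpy` Generator seeded from the scenario seed
  drives all sampling; outputs carry no timestamps and the funnel report
  stores stage paths relative to the run directory, so identical
  configuration and seed reproduce byte-identical bundles and runs.
* Degenerate inputs: sequences shorter than 9 bp scan to empty; an empty
  intermediate stage propagates empty outputs while the report stays
  complete; chromosomes with no genes drop their candidates with a logged
  warning; a span ≤ 0, a malformed bedGraph value column, unknown
  configuration keys, missing input files and duplicate FASTA names all
  fail fast with a clear error before any stage output is written.
* Stage order is fixed (scan → SNP join → chromatin → neighborhood →
  upstream → evidence → spacing → conservation); `skip` allows ablation but
  never reordering. Every filter returns a subset of its input, so funnel
  counts are monotone from the SNP stage onward.

## Known limitations

* Exact-consensus matching cannot reproduce score-based scanner output
  counts bit-for-bit (see Motif model).
* The 10 kb upstream restriction misses downstream and long-range
  regulatory elements; this mirrors the protocol's scope, not a belief
  about enhancer biology.
* Study counts in `FREQ` over-approximate "independent subjects" when one
  subject appears in several studies.
* Conservation is motif-presence in an orthologous window, not positional
  alignment; liftover/phyloP-style conservation is out of scope.
* The funnel ends at a ranked candidate table; the final expert review of
  individual candidates is intentionally manual.
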