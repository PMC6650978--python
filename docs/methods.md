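# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and gene models

All in-memory intervals are 0-based half-open; GFF3 I/O converts to/from
1-based inclusive at the file boundary only, so interval arithmetic never
mixes conventions. Chromosome names follow the `chr{1-7}{A|B|D}` dialect.
A `GeneModel` carries sorted, non-overlapping exon intervals, the spliced
CDS (minus-strand genes reverse-complemented, terminal stop excluded) and
its translation; `translate(cds) == protein` is an enforced invariant.
The pipeline works at gene level: a multi-transcript GFF3 keeps the
transcript with the longest CDS (logged). Exon structure is taken from CDS
features, which is exact for the fully coding family genes this pipeline
targets. N bases are allowed in assemblies; k-mers containing N are never
seeded and N mismatches in alignments, which biases identity estimates
conservatively downward.

## Family identification

The search re-creates an iterative domain-profile + pairwise-similarity
strategy as a fixpoint closure:

1. A PSSM per domain is built from a seed alignment: columns with > 50 %
   gaps are dropped; scores are `2·log2(f_a / 0.05)` half-bits with
   `f_a = (count_a + w·0.05)/(n + w)` (pseudocount weight `w = 1`,
   uniform 0.05 background).
2. Every protein is scanned for the best ungapped profile window. Its
   E-value is `database_size × P(shuffle ≥ score)` where the null is the
   best-window score of shuffled copies of the same protein
   (`n_shuffles = 200`). Inside the shuffle range the plus-one empirical
   tail `(count+1)/(n+1)` is used; a score exceeding every shuffle takes
   the right tail of a Gumbel fitted to the shuffle scores by the method
   of moments. The empirical tail alone cannot certify probabilities
   below `1/(n+1)`, which a per-database expectation cut-off of 0.1 over
   hundreds of proteins requires; the Gumbel tail is the standard
   extrapolation for maxima of i.i.d. window scores. Scan cut-off:
   `E < 0.1`.
3. Confirmed members seed Smith–Waterman searches of the whole proteome
   (BLOSUM62, gap open 11 / extend 1, a length-k gap costing
   `11 + k`). E-values use the Karlin–Altschul form
   `E = K·m·n·exp(−λS)` with ungapped-protein constants `λ = 0.267`,
   `K = 0.041` and `n` the total database length. Search cut-off:
   `E < 1e-5`.
4. New hits are re-scanned for the domains; only domain-confirmed
   proteins enter the member set. Either domain suffices for membership
   (both are reported when present). The closure is monotone and errors
   out after 10 iterations if still growing.

Absolute E-values here only gate the closure; the decision thresholds are
the ones stated above, and the constants are exposed as arguments.

## Homoeolog grouping

Identity is computed on a global protein alignment as identical residues
divided by the length of the longer sequence, so truncations count
against identity ("X % over the longest sequence"). The alignment is a
unit-cost (edit-distance) global alignment; because co-optimal paths can
count matches differently in the two directions, arguments are put in a
canonical order first, making the measure exactly symmetric.

Clustering is first-fit greedy incremental: sequences sorted by length
descending (ties by id), the longest founds cluster #0, each next
sequence joins the first cluster whose representative it matches at
≥ 90 %, else founds a new cluster. Cluster numbering therefore follows
creation order after length sorting. Best-fit assignment would be a
one-line change but first-fit matches the behaviour of the incremental
clustering tools this emulates.

Group assignment reduces "similar positions on homoeologous chromosomes"
to same-chromosome-number across pairwise-distinct subgenomes; no
within-chromosome distance test is applied, because none is quantified in
the protocols this follows. Clusters larger than 3 are partitioned by
chromosome number and qualifying sub-partitions become "probable"
pairs/triplets — one defensible reading of an under-specified rule; the
notes field records the provenance of every such group.

## Structural classification

Type Ib = 0 introns, Type Ia = 1, Type II = > 1. For Type Ia the
conserved ancestral intron position is recognised by the fixed-length
rule — the CDS downstream of the intron is exactly 174 bp — and
corroborated by the alignment test: both introns must map to the same
column of a global CDS alignment (match +2 / mismatch −3 / gap
−(5+2k)), flanked on both sides by residue–residue columns. A
gap-adjacent intron is *not* conserved; that is the strict reading of
"between two aligning bases". The 174-bp rule is measured on CDS, which
equals genomic exon length when the exon is fully coding.

Second-exon indel reports align the second-exon CDS segments globally and
report each gap run as a signed event (insertions = bases the gene has
that the reference lacks). The "ancestral reference" is the
conserved-intron gene with the highest CDS identity to the query.

Retro-signature scanning works in transcription orientation: a polyA is
a run of ≥ 8 bases at ≥ 90 % A within 200 bp downstream of the gene end;
a target-site duplication is the k-mer (k from 15 down to 4) immediately
upstream of the gene recurring within ± 3 bp of the polyA end (or the
gene end when no polyA is found). The strict adjacency anchor keeps the
false-positive rate of the short-k end low (~3 % on random flanks); a
windowed search at k = 4 would fire on almost any 200-bp flank. The
polyA purity (90 %) and k-range (4–15) follow retrogene-literature
conventions.

## Duplication scan

Windows are `[gene_start − 100 kb, gene_end + 100 kb]` clipped to the
chromosome; same-chromosome genes closer than 100 kb share one window
spanning the most distal coordinates ± flank. All distinct window pairs
(including same-chromosome pairs) are scanned on both strands:

- **Seeding**: shared 14-mers; k-mers occurring > 10 times in a window
  are skipped (repeat masking at seed level).
- **Chaining**: anchors grouped within ± 16 diagonals, split on
  positional gaps > 2 kb, kept with ≥ 3 anchors spanning ≥ 1 kb; chains
  overlapping within 1 kb on both axes are unioned.
- **Extension/scoring**: each chained region is aligned end-to-end with
  a unit-cost aligner; identity = matches / alignment columns; the score
  re-weights the alignment operations at match +1 / mismatch −2 /
  gap −(5+2k); `E = K·m·n·exp(−λS)` with nucleotide constants
  `λ = 1.28`, `K = 0.46` and m, n the window lengths.
- **Filters**: identity ≥ 0.90, aligned span ≥ 3 kb, `E < 1e-100`. Hits
  whose two loci overlap on the same chromosome are dropped: nearby
  windows of one chromosome share genomic sequence, and a locus aligned
  to (part of) itself is not a duplication. This also removes the
  trivial self-diagonal.
- **Non-overlap resolution**: the fragment set is built greedily by
  score (ties: longer first, then coordinates) accepting a hit iff each
  of its loci overlaps every same-chromosome locus of every accepted
  fragment by ≤ 10 % of the shorter span. Strict 0 % would discard
  legitimate abutting repeats whose extensions jitter by a few bases.
  Fragments are counted once per unordered locus pair.

At ≥ 90 % identity a 14-mer match occurs every ~60 bp in expectation, so
planted fragments are densely anchored; two random 50-kb windows share
only ~150 spurious 14-mers, which never chain past the filters.

## Expression analysis

Genes with CPM ≥ 1 in ≥ 3 samples are kept. TMM factors follow the
trimmed-mean-of-M-values scheme: reference = sample whose
75th-percentile count fraction is closest to the mean of those fractions;
per sample, M/A values on doubly-positive genes, top and bottom 30 % of
M and 5 % of A removed by rank, factor = 2^(inverse-variance-weighted
mean M), all factors rescaled to geometric mean 1. One test cross-checks
the factors against the Bioconductor reference implementation on a toy
matrix. log2-CPM uses `log2((y + 0.5)/(N·f + 1)·1e6)`.

Precision weights re-create the voom idea: per-gene residual SDs around
group means, `sqrt(sd)` smoothed against average log2 count by lowess
(span 0.5, 2 robustness iterations), weight = trend(fitted
log-count)^−4, with a logged fallback to unit weights when the trend is
degenerate.

The moderated t shrinks per-gene variances toward a prior estimated by
moments on `log s²` under a scaled-F model: `ψ'(d0/2) = Var(log s²) −
ψ'(d/2)` (trigamma inverted by Newton iteration), posterior variance
`(d0·s0² + d·s²)/(d0 + d)`, t referred to a t-distribution with `d + d0`
degrees of freedom. When the observed spread of `log s²` does not exceed
its sampling variance, `d0 = ∞` and all genes share the pooled variance;
`prior_df = 0` disables moderation and reproduces the ordinary
two-sample t exactly (tested). DEG calls use strict inequalities:
|log2FC| > 1 and BH-adjusted p < 0.05.

Hierarchical clustering is Euclidean/average-linkage (UPGMA) over gene
profiles with a Newick export. Homoeolog expression partitioning flags a
group when a member's mean linear expression falls below 5 % of the
group maximum (silenced; a member removed by the low-expression filter
counts as silenced) or any member pair differs by more than 1 log2 unit;
both thresholds are package conventions, since partitioning is usually
described qualitatively. Expression breadth: constitutive = expressed
(mean log2-CPM > 1) in all tissues with max/min linear tissue ratio < 4;
tissue-specific = expressed in one tissue at ≥ 4× every other; levels
weak/moderate/high by tertiles of overall mean among expressed genes.

## Synthetic data: what it emulates, what it does not

The generator plants every structure the stages detect, under these
default study conditions: 21 chromosomes of 1 Mb; a 92-member family
(8 triplets + 11 pairs at 0.95 protein identity to a per-group template,
giving ≥ 0.90 pairwise identity within groups, plus 46 singlets at 0.75
identity to the family ancestor); ≥ 200 background genes; ~43 %
intronless members, half of them with planted TSD (5 bp) + polyA (12 bp)
vestiges; conserved-intron genes with a 174-bp terminal coding exon and
shifted-intron genes at ± 9/15/21 nt; two singlets carrying known
second-exon indels (−15; +3 and +6) against a recorded reference; two
tandem clusters of singlets; 30 segmental duplications of 3–13 kb at
90–99 % identity planted within ± 80 kb of family genes on different
chromosomes, never overlapping each other or any gene; and three repeat
elements of 500 bp pasted 6–10 times per chromosome at 95 % identity as
near-identity noise for the scanner.

Expression counts are negative binomial (dispersion 0.1) over 21
libraries — grain/spike/root controls and leaf under
control/drought/heat/drought+heat, 3 replicates each, library-size
factors in [0.5, 2] — with planted effects: 20 silent genes, 11
grain-specific genes, 3 partitioned triplets (one member at 1/200 of its
group baseline), and 10 % of genes differentially expressed at
|log2FC| = 2 in the leaf heat-vs-control contrast.

Protein divergence is simulated by exact-count residue substitution, so
realised identities sit on their targets; CDSs reuse template codons at
conserved residues, keeping nucleotide and protein divergence coupled.
Family indels are frame-preserving (multiples of 3) only. The generator
does *not* emulate: realistic TE taxonomy or repeat landscapes,
phylogenetic sequence evolution (no substitution-model heterogeneity, no
synonymous-site divergence beyond codon resampling), frame-breaking
indels, alternative splicing, read-level RNA-seq (counts only), GC or
mappability biases. Passing tests therefore demonstrate the correctness
of the algorithms under controlled conditions, not performance on real
assemblies, where repeat density, fragmented annotations and
between-release coordinate drift dominate the error budget.

Determinism: a single generator seeded from the config drives genome
construction; expression counts use a child seed. Identical configs give
byte-identical FASTA/GFF3/TSV outputs.

## Problem sizes and runtime

Unit tests run on a reduced configuration (9 × 150 kb chromosomes,
2 triplets + 2 pairs + 8 singlets, 30 background genes) and finish in
seconds. The acceptance checks and `scripts/acceptance.py` use the
default conditions above; the dominant cost is the all-pairs window scan
(~60 windows over a 21-Mb genome), and a complete run takes a few
minutes on one CPU. The moderated-t calibration uses 10,000 null genes
at n = 3 vs 3.

## Known limitations

- The PSSM scan is ungapped; a domain split by a long insertion would
  score as two windows and may be missed at the 0.1 cut-off. The
  pairwise-search arm of the closure compensates in practice.
- Greedy first-fit clustering is order-dependent by construction; a
  sequence equidistant from two representatives joins the first-created
  cluster.
- The duplication scanner reports one fragment per chained region; a
  duplication interrupted by a large insertion (> 2 kb) is reported as
  two fragments, which the 10 % overlap rule then keeps or merges
  depending on geometry.
- E-value constants are literature defaults, not fitted to the scoring
  schemes; they gate decisions only through the stated thresholds.
- The homoeolog expression-partitioning thresholds (5 % silence, 1 log2
  divergence) are conventions; sensitivity to them is not explored.
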