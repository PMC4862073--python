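# Methods

This note documents the models, conventions and numerical choices behind
`hoxatlas`, and what its synthetic-data validation does and does not show
about real genomes.

## Coordinates and the data model

All intervals are stored 0-based half-open; GFF3 I/O converts from and to
the format's 1-based inclusive coordinates at the boundary, which keeps
every piece of gap arithmetic a plain subtraction. A gene's
*transcription unit* is the interval from the first to the last exon over
all of its transcripts, UTRs included. This is the span measure used by
every cluster metric: the field's cluster-size figures are quoted from
transcriptional start to transcriptional stop, and using the union over
isoforms (rather than one representative isoform) gives one well-defined
value per gene when annotations disagree about isoforms. UTRs absent from
an annotation are inferred as exon-minus-CDS, split 5'/3' by strand; when
a gene has no CDS-bearing transcript its architecture fields are flagged
missing rather than imputed as zero, so species means are computed over
genes with data only.

## Cluster dispersion metrics

For a set of genes labelled with the ten canonical Hox classes (lab, pb,
Hox3, Dfd, Scr, ftz, Antp, Ubx, abd-A, Abd-B):

* **Span** — distance from the transcription start of the most 3' Hox
  gene to the transcription stop of the most 5' one. For clusters spread
  over several scaffolds the user supplies the expected scaffold order;
  the cross-scaffold contribution is the *minimum* gap (trailing flank of
  the upstream scaffold plus leading flank of the downstream one), and is
  labelled as a minimum everywhere, since unlinked scaffolds bound the
  true distance from below.
* **Intervening space** — span minus the union of Hox transcription
  units. Overlapping or nested units are merged before subtraction, so
  span = merged Hox bp + intervening bp holds exactly on one scaffold.
* **Intervening genes** — protein-coding genes whose transcription unit
  is fully contained in the gap between adjacent Hox genes. Genes that
  only partially overlap a gap are reported in a separate warning list
  rather than counted, keeping the counts reproducible integers.
* **Splits** — a cluster is split when adjacent Hox genes sit on
  different scaffolds, or when an intra-scaffold gap exceeds a threshold.
  The threshold defaults to 1 Mb; the literature never defines "split"
  numerically, and 1 Mb cleanly separates the multi-megabase breaks seen
  in flies, silk moths and spider mites from ordinary intergenic spacing.
  It is a flag on the CLI and an argument in the API.
* **Orientation** — the reference strand is the majority strand among the
  cluster's genes (ties resolved to the strand of lab, the 3'-most
  class); inversions are the genes on the other strand, and orientation
  runs are counted along the cluster order.
* **Tandem duplicates** — a class with more than one labelled gene is a
  duplicate; it is tandem when its copies are adjacent in the cluster
  (no other Hox class between them).

Megabase values in reports are rounded half-up to two decimals, matching
the precision such figures are printed at.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment under
affine gaps run on Biopython's `PairwiseAligner` (a C implementation of
the Gotoh recursion) behind this package's scoring conventions. A gap of
length L costs `gap_open + (L-1) * gap_extend`. Percent identity is
100 × identities / alignment columns with gap columns in the denominator
(the EMBOSS convention; an ungapped-denominator variant is available
behind a flag). Ties between co-optimal alignments resolve to the
engine's deterministic first-optimal ordering, so outputs are bit-stable.

Two default schemes serve two jobs:

* **needle-style** (match +5 / mismatch −4, gap 10/0.5; BLOSUM62 for
  protein) for paralog-divergence identities. These are the most
  plausible settings behind published percent-identity figures for Hox
  paralog pairs; identities quoted under other conventions can shift by
  1–3 points, so reproduction of such numbers carries a ±2-point
  tolerance.
* **megablast-style** (match +2 / mismatch −3, gap 5/2) for the genome
  miRNA screen. This is a deliberate split: with the needle gap costs
  (extension 0.5) a *local* search over a scaffold can chain random
  k-mer matches through nearly free long gaps and accumulates arbitrarily
  high-scoring spurious alignments. Proportional gap costs remove that
  pathology while leaving substitution-diverged homologs findable.

Multiple local hits come from iterated Smith–Waterman: the best hit is
reported, its target interval masked, and the flanking segments searched
recursively, so hits never overlap in the target. Both target strands are
searched for nucleotide queries.

The local screen has no E-value model (heuristic seeding and
Karlin–Altschul statistics are out of scope). Consequently, on
megabase-scale sequence, chance hits at the 20-nt/80% operating point are
*expected* at a low rate; the screen is a candidate generator, and
specificity comes from the downstream hairpin filter (see below). This
mirrors how homology-based miRNA annotation is actually run.

## RNA folding and the hairpin filter

Secondary structure is predicted by free-energy minimisation under a
nearest-neighbour model: Watson–Crick and GU wobble pairs; stacking free
energies of Turner-style magnitude; hairpin, bulge and internal-loop
initiation penalties by size with Jacobson–Stockmayer `1.75·RT·ln(n/n₀)`
extrapolation beyond the tables; an internal-loop asymmetry penalty of
0.5 kcal/mol per unpaired-count difference capped at 3; and an affine
multiloop term (3.4 kcal/mol initiation + 0.4 per branch, unpaired bases
free). Structures are pseudoknot-free with a minimum hairpin loop of
three; internal/bulge loops are capped at 30 unpaired nucleotides, the
standard dynamic-programming restriction. Energies are kcal/mol at 37 °C.

The minimiser is a Zuker-style dynamic program with a numba-compiled
fill; the model itself is *defined* by the structure-scoring function
(loop decomposition), and the DP is validated against exhaustive
enumeration of all structures for sequences up to 22 nt. The model is
calibrated for threshold behaviour — genuine pre-miRNA-like stem-loops
score far below the −20 kcal/mol cut-off and dinucleotide-shuffled
controls do not — and makes no claim of parity with any full parameter
set (terminal mismatches, dangles and special loops are omitted).

A candidate passes the hairpin filter iff:

1. its MFE is ≤ −20 kcal/mol (inclusive, as are all the screen's
   boundaries);
2. the structural *component* containing the mature sequence is a single
   stem-loop — exactly one terminal loop, no multiloop. Topology is
   judged per component because candidates are extended with flanking
   genomic sequence, and a random flank frequently folds a small
   independent side-stem at the exterior level; that is not a branched
   hairpin. Multiloop-containing components still fail.
3. the mature sequence lies entirely on one arm of that stem with at
   least 60% of its bases paired. The mature-on-stem criterion is stated
   qualitatively in the literature; 60% is this package's
   quantification, surfaced as a parameter.

The mature is located in the candidate by exact match or, failing that,
by local alignment covering ≥70% of its length; otherwise the filter
raises a location error.

Resolved loci merge overlapping same-query hits; non-overlapping hits
within 500 bp are reported as distinct tandem copies of one locus (the
spacing at which tandem miRNA copies have been observed). Positions are
labelled relative to the Hox transcription units on the same scaffold —
`between(X,Y)` with the pair ordered canonically 3'→5', `downstream(lab)`
/ `upstream(Abd-B)` beyond the cluster ends under cluster polarity, or
`non_hox_scaffold`.

Note that a near-perfect hairpin is quasi-palindromic, so the screen
usually reports the same locus on both strands; duplicate resolution
keeps them as strand-separate records and the strand of the planted or
annotated copy scores higher.

## HKY85 maximum likelihood

The substitution model is HKY85: transition/transversion rate ratio κ and
stationary frequencies π, rate matrix normalised to one expected
substitution per site per unit branch length. Transition probabilities
come from the eigendecomposition of the symmetrised generator, computed
once per parameter set. The likelihood is Felsenstein pruning over
compressed site patterns; gaps and N are missing data (partial likelihood
one). Base frequencies default to empirical counts (with a pseudocount);
κ can be co-estimated. No rate heterogeneity is modelled.

Branch lengths are fitted by coordinate-wise bounded Brent optimisation
(branch bounds 10⁻⁸–10, round tolerance 10⁻⁶ log-units, warning +
best-so-far on non-convergence). Topology search starts from
neighbor-joining on pairwise two-sequence ML distances and hill-climbs by
nearest-neighbor interchange until no move improves the log-likelihood by
more than 10⁻⁶; NNI-only search is adequate at the tens-of-taxa scale
these trees have, so SPR is omitted. Paralog support reports whether the
ML tree places a focal pair as sisters and the log-likelihood difference
against the best tree constrained to separate them (exhaustive over all
topologies for ≤5 taxa, constrained NNI search otherwise).

## The synthetic-data generator

The generator builds annotated genomes with the organisational features
the analysis measures, each recorded in a ground-truth object computed by
direct arithmetic on the layout at construction time — deliberately not
by calling the metrics code it validates.

* Intergenic gaps default to log-uniform between 1 kb and 500 kb, the
  range spanning the tightest and most dispersed arthropod arrangements
  on record; tests and examples use narrower explicit ranges to keep
  generated genomes small, which changes problem size, not logic.
* Hox genes get a simple three-exon structure with configurable exon,
  intron and UTR length laws; intervening genes are single-exon
  protein-coding dummies placed fully inside their gap.
* Losses drop classes; duplications insert adjacent (tandem) or distal
  copies; inversions put listed classes on the minus strand; a split
  places the remainder of the cluster on a second scaffold with exact
  flank lengths, so the planted minimum gap is known to the base pair.
* Planted hairpins overwrite intergenic background (overwriting rather
  than inserting keeps all gene coordinates stable). Divergence mutates
  paired bases compensatorily with probability 0.8 — preserving the stem
  — and breaks the pair otherwise, so divergence degrades both identity
  and MFE realistically. Built-in templates are *synthetic* stand-ins
  for the conserved Hox-associated miRNA stem-loops, constructed as
  near-perfect 28-bp stems, not curated miRBase sequences.
* `simulate_hky85` evolves i.i.d. sites from π down a tree;
  `mutate_paralog` substitutes (optionally after a 3n 5'-truncation that
  spares a 3' homeodomain-sized window) until the global-alignment
  identity is within ±1 point of a target.

Everything is deterministic per seed; identical spec + seed gives
byte-identical FASTA/GFF3/TSV output.

**What passing on synthetic data does not show.** Generated background is
i.i.d. sequence without repeats, transposable elements, codon structure
or GC heterogeneity; gene models are simplistic; planted hairpins are
cleaner than real pre-miRNAs. Perfect recall/zero false positives on
planted genomes therefore validates the pipeline's logic and thresholds,
not its error rates on real assemblies, where repeat-derived hairpins and
annotation noise are the dominant failure modes.

## Validation set-up and problem sizes

The test suite checks every dynamic program against an independent
exhaustive oracle at small size (alignments ≤6 nt over sampled pairs,
folding ≤22 nt, likelihood ≤5 taxa × ≤10 sites with exhaustive
internal-state summation), exact ground-truth closure of all cluster
metrics on 50 random generated layouts, miRNA recovery (100% recall, 0
false loci) over 20 seeded 100-kb genomes at ≤10% hairpin divergence with
the threshold boundary cases asserted inclusively, and HKY85 recovery: κ
within 10% at 10,000 sites (κ ∈ {2, 4, 8}), mean branch-length relative
error under 15% at 1,000 sites over 20 seeds, ≥95% quartet topology
recovery with a long internal branch, and the 5-taxon search matching the
exhaustive 15-topology optimum. "Within 15% over 20 seeds" is read as
the mean relative error across seeds and branches, the estimator the
statement is about. `scripts/acceptance.py` re-runs scaled versions of
these analyses (10 genomes / 10 topology seeds / 20 layouts) from a
single seed and writes the measured quantities as JSON.

## Known limitations

* Tier-two reproduction against real genome-database annotations
  requires the original downloads and is not part of the offline suite.
* The screen's identity/length thresholds are applied to exact local
  alignments, not BLAST HSPs; identities computed over different HSP
  extents can differ near the 80% boundary.
* The energy model's absolute kcal/mol values are approximate; only
  threshold behaviour (planted vs shuffled) is contractual.
* `are_sisters`-style support values come from point likelihoods;
  bootstrap resampling is available but not wired into acceptance.
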