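# Methods

## The analysis model

The package targets a four-library salinity experiment on a de novo
transcriptome: one sequencing library per organ × condition cell
(shoot-control CS, shoot-NaCl NS, root-control CR, root-NaCl NR), no
biological replicates, and a unigene catalog standing in for gene models.
Every statistical choice below follows from that design.

### Read screening

Trimming runs in a fixed order per read: adapter removal (suffix-of-read /
prefix-of-adapter match, overlap ≥ `min_adapter_overlap`, mismatch rate ≤
`adapter_max_error_rate`, everything 3′ of the match cut), then terminal
poly(A) (3′) / poly(T) (5′) runs of ≥ `homopolymer_min_run` bases, then
stripping of bases with QV < `end_trim_qv` from both ends. The screen then
discards a read when (1) average QV ≤ 17, (2) length ≤ 20 bp (16 bp in the
short-tag profile), (3) the fraction of bases with QV < 10 is ≥ 10%, or
(4) the read contains an `N`. Criteria (3) and (4) are stated as keep
conditions in the source procedure, so the screen discards their
complement; the 10% boundary itself discards (strict keep). A pair is
dropped when either mate fails, because downstream counting is
fragment-based. Duplicate removal deletes a pair only when **both** mates
are byte-identical to a previously seen pair, keeping the first
occurrence. tRNA/rRNA exclusion is a plain id blacklist — which reads to
drop is an input, not a similarity search.

Defaults: `min_adapter_overlap=3`, `adapter_max_error_rate=0.1`
(cutadapt-like semantics), `homopolymer_min_run=10`. These are standard
practice values; the original procedure names the tool but not its
parameters. At overlap 3, chance 3-mer suffix matches trim ~1.6% of clean
reads by a few bases — noise-free restoration checks therefore run with
overlap 8, where the chance-match probability is ~10⁻⁵.

### Unique-hit counting and FPKM

A fragment counts toward a unigene iff all its mapped records (both mates
included) name that single reference; records naming ≥ 2 distinct
references mark the fragment as a multi-hit contributing nothing. MAPQ is
ignored — with a highly redundant de novo catalog, aligner MAPQ values are
not a reliable uniqueness signal, the reference-name set is.
FPKM(g,s) = 10⁹·C/(N·L) with N the column total of unique-hit counts, so
Σ_g FPKM(g,s)·L(g) = 10⁹ holds exactly per sample. A gene is "expressed in
an organ" at ≥ 1 fragment across the organ's two libraries; this universe
is both the DE testing family and the enrichment reference.

### Differential expression

Kal's Z compares one gene's proportion of the library total between the
organ's control and NaCl libraries, with unpooled variance
p₁(1−p₁)/N₁ + p₂(1−p₂)/N₂ (the form used for single-library SAGE-style
comparisons; a pooled variant is available via `variance="pooled"`). A
one-sided zero (x₁=0, x₂>0) stays defined through the non-zero side's
variance; (0,0) genes are outside the tested universe. P-values are
two-sided normal tails, Bonferroni-corrected with m = the organ's
expressed-gene count, and called at corrected P ≤ 0.05 (α ≤ 0 calls
nothing, even where the corrected P underflows to exactly 0).

**Known limitation, deliberately kept:** the test models sampling noise
only. On overdispersed (negative-binomial) counts it is anticonservative —
in the default synthetic run roughly 6× more genes are called than were
planted. This is a property of replicate-free library comparison itself,
not of the implementation; the test suite verifies calibration where the
model holds (Poisson nulls) and truth recovery where signal is planted.
The normal approximation is also inaccurate far in the tails at modest
depth: on Poisson nulls with mean count 500 per gene the family-wise error
at α=0.05 over 2000 genes is ~0.085 rather than ≤0.05, dropping to
0.04–0.06 by mean count 2000. Calibration runs therefore use mean 2000.

### Enrichment

Per term, P(X ≥ k) from the hypergeometric distribution (equivalently
one-sided Fisher on the 2×2 table), computed exactly. Up- and
down-regulated sets are tested separately, as are the GO and pathway
vocabularies (separate Bonferroni families, m = terms with ≥ 1 reference
carrier). Annotations are tested as supplied — no ontology-graph
propagation.

### Correspondence analysis

CA factorizes S = (P − rcᵀ)/√(rcᵀ) by SVD, with row principal and column
standard coordinates (asymmetric map — the gene cloud is the object of
interest). Total inertia equals the matrix's Pearson chi-square over the
grand total, and inter-row distances in full principal coordinates equal
chi-square distances between row profiles; both identities are tested to
10⁻⁸. With four samples there are at most three non-trivial axes, so the
full geometry is a tetrahedron whose corners are reached by rows with all
mass in one column — exactly the four appended guide genes. Guide
magnitude defaults to the 99th percentile of row sums; a guide's profile
(hence its summit role) is magnitude-independent, though gene coordinates
shift slightly with the mass it adds. Region labels use θ_summit=0.25 and
θ_edge=0.15 of the mean summit–centroid distance; the original group I/II
reading was visual, so the thresholds are configurable and echoed in
output. All-zero rows are dropped (with a warning), not pseudo-counted.
Coordinates are unique up to axis sign; every distance-derived output is
sign-invariant. Subset clustering is average-linkage agglomerative on the
3-D coordinates, cut at `linkage_cut` × the same scale.

### qPCR

ΔΔCt per biological replicate (technical replicates are averaged first),
fold = 2^(−ΔΔCt), mean ± SE across replicates **on the fold scale**
(matching error bars drawn on fold axes; a log₂-scale summary is behind
`log_scale_se`). Concordance with sequencing is sign agreement of fold vs
1 against the FPKM ratio.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis must cope
with, not sequencing physics:

- **Counts** are gamma-Poisson: mean μ(g,s) = N_s·w(g,s)/Σw(·,s), with
  baseline abundances log-normal(σ=1), the fold-change multiplier applied
  in responsive organs' NaCl columns, and organ-specific genes as
  structural zeros. `dispersion` is the NB overdispersion (variance
  μ+φμ²), default 0.05 — moderate biological variability; 0 recovers
  Poisson. Because each column is normalized to its library size, expected
  totals are exact while the realized NaCl/control expectation ratio is
  fold × a compositional factor (~5% at the defaults) — the same
  compositional behaviour real RNA-seq shows. The defaults (fold 4,
  5% responsive genes, half up, 10⁶ fragments/library) are the study
  conditions used throughout the validation.
- **Reads** are 100 bp pairs from fragment positions sampled without
  replacement per gene (so only planted duplicates are byte-identical;
  duplicate truth is nonetheless recomputed by the byte-identity rule).
  Contamination classes: adapter read-through and poly(A) tailing
  (mutually exclusive, each replacing the 3′ end of mate 1 with the true
  insert length recorded), an internal `N` planted inside the clean
  portion, QV-2 flanks on mate 2, and duplicate pairs. Qualities are
  Sanger/Phred+33.
- **Alignments** flag each read multi-mapped with probability
  `multimap_fraction`; multi reads emit two records with distinct
  reference names, unique reads one.
- **qPCR** Ct values are baseline − log₂(expression) + Gaussian noise,
  reference fold pinned at 1.

What the generator does **not** emulate: platform error profiles,
assembly artifacts (chimeras, fragmented transcripts, redundant isoforms),
positional coverage bias, and genuinely distinct biology for the second
"species" (the cross-species comparison runs on a second independent
synthetic experiment). Passing tests therefore demonstrate correctness of
the statistical machinery under its stated model, not robustness to
assembly pathology.

## Problem sizes

Validation runs use sizes at which the measured quantities are stable:
10⁴ genes for the raw type-I error, 200 × 2000 genes for family-wise
control, 500 random tables for hypergeometric exactness, 50 replicates for
planted-enrichment recovery (odds 8, term size ~50, 500 responsive genes
in 10⁴), 5000 genes × 10⁶ fragments for end-to-end recovery, 2400 read
pairs for QC truth recovery, and 10⁴ reads at 50% multi-mapping for
counting. The full suite and the acceptance script each complete in well
under a minute.

## Open design points, resolved

- Whether the original work tested all unigenes or only expressed ones per
  organ: expressed-only, since the expressed universes are reported ahead
  of the test and Bonferroni over never-observed genes is meaningless.
- Whether the 10% low-quality criterion is strict or inclusive: the keep
  condition is "< 10%", so exactly 10% discards.
- Fold vs log SE for qPCR error bars: fold scale by default, matching how
  such results are plotted.
- Raw FPKM (no transform) enters the CA, and guide magnitude is data-driven
  via the row-sum percentile rather than a fixed constant.
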