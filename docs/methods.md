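# Methods

## The representation model

`prism` treats "summarising data" as applying *entropy-reducing
representation operators* under *models* of the data.  A dataset of N
elements and a panel of M models, combined with K operators, yields an
N × M × K tensor.  The operator set shipped is: collection mean and
standard deviation (model-independent, aggregative), rank under an
ordering model, bin centre and bin occupancy under a binning model, and
self-information h = −ln p under a probability model.  A model-fitting
operator (representation by a fitted value under some general model) is
deliberately only an extension point — the framework defines it
abstractly but no concrete fit ships; calling `op_model_fit` raises
`not-implemented`.

The tensor's row slices (spectra, one per data element) and column
slices (co-spectra, one per model) are numpy views of the same array:
the duality between data and models is transposition by construction,
never a recomputation, so the duality invariant holds exactly.

### Units and conventions

* Self-information is in **nats** everywhere (natural log); the log base
  is recorded in tensor metadata.
* Ranks run 1..N; ties default to a deterministic ordinal order with the
  element id as tie-break ("ordinal-lexicographic"), with mid-rank
  averaging available by flag.  The choice is a package convention: any
  tie rule is defensible, but determinism makes runs reproducible.
* Coordinates are 0-based half-open internally; 1-based only at I/O
  boundaries that require it (e.g. BLAST tabular input).

### Unobserved bins

No finite sample assigns a probability to a bin it never saw, yet panel
representations constantly query models about other models' elements.
Unobserved bins get a half pseudo-count probability
p\* = 0.5 / (total_count + 0.5), hence h\* = −ln p\*: finite, larger than
every observed bin's self-information, and slowly increasing with the
model's sample size (a bigger sample makes absence more surprising).
Every such cell is flagged `unobserved` in the tensor so downstream
consumers can exclude it; the Euclidean metric offers a
`pairwise-complete` policy (compare only co-unflagged coordinates,
rescale by √(L/L_used)) alongside the default pseudo-count-filled one.

Windowed alignment-depth models are stored as *unnormalised* probability
models: each query's probability is its own window depth over the total
aligned, so the values need not sum to one across queries.  The
`ProbabilityModel.normalised` flag records which contract a model obeys;
the sum-to-one invariant (±1e-9) is enforced only for normalised models.

## k-mer front-end

`count_kmers` samples whole reads (Bernoulli, seeded) — the sampling
unit is the record, not the window — then counts every overlapping
window of retained reads, skipping windows containing non-ACGT symbols.
Counting is vectorised (2-bit base encoding, sliding windows,
`bincount` over 4^k codes); an exhaustive-enumeration oracle in the test
suite pins the fast path at rate 1.  k defaults to 6 (4096 bins — large
enough to separate species composition, small enough that modest read
counts populate the spectrum); any k ≥ 1 works in memory up to about
k = 12.  Strands are counted as written by default because the main QC
targets (adapters, primers) are strand-specific; a lexmin-of-strand
canonicalisation is available for composition work.

The zipfian co-spectrum sorts observed bins by descending probability
(lexicographic tie-break on the k-mer for determinism), assigns ranks
1..D and pairs them with h = −ln p.  Storage keeps raw ranks; plots use
ln rank.

### Turning-point detection

The detector answers one question: does the curve h(ln r) bend somewhere
it should not?  The curve is resampled onto a 200-point uniform grid in
ln-rank (the raw ranks crowd exponentially toward high ranks, where
finite differences would explode), smoothed with a centred 9-point
moving average, and differentiated twice.  Local extrema of |h''| are
reported when they exceed **both** 3× the median absolute second
derivative (a scale-free noise floor) and an absolute floor of 1.5
nats per unit ln-rank squared.  The floor matters twice: on an exactly
linear curve the median is pure float noise, so a relative threshold
alone would flag numerical dust; and every finite sample shows gentle
global curvature (its h quantiles are not exactly log-linear) that the
relative threshold alone would sometimes promote.  The rightmost 10% of
the ln-rank range is excluded: the sharp upturn among the rarest words
(counts of 1–2) is present in every finite sample and carries no
artefact signal.  On the synthetic study conditions the separation is
wide — clean lanes peak below 0.9 on the interior, 5% adapter spike-ins
above 3.7 — but the floor is a property of curve geometry, not of any
particular generator setting.

### Contaminant assembly

`assemble_enriched_kmers` greedily merges the selected k-mer set:
repeatedly take the pair of fragments with the longest exact
suffix–prefix overlap (≥ min_overlap, default k−1), preferring higher
combined count then lexicographic order on ties, absorbing contained
fragments, until no admissible overlap remains.  Greedy overlap assembly
is exact whenever the selected k-mers tile a string without repeated
k-mers — the adapter case — and that property is tested directly
(random strings of length ≤ 60 with unique k-mers reconstruct exactly).
It is not a general-purpose assembler and makes no attempt at error
correction or repeat resolution.

## Alignment front-end

Hit tables are reduced to best hits per (query, reference) — maximum
percent identity, ties to the smallest position then lexicographically
smallest contig.  The depth model uses a *sliding* window centred on
each query's own position (half-open, [c − w/2, c + w/2)), confined to
one contig, rather than fixed genome bins; depth is computed by sorted
binary search and pinned against an O(n²) oracle in tests.  Window width
default is 2000 bases and is exposed everywhere — it is a tunable with
no single right value (it should roughly match the locus scale of the
data); doubling it can only increase depths (tested monotonicity).
Whether depth should count all alignments or best hits only is a
genuinely open choice; the package uses best hits, which makes depth a
property of the query layout rather than of alignment multiplicity.

## Taxa front-end

Taxonomy names are opaque strings (trimmed of surrounding whitespace,
case preserved) — the approach is expressly non-semantic, so no
normalisation or taxonomy-tree rollup is attempted.  A batch's
co-spectrum is h = −ln(count/rowsum) over the union of names across all
batches; zero cells are flagged and pseudo-counted.  `cumulative_update`
re-unions the name universe when new batches arrive and zero-backfills
earlier batches, which changes only their padding, never their
probabilities (tested).

## Metrics

* **Euclidean** — scipy `cdist` behind the package's missing-data
  policies.
* **Zipfian distance** — d(a,b)² = Σ_w (h_a(w) − h_b(w))² / r̄(w) over
  the union of bins, r̄ the mean of the two ranks; a bin absent from one
  co-spectrum contributes that model's pseudo-count h at rank D+1.  The
  inverse-rank weight concentrates the comparison on frequent words,
  where empirical h is stable, and makes the metric depend only on
  (h, rank) pairs — bin relabeling invariance is tested.  Mean-of-ranks
  is the package's convention for the weight; other conventions
  (min, max, geometric mean) would serve equally.
* **Cluster-projection** — k-means (scikit-learn, seeded k-means++, one
  initialisation, 100 iterations, tol 1e-6) on the N spectra; each
  co-spectrum is projected to its vector of within-cluster means and
  compared Euclidean-wise.  This equalises the weight of co-varying
  element groups (e.g. gene families) regardless of their size.  The
  default of 300 clusters reflects the dimensionality at which panel
  relationships stabilise in the motivating application; with
  n_clusters = N the projection is a permutation and the metric
  collapses to plain Euclidean (tested exactly).

All three are weighted or projected L2 forms; symmetry, identity of
indiscernibles on the representation, and the triangle inequality are
verified on random instances at 1e-9.  One caveat: because the zipfian
weight 1/r̄ depends on the pair being compared, that distance is a
*near-metric* — adversarial search over contrived tiny co-spectra (a
handful of bins with near-tied probabilities) can construct mild
triangle-inequality violations, although random realistic instances
show none.  Consumers that strictly require a metric (e.g. some
indexing structures) should use the Euclidean or cluster-projection
distances instead.

## Embedding and ordering

Classical (Torgerson) MDS: double-centre −D²/2, eigendecompose, scale
the top eigenvectors by √eigenvalue; negative eigenvalues (non-Euclidean
input) contribute zero coordinates.  Chosen over iterative stress
majorisation because it is deterministic and exact in the
Euclidean-embeddable limit (a 3-4-5 triangle reproduces its distances to
1e-9, tested); axis signs are fixed by making each axis's first nonzero
loading positive.  Kruskal stress-1 is reported.

Heatmap ordering runs scipy average-linkage independently on rows and
columns; leaf order puts the smaller cluster first at each merge, with
size ties broken on the lexicographically smallest member row — a
content-based rule, so the order is equivariant under input permutation
(a label-based tie-break would not be).  Dendrograms serialise to
Newick with branch lengths equal to merge-height differences
(ultrametric).

## Synthetic data: what it emulates, and what it does not

The generators are first-class, seeded, pure functions of their
configuration, built so each pipeline's target structure is planted and
recoverable:

* **Reads** — order-1 Markov chains per species (rows of the transition
  matrix drawn Dirichlet(uniformity/4); uniformity 60 gives clearly
  species-distinct 6-mer spectra, 800 a near-uniform background);
  repeat families as tiled units replacing whole reads at their genome
  fraction; adapter read-through by splicing the full adapter into a
  read at a random position in its 3' half; negative controls from a
  near-uniform iid base model.  Default lane scale is 300 reads × 101 bp
  per sample (2000 for single-sample spike experiments) — deliberately
  desk-scale; it populates a 4096-bin spectrum to mean counts of ~7–47,
  which is the noise regime the recovery checks exercise.
* **Hit tables** — query loci as Gaussian dense clusters plus uniform
  sparse background on a virtual contig; each reference applies an
  optional segment relocation; percent identities 80 + 20·Beta(8, 2).
  The canned rearrangement panel relocates an isolated 20-query segment
  into a 200-query dense cluster, so inside-segment queries change
  window depth by well over one nat under exactly one reference.
* **Taxa tables** — per-species Dirichlet(1.0) base profiles over an
  opaque 40-taxon pool, keyed by species name (stable across tables);
  batches draw Dirichlet(500·base) perturbations and one multinomial of
  n_hits = 2000.

What the generators do **not** reproduce: realistic genome word
distributions (real genomes are far more skewed than the near-uniform
spike background; a heavily skewed background would push adapter k-mers
off the top ranks at a 5% spike rate, and real detection there leans on
the much larger read counts of production data), sequencing error
models and quality scores, alignment ambiguity (every query aligns to
every reference exactly once), and the 4000-taxon breadth of real
facility QC tables.  Passing recovery tests therefore demonstrates that
the machinery extracts planted structure at desk scale under honest
noise — not that these parameter values characterise any particular
instrument or species.

## Numerical and degenerate-input choices

* Probability sums are validated to 1e-9; distance symmetry/diagonal to
  1e-9; MDS eigenvalues below 1e-12 are treated as zero.
* All-zero distance matrices embed to all-zero coordinates with stress 0.
* Empty datasets, empty batches, unknown ids, kind-mismatched
  operator/model pairs, k mismatches between zipfian co-spectra, and
  unbinnable/unordered payloads raise `PrismError` with stable kebab-case
  codes (`empty-dataset`, `operator-model-kind-mismatch`, …).
* scikit-learn's k-means relocates empty clusters internally; the
  re-seed-once-then-fail branch for degenerate clusterings is defensive.
* Every stochastic path takes an explicit seed; lane simulation derives
  per-sample streams from (lane seed, sample index) so outputs are
  byte-reproducible.

## Known limitations

* The greedy assembler collapses repeated k-mers; contaminants with
  internal repeats longer than k−1 will not reconstruct uniquely.
* The turning-point detector reports curvature extrema, not artefact
  classifications; interpreting a turning point (adapter, biased
  sampling, amplicon structure) remains the analyst's call.
* Cluster-projection distances inherit k-means' dependence on the seed
  when clusters are not well separated; the seed is part of the result's
  provenance.
* `pctid_cospectra` treats "no hit" as identity 0 with a flag; callers
  comparing panels with very different sensitivity should use the flag
  mask rather than the raw zeros.
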