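# prism — non-semantic labelling for sequencing QC and multi-reference analysis

`prism` represents bioinformatic data — sequencing files, alignment hit
tables, taxonomy hit counts — by *where they sit in a metric space* rather
than by what their sequences or taxon names say.  Each data element is
mapped through a panel of models and a panel of entropy-reducing
representation operators into a tensor of statistics; rows of that tensor
(*spectra*) label data elements, columns (*co-spectra*) label models, and
distances between them drive clustering, outlier screens and 2D
embeddings.  The package is aimed at people running sequencing facilities
and non-model-organism projects: lane-level QC (adapter read-through,
mixed-species lanes, mislabelled batches) and reference-panel comparison
(rearrangements, assembly relatedness) without annotation or a finished
reference.

## The representation

For a dataset `x_1 … x_N` and a model `m_j`, a scalar representation
operator maps each element to a number:

* `mean`, `sd` — the collection mean / standard deviation (aggregative);
* `rank` — the element's rank under an ordering model (injective up to
  ties);
* `bin`, `freq` — the element's bin centre / bin occupancy under a binning
  model;
* `info` — the self-information **h = −ln p_j(x_i)** (in nats) under a
  probability model, the "surprise" of seeing the element.

Combining a model panel with an operator panel tensorially,
`(m_1 … m_M) ⊗ (R, I)` say, gives each element a nested representation;
with the `info` operator alone, element `x_i` gets the spectrum
`s_i = (h_{1i}, …, h_{Mi})` and model `m_j` dually gets the co-spectrum
`s^j = (h_{j1}, …, h_{jN})` — the same tensor read along the other axis.

Three front-ends build the probability models:

* **kmer** — empirical k-mer frequencies of a (subsampled) FASTQ/FASTA
  file (k = 6 by default).  Sorting bins by descending probability pairs
  each k-mer with a rank, giving the *zipfian co-spectrum*
  `(r_1, h_1, …, r_D, h_D)`: linear in (ln rank, h) for power-law word
  frequencies, with slope tracking repeat content and sharp turning
  points flagging technical artefacts.  Enriched k-mers greedily assemble
  into contaminant contigs.
* **aligninfo** — windowed alignment-depth models over a reference panel:
  `p_j(x_i)` is the depth in a window centred on `x_i`'s best-hit position
  on reference `j`, divided by the total queries aligned to `j`.  Also
  best-hit percent-identity co-spectra for comparing many draft
  assemblies.
* **taxa** — per-batch BLAST taxonomy hit counts over the union of all
  taxa names ever seen, accumulated facility-style across runs.

On top sit three metrics (Euclidean; rank-inverse-weighted zipfian
distance; cluster-projection distance, which k-means-clusters the spectra
and compares co-spectra on within-cluster means), classical MDS
embedding, average-linkage heatmap ordering with Newick dendrograms, and
a fully seeded synthetic-data module that plants recoverable structure
(species mixtures, adapter spike-ins, segment relocations, batch
mislabelling) in all three input classes.

## Worked example

`examples/03_adapter_detection_and_assembly.py` simulates one clean
sample and one with adapter read-through in 5% of reads, then diagnoses
and reconstructs the contaminant:

```text
adapter rate 0.0: 0 turning point(s)
adapter rate 0.05: 2 turning point(s), strongest at rank 28
longest assembled contig: AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGCTA
planted adapter:          AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGCTA
exact reconstruction: True
```

The clean lane's zipfian curve is smooth in ln-rank, so no turning point
is reported.  The spiked lane's 33 co-abundant adapter 6-mers occupy the
top ranks, put a sharp step (turning point) near rank 33 into the curve,
and greedy suffix–prefix assembly of those 6-mers returns the complete
38-base adapter — recovered from k-mer statistics alone, with no prior
knowledge of the adapter sequence.

The other examples walk the remaining capabilities: operator algebra and
duality (`01`), mixed-species lane clustering by zipfian distance (`02`),
rearrangement detection via off-diagonal 2D sub-spectra (`04`), and
cumulative taxa-batch QC catching a mislabelled batch (`05`).  Each
prints what it computes and what the numbers mean.

A thin CLI wires the same calls into shell workflows
(`prism kmer zipf`, `prism qc-lane`, `prism taxa qc`, …); every run
writes a `manifest.json` with its inputs, parameters and seed.

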