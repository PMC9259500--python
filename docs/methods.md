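# Methods

## Scope and model of the analysis

`seascape` implements the computational core of a genome-resolved survey of
microbial biosynthetic potential: from per-genome quality estimates and an
ANI matrix to species clusters; from BGC domain-feature vectors to gene
cluster families (GCFs) and clans (GCCs); from family assignments and a
reference feature table to novelty calls; from alignment summaries to
per-cell family abundances; and from abundance profiles to community types
and diversity statistics. Upstream sequence-level tools (assembly, binning,
quality estimation, BGC prediction, domain extraction, read alignment,
taxonomy) are treated as providers of the input tables, not re-implemented.

## Genome quality

Each genome carries up to two estimator outputs (completeness/contamination
and completion/redundancy). A genome is retained when **either** estimator
reports completeness ≥ 50% and contamination ≤ 10%; the estimates are then
averaged into mcpl and mctn (a single estimate stands alone when the other
estimator is missing — discarding such genomes would bias against isolate
references that only ever receive one estimate). Quality classes follow the
community-standard cascade: high (mcpl ≥ 90, mctn ≤ 5), good (≥ 70, ≤ 10),
medium (≥ 50, ≤ 10), else fair. The published form of the fair class
("mcpl ≤ 90% or mctn ≥ 10%") overlaps the other classes if read literally;
the cascade is the only consistent reading and is what is implemented.

Scores: Q = mcpl − 5·mctn and
Q′ = Q + mctn·(strain heterogeneity)/100 + 0.5·log₁₀(N50).
The log base is not stated where the formula is printed; base 10 matches the
dRep implementation the formula is attributed to. Species are clustered by
average linkage on (100 − ANI)/100 cut at 0.05 (the 95% ANI species
boundary); the two-stage Mash/ANImf scheme of dRep collapses to one linkage
pass here because ANI computation itself is out of scope and the matrix is
an input. Representatives maximize Q′, with deterministic tie-breaks (larger
N50, then smaller genome id) that the source procedure leaves unspecified.

Completeness-corrected genome size is length/(completeness/100), applied
only inside `corrected_genome_size`; completeness is a percentage (0–100]
everywhere else.

## Family and clan clustering

All-vs-all cosine distances between nonnegative BGC domain-weight vectors
feed **one** average-linkage dendrogram, cut at 0.2 (GCF) and 0.8 (GCC).
Cutting a single tree at two heights makes GCF ⊂ GCC nesting structural
rather than empirical; the assignment object asserts it on every run anyway.
Feature weights are used raw: cosine distance is scale-invariant, so
per-row normalization would be a no-op, and sub-pfam refinement is upstream.
Cluster labels are canonicalized by the lexicographically smallest member
id, making output invariant to input row order. The distance matrix is held
dense; at the intended desk scale (≲ 20,000 BGCs) this is ≤ ~3 GB of
float64 condensed distances.

Filtering keeps BGCs on scaffolds ≥ 5 kb (fragmentation guard) and can drop
externally sourced genomes not detected in the sample set. Dereplication
keeps the longest BGC per (GCF, species), ties to the smaller id; BGCs on
unbinned scaffolds join clustering but are skipped by dereplication because
they lack a species label. The contig-edge "complete" flag is carried and
reported, never used to filter.

## Novelty

Per representative BGC, the minimum cosine distance to each reference table
(vocabularies reconciled by union, absent domains zero — exact for cosine);
per family, the mean of member minima. Novel GCF: mean > 0.2 (strict — a
family exactly at the threshold is not novel); remote GCC: mean > 0.4,
twice the family-defining threshold. Display percentages round half-up to
integer percent (computed with exact rational arithmetic so binary-float
representation can never flip a half); machine outputs keep full precision.

## Profiling

Alignment filters are inclusive at the boundary. Presets: `genome`
(≥ 45 aligned bases, ≥ 97% identity, ≥ 80% of the read covered) for genome
detection/mapping rates; `gene` (≥ 45 bases, ≥ 95% identity) for
gene-catalogue profiling. Fractional assignment is single-pass: unique
inserts count 1; each ambiguous insert is split across its targets in
proportion to the targets' final unique counts, uniformly when none has
unique support. No EM iteration — the procedure is a one-step proportional
allocation, and the suite checks exact conservation (Σ assigned = number of
inserts, to 1e−9 per insert) and equivalence with a per-insert enumeration
oracle.

Gene abundance is inserts per kilobase (any consistent unit cancels in the
cell normalization and log-ratios). BGC abundance is the median over its
biosynthetic genes (even count → mean of the middle two); family abundance
is the sum over the family's dereplicated representatives. Cell
normalization divides by the sample's summed marker-gene (mOTU) abundance —
the phrase "mOTU count per sample" admits a summed-abundance or
marker-median reading; summed abundance is the default here and the
transcriptomic path uses the marker-median variant explicitly. Zero
normalizers yield missing values, never infinities. Prevalence is the
percentage of samples with abundance > 0.

Average genome size per sample: relative mOTU abundances (renormalized over
surviving mOTUs) weight the per-mOTU mean of completeness-corrected member
sizes, with members below 70% completeness excluded. Transcript activity is
log₂(length-normalized count / marker median), where the marker median is
taken over marker genes with nonzero counts; a sample counts as detected
only when strictly more than 5 of the 10 marker genes are seen, and
zero-count genes are missing rather than −∞.

## Community structure

Euclidean distances between per-cell GCF profiles; a pluggable embedding
(deterministic PCA by default, UMAP behind the same call when installed —
the bespoke content is the cluster-size criterion and the test, which must
not depend on one reducer); HDBSCAN density clustering with the minimum
cluster size chosen by maximizing the summed per-point membership
probability, noise points contributing zero and ties going to the smallest
candidate. The default candidate grid {2, 5, 10, 20, 50} (capped at n/2) is
a design choice; no grid is prescribed by the source procedure. Cluster
structure is tested with PERMANOVA **on the non-reduced distances**:
pseudo-F from the standard sum-of-squared-distances decomposition, p from
seeded label permutations with the add-one estimator (never exactly zero),
999 permutations by default. Noise-labelled samples are excluded. A
balanced variant resamples equal group sizes R times (default 20) and
reports median F and p, as a control against group-size bias.

Shannon diversity of product types uses natural log over canonicalized
(order-independent multiset) type keys; BGC-rich species have at least one
genome with strictly more than 15 BGCs; the predatory index is
#predatory − #non-predatory marker hits.

## Synthetic data: what it emulates, and what it does not

The generators plant known answers into every input table. Geometry of the
BGC universe: each clan owns a disjoint vocabulary block (between-clan
cosine distance ≈ 1 > 0.8); within a clan, family centroids share a common
component and carry equal-norm disjoint private components, so within-clan
family distances sit near 0.5, between the two cuts. Member vectors apply
multiplicative gamma jitter with coefficient of variation σ chosen by
σ² = noise/(1 − noise), which makes the expected within-family cosine
distance equal the `noise` parameter (for two independently jittered copies
of a centroid, E[distance] ≈ σ²/(1 + σ²)). Sparse spurious-domain additions
(rate 2·noise, weight 5% of the mean nonzero weight) are second-order.
**Calibration bound:** for noise ≤ 0.10 the 0.2/0.8 cuts recover the planted
partitions exactly; the suite checks ARI = 1.0 on 10 seeds at the bound.
noise = 0 reproduces centroids verbatim.

Genome collections have block ANI (within-species 99.05–99.95, within-genus
85.5–93.5 with species paired two by two, otherwise 72–79) and quality
estimates cycling through class templates so all four classes and both
retention routes occur. Profiles plant community types as type-exclusive
GCF usage (weight 5.0 vs 0.1); insert counts are Poisson at unit depth
multiplied by an integer per-sample depth factor (1–4), so depth rescaling
is exact, not approximate; a configurable fraction of inserts lists two
candidate targets. Default sizes (3 clans × 4 families × 5 BGCs, 8 species
× 3 genomes, 24 samples, 2 community types, 10% ambiguous inserts) keep the
full pipeline near one second while leaving every rule with positive and
negative cases.

What the generators do **not** emulate: real domain-weight distributions
(BiG-SLICE sub-pfam features are not modelled; weights are generic gamma
scores), BGC fragmentation correlated with assembly quality, phylogenetic
correlation between families and taxa, compositional coupling between
samples, or read-level error. Passing tests therefore demonstrate that the
operations implement their rules and recover structure of the planted kind;
they do not certify performance on real ocean metagenomes.

## Numerical choices

Cosine distances are clipped to [0, 1] against floating-point drift.
Seeding: one root integer seed; each generator table uses
`default_rng([seed, stream])` so adding a table never shifts existing
outputs. All tie-breaks (representatives, dereplication, labels, candidate
sizes) are deterministic and documented above. Division by zero anywhere in
profiling yields missing values with a logged warning. Statistical checks
in the suite run at reduced sizes chosen to finish quickly on one CPU
(e.g. the PERMANOVA null calibration uses 500 simulations of 16 samples
with 999 permutations); sizes are stated in the tests themselves.

## Known limitations

- Average-linkage cuts use the cophenetic criterion (merges at height ≤ t);
  with tied distances the merge order, and hence the partition, can depend
  on floating-point tie-breaking — ties have measure zero for the
  continuous feature models used here.
- The dense distance matrix bounds practical problem size (~20k BGCs).
- PERMANOVA assumes exchangeability under the null; the balanced-resampling
  control addresses unequal group sizes, not dispersion differences.
- The novelty call is distance-based only; shared-membership "overlap" with
  a reference family is out of scope.
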