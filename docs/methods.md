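# Methods

## Model

`phagesig` measures phage/plasmid-host relatedness with two
alignment-free genome distances that probe different biology.

**Compositional distance (k4freq).** Every genome X is summarized by
its genomic signature: the vector of relative frequencies
f_w(X) = X_w / S_X over all 4^k words w, where X_w is the
sliding-window occurrence count and S_X = Σ_w X_w. Two genomes are
compared by the Euclidean distance between their k = 4 signatures.
The biological premise is amelioration: DNA that replicates inside a
host lineage converges to that lineage's mutational and
codon-usage biases, so a temperate phage's tetramer signature tracks
its host group while an obligately lytic phage's does not. k = 4 is
used for phage/plasmid-to-host distances because phage and plasmid
genomes (tens of kb) give stable tetramer estimates but noisy
longer-word estimates; k = 6 is used for clustering bacterial genomes,
which are long enough to estimate 4096 frequencies reliably.

**Exact-match distance (k14exact / DSW).** With X the genome of
smaller total (S_X ≤ S_Y, ties keeping the first argument as X):

    SIM(X, Y) = Σ_{w : Y_w > 0} X_w / S_X,    DSW(X, Y) = 1 − SIM(X, Y)

SIM weights the query side by occurrence (X_w / S_X) but tests the
target side only for presence (Y_w > 0); it is deliberately not a
Jaccard index on distinct words. The word length is chosen so that a
shared word is evidence of common descent rather than chance: under an
i.i.d. uniform null, a fixed k-word occurs in a genome of length L
with probability 1 − (1 − 4^−k)^(L−k+1), which at L = 5 Mb is ≈ 7.2%
for k = 13 and ≈ 1.85% for k = 14 — the smallest k under a 2% ceiling,
hence the default k = 14. DSW = 0 therefore means the smaller genome
occurs verbatim in the larger (a prophage or an integrated plasmid);
DSW = 1 means no shared 14-mer at all. Distances of real
phage-host pairs live near 1 (a 50 kb phage shares at most a tiny
occurrence-fraction of a 5 Mb chromosome), which is why meaningful
thresholds for this method sit around 0.95.

### Counting conventions

* Windows never span a contig boundary: junctions in multi-contig
  assemblies are artifacts, not sequence.
* A window containing any non-ACGT base is skipped and tallied in
  `skipped_windows`, so ambiguity codes neither match anything nor
  distort the denominator (S_X naturally renormalizes).
* Only the deposited strand is counted by default
  (`strand_mode="forward"`); `"both"` also counts the reverse
  complement of each contig. Double-stranded genomes are close to
  strand-symmetric in composition, so the choice rarely moves k4freq
  materially, but it is exposed because it is a genuine degree of
  freedom.
* Counts are stored sparsely (sorted 2-bit-packed word codes plus
  counts). At k = 14 the word space is 4^14 ≈ 2.7·10^8, so dense
  per-genome tables are never materialized; SIM is a merge of two
  sorted code arrays (binary search), O((n+m) log m).
* Word order is lexicographic over A<C<G<T everywhere, so signature
  vectors are bit-comparable across runs.

## Host clustering

Host genomes are embedded by k = 6 signatures, mean-centered and
projected by PCA (no column scaling — standardizing 4096 mostly-tiny
frequency columns would inflate rare-word noise), then clustered with
DBSCAN at eps = 0.50, MinPts = 10. Genomes in no dense region are
noise and are dropped before group-distance work, since a host group
needs coherent members for its mean distance to mean anything.

Numerical choices:

* **Embedding scale.** A Euclidean eps is only meaningful on a fixed
  scale, and raw PCA scores of frequency vectors live at ~10^-2. By
  default each retained component is standardized to unit variance
  before DBSCAN, making eps = 0.50 dimensionless and portable across
  datasets. Consequence to be aware of: a collection with *no* density
  structure (one homogeneous blob) rescales to unit spread and is
  reported as all-noise — read that as "no density contrast", and use
  `scale="none"` to apply eps on the raw score scale instead.
* **Components.** Default 2 (the usual regime where genus-scale
  composition separates); configurable.
* **Determinism.** Genomes are sorted by id before clustering, so the
  partition is invariant to input order; each PCA component's sign is
  fixed so its largest-magnitude loading is positive; clusters are
  renumbered by decreasing size with ties broken by smallest member
  id. Identical inputs give identical reports bit-for-bit.
* Fewer genomes than MinPts cannot form any cluster: the report is
  all-noise by construction, a warning case rather than an error.

## Threshold learning and classification

For each phage (or plasmid) the distance to every member of its
associated host group is computed; the group summary is the arithmetic
mean, the sample standard deviation (n − 1; 0 for a single host), the
minimum, and n. Given labelled training elements, the classifier
"lysogenic iff mean distance ≤ t" is swept over candidate thresholds —
midpoints between consecutive sorted unique distances plus sentinels
below the minimum and above the maximum — producing an ROC curve
(positive class = lysogenic). AUC is the trapezoid area over the
curve sorted by FPR (equal to the Mann-Whitney concordance
probability, which the tests verify independently). The operating
threshold is the candidate whose (FPR, TPR) is closest in Euclidean
distance to the ideal classifier (0, 1); ties go to the smallest
threshold. The midpoint of the two class means is also reported for
comparison, since published thresholds for this family of methods read
as close to that quantity; the ROC closest-point rule is the canonical
estimator here. Calls are hard (no abstention band); the boundary
mean = t goes to lysogenic. Thresholds are method-specific (k4freq
values live near 0.02-0.05, k14exact near 0.9-1.0) and the CLI warns
when a threshold is on the wrong side of 0.5 for its method.

Between-class significance testing (e.g. Kruskal-Wallis across groups)
is routine statistics outside the method core; the emitted distance
tables are tidy TSV precisely so standard packages can consume them.

## Association screening

`association_screen` computes a GroupDistance for every element x
cluster pair. With annotations it marks each element's own cluster and
flags, as candidate horizontal transfer, any non-associated pair whose
mean falls below the mean of that cluster's own associated elements —
the k14exact variant is the sensitive one here, since an element
sharing a large verbatim fraction with even one foreign genome drives
its minimum (reported) and mean down sharply. Clusters with no
annotated elements of their own yield no flags (no baseline).

## Synthetic data

The generator builds the compositional world the distances assume,
with known truth labels:

* **Host groups** are order-0 (optionally order-1 Markov) sequence
  models whose base compositions are spaced over GC 35-65% — the
  realistic span between bacterial genera — with small seeded AT/GC
  skews so equal-GC groups still differ. Genomes are i.i.d. draws of
  200 kb by default (a deliberate ~20x shortening of real chromosomes
  for test speed; lengths are config knobs and all statistics used are
  length-normalized).
* **Lysogenic-like phages** (50 kb) are drawn from their host group's
  composition (amelioration) and additionally spliced as prophages
  into 3 of the group's 20 host strains — temperate phages physically
  reside in host chromosomes, and this residence is exactly what the
  exact-match distance detects. Insertion positions are chosen in
  original host coordinates and applied high-to-low so that multiple
  prophages in one host stay contiguous (an insertion can never split
  an earlier one).
* **Lytic-like phages** mix the group composition with a
  phage-specific alien composition at weight 0.35 — a clear but not
  caricatured divergence; at weight 0 the two classes are statistically
  identical and learned thresholds are uninformative (AUC ≈ 0.5),
  which the tests confirm.
* **Outlier hosts** (GC ≈ 80%) model distant taxa with too few
  relatives to form a cluster; density clustering should reject them
  as noise.
* **Disjoint pairs** are built over the {A,C} vs {G,T} alphabets, so
  no k-word (k ≥ 1) can be shared; the construction is verified by
  brute-force intersection before returning.

Everything is a pure function of (config, seed): a seed reproduces
byte-identical FASTA.

What the generator does *not* emulate: real genomes' repeat structure,
shared mobile elements and horizontally exchanged genes between
groups, within-genus compositional gradients, partial prophage decay,
or assembly noise. Passing the synthetic recovery tests therefore
shows the pipeline is correct and well-conditioned under its own
assumptions — clean compositional groups, genuine verbatim residence —
not that real-data accuracy will match; on real references the class
overlap is substantially larger (published class means for this method
family sit at 0.030 vs 0.019 for k4freq, 0.965 vs 0.895 for k14exact).

## Problem sizes

The default test-time study is 3 host groups x 20 genomes of 200 kb,
50 + 50 phages of 50 kb (prophages in 3 strains each): large enough
that hexamer clustering, both distances, ROC learning and
classification all operate in their intended regime, small enough that
the full suite runs in well under a minute of compute for generation
plus a few tens of seconds for the k = 14 counting. The exact-match
identities are exercised at realistic scale (40 kb phage in a 1 Mb
host; 5 Mb random genomes for the random-match rate).

## Known limitations

* Group-level, not strain-level: neither distance resolves which
  strain of a group a phage infects (consistent with the method
  family's published behaviour); calls are relative to a host *group*.
* Thresholds are dataset-dependent. The learned threshold reflects the
  training collection's taxa and label quality; applying a threshold
  learned on one collection to another assumes comparable composition
  spread.
* DSW is asymmetric in information content: it asks only whether the
  smaller genome's words exist in the larger one, so a chimeric query
  half-contained in a host scores SIM ≈ 0.5 regardless of what the
  other half is.
* Hard calls near the threshold carry no confidence measure; elements
  with mean distance within ~1 sd of the threshold deserve manual
  review.
* The random-match closed form assumes i.i.d. uniform bases; skewed
  composition raises the chance-match rate somewhat, so the 2% design
  ceiling is approximate for extreme-GC genomes.
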