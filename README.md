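# phagesig

Alignment-free genomic distances for linking phages and plasmids to
bacterial hosts and inferring phage life cycle (lytic vs lysogenic)
directly from genome sequence — no alignment, annotation, or marker
genes.

**Who it is for.** Phage biologists and microbiome researchers who have
candidate phage/plasmid genomes (isolates, MAG-associated contigs,
single-cell assemblies) and a set of candidate host genomes, and want a
fast, assembly-only answer to: *does this phage look temperate or lytic
with respect to this host group? Does this plasmid's host annotation
look right, or has it moved across taxa?*

## The two distances

For a genome X, let X<sub>w</sub> be the sliding-window occurrence
count of the k-mer w and S<sub>X</sub> = Σ<sub>w</sub> X<sub>w</sub>.
The genomic signature of X is the relative-frequency vector
f<sub>w</sub>(X) = X<sub>w</sub> / S<sub>X</sub> over all 4<sup>k</sup>
words.

**k4freq** — the Euclidean distance between tetramer (k = 4)
signatures:

    Eu(X, Y) = sqrt( Σ_w ( f_w(X) − f_w(Y) )² )

This measures compositional similarity. Temperate phages *ameliorate*:
residence in host chromosomes drags their oligonucleotide composition
toward the host's, so short k4freq distance to a host group is evidence
of a lysogenic lifestyle.

**k14exact (DSW)** — with X the genome of smaller total
(S<sub>X</sub> ≤ S<sub>Y</sub>):

    SIM(X, Y) = Σ_{w : Y_w > 0} X_w / S_X        DSW(X, Y) = 1 − SIM(X, Y)

the occurrence-weighted fraction of X's 14-mers whose word occurs at
least once in Y. At k = 14 a shared word is essentially never chance
between bacterial-scale genomes (expected random-match rate
1 − (1 − 4<sup>−14</sup>)<sup>L−13</sup> ≈ 1.8% for L = 5 Mb), so
DSW = 0 means X is inserted verbatim in Y (a prophage) and DSW = 1
means the genomes share no 14-mer at all.

Around the distances the package provides hexamer-signature host
clustering (PCA + DBSCAN, eps = 0.50, MinPts = 10), ROC-based threshold
learning (best threshold = curve point closest to (0, 1)), hard
lytic/lysogenic calls (lysogenic iff mean distance ≤ threshold), phage
reactivity ranking, plasmid–host association screening with
horizontal-transfer flags, and a synthetic-genome generator with known
truth labels.

## Worked example

Generate a small synthetic study (3 host "genera" of 6 strains each,
6 temperate phages integrated into 2 strains apiece, 6 compositionally
divergent lytic phages), then learn and apply the k14exact threshold:

```bash
phagesig simulate --seed 3 --groups 3 --genomes 6 --genome-length 20000 \
    --phage-length 4000 --lysogenic 6 --lytic 6 --prophage-hosts 2 -o fixtures/
phagesig dist --method k14exact fixtures/phages.fasta fixtures/hosts/ -o dist.tsv
phagesig threshold --method k14exact dist.tsv fixtures/truth.tsv -o roc.json
```

`threshold` logs, for this seed:

```
INFO AUC 1.0000, best threshold 0.944347; wrote roc.json
```

i.e. the phage-to-host mean exact-match distances separate the two
planted lifestyles perfectly (AUC 1.0), and the ROC point closest to
the ideal classifier puts the decision boundary at DSW ≈ 0.944 —
temperate phages score lower because each resides verbatim in two of
the 18 host genomes. Applying the threshold:

```bash
phagesig classify --method k14exact --threshold 0.944347 dist.tsv -o calls.tsv
```

writes one row per phage, e.g. `phage_lyso_001  all  k14exact
0.888833  0.944347  lysogenic`: this phage's mean distance to the host
set (0.889) is below the threshold, so it is called lysogenic — which
matches its planted label (all 12 calls do).

`phagesig kchoice --length 5000000` reproduces the choice of word
length: k = 14 is the smallest k whose expected random-match rate
against a 5 Mb genome is below 2% (≈ 1.85%; k = 13 gives ≈ 7.2%).

## Applying to a real reference set

The thresholds shipped in the literature for this family of methods
(≈ 0.026 for k4freq, ≈ 0.955 for k14exact) derive from thousands of
RefSeq host genomes and labelled phages and cannot be recomputed from
this repository alone. Given such a collection — host genomes (one
FASTA per genome) in `hosts/`, phage genomes in `phages.fasta`, and a
`labels.tsv` association table with `element_id, role, host_group,
lifestyle` columns — the full workflow is:

```bash
# 1. hexamer clustering of hosts; drop unclustered (noise) genomes
phagesig cluster --k 6 --eps 0.50 --min-pts 10 hosts/ -o clusters.json

# 2. phage-to-host distances, one table per method
phagesig dist --method k4freq   phages.fasta hosts/ -o dist_k4.tsv
phagesig dist --method k14exact phages.fasta hosts/ -o dist_k14.tsv

# 3. learn each method's lytic/lysogenic threshold from the labelled pairs
phagesig threshold --method k4freq   dist_k4.tsv  labels.tsv -o roc_k4.json
phagesig threshold --method k14exact dist_k14.tsv labels.tsv -o roc_k14.json

# 4. classify unlabelled phages / rank candidate broad-host-range phages
phagesig classify --method k4freq --threshold <from roc_k4.json> dist_k4.tsv -o calls.tsv
phagesig rank --method k4freq --threshold <from roc_k4.json> dist_k4.tsv -o rank.tsv

# 5. plasmid screening against the host clusters (flags candidate
#    cross-cluster horizontal transfer)
phagesig screen --method k14exact --clusters clusters.json \
    --associations labels.tsv plasmids.fasta hosts/ -o screen.tsv
```

Step 2's table should be restricted to each element's associated host
group before step 3 (run `dist` per group, or filter the TSV); group
comparisons such as Kruskal–Wallis between lytic and lysogenic
distances can be run on `dist_*.tsv` with standard statistics packages.

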