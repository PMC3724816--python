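# favtree

Whole-genome phylogenies from averaged best-hit E-value similarity.

`favtree` implements an alignment-free method for estimating evolutionary
distances between prokaryotic genomes from all-vs-all protein similarity
searches, and for building neighbor-joining trees from them. It is aimed at
microbial phylogenomics: situations where whole proteomes are available,
single-marker trees (16S rDNA) lack resolution, and ortholog-set methods
discard too many genes. The method uses essentially every protein in both
genomes.

## The method

For an ordered genome pair (X, Y), every query protein of X contributes one
point on a two-dimensional display: its self best-match log₁₀ E-value
(X searched against X — the best match is the protein itself) on the x axis,
and its best-match log₁₀ E-value against Y on the y axis. E-values of zero
are floored at 10⁻¹⁸⁰ (log value −180); hits above the search cut-off
(E = 10) are discarded. Averaging the coordinates over the n points gives
(AvE_X, AvE_Y), and after shifting the origin to the cut-off point
(C_OV, C_OV):

    m = (AvE_Y − C_OV) / (AvE_X − C_OV),   C_OV = log₁₀ 10 = 1

m = 1 for identical genomes and m = 0 when no similarity survives the
cut-off. The dissimilarity statistic is the departure of this slope from the
diagonal, tan θ = (1 − m)/(1 + m) (the tangent of the angle between the two
lines; the simpler reading 1 − m is available as the `complement`
convention). tan θ is calibrated against 16S rDNA substitution rates
S (percent substituted sites among ungapped aligned columns) through an
exponential regression

    S = const1 · (e^{const2 · tan θ} − 1)

fit by least squares on the untransformed S scale (published constants
const1 = 5.0112, const2 = 2.2223 ship as the `satoh2013` preset). The
calibrated value F = S(tan θ) is a distance on the percent-substitution
scale. Because search results are asymmetric, each unordered pair has two
values F_XY and F_YX; the indices

    F_AV = (F_XY + F_YX)/2,  F_H = max,  F_L = min

combine them, and F_AV — the index robust to unequal gene content — is the
default for tree building. Trees are inferred with Saitou–Nei neighbor
joining; uncertainty comes from a bootstrap that resamples k best-match
(gene, E-value) points with replacement within every ordered pair, B times,
summarized by a strict-majority consensus.

## Worked example

Everything below is synthetic and self-contained: `simulate` draws a random
6-taxon tree, derives per-pair target slopes from its path lengths through
the inverse calibration, and writes noise-free best-match tables plus the
generating tree.

```
$ favtree simulate --taxa 6 --genes 200 --seed 11 -o demo
wrote 36 best-match tables and true_tree.nwk to demo

$ favtree run --tables demo/tables --bootstrap 100 --resample 1000 --seed 11 -o demo/out
artifacts in demo/out (config sha256:1b9d06bba5b9c66a)
```

`demo/out/similarity.tsv` holds the per-ordered-pair statistic — n is the
number of plotted points, m the slope, tan_theta the dissimilarity:

```
query_taxon  subject_taxon  AvE_X        AvE_Y        n    m          tan_theta
T0           T1             -87.9440742  -54.9897734  200  0.6294941  0.2273747
T0           T2             -87.9440742  -68.3462708  200  0.7796615  0.1238092
```

`demo/out/tree.nwk` is the F_AV neighbor-joining tree (branch lengths on the
percent-substitution scale) and `demo/out/bootstrap_consensus.nwk` the
consensus of 100 replicate trees, supports out of 100 as internal labels:

```
(T0,T2,(T1,(T4,(T3,T5)100)100)100);
```

Every internal split reaches 100/100 here because the fixture is noise-free.
Both trees match the generating topology:

```
$ favtree compare demo/true_tree.nwk demo/out/tree.nwk
RF distance: 0
```

With real data you would start from tabular search output instead:
`favtree prep --hits X_vs_Y.tsv --query-taxon X --subject-taxon Y -o tables`
(one file per ordered pair, self pairs included), optionally fit your own
calibration from aligned 16S pairs with `favtree calibrate`, and continue
with `distmat`, `tree`, `bootstrap`, or the one-shot `run`. The
`--rbh-only` flag restricts the statistic to reciprocal best hits;
`reduce-genes` reruns the inference while subsampling one genome's gene set
to probe gene-content robustness.

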