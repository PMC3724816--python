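# Methods

## Model and procedure

The package estimates genome-pair distances from the E-values of
best-matched proteins. The underlying assumption is that, for an ordered
pair (X, Y), the cloud of points (self log₁₀ E-value, cross log₁₀ E-value)
over X's query proteins is well summarized by the line through the cut-off
point (C_OV, C_OV) and the averaged coordinates (AvE_X, AvE_Y): its slope m
measures how much of each protein's self-similarity is retained against the
other genome, averaged over (almost) the whole proteome. Averaging log
E-values before forming the ratio normalizes for protein length, which
dominates the magnitude of self E-values; no per-gene ortholog filtering is
applied, so lateral transfer and gene-content differences enter the
statistic rather than being excluded.

Pipeline stages and where they live:

1. **Preprocessing** (`io`): best hit = lowest raw E-value per query among
   rows admitted by the cut-off; log₁₀ transform with E = 0 → −180 (also the
   clip floor for underflow). Ties at the minimum keep the first row in
   input order, matching the convention that search tools emit their best
   hit first; this makes parsing deterministic for a fixed file.
2. **Similarity** (`similarity`): points, averages, slope, tan θ. Genes
   without an admitted cross hit have no y coordinate and contribute no
   point; n counts plotted points only. The slope is clamped to [0, 1] with
   a warning — sampling noise can push AvE_Y marginally past AvE_X for
   near-identical genomes. A pair with zero shared points is scored
   tan θ = 1 with a logged warning rather than aborting a whole-matrix run.
3. **Calibration** (`calibration`): S from ungapped pairwise 16S alignment
   columns (U≡T; ambiguity codes excluded column-wise like gaps, since the
   substitution count is only meaningful over unambiguous sites);
   least-squares fit of S(tan θ) with scipy's Levenberg–Marquardt,
   initialized at const1 = max(S)/e, const2 = 1, which places the curve
   inside the data range and converges on all simulated calibration clouds
   we generate. R² is reported on the untransformed S scale. All points are
   used: both orientations of every pair and every 16S copy combination.
4. **Distances** (`distances`): F indices and symmetric matrices.
5. **Trees** (`trees`): neighbor joining, consensus, bootstrap,
   gene-reduction experiment, Jukes–Cantor 16S reference distances.

## Conventions chosen where the algebra was open

* **tan θ**: two readings satisfy the printed endpoints (0 at m = 1, 1 at
  m = 0). The default `angle` convention, (1 − m)/(1 + m), is the tangent of
  the actual angle between the slope-m line and the diagonal; `complement`
  (1 − m) is kept as an option. The two are monotone re-parameterizations of
  each other, and the calibration is refit (and tagged) per convention, so
  tree topologies are insensitive to the choice; models carry their
  convention and refuse evaluation under the other one.
* **Calibration form**: the default S = const1·(e^{const2·tanθ} − 1) forces
  S(0) = 0 — identical genomes must show zero 16S divergence. The pure
  exponential is available (`form="exp"`) for sensitivity analysis.
* **F_H / F_L**: read as max/min of the two orientations, which is the only
  two-case reading consistent with their names.
* **Orientation matrices**: F_XY and F_YX are asymmetric per ordered pair;
  neighbor joining needs a symmetric input, so "X" is fixed as the taxon
  earlier in the matrix label ordering and both cells of an unordered pair
  receive that orientation's value.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| cut-off E-value | 10 (C_OV = 1 on log scale) | E-value | hit admission + origin shift |
| zero-E sentinel | −180 | log₁₀ E | floor for E = 0 and underflow |
| convention | angle | — | tan θ definition |
| calibration | `satoh2013` preset (5.0112, 2.2223) | S in % | tan θ → distance scale |
| index | F_AV | % substitutions | matrix entry for tree building |
| bootstrap B, k | 100, 1000 | — | replicates; points resampled per ordered pair |
| reduction fraction, R | 0.10, 10 | — | gene-content robustness experiment |

Defaults reproduce the method's published settings.

## Resampling semantics

The bootstrap unit is the (query gene, E-value) point, drawn with
replacement, independently per ordered genome pair within each replicate —
the only reading under which every matrix entry stays defined for every
replicate. Replicate r uses the seed stream (seed, r) of numpy's
`default_rng`, so single replicates are individually reproducible and
support values are invariant to replicate order. The consensus is strict
majority (> 50%, a 50/50 split is excluded), over *unrooted* bipartitions:
NJ roots its output arbitrarily, so counting rooted clades would lose
support on identically shaped replicates; the implementation normalizes
each split to the side not containing the lexicographically first leaf. An
extended-majority option greedily adds compatible minority splits.
Consensus trees carry supports but no branch lengths.

The gene-reduction experiment subsamples ⌊fraction·N⌋ genes of one taxon
without replacement and rebuilds every table involving that taxon. It
operates on best-match tables, not by re-running a search: queries of other
genomes whose best match was removed are treated as having no admitted best
match (their second-best hit in the reduced database is unknowable from the
tables). This slightly overstates the perturbation relative to a true
re-search, which is conservative for the robustness claim being tested.

## Negative branch lengths and other numerics

* NJ is scikit-bio's Saitou–Nei implementation with negative branch-length
  estimates clamped to zero; on additive input no clamping occurs and the
  generating tree is recovered exactly (verified to < 1e−14 in path
  lengths).
* Jukes–Cantor distances error at p ≥ 0.75 (saturation) naming the pair.
* PHYLIP matrices are written with 10-character names; longer names are
  truncated with a collision check and restored on read via a sidecar label
  map. Values survive a round-trip to at least 6 significant digits.
* A 2-taxon matrix yields the single-edge tree with the distance split
  evenly between the two pendant branches (only the total is identifiable).
* The slope is exactly 1 (and tan θ exactly 0) for any self-comparison
  because the two coordinate vectors are the same object; no tolerance is
  involved.

## What the synthetic generators emulate — and what they do not

`synthetic.gen_best_hit_tables` synthesizes the E-value geometry directly:
self log-E values uniform in [−180, −5] (mirroring the length-driven spread
of real self matches), cross values placed on the line of slope `target_m`
through the cut-off point plus optional Gaussian noise, clipped to
[−180, C_OV]. Target slopes can be set per ordered pair or derived from a
generating tree by inverting the calibration, which makes end-to-end
topology recovery checkable (path lengths must stay below the model's value
at tan θ = 1, ≈ 41% for the preset). What is *not* modeled: real search
behavior (score statistics, low-complexity filtering), paralogy and gene
duplication, indels, genuinely missing best hits, and lateral transfer.
Passing tests therefore demonstrate the correctness of the math and the
pipeline's determinism — not that the statistic resolves any particular
real clade.

`evolve_sequences` runs a plain Jukes–Cantor process (uniform root, equal
rates, no gamma variation, no indels) to produce gapless 16S-like
alignments for the substitution-rate and reference-tree code paths.

Problem sizes used in the test and acceptance suites — 5–12 leaves for the
NJ oracle (200 random matrices), 8 taxa × 300 genes for the end-to-end and
gene-reduction fixtures, 5,000 calibration points — were chosen to exercise
every code path at the method's published replicate counts (B = 100,
k = 1000) while keeping the whole suite near-instant; the statistics
involved are insensitive to further scale.

## Known limitations

* The calibration preset was fit on a specific set of prokaryotic genomes;
  distances for taxa far outside that range extrapolate the exponential.
* tan θ saturates at 1, so very distant pairs compress near the model's
  maximum; the method is not designed for inter-domain distances.
* The F indices are not guaranteed metric (triangle inequality) on noisy
  data; NJ tolerates this, but strong non-additivity will surface as
  negative branch estimates (clamped, with the matrix left untouched).
* Gene-content reduction from tables is an approximation of re-searching
  against a reduced database (see above).
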