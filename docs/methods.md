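# Methods

## The model

`phylonull` treats community assembly inference as a null-model problem:
every statistic is an observed quantity standardized against an explicit
randomization, and the ecological interpretation lives entirely in the
direction and magnitude of the departure.

**Patristic distances.** The tree is read as strict Newick (missing branch
lengths are rejected by default; a config flag can default them to 1.0,
but silent defaults corrupt distance-based statistics, so this is opt-in).
`d(i,j)` is the sum of branch lengths on the tip-to-tip path. All matrices
use the pruned tree's tip order, and the feature table is reordered to
match, so outputs are deterministic.

**Alpha scale.** For a sample with relative abundances `p`:

- weighted MPD = `Σ_{i≠j} p_i p_j d(i,j) / Σ_{i≠j} p_i p_j` (conspecific
  pairs excluded; note picante's `abundance.weighted=TRUE` variant keeps
  the zero-distance diagonal in the weighting — the cross-check test
  rescales for this),
- weighted MNTD = `Σ_i p_i · min_{j≠i, present} d(i,j)`,
- NRI/NTI are the negated standardized effect sizes, so positive values
  mean clustering.

**Beta scale.** βMNTD(a,b) averages the two directional abundance-weighted
means of each present taxon's distance to its nearest taxon present in the
other sample. A taxon present in both samples is its own nearest relative
at distance zero; consequently βMNTD responds to turnover in *membership*,
not in relative dominance of shared taxa — a property that matters for
simulation design (below). A between-community-MPD variant
(`beta_metric="bmpd"`, the `comdist` statistic) is available behind a
config flag; the nearest-taxon form is the default because the framework's
definition of βNTI is stated in terms of βMNTD.

**The null.** The "taxa labels" scheme: the taxon labels of the pool's
distance matrix are permuted uniformly at random, leaving the distance
values unchanged as a multiset. Null distributions use 999 iterations by
default and are generated per pool — one compartment × week group — so
each week's communities are compared against their own taxon pool. For
βNTI all pairs in a pool are evaluated on the *same* shuffled matrix in a
given iteration (one shared permutation stream per pool), which preserves
the co-occurrence structure across pairs. Implementation note: shuffling
matrix labels is algebraically identical to applying the inverse
permutation to the abundance vectors, which avoids copying the matrix;
unit tests verify the identity against literal shuffled-matrix loops to
1e-12. Degenerate nulls (sd = 0, e.g. star trees or identical samples)
yield NaN with a warning, never ±infinity.

**RC_bray.** For each sample, null communities preserve observed richness
S and total abundance N: S species are drawn without replacement with
probability proportional to occupancy across the pool (a variant weights
by occupancy × pool relative abundance), each drawn species receives one
individual, and the remaining N − S individuals are allocated
multinomially by pool-wide relative abundance. RC = 2·[(#(null BC < obs)
+ ½·#(ties))/n_iter] − 1 ∈ [−1, 1]. Null communities are generated once
per sample and paired across samples per iteration rather than redrawn per
pair; the per-pair marginal null is identical (a sample's null draw
depends only on its own S, N and the pool) and the cost drops from
O(pairs) to O(samples) community draws. The null allocates discrete
individuals, so non-integer (spike-normalized) tables are first rescaled
by a single common factor until the smallest sample total reaches a floor
(default 1000) and rounded.

**Classification.** The decision tree tests determinism first: βNTI > 2 →
heterogeneous selection, βNTI < −2 → homogeneous selection; only within
|βNTI| < 2 is RC consulted (> +0.95 dispersal limitation, < −0.95
homogenizing dispersal, else drift/diversification). All inequalities are
strict; boundary-exact values fall to the stochastic/drift side and are
logged. Thresholds (2, 0.95) are configurable. Pairs with NaN in either
statistic are excluded and counted. Dominant-process ties break toward the
deterministic categories and are logged.

**Preprocessing order.** Singleton removal (dataset-wide total ≤ 1) →
spike normalization → tree alignment. The order is a package choice:
filtering raw integer counts first keeps "represented once" meaningful;
normalizing after filtering preserves within-sample ratios. Alpha
diversity is computed on the filtered counts with the spike column
*dropped* rather than divided out, because ACE is defined on integer
counts.

**Reproducibility.** One run seed; per-pool RNG substreams are derived
from (seed, CRC32 of the group key, stream name) via `SeedSequence`, so
results are independent of pool execution order and byte-identical across
reruns. Every TSV carries a header comment with the package version, input
hashes and seed.

## The synthetic-data generator

The generator emulates the *structure* of a season-long plant-compartment
survey: a shared species pool on one phylogeny, 3 compartments × 10 weeks
of null pools, replicate samples per pool with NAM-line/block/BBCH labels,
and an internal-standard spike taxon in root and rhizosphere samples
(lognormal jitter around a configurable depth emulates extraction
efficiency; leaf samples carry no spike, as spiking leaves is impractical
at their low bacterial loads).

- **Trees** are pure-birth (Yule): exponential waiting times with rate
  λ·k, plus one final Exp(λn) interval so every pendant edge is strictly
  positive.
- **Traits** evolve by Brownian motion (child = parent + N(0, σ²·branch))
  and are standardized to unit variance across tips, so filter widths and
  optima are in trait-SD units.
- **Communities**: sampling weights `(1−m)·local + m·metacommunity`, where
  local is the normalized product of Gaussian trait fitness
  `exp(−(trait − optimum)²/2σ_f²)` and an optional per-sample lottery;
  n_individuals are drawn multinomially (totals conserved exactly). The
  metacommunity is a lognormal abundance profile.

Five regime recipes map onto the five classification outcomes; the
defaults (in `regime_params.py`) are the calibrated study conditions at
the reference scale of 10 samples × 200 taxa × 1000 individuals:

| regime | key settings | mechanism |
|---|---|---|
| homogeneous_selection | σ_f = 0.3, m = 0.015, founder_keep = 0.5, trait_jump = 5 | shared narrow filter on a derived clade; membership lottery turns over clade subsets |
| heterogeneous_selection | σ_f = 0.25, 5 patches spread ±2.0, m = 0.02 | samples filtered toward distant optima |
| dispersal_limitation | no filter, m = 0.30, founder_alpha = 0.05 | strong per-sample gamma lottery: different random dominants per sample |
| homogenizing_dispersal | no filter, m = 1.0 | every sample drawn from the one metacommunity |
| neutral_drift | no filter, m = 0.5 | uniform local weights; only multinomial noise |

Two design points deserve explanation. First, because βMNTD ignores shared
taxa, "homogeneous selection" is only detectable when samples contain
*different but related* taxa — hence the Bernoulli membership lottery
(`founder_keep`), which turns over which clade members are present while
keeping the survivors' weights even (a gamma lottery concentrates weight
on too few taxa and starves the null of effective terms). Second, a plain
Brownian trait does not make trait-similar taxa phylogenetically tight
enough at 200 tips: taxa from unrelated clades converge on the same trait
values, and the filtered set is only weakly clustered. The homogeneous
regime therefore adds a single clade-level jump to the trait (a key
innovation on one internal branch holding 15–30% of tips) and centres the
filter on the derived clade; single-patch optima without a jump sit at the
0.95 trait quantile, where the Brownian extremes are most clade-like.

**What passing tests do and do not show.** The generator reproduces the
pieces of real data the null models respond to — phylogenetically
structured selection, membership turnover, dominance lotteries, spike
scaling, the pool design — but not sequencing artifacts (chimeras,
contamination, compositional read-depth variation), taxon-abundance
distributions fit to real surveys, temporal autocorrelation between weeks,
or genuine birth–death community dynamics. Regime recovery shows the
statistics respond to the intended mechanisms at realistic scale, not that
field data of a given survey will be classified correctly.

## Calibration audit

`calibration.py` runs the framework against its own null: communities are
even abundance profiles over 24 of 64 taxa whose identities are assigned
by uniform label permutation — exactly one draw from the distribution the
statistics standardize against. Under this construction SES(MPD) and
SES(MNTD) have mean ≈ 0 and sd ≈ 1 (measured: +0.01 ± 0.97 and
+0.02 ± 0.98 over 1000 replicates), and the deterministic-selection call
|βNTI| > 2 fires at ≈ 4.4–4.9% — the nominal two-tailed 5% less the small
deficit expected for a t-like statistic with a mildly skewed null. The
even 24-taxon profile is used because the 5% reading of a ±2 threshold
presumes a near-Gaussian null, which needs enough effective non-shared
taxa per sample; heavily dominated profiles make the null βMNTD skewed and
the call conservative. Pairs within a pool share samples, a tree and a
permutation stream and are strongly correlated, so the false-positive
audit spreads its ~1000-pair budget over 20 independent replicate pools
(fresh Yule tree each) rather than deepening one pool.

## Numerical choices and problem sizes

- Null sd uses the n−1 denominator; βNTI accumulates sums and squared sums
  in float64 over 999 iterations (values are O(1), no cancellation risk).
- RC ties are counted at half weight with a 1e-12 absolute tolerance.
- Group standard errors use sd/√n with n−1; single-member groups report
  NaN rather than 0; Pielou of a one-taxon sample is NaN (0/0) and is
  dropped (and counted) from group means rather than imputed as 0.
- ACE uses the classic rare/abundant cutoff of 10; an all-singleton rare
  group (zero coverage) falls back to bias-corrected Chao1 with a warning.
- Simpson defaults to the complement form (1 − Σp², the phyloseq
  `estimate_richness` convention); the inverse form is a config switch.
- Test problem sizes: oracle equivalence uses exhaustive subsets of ≤6-tip
  trees; self-calibration uses 1000 SES replicates and 60 replicate βNTI
  pools; regime recovery runs all five regimes at the full reference scale
  (10 × 200 × 1000, 999 iterations) over five seeds. The whole suite runs
  in a couple of minutes on one core.

## Known limitations

- The taxa-shuffle null is the only null family implemented (no
  independent-swap or trial-swap richness-constrained nulls).
- RC_bray's two-stage draw can be slow for very large pools; it is
  vectorized per sample but the species-draw stage loops over iterations.
- βNTI magnitudes are bounded by pool breadth: with small taxon pools and
  dense samples the null has little room to differ from the observation,
  and |βNTI| > 2 becomes hard to reach regardless of the true assembly
  process. This is a property of the statistic at small scale, not of the
  implementation; interpret shallow pools cautiously.
- The generator's regimes are calibrated at the reference scale; at very
  different scales the recipes may need re-tuning (the defaults live in
  one module and are plain data).
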