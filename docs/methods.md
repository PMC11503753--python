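# Methods

## Model and test

`pathdcor` tests statistical dependence between a pathway's expression
submatrix $X \in \mathbb{R}^{n \times r_i}$ and the spot coordinate
matrix $Y \in \mathbb{R}^{n \times 2}$ using the empirical Brownian
distance covariance. Both variables are treated as random vectors; no
functional form of the spatial trend is assumed, so monotone, patchy,
and nonlinear patterns are all visible to the test. The implementation
uses the V-statistic (biased) estimator: pairwise Euclidean distance
matrices are double-centered and
$\mathcal{V}_n^2 = n^{-2}\sum_{kl} A_{kl}B_{kl}$, normalized to
$\mathcal{R}_n \in [0,1]$ by the geometric mean of the two
self-covariances, with $\mathcal{R}_n = 0$ whenever a self-covariance
vanishes (a constant sample). The unbiased U-statistic variant is not
used. Each statistic evaluation is $O(n^2)$ time and memory, which
bounds the practical spot count at a few thousand per test.

### Permutation null

The null distribution is built by shuffling the sample labels of the
expression side while the coordinates stay fixed. Because double
centering commutes with a simultaneous row/column permutation, each
permuted statistic is obtained by conjugating the expression side's
centered matrix with the permutation; the coordinate side's centered
matrix and both self-covariance terms are computed once per test. The
p-value uses the add-one convention
$p = (1+\#\{R^{(b)} \ge R_{\text{obs}}\})/(1+B)$: it is never zero, ties
count as exceedances, and the attainable floor is $1/(B+1)$ (0.0001 at
the default $B = 10{,}000$). Since the fixed side is never permuted, the
self-covariances are permutation-invariant and ordering permuted
statistics by dCor or by dCov is equivalent; dCor is used.

A screen shares one block of permutation indices across all pathways
(`share_permutations=True`): p-values become directly comparable and
the ranking does not depend on the order in which sets are tested.
Per-set independent streams are available by flag.

## Preprocessing

Raw counts are filtered to genes detected (count > 0) in at least
`min_cells` spots (default 20, inclusive), scaled per spot to a common
target total — the median of spot totals by default, matching the usual
single-cell normalization convention — and transformed by
$x \mapsto \ln(1+x)$. Gene sets are filtered on their *annotated* size
(default 12–100, inclusive) before intersecting with the measured
genes; whether to filter before or after intersection is genuinely open,
and "before" was chosen because annotated size is a property of the
pathway rather than of the platform. A separate guard skips sets with
fewer than `min_genes_used` (default 5) measured genes — dCor on a
couple of genes is dominated by noise and, at $r_i \le 2$ in the
region contrast, degenerates to exactly 1. Sets of size one are valid
(the per-gene mode is the screen run on singleton sets).

Mixing expression and coordinates is done by an exact spot-id join:
any mismatch between the spot sets is an error, never a silent subset,
because dropping spots changes $n$ and with it every statistic.

## Multiple testing

Benjamini–Hochberg q-values are always emitted. A local false discovery
rate is added when at least 50 sets were tested: p-values are clipped to
$[1/(B+1), 1-1/(B+1)]$ (permutation p-values have an atom at the floor),
probit-transformed to $z = \Phi^{-1}(1-p)$, the marginal density $f(z)$
is fitted by Lindsey's method (Poisson regression of histogram counts on
a degree-7 polynomial basis, 71 bins), the null proportion $\pi_0$ is
estimated by central matching against the theoretical N(0,1) null over
$|z| \le 1$, and $\text{fdr}(z) = \pi_0 f_0(z)/f(z)$ clipped to [0,1].
With permutation p-values the resolution of the fdr is limited by $B$;
$B \ge 10\,m$ permutations for $m$ tested sets is recommended. Below 50
tests the density fit is unstable and the column is omitted with a
warning.

The Cauchy (ACAT-style) combination
$T = \frac{1}{k}\sum_i \tan(\pi(0.5 - p_i))$, aggregated through the
standard Cauchy upper tail, is provided for building pathway p-values
from per-gene tests; it is exact for a single input and robust to
dependence among the combined p-values.

## Region contrast

Spots of one cell type are split by a spatial neighbor rule: *inner* if
every neighbor (of any type) shares the cell type, *edge* otherwise.
The neighbor rule is a mandatory, logged parameter because no single
convention fits all platforms: `hex6` (6 nearest) suits Visium's
hexagonal lattice, `grid4` square lattices, and explicit `knn`/`radius`
rules cover irregular layouts. k-NN ties at equal distance break toward
the smaller spot index; spots with no neighbors (possible under the
radius rule) are inner by vacuous truth, configurable.

For a pathway with $r_i$ measured genes the *genes* become the samples:
gene $k$'s expression vector over the edge spots (length
$n_{\text{edge}}$) and over the inner spots (length $n_{\text{in}}$)
yield two $r_i \times r_i$ gene distance matrices, and dCor between
them measures whether the pathway's internal gene–gene structure is
preserved across the regions. Pathways are ranked ascending — near-zero
values flag divergent regional behavior. Per-gene standardization
within region is off by default (the statistic is already invariant to
a global rescaling of either region); no permutation p-value is
attached by default since the ranking is the deliverable, but a
gene-label permutation p-value is available by flag.

A caveat users should know: the V-statistic dCor does not vanish under
independence when the ambient dimension (spots per region) is
comparable to or larger than the sample count (genes). Distances
concentrate and the statistic carries a positive bias that grows with
dimension — fully independent 100-gene/50-spot regions give dCor around
0.8, not 0. The *ranking* across pathways analyzed under the same
regions remains meaningful because all sets share $n_{\text{in}}$,
$n_{\text{edge}}$; absolute values should be compared only at matching
$r_i$, which is why $r_i$ is reported alongside dCor.

## Simulator

The generator emulates a tumor-section geometry: a unit square grid
(default 30×30) with a central disk covering `cancer_fraction` (default
0.25) of the spots. Half of 3000 genes are spatially variable. A
non-SVG is i.i.d. Normal(1, 1). An SVG is the mixture
`scale * st + (1 - scale) * rand` where `st` is multivariate normal
over spots — cancer spots share a gene-specific mean drawn U(2, 5),
remaining spots U(0, 2) — `rand` is i.i.d. U(1, 5), and
`scale ~ U(0.1, 0.2)` keeps each single gene's pattern weak so that
only aggregation over a pathway reveals it. Twenty pathways of one
hundred genes each mix fifty SVG with fifty non-SVG genes, drawn
without replacement from the two pools.

The MVN covariance is taken over spots (it is what correlates
expression across locations). A symmetric matrix with U(0, 1)
off-diagonal entries and unit diagonal is generally indefinite; it is
repaired by clipping eigenvalues at $10^{-8}$ and renormalizing the
diagonal to 1 (a congruence, so positive semidefiniteness is
preserved). One covariance is shared across all SVGs per dataset
(per-gene covariances available by flag at $O(n^2)$ memory each);
independent per-gene draws from the shared covariance still differ per
gene. Simulated values are continuous and can be negative, so they are
emitted on the normalized-log layer and the count-normalization step
does not apply to them.

What the simulator does *not* emulate: count noise (no negative
binomial sampling), library-size variation, spatial autocorrelation
beyond the region-mean structure, and realistic pathway overlap (sets
are disjoint in SVG membership). Passing power/calibration tests on
this generator therefore demonstrates the statistical machinery —
detection of weak aggregate spatial signal at correct type-I error —
not robustness to count-model misspecification.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the simulation design at
a reduced size chosen to keep a full run on a single CPU comfortable:
400 spots, 10 pathways of 100 genes (50 SVG each), 500 permutations for
the power check; 10 independent 100-spot null datasets × 20 pathways at
200 permutations for calibration; 100 genes × 50 spots per region × 20
replicates for the contrast summaries. Engine correctness is checked
against naive loop implementations at $n \le 40$, and permutation
counting against exhaustive enumeration at $n = 5$ (120 permutations).

## Numerical choices

- $\mathcal{V}_n^2$ is clamped at zero; a negative value beyond
  $10^{-12}$ of the statistic's scale raises instead of clamping, since
  the V-statistic is nonnegative by construction and a large negative
  value signals a bug.
- $\mathcal{R}_n^2$ is clipped to [0, 1] before the square root
  (Cauchy–Schwarz holds exactly; float error does not).
- Cauchy combination inputs are clipped to $[10^{-15}, 1-10^{-15}]$.
- Ranking ties (equal dCor) break lexicographically by set id so output
  ordering is total and runs are byte-reproducible.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; the screen derives per-set streams from (seed, crc32 of
  the set id) when permutation sharing is disabled.

## Known limitations

- $O(n^2)$ memory per distance matrix: ~8 GB at $n \approx 30{,}000$
  spots makes whole-slide single-cell resolutions impractical without
  subsampling.
- Permutation p-values have resolution $1/(B+1)$; local FDR on few sets
  or small $B$ is accordingly coarse.
- The high-dimensional bias of the V-statistic (see Region contrast)
  means gene-space dCor values are comparable only within an analysis,
  not across datasets with different region sizes.
- The local FDR estimator assumes the theoretical N(0, 1) null after
  the probit transform; strong dependence among pathway tests (shared
  genes) can make the empirical null wider and the fdr anti-
  conservative.
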