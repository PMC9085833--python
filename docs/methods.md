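# Methods

## The prioritisation model

The pipeline treats gene prioritisation as a guilt-by-association problem on
a biological distance matrix. Distances d(a, b) are dimensionless
protein-interaction-network path costs, non-negative, finite, and in general
**asymmetric** (the best route a→b need not be the reverse of b→a). The
package never computes these distances; it consumes them as square or
long-format TSV, or as a per-gene ranking relative to one core gene.

Around the core gene (UCP1 throughout the bundled analysis) the "connectome"
is the top fraction f of the genome by proximity p-value. The cut keeps
ranks ≤ ⌈f·N⌉, where N is the number of rows in the ranking supplied — the
genome size is a property of the input, not a constant of the package. Ties
in p-value are broken by ascending distance and then by gene symbol, making
the cut deterministic; the core is included during extraction and excluded
from every reported size and downstream statistic, which is what makes a
168-gene extraction a "167-gene connectome".

## Closeness permutation tests

Both tests compare an observed median pair distance against medians of
random, equally sized sets of distances from a null pool.

- *Within-group*: the observed statistic is the median over **all ordered
  pairs** of group members, |G|·(|G|−1) values — both directions of an
  asymmetric matrix, which is exactly how 60 known genes give 3540
  distances. The null pool is the group×complement distances in the
  group→complement direction.
- *Cross-group*: the observed statistic is the median of the
  candidates→known directed distances (|A|·|B| values; 107×60 = 6420), and
  the null pool is known→outside distances, "outside" meaning genes beyond
  the connectome.

One direction per pair is the default everywhere so that observed and null
statistics count the same number of values per pair; a flag pools both
directions. Each null set is drawn **without replacement within a set**,
independently across sets (with-replacement sampling is an option). The
complement for the within test defaults to *all* non-group genes rather than
only non-connectome genes — both readings of "other genes" are defensible,
so both are exposed; the core gene is excluded from every pool.

P-values: with b of n null medians ≤ the observed value (ties count as
extreme), the package reports the raw proportion b/n, the bias-adjusted
(b+1)/(n+1) (which respects the Monte-Carlo resolution floor 1/(n+1)), a
display bound "p < 1/n" when b = 0, and an exact 95% Clopper–Pearson
interval on b/n. The adjusted estimator is what the calibration and power
benchmarks threshold on. No multiple-testing correction is applied across
tests. n_perm defaults to 10⁶ in the run configuration; the benchmark suite
runs at 2×10³–10⁵ (see below).

## Functional genomic alignment

Neighbour joining (Saitou–Nei, via scikit-bio) over the connectome genes
produces an unrooted binary tree whose leaves are the genes — a hierarchical
clustering by functional distance, with no evolutionary reading. NJ needs a
symmetric dissimilarity; asymmetric input is symmetrized by the arithmetic
mean of the two directions (unbiased, order-independent, idempotent on
symmetric input). Negative branch-length estimates, which NJ can produce on
non-additive input, are clamped to zero (flag, default on). Determinism and
input-order invariance come from sorting gene ids before joining and
canonicalizing the tree — children ordered by smallest descendant leaf —
before Newick serialisation at 10 significant digits. On exactly additive
matrices the implementation must recover topology (Robinson–Foulds 0) and
all path lengths to numerical precision; this, plus a cross-check against
R's ape::nj, is the correctness argument.

## Expression enrichment

Studies arrive as processed probe×sample log-intensity matrices with a
probe→gene map. Probes annotated to zero or several genes are dropped
(ambiguous annotation); the remainder collapse by a two-stage median —
median across samples per probe, then median across a gene's probes. The
source procedure specifies only the probe→gene median; the sample dimension
is unstated, so the two-stage form is the default and a single pooled median
over all of a gene's probe×sample values is available as an option.

A study's top set is the genes **strictly above** the 95th-percentile of its
per-gene summaries, with the percentile computed by linear interpolation
between order statistics (h = (N−1)p + 1): 1000 distinct values give a
threshold of 950.05 and a top set of exactly 50. The enrichment statistic is
|query ∩ ⋃ top sets|; null sets are size-matched draws from the universe of
genes that *have* summaries (around 20k in real studies), which keeps the
resampling frame identical to the observed count's. For a single study this
null is exactly hypergeometric, which the benchmark suite uses as an oracle.
Query genes without summaries are dropped with a warning, since they can
never be counted.

## Synthetic generators

`DistanceSimSpec` plants a low-distance module around the core inside an
otherwise exchangeable matrix: module pairs (core included) draw log-normal
distances with log-mean ln 4.7, everything else ln 9.0 (both σ = 0.35), and
independent N(0, 0.25) per-direction noise truncated at zero supplies the
asymmetry. Log-normal is the natural family for non-negative sums of
positive edge weights; the medians echo the scale of the real connectome
(observed within-known median ≈ 4.7 against a background around 9). The
default module size is 60 — the known-gene set — so the fixture pipeline
reproduces the real pair counts end to end; `published_connectome_spec`
plants the full 167-gene connectome by name. Setting the within parameters
equal to the background gives the exchangeable null used for calibration.

`ExpressionSimSpec` gives each gene a N(7, 2) baseline log-intensity, shifts
planted genes by +6, assigns probes round-robin (10% annotated to a second
gene and therefore discarded by collapsing), and adds N(0, 0.5) noise per
value. The +6 shift clears the background's 95th percentile by design
(normal-tail: P(N(13,2) > q₀.₉₅ of N(7,2)) ≈ 0.91).

What the generators deliberately do **not** emulate: correlation structure
between pairs sharing a gene (every ordered pair is independent, which real
path-length matrices violate), probe-level covariance and batch effects,
heavy annotation pathologies, and realistic effect sizes — the planted
signals are strong. Green power tests therefore demonstrate that the
machinery detects structure it is pointed at, not that real tissues carry
signals this clean; the calibration tests, run on exchangeable nulls, are
the part that transfers directly.

## Benchmark problem sizes and numerical notes

The benchmark suite (shared by the acceptance script and tests) uses sizes
chosen for a single CPU: calibration runs 500 replicates at n_perm = 2000 on
a 400-gene null matrix with a 15-gene group (calibration is a property of
the statistic, not of the matrix size); power runs 100 seeds of the
*default* planted spec (2000 genes, module 60) at n_perm = 2000 — the
smallest n at which (b+1)/(n+1) can reach the 10⁻³ threshold; the sampling
oracle enumerates all C(8,2) subsets of an 8-distance pool against 10⁵
draws; NJ recovery uses 50 random additive trees of 5–40 leaves.

Two behaviours worth knowing:

- The enrichment count is integer-valued with a short support, so its
  permutation test is conservative: the realised type-I rate at the 0.05
  level is typically 2–4% rather than 5%, and fluctuates with the top-set
  size. This is the ordinary discreteness of count statistics, not a defect
  of the sampler — the sampler itself matches the hypergeometric law to
  within Monte-Carlo error.
- File round-trips are bit-exact because floats are written with shortest
  round-trip (repr) formatting and re-parsed by Python's float; Newick
  lengths are limited to 10 significant digits, and round-trip identity is
  asserted at that precision.

## Limitations

Gene symbols are matched case-sensitively after whitespace stripping; there
is no alias or ortholog resolution. Raw-array processing (RMA, quality
outlier removal) is upstream of this package, which consumes processed
matrices. The published confidence intervals around the original Monte-Carlo
p-values are not reproducible from any standard binomial interval at the
stated n and are not matched; the package reports Clopper–Pearson. Tree
rendering (fan plots) is out of scope — the Newick output and the leaf-class
TSV are meant for external plotting.
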