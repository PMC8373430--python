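# Methods

This note documents the models, defaults and numerical conventions behind
`methmargin`, and what the synthetic cohorts do and do not establish.

## Coordinates and calls

CpG sites are indexed by the 0-based plus-strand position of the C of each
CpG dinucleotide; reverse-strand evidence is assumed collapsed onto the
plus-strand C upstream (CpG methylation is symmetric).  Within a contig a
site is addressed by its *slot* (rank in the sorted position list); BED
output is half-open, and a block/region span runs from the first C through
the final G (end = last C position + 2).  Read-level calls use `M`, `U`
and `.`; a `.` contributes to no substring, no depth and no count — a
no-call neither supports nor refutes a methylation haplotype, so treating
it as anything else would inflate loads.

## Block partitioning

For each adjacent CpG pair, joint calls from reads covering both sites give
counts (n11, n10, n01, n00) and r² = (p11 − pA·pB)² / (pA(1−pA)pB(1−pB)) on
observed frequencies.  r² is undefined (missing) when fewer than
`min_pair_reads` (default 5) reads cover the pair or a margin is
monomorphic.  Blocks are maximal runs of pairs with defined r² ≥ `r2_min`
(default 0.5), kept when they span ≥ `min_cpgs` (default 3) CpGs.  Blocks
never span contigs or uncovered pairs.  Discovery pools reads across all
samples by default so blocks are shared coordinates for all seven
positions; per-group discovery is available by argument.  The thresholds
are deliberate, configurable assumptions in the spirit of the established
methylation-haplotype-block methodology, which does not fix them
universally.

## Block scores

Six per-(block, sample) metrics, all in [0, 1], missing (NaN) rather than
zero when support fails:

* **AMF** — methylated calls / informative calls.
* **MHL, MHL3, UMHL, UMHL3** — for substring length l = 1..L, P_l is the
  fraction of observed gapless length-l substrings (no `.`) whose calls are
  all M (or all U for the U-loads); the load is Σ w_l P_l / Σ w_l with
  w_l = l (linear) or l³ (cubic), summing over lengths with at least one
  observed substring.  The cubic weight makes long fully (un)methylated
  haplotypes dominate.  By construction UMHL(reads) = MHL(complemented
  reads) exactly.
* **PDR** — among reads with ≥ `pdr_min_read_cpgs` (default 4, the common
  epiallele convention) informative calls in the block, the fraction
  carrying both an M and a U.

## Differential methylation

**DMC model.**  Counts are modelled per site as beta-binomial.  Group
proportions are coverage-weighted pools p̂_g = Σm/Σn.  Dispersion φ is
estimated per site by the method of moments from squared residuals of
per-sample proportions around p̂_g, pooled over both groups, with a
k/(k−1) rescaling per group because residuals around the pooled estimate
lose one degree of freedom (without it φ is biased low and the test is
anticonservative).  φ̂ is then shrunk toward the genome-wide median φ̃ with
empirical-Bayes weight m/(m + n_samples), m = 4 by default; sites where the
moment estimator is undefined (fixated proportions) fall back to φ̃.  The
Wald statistic is Δβ̂/SE with Var(β̂_g) = p_g(1−p_g)·Σ n_i(1+(n_i−1)φ̂) /
(Σn_i)², two-sided normal p-value, BH-adjusted.  No smoothing across sites
is applied: the intended input is RRBS, where covered CpGs cluster tightly
and smoothing is a whole-genome-bisulfite concern.  Calibration is
established by Monte-Carlo (empirical size ≈ 0.05 on overdispersed null
data at 15 vs 15, depth 30) rather than by matching any external
implementation output-for-output.  Degenerate sites: SE = 0 with Δβ = 0
gives p = 1; SE = 0 with Δβ ≠ 0 gives p = 0.

**DMR rule.**  Tested CpGs at most `max_gap_bp` (default 100 bp) apart form
chains; a chain is emitted when it has ≥ 3 CpGs, at least one with
p < 0.05, and a significant fraction strictly above 10%.  No base-pair
length cap.  The region effect is the unweighted mean of member Δβ.  The
per-CpG α and the 10% fraction are fixed by the selection standard; the
gap width and the region-level combination — a directional Stouffer sum
with √coverage weights — are this package's choices and are exposed as
parameters.

**Selection standard.**  Markers of all three layers are kept when
FDR < 0.05 and |effect| > 0.2; direction is high iff mean(TC) > mean(PN).
The 0.2 floor is applied to MHB score differences as well as Δβ for
uniformity.  MHB markers use a two-sided, unpaired Wilcoxon rank-sum test
across samples (a paired test is not assumed), and require ≥ `min_group_n`
(default 5) non-missing samples per group — below that the rank-sum null
is too coarse to be useful.

## Spatial classification

Position means are arithmetic means over patients (≥ `min_group_n`
samples, else missing).  With d = +1 (high) or −1 (low),
k1 = d(M_TC − M_TE), k2 = d(M_TE − M_P5), and K = k1/k2 when k2 > 0;
K < 1 is Steep, K ≥ 1 Gradual, the boundary deliberately Gradual.  Two
edge conventions are this package's: when k2 ≤ 0 but k1 > 0 the marker
decays only inside the tumor, which reads as Gradual (K = +∞); when both
are ≤ 0 the marker is flagged non-monotone and left unclassified instead
of being silently binned.  The classification is exactly invariant under
complementing scores and flipping direction, and scale-free in deviations
from the normal-tissue baseline.

Position-pair comparisons collapse a marker set to one value per sample
(mean over the set's markers) and apply the Wilcoxon rank-sum test: exact
null enumeration when both groups have ≤ 10 observations and no ties,
otherwise the normal approximation with tie correction (so n = 15 cohorts
use the approximation, matching common practice); degenerate all-equal
input gives p = 1.  BH adjustment is applied within each emitted table,
not globally across analyses.

## Synthetic cohorts

The generator emulates a 15-patient, 7-position transect design.  Blocks
of 4–8 CpGs (20 bp spacing, 1 kb between blocks) follow archetype
templates over (TC, TE, P5, P10, P15, P20, PN):

* S-high: (0.80, 0.75, 0.20, 0.20, 0.20, 0.20, 0.20) — plateau, cliff at 5 mm;
* G-high: (0.80, 0.55, 0.32, 0.22, 0.20, 0.20, 0.20) — smooth decay;
* S-low/G-low: elementwise 1 − high; null: flat 0.5.

Both signal families span Δ = 0.6 between core and normal, comfortably
above the 0.2 selection floor.  The default mixture is 6 S-high, 6 S-low,
1 G-high, 1 G-low and 26 null blocks: the 12:2 steep:gradual ratio follows
the ~86%/14% composition reported for this marker class, which matters
because the gradual template's noiseless K is only 0.25/0.23 ≈ 1.09 — an
individual gradual marker sits close to the class boundary by construction,
so the realized composition, not just per-marker noise, shapes aggregate
classification accuracy.

Per (patient, block) a baseline shift is drawn once as N(0, 0.3) on the
logit scale and shared across positions (paired transect design).  Each
sample contributes Poisson(30) reads per block; a read comes from the
methylated epiallele with probability equal to the block's effective mean
and emits per-CpG Bernoulli(0.95) M calls (0.05 on the unmethylated
epiallele); incomplete bisulfite conversion then flips U→M with
probability 0.007 (99.3% conversion).  The two-epiallele model makes
haplotype loads respond more sharply than AMF, which is the premise of
block-level scoring; a consequence worth knowing is that a read's
discordance probability, 1 − 0.95^L − 0.05^L, does not depend on the
mixture weight, so PDR is nearly flat across block means and carries no
TC-vs-PN signal under this generator.

What passing recovery tests show — and what they do not: the simulator has
no fragment-length variation across blocks' boundaries, no coverage bias,
no copy-number or purity gradients, no FFPE artifacts, and its archetypes
are clean step/decay shapes.  Recovery at sensitivity ≈ 1 and FDR ≈ 0 under
these conditions validates the statistical machinery, not performance on
real margin cohorts.

## Determinism and output conventions

All randomness flows from a single named seed (`numpy` Generator).  Output
tables are TSV with `#` header comments carrying the package version, a
hash of the effective configuration and the seed — never timestamps — so a
rerun with the same config and seed is byte-identical.  Parameters are
validated against their documented ranges before any stage runs; stages
fail with the missing path's name when a dependency has not been produced.

## Problem sizes used in verification

Verification runs use 200 random blocks for the load oracle, 2,000 sites
for null calibration, and 20 default cohorts (40 blocks × 105 samples
each) for recovery — sizes at which every Monte-Carlo band in the test
suite is stable across seeds while the whole suite stays fast on a laptop.
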