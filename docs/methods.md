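# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## LD and haplotypes

r² is computed from phased haplotype frequencies: for 0/1 haplotype
columns, the squared Pearson correlation equals D²/(p_A q_A p_B q_B).
Monomorphic SNPs have undefined r² and are reported missing, so they can
never enter an LD set. Tag expansion uses a strict inequality at the
configurable threshold (default r² > 0.8). Haplotype merging is the
connected components of the set-overlap graph (any shared SNP) within a
population, then components sharing a tag SNP are merged across
populations; output is ordered by leftmost member position, so the result
is deterministic and idempotent. Haplotype frequency is defined as the
frequency of the joint *minor-allele* configuration over phased
haplotypes — the definition is a package choice (which allele combination
constitutes "the haplotype" is otherwise ambiguous) and is flagged when
≤ 0.005. Input panels can be re-filtered from raw VCF with MAF > 0.01 and
an exact Hardy–Weinberg test (p > 0.01); the HWE test is the standard
exact conditional distribution of heterozygote counts.

## FlowFISH screen model

The sorter captures two 30% expression tails split into three contiguous
bins of the stated design fractions, trimming the extreme 0.1% per side;
bin boundaries are standard-normal quantiles of the cumulative design
fractions, and all effects are expressed in units of the global
log-expression σ (σ ≡ 1 in z-space).

Per guide, bin counts are modeled as multinomial across the six bins with
class probabilities proportional to `depth_b · f_b(μ) / w_b`, where
`f_b(μ) = Φ(b_hi−μ) − Φ(b_lo−μ)`, `depth_b` is total reads sequenced in
the bin and `w_b` the library-wide occupancy of bin b. A pseudocount of
one read per 100,000 bin reads is added first; it acts as a prior pulling
toward no effect and guarantees positive counts. The MLE is found on a
coarse grid (step 0.01σ over [−6σ, 6σ]) followed by a local fine grid
(step 0.0005σ); a bounded scalar optimizer over the same likelihood is
kept as an independent cross-check.

`w_b` is initialized to the design capture fractions, which is exact when
effects are sparse. When a non-negligible fraction of guides shares a true
effect, fixed offsets bias all estimates toward the library average
(sequencing renormalizes read totals per bin), so by default the estimator
iterates a fixed point: fit all μ̂, recompute `w_b` as the
abundance-weighted mean occupancy under the fits, refit (up to 40
iterations on the coarse grid, early-stopped at max |Δw| < 1e-7). Setting
`refine=0` recovers the fixed-offset behaviour. The likelihood is
Poisson/multinomial rather than negative binomial: no dispersion estimate
is available at the per-guide level, the MLE of μ is consistent either
way, and z-standardization against non-targeting guides absorbs the extra
variance.

Guide z-scores subtract the non-targeting mean and, by default, divide by
the non-targeting standard deviation so z is scale-free (`standardize=False`
gives pure centering). Element significance is the Stouffer sum Σz/√n
scaled by the SD of non-targeting Stouffer scores at the same group size
n, built from 10 seeded shuffles of the non-targeting pool so each NT
guide is used exactly 10 times. P-values are one-tailed in the assay
direction (down for CRISPRi, up for CRISPRa) and BH-corrected across
targeted elements within a replicate (non-targeting pseudo-elements are
excluded from the FDR family). An element is a hit when both selected
replicates (the two with the strongest promoter-control effect, when more
than two exist) are below FDR √0.1 ≈ 0.316 with identical direction.
SNP footprints are inclusive: element ± 100 bp for CRISPRi tiling, the
SNP's own ± 25 bp window (pad 0) for CRISPRa.

Off-target scoring uses the 20-position mismatch weight vector with the
printed product/distance/n² form; for a single mismatch the mean pairwise
distance d̄ is undefined and set to 19 (distance factor 1). Aggregation
puts single-site scores on the 0–100 scale before
`S = 100·100/(100+Σ)`, so a clean guide scores 100 — taken literally with
fractional site scores the formula would pin every guide near 1, which
contradicts the stated 0–100 range.

## MPRA

Expression is the natural log of RNA/DNA from raw counts (a config switch
flips the orientation; positive = higher expression). Processing order:
coverage filter (DNA ≥ 30, RNA ≥ 4; boundary values retained) → log ratio
→ global median centering → per-integer-%GC mean centering → blackball
exclusion → re-centering. Blackballed 5-mers are those whose containing
tags average |expression| > 0.15 (strict), detected per replicate and
unioned across replicates of a delivery mode because barcode artifacts are
sequence-intrinsic. A 5-mer carried by every tag can never be blackballed
(its mean is the global, centered mean); conversely, 5-mers overlapping a
true artifact by four bases are substring-correlated with it and may be
dragged over the threshold — exclusion is deliberately conservative.
Allelic tests are pooled-variance Student's t (df = n_A+n_B−2),
two-sided, on variants with ≥ 80 good tags across both alleles (and ≥ 2
per allele per replicate); non-reference alleles are each tested against
reference. Hits need BH FDR < 0.1 in ≥ 2 replicates and a consistent
direction across all tested replicates; variants tested in fewer than two
replicates are reported untestable, not negative.

## Motif scoring

GOMER-style occupancy: every window on both strands binds independently
with probability p_w, and the sequence score is log(1 − Π(1−p_w)). The
window probability is the PWM-to-uniform-background likelihood ratio
normalized by the consensus ratio (p_w = r_w/r_max), i.e. the scaling
constant mapping affinities to probabilities is fixed at the consensus
affinity; PWM probabilities are floored at 1e-3 and renormalized.
Equivalence with other GOMER parameterizations is property-level (strand
symmetry, monotonicity, window enumeration), not bit-level. The bound
threshold is calibrated per PWM as the 5th percentile of per-variant
best-allele scores, so > 95% of the variant universe qualifies as bound;
disruption additionally requires |Δ log score| ≥ 0.1 (inclusive). The
ChIP intersection defaults to same-TF (a disrupted motif counts only
inside that TF's ChIP interval); an any-TF mode is available since TF
identity matching is a modeling choice.

## Enrichment and nulls

Counts per assay track: n_H (assayed hits), n_T (tag SNPs with ≥ 1
assayed member in their LD set — tags whose whole set went unassayed are
excluded so technical failures are not penalized), n_TH (tags with ≥ 1
hit member). Credible-set mode replaces LD sets with credible sets and
counts sets containing ≥ 1 hit. The genomic-shift null circularly rotates
the hit vector along the assayed SNPs in genomic order, one draw per
offset (exactly n−1 draws, fully deterministic); the permutation null
shuffles hit labels (seeded, default 1000 draws). Since n_H and n_T are
invariant under both randomizations, the joint (pseudo-precision AND
pseudo-recall) exceedance reduces to an n_TH exceedance; ties count as
exceedances, and the count is floored at one draw so the empirical p is
never 0 and never below 1/(n−1). Every null draw satisfies
pp = (n_T/n_H)·pr exactly. Fold enrichment divides the observed
pseudo-precision by the null mean; the 95% CI divides by the 97.5th/2.5th
null percentiles, with an infinite upper bound when the lower percentile
is 0. The HiChIP hit threshold (normalized interaction score 20) is
applied inclusively. Accessibility restriction intersects assayed masks
with the accessible-SNP set and recomputes counts and nulls on the
subset. High priority = CRISPRi hit OR (T-MPRA hit AND accessible).

## Synthetic-data generator

The generator emulates the structure each estimator assumes, with planted
truth; per-generator RNG streams are derived from `SimConfig.seed` plus
stable offsets, so outputs are byte-identical per seed and adding a
generator does not perturb the others.

- **Genotypes**: haplotypes share a latent founder indicator per LD block;
  each SNP copies it with per-SNP flip noise (uniform on [0, 0.04]),
  giving high within-block and ~0 between-block r². Block minor
  frequencies are uniform on [0.1, 0.5]; every emitted SNP is checked to
  have empirical MAF > 0.01 (resampled, or a degenerate-config error).
  Tag blocks carry a noise-free partner SNP so each tag has a guaranteed
  r² > 0.8 proxy. A copy-SNP mode duplicates the first SNP of each block.
  Defaults: 120 SNPs, 500 diploid samples, blocks of 8, 6 tags, 3 causal.
  This is a block-copula construction, not a coalescent: it has no
  recombination gradient, no allele-frequency spectrum realism, and no
  population divergence — sufficient for controllable r² structure,
  nothing more.
- **FlowFISH**: cells per guide are normal in log expression (effects in
  σ units), sorted at the design quantiles; reads per bin are negative
  binomial (size 10) around each guide's depth share; guide abundances are
  log-normal (σ = 0.3). Defaults: ~30 guides/element, 6000 non-targeting
  guides, 10⁶ reads/bin, a −2σ promoter positive control, 2 replicates.
- **MPRA**: ~250 random 20-mer tags per allele; RNA is negative binomial
  around DNA · exp(allele effect + 0.02·(%GC−45) + artifact + tag noise),
  rescaled to library depth; artifact 5-mers (default "ACGCG", +0.5 log
  units) affect any tag containing them. 3 replicates, ~100 reads/tag.
- **Hit tracks**: hits occur in runs (default 3–5 SNPs): causal SNPs seed
  runs with a sensitivity parameter, background runs start per SNP at a
  background rate; assay coverage is an independent per-SNP rate.
- **Motifs**: one information-rich PWM (8 bp, consensus probability
  0.92). Disrupting variants sit at an informative column of a planted
  consensus site with the worst base as the alternate; neutral variants
  carry a consensus site *away* from the variant, so the region is bound
  but the variant lies outside the site.

The negative-binomial size (10), GC slope, artifact effect, and track
cluster/sensitivity/background parameters are calibration placeholders:
the underlying experiments do not pin them down, so passing tests show
internal consistency of the estimators with their generative assumptions
at realistic depths — not performance on real screens, where dispersion
is guide-dependent, GC effects are nonlinear, LD is not block-diagonal,
and assay coverage is far from uniform.

## Problem sizes

The shipped analysis and checks run at desk scale as the package's own
choice of benchmark size: a 120-SNP locus with 500 samples; estimator
recovery with 1000 effect guides + 6000 non-targeting at 10⁶ reads/bin;
null-screen calibration with 30 inert elements; MPRA power with 25 causal
+ 25 null variants at 250 tags/allele; shift-null comparisons summarized
over 15 independent track draws. All are configurable upward through
`SimConfig`.

## Known limitations

- The FlowFISH dispersion is not estimated from data; the NB option uses
  a fixed size parameter.
- The composition fixed point can slightly overshoot when per-guide noise
  is large (the occupancy map is nonlinear in μ̂); effects relative to the
  non-targeting distribution are unaffected.
- Blackballing can remove tags carrying 5-mers merely correlated with a
  true artifact; with few tags per 5-mer (small libraries) the rule is
  aggressive by construction.
- Credible sets are consumed as inputs; fine-mapping itself, genome-wide
  LD, read alignment and peak calling are out of scope.
- The curated prioritized-variant table ships as static package data; it
  is bookkeeping input, not a computed result.
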