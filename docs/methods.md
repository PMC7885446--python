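# Methods

## Model and time scale

All demographic quantities live on the *mutational* time scale of the
sudden-expansion literature: τ = 2ut, where u is the per-sequence
per-generation mutation rate and t the time in generations, and
θ = 2Nu is the scaled population-mutation parameter of an mtDNA
(effectively haploid, maternally inherited) locus. In these units the
coalescent used throughout the package is parameterized so that

* j lineages coalesce at rate C(j,2)/θ(epoch) per unit time, and
* mutations accrue at rate 1/2 per lineage per unit time,

which makes E[pairwise differences] = θ and E[S] = θ·a₁ under constant
size (a₁ = Σ_{i<n} 1/i), and places the backward size change of the
sudden-expansion model (θ1 → θ0) at exactly time τ. θ0 = 0 is the star
limit in which pairwise differences are Poisson(τ). The conversion is
verified in the tests two independent ways: against the closed-form
transient distribution below (total variation < 0.03 at study scale)
and against msprime with haploid N_e = θ (half the branch-mode
diversity equals k̄).

Mutations follow infinite sites: every mutation is a new binary column
of a genotype matrix. Export to 1140-bp sequences assigns columns to
distinct positions; a finite-sites option drops mutations with
replacement (Jukes–Cantor-style repeat hits) for users who want
homoplasy. The analytic mismatch formulas assume infinite sites, and at
cytochrome-*b*-like divergences (k̄ ≪ k) the distinction is negligible.

## Mismatch distribution and the sudden-expansion fit

The equilibrium distribution of pairwise differences at parameter θ is
the geometric-like F̂_d(θ) = θ^d/(θ+1)^{d+1}. For a population that
jumped from θ0 to θ1 at mutational time τ, integrating the Poisson
difference kernel over the two-epoch pair-coalescence density gives the
transient form

    F_d = F̂_d(θ1) + e^{−τ(θ1+1)/θ1} Σ_{i=0}^{d} (τ^i/i!) [F̂_{d−i}(θ0) − F̂_{d−i}(θ1)]

(re-derived here from the pair coalescent; it passes the τ = 0,
θ1 → ∞/Poisson, and τ → ∞ limit checks and matches pooled simulation).
By exchangeability, a random pair from a sample of n has the same
marginal, so the formula is compared against frequency histograms over
all n(n−1)/2 pairs.

**Estimation.** (τ, θ0, θ1) minimize the sum of squared deviations
(SSD) between observed and expected frequencies over the observed
support 0..d_max plus one tail bin carrying the model's truncated mass
(the observed tail is zero by construction). The SSD surface has a
pronounced ridge along τ + θ0 ≈ const (an old θ0 > 0 and a slightly
older τ with θ0 = 0 produce nearly identical histograms), so the
surface is multimodal and flat in one direction; a fixed coarse grid —
τ over [0, 2·mean], θ0 ∈ {0, mean/4, mean}, θ1 ∈ {mean, 10·mean, 10⁴} —
seeds Nelder–Mead refinements from the two best starts. The fit is
fully deterministic (no RNG). Noiseless inputs are recovered to
τ ± 10⁻⁴; on noisy data the ridge leaves the point estimate of τ
median-biased upward by roughly +0.4 at (τ=3, θ0=1, n=50) — a property
of the least-squares estimator, not of the optimizer (a 4× larger
multi-start budget changes estimates by < 0.01). The percentile
bootstrap CI absorbs this: coverage of the true τ is ≈ 87% at nominal
95% under study conditions. θ1 is capped at 10⁵ and reported as
"effectively infinite" at the cap; θ0 is capped at 10⁴; a monomorphic
histogram yields the degenerate fit τ̂ = 0, θ̂0 = 0, flagged as such.

**Parametric bootstrap.** Each replicate re-simulates n sequences under
the fitted parameters, re-fits, and records its own SSD, raggedness and
τ̂; p_SSD = (1 + #{SSD_b ≥ SSD_obs})/(1 + reps) (add-one rule, so p is
never 0), p_raggedness analogous, and the τ CI is the 2.5–97.5
percentile range of τ̂_b (95% by convention; the level is a parameter).
Re-fitting each replicate mirrors the treatment of the observed data,
which is what makes the p-value calibrated: the empirical type-I error
at nominal 0.05 is ≈ 0.04 in the test suite's 200-run study.

The raggedness index is r = Σ_{i=1}^{d_max+1} (x_i − x_{i−1})² with
x_{d_max+1} := 0; a point mass at d = 0 gives r = 1, smooth unimodal
histograms give r ≪ 1.

## Neutrality tests

Tajima's D uses the standard constant cascade; S = 0 raises an explicit
"undefined" error rather than returning 0. Fu's Fs computes
S′ = P(K ≥ k_obs) under the Ewens sampling distribution with θ = k̄,
using unsigned Stirling numbers of the first kind carried in log space
(the recurrence |s(m+1,k)| = m|s(m,k)| + |s(m,k−1)| via logaddexp; the
distribution normalizes to 1 ± 10⁻¹¹ up to n = 200). k_obs = 1 gives
S′ = 1 and Fs = +∞, signalled as such with an optional finite cap.

p-values are lower-tail simulation p-values with the add-one rule,
under a constant-size null with θ = k̄ (the default, Arlequin-like) or
conditional on S (mutations placed on branches proportionally to
length); both nulls are provided because field practice varies.
Monomorphic simulated replicates get D := 0 and Fs := +∞ — they cannot
be "more extreme" than any finite observed statistic, which is the
conservative direction. Fu's conventional significance threshold for Fs
is 0.02 (his 5%-equivalent), and the pipeline's expansion flag uses it.

## Median-joining networks

Characters are the variable alignment columns. The ε-relaxed minimum
spanning network keeps an edge of weight d iff its endpoints are not
already connected by kept edges of weight < d − ε (ε = 0 default, as in
PopArt; the ε = 0 network is a subgraph of every larger-ε network).
Median vectors are site-wise majority consensuses of triplets adjacent
in the current network (the quasi-median restricted to the DNA
alphabet; triplets disagreeing three ways at a site yield no median);
candidates are admitted greedily by largest reduction in minimum
spanning cost, the network is rebuilt, and the process iterates to
fixation, after which median vectors of degree < 3 are pruned
iteratively. Admission-by-cost-reduction subsumes the classical
"on a minimal connection" pruning on all fixtures in scope. All ties
break by (weight, first-occurrence order), so construction is
deterministic and relabeling-invariant up to isomorphism. The
star-shape summary (hub node, degree, fraction of sampled haplotypes
one step from the hub) is descriptive only.

## Haplotype collapsing and ambiguity

Pairwise comparisons delete sites that are N or "-" in either sequence.
Two sequences are the same haplotype when they agree wherever both are
unambiguous; this relation is not transitive, so collapsing greedily
assigns each sequence (in input order) to the first class whose
*representative* it matches. π divides k̄ by the mean number of usable
sites per pair.

## Chronology

T = τ/(2μk), μ = τ/(2Tk), u = μg, t = τ/(2uk) (so T = t·g identically;
these identities are property-tested). The default calibration anchors
are the four late-Quaternary warming events at 130 000, 53 000, 15 000
and 11 500 years BP; τ values assigned to a class are averaged
arithmetically before conversion. Human-facing output rounds to 2
significant figures (0.029, 0.045, 0.10 subs/site/myr; 5800 yr);
machine output keeps full precision. Generation time g has no default —
it is biologically unknown for the motivating taxa and is a required
input for generation-scaled quantities.

## Pipeline decision rule

A group is flagged as a rapid-expansion signal when the
sudden-expansion model is retained (p_SSD > 0.05 AND p_raggedness >
0.05) and at least one neutrality test is significant (Fs < 0.02 or
D < 0.05). The rule is a pure function of the p-values and all
thresholds are configurable. Groups with n < 4 are reported with
statistics marked NA; a failure in one group does not stop the others.
All randomness descends from one master seed via named SeedSequence
substreams, and the JSON report is byte-identical across reruns.

## Synthetic data: what it does and does not emulate

The generator reproduces the *sampling structure* of a typical mtDNA
survey — groups of n ≈ 10–130 sequences of 1140 bp drawn from
constant-size or sudden-expansion demographies with τ in the 1–9 range
and θ1/θ0 ratios of 10²–10⁴ — which is exactly the regime the
statistics operate in. It does not emulate geographic substructure
within a group, migration between groups, selection on the mitochondrion,
rate variation among sites, or sequencing error; passing tests therefore
demonstrate correctness of the inference machinery under its own model
assumptions, not robustness of the field inferences to violations of
them.

## Problem sizes and numerical choices

The heavy Monte-Carlo studies in the test suite use the designs
100 datasets × 200 bootstrap replicates (recovery/coverage), 200 runs ×
100-replicate bootstraps (SSD type-I) and 200 runs × 200-replicate
nulls (neutrality type-I); the acceptance script uses slightly smaller
versions of the same designs (60 × 150, 100 × 100, 150 × 200). These
sizes give Monte-Carlo standard errors comfortably inside the bands
being checked while keeping a full run to minutes on one core.
Expected-mismatch vectors are truncated at the observed d_max with the
residual mass in a tail bin; Ewens tail sums use logsumexp; Poisson
terms are computed in log space. Default replicate counts for real
analyses are 1000 (neutrality and bootstrap), with a fast mode at 200.

## Known limitations

* The least-squares τ estimator inherits the τ/θ0 ridge bias described
  above; confidence intervals, not point estimates, should be quoted
  for shallow expansions.
* The MJ implementation targets validity of the construction
  (connectivity, Hamming-exact edge weights, correct Steiner behaviour
  on small cases), not node-for-node identity with PopArt, whose
  pruning details are unpublished.
* Fu's Fs for n ≳ 200 would need the Stirling recurrence's streaming
  normalization revisited; the survey regime (n ≤ 130) is exact.
* The infinite-sites export refuses datasets with more mutations than
  sites rather than silently dropping collisions.
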