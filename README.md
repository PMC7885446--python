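# molexpand

Demographic inference and expansion dating for aligned mitochondrial
haplotype data — the analysis stack used in phylogeographic surveys of
small mammals (the motivating system is Japanese moles sampled for the
1140-bp cytochrome *b* gene), with a coalescent simulator standing in
for field data.

## What it computes

Given an alignment of mtDNA haplotypes split into geographic groups,
`molexpand` answers, per group:

1. **How variable is it?** Segregating sites *S*, mean pairwise
   differences k̄, nucleotide diversity π (pairwise deletion of
   ambiguous sites).
2. **Did it grow?** Tajima's *D* (contrast of k̄ with the Watterson
   estimator *S*/a₁) and Fu's *Fs*, based on the Ewens-sampling
   probability *S′* = P(K ≥ k_obs | θ = k̄) with
   *Fs* = ln *S′* − ln(1 − *S′*); both tested against 1000 constant-size
   coalescent replicates (lower tail).
3. **When did it grow?** The mismatch distribution (histogram of
   pairwise differences) is fitted by least squares to the
   sudden-expansion model: equilibrium distribution
   F̂_d(θ) = θ^d/(θ+1)^{d+1} and transient distribution

       F_d(τ, θ0, θ1) = F̂_d(θ1)
         + e^{−τ(θ1+1)/θ1} Σ_{i=0}^{d} (τ^i/i!) [F̂_{d−i}(θ0) − F̂_{d−i}(θ1)]

   giving the expansion age τ (mutational units), with a parametric
   bootstrap for the SSD and raggedness goodness-of-fit p-values and a
   percentile CI on τ.
4. **What does it look like?** A median-joining haplotype network with
   inferred median vectors, plus a star-shape summary (expansions leave
   star-like networks).
5. **When in calendar time?** τ converts to years via T = τ/(2μk) and
   to a rate via μ = τ/(2Tk); anchoring τ classes to late-Quaternary
   calibration points (130 000, 53 000, 15 000, 11 500 years BP) yields
   the time-dependent rate table.

The built-in coalescent simulator (`molexpand.coalsim`) draws samples
under constant-size and sudden-expansion demographies in mutational
time, supplies neutrality nulls and bootstrap replicates, and generates
multi-group synthetic surveys.

## Worked example

```python
from molexpand import (DemographyConfig, MismatchDistribution, simulate,
                       fit_sudden_expansion, parametric_bootstrap)
from molexpand.coalsim import mismatch_counts_from_matrix

sample = simulate(DemographyConfig(model="sudden_expansion",
                                   theta0=1.0, theta1=1000.0, tau=3.0,
                                   n=50, seed=7))
obs = MismatchDistribution(counts=mismatch_counts_from_matrix(sample.genotypes))
fit = parametric_bootstrap(fit_sudden_expansion(obs), n=50, reps=200, seed=11)
```

printed (see `examples/03_mismatch_fit.py`):

```
tau-hat = 3.37 (true 3.0), 95% CI = (1.89, 4.15)
theta0-hat = 0.00, theta1-hat = effectively infinite
SSD = 0.00073, p_SSD = 0.627
raggedness r = 0.0248, p_r = 0.542
```

The fitted expansion age τ̂ ≈ 3.4 recovers the simulated τ = 3 within
its CI; the large p_SSD and p_r mean the smooth unimodal expansion model
is not rejected. Converting a shallow expansion of τ = 1.32 at the
young-epoch rate of 0.10 subs/site/myr over 1140 bp dates it to ~5800
years before present (`examples/05_network_and_chronology.py`).

The `examples/` directory holds one short narrative script per
capability; each builds or simulates a small input, runs the method and
prints what the numbers mean. A thin CLI mirrors the library:
`molexpand simulate|collapse|stats|mismatch|network|date|pipeline --help`.

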