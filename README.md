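# rdnapanel

Simulation and analysis tools for rDNA copy-number genetics in
*Caenorhabditis elegans* recombinant inbred line (RIL) panels.

## The problem

The 45S ribosomal DNA in *C. elegans* is a single tandem array of 7.2 kb
units at the right tip of chromosome I, and wild isolates carry anywhere
from ~70 to ~420 copies per haploid genome — a difference of up to 2.5 Mb
of DNA. Studying whether such variation is stable, selected, or
phenotypically consequential requires a pipeline of interlocking
quantitative steps: simulating a two-parent cross whose marker-linked rDNA
alleles segregate under viability selection, estimating copy number from
short-read depth, validating array sizes on pulsed-field (CHEF) gels,
reconstructing parental haploblocks from noisy genotype calls, scanning
for segregation distortion, quantifying copy-number drift, and inferring
selection coefficients from competitive fitness assays.

`rdnapanel` implements that pipeline end to end, with a synthetic-data
module that generates every input under seeded, reproducible conditions,
so each statistical component can be validated against known truth.

## Core models

**Copy number from read depth.** The reference assembly collapses the
array, so reads from all *c* true copies pile onto a short reference span
of *u* units. With single-copy bins ~ Poisson(λ) and rDNA bins ~
Poisson(λ·c/u), the joint MLE is closed-form:

    ĉ = u · (rDNA reads per bp) / (single-copy reads per bp)

with a 95% CI from the profile likelihood in *c* (deviance drop 3.84).

**Haploblocks.** A two-state HMM per line per chromosome: hidden states
are parental origins {A, B}, transitions are Haldane recombination
fractions r = ½(1 − e^(−2d)) from the cM map, emissions allow per-call
error ε. Max-marginal decoding (argmax of forward–backward posteriors)
yields blocks; segregation distortion is an exact binomial test of each
marker's allele counts against 50:50 with Bonferroni correction.

**CHEF sizing.** A ladder calibrates a strictly decreasing
distance → size mapping (log-linear fit or monotone interpolation);
band size ÷ 7.2 kb gives copies.

**Drift.** Copy loss/gain as Poisson events per cell division
(~15 divisions per worm generation): at one copy lost per 120 or 67
divisions, the expected loss over 20 generations floors to 2 and 4
copies.

**Competition.** A two-genotype Wright–Fisher process: with focal fitness
1+s, the post-selection proportion is p′ = p(1+s)/(p(1+s)+(1−p)) and the
next census is Binomial(N, p′)/N. Its infinite-N limit
p_t = p₀(1+s)^t / (p₀(1+s)^t + 1 − p₀) inverts exactly to estimate s from
an observed final proportion; the interval is the set of s whose
simulated final-proportion distribution contains the observation in its
central 95%.

## Worked example

```python
import numpy as np
from rdnapanel import (
    PanelConfig, build_default_genome, estimate_copy_number, infer_selection,
    simulate_depth_profile, simulate_ril_panel, test_cosegregation,
)

genome = build_default_genome()
rng = np.random.default_rng(0)
panel = simulate_ril_panel(PanelConfig(n_lines=118, seed=0), genome, rng)

estimates = []
for line in panel:
    profile = simulate_depth_profile(line, genome, mean_depth=30.0,
                                     rng=rng, chromosomes=["I"])
    estimates.append(estimate_copy_number(profile))

first = estimates[0]
print(f"line 0: c_hat = {first.c_hat:.1f}, 95% CI = "
      f"({first.ci95[0]:.1f}, {first.ci95[1]:.1f}), class = {first.allele_class}")

coseg = test_cosegregation([l.transgene for l in panel],
                           [e.allele_class for e in estimates])
print(f"transgene-rDNA concordance: {coseg.concordance:.3f} over {len(panel)} lines")

est = infer_selection(p_final=0.15, p0=0.5, generations=11, N=1000,
                      rng=np.random.default_rng(0))
print(f"s_hat = {est.s_hat:.3f}, 95% interval = "
      f"({est.interval[0]:.3f}, {est.interval[1]:.3f})")
```

Output:

```
line 0: c_hat = 130.3, 95% CI = (128.7, 131.9), class = LOW
transgene-rDNA concordance: 1.000 over 118 lines
s_hat = -0.146, 95% interval = (-0.183, -0.108)
```

The first line inherited the low-copy parental allele (truth: 130
copies); the depth-ratio MLE recovers it within ~1 copy at 30× coverage.
All 118 lines show the GFP transgene co-segregating with the low-copy
allele. The last line answers "what selection coefficient drives a
50:50 mix down to 15% in 11 generations at census 1000?": about a 15%
per-generation fitness disadvantage.

A command-line layer wraps the same functions:

```sh
rdnapanel simulate panel --seed 1 --out panel/
rdnapanel distortion --genotypes panel/genotypes.tsv --markers panel/markers.tsv
rdnapanel infer-s --p-final 0.15
```

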