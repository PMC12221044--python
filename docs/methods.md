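# Methods

## Scope and design

`rdnapanel` models the quantitative workflow of an rDNA copy-number RIL
experiment in *C. elegans*: cross simulation, depth-based copy-number
estimation, CHEF gel sizing, haploblock/distortion genotyping, stability
analysis, and Wright–Fisher competition. Each analysis module reads
plain-text formats (TSV/bedGraph depth, genotype TSV, CSV event tables)
and can therefore run on real data with the same code paths the synthetic
generators exercise.

## Genome model and coordinates

Six chromosomes with ce11-era lengths (~100 Mb total). The rDNA array is
terminal on chromosome I with a 7.2 kb unit; the reference assembly is
modeled as collapsing it to `reference_unit_count` units (default 1). The
toxin–antitoxin incompatibility locus sits at 2,300,000 bp on chromosome
I and the GFP transgene marker on the right arm proximal to the array.
Internally all intervals are half-open 0-based; writers emit 1-based
inclusive coordinates (bedGraph stays 0-based, per that format).

The genetic map is uniform at 50 cM per chromosome with an obligate
single crossover per meiosis (Poisson extras), and Haldane's map function
converts cM gaps to recombination fractions. A uniform map reproduces the
observed 1–4 haploblocks per chromosome but overstates recombination near
chromosome tips, where *C. elegans* crossovers are suppressed. For that
reason the default transgene position is placed ~65 kb (~0.2 cM under the
uniform map) from the array: this effective genetic distance reproduces
the complete marker–array co-segregation seen in the cross, whereas
placing the marker megabases away on a uniform map would synthesize
recombinants the tip-suppressed real map does not produce.

## Cross simulation

The F1 is formed from a high-copy hermaphrodite and a low-copy male, so
mitochondria are fixed for the high-copy parent. F2 founders are drawn by
selfing under viability selection: offspring of a heterozygous parent
that are homozygous for the incompatibility-null (high-copy parent)
allele survive with probability 1/3. The study reports only the direction
of the resulting distortion; 1/3 corresponds to the toxin killing about
two-thirds of susceptible homozygotes and is exposed as
`incompatibility_penalty`. Founders are screened to a configurable split
of transgene-homozygous-positive vs -negative lines (default 50:50), then
selfed with single-offspring descent for 10 generations. Expected
per-locus heterozygosity after g selfing generations is (1/2)^g, which
the suite verifies.

Per-homolog rDNA copy counts ride with whichever homolog spans the rDNA
locus at each meiosis. Copy-number drift is modeled as independent
Poisson loss and gain per cell division, with defaults loss = 1/120 per
division, gain = 0, and 15 divisions per organismal generation; the cited
loss rate is treated as per cell division, matching the arithmetic that
predicts a 2–4 copy loss over 20 worm generations (floor of 2.5 and
~4.48 at the 1/120 and 1/67 bounds).

## Depth profiles and the copy-number MLE

Binned read counts are independent Poisson draws; reads from all true
copies collapse onto the reference rDNA span. The estimator uses only
class totals, so it is invariant to re-binning and to the bin size used;
bins are split at the rDNA boundary and rates scale with bin width.
Blacklisted bins are flagged at generation time and excluded from every
likelihood. The MLE is the closed-form depth ratio; the 95% CI is the
profile likelihood in c with λ profiled out analytically, solved by
bracketed root-finding on the deviance (χ²₁ 0.95 quantile, 3.84). Zero
rDNA reads give ĉ = 0 with a one-sided interval; zero single-copy reads
are an error. Estimates are haploid copies; a heterozygous line
contributes the mean of its homolog counts, which is what collapsed-depth
sequencing of a mixed array pair measures.

At the study's conditions (30× depth, single-unit reference) the suite
verifies mean recovery within 1% at 73/130/417 copies and CI coverage
≥ 92% over 200 replicates per allele. Allele classification uses the
non-overlapping class bounds observed in the panel: LOW ≤ 200 copies,
HIGH ≥ 300.

What the generator does *not* model: GC/mappability bias, batch effects
between sequencing rounds (the study itself notes a possible systematic
inflation between batches; only control-strain deltas could expose it),
overdispersion beyond Poisson, and read-level artifacts. Passing tests
therefore show the estimator is correct under its stated model, not that
real libraries are free of these biases.

## CHEF sizing

Ladders must be strictly size-decreasing in migration distance with ≥ 3
bands. Default calibration fits log10(size) linearly in distance;
interpolation mode joins ladder points piecewise-linearly in (distance,
log10 size) and is exact at the nodes. Simulated runs place fragments on
the same fitted relationship plus Gaussian distance noise, so the
zero-noise round trip is exact in both modes — by construction, which is
the point: it validates the algebraic inverse, not gel physics. Fragment
size divides by 7.2 kb without subtracting the 3,927 bp restriction flank
by default (matching how the published copy numbers were computed);
`flank_bp` subtracts it when wanted. Out-of-range queries are flagged and
warned, not refused.

## Haploblocks and distortion

The two-state HMM uses a uniform initial distribution, Haldane transition
probabilities, and emissions correct with probability 1 − ε. H calls in
inbred lines (true heterozygosity ~(1/2)^10 after selfing) are treated as
error mass split equally between states, making them uninformative to the
chain, as are N calls; a `drop` policy is equivalent for decoding.
Posteriors come from a scaled forward–backward pass and are verified
against exhaustive 2^n path enumeration to 1e-10 on chains up to 12
markers. Decoding is max-marginal with ties broken toward the previous
marker's label (toward A at the first marker); blocks take breakpoints at
inter-marker midpoints and terminal blocks extend to chromosome ends when
lengths are supplied. An all-missing chromosome yields a single block by
the prior with a warning.

The distortion scan is a two-sided exact binomial test per marker against
0.5 over informative lines, Bonferroni-corrected across the markers
actually tested (markers with < 2 informative lines are excluded and
reported). Bonferroni matches the original analysis; FDR is deliberately
not the default. On neutral panels (118 lines × 1000 markers) the
fraction of panels with any flag stays below the nominal 5% (the
correction is conservative under linkage); with the incompatibility
penalty active, flags localize around 2.3 Mb on chromosome I.

## Competition and selection inference

COPAS censuses use the published gates: green peak height > 50,000 is
GFP(+), < 20,000 is GFP(−), and the handful of in-between events are
excluded from proportions (their assignment is immaterial at ≤ 3 per
1000). The synthetic event generator draws fluorescence from truncated
lognormal components with medians at 200,000 and 5,000 (arbitrary units)
plus an explicit 0.1% ambiguous mass, so gating behavior is controlled by
parameters rather than by tail accidents.

The Wright–Fisher model applies viability selection then a single
Binomial(N) bottleneck per generation (default N = 1000, 11 generations,
p₀ = 0.5); the chunk-transfer census is not modeled separately but an
optional second bottleneck size is exposed. States 0 and 1 absorb. The
point estimate of s inverts the deterministic logistic trajectory
exactly; the interval is grid-based: an s is accepted when the simulated
final-proportion distribution at the experiment's N and duration (1000
replicates per grid point, 0.005 grid step) places the observation within
its central 95%, and the reported endpoints extend half a grid step past
the extreme accepted points, since the true acceptance boundary lies
between grid points. Measured coverage of a true s = −0.10 is 92–96%.
Relative fitness between a test and control competition is the difference
of inferred s with independently combined interval endpoints; note the
inversion is symmetric in log(1+s), not in s, so opposite end-proportions
do not give equal-magnitude coefficients.

## Numerical and degenerate-input choices

- Profile-likelihood roots are found by expanding brackets then `brentq`;
  the lower bound collapses to 0 when the deviance never rises above the
  cutoff below ĉ.
- Shapiro–Wilk on copy-number deltas delegates to scipy; all-constant
  deltas are reported as "normality undefined" rather than raising.
- The integer drift prediction uses floor, not rounding, so the 2–4 copy
  bracket follows from expectations of 2.5 and 4.48.
- Exact binomial p-values are cached by (k, n) during panel scans.
- All generators take a `numpy.random.Generator`; identical (config,
  seed) pairs are bit-reproducible.

## Problem sizes in the test suite and acceptance script

The suite runs study-scale checks where they are cheap (118-line panels,
1000-marker scans, 10⁴ Wright–Fisher replicates) and reduces replicate
counts where precision permits: the acceptance script uses 100 estimator
replicates per allele, 50 neutral panels for the type-I rate, 10 selection
panels for distortion localization, and 100 recovery experiments. These
sizes give Monte-Carlo standard errors comfortably inside the margins
being checked.

## Known limitations

- No sequence-level read simulation or alignment; depth is generated at
  the bin level, and genotype ingestion starts from calls.
- Single-locus viability selection only; no male frequency, outcrossing,
  or stage structure in competitions.
- The copy-number likelihood is Poisson; overdispersed libraries would
  need a negative-binomial extension and wider intervals.
- No QTL mapping, no batch correction, and no modeling of the
  chunk-transfer demography beyond the optional second bottleneck.
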