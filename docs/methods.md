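# Methods

## The growth model

Body weight of a growing chicken is modelled with the Gompertz sigmoid in
two algebraically equivalent parameterizations:

* **G1 (classic form)** `BW(t) = BWa · exp(−b · exp(−k·t))`, with the adult
  (asymptotic) weight `BWa` (g), the dimensionless shape parameter `b`
  (equal to `ln(BWa/BW0)`, `BW0` the model-implied hatch weight) and the
  relative growth-rate constant `k` (1/day).
* **G2 (lag-time form)** `BW(t) = BWa · exp{−exp((e·μ/BWa)(λ−t) + 1)}`,
  with the absolute growth rate at the inflection point `μ` (g/day) and the
  lag time `λ` (days) — the intercept of the inflection tangent with the
  time axis, i.e. the modelled delay before rapid growth.

Equating the two forms gives the exact maps `μ = BWa·k/e`,
`λ = (ln b − 1)/k` and their inverses; `flockfit.convert_g1_to_g2` /
`convert_g2_to_g1` implement them and round-trip to 1e−10 relative.  Every
Gompertz curve inflects at `BWa/e` (the constant 1/e = 0.367879…, kept at
full precision internally; 0.368 is a display rounding).  Derived traits:
inflection weight `BWip = BWa/e`, inflection age `Tip = ln(b)/k`
(equivalently `λ + BWa/(e·μ)`; the G2 path computes the closed form and
cross-checks it against a numeric root of the defining equation to 1e−6 d),
maximum growth rate `MGR = BWip·k = μ`, weight at slaughter age
`BWs = BW(180 d)` and degree of maturity `Dm = BWs/BWa`.

Time is measured in days with hatch at day 0; week inputs convert as
`days = 7·week`.  A negative `λ` (equivalently `b < e`) is mathematically
valid — a bird already accelerating at hatch — and is admitted with a
warning rather than rejected.

## Fitting

Each bird is fitted separately by unweighted nonlinear least squares
(scipy's trust-region reflective method) in whichever parameterization is
requested; group curves are means of per-bird parameters, never pooled
fits — which is why group-mean derived traits differ slightly from algebra
applied to rounded group-mean parameters.  Box bounds keep the optimizer
out of degenerate corners: `BWa ∈ (max weight, 10·max weight]`,
`k ∈ (1e−4, 1)`, `b ∈ (0.1, 20]` (the G2 box is the loosened image of this
one).  Self-starting values: `BWa₀ = 1.2·max weight`, `b₀` from the first
weight, `k₀` from an ordinary regression of `ln(−ln(BW/BWa₀))` on time,
falling back to fixed defaults (2500 g, 3.5, 0.015/d) on degenerate input.
Tolerances are set to 1e−12 so that refitting from a fit's own estimates is
a fixed point; a trajectory with no growth signal is returned with
`converged=False`, never silently.

Goodness of fit is the adjusted coefficient of determination and
`AIC = n·ln(RSS/n) + 2(p+1)` with the residual variance counted as a
parameter.  Because G1 and G2 span the *same* three-parameter curve family,
a converged optimizer reaches the same minimal RSS in either form and their
AICs can only tie up to numerical precision; the package therefore compares
AIC *orderings* with tie tolerance and makes no claim that one form "fits
better" on data the other generated.  A perfect fit (RSS = 0) reports
`AIC = −inf` as a sentinel and `r²_adj = 1`.

The low-level `GompertzModel` accepts any series of ≥ 3 points (three
observations determine three parameters, and a noiseless 3-point series is
interpolated exactly); the trajectory-level helpers demand ≥ 5 points
before a fit is trusted.

## Group statistics

Weekly weights and fitted parameters are analysed with a two-way ANOVA
(breed, sex, breed×sex; Type-II sums of squares) optionally extended by a
random effect whose covariance is proportional to a bird-by-bird
relationship matrix (an animal-model-style single variance component).  The
relationship matrix is the proportion of shared alleles over multi-locus
marker genotypes (multiset intersection per locus, averaged over loci with
both birds typed).  The variance ratio is profiled by restricted maximum
likelihood over a fixed grid (0 and 31 log-spaced points in [1e−3, 1e3]);
the response and design are then whitened through the eigendecomposition of
the relationship matrix and F-tests proceed as in ordinary least squares.
With the identity matrix the procedure reduces exactly to ordinary two-way
ANOVA (verified against statsmodels to 1e−8).  Backward elimination removes
the least significant removable term at α = 0.05, interaction before its
main effects.

Group means are compared with the Waller–Duncan k-ratio t-test (k = 100,
the conventional value corresponding roughly to a 5% comparison-wise
level).  The critical value implemented here is the minimum-average-risk
Bayes rule conditional on the observed F statistic: the marginal variance
of a standardized mean difference is F, so the prior variance is F − 1, the
posterior of the difference is centred at `t(1 − 1/F)` with scale
`sqrt(1 − 1/F)`, and the critical t solves
`k·E[(−δ)₊ | t] = E[(δ)₊ | t]` under linear losses, with Student-t tails at
the error df absorbing residual-variance uncertainty.  The full
Waller–Duncan double integral over both variance-estimate distributions is
not reproduced; the conditional rule has the right limits (t → 1.72 for
k = 100 as F → ∞; no separation at all for F ≤ 1) and is checked by
calibration-style tests only.  Letters are assigned by the usual
sorted-window display and are invariant to group ordering.

Sexual dimorphism is summarised as Δ = (male − female)/female × 100,
rounded only for display.

## PAX7 minisatellite

Allele calling maps amplicon lengths to the nearest reference length within
±3 bp: E = 588 bp (three 31-bp repeat units), F = 557 bp (two units),
G = 525 bp (one unit plus a single-nucleotide deletion: 557 − 31 − 1).  One
observed length is called homozygous.  E is retained in the allele model
even where only F and G segregate.

Hardy–Weinberg proportions are tested by allele randomization: alleles are
permuted among individuals and re-paired 2000 times (default); the
deviation statistic is |observed − expected heterozygosity| and the p-value
is the add-one-corrected fraction of permutations at least as deviant.  The
statistic is discrete, so at small sample sizes the test is conservative;
at the cohort scale (~200 birds) it holds its nominal 5% level (checked by
simulation).  Breed differentiation uses the Weir–Cockerham variance-
component estimator of Fst summed over alleles at the single locus.
The weight–genotype association is a per-age one-way ANOVA within a
breed-sex group with Waller–Duncan letters; ages are analysed independently
(no repeated-measures structure), matching the conventional presentation.

## Synthetic flocks

The generator reproduces the study design it stands in for: four breed-sex
groups of 46/47/54/54 birds weighed biweekly from hatch to 32 weeks (17
ages).  Group-level truth is the published group-mean classic-form
parameters (the blond breed's female asymptote is 2012 g; the bare "201"
that appears in one printed table is treated as a typo for it).  Per-bird
parameters are drawn log-normally around group truth with the mean
preserved; default CVs are back-calculated from the published SEMs
(SEM·√n ≈ 15% for the asymptote, 11% for the shape; the rate's SEM prints
as 0.000 so its CV is set to a typical 8%).  Measurement noise is
multiplicative Gaussian (default CV 5%) — weights span 39 g to ~2.5 kg, so
constant-CV is the defensible error model.  The optional biphasic slowdown
scales growth *increments* (not levels) inside a 91–147 d window, keeping
trajectories monotone; the optional genotype effect adds a fixed number of
grams to the asymptote per favourable allele from an onset age (default
98 d) onward, scaled along the trajectory.  Marker genotypes are uniform
and independent by default, or drawn in full-sib blocks to create family
structure; between-bird parameter draws are independent across parameters
(a correlation hook is deliberately not defaulted, as the real structure is
unknown).

What the generator does **not** emulate: feed intake and environment,
mortality/dropout, seasonal photoperiod effects, heteroscedasticity beyond
constant CV, and genuine pedigree structure.  Passing recovery tests
therefore show the estimators are consistent under the stated error model,
not that real flocks satisfy that model.

## Problem sizes and numerical choices

Calibration and recovery checks are scaled to run comfortably on one CPU:
parameter recovery uses 25 replicate flocks of 50 birds/group at 5% noise
and 8% between-bird CVs; type-I calibrations use 500–1000 replicates; the
association power simulation uses 25 replicate groups of 54 hens with a
150 g/allele asymptote effect (≈1.5 within-group SD between the two
homozygotes).  Dimorphism recovery is judged on the replicate average,
since a single flock's realized dimorphism wobbles ±2–3 points with the
between-bird draw alone.  All simulations are seed-deterministic
(numpy Generator); HWE permutations are vectorized argsorts.

## Known limitations

* The Waller–Duncan critical value conditions on the observed F rather
  than integrating over the numerator chi-square; published tables are
  reproduced only approximately (within a few percent at moderate df).
* The REML profile is a grid search over one variance ratio; multiple
  variance components are out of scope.
* The per-age ANOVAs are reported without multiplicity correction by
  default, mirroring the conventional weekly presentation; a Bonferroni
  flag is left to the caller.
* The AIC formula is one of several conventions; only orderings, never
  levels, are meaningful across software.
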