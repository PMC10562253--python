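# Methods

## Model

Hematopoietic stem cells form a pool whose drift scale is set by Nτ, the
product of the stem-cell number N and the symmetric division time τ
(years); Nτ ≈ 100,000 years is the default, taken from independent
estimates, and is configurable everywhere. A given mCA is acquired at a
constant rate μ per cell per year; a clone that survives stochastic drift
expands exponentially at its fitness effect s per year. Writing
x = f/(1−f) for the odds of the clone's cell fraction f, a surviving clone
born at time t₀ has x exponentially distributed with mean
e^{s(t−t₀)}/(Nτs), and surviving clones arrive at rate Nτμ·s per year.
Pooling over birth times gives the per-person density per unit
l = log f:

    ρ(l) = Nτμ/(1 − e^l) · exp(−e^l / (φ(1 − e^l))),
    φ(t) = (e^{st} − 1)/(Nτs).

ρ plateaus at Nτμ for f ≪ φ and falls off exponentially above φ. In odds
space the density is Nτμ·e^{−x/φ}/x, so every prevalence integral reduces
to exponential integrals:

    P(f₀ < f < f₁ | t) = Nτμ·[E1(x₀/φ) − E1(x₁/φ)].

This closed form (scipy's `exp1`) is used throughout instead of numerical
quadrature; the test suite verifies agreement with adaptive quadrature to
1e-8 relative. φ is evaluated in log space with a series limit for
s·t < 1e-8, so s = 0 and very large s·t are both exact and overflow-free.

Cohort-level quantities average the per-age expressions over the age
mixture (defaults: decades 40–49/50–59/60–69 weighted 23.8/33.6/42.6%),
each decade represented by its midpoint (45/55/65). Decade midpoints
introduce a ≲1% error in decade-level prevalences relative to exact
within-decade averaging; this is negligible against sampling noise at the
problem sizes used, and the representative ages are configurable per
`AgeGroup`.

### Detection windows

Calls are observable between a 0.7% lower limit (long-range-phasing
sensitivity) and a class-specific upper limit: 67% for losses and 54% for
CN-LOH (heterozygous SNPs drop out of the upstream caller above a B-allele
frequency deviation of 0.25); gains and allosomal losses have no upper
cut-off. The per-mCA lower limit used in age-trend work is 1.5× the
smallest observed cell fraction, which suppresses false negatives near the
sensitivity floor.

## Estimator

For one mCA with observed fractions f₁ ≤ … ≤ f_n, the fit minimises

    Σᵢ [log C_pred(fᵢ) − log C_obs(fᵢ)]²,

where C_obs(fᵢ) is the observed cumulative rank (midranks for ties) and
C_pred(f) = cohort_size · Nτμ · E_age[E1(x₀/φ) − E1(x_f/φ)] is the
predicted cumulative count, evaluated at the observed (logit) cell
fractions. Using every call avoids binning arbitrariness, and the
log-cumulative form is robust in sparse high-fraction tails. Because the
objective is exactly quadratic in log(Nτμ), the amplitude is profiled out
in closed form; the remaining 1-D problem in s is solved by a 60-point
log-spaced grid scan over s ∈ [0.02, 1] followed by bounded Brent
refinement between the neighbouring grid points. This is the exact joint
optimum of the stated objective, deterministic and free of tie-traps. The
amplitude box is [1e-7, 1]; the upper end must exceed the allosomal
amplitudes (mosaic loss of X reaches Nτμ ≈ 0.16).

A useful structural property: C_pred below any cut-off does not involve
the upper window edge, so upper-truncation censoring cannot bias the fit
through window misspecification — its only cost is the loss of high-
fraction information. For truths whose density mass lies mostly above the
cut-off (losses with s ≳ 0.24), s becomes weakly identified from above:
point estimates fall below truth and the bootstrap upper quantile drifts
to the search bound, which is flagged (`upper_ci_undetermined`, defined as
the 97.5% bootstrap quantile landing within one grid step of the s upper
bound).

Confidence intervals are percentile intervals from B = 200 nonparametric
bootstrap resamples of the calls (refit each), clipped to the search box
and widened to contain the point estimate. μ inherits its interval from
the amplitude via μ = Nτμ/Nτ.

### Sex differences

Sexes are fit independently (per-sex cohort sizes; default minimum 10
calls per side, computed on persons carrying a single autosomal mCA). The
fold-difference probability curve for s or μ is the distribution of ratios
of paired bootstrap draws; the p value is the mass of that curve at ratios
≤ 1 (ties counted half), keeping the caller's A/B orientation, and
"significant" means p < 0.05. With a fixed orientation this one-sided
construction is uniform under the null (measured 5.5% rejection over 200
null repetitions); a difference in the opposite direction is tested by
swapping the arguments.

## Age dependence

Observed prevalence counts each person once per mCA per decade, above the
mCA's detection floor. Expected prevalence comes from the fitted (s, Nτμ)
through the prevalence integral at the decade midpoints. Both trends are
summarised by a weighted least-squares line p = mt + C with weight T/(2p)
per decade (T = persons in the decade) — proportional to the inverse
binomial variance of a small prevalence — and decades with zero observed
carriers are excluded from both gradients. The deviation statistic is
(m_obs − m_exp)/m_exp.

The deviation test builds its difference probability curve from joint
Poisson-bootstrap resamples: every call receives a Poisson(1) weight, each
resample is refit (giving an expected-gradient draw) and recounted per
decade (giving an observed-gradient draw). Poisson weights reproduce the
independent-Poisson fluctuations of both decade counts and the total call
count, and — crucially — retain the strong positive correlation between
the fitted model and the observed counts, which share the same data.
Construction matters here: pairing independent binomial count draws with
fit-bootstrap draws overstates the difference variance (measured
correlation ≈ 0.7) and rejects at only ~1% at nominal 5%; that variant is
kept as the `calls=None` fallback. The p value is two-sided,
2·min(P(diff ≤ 0), P(diff ≥ 0)), so both stronger- and weaker-than-
expected age dependence can reach significance; the joint test rejects at
3.5% (200 null repetitions at ~1,700 calls) and 6.0% (150 repetitions at
~450 calls).

The linear-in-age approximation P ≈ Nτμ·log(φ/f_lim) ≈ Nτμ·s·t + C is
exposed with its validity flag (f_lim < φ). Its relative error against the
exact integral is ≈ γ/ln(φ/f_lim) (γ the Euler–Mascheroni constant, which
the logarithmic form drops), so it reaches 10% accuracy only once
φ/f_lim ≳ 600 — a slower approach than is sometimes assumed.

## Mosaic loss of X: two components

When two events with (s₂ − s₁)·t ≫ 1 and μ₁ ≫ μ₂ underlie one label, the
spectrum shows a fall-off (set by φ₁) followed by a second plateau (set by
Nτμ₂) — two separated regimes that can be fit independently. The split
proposal scans the smoothed (3-bin moving average) log-density of a
40-bin spectrum upward past the density maximum and triggers at the first
bin where the slope recovers above half its running minimum, after a
cumulative drop of ≥1.5 nats, with the recovery sustained (mean of the
next 4 slopes above the same threshold). The lower split is that bin's
geometric centre; the upper split sits three bins higher, excising the
region where both components contribute. Calls between the splits enter
neither component fit. On the reference two-component scenario
(s₁ = 0.07, μ₁ = 1.6e-6; s₂ = 0.16, μ₂ = 1e-8; ~500,000 women) the
proposal lands at ≈8–9% and ≈13% cell fraction and both (s, μ) pairs are
recovered within 2 percentage points / 2-fold. Single-component spectra
(mosaic loss of Y) raise a no-plateau error instead of silently splitting.
The automated rule replaces what is fundamentally a visual judgement, so
manual splits always override it, and `regime_diagnostic()` reports
(s₂ − s₁)·t and μ₁/μ₂ so users can judge whether the separated-regime
assumption holds.

## Synthetic cohorts

The generator emulates a biobank cross-section: 482,789 people by default
(261,890 women, 220,899 men), ages uniform within decades weighted
23.8/33.6/42.6%. Per person and per mCA component, the detectable-clone
count is Poisson with the prevalence-integral mean at that person's age —
the exact consequence of independent rare clone initiations — and each
clone's cell fraction is drawn by inverting the truncated odds-space CDF
(E1 inversion on a 20,000-point log grid polished with two Newton steps;
inversion error is far below Kolmogorov–Smirnov resolution at any
realistic n). Event lengths are drawn uniformly from class-specific ranges
wide enough to exercise the allosomal size filters (mLOY > 2 MB,
mLOX > 125 MB).

The forward simulator is the generative process the density is derived
from (surviving-clone arrivals at rate Nτμ·s per year; exponential odds
conditioned on survival), so pooled spectra agree with ρ(l) bin by bin —
the two generators are mutual oracles, and an exact continuous-time
birth–death mode (division rate (1+sτ)/2τ, death rate (1−sτ)/2τ) is kept
behind `mode="exact"` for small-scale validation of the conditioned-
exponential approximation itself. A desk-scale guard refuses runs with
more than 1e6 expected mutant arrivals.

An interference mode emits, for persons carrying multiple independent
allosomal clones, a single call with the summed (mLOY) or absolute-
difference (mLOX) cell fraction — the negative control for whether
co-occurring events could mimic the observed spectral features.

What the generator does **not** emulate: SNP-array intensity noise, the
caller's false positives, per-person acquisition-rate heterogeneity
(germline predisposition), clonal competition, age- or sex-dependent s,
and co-occurring SNV drivers. Passing recovery tests therefore show the
estimator is correct when the constant-(s, μ) branching model holds; they
do not validate that model against real blood.

## Problem sizes and numerical choices

Tests and the acceptance script scale the study down where full size adds
nothing: parameter-recovery batteries use 500,000-person cohorts (50
seeds); null calibrations use 150–200 repetitions with ~120–450 calls per
repetition and B = 80 bootstrap replicates — sizes chosen so Monte-Carlo
error stays well inside the asserted bands. All randomness flows from
numpy `SeedSequence`s; every fit records its seed, and identical inputs
give bit-identical outputs. Ties in cell fraction take midranks;
evaluation points are clamped strictly above the window floor;
log-densities floor at 1e-300 to keep the profiled objective finite.

## Known limitations

- s below ~0.07 per year is barely identifiable at a 0.7% detection
  limit within a 40–70-year age range; the search box floor is 0.02.
- For highly fit losses/CN-LOH the upper cut-off leaves s unbounded
  above; estimates are conservative and flagged, not corrected.
- The two-component split rule assumes clearly separated regimes; with
  (s₂−s₁)·t of order 1 the exclusion band under-covers the mixed region.
- The fold-difference and deviation tests are bootstrap-calibrated, not
  exact; their measured null rejection rates are 3.5–6% at nominal 5%.
- Arm-level labels assume all events on an arm share one fitness effect;
  length-stratified fits (filter by `length_mb`, then `fit_single`) are
  the supported way to probe that assumption.
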