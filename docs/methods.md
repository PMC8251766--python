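# Methods

This note documents the statistical machinery in `vpdmeta`: the models, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical details that matter for
reproducing a run.

## Effect sizes

The unit of analysis is a *study*: one species in one experiment, measured
for one trait under a control and a high vapor-pressure-deficit (VPD)
treatment. The per-study effect is the log response ratio

    L = ln(x̄h / x̄c),

chosen over the raw ratio because it is antisymmetric in the two arms and
closer to normal in small samples. Its sampling variance is the
delta-method (large-sample) form

    v = sh² / (nh x̄h²) + sc² / (nc x̄c²).

A second form with un-squared arm means in the denominators is implemented
behind `variance_form="as_printed"` because some published syntheses
typeset it that way. That form is not invariant under a change of the
trait's units (rescaling means and SDs by a constant rescales it by the
same constant), which is dimensionally untenable for the variance of a log
ratio; the delta-method form is therefore the default, and the asymmetry
is pinned by a regression test. The magnitude of the manipulation enters
as the log VPD ratio ln(VPDh/VPDc). No small-sample bias correction is
applied to L.

Pooled results are reported on the *effect size* scale R − 1 = exp(L*) − 1,
the proportional change of the trait under high VPD.

## Missing-SD imputation

Roughly a third of extracted studies report no dispersion statistic. For a
trait with at least one SD-reporting study, each missing arm SD is imputed
as CV̄ · mean, with CV̄ the mean coefficient of variation over all reported
arms of that trait. Both arm-level CVs enter the donor pool by default
(`pooled_arms`), which maximizes the pool for sparse traits; `per_study`
averaging (one CV per study, then across studies) is available since the
choice between the two is genuinely open. The pass is single-shot —
imputed SDs never feed back into CV̄ — deterministic, and never alters
means, sample sizes, or reported values. A record missing only one arm's
SD has only that arm imputed.

Traits with *no* reported SD anywhere cannot be variance-weighted at all;
every study of such a trait receives weight 1 (unit weighting). The scheme
is all-or-nothing per trait: after imputation a trait is either fully
variance-weighted or fully unit-weighted.

One case the weighting cannot rescue: a record whose sample sizes are
missing can never form a variance, even with imputed SDs. Such records are
excluded from variance-weighted pooling and from meta-regression (and
counted in the imputation report); under unit weighting they participate
normally. Imputed variances are treated as known thereafter — no multiple
imputation or uncertainty inflation.

## Pooling and BCa intervals

Per trait, the pooled log ratio is the fixed-effect inverse-variance mean
L* = Σ wᵢLᵢ/Σ wᵢ with wᵢ = 1/vᵢ (arithmetic mean under unit weighting).
Between-study heterogeneity deliberately does *not* enter these weights;
the pooled table and the meta-regression are separate machines.

Uncertainty comes from a nonparametric bootstrap over studies: (L, v)
pairs are resampled jointly with replacement — weights travel with their
studies — and L* is recomputed B = 4999 times. The 95% interval is
bias-corrected and accelerated (BCa):

* bias correction z₀ = Φ⁻¹(fraction of replicates below the observed L*),
  with replicates tied to the observed value counted half below (midrank
  convention — small traits produce many exact ties);
* acceleration a = Σd³ / (6 (Σd²)^{3/2}), d = mean(jack) − jack, from
  leave-one-study-out values of L*;
* interval endpoints are replicate quantiles at the z₀/a-adjusted levels.

Degenerate replicate sets (all equal) give a zero-width interval at the
observed value. If every replicate falls strictly on one side of the
observed statistic, z₀ is infinite and the plain percentile interval is
returned, flagged `percentile_fallback`. Traits with fewer than 3 studies
report the point estimate with no interval at all. Quantiles use linear
interpolation (`numpy.quantile` default); the implementation reproduces
`scipy.stats.bootstrap(method="BCa")` endpoints exactly when fed the same
replicates, which the test suite asserts.

Seeds: every bootstrap stream is derived by SHA-256 hashing of the master
seed and the (trait, condition) label, and studies are sorted by id before
resampling, so results are invariant to database row order and to which
other traits are present.

## Meta-regression

For traits measured in more than 20 studies the model is

    Lᵢ ~ N(xᵢᵀβ, vᵢ + τ²),

with moderators log VPD ratio, day temperature, treatment duration and
plant age (continuous) and irrigation frequency (2 levels) and soil type
(5 levels) dummy-coded against fixed reference levels. Rows missing a
required moderator are dropped and listed; data-absent levels are pruned
(the first remaining level becomes the reference if the configured one is
absent).

τ² is estimated by REML via Fisher scoring on the profiled score
−½tr(P) + ½LᵀP²L with expected information ½tr(P²), where P is the REML
projection at the current τ²; the iteration starts from the
DerSimonian–Laird moment estimate, projects to τ² ≥ 0, and stops when the
step falls below 1e-8 (relative), with a 100-iteration budget. A boundary
solution at 0 with non-positive score is accepted. DerSimonian–Laird is
available as `method="dl"`. The fit then solves weighted least squares
with weights 1/(vᵢ + τ̂²); inference is normal-theory Wald z by default,
with the Knapp–Hartung adjustment (scaled covariance, t/F reference) as
`inference="knha"`. Both variants, τ² included, reproduce the standard
mixed-model meta-regression results of R's `metafor::rma` to ≈1e-6 on
frozen fixtures in the test suite. QM is the Wald chi-square over all
non-intercept coefficients.

Model selection is backward elimination: each round refits and removes the
single moderator with the largest p exceeding α = 0.05 — categorical
moderators are tested and removed as whole blocks via their omnibus p —
until every remaining moderator is significant or none remain. p-value
ties are broken by removing the later-listed moderator, making the
elimination order deterministic. No multiple-testing correction is applied
across traits or moderators; the pooled table offers an opt-in
Benjamini–Hochberg column as a clearly-marked diagnostic.

Plant groupings (evolutionary history, growth habit, growth duration, end
use) are analysed one factor at a time — several groupings jointly would
introduce redundant dummies — for traits spanning more than 20 species,
with levels carried by fewer than 2 studies pruned. Unit-weight traits are
excluded from all meta-regressions (no defined v), and the exclusion is
recorded.

## Synthetic data generator

The generator emits study tables with the structure the analysis assumes,
plus a truth object for recovery tests. Per study of trait t:

* true effect θᵢ = μ_t + βᵀ(xᵢ − x̄) + N(0, τ_t²), with moderator
  contributions centered at the scenario's central conditions (log VPD
  ratio at ln 4, temperature at 23 °C, …) so μ_t stays the mean effect;
* control mean from a log-normal around the trait's scale; high mean =
  control mean · exp(θᵢ); arm SDs = CV · mean with CV ~ U(0.05, 0.30); arm
  sample sizes uniform on 3–10;
* *observed* arm means drawn as normal sample means N(mean, SD/√n) — the
  realized L is then a noisy estimate of θᵢ whose variance matches the
  delta-method v, which a consistency test verifies within 10%;
* SD pairs masked missing with probability 0.34 (so ~66% of studies keep
  complete SDs); designated traits can be forced all-missing to exercise
  the unit-weight path.

Covariate marginals mimic the emulated database: VPD control/high centered
at 0.4/1.6 kPa, day temperature 23 ± 2 °C, treatment durations 5–60 days,
and plant-grouping frequencies matching the reported species composition
(74% dicots, 71% perennials, 70% non-crops, forb/woody-dominated, mostly
hydroponic or artificial media). `scenario_paperlike()` packages all 59
catalog traits with study and species counts echoing the catalog's
reference counts (~840 studies total at scale 1), signed mean effects
(conductance, biomass and height shrink; transpiration and leaf N
increase), VPD-ratio slopes planted on three traits, and the three
all-missing-SD traits. Per-trait substreams are derived by stable hashing,
so adding a trait never perturbs another trait's draws.

What the generator does **not** emulate: correlated moderators (real
irrigation practice correlates with soil type and species), non-normal
arm-mean sampling at small n, species- or paper-level random effects
(each study is independent given its moderators), digitization error, and
publication bias. Passing recovery tests therefore show the estimators are
correct under the stated model, not that the model captures every feature
of extracted literature data.

## Calibration results the test suite computes

* REML τ̂² agrees with a dense grid search of the restricted likelihood to
  1e-4 and is exactly 0 when residuals vanish.
* A planted VPD-ratio slope of −0.4 (200 studies, τ = 0.1) is covered by
  β̂ ± 2 SE in ≈95% of seeds; the Wald moderator test's type-I error at 60
  studies is ≈0.05–0.06 (the small-sample liberality of normal-theory z
  tests — Knapp–Hartung tightens it).
* Backward elimination always retains a strong moderator (|β|/SE ≫ 2) and
  reaches the exactly-correct minimal model in ≈82–85% of seeds with three
  null moderators present; the shortfall from (1 − α)³ ≈ 0.86 is the
  expected compound false-retention of repeated uncorrected 5%-level
  tests, not an implementation artifact.
* Empirical 95% BCa coverage over 1000 simulated 20-study traits is
  ≈0.89–0.93, not the nominal 0.95: BCa is known to undercover at small
  study counts, and inverse-variance weights under heterogeneity shrink
  the effective sample size further (with equal weights the same
  simulation gives ≈0.93). This is a property of the interval the pipeline
  deliberately reproduces, worth keeping in mind when reading CIs for
  traits with few studies.

## Problem sizes and runtime choices

Test and acceptance runs use the paper-like scenario at scale 1 (~840
studies) or below, B = 199–4999 bootstrap replicates, and 500–1000
simulation replicates for coverage/calibration checks; these sizes give
Monte-Carlo standard errors comfortably below the decision margins of the
assertions while keeping a full run in seconds on one core.

## Known limitations

* Fixed-effect weights in the pooled table (by design) make L* a
  precision-weighted, not heterogeneity-weighted, summary; under strong
  heterogeneity it leans toward low-variance studies.
* No species, paper or phylogenetic random effects; studies from one paper
  are treated as independent.
* Imputed SDs are treated as known, slightly overstating the precision of
  imputed studies.
* The `as_printed` variance form is provided for replication only and
  should not be used for new analyses (unit-dependent).
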