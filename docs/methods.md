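# Methods

## Data model

A cohort is a pair of tables sharing a 15-motive catalog (the TEMS basic
motives, in survey order) and a 1–4 Likert scale: a **trait table** with one
row per participant, and an **event table** with one row per logged eating
occasion (participant, diary day ≥ 1, meal type from the closed set
{breakfast, lunch, afternoon_tea, snack, dinner}, 15 state ratings).
Validation is strict and located: any out-of-range cell, unknown category,
missing motive column or orphan event is rejected with the row and field
named.  Raw inputs must be integer ratings (`strict_integer=True`); derived
profiles (averages) are real-valued by design, so one numeric type serves
both.  Meal categories are serialized as whitespace-free tokens
(`afternoon_tea`).  Participant ids are opaque strings ordered by first
appearance; analyses impose their own orders where needed.

## Aggregation

State profiles are unweighted means of all of a participant's events per
motive ("averaged across all eating occasions"); no reweighting by day or
meal type.  Within-person fluctuation is the per-motive sample variance
(n−1); it is undefined (NaN) below two events.  `min_events` defaults to 1 —
a stricter threshold would silently shrink the cohort, so excluded
participants are always returned explicitly.  Occasion summaries report
counts and percentage shares rounded to one decimal.

## Similarity indices

`ICC_de` is implemented in closed form (grand-mean-centred cross-product over
the average of the two centred sums of squares); the doubled-data Pearson
construction serves as the independent oracle in the tests, and the two agree
to 1e-10.  Shape is the Pearson correlation; scatter and elevation are raw
differences of profile variances (n−1, consistent with aggregation) and
means, with the trait-minus-state sign convention throughout (positive
elevation = overestimation).  Zero-variance degeneracies return NaN rather
than raising, so batch per-participant analysis never aborts; the
`variance_explained_pct` field is ICC_de²·100.

The group-level pair averages *person means*, not pooled events, so each
participant contributes equally regardless of logging frequency; the tests
document the difference against a pooled-events computation on a two-person
fixture.

Properties enforced by tests: joint affine invariance of ICC_de and r;
ICC_de = r when the two profiles share mean and variance; ICC_de strictly
decreasing in the size of a pure elevation offset.

## Per-motive comparisons

Each motive gets a paired t test (two-sided, df = n−1) of trait vs. averaged
state rating across participants, the between-person trait–state Pearson
correlation, and Cohen's d.  The default d convention is
**d_av = mean difference / ((SD_trait + SD_state)/2)**: with the reference
grand statistics (difference 0.53, SDs 0.31 and 0.23) it gives ≈ 1.96,
matching the published effect size, whereas d_z = t/√n would give ≈ 1.52;
d_z remains available via `d_convention="z"`.  Raw p-values are primary
(matching how such studies report them); a Holm-adjusted column is emitted
alongside.  Effect bands use strict thresholds |d| > 0.8 / 0.5 / 0.3;
correlation bands use r ≥ 0.50 (inclusive) and r > 0.30.  `compare_motive`
requires three matched participants; the batch `compare_all_motives` instead
degrades to NaN statistics so tiny cohorts still produce the full 15-row
table.  A motive counts as *overestimated* when p < α and the mean
difference is positive.

## Synthetic cohorts

The generator emulates the reference design: 35 participants, 8 diary days,
zero-truncated Poisson(3.2) events per day (≈ 900 occasions; truncation
reflects that a logging day without a single eating event does not occur, and
pushes totals slightly above the untruncated mean).  Per participant and
motive, a latent trait λ ~ N(μ_m, σ_b²) with μ_m linearly declining over
[3.5, 1.3] in catalog order (the typical declining motive profile); the
latent state level is a bias-shifted convex mixture
η = (μ_m − bias_m) + ρ(λ − μ_m) + √(1−ρ²)·σ_b·Z, so the trait–state coupling
ρ is exactly the latent correlation while the between-person SD is preserved.
Observed ratings round half-up and clamp to [1, 4] — one draw for the trait,
one noisy draw N(η, σ_w,m²) per event for states.  Meal types are categorical
with the observed study shares.  All randomness flows from one seed.

Defaults (units: points on the 1–4 scale): bias 0.53 on 12 motives and 0 on
convenience, visual appeal and social image; ρ = 0.5; σ_b = 0.4;
σ_w = 0.85 for the five high-fluctuation motives (visual appeal, pleasure,
convenience, health, natural concerns), 0.45 for the four low-fluctuation
motives (sociability, weight control, traditional eating, affect
regulation), 0.5 otherwise.  The SD tiers were chosen once, before the
acceptance tests were written, so that observed per-motive state variances
span ≈ 0.13–0.70 — the range reported for the real cohort — while grand
elevation recovery stays within ±0.12 of the configured mean bias.

**What the generator does and does not emulate.**  It reproduces the marginal
structure the analyses rely on (declining motive means, elevation bias,
motive-specific fluctuation, positive trait–state coupling, realistic event
counts and meal mix, floor/ceiling compression from the discrete scale).  It
has no circadian or weekday structure, no autocorrelation between consecutive
events, no missing data, and no participant-level response styles beyond the
latent levels.  Passing tests therefore demonstrate that the *pipeline*
recovers known structure from data of this shape — not that real EMA data
satisfy the model.

Two discretization effects are worth knowing about.  First, rounding and
clamping compress realized elevation for motives whose latent mean sits near
the floor (social norms most of all) — faithful to real bounded scales, and
the reason that motive shows the smallest realized effect.  Second, because
the trait is a single rounded draw while the state mean averages many noisier
rounded draws, clamping shifts the two *observed* means differently near the
scale bounds even with zero latent bias.  The type-I-error calibration
therefore uses interior motive means (linspace 3.1→1.9), where the observed
means genuinely satisfy the null the paired t test is testing.

## Visualization

The matrix is plain deterministic SVG: 21 columns (profile sparkline,
across-motive average, 15 motive cells, 4 index cells), one group row
("average participant") then one row per participant, by default in
descending overall similarity with ties broken by ascending participant id
and undefined values last.  Within a cell, dash height maps the rating
linearly (1 bottom, 4 ceiling); the difference square's **area** — not side —
is proportional to |trait − state| (perceptually honest magnitude encoding);
blue marks trait-dominant, orange state-dominant; color depth maps the pair
mean from [1, 4] onto [0.25, 1]; background gray scales with the
within-person state variance relative to the cohort maximum (undefined
variance renders white with a `var?` note).  Index-cell lightness maps
correlations via (v+1)/2 and differences via 1 − |v|/range with
data-independent ranges 3 (elevation, the widest possible mean difference)
and 2.25 (scatter, the maximum variance of a 1–4-bounded variable), so
renderings are comparable across cohorts; undefined indices hatch.  The
group row's cell shading uses the across-participant mean of within-person
variances.

## Numerical and scope choices

Problem sizes in the test-suite Monte-Carlo checks — 20 seeds for recovery
and power, 134 null cohorts (2,010 motive tests) for type-I calibration,
1,000 random pairs for the ICC oracle — give comfortable margins for the
properties asserted while keeping the whole suite in seconds.  Rounding is
half-up then clamp.  No confidence intervals on ICC_de are computed (point
values only); no mixed-effects modelling of event-level data (analyses
aggregate to person means first); the interactive explorer this matrix view
descends from is out of scope — the rendering is static by design.
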