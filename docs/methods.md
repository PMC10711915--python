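# Methods

## Setting

The Soft Drinks Industry Levy (SDIL) was announced on 16 March 2016 and
implemented on 6 April 2018. The evaluation design treats these as two linked
interruptions in weekly household purchasing series and asks, category by
category, how observed purchasing one year after implementation compares with
a counterfactual projected from earlier trends. The original study ran on a
proprietary household purchase panel (~22,000 households reporting weekly,
March 2014 – March 2019); this package reproduces the full analytical
machinery on synthetic panels whose ground truth is known exactly.

## Weekly calendar

Weeks are consecutive 7-day blocks starting Monday 2014-02-24, giving 107
complete pre-announcement weeks, the announcement in week 107, implementation
in week 214, and 52 post-implementation weeks (266 weeks, ending late March
2019). Real panel week alignment is unpublished; consecutive 7-day blocks are
the simplest faithful choice.

## Levy classification

Products map to exactly one category with this precedence: excluded groups
(infant formula, medical drinks, skimmed milk) → toiletries / confectionery
by product group → exemptions (milk content >75%, alcohol >1.2% ABV or
alcohol-replacement group, powders, 100% juice with no added sugar) → bottled
water → sugar tiers (≥8 g/100 mL high tier, ≥5–<8 low tier, >0–<5 and 0 g
no-levy). Tier boundaries are inclusive at the threshold (8.0 → high tier,
5.0 → low tier), matching the ≥ definitions. "No added sugar" is a catalogue
flag, not inferred from composition. Sugar concentrations are taken as given;
no correction against external sources is attempted.

Small manufacturers are flagged from observed purchases: levy-liable volume
(the four tier categories; bottled water is kept separate throughout) is
summed per manufacturer per calendar year, averaged over the span's years
(zero-volume years count), and compared against a strict `<` threshold. The
published thresholds (1 M and 0.5 M litres/year) describe volumes observed in
the full-size panel, so runs on scaled panels scale them proportionally to
panel size. Because no public register of exempt small producers exists, the
flag is an approximation by construction. The sensitivity exclusion drops
flagged manufacturers' levy-liable products only — the small-producer
exemption the flag approximates covers levy-liable drinks, and this keeps
exempt categories intact.

## Aggregation

A household-week is dropped when it records fewer than six purchases (the
panel operator's rule) or spends less than a configurable minimum (default 0;
the real minimum is undisclosed). Excluded household-weeks leave the weights
table too. Panel membership per week is defined by the weights table: an
in-panel household with no purchases in a category contributes zero, so
weekly means dilute correctly over non-purchasers. The weekly outcome is the
weighted mean Σwₕxₕ/Σwₕ of household totals (volume, or sugar mass =
Σ quantity × concentration/100). Combined groupings (all soft drinks,
levy-liable only, sugar bands irrespective of eligibility) are week-wise sums
of member series; powder grams add to liquid millilitres numerically, labelled
mL-equivalent, and bottled water counts inside "all soft drinks" but outside
the levy-liable subtotal. Weeks with an empty panel are an error, never
imputed.

## The interrupted time series model

Ordinary least squares on: intercept, linear week index, level + slope terms
switched on at the announcement, level + slope terms at the implementation,
two annual harmonic pairs (period 52.18 weeks = 365.25/7, so the cycle does
not drift over five years), a December–January indicator, an optional
Easter-week indicator (used for confectionery), and the control category's
observed series. Analysis 1 (announcement) fits weeks 0–210 with announcement
terms only; analyses 2 and 3 fit the full span with both interruptions,
counting respectively the implementation terms or all four as "the
intervention". Designs are checked for full rank — a constant or
deterministic control is rejected rather than silently dropped — and windows
must exceed the parameter count by at least ten weeks.

Default uncertainty is heteroskedasticity-and-autocorrelation-consistent
(Newey–West) with lag ⌊4(n/100)^{2/9}⌋ (4 at n = 266). An iterated AR(1)
generalized-least-squares alternative (`error_model="ar1-gls"`) is exposed;
because the synthetic disturbances are exactly AR(1), the GLS intervals are
the correctly specified choice there, and the calibration suites evaluate
them. At this series length the HAC intervals are noticeably anticonservative
for long-horizon level+slope contrasts, which is a known small-lag property
rather than an implementation artifact.

Effects: absolute change = c′β with the analysis' intervention columns at
their evaluation-week values, SE = √(c′Σc); relative change =
100(ŷ_obs−ŷ_cf)/ŷ_cf with first-order delta-method variance using gradient
100(ŷ_cf·a − ŷ_obs·b)/ŷ_cf². All intervals use the normal 1.96 quantile (no
small-sample t correction, matching the large weekly panel behind each
point). Evaluation defaults to the last week of the window; if the projected
counterfactual is non-positive there, it moves to the last week with a
positive counterfactual and the estimate carries a degenerate flag. Reported
tables round volumes and sugar to 1 d.p. and percentages to 1 d.p.;
"significant" means the absolute-change 95% CI excludes zero.

## Synthetic panel generator

Each category's expected weekly per-household outcome is

baseline + trend·t + amplitude·sin(2πt/52.18) + Christmas uplift (weeks
starting in December or January) + Easter uplift (confectionery only) +
level/slope changes at each interruption.

Realised household values add (i) a time-constant Normal household effect,
(ii) a week-level AR(1) disturbance common to all households, and optionally
(iii) a market-wide AR(1) shock shared across categories (scaled by a
per-category loading; off by default). The aggregated weekly series is then
exactly a segmented-regression mean plus AR(1) noise — deliberately the
structure the analysis model assumes, so parameter-recovery tests are fair
rather than confounded by model misspecification. Expected paths that go
negative anywhere in the span are a configuration error (truncating would
bias recovery tests); realised household-week quantities are clipped at zero,
which under the default parameters occurs with negligible probability.

Each household-week-category total is assigned to one product of that
category (chosen with probability proportional to manufacturer share
weights), so category sums are exact and the same events exercise
classification, manufacturer flagging and aggregation. All products within a
category share one sugar concentration, chosen to reproduce the category's
published sugar-to-volume ratio, so sugar series have the same closed-form
ground truth as volume series. Household weights are i.i.d. lognormal with
mean 1 (the real weights are proprietary), written per household-week.

Default conditions anchor baselines, trends, seasonal and holiday uplifts to
the published pre-announcement weekly means (e.g. high tier ≈ 880 mL and 98 g
sugar per household per week), with interruption effects carrying the
published signs and whole-intervention magnitudes of comparable size. The
three published per-category estimates cannot all be matched by one level +
slope injection (two of the analyses share an evaluation week), so exactness
checks instead inject −171.6 mL at implementation and +30.8 mL at
announcement, making the implementation-only and whole-intervention analyses
recover −171.6 and −140.8 exactly on noiseless data. The default panel is
1,000 households (the demonstration scripts use 150; tests use 4–25):
because the dominant series-level noise is the common weekly disturbance,
weekly-series statistics are essentially independent of panel size, and the
methods scale unchanged to the real panel's ~22,000 households.

What the generator does **not** emulate: zero-inflated purchasing (every
simulated household buys every category every week, so the six-purchase
filter never binds on defaults), reformulation over time (concentrations are
static, so sugar-band membership is constant), price pass-through and
consumer choice mechanisms (effects are injected directly), within-category
concentration heterogeneity, and the proprietary weight construction.
Passing tests therefore demonstrate the estimator's correctness under its own
assumptions, not robustness to the real data's messiness.

## Problem sizes for the checking suites

Calibration runs use 200 replicate panels of 25 households over the full
266-week calendar (AR(1) ρ = 0.5, injected level and slope changes at both
interruptions); the delta-vs-bootstrap comparison uses 10⁴ parametric draws
on one fixed fit; the classification partition sweep uses 10⁴ randomised
products; Monte-Carlo mean-consistency uses 200 replicates of a 10-household,
30-week panel. These sizes give standard errors comfortably inside the
asserted bands.

## Known limitations

- The exact published model specification (number of harmonics, error
  structure, how the control enters) lives in unavailable supplementary
  material; the design here reproduces every feature attested in the main
  text and figure captions, but it is a documented substitute, not a claim
  about the original code.
- Analysis 2's fit window starts at the beginning of the data with
  announcement terms as nuisance covariates; a window starting at the
  announcement is available via `InterruptionSpec.window`.
- The delta method is first order; strongly skewed ratio distributions (small
  counterfactual relative to its SE) are summarised imperfectly, which is why
  the bootstrap comparison fixes a moderate-noise fit.
- Manufacturer volumes are share-driven; absolute litres depend on panel
  size, so small-manufacturer thresholds must be scaled to the panel.
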