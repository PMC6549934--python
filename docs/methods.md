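# Methods

## The assessment model

A water-quality objective hierarchy is a tree. Leaves bind measurable
attributes — nutrient concentrations (NH₄, PO₄, NO₃, mg/L) and one mixture
risk quotient per pesticide mode of action — through *measurable value
functions* onto a common scale v ∈ [0, 1] (1 = objective fully met,
0 = worst case to be expected). Internal nodes combine child values with an
aggregation operator and child weights summing to 1. The whole construction
is preference information: it encodes how much a decision maker cares about
each sub-objective and how much a good one may compensate a bad one.

### Value functions

A value function is piecewise-linear through six anchors: level 0 → v = 1,
the four class-boundary levels → v = 0.8 / 0.6 / 0.4 / 0.2, the worst-case
level → v = 0. Outside the breakpoint range evaluation clamps (no
extrapolation: v must stay in [0, 1]). The class bands on the value scale
are the equal 0.2-wide intervals; the good/moderate boundary — the legal
threshold — is v = 0.6. A value exactly on a class boundary belongs to the
*better* class, because a site exactly at the legal threshold still meets
the standard. For attributes with only a pass/fail criterion a three-anchor
variant is provided (0 → 1, threshold → 0.6, worst → 0).

### Aggregation operators

Four operators, applied per node:

| operator | formula | compensation |
|---|---|---|
| minimum | min(vᵢ) | none |
| additive | Σ wᵢ vᵢ | full |
| additive–minimum | α·Σwᵢvᵢ + (1−α)·min(vᵢ) | partial, α ∈ [0,1] |
| geometric offset | (Π(vᵢ+δ)^wᵢ) − δ | partial, δ ≥ 0 |

Defaults α = 0.5, δ = 0.1. Limits used as test oracles: α = 1 ↦ additive,
α = 0 ↦ minimum; δ = 0 is the weighted geometric mean (zero-annihilating),
δ → ∞ tends to the additive mean (δ = 10⁶ agrees within 10⁻⁴). Ordering
v_min ≤ v_add−min ≤ v_add and the AM–GM inequality v_geo−off ≤ v_add hold for
all inputs.

Numerical conventions: the geometric product is evaluated in log space; a
child with vᵢ + δ = 0 and wᵢ > 0 forces the node to the limit value 0, and
0⁰ counts as 1 so zero-weight children never contribute. Results are clipped
to [0, 1] against round-off. Node weights must sum to 1 within 10⁻⁶.
With a single child every operator returns the child's value.

Missing leaf data: by default the missing leaf is dropped and its siblings'
weights are renormalized, with a warning (monitoring data are routinely
incomplete; silently dropping without a flag would be misleading). A strict
mode raises instead.

### Pesticide mixtures

Substances are grouped by toxic mode of action (photosynthesis inhibition,
auxin activity, very-long-chain-fatty-acid synthesis inhibition,
acetylcholinesterase inhibition). Within a group, concentration addition:
RQ = Σ cᵢ/EQSᵢ, computed against chronic and acute standards separately.
The RQ→value translation anchors RQ 0 → v = 1 and RQ 1 → v = 0.6 (at the
standard means at the legal threshold); the remaining class boundaries are
log-spaced between RQ 1 and a configurable worst case (default RQ 100 →
v = 0), with the v = 0.8 boundary one half log-step below RQ 1. Log spacing
was chosen because exposure ratios are multiplicative quantities; all
boundaries are editable in the config. A group's leaf value is by default
min(v(RQ_chronic), v(RQ_acute)) — the worse standard governs — configurable
to chronic-only. An acute EQS below the chronic one triggers a warning (not
an error): acute standards are normally less strict.

### Uncertainty propagation

Prediction uncertainty arrives as a joint Monte Carlo sample of all leaf
attributes. Every draw is pushed through the full hierarchy (vectorised,
equivalent to a per-draw loop to 10⁻¹²) and only the resulting per-node
value samples are summarized: median and the 5%/95% quantiles (a 90%
interval, the reporting default; the probabilities are configurable).
Aggregating summaries instead of samples would be wrong for any nonlinear
operator — with the minimum and anti-correlated leaves the root median lies
strictly below the minimum of the leaf medians, which the tests demonstrate.
Quantiles use linear interpolation of order statistics (Hyndman–Fan type 7),
fixed so results are bit-reproducible.

Grab-sample emulation: levels are read off a dated series at scheduled
monitoring dates; the attribute statistic entering the value function
defaults to the 90th percentile of the sampled concentrations
(precautionary monitoring practice; configurable).

### Costs and scenarios

Costs per alternative are annual (min, best, max) interval bounds — min and
max play the role of confidence bounds; no parametric distribution is
assumed. Under a socio-economic scenario the mean taxable income compounds
geometrically at the scenario's annual rate over the horizon (default 35
years, base year 2015 → horizon 2050, configurable) while the population
change applies as a single factor (the scenarios state horizon-year
populations directly). Relative cost = 100·cost/(population·income), in %
of mean taxable income per inhabitant. The four shipped scenarios:
status quo (+0.4%/yr income, population unchanged), moderate growth
(+2%/yr, +20%), exploding growth (+4%/yr, +730%), decline (−1.5%/yr, −20%).
The base population of the toy catchment is 24 000; the base mean taxable
income (50 000/yr) is illustrative and must be supplied for real use.

### Decision layer

Ranking: competition ranking (1, 2, 2, 4) on median overall value per
(scenario, climate) cell; exact ties share a rank. Dominance: A is dominated
iff some B is weakly better in every oriented objective (value: higher
better; cost: lower better) and strictly better in one; the default runs on
medians, and a separate conservative mode requires full interval separation
(it goes beyond the median-based analysis and rarely fires). Trade-off
tables are lossless records of (alternative, scenario, climate) outcomes;
the plotting hook draws cost-vs-value points with interval bars.

## The synthetic catchment

The generator emulates the *output* of a catchment water-quality model — a
joint attribute sample per (alternative, scenario, climate) — not its
hydrology. Levels are log-normal, `median · exp(ln(spread)·Z)`: positive,
skewed, with the stated median exact. Spreads (geometric s.d.) default to
1.15–1.2 for nutrients and 2.0–2.5 for the pesticide groups, so pesticide
90% intervals span about a factor 20 — wide enough that the current-practice
assessment class is genuinely uncertain, which is the situation the method
exists for. The standard-normal draws are shared across alternatives within
a (scenario, climate) cell: the emulated model is "re-run" on the same input
realisations with modified source terms, so alternative comparisons are
paired, as in the real modelling chain. Draws are assessment-statistic
replicates, not time steps; no temporal autocorrelation is modelled (the
grab-sampling utilities are exercised on a separate dated series).

Alternatives scale attribute medians with source-reduction factors in
[0, 1]: e.g. the WWTP upgrade cuts point-source loads (NH₄ ×0.5, PO₄ and
micropollutants ×0.6), organic farming removes most agricultural pesticides
(RQ ×0.15), the nature park slightly more (×0.18) at much higher cost, and
urban-drainage measures trim nutrients by 5–15%. The combined alternative
"All" takes the element-wise minimum of its constituents' factors — measures
addressing the same source do not double-count; this is a fixture
convention, not an empirical claim. Scenario load multipliers are mild
(±5–15% on urban-source attributes, −10% on NO₃ under strong urbanisation)
and a future climate adds +5% across loads. Under these conditions current
practice sits in the moderate band (overall median ≈ 0.42–0.43, pesticides
worst), every single measure stays below the legal threshold, and only the
combination crosses into the good state (≈ 0.62–0.64) — in every scenario
and climate.

All concentrations, class boundaries, EQS entries and costs in the fixture
are illustrative, clearly non-regulatory, and shipped as editable configs;
they demonstrate formats and qualitative behaviour, not any real catchment.

## Problem sizes

The default end-to-end run evaluates 10 alternatives × 4 scenarios ×
2 climates at 1000 draws (80 000 hierarchy evaluations, a few seconds);
property suites use 1000 random instances per invariant. These sizes give
stable medians (standard error ≈ 0.004 on the overall value) while keeping
the full suite fast.

## What passing tests do and do not show

The synthetic catchment demonstrates that the assessment chain is correct,
monotone, seed-reproducible and able to reproduce the qualitative case-study
structure it was designed around. It does not validate any real catchment:
real attribute samples come from a calibrated pollutant-pathway model with
temporal structure, inter-attribute correlation from shared drivers, and
calibration bias, none of which the log-normal emulation carries. Cost
figures enter as exogenous estimates; deriving them (contribution margins,
capital-cost annualisation) is out of scope, as are stakeholder preference
elicitation and the climate-model chain (represented by a scalar modifier).

## Known limitations

- Value functions are restricted to monotone piecewise-linear shapes; the
  framework of measurable value functions is more general.
- The mixture rule is concentration addition within a mode-of-action group;
  alternative groupings (by most sensitive target organism) and interaction
  effects are not implemented.
- Dominance on medians ignores uncertainty unless the conservative mode is
  chosen; no stochastic-dominance machinery is provided.
- Costs accept pre-annualized values only; no discounting is performed.
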