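# Methods

This note records the modeling conventions behind `nutribca`: the economic
evaluation of an agriculture–nutrition intervention delivered through
community-based ECD centers in southern Malawi, costed over a 12-month
horizon from a societal perspective and valued in 2016 USD.

## Parameter registry

All assumptions live in a single validated `ParameterSet`; its defaults are
the packaged base case. Cross-field invariants are enforced at
construction: program + community cost equals the total exactly, deaths
averted cannot exceed stunting cases averted, the base-case discount rate
must be among the listed rates, and employment ages must be ordered around
the child's 2016 age. Two documented tensions in the source assumptions are
carried, not corrected:

- The share of population aged 6–24 months is 3.27% in the registry of
  record; the alternative 3.18% appears as the module constant
  `FRAC_AGE_6_24_TEXT` for scenario use.
- Deaths averted are carried both unrounded (10.78, the value consistent
  with the published $18,310-per-death ICER and the $79,653 mortality
  benefit: 197,377 / 18,310 = 79,653 / 7,389 = 10.78) and as the display
  integer 11. Monetary computations (mortality benefit, per-death ICER,
  productivity netting) use 10.78; the DALY computation uses 11 (below).

## Costing

Capital purchases enter at their equivalent annual cost
`cost · r/(1 − (1+r)^−L)` at r = 3% (preschool equipment life 10 y; the
production manual 5 y). Volunteer beneficiary time is valued at 50% of the
$23 monthly minimum wage. The wage is monthly; hours are converted at 176
working hours per month (22 days × 8 h), a declared convention of this
package — the source states no hourly basis. Both the shadow share and the
hours basis are configurable. Cost-efficiency ratios divide the grand total
by children (1,017), households (900) and beneficiaries (4,806) reached,
displayed to the nearest dollar but stored at full precision.

## Health effects and DALYs

Stunting cases averted in the trial arm scale to the implementation area by
the ratio of area children aged 6–24 months (118,261 × 3.27%) to the trial
sample (304). The scaled count of record is 332; the exact derivation of
that figure is under-determined in the source (trial-arm case count, 3.27%
vs 3.18%), so 332 is a parameter, and the scaling operation exposes the
stated procedure. Deaths averted come from an external lives-saved model
and are never computed here.

DALY convention: YLLs are discounted at 3% over the sex-averaged remaining
life expectancy at the mean death age of 2.6 y (standard 79.05 y, Malawi
65.9 y); YLDs are undiscounted (cases × LE × 0.002); all 332 averted cases
count as non-fatal in the YLD term, and the YLL term uses the display
deaths count of 11. This combination reproduces the published totals to
about 1.3% (383.7 vs 382 standard; 358.1 vs 363 Malawi). The convention is
inferred rather than stated — purely undiscounted or fully discounted
variants miss the published totals by large margins but remain selectable
via `yll_discount` and `le_source`.

## Benefit valuation

**VSL transfer.** Four population-average methods are implemented:
US extrapolation (9.4m × (1,220/57,900)^1.5 ≈ 28,751 intl$), constant VSLY
(spread over 33.8 undiscounted adult years, times 63.3 YLLs at death age
2), and 160× / 100× GNI per capita. International dollars convert to market
USD at the PPP price-level ratio 0.257 (implied identically by every
published intl$/USD pair). The base case uses the US extrapolation — the
smallest of the four.

**Timing conventions.** Productivity payments arrive at integer years
t = 14..58 after 2016 (a 2-year-old earning from age 16 to 60, 45 working
years); agriculture at t = 1..20. The stunted wage is backed out of the
economy-average wage via `w_s = 750 / (1 + 0.30 · 0.63)` ≈ $630.8, so the
annual gain is ≈ $189.2. These choices reproduce all three published
productivity totals within 0.04% and are the only combination tested that
does so at every rate.

**Agriculture calibration.** The per-crop supplemental quantities
underlying the annual production value are not published with the
evaluation, so the annual base is calibrated such that the 3%-discount
stream's present value equals $179,509, giving ≈ $9,413/yr. Only the sold
half of the stream appreciates with GNI growth; the consumed half stays at
constant 2016 prices. This mixed model then lands on the published 5% and
10% values within 0.16% — a structural validation, since those two numbers
are not calibration targets. Residual ≤0.2% gaps on the 5% streams likely
reflect unstated spreadsheet conventions and were not chased further.

## Sensitivity analysis

The PSA redraws six inputs per iteration: stunting and deaths averted from
a bivariate normal (means 332/11, SDs 82/1, correlation 0.55 via the
triangular transform of independent standard normals; no truncation —
negative values sit beyond 4 SDs), and wage premium U(0.11, 0.82), GNI
growth U(0.02, 0.07), share sold U(0.25, 0.75), cost U(157,902, 236,853).
The VSL is held fixed at the US extrapolation: it is already the smallest
estimate, and varying it could only inflate returns. Each draw re-prices
all three streams at the base-case 10% rate; the agriculture stream keeps
its calibrated annual base and re-evaluates the growth-discount factor with
the drawn growth rate and sold share (whether the original analysis
recalibrated per draw is unknowable; the tornado shows this stream is the
least influential, bounding the ambiguity). Draws are fully vectorized and
bit-reproducible under a fixed seed.

The tornado analysis moves one input at a time to its bounds: the uniform
inputs use their ranges; the two normal inputs use mean ± 1 SD, since the
underlying figure's bounds are not published. Results are ordered by the
absolute BCR swing.

## Synthetic data

The generator emulates the two upstream datasets at their study scale. The
trial simulator produces 60 clusters split evenly between arms with ~5
children per cluster per period, baseline prevalence 0.37 in both arms and
an endline treatment prevalence shifted by the programmed effect (default
−17 pp); cluster heterogeneity is a normal random effect on the logit scale
(default SD 0.3, chosen as a moderate between-cluster spread since no ICC
is reported) shared across periods, so the DID estimator removes it in
expectation. Cell probabilities are clipped to [0.01, 0.99]. The ledger
simulator Dirichlet-splits each payer's target across items — always
including a 10-year capital item and a community volunteer-time item — and
back-solves purchase amounts and hours so the valued aggregate reproduces
the targets to rounding error. What passing these tests shows is that the
pipeline's estimators recover programmed inputs under the assumed
structure; the simulators do not emulate midline waves, attrition,
informative cluster sizes or measurement error in anthropometry, so they
say nothing about robustness to those features of real trial data.

## Numerical choices and scale

All arithmetic is double precision with display rounding applied only at
output (dollars to the nearest unit, BCRs to 2 decimals). Discounted sums
are evaluated as explicit year-indexed sums (vectorized), matching a
year-by-year loop to 1e-12 relative; the annuitization inverts the same
kernel, so the discounted annuity payments recover the principal to 1e-9.
Degenerate inputs are defined rather than special-cased: zero discount
rates reduce to straight-line/undiscounted sums, zero-SD or collapsed-range
distributions make the Monte Carlo reproduce the deterministic base case
exactly. Default simulation sizes — 10,000 PSA draws, 200 trial replicates
for the DID-recovery check, 100,000 draws for moment-recovery checks — keep
every stage well under a minute on one CPU while leaving Monte Carlo error
far inside the assertion tolerances.

## Known limitations

- Benefits from improved diets, micronutrient intake and women's
  empowerment are deliberately unvalued, mirroring the evaluation's scope;
  the package therefore understates total benefits in the same way.
- The lives-saved model linking stunting reduction to mortality is treated
  as a black box; deaths averted are an input.
- The DALY convention and the tornado bounds for the two normal parameters
  are inferred, not published.
- No currency conversion or inflation adjustment beyond the modeled growth
  rates; ledgers are assumed to be in 2016 USD.
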