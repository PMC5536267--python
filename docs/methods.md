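# Methods

## The instrument and its data

The Effort Discounting Questionnaire (EDQ) is a fixed-choice titration
procedure.  One page per condition opposes a constant effortful payoff
(amount `A` in PLN, delivered after a fixed 30-minute delay during which the
effort is exerted) to 30 effortless alternatives descending from `A` to 0.
The canonical ladder is the printed PLN 80 list (80, 79, 77, 74, …, 2, 1, 0);
ladders for other amounts reuse its percentage profile scaled to `A` and
rounded half-up to integer PLN, preserving the 100%→0% span and 30 rows.
The design crosses 2 effort domains x 3 amounts (80, 400, 3000) x 5 effort
intensities (30–150 units), 30 conditions, plus optional zero-effort
(delay-only) pages.

The indifference point (IP) of a page is the last effortless amount chosen
before the switch to the effortful option; choosing the effortful option in
the top row records IP = `A` (no discounting), never switching records
IP = 0 (full discounting).  A rational agent with valuation `V` that prefers
the effortless amount whenever it is at least `V` therefore produces
IP = the smallest ladder value ≥ `V`: the instrument reads valuations on a
ceiling-quantized grid, to within one local rung gap.  Zero-effort pages
measure the delay-only ("first") indifference point and are excluded from
every analysis.

## Fitting

Seven subjective-value functions (see README) are estimated by nonlinear
least squares *jointly across reward magnitudes*: the residual vector stacks
the three 5-point magnitude blocks, each with its own `l` (and `s`).  This
block-structured joint estimation is algebraically identical to
dummy-variable coding of magnitude-specific parameters; because the
objective separates over blocks, an independent per-magnitude fit is used as
a decomposition oracle in the tests (joint SSe = sum of block SSe to 1e-8
relative).

Goodness of fit is the pooled R² = 1 − SSe/SST with SST about the grand mean
of all 15 points.  When the grand mean explains more variance than the model
(R² < 0, or SST = 0), R² is recorded as 0, the fit is flagged *clamped* and
the parameters are set to missing.  Note that the pooled convention makes
R² generous for multi-magnitude data — most of SST is between-magnitude
variance — so R² near 1 is typical and model discrimination rests on SSe
ratios via the information criteria.

Numerical choices:

* bounds `l ∈ [0, 1e3]` (the ceiling is numerical: every model is saturated
  at the smallest design effort long before `l` reaches it), `s ∈ (0, 10]`
  for the exponent models, and `s ∈ [−4A, A)` for the two-parameter
  exponential.  The lower asymptote floor is numerical: along
  `s → −∞, l → 0` the family degenerates into a straight line of finite
  slope `(A−s)l`, an infinite ridge that otherwise stalls the optimiser;
  asymptotes below −4A have no behavioural reading and near-linear fits
  remain attainable.
* multi-start over a fixed grid: `l ∈ {1e-6 … 1}` (log-spaced),
  `s ∈ {0.25, 0.5, 1, 2, 4}` (exponent models; the grid contains each
  nested special case) or `s/A ∈ {−0.5, 0, 0.5}` (exp2), plus one
  data-driven start (per-magnitude grid point with lowest block SSe).  All
  grid starts are scored by initial SSe; the best eight are polished with
  `scipy.optimize.least_squares` (trf, analytic Jacobians, `x_scale='jac'`,
  tolerances 1e-10, ≤ 500 evaluations per start; low-dimensional
  single-magnitude fits polish every start).  The incumbent is then
  re-polished (trust-region restart) until the SSe stops improving, which
  finishes ridge solutions such as cliff-shaped data pushing an exponent to
  its bound.  Everything is deterministic: no randomness enters the fit.
* ties and degenerate inputs: negative predictions of the parabolic and
  power models are retained, never clamped (an effort cost may exceed the
  reward's worth); a perfect fit (SSe = 0) propagates a −∞ criterion
  sentinel with a warning; non-convergence yields R² = 0 with a flag.

## Model selection

`AIC = n ln(SSe/n) + 2p`, `AICc = AIC + 2p(p+1)/(n−p−1)`,
`BIC = n ln(SSe/n) + ln(n)p`, with `n = 15` indifference points per subject
x domain and `p` the regression parameters only (3 or 6; an error-variance
term would shift equal-complexity models equally and cancel in deltas).
Deltas subtract the best (lowest) model.  Group-level selection is run both
on the fit to median IPs and on criterion values summed across subjects
(fixed-effects aggregation); subjects with any clamped, non-converged or
non-finite criterion are excluded listwise from sums and frequency counts
(logged).  Best-model counts credit every model tied at a subject's
minimum; ties are logged so the no-credit variant is recomputable.

## Nonparametric suite

Friedman's test uses mid-ranks and the tie-corrected statistic (a fully
tied matrix carries no ordering information and returns χ² = 0).  Wilcoxon's
signed-rank test drops zero differences, mid-ranks the absolute values, and
uses the tie-corrected normal approximation without continuity correction;
the sign convention is Z > 0 when the first sample tends to exceed the
second, and the matched-pairs effect size is r = |Z|/√(2·n_pairs) — the
convention consistent with r ≈ .30 at Z = 4.56 for 114 pairs.  Šidák's
adjustment 1 − (1−p)^m is computed via `expm1/log1p` so tiny p survive, and
never falls below the raw p.  Counts of R² = 0 (clamped) cases are compared
with Cochran's Q and continuity-corrected McNemar tests,
χ² = (|b−c|−1)²/(b+c), on the discordant counts.  Spearman's ρ uses
mid-ranks.  Friedman/Wilcoxon/Spearman are delegated to scipy and Cochran's
Q to statsmodels; the test suite checks each against the closed-form hand
formula on small matrices.

## The synthetic cohort

The generator emulates the statistical structure the analysis is designed to
detect, with the power function as the default generating model:

* **Parameters.**  Per domain and magnitude, `l` and `s` are log-normal
  (positively skewed).  Medians: `s = (1.2, 1.8, 2.8)` for PLN
  (80, 400, 3000) — curvature rising with amount — and `l` chosen so the
  median agent devalues by 40%/25%/12% of `A` at the highest effort
  (`l ≈ 7.8e-2, 1.21e-2, 2.9e-4`).  A single marginal-median agent taken
  from fitted-parameter tables would be inconsistent (fitted `l` and `s`
  trade off almost deterministically), so the defaults are anchored on the
  observable devaluation depth instead.  Log-sds 0.55 (`l`) and 0.08 (`s`)
  give a devaluation-depth log-sd ≈ 0.68: most agents discount gradually,
  a few per cent are non-discounters or full (floor) discounters.  Because
  `s` multiplies `ln E ≈ 5` in the depth exponent, even modest `s` spread
  explodes depth heterogeneity; the small `s` sd is what keeps response
  patterns non-degenerate.
* **Structure.**  Within an agent, one shared multiplier per parameter and
  domain scales the ordered medians, so `l` strictly decreases and `s`
  strictly increases with amount for *every* agent (the magnitude effect is
  built in, not just on average).  Cross-domain dependence comes from a
  shared standard-normal latent mixed with weight √ρ (defaults ρ_l = 0.5,
  ρ_s = 0.45), giving positive physical–cognitive parameter correlations.
* **Choices.**  Each condition gets a single valuation draw
  `V = SV + ε`, `ε ~ N(0, (0.03A)²)` by default, truncated to the ladder's
  range [0, A]; the agent chooses effortless on every row offering ≥ V.
  One draw per page (not per row) guarantees the single-switch pattern the
  EDQ stop-rule enforces behaviourally.  Zero-effort pages get V = A.

What the generator does *not* emulate: within-page preference reversals,
response perseveration or lapses, order effects (page order is permuted but
behaviourally inert), agents whose true functional form differs from the
configured model, and negative valuations expressed as losses (the ladder
cannot record them; truncation at 0 censors steep discounters).  Passing
tests therefore show that the pipeline is internally consistent and that
the analysis detects structure the generator encodes — not that real
cohorts follow a power law.

## Identifiability limits (what the tests mean)

* **Quantization.**  Even noiseless choices pin parameters down only to the
  ladder resolution.  The recovery experiment fits 50 noiseless agents and
  compares each relative error with a per-agent brute-force bound: the true
  subjective values are shifted by ± half the local rung gap (clipped to
  [0, A] like the data), refitted, and the largest parameter deviation
  taken as the bound.  Where discounting is shallow relative to the rung
  size (notably `l` at PLN 3000), both the error and the bound are large —
  the instrument, not the optimiser, is the limit.
* **Power vs Rachlin.**  For shallow devaluation `A/(1+x) ≈ A(1−x)`, so
  Rachlin's hyperboloid reproduces power-function data almost exactly over
  five effort levels; floor-censored agents (valuations truncated at 0)
  produce large per-agent criterion margins of either sign.  At the default
  noise (σ = 0.03A) the expected per-subject AICc margin in favour of the
  generating power model is ≈ +1–2 with an sd ≈ 11, so the 114-subject
  summed-criterion winner is power in most cohorts but not all: across six
  generator seeds the power function took summed ΔAICc = ΔBIC = 0 in both
  domains four times (margins +67 to +328 over Rachlin) and lost one domain
  twice (−64, −199).  The generative-selection test and README example use
  the canonical seed 1.  Margins over all non-Rachlin models exceed +15
  AICc per subject and are seed-robust.  For the same reason the
  per-subject best-model frequency ranking under BIC (power vs parabola) is
  sampling noise under default conditions and is reported in
  `selection_summary.json` rather than asserted.

## Problem sizes

Default experiments: 114-agent cohorts for the selection and
magnitude-effect analyses (the canonical cohort size), 50 agents for
noiseless recovery, 20 random datasets x 7 models for the decomposition
oracle.  These sizes make the full test suite and the acceptance script run
in minutes on a single core while keeping the statistical checks sharp.
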