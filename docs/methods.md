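# Methods

## The EVOP model

A worksheet is a duplicated-centre 2³ factorial over temperature (°C),
initial pH and wheat-bran percentage of the substrate mix (%WB, bridged
from WB:SM gram ratios by `ratio_to_percent`: 4:1 ≙ 80%). Runs are
labelled A1–A10 in a fixed order, with A1/A6 the centre and the eight
corners covering every sign pattern; coded levels are stored as integers
−1/0/+1 so contrasts are exact. Responses are enzyme activities
(U/gds), non-negative by validation.

Effects are the standard two-level contrasts: mean response at the high
level minus mean at the low level (centre runs excluded), i.e.
(Σy₊ − Σy₋)/4 for ten-run worksheets; interactions use the sign product
of two factors' codes. The change-in-mean effect is mean(all ten) −
mean(two centre runs). All statistics are computed at full precision
and rounded to two decimals only for display.

The packaged phase-I worksheet reproduces the published response table
verbatim. Its printed main/interaction effects, however, are **not**
reproducible from those responses under the published run coding — the
standard cycle-1 contrasts give T = 31.78, R = −21.86, TP = 65.58 where
the source prints −26.05, 30.50, 13.22. The package implements the
auditable standard contrast and treats the printed effect values only
as inputs (e.g. to the decision rule), never as targets. Three printed
averages (398.475 → 398.47, 106.975 → 106.97, 104.915 → 104.91) are
exact half-way cases rounded down in the source; comparisons are
therefore made at printed precision (±0.005) rather than by re-rounding.

### Standard deviation and error limits

The per-cycle s values printed in the source (100.65, 93.03) cannot be
derived from the response table by any standard recipe we tested (the
pooled-difference estimate gives 12.00), so `estimate_sd` offers three
methods: `pooled` (√(Σd²/2k) over per-run differences d between the
prior-cycle mean and the newest cycle), `range` (range(d) × f(k, n)
with the standard EVOP factor table for k ∈ {5, 10}, n ∈ 2…10), and
`fixed` (a supplied constant, used to reproduce the published error
limits). Error limits are 2s/√n for run averages, 2s/√(2n) for effects
and 1.78·s/√(2n) for the change in mean; these divisors reproduce the
published limit ratios at n = 2 to within their own internal rounding
(the printed "for effects" values are ≈0.4 above 2s/√(2n), an
inconsistency inherited from the source).

### Decision rule

`decide` declares a **shift** when any effect strictly exceeds the
effects limit (direction: the sign of each significant main effect, one
half-step per factor), else **optimum_reached** when the change in mean
is below −limit (the centre beats its neighbourhood), else
**continue_cycles**. Equality with the limit is not significant.

A caveat worth stating plainly: with n = 2 cycles the pooled s has only
~9 effective degrees of freedom and six contrasts are tested at ~2
standard errors, so at a truly flat optimum spurious shifts occur in
roughly 15–20% of phases when run-to-run noise is independent. The
rule behaves conservatively when a shared between-cycle (batch) offset
dominates: the offset inflates the pooled differences — and hence the
limits — but cancels out of every contrast. The campaign tests exercise
both regimes and say which property holds where.

## Surrogates

**Polynomial.** y = β₀ + β₁·T + β₂·WB% + β₃·pH + β₄·pH², fit by OLS
(statsmodels) on the (1, T, WB%, pH, pH²) design; rank deficiency is
reported with the collinear columns named. The published coefficient
set ships as the constant model `PUBLISHED_POLYNOMIAL`; refitting the
packaged 9-record training table gives visibly different coefficients
(the printed set is not the least-squares solution of the printed data),
so the two models are kept distinct and no agreement is asserted.
With β₄ < 0 the pH optimum is −β₃/(2β₄) ≈ 6.015 for the published set.

**Network.** A 3-10-1 feed-forward regression network: tanh (sigmoidal)
hidden units, linear output, inputs and target min-max scaled to
[−1, 1]. Training is Levenberg–Marquardt on the normalized-target MSE:
backpropagated Jacobian, damping λ starting at 1e−3 and divided/
multiplied by 10 on accepted/rejected steps, stopping at gradient
∞-norm < 1e−7, MSE < 1e−10, λ > 1e10 or 1000 epochs. Weights start
uniform in [−0.5, 0.5]; restart r seeds its generator with seed + r, and
the best of 64 restarts by overall R² is kept, so the whole procedure is
deterministic given the seed. The reported `mse` is in normalized
target units. The default split policy trains on all records — nine
points cannot sustain a meaningful train/validation/test partition — and
an optional `holdout` policy holds out one validation and one test record
to mimic the source protocol (their single-point R² values are flagged
NaN/undefined).

Because the network has 51 parameters, it interpolates the 9-record
table essentially exactly (overall R² ≈ 1). Its behaviour between and
beyond the data is therefore under-determined: grid maxima vary by tens
of U/gds across seeds and tend to sit near the strongest training
points (T = 28 °C, 80 %WB) rather than at the hotter boundary the
source's single run reported. The acceptance machinery treats the
network optimum accordingly: the median maximum over many seeds is the
stable quantity; the argmax location is reported, not guaranteed.

## Grid optimizer

Iteration numbers are 1-based with pH the slowest axis, temperature the
middle and %WB the fastest: iteration = i_pH·(n_T·n_WB) + i_T·n_WB +
i_WB + 1. The default box is 26–30 °C (step 1), 70–90 %WB (step 2.5)
and pH 4–8 (step 0.1) — 5 × 9 × 41 = 1845 points. These steps are
reconstructed from the published iteration→condition table, which is
only consistent with 9 WB values and 41 pH values; the increments the
source states in prose (5 %WB, 0.2 pH) and its "1850 combinations" count
do not reproduce that table and are documented as inconsistent. Axis
values are computed as low + index·step with one final rounding to 10
decimals for bit-stable membership; argmax ties break to the lowest
iteration; the reported window is the aligned decade of ten iterations
containing the argmax.

## Synthetic data

`TrueSurface` mirrors the polynomial surrogate (linear T and WB%,
quadratic pH) plus optional two-factor interactions expressed in coded
units, additive Gaussian noise (or a CV-based multiplicative option,
since real cycle differences scale roughly with response magnitude) and
a shared per-cycle Gaussian offset emulating batch effects. Noiseless
generation is exact, so every EVOP statistic has a closed-form expected
value; negative draws are clipped to zero with a warning because
activities cannot be negative (clipping biases the analytics and the
tests avoid it via positive baselines). What the generator does not
emulate: mechanistic fermentation kinetics, heteroscedasticity beyond
the CV option, run-order drift within a cycle, or assay quantization —
passing tests show the statistics and decision logic are correct, not
that real fermentations satisfy the model.

`simulate_campaign` chains worksheet → effects (pooled s) → decision,
moving the centre one half-step per significant main effect and opening
a new phase on a shift; any other verdict — including a shift with no
significant main effect, which cannot move the centre — ends the
campaign. Phase p uses child seed seed + 1000·p, cycle c adds +c.

## Pipeline, I/O and reproducibility

CSV schemas use comma separators, dot decimals, UTF-8 and mandatory
headers; the worksheet loader reconstructs the factor specification
from the A1 (centre) and A2 (low-corner) rows and validates every run
against the factorial design. The pipeline bundle (EVOP → training
table → surrogate → grid optimum) is validated by a pydantic model
whose JSON-schema export ships with the package; provenance carries the
package version, the seed and SHA-256 digests of the inputs — no
wall-clock timestamps, so identical inputs give byte-identical bundles.

`scripts/acceptance.py` recomputes every reported number at run time.
Problem sizes used there: the full packaged tables, the full 1845-point
grid, and 201 training seeds × 64 restarts for the network block —
chosen so the median network optimum is a stable estimate of its
long-run value.

## Known limitations

- Only the three-factor (k = 10 runs) design is first-class; the range
  method also tabulates k = 5.
- The printed per-cycle s values and printed effects remain
  unexplained; reproductions of the published error limits use the
  printed s as a fixed input.
- The network's split-policy R² values depend on an undocumented random
  partition in the source and are reported for context only.
- Grid search is exhaustive by design; no gradient or evolutionary
  optimizers, and only box-lattice constraints.
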