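# evopt

Evolutionary-operation (EVOP) factorial screening statistics and
surrogate-based grid optimization for fermentation media, built around a
solid-state-fermentation alkaline-protease case study: incubation
temperature, initial pH and the wheat-bran share of a wheat-bran +
soybean-meal substrate are screened around a working optimum, and the
resulting response table feeds two surrogates — a polynomial response
surface and a small feed-forward neural network — that are optimized
exhaustively over a constrained condition lattice.

The package is aimed at bioprocess engineers who want the whole loop —
design, decision rule, surrogate, optimum — as tested, reproducible code
rather than spreadsheet arithmetic.

## The methods

**EVOP worksheet.** One phase perturbs the current operating centre
along a duplicated-centre 2³ factorial: runs A1/A6 at the centre, A2–A10
at the corners, the whole set replicated in cycles. For a response
vector *y* the main effect of a factor is the mean at its high level
minus the mean at its low level,

    effect = ( Σ y₊ − Σ y₋ ) / 4,

interactions use the sign product of two factors, and the change-in-mean
effect mean(all 10) − mean(centre) measures whether the centre beats its
neighbourhood. Effects are compared with error limits built from a
standard-deviation estimate *s*:

    for averages        2·s/√n
    for effects         2·s/√(2n)
    for change in mean  1.78·s/√(2n)

Any effect beyond its limit ⇒ shift the centre one half-step along each
significant main effect; otherwise a strongly negative change-in-mean ⇒
the optimum is reached; otherwise run more cycles.

**Surrogates.** A quadratic-in-pH polynomial
y = β₀ + β₁·T + β₂·WB% + β₃·pH + β₄·pH² (ordinary least squares, plus
the published coefficient set as a named constant model), and a 3-10-1
network (tanh hidden layer, linear output, inputs and target min-max
scaled to [−1, 1]) trained by Levenberg–Marquardt with 64 random
restarts, keeping the restart with the best overall R².

**Grid optimizer.** Candidates form a lattice (26–30 °C by 1,
70–90 %WB by 2.5, pH 4–8 by 0.1; 1845 points) enumerated with 1-based
iteration numbers, pH slowest and %WB fastest; the surrogate is
evaluated everywhere and the argmax reported with the aligned
10-iteration window around it.

**Synthetic data.** `evopt.synthetic` generates surfaces, noisy
worksheets and multi-phase campaigns with known ground truth, so every
stage is testable against closed-form values.

## Worked example

```python
>>> from evopt import build_report, decide, error_limits, optimize, PUBLISHED_POLYNOMIAL
>>> from evopt.io import load_table4
>>> ws = load_table4()                      # packaged phase-I worksheet
>>> rep = build_report(ws, responses=ws.responses()[0], sd_method="fixed", sd=100.65)
>>> round(rep.change_in_mean, 2)
-231.95
>>> lim = error_limits(rep.s, ws.n_cycles)
>>> round(lim.for_effects, 2)
100.65
>>> decide(rep, lim).verdict
'optimum_reached'
>>> res = optimize(PUBLISHED_POLYNOMIAL)        # exhaustive search, 1845 points
>>> (res.argmax.temperature_C, res.argmax.wb_percent, res.argmax.pH,
...  round(res.argmax.predicted, 2))
(30.0, 70.0, 6.0, 419.96)
```

The change-in-mean is far below its limit while no effect exceeds
±100.65, so the decision rule declares the centre (28 °C, pH 6, 80 %WB)
optimal — its best observed run is 412.79 U/gds. The polynomial
surrogate then predicts a slightly better operating point on the hotter,
bran-leaner boundary of the box at near-neutral pH.

The same chain is available from the shell:

```bash
evop analyze --worksheet table4.csv --sd-method fixed --sd 100.65 --out report.json
surrogate fit --data table2.csv --model mfnn --seed 1 --restarts 64 --out model.json
surrogate optimize --model model.json --out result.csv
pipeline run --model published_polynomial --out bundle.json
```

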