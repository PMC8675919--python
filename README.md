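# odorddm

Drift-diffusion analysis of olfactory figure–background segregation:
why do mice make *faster* decisions on *harder* trials?

When a target odorant is embedded in a random background mixture,
detection performance drops as the number of background odorants grows.
This package analyzes that interference through the drift-diffusion
model (DDM) of two-alternative decisions and is aimed at researchers in
decision neuroscience / psychophysics who want to (i) derive the
closed-form predictions of competing interference mechanisms, (ii)
simulate the head-fixed mouse odor-detection task end to end, and
(iii) fit per-condition drift and diffusion to trial-level choice/RT
data with the chi-square quantile method.

## The model

A decision variable `x` accumulates evidence, `dx/dt = A + ξ`, with
drift `A`, white noise of variance `c²` per unit time, start point
`mθ` (`m ∈ (−1, 1)`), and absorbing bounds `±θ` ("report present" /
"report absent").  With `r = 2Aθ/c²`,

- choice probability  `p = [exp(r) − exp(−rm)] / [2 sinh(r)]`,
- mean decision time  `E[DT] = θ[cosh(r) − m·sinh(r) − exp(−rm)] / [A·sinh(r)]`,
- `∂p/∂A > 0`, `sign(∂p/∂c²) = −sign(A)`, and `∂E[DT]/∂c² < 0`
  everywhere (all three carry the strictly positive factor
  `g(r) = exp(−rm)[cosh(r) + m·sinh(r)] − 1`).

Three interference mechanisms map background count `#BG` onto the
parameters: **false signal** (`A_i = A_i0 + k·#BG`), **signal
reduction** (`A_i = A_i0 − k·#BG`), and **noise boost**
(`c² = c0² + k·#BG`).  Their predictions differ qualitatively and are
parameter-free: false signal raises the report-present probability on
both trial types, signal reduction lowers it on both, and only the
noise boost contracts choices toward chance `(1+m)/2` *while speeding
decisions up* — the paradoxical speed–accuracy signature.

Fitting uses the chi-square quantile method: per condition, correct
and error RTs are split into 6 bins at the 0.1/0.3/0.5/0.7/0.9
quantiles (12 summary statistics × 18 conditions = 216), expected
frequencies come from the theoretical defective first-passage CDF plus
a 5% uniform outlier component, and `Σ(O−E)²/E` is minimized over 38
parameters per mouse (a threshold/drift pair per condition plus one
shared start fraction and non-decision time).  Fitted values are
rescaled to the `θ' = 1` (`θ = 1/2`) gauge: `A = A_fit/θ_fit`,
`c² = 1/θ_fit²`, `m = 2m' − 1`.

## Worked example

```python
import numpy as np
from odorddm import (
    TaskConfig, generate_mouse_dataset, filter_sessions,
    normalize_reaction_times, QuantileDDMFitter,
    parameter_recovery_report,
)

cfg = TaskConfig(n_sessions=12, seed=3)          # ~3000 trials
trials = generate_mouse_dataset(cfg)
kept, summary = filter_sessions(trials)          # b >= 0.5, accuracy >= 70%
kept = normalize_reaction_times(kept)

fitter = QuantileDDMFitter(seed=0).fit(kept)     # 38-parameter fit
report = parameter_recovery_report(cfg.ground_truth, fitter.result_)
print(report[["parameter", "correlation", "estimate_trend_slope"]].to_string(index=False))
```

prints (numbers from this exact run):

```
    parameter  correlation  estimate_trend_slope
        drift     0.979256             -0.073240
diffusion_var     0.914869              0.096356
```

i.e. on data generated under the combined mechanism (drift magnitude
falling by 0.06 and diffusion variance rising by 0.15 per background
odorant), the fit recovers per-condition drifts correlated 0.98 with
the generating values, a negative background trend in |drift| and a
positive one in diffusion — the study's headline pattern.  With the
full-size generator defaults (65 sessions, ~900 trials/condition) the
recovery is correspondingly tighter.

A shell pipeline wraps the same steps:

```sh
odorddm generate --seed 1 -o run/
odorddm preprocess run/trials.tsv -o run/
odorddm fit run/trials_preprocessed.tsv -o run/
odorddm predict run/trials_preprocessed.tsv run/fit_m1.json -o run/
odorddm evaluate run/trials_preprocessed.tsv run/fit_m1.json -o run/
```

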