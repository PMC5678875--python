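# fanova-activity

Functional data analysis of children's daily physical-activity profiles
from accelerometer counts: quasi-likelihood B-spline smoothing with
GCV-selected dimension, weighted functional ANOVA over categorical
covariates, permutation functional F tests, bootstrap confidence bands,
and time-window-averaged coefficients — plus a synthetic cohort generator
with known ground truth so every stage can be validated by parameter
recovery.

## The problem

Hip-worn accelerometers record activity *counts* in 15-second epochs over
a child's waking day. Summing them to a single daily total discards when
in the day children are active. Treating each day as a smooth function of
clock time instead lets activity differences between groups (sex, season,
travel mode to school, …) be localised in time: a deficit confined to the
lunch break is invisible in a daily total but obvious in a contrast
function.

## The model

Counts for child *i* are aggregated to one-minute epochs on the common
window 08:30–19:30 (exactly 660 minutes, after wear-time QC and sampling
one day per child). Each profile is represented in an order-4 B-spline
basis,

    y_i(t) = φ(t)ᵀ c_i ,

with `c_i` estimated by a quasi-likelihood GLM — identity link, variance
linear in the mean — which accommodates the strong overdispersion of
count data without a full distributional assumption. The basis dimension
*k* minimises the generalised cross-validation score
`GCV = n · Σ (y−μ̂)²/μ̂ / (n−k)²` averaged over children.

The smoothed profiles then enter the functional ANOVA

    y_{i,g}(t) = α₀(t) + α_g(t) + ε_{i,g}(t) ,

where `α₀(t)` is the reference-category profile and `α_g(t)` the
time-specific contrast of level *g*, extended additively to several
covariates and estimated by inverse-probability-weighted least squares on
the basis coefficients. Significance comes from a permutation functional
F test (max-over-time F statistic); uncertainty from pointwise percentile
bootstrap bands over children; and a contrast can be summarised over a
clock window (e.g. 12:00–13:30) by its length-normalised integral
`ᾱ_g`, in counts/min.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

```python
import numpy as np
from fanova_activity import (
    SimulationConfig, simulate_minute_profiles, smooth_dataset,
    DesignSpec, build_design, fit_fanova, bootstrap_ci, window_average,
)

config = SimulationConfig(n_children=400)      # defaults: phi=5, IPW weights,
Y, cov, truth = simulate_minute_profiles(config, seed=1)  # known effects

smoothed = smooth_dataset(Y, k=39, child_ids=cov["child_id"].tolist())
print(f"Pearson dispersion {smoothed.dispersions.mean():.2f}")

spec = DesignSpec.from_refs({"sex": "Male", "transport": "Active"})
boot = bootstrap_ci(smoothed, cov, spec, n_bootstrap=199, seed=2,
                    weights=cov["weight"].to_numpy())
est, lo, hi = boot.window_ci("sex=Female", (720, 810))   # 12:00-13:30
print(f"sex contrast over lunch: {est:.1f} (95% CI {lo:.1f}; {hi:.1f})")
```

prints

```
Pearson dispersion 4.98
sex contrast over lunch: -70.1 (95% CI -71.1; -69.1)
```

The dispersion recovers the generator's variance-to-mean ratio of 5, and
the lunch-window contrast recovers the ground-truth −70 counts/min
deficit for girls within its confidence interval.

## The analysis scripts

`analysis/01_simulate.py` … `05_report.py` run the full study on a
300-child synthetic cohort through the file-based path: epoch generation,
QC filtering (≥ 600 worn minutes in 07:00–22:00, complete 660-minute
common window), GCV smoothing, FANOVA inference, and a final comparison
of every recovered contrast-window summary against its analytic truth.
Summary tables land in `results/`, bulky intermediates in `scratch/`.
The same pipeline is scriptable from one JSON config via the console
entry point, e.g. `fanova-activity run --config run.json`.

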