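# perturbwalk

Margin-of-stability analysis of treadmill belt-acceleration perturbations
during walking, for researchers studying reactive balance and falls risk in
older adults.

Falls in older adults most often happen when a slip or trip suddenly changes
the relationship between the body's centre of mass and its base of support
during walking.  A treadmill protocol probes this directly: participants
walk at a speed normalized to their individual stability, and the belt under
one foot is accelerated without warning; how far stability is displaced and
how quickly — and whether responses improve over repeated perturbations —
are candidate markers of falls risk.  `perturbwalk` implements the full
analysis pipeline for such experiments, together with a synthetic gait
generator that provides exact ground truth for every stage.

## The model

Dynamic stability is quantified with the **margin of stability (MoS)** of
the extrapolated centre of mass (Hof's inverted-pendulum construct).  With
CoM anteroposterior position `x`, belt-relative velocity `v`, pendulum
length `l` and `ω₀ = √(g/l)`:

```
XCoM(t) = x(t) + v(t) / ω₀
MoS     = x_BoS − XCoM          (at foot touchdown)
```

where the anterior boundary of the base of support `x_BoS` is the leading
hallux marker.  The CoM is proxied from a reduced six-marker set (C7,
sacrum, both trochanters, both halluces) as a weighted mean of sacrum,
mid-trochanter and C7.  Positive MoS means the extrapolated CoM is behind
the anterior boundary — a mechanically recoverable configuration.

On top of this the package provides:

* **Stability-normalized walking speed** — fit mean MoS (final 10 steps)
  against trial speed over 0.4–1.8 m/s and solve for the speed giving
  MoS = 0.05 m, so that all participants are perturbed at equivalent
  baseline stability.
* **Perturbation analysis** — belt profiles (3 m/s² ramp to 180% of
  baseline speed, triggered when the perturbed-side hallux passes the
  contralateral one, released at toe-off), Base/Pre/Post1–8 step labeling,
  and recovery-step counts (steps until MoS returns within 0.05 m of the
  pre-perturbation baseline, scanned backward from the eighth recovery
  step).
* **Spatiotemporal gait variability** — step length, width, time and double
  support time with means and coefficients of variation.
* **Group statistics** — mixed two-way repeated-measures ANOVA
  (group × step), Mann-Whitney U, Friedman, Wilcoxon signed-rank, Dunnett
  and Sidak multiple comparisons, and effect-size / sample-size utilities,
  with exact small-sample null distributions where tied integer data make
  the usual approximations invalid.

## Worked example

Solve a synthetic participant's stability-normalized walking speed from
eight unperturbed trials:

```python
import numpy as np
from perturbwalk import (GaitModelParams, StabilitySpeedModel,
                         compute_mos_series, generate_unperturbed_trial,
                         mean_mos_final_steps)

params = GaitModelParams(seed=11)
speeds = np.arange(0.4, 1.81, 0.2)
means = []
for v in speeds:
    trial = generate_unperturbed_trial(params, float(v), 40.0)
    mos = compute_mos_series(trial.markers, forces=trial.forces.as_dict())
    means.append(mean_mos_final_steps(mos, 10))
results = StabilitySpeedModel(speeds, means, target_mos=0.05).fit()
print(results.summary())
```

prints

```
Stability-normalized walking speed
----------------------------------
fit: quadratic over 0.40-1.80 m/s (8 speeds)
coefficients (highest power first): +0.01706, -0.15660, +0.23059
target MoS: 0.050 m
normalized speed: 1.35 m/s
max |residual|: 0.0024 m
```

Mean MoS falls with speed (the fitted quadratic), and this participant
reaches the 0.05 m target at 1.35 m/s — the speed at which their
perturbation trials would be run.  Perturbation sessions are generated with
`generate_perturbation_session`, labeled with `label_all`, and cohorts are
compared with `PerturbationStudy(mos_long, recovery).fit().summary()`.

A thin CLI mirrors the library: `perturbwalk simulate`, `perturbwalk
stability`, `perturbwalk perturb`.

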