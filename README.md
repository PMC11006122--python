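# seirb

Practical identifiability of behavioral epidemic models, studied by
simulation: when, and from which data, can the parameters of an SEIR model
with endogenous societal risk response be recovered?

## The problem

Epidemic models that feed observed mortality back into behavior — deaths
raise perceived risk, perceived risk lowers contact rates, lower contacts
suppress transmission — reproduce the multi-wave trajectories seen in real
outbreaks with a single fixed parameterization. But the balancing feedback
only expresses itself in data *after* the first wave has crested, which
raises a practical question for anyone calibrating such a model in the
early days of an outbreak: are the behavioral parameters estimable at all
from what has been observed so far, and what does getting them wrong cost
in forecast accuracy?

This package answers that question experimentally. It provides:

* **`model_core`** — the SEIRb model: classical SEIR flows plus a
  risk-response feedback and multiplicative autocorrelated (pink) noise on
  the exposure rate,

  $$\dot S = -\beta_0\, c(p)\, \varepsilon(t)\, S I / N, \qquad
    c(p) = \frac{1}{1 + \alpha p},$$

  where $p$ is perceived risk — recorded daily deaths per million smoothed
  with time constant $\lambda_p$ (the *time to perceive risk*) — and
  $\alpha$ is the *sensitivity to risk*. $\varepsilon(t)$ is exponentially
  smoothed Gaussian white noise (mean 1, sd 0.3, correlation time 15 d).
  Setting $\alpha = 0$ recovers plain SEIR. Exposed persons become
  infectious after a 4-day incubation, leave the infectious state after
  10 days, and a fraction `ifr` of them die, recorded after a further
  10-day delay.
* **`synthetic_data`** — a replicated stochastic ground-truth corpus
  (by default 100 noise seeds over 730 days) and windowed views of the two
  observable channels: daily deaths and the contact-rate multiplier.
* **`calibration`** — scale-free least-squares estimation of the masked
  parameters ($\beta_0$; $\alpha$, $\lambda_p$) from an observation
  window, via seeded multi-start bounded least squares, plus 365-day-ahead
  death projection scored by cumulative daily MAPE.
* **`experiments`** — the 3×3 experiment grid: perfect model with deaths
  data (H1), behavior-blind SEIR with deaths data (H2), perfect model with
  deaths + contact data (H3), each calibrated on the first 60, 120, or 365
  days of every replicate; bias/variance summaries, paired Wilcoxon /
  Mann-Whitney stage comparisons, and projection-error changes normalized
  to the early-60-day baseline.
* **`sensitivity`** — robustness sweeps: perception delay 20–200 d,
  seasonality / waning immunity / variant emergence, extra masked disease
  parameters, and thinned contact-rate samples.
* **`cli_io`** — validated YAML configs, manifests, and a `seirb` command
  line (`generate`, `fit`, `run-design`, `sweep`, `run-all`).

## Worked example

Calibrate one stochastic replicate from a 60-day and a 365-day window and
score the 365-day-ahead death projection:

```python
from seirb import (ParameterSet, generate, window, DataWindow,
                   CalibrationSpec, fit, project, mape_cumulative)

truth = ParameterSet()          # beta0=0.25, alpha=2.0, lambda_p=60 d
corpus = generate(truth, n_reps=5, horizon=730, base_seed=0)

for length in (60, 365):
    obs = window(corpus, DataWindow(replicate_id=3, length=length,
                                    channels=("daily_deaths",)))
    result = fit(CalibrationSpec(), obs, truth)
    proj = project(result.estimates, CalibrationSpec(), truth,
                   t_start=length, horizon=365)
    actual = corpus.replicates[3].daily_deaths[length + 1:length + 366]
    est = {k: round(v, 3) for k, v in result.estimates.items()}
    print(f"{length:3d}-day window: {est}  projection MAPE="
          f"{mape_cumulative(proj, actual):.1f}%")
```

```
 60-day window: {'beta0': 0.251, 'alpha': 0.0, 'lambda_p': 365.0}  projection MAPE=2629.1%
365-day window: {'beta0': 0.268, 'alpha': 1.729, 'lambda_p': 66.479}  projection MAPE=94.6%
```

The 60-day fit reproduces the observed deaths essentially perfectly — yet
it does so with the feedback switched off ($\alpha \to 0$, $\lambda_p$ at
its bound): the pre-peak window contains almost no information about
behavior, so the projected epidemic is a single enormous wave and the
forecast error is ~26× larger than after one year of data. The infectivity
rate $\beta_0$, by contrast, is close to its true value 0.25 in both fits.
Individual replicates vary (noise occasionally favors a short window); the
distributional statements over many replicates are what the experiment
grid quantifies.

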