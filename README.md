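# affectrecall

Tools for studying **value-based decision-making between affective and
non-affective reward memories**: how a single large win or loss on a wheel
of fortune (WoF), experienced between reinforcement-learning blocks, biases
the way people later recall the reward probabilities of shapes learned
under that mood state.

The package encodes the two canonical experimental designs (a 14-shape lab
study with sided stimulus presentation and pupillometry, and a 24-shape
online study with randomised sides), generates synthetic multi-subject
datasets with the statistical structure the analyses assume, and implements
the full analysis chain:

* **Probability-weighting choice model.** Learned reward probabilities are
  recalled through the 2-parameter exponential-of-log weighting function

  $$w(p) = \exp\!\bigl(-\delta\,(-\ln p)^{\gamma}\bigr),
  \qquad \delta, \gamma > 0,$$

  with elevation δ and curvature γ (δ = γ = 1 is unbiased recall).  Choice
  between two shapes is a softmax on the difference of weighted
  probabilities with inverse temperature β.  One (δ, γ) pair is fitted per
  *screen side* in the sided design and per *WoF valence* (post-win /
  post-loss) in the randomised design, by bounded multi-restart maximum
  likelihood.
* **Benchmarks.** A random-choice model (per-trial log-likelihood
  ln 0.5 ≈ −0.69 by construction) and an identity-weighting model with a
  single β, compared to the full model by paired t-tests on per-trial NLL.
* **Bias indices.** The area under the weighting curve (AuC) of the win arm
  minus the loss arm (positive = positive memory bias), its model-free twin
  (count of high-probability post-win minus post-loss choices), a WoF-coded
  per-subject logistic contrast, and a covariate regression of the bias
  index on standardised depression scores, age, gender and WoF order.
* **Rescorla–Wagner learning** for the RL blocks (simulation, MLE fitting,
  accuracy summaries) and a mood-rating manipulation check.
* **Model-based pupillometry.** Blink interpolation → zero-phase 3.75 Hz
  Butterworth low-pass → session z-scoring → event-locked epochs with 2-s
  baselines and a strict >50 %-interpolated exclusion rule; a trial-wise
  GLM of the pre-choice pupil response on model-derived expected values and
  luminance controls; 3 × 4 valence-by-timebin rmANOVAs of the 4-s
  outcome window; and a sustained-dilation bias index correlated with the
  behavioural one.

## Worked example

Simulate a small online-style cohort and run the behavioural chain:

```python
from affectrecall import report

manifest = report.run_pipeline(
    {"study": "study2", "n_subjects": 8, "seed": 7, "n_restarts": 5},
    "demo_run")
print(open("demo_run/summary.txt").read())
```

```
config_hash: 8ef7a887edfa40cd
study: study2
n_subjects: 8
mean P(correct) final block: 0.752
mean delta AuC: +0.1156 (one-sample t p = 0.0086)
```

The cohort learns the task (75 % correct in the final blocks), and the
fitted weighting curves show a positive mean win-minus-loss AuC difference
of +0.116 — the signature of positive memory bias — significant even at
n = 8 because the default generator injects the effect.  The accompanying
`group_tests.json` records the model comparison: the full weighting model
beats the random-choice benchmark (paired t(7) = −8.37, p < 0.001 on
per-trial NLL; negative t means lower NLL, i.e. a better fit).

The same stages are available from the shell:

```bash
affectrecall all --config cfg.json --seed 7 --out demo_run
affectrecall simulate --study study1 --n-subjects 4 --with-pupil --out data/
```

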