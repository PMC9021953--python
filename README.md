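# igtpain

Computational cognitive modeling of Iowa Gambling Task (IGT) behavior in
chronic pain: task simulation, four reinforcement-learning choice models,
hierarchical Bayesian estimation with group contrasts, one-step-ahead
LOOIC model comparison, and linkage of cognitive parameters to Brief Pain
Inventory (BPI-SF) scores.

## The scientific problem

Standard IGT summaries (total gain, learning scores over five 20-trial
blocks) often fail to separate clinical groups, especially in noisy
web-collected data. Cognitive models decompose trial-by-trial choices
into interpretable parameters — learning rates, loss aversion,
perseverance — that can differ between groups even when behavioral
summaries do not. This package implements that full analysis pipeline
for two-cohort IGT studies and, because such studies rarely deposit raw
data, ships a synthetic-cohort generator that produces every input the
pipeline needs with known ground truth.

The models, for scaled net outcome x(t) of the chosen deck:

- **PVL-Delta / PVL-Decay** — prospect utility
  u(x) = x^α (x ≥ 0), −λ|x|^α (x < 0); expectancy updates
  E ← E + A·(u − E) (delta, chosen deck only) or E ← A·E plus u on the
  chosen deck (decay); softmax with sensitivity θ = 3^c − 1.
- **VPP** — PVL-Delta plus a perseverance trace P (decay k, gain/loss
  impacts ep_p / ep_n), values V = w·E + (1 − w)·P.
- **ORL** — expected value EV (rates A+ after gains, A− after losses),
  win frequency EF with a fictive update of unchosen decks toward
  −sgn(x)/3, perseverance PS with decay 1/(1 + K), K = 3^K′ − 1;
  values V = EV + β_F·EF + β_P·PS, unit-sensitivity softmax.

Each model is fitted per group with a hierarchical prior
(mu_p ~ N(0,1), sigma_p ~ HalfNormal(1), probit links onto each
parameter's range) by an adaptive Metropolis-within-Gibbs sampler with
interweaved non-centered moves (see `docs/methods.md`). Group
differences are read off the 95% highest-density interval (HDI) of the
draw-wise difference of group means; model fit is compared by
PSIS-LOO-based LOOIC over per-trial choices.

## Worked example

```python
import dataclasses, pandas as pd
import igtpain as ig
from igtpain.inference import MCMCConfig, fit_group, group_difference
from igtpain.pain import parameter_pain_report, score_bpisf

study = ig.generate_study(seed=7, n_trials=100)          # 25 healthy + 20 chronic pain
healthy = [s for s in study.sessions if s.group == "healthy"]
pain = [s for s in study.sessions if s.group == "chronic_pain"]

mcmc = MCMCConfig(chains=2, warmup=500, draws=400, thin=2, seed=11)
fit_h = fit_group(healthy, "orl", mcmc=mcmc)
fit_p = fit_group(pain, "orl", mcmc=dataclasses.replace(mcmc, seed=12))

for param in ("a_rew", "beta_p"):
    c = group_difference(fit_p, fit_h, param, mass=0.95, seed=0)
    print(param, c.mean_diff, c.interval, c.exceeds_zero)

means = pd.concat([fit_h.subject_posterior_means(), fit_p.subject_posterior_means()])
profiles = {sid: score_bpisf(r) for sid, (_, r) in study.responses.items()}
report = parameter_pain_report(means, profiles)
```

Output (seed 7):

```
subjects: 45  mean total gain: 2006 EUR
a_rew   pain-healthy diff +0.26 95% HDI [+0.17, +0.35] excludes 0: True
beta_p  pain-healthy diff -2.81 95% HDI [-3.81, -1.82] excludes 0: True
corr(A+, severity): r=0.62  p=0.0000  n=45
```

The symptomatic cohort was generated with a reward learning rate 0.30
above the healthy cohort and a perseverance weight 3.0 below it; the
fitted contrasts recover both directions with HDIs excluding zero. The
positive correlation between recovered A+ and BPI-SF severity reflects
the generator's built-in linear linkage of pain levels to the reward
learning rate.

There is also a CLI wrapping the same pipeline:

```sh
igtpain simulate --out-dir study --seed 3
igtpain fit --data-dir study --out-dir fits --sampler-seed 7 --chains 2 --warmup 500 --draws 400
igtpain compare --fit-dir fits --out-dir reports
igtpain report --data-dir study --fit-dir fits --out-dir reports
```

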