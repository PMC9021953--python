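# Methods

## The task environment

The Iowa Gambling Task (IGT) presents four decks. Every draw pays a
constant reward (A, B: €100; C, D: €50); within each 10-draw cycle from a
deck, a fixed number of draws additionally carries a loss (A, C: 5 of 10;
B, D: 1 of 10) with per-cycle totals of −€1250 (A, B) and −€250 (C, D).
Net outcome per complete cycle is therefore −€250 for the "bad" decks
A/B and +€250 for the "good" decks C/D. Sessions start from a €2000
endowment and end after 100 trials.

Two aspects of the schedule are not pinned down by the published payoff
table and are package design choices:

- **Loss placement.** The per-trial positions of losses inside a cycle
  are a uniformly random permutation, freshly drawn (seeded) for each
  cycle, with the cycle's loss total split equally across loss trials.
  This preserves the marginal per-cycle structure without asserting an
  unpublished fixed schedule.
- **Deck depletion.** Decks are inexhaustible; cycles repeat indefinitely.

Money is stored as exact euro amounts in trial records; the division by
`outcome_scale` (default 100) happens only when outcomes enter cognitive
models, keeping `x^alpha` and softmax arguments numerically tame. Trial
and block indices are 1-based throughout.

## The cognitive models

All four models turn the history of (chosen deck, net outcome x) pairs
into softmax choice probabilities over the four decks, starting from an
all-zero latent state (so the first choice is uniform at 1/4).

**PVL-Delta / PVL-Decay** share a prospect-theory utility
u(x) = x^α for x ≥ 0 and −λ·|x|^α for x < 0, with outcome sensitivity
α ∈ (0,1) and loss aversion λ ∈ (0,10). PVL-Delta updates only the
chosen deck's expectancy, E ← E + A·(u − E); PVL-Decay discounts every
deck by A and adds u to the chosen deck. Choice uses softmax sensitivity
θ = 3^c − 1 with consistency c ∈ [0,5], so θ ∈ [0,242].

**VPP** extends PVL-Delta with a perseverance trace P that decays by
k ∈ [0,1] each trial and is incremented on the chosen deck by a gain
impact (ep_p) after non-negative outcomes or a loss impact (ep_n) after
losses. Values mix as V = w·E + (1−w)·P. The upper bound of k is taken
as 1 (a decay proportion); the impacts are unbounded reals.

**ORL** tracks expected value EV (updated with rate A+ after gains, A−
after losses), a win-frequency signal EF (chosen deck moves toward
sgn(x); unchosen decks receive a fictive update toward −sgn(x)/3), and
an outcome-independent perseverance trace PS with PS_chosen = 1/(1+K),
PS_others ← PS/(1+K), K = 3^K′ − 1, K′ ∈ [0,5]. Values are
V = EV + β_F·EF + β_P·PS with unit softmax sensitivity.

Two ORL details are genuinely open in the sources available to us and
were fixed as follows:

- The fictive frequency update for unchosen decks uses the
  *opposite-valence* learning rate (A− after gains, A+ after losses),
  following the original ORL formulation; a `same_rate_fictive` toggle
  on `ORLParams` selects the same-valence reading instead.
- At x = 0 the gain branch applies for rate selection and the VPP gain
  impact (consistent with the utility function's x ≥ 0 branch), while
  sgn(0) = 0 in the frequency targets.

## Hierarchical Bayesian estimation

Each (model, group) pair is fitted independently — two priors, one per
group — which mirrors how the group contrast is constructed. Per
cognitive parameter p and subject s:

    mu_p    ~ Normal(0, 1)
    sigma_p ~ HalfNormal(1)
    z_sp    ~ Normal(mu_p, sigma_p)
    theta_sp = Phi(z_sp) · U_p      (bounded parameters)
             = z_sp                 (unbounded: ep_p, ep_n, beta_F, beta_P)

with U the parameter's upper bound (1 for rates and w, 10 for λ, 5 for
c and K′). Since no probabilistic-programming engine ships in this
stack, the sampler is written here: a Metropolis-within-Gibbs scheme
with, per iteration,

1. component-wise adaptive random-walk updates of each subject
   parameter (vectorized across chains × subjects; target acceptance
   0.44),
2. a joint random-walk update per subject along the Cholesky factor of
   an adaptively estimated per-subject posterior covariance
   (adaptive-Metropolis style, target acceptance 0.30),
3. a conjugate Gibbs draw of each group mean,
4. an adaptive MH update of each log group spread, and
5. an interweaved non-centered move per parameter — translating mu_p
   and rescaling sigma_p while holding the standardized subject effects
   fixed (ancillarity–sufficiency interweaving). This step is what keeps
   the group-level quantities mixing when a parameter is weakly
   identified at 100 trials per subject (the funnel regime).

All proposal scales adapt only during warmup and are frozen afterwards.
Chains run simultaneously as extra rows of the vectorized likelihood
(compiled trial-loop kernels). Convergence is summarized by the maximum
split-R̂ over group-level quantities; fits with R̂ ≥ 1.05 carry an
explicit warning in their diagnostics, never silently dropped. Default
sampler settings (4 chains, 1000 warmup, 1000 retained draws, thinning
2) are configurable; the test suite and the acceptance script use 2
chains × (500 warmup + 400 draws, thinning 2), which keeps the maximum
group-level R̂ around 1.05 on the synthetic cohorts while holding a full
four-model study to a few minutes on one core.

Known limitation: the ORL decay K′ (and, at these trial counts, several
VPP parameters) is weakly identified from 100 trials; its posterior is
prior-dominated, individual estimates shrink hard toward the group mean,
and recovery correlations for it are near zero. This is a property of
the design (trials per subject), not of the sampler; learning rates
recover well (r ≈ 0.8 at n=30 × 100 trials).

Group contrasts are draw-wise differences of the natural-scale group
means of two independent fits, paired after an independent seeded
shuffle per fit; a difference is flagged when the 95% highest-density
interval excludes zero. The HDI is the narrowest contiguous interval
containing ⌈mass·n⌉ sorted samples.

A per-subject maximum-likelihood baseline (Nelder–Mead through the same
links, a few random restarts) exists solely as the comparison point for
the shrinkage check: the variance of hierarchical individual posterior
means must not exceed the variance of the per-subject ML estimates.

## Model comparison

One "point" is one trial's observed choice, so leave-one-out expected
log predictive density is a one-step-ahead criterion;
LOOIC = −2·elpd, lower is better. Importance weights are
Pareto-smoothed (PSIS, via arviz); points with shape diagnostic k > 0.7
are counted and reported, never refitted. The comparison table reports
per-group LOOIC, its standard error, and the summed LOOIC, sorted
ascending with the best model per column marked.

## Pain scoring and statistics

BPI-SF severity is the mean of the four intensity items (worst, least,
average, now); interference is the mean of seven daily-life items, which
split into the affective subdimension REM (relations, enjoyment, mood)
and the activity subdimension WASW (walking, general activity, sleep,
work), so interference = (3·REM + 4·WASW)/7 identically. Items must be
integers in [0,10]; nothing is imputed.

Group comparisons use the pooled-variance two-sample t test with
Cohen's d on the pooled SD. Correlations are Pearson r with a Fisher-z
95% CI. The parameter–pain report correlates each subject-level
posterior-mean parameter (pooled over both groups) with each of the
four pain measures and reports raw p-values — no multiplicity
adjustment by default, with an optional Benjamini–Hochberg column.

## The synthetic cohort generator

Because no behavioral data ship with this package, the generator is the
source of every input. The default study has two ORL cohorts — 25
"healthy" and 20 "chronic pain" subjects — whose generating parameter
distributions differ in exactly two locations: the reward learning rate
(0.15 vs 0.45, sd 0.08; truncated normal) and the perseverance weight
(+1.5 vs −1.5, sd 1.0), with punishment rate (0.10, sd 0.05), decay
(K′ 0.8, sd 0.3) and frequency weight (1.5, sd 0.5) shared. These
constants are SYNTHETIC package choices (recorded as such in the study
manifest): the directions encode the qualitative group differences the
package is built to detect — faster reward learning and reduced choice
persistence in the symptomatic group — and the magnitudes are set so a
cohort of this size detects them reliably but not trivially.

Pain items are generated at item level so the scorer is genuinely
exercised: each subject's severity/REM/WASW level is a linear function
of the true reward learning rate (severity = 1 + 8·A+ + noise,
sd 0.8) plus item-level noise (sd 1.0), rounded and clipped to the
0–10 integer scale. With these constants the healthy cohort averages
severity ≈ 2.2 and the symptomatic cohort ≈ 4.6 — the realistic range
for such questionnaires. A `vpp_regimes()` pair (elevated learning rate
in the symptomatic group) ships as an alternative, and
`recovery_regime()` provides a single deliberately broad ORL cohort for
parameter-recovery studies.

What the generator does *not* emulate: dropout, attrition, device or
browser artifacts, reaction times, within-session non-stationarity
(fatigue, distraction), or any model-misspecification gap between the
generating process and the fitted families. Passing tests therefore
demonstrate that the pipeline is correct and well-powered under its own
assumptions, not that those assumptions hold for any real population.

## Numerical choices

- Softmax computations subtract the row maximum before exponentiation;
  probabilities sum to 1 within 1e−12 for pre-stabilization values up
  to ±700.
- Probit links clamp Phi(z) to [1e−13, 1−1e−13] before scaling so that
  saturating draws cannot touch the closed bounds.
- Ragged cohorts (unequal session lengths) are padded with a choice of
  −1; padded trials contribute zero log-likelihood and are excluded
  from the pointwise matrix.
- Ties in the HDI window (constant samples) resolve to the first
  narrowest window, giving a zero-width interval at the common value.
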