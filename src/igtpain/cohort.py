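"""Synthetic study generator: two cohorts of model-driven IGT agents with
linked pain questionnaires.

The defaults emulate the structure of a two-group chronic-pain IGT study:
a healthy cohort (n=25) and a symptomatic cohort (n=20) of ORL agents whose
generating parameters differ in the reward learning rate (higher in the
symptomatic group) and the perseverance weight (lower, i.e. switch-prone, in
the symptomatic group), with BPI-SF items generated from a linear linkage of
pain levels to each subject's true parameters plus noise.

All numeric generating values are SYNTHETIC package constants (recorded as
such in the manifest); they are not estimates taken from any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import task
from .inference import PARAM_BOUNDS
from ._batch import PARAM_ORDER
from .models import params_from_dict, simulate_agent
from .pain import (
    BPISFResponses,
    REM_ITEMS,
    SEVERITY_ITEMS,
    WASW_ITEMS,
    write_bpisf,
)

HEALTHY = "healthy"
CHRONIC_PAIN = "chronic_pain"


@dataclass(frozen=True)
class PainLinkage:
    """Linear map from true parameters to one 0-10 pain level."""

    intercept: float
    slopes: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.8
    item_sd: float = 1.0


@dataclass(frozen=True)
class CohortRegime:
    """Generating distribution of one cohort.

    param_dists maps parameter name -> (location, spread); bounded
    parameters are sampled from the matching truncated normal. Pain levels
    for severity / REM / WASW derive from the linkages; items are the level
    plus item noise, rounded and clipped to the 0-10 integer scale.
    """

    group: str
    n_subjects: int
    model: str
    param_dists: dict[str, tuple[float, float]]
    severity: PainLinkage
    rem: PainLinkage
    wasw: PainLinkage


_SHARED_ORL = {
    "a_pun": (0.10, 0.05),
    "k_prime": (0.8, 0.3),
    "beta_f": (1.5, 0.5),
}

#: SYNTHETIC pain linkage: severity rises with the reward learning rate.
_LINK_SEV = PainLinkage(intercept=1.0, slopes={"a_rew": 8.0}, noise_sd=0.8)
_LINK_REM = PainLinkage(intercept=0.6, slopes={"a_rew": 9.0}, noise_sd=1.0)
_LINK_WASW = PainLinkage(intercept=0.6, slopes={"a_rew": 8.5}, noise_sd=1.0)


def default_regimes() -> tuple[CohortRegime, CohortRegime]:
    """Healthy / symptomatic ORL regimes.

    The symptomatic cohort has an elevated reward learning rate
    (0.45 vs 0.15) and a negative perseverance weight (-1.5 vs +1.5);
    punishment learning rate, decay, and frequency weight are shared.
    """
    healthy = CohortRegime(
        group=HEALTHY,
        n_subjects=25,
        model="orl",
        param_dists={"a_rew": (0.15, 0.08), **_SHARED_ORL, "beta_p": (1.5, 1.0)},
        severity=_LINK_SEV,
        rem=_LINK_REM,
        wasw=_LINK_WASW,
    )
    pain = CohortRegime(
        group=CHRONIC_PAIN,
        n_subjects=20,
        model="orl",
        param_dists={"a_rew": (0.45, 0.08), **_SHARED_ORL, "beta_p": (-1.5, 1.0)},
        severity=_LINK_SEV,
        rem=_LINK_REM,
        wasw=_LINK_WASW,
    )
    return healthy, pain


def vpp_regimes() -> tuple[CohortRegime, CohortRegime]:
    """Alternative VPP regime pair: elevated learning rate in the symptomatic group."""
    shared = {
        "alpha": (0.4, 0.1),
        "lam": (1.5, 0.5),
        "c": (1.0, 0.3),
        "k": (0.5, 0.15),
        "ep_p": (1.0, 0.8),
        "ep_n": (-0.5, 0.8),
        "w": (0.6, 0.1),
    }
    link_sev = PainLinkage(intercept=1.2, slopes={"a": 6.0}, noise_sd=0.8)
    link_rem = PainLinkage(intercept=0.8, slopes={"a": 7.0}, noise_sd=1.0)
    link_wasw = PainLinkage(intercept=0.8, slopes={"a": 6.5}, noise_sd=1.0)
    healthy = CohortRegime(
        group=HEALTHY,
        n_subjects=25,
        model="vpp",
        param_dists={"a": (0.2, 0.1), **shared},
        severity=link_sev,
        rem=link_rem,
        wasw=link_wasw,
    )
    pain = CohortRegime(
        group=CHRONIC_PAIN,
        n_subjects=20,
        model="vpp",
        param_dists={"a": (0.55, 0.1), **shared},
        severity=link_sev,
        rem=link_rem,
        wasw=link_wasw,
    )
    return healthy, pain


def recovery_regime(n_subjects: int = 30) -> CohortRegime:
    """Single broad ORL cohort for parameter-recovery studies.

    Spreads are deliberately wide (e.g. learning-rate sd 0.15) so that
    recovery correlations measure estimation quality rather than the
    truncation of a narrow generating range.
    """
    return CohortRegime(
        group="recovery",
        n_subjects=n_subjects,
        model="orl",
        param_dists={
            "a_rew": (0.35, 0.15),
            "a_pun": (0.25, 0.12),
            "k_prime": (1.0, 0.5),
            "beta_f": (1.5, 1.0),
            "beta_p": (0.5, 1.5),
        },
        severity=_LINK_SEV,
        rem=_LINK_REM,
        wasw=_LINK_WASW,
    )


def _sample_param(
    name: str, loc: float, spread: float, upper: float | None, rng: np.random.Generator
) -> float:
    if upper is None:
        return float(rng.normal(loc, spread))
    lo, hi = 1e-4, upper - 1e-4
    a, b = (lo - loc) / spread, (hi - loc) / spread
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=spread, random_state=rng))


def _items(level: float, names: tuple[str, ...], item_sd: float, rng) -> dict[str, int]:
    vals = rng.normal(level, item_sd, size=len(names))
    return {k: int(np.clip(np.rint(v), 0, 10)) for k, v in zip(names, vals)}


@dataclass
class StudyData:
    """One complete synthetic study with its ground truth."""

    sessions: list[task.SessionRecord]
    true_params: pd.DataFrame  # indexed by subject_id; columns: group + params
    responses: dict[str, tuple[str, BPISFResponses]]
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        task.write_trial_log(self.sessions, out / "trials.csv")
        write_bpisf(self.responses, out / "bpisf.csv")
        self.true_params.to_csv(out / "true_params.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def generate_study(
    regimes: tuple[CohortRegime, CohortRegime] | None = None,
    n_trials: int = 100,
    seed: int = 0,
    scheme: task.PayoffScheme | None = None,
) -> StudyData:
    """Generate sessions, true parameters, and BPI-SF items for both cohorts.

    Fully reproducible under ``seed``; the manifest records regimes, seed,
    and per-subject true parameters so downstream recovery is checkable.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    regimes = regimes or default_regimes()
    scheme = scheme or task.build_payoff_scheme()
    root = np.random.SeedSequence(seed)

    sessions: list[task.SessionRecord] = []
    rows = []
    responses: dict[str, tuple[str, BPISFResponses]] = {}
    prefix = {HEALTHY: "hc", CHRONIC_PAIN: "cp"}

    for regime, reg_seq in zip(regimes, root.spawn(len(regimes))):
        names = PARAM_ORDER[regime.model]
        uppers = dict(zip(names, PARAM_BOUNDS[regime.model]))
        for i, subj_seq in enumerate(reg_seq.spawn(regime.n_subjects), start=1):
            rng = np.random.default_rng(subj_seq)
            sid = f"{prefix.get(regime.group, regime.group[:2])}{i:02d}"
            values = {
                p: _sample_param(p, *regime.param_dists[p], uppers[p], rng)
                for p in names
            }
            params = params_from_dict(regime.model, values)
            agent_seed = int(rng.integers(2**31 - 1))
            session = simulate_agent(
                regime.model,
                params,
                scheme,
                n_trials=n_trials,
                seed=agent_seed,
                subject_id=sid,
                group=regime.group,
            )
            sessions.append(session)

            items: dict[str, int] = {}
            for linkage, item_names in (
                (regime.severity, SEVERITY_ITEMS),
                (regime.rem, REM_ITEMS),
                (regime.wasw, WASW_ITEMS),
            ):
                level = linkage.intercept + sum(
                    s * values[p] for p, s in linkage.slopes.items()
                )
                level += rng.normal(0.0, linkage.noise_sd)
                items.update(_items(level, item_names, linkage.item_sd, rng))
            responses[sid] = (regime.group, BPISFResponses(**items))
            rows.append({"subject_id": sid, "group": regime.group, **values})

    true_params = pd.DataFrame(rows).set_index("subject_id")
    manifest = {
        "generator": "SYNTHETIC",
        "seed": seed,
        "n_trials": n_trials,
        "model": regimes[0].model,
        "regimes": [asdict(r) for r in regimes],
        "true_params": true_params.reset_index().to_dict("records"),
    }
    return StudyData(
        sessions=sessions, true_params=true_params, responses=responses, manifest=manifest
    )
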