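"""BPI-SF pain scoring and behavior/parameter/pain statistics.

The Brief Pain Inventory-Short Form rates pain intensity (worst, least,
average, now) and the interference of pain with seven daily-life domains,
all on 0-10 integer scales. Interference splits into an affective
subdimension (relations with others, enjoyment of life, mood: REM) and an
activity subdimension (walking, general activity, sleep, work: WASW).
Severity and interference scores are plain item means, so
interference = (3*REM + 4*WASW) / 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEVERITY_ITEMS = ("worst", "least", "average", "now")
REM_ITEMS = ("relations", "enjoyment", "mood")
WASW_ITEMS = ("walking", "general_activity", "sleep", "work")
INTERFERENCE_ITEMS = REM_ITEMS + WASW_ITEMS
PAIN_MEASURES = ("severity", "interference", "rem", "wasw")


class ValidationError(ValueError):
    """A questionnaire item is missing or out of range."""


class AlignmentError(ValueError):
    """Subject identifiers do not line up across inputs."""


@dataclass(frozen=True)
class BPISFResponses:
    """Raw item responses of one subject (integers 0-10; treatments free text)."""

    worst: int
    least: int
    average: int
    now: int
    general_activity: int
    mood: int
    walking: int
    work: int
    relations: int
    sleep: int
    enjoyment: int
    treatments: str = ""

    def __post_init__(self):
        for f in dc_fields(self):
            if f.name == "treatments":
                continue
            v = getattr(self, f.name)
            if v is None or not np.isfinite(v):
                raise ValidationError(f"item {f.name!r} is missing")
            if not 0 <= v <= 10:
                raise ValidationError(f"item {f.name!r} = {v} outside the 0-10 scale")


@dataclass(frozen=True)
class PainProfile:
    """Scored BPI-SF: severity, interference, and its two subdimensions."""

    severity: float
    interference: float
    rem: float
    wasw: float


def score_bpisf(responses: BPISFResponses) -> PainProfile:
    """Score a response set into severity / interference / REM / WASW means."""
    sev = float(np.mean([getattr(responses, k) for k in SEVERITY_ITEMS]))
    rem = float(np.mean([getattr(responses, k) for k in REM_ITEMS]))
    wasw = float(np.mean([getattr(responses, k) for k in WASW_ITEMS]))
    interference = float(np.mean([getattr(responses, k) for k in INTERFERENCE_ITEMS]))
    return PainProfile(severity=sev, interference=interference, rem=rem, wasw=wasw)


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sample t test with Cohen's d and CI of the difference."""

    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    ci_low: float
    ci_high: float


def compare_groups(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """Unpaired two-tailed t test (pooled variance) between the two group labels."""
    values = np.asarray(values, dtype=float)
    labels = pd.unique(np.asarray(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {list(labels)}")
    a = values[np.asarray(groups) == labels[0]]
    b = values[np.asarray(groups) == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    se = sp * np.sqrt(1 / n1 + 1 / n2)
    tcrit = stats.t.ppf(0.975, df)
    diff = a.mean() - b.mean()
    return GroupComparison(
        t=float(t),
        df=df,
        p=float(p),
        cohen_d=float(d),
        mean_diff=float(diff),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with a Fisher-transform 95% CI and a two-sided p-value."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("correlate needs two equal-length vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return CorrelationResult(r=float(r), ci_low=float(lo), ci_high=float(hi), p=float(p), n=x.size)


def parameter_pain_report(
    posterior_means: pd.DataFrame,
    profiles: dict[str, PainProfile],
    adjust: bool = False,
) -> pd.DataFrame:
    """Correlate each subject-level posterior-mean parameter with each pain measure.

    ``posterior_means``: subjects x parameters frame indexed by subject_id,
    pooled over groups (e.g. concatenated PosteriorFit.subject_posterior_means()).
    Reports raw (unadjusted) p-values; ``adjust=True`` adds Benjamini-Hochberg
    q-values for users who want multiplicity control.
    """
    missing = set(posterior_means.index) ^ set(profiles)
    if missing:
        raise AlignmentError(f"subject IDs do not align across fits and profiles: {sorted(missing)}")
    ids = list(posterior_means.index)
    rows = []
    for param in posterior_means.columns:
        x = posterior_means[param].to_numpy()
        for measure in PAIN_MEASURES:
            y = np.array([getattr(profiles[s], measure) for s in ids])
            res = correlate(x, y)
            rows.append(
                {
                    "param": param,
                    "measure": measure,
                    "r": res.r,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                    "log_bf10": np.nan,  # reserved; not computed here
                }
            )
    df = pd.DataFrame(rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        df["q_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df.attrs["multiplicity_adjustment"] = "benjamini-hochberg" if adjust else "none"
    return df


# ---------------------------------------------------------------------------
# CSV interfaces

BPI_COLUMNS = ["subject_id", "group"] + list(SEVERITY_ITEMS) + list(INTERFERENCE_ITEMS)


def write_bpisf(responses: dict[str, tuple[str, BPISFResponses]], path) -> None:
    """Write responses keyed by subject_id -> (group, responses) to CSV."""
    rows = []
    for sid, (grp, r) in responses.items():
        row = {"subject_id": sid, "group": grp}
        row.update({k: getattr(r, k) for k in SEVERITY_ITEMS + INTERFERENCE_ITEMS})
        rows.append(row)
    pd.DataFrame(rows, columns=BPI_COLUMNS).to_csv(path, index=False)


def read_bpisf(path) -> dict[str, tuple[str, BPISFResponses]]:
    df = pd.read_csv(path)
    missing = set(BPI_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"BPI-SF file missing columns {sorted(missing)}")
    out = {}
    for rec in df.to_dict("records"):
        sid, grp = str(rec.pop("subject_id")), str(rec.pop("group"))
        items = {k: int(rec[k]) for k in SEVERITY_ITEMS + INTERFERENCE_ITEMS}
        out[sid] = (grp, BPISFResponses(**items))
    return out
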