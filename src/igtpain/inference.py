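"""Hierarchical Bayesian estimation of the IGT models, one fit per group.

Model structure (per cognitive parameter p, subjects s = 1..S):

    mu_p      ~ Normal(0, mu_scale)              group mean, unconstrained scale
    sigma_p   ~ HalfNormal(sigma_scale)          group spread
    z_{s,p}   ~ Normal(mu_p, sigma_p)            subject value, unconstrained
    theta_{s,p} = Phi(z_{s,p}) * U_p             bounded parameters (U = upper bound)
                 = z_{s,p}                        unbounded parameters

Choices enter through the sequential softmax likelihood of the chosen model.
Sampling is Metropolis-within-Gibbs: the group mean is conjugate given the
subject values and is Gibbs-sampled; group spreads use adaptive random-walk
MH on the log scale; subject vectors use joint adaptive random-walk MH with
the likelihood evaluated vectorized across subjects. Proposal scales adapt
toward ~30% acceptance during warmup and are frozen afterwards.

Each group is fitted independently with its own prior, and group contrasts
are formed on draw-wise differences of the (natural-scale) group means, with
significance read off the 95% highest-density interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, special

from ._batch import PARAM_ORDER, batch_loglik, pack_sessions
from .models import ModelParams, params_from_dict
from .task import SessionRecord

#: Upper link bounds per parameter; None = identity link (unbounded).
PARAM_BOUNDS = {
    "pvl_delta": (1.0, 10.0, 1.0, 5.0),
    "pvl_decay": (1.0, 10.0, 1.0, 5.0),
    "vpp": (1.0, 10.0, 1.0, 5.0, 1.0, None, None, 1.0),
    "orl": (1.0, 1.0, 5.0, None, None),
}


class DataError(ValueError):
    """Input data unsuitable for fitting."""


class UsageError(ValueError):
    """Operation invoked on incompatible objects."""


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors on the unconstrained scale.

    mu_loc/mu_scale: normal prior on each group mean (default standard normal);
    sigma_scale: half-normal scale of the group spread.
    """

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 1.0


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``draws`` are retained per chain after ``warmup`` iterations; ``thin``
    keeps every thin-th post-warmup iteration (so the chain advances
    draws*thin iterations after warmup).
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 2
    seed: int = 0
    target_accept: float = 0.30
    init_jitter: float = 0.10


def link(z: np.ndarray, uppers: Sequence[float | None]) -> np.ndarray:
    """Map unconstrained values to natural scale along the last axis.

    Bounded parameters use a probit transform scaled to (0, U), nudged off
    the endpoints where Phi saturates in floating point.
    """
    z = np.asarray(z, dtype=float)
    out = z.copy()
    for j, U in enumerate(uppers):
        if U is not None:
            out[..., j] = np.clip(special.ndtr(z[..., j]), 1e-13, 1.0 - 1e-13) * U
    return out


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one (model, group) fit.

    ``idata`` holds the posterior (group means on both scales, spreads,
    subject-level natural parameters) and the pointwise log-likelihood
    (one point per observed trial, flattened subject-major).
    """

    model: str
    group: str
    subject_ids: list[str]
    param_names: tuple[str, ...]
    idata: az.InferenceData
    diagnostics: dict = field(default_factory=dict)
    scale: float = 100.0

    @property
    def n_draws_total(self) -> int:
        post = self.idata.posterior
        return post.sizes["chain"] * post.sizes["draw"]

    def group_mean_draws(self, param: str) -> np.ndarray:
        """Flattened draws of the natural-scale group mean of ``param``."""
        return self.idata.posterior[f"mu_{param}"].values.reshape(-1)

    def subject_draws(self, param: str) -> np.ndarray:
        """Draws of subject-level natural parameters, shape (total draws, S)."""
        da = self.idata.posterior[param]
        return da.values.reshape(-1, da.sizes["subject"])

    def subject_posterior_means(self) -> pd.DataFrame:
        """Posterior-mean natural parameters, one row per subject."""
        data = {p: self.subject_draws(p).mean(axis=0) for p in self.param_names}
        return pd.DataFrame(data, index=pd.Index(self.subject_ids, name="subject_id"))


def _sample_chains(
    model: str,
    choices: np.ndarray,
    xs: np.ndarray,
    uppers: Sequence[float | None],
    priors: PriorSpec,
    cfg: MCMCConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run all chains simultaneously (chains share the trial loop as extra rows)."""
    C = cfg.chains
    S, T = choices.shape
    P = len(uppers)

    choices_rep = np.tile(choices, (C, 1))
    xs_rep = np.tile(xs, (C, 1))

    Z = rng.normal(0.0, cfg.init_jitter, size=(C, S, P))
    mu = np.zeros((C, P))
    sigma = np.full((C, P), 0.5)

    step_zp = np.full((C, S, P), 0.3)  # component-wise subject proposals
    step_z = np.full((C, S), 0.3)  # joint subject proposal (scalar x Cholesky)
    step_s = np.full((C, P), 0.3)
    step_nc_mu = np.full((C, P), 0.2)  # interweaved group-mean translation
    step_nc = np.full((C, P), 0.3)  # interweaved group-spread rescaling
    # adaptive-Metropolis state: running moments of Z per (chain, subject)
    chol = np.broadcast_to(np.eye(P), (C, S, P, P)).copy()
    am_n = 0
    am_mean = np.zeros((C, S, P))
    am_M2 = np.zeros((C, S, P, P))

    def loglik(Zmat: np.ndarray) -> np.ndarray:
        theta = link(Zmat.reshape(C * S, P), uppers)
        return batch_loglik(model, theta, choices_rep, xs_rep).sum(axis=1).reshape(C, S)

    ll = loglik(Z)

    n_iter = cfg.warmup + cfg.draws * cfg.thin
    keep_Z = np.empty((C, cfg.draws, S, P))
    keep_mu = np.empty((C, cfg.draws, P))
    keep_sigma = np.empty((C, cfg.draws, P))
    acc_z_count = 0.0
    kept = 0

    mu_prior_prec = 1.0 / priors.mu_scale**2

    def _lp_prior(Zmat: np.ndarray) -> np.ndarray:
        return -0.5 * (((Zmat - mu[:, None, :]) / sigma[:, None, :]) ** 2).sum(axis=2)

    for it in range(n_iter):
        adapting = it < cfg.warmup

        # --- subject-level component-wise RW-MH, vectorized over (chain, subject)
        for j in range(P):
            prop = Z.copy()
            prop[:, :, j] += step_zp[:, :, j] * rng.standard_normal((C, S))
            ll_prop = loglik(prop)
            dz = prop[:, :, j] - mu[:, None, j]
            dz0 = Z[:, :, j] - mu[:, None, j]
            dlp = -0.5 * (dz**2 - dz0**2) / sigma[:, None, j] ** 2
            accept = np.log(rng.random((C, S))) < (ll_prop - ll + dlp)
            Z[:, :, j] = np.where(accept, prop[:, :, j], Z[:, :, j])
            ll = np.where(accept, ll_prop, ll)
            if adapting:
                step_zp[:, :, j] *= np.exp(0.1 * (accept.astype(float) - 0.44))
                np.clip(step_zp, 1e-3, 5.0, out=step_zp)

        # --- subject-level joint RW-MH along the adapted covariance
        eps = rng.standard_normal((C, S, P))
        prop = Z + step_z[..., None] * np.einsum("csij,csj->csi", chol, eps)
        ll_prop = loglik(prop)
        log_alpha = (ll_prop + _lp_prior(prop)) - (ll + _lp_prior(Z))
        accept = np.log(rng.random((C, S))) < log_alpha
        Z = np.where(accept[..., None], prop, Z)
        ll = np.where(accept, ll_prop, ll)
        if adapting:
            step_z *= np.exp(0.05 * (accept.astype(float) - cfg.target_accept))
            np.clip(step_z, 1e-3, 5.0, out=step_z)
            # Welford update of per-subject posterior moments; refresh the
            # proposal Cholesky periodically once enough history exists
            am_n += 1
            delta = Z - am_mean
            am_mean += delta / am_n
            am_M2 += np.einsum("csi,csj->csij", delta, Z - am_mean)
            if am_n >= 100 and it % 25 == 0:
                cov = am_M2 / (am_n - 1) + 1e-6 * np.eye(P)
                chol = np.linalg.cholesky(cov)
        else:
            acc_z_count += accept.mean()

        # --- group means: conjugate normal given Z and sigma
        prec = S / sigma**2 + mu_prior_prec
        mean = (Z.sum(axis=1) / sigma**2 + priors.mu_loc * mu_prior_prec) / prec
        mu = mean + rng.standard_normal((C, P)) / np.sqrt(prec)

        # --- group spreads: RW-MH on log sigma (half-normal prior + Jacobian)
        ls = np.log(sigma)
        ls_prop = ls + step_s * rng.standard_normal((C, P))
        sig_prop = np.exp(ls_prop)
        sq = ((Z - mu[:, None, :]) ** 2).sum(axis=1)

        def _lp_sigma(s: np.ndarray, logs: np.ndarray) -> np.ndarray:
            return (
                -S * logs
                - sq / (2.0 * s**2)
                - s**2 / (2.0 * priors.sigma_scale**2)
                + logs  # Jacobian of the log transform
            )

        log_alpha_s = _lp_sigma(sig_prop, ls_prop) - _lp_sigma(sigma, ls)
        acc_s = np.log(rng.random((C, P))) < log_alpha_s
        sigma = np.where(acc_s, sig_prop, sigma)
        if adapting:
            step_s *= np.exp(0.05 * (acc_s.astype(float) - cfg.target_accept))
            np.clip(step_s, 1e-3, 5.0, out=step_s)

        # --- interweaved non-centered move per parameter: shift
        # (mu_p, log sigma_p) holding the standardized subject effects of
        # that parameter fixed. This ancillarity-sufficiency interweaving
        # step breaks the funnel for weakly identified parameters.
        def _lp_group(m: np.ndarray, s: np.ndarray, logs: np.ndarray) -> np.ndarray:
            return (
                -0.5 * mu_prior_prec * ((m - priors.mu_loc) ** 2)
                - s**2 / (2.0 * priors.sigma_scale**2)
                + logs  # Jacobian of the log transform
            )

        for p_idx in range(P):
            Zt_p = (Z[:, :, p_idx] - mu[:, None, p_idx]) / sigma[:, None, p_idx]

            # translate mu_p, carrying the subjects along
            mu_prop_p = mu[:, p_idx] + step_nc_mu[:, p_idx] * rng.standard_normal(C)
            Z_prop = Z.copy()
            Z_prop[:, :, p_idx] = mu_prop_p[:, None] + sigma[:, None, p_idx] * Zt_p
            ll_prop2 = loglik(Z_prop)
            log_alpha_nc = (
                ll_prop2.sum(axis=1)
                - ll.sum(axis=1)
                - 0.5
                * mu_prior_prec
                * ((mu_prop_p - priors.mu_loc) ** 2 - (mu[:, p_idx] - priors.mu_loc) ** 2)
            )
            acc_nc = np.log(rng.random(C)) < log_alpha_nc
            mu[:, p_idx] = np.where(acc_nc, mu_prop_p, mu[:, p_idx])
            Z = np.where(acc_nc[:, None, None], Z_prop, Z)
            ll = np.where(acc_nc[:, None], ll_prop2, ll)
            if adapting:
                step_nc_mu[:, p_idx] *= np.exp(0.1 * (acc_nc.astype(float) - 0.35))
                np.clip(step_nc_mu, 1e-3, 2.0, out=step_nc_mu)

            # rescale sigma_p about mu_p, carrying the subjects along
            ls_cur_p = np.log(sigma[:, p_idx])
            ls_prop_p = ls_cur_p + step_nc[:, p_idx] * rng.standard_normal(C)
            sig_prop_p = np.exp(ls_prop_p)
            Z_prop = Z.copy()
            Z_prop[:, :, p_idx] = mu[:, None, p_idx] + sig_prop_p[:, None] * Zt_p
            ll_prop2 = loglik(Z_prop)
            log_alpha_nc = (
                ll_prop2.sum(axis=1)
                + _lp_group(mu[:, p_idx], sig_prop_p, ls_prop_p)
                - ll.sum(axis=1)
                - _lp_group(mu[:, p_idx], sigma[:, p_idx], ls_cur_p)
            )
            acc_nc = np.log(rng.random(C)) < log_alpha_nc
            sigma[:, p_idx] = np.where(acc_nc, sig_prop_p, sigma[:, p_idx])
            Z = np.where(acc_nc[:, None, None], Z_prop, Z)
            ll = np.where(acc_nc[:, None], ll_prop2, ll)
            if adapting:
                step_nc[:, p_idx] *= np.exp(0.1 * (acc_nc.astype(float) - 0.35))
                np.clip(step_nc, 1e-3, 3.0, out=step_nc)

        if not adapting and (it - cfg.warmup) % cfg.thin == cfg.thin - 1:
            keep_Z[:, kept] = Z
            keep_mu[:, kept] = mu
            keep_sigma[:, kept] = sigma
            kept += 1

    return {
        "Z": keep_Z,
        "mu_raw": keep_mu,
        "sigma": keep_sigma,
        "accept_rate": acc_z_count / max(cfg.draws * cfg.thin, 1),
    }


def fit_group(
    sessions: Sequence[SessionRecord],
    model: str,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    scale: float = 100.0,
    group: str | None = None,
) -> PosteriorFit:
    """Fit one model hierarchically to one group of sessions."""
    if len(sessions) < 2:
        raise DataError("hierarchical fitting needs at least 2 subjects")
    if model not in PARAM_ORDER:
        raise UsageError(f"unknown model id {model!r}")
    priors = priors or PriorSpec()
    cfg = mcmc or MCMCConfig()
    names = PARAM_ORDER[model]
    uppers = PARAM_BOUNDS[model]
    group = group or sessions[0].group

    choices, xs = pack_sessions(sessions, scale)
    S, T = choices.shape

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    res = _sample_chains(model, choices, xs, uppers, priors, cfg, rng)
    mu_raw = res["mu_raw"]  # (chain, draw, P)
    sigma = res["sigma"]
    Z = res["Z"]  # (chain, draw, S, P)
    theta = link(Z, uppers)
    mu_nat = link(mu_raw, uppers)

    posterior = {}
    for j, p in enumerate(names):
        posterior[f"mu_{p}"] = mu_nat[..., j]
        posterior[f"mu_raw_{p}"] = mu_raw[..., j]
        posterior[f"sigma_{p}"] = sigma[..., j]
        posterior[p] = theta[..., j]

    # pointwise log-likelihood on retained draws, flattened over (draw, subject)
    n_chain, n_draw = mu_raw.shape[:2]
    valid = (choices >= 0).reshape(-1)
    ll_chains = []
    for c in range(n_chain):
        th = theta[c].reshape(n_draw * S, -1)
        ch_rep = np.repeat(choices[None, :, :], n_draw, axis=0).reshape(n_draw * S, T)
        xs_rep = np.repeat(xs[None, :, :], n_draw, axis=0).reshape(n_draw * S, T)
        pw = batch_loglik(model, th, ch_rep, xs_rep).reshape(n_draw, S * T)
        ll_chains.append(pw[:, valid])
    log_lik = np.stack(ll_chains)  # (chain, draw, obs)

    subject_ids = [s.subject_id for s in sessions]
    obs_subject = np.repeat(np.arange(S), T)[valid]
    obs_trial = np.tile(np.arange(1, T + 1), S)[valid]

    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"choice": log_lik},
        coords={"subject": subject_ids, "obs": np.arange(valid.sum())},
        dims={p: ["subject"] for p in names} | {"choice": ["obs"]},
    )
    idata.log_likelihood["choice"] = idata.log_likelihood["choice"].assign_coords(
        obs_subject=("obs", obs_subject), obs_trial=("obs", obs_trial)
    )

    group_vars = [f"mu_raw_{p}" for p in names] + [f"sigma_{p}" for p in names]
    rhat = az.rhat(idata, var_names=group_vars)
    rhat_max = float(max(rhat[v].values.max() for v in group_vars))
    diagnostics = {
        "rhat_max_group": rhat_max,
        "accept_rate": float(res["accept_rate"]),
        "divergences": 0,
        "converged": bool(rhat_max < 1.05),
    }
    if not diagnostics["converged"]:
        diagnostics["warning"] = f"split-Rhat up to {rhat_max:.3f} >= 1.05 on group-level quantities"

    return PosteriorFit(
        model=model,
        group=group,
        subject_ids=subject_ids,
        param_names=names,
        idata=idata,
        diagnostics=diagnostics,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# HDI machinery and group contrasts


@dataclass(frozen=True)
class HDInterval:
    """Narrowest contiguous interval holding ``mass`` of the samples."""

    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def hdi(samples: np.ndarray, mass: float = 0.95) -> HDInterval:
    """Highest-density interval by the sorted sliding-window construction."""
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    n = x.size
    if n < 10:
        raise DataError(f"need at least 10 samples for an HDI, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0,1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HDInterval(lower=float(x[i]), upper=float(x[i + k - 1]), mass=mass)


@dataclass(frozen=True)
class GroupContrast:
    """HDI of the draw-wise difference of natural-scale group means (a - b)."""

    param: str
    interval: HDInterval
    mean_diff: float
    exceeds_zero: bool


def group_difference(
    fit_a: PosteriorFit,
    fit_b: PosteriorFit,
    param: str,
    mass: float = 0.95,
    seed: int = 0,
) -> GroupContrast:
    """Contrast a parameter's group mean across two independent fits.

    Draws from independent fits carry no joint ordering, so each side is
    independently shuffled (seeded) before pairing; the larger set is
    truncated to the smaller.
    """
    if fit_a.model != fit_b.model:
        raise UsageError(f"cannot contrast fits of {fit_a.model} and {fit_b.model}")
    rng = np.random.default_rng(seed)
    a = rng.permutation(fit_a.group_mean_draws(param))
    b = rng.permutation(fit_b.group_mean_draws(param))
    n = min(a.size, b.size)
    diff = a[:n] - b[:n]
    interval = hdi(diff, mass)
    return GroupContrast(
        param=param,
        interval=interval,
        mean_diff=float(diff.mean()),
        exceeds_zero=not interval.contains(0.0),
    )


def posterior_summary(fit: PosteriorFit, mass: float = 0.95) -> pd.DataFrame:
    """Mean/SD/HDI per parameter at group and individual levels."""
    rows = []
    for p in fit.param_names:
        for level, draws in (
            ("group_mean", fit.group_mean_draws(p)),
            ("group_sd", fit.idata.posterior[f"sigma_{p}"].values.reshape(-1)),
        ):
            iv = hdi(draws, mass)
            rows.append((level, "", p, draws.mean(), draws.std(ddof=1), iv.lower, iv.upper))
        subj = fit.subject_draws(p)
        for i, sid in enumerate(fit.subject_ids):
            iv = hdi(subj[:, i], mass)
            rows.append(
                ("subject", sid, p, subj[:, i].mean(), subj[:, i].std(ddof=1), iv.lower, iv.upper)
            )
    return pd.DataFrame(
        rows, columns=["level", "subject_id", "param", "mean", "sd", "hdi_low", "hdi_high"]
    )


# ---------------------------------------------------------------------------
# Fit archives


def save_fit(fit: PosteriorFit, out_dir) -> None:
    """Archive a fit: draws + pointwise log-likelihood (npz) and a JSON manifest."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    post = fit.idata.posterior
    arrays = {v: post[v].values for v in post.data_vars}
    ll = fit.idata.log_likelihood["choice"]
    arrays["__log_lik"] = ll.values
    arrays["__obs_subject"] = ll.obs_subject.values
    arrays["__obs_trial"] = ll.obs_trial.values
    np.savez_compressed(out / "draws.npz", **arrays)
    manifest = {
        "model": fit.model,
        "group": fit.group,
        "subject_ids": fit.subject_ids,
        "param_names": list(fit.param_names),
        "diagnostics": fit.diagnostics,
        "scale": fit.scale,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_fit(in_dir) -> PosteriorFit:
    """Load a fit archive written by :func:`save_fit`."""
    import json
    from pathlib import Path

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    with np.load(src / "draws.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    log_lik = arrays.pop("__log_lik")
    obs_subject = arrays.pop("__obs_subject")
    obs_trial = arrays.pop("__obs_trial")
    names = manifest["param_names"]
    idata = az.from_dict(
        posterior=arrays,
        log_likelihood={"choice": log_lik},
        coords={"subject": manifest["subject_ids"], "obs": np.arange(log_lik.shape[-1])},
        dims={p: ["subject"] for p in names} | {"choice": ["obs"]},
    )
    idata.log_likelihood["choice"] = idata.log_likelihood["choice"].assign_coords(
        obs_subject=("obs", obs_subject), obs_trial=("obs", obs_trial)
    )
    return PosteriorFit(
        model=manifest["model"],
        group=manifest["group"],
        subject_ids=list(manifest["subject_ids"]),
        param_names=tuple(names),
        idata=idata,
        diagnostics=manifest["diagnostics"],
        scale=manifest["scale"],
    )


# ---------------------------------------------------------------------------
# Per-subject maximum-likelihood baseline (for shrinkage checks)


def fit_subject_ml(
    session: SessionRecord, model: str, scale: float = 100.0, seed: int = 0
) -> ModelParams:
    """Maximum-likelihood point estimate for a single subject.

    Optimizes on the unconstrained scale through the same links as the
    hierarchical model (Nelder-Mead with a few random restarts).
    """
    names = PARAM_ORDER[model]
    uppers = PARAM_BOUNDS[model]
    choices = session.choices[None, :]
    xs = (session.nets / scale)[None, :]

    def nll(z: np.ndarray) -> float:
        theta = link(z[None, :], uppers)
        return -float(batch_loglik(model, theta, choices, xs).sum())

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(3):
        z0 = rng.normal(0, 0.5, size=len(names))
        res = optimize.minimize(nll, z0, method="Nelder-Mead", options={"maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    theta = link(best.x[None, :], uppers)[0]
    return params_from_dict(model, dict(zip(names, (float(v) for v in theta))))
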