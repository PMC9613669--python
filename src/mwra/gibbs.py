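"""Blocked Gibbs sampler for Gaussian linear mixed models.

All three hierarchical models in this package (net-migration proportions,
log-ASFR, and the log-population model) are linear-Gaussian once written on
the appropriate scale:

    y_i = x_i' beta + sum_k z_{k,i}' u_k + eps_i,
    eps_i ~ N(0, sigma^2),   u_k ~ N(0, tau_k^2 I),
    beta_j ~ N(b0_j, s_j^2), tau_k, sigma ~ Half-Normal(prior sd).

Location blocks (beta and each u_k) therefore have exact multivariate-normal
full conditionals and are sampled jointly per block; the scale parameters are
not conjugate under half-normal priors and are updated by univariate slice
sampling on the log scale.  Random-walk smoothers are expressed as dense
effects whose design matrix maps increments to cumulative levels, so the
whole walk is updated in one conjugate block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

_SCALE_FLOOR = 1e-4


@dataclass
class GroupEffect:
    """Exchangeable random effect over a grouping factor (one-hot design)."""

    name: str
    codes: np.ndarray  # (n,) integer level codes in [0, n_levels)
    n_levels: int
    scale_prior_sd: float = 1.0
    labels: Sequence | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.codes.min() < 0 or self.codes.max() >= self.n_levels:
            raise ValueError(f"effect {self.name}: codes outside [0, n_levels)")


@dataclass
class DenseEffect:
    """Random-effect block with an arbitrary dense design matrix.

    Used for random walks: columns are increments, rows accumulate them.
    """

    name: str
    Z: np.ndarray  # (n, q)
    scale_prior_sd: float = 1.0
    labels: Sequence | None = None


@dataclass
class PosteriorDraws:
    """Labelled MCMC output with chain and draw indices retained.

    ``params[name]`` has shape ``(n_chains, n_kept)`` for scalars and
    ``(n_chains, n_kept, k)`` for vector-valued parameters, whose trailing
    axis is labelled by ``coords[name]``.
    """

    params: dict[str, np.ndarray]
    coords: dict[str, Sequence] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (n_chains * n_kept, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def median(self, name: str) -> np.ndarray:
        return np.median(self.stacked(name), axis=0)

    def quantile(self, name: str, q) -> np.ndarray:
        return np.quantile(self.stacked(name), q, axis=0)

    def compute_rhat(self) -> dict[str, np.ndarray]:
        from .summary import gelman_rubin

        out = {}
        for name, a in self.params.items():
            if a.ndim == 2:
                out[name] = gelman_rubin(a)
            else:
                out[name] = np.array(
                    [gelman_rubin(a[:, :, j]) for j in range(a.shape[2])]
                )
        return out

    def flag_convergence(self, rhat_threshold: float = 1.1) -> None:
        """Attach split-R-hat diagnostics; append a warning if any exceed."""
        rhat = self.compute_rhat()
        self.diagnostics["rhat"] = rhat
        worst = max(float(np.nanmax(np.atleast_1d(v))) for v in rhat.values())
        self.diagnostics["rhat_max"] = worst
        if worst >= rhat_threshold:
            bad = [
                k
                for k, v in rhat.items()
                if np.nanmax(np.atleast_1d(v)) >= rhat_threshold
            ]
            self.warnings.append(
                f"non-convergence: split-R-hat >= {rhat_threshold} for {bad} "
                f"(max {worst:.3f})"
            )


def _slice_sample_log_scale(
    current: float,
    sum_sq: float,
    n_terms: int,
    prior_sd: float,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """Slice-sample a scale s with likelihood s^-n exp(-S/(2 s^2)) and
    Half-Normal(prior_sd) prior, parameterized as t = log s."""

    def logp(t: float) -> float:
        s2 = np.exp(2.0 * t)
        return -(n_terms - 1) * t - 0.5 * sum_sq / s2 - 0.5 * s2 / prior_sd**2

    t0 = np.log(max(current, _SCALE_FLOOR))
    ly = logp(t0) - rng.exponential()
    u = rng.uniform(0.0, width)
    lo, hi = t0 - u, t0 - u + width
    for _ in range(max_steps):
        if logp(lo) <= ly:
            break
        lo -= width
    for _ in range(max_steps):
        if logp(hi) <= ly:
            break
        hi += width
    for _ in range(100):
        t1 = rng.uniform(lo, hi)
        if logp(t1) > ly:
            return float(max(np.exp(t1), _SCALE_FLOOR))
        if t1 < t0:
            lo = t1
        else:
            hi = t1
    return current  # pragma: no cover - shrinkage exhausted


def _draw_mvn_from_precision(
    prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(prec^{-1} lin, prec^{-1}) via Cholesky of the precision."""
    try:
        c, low = cho_factor(prec, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(prec) / len(lin)
        c, low = cho_factor(prec + jitter * np.eye(len(lin)), lower=True)
    mean = cho_solve((c, low), lin)
    z = rng.standard_normal(len(lin))
    # solve L' x = z gives x ~ N(0, prec^{-1})
    return mean + solve_triangular(c, z, lower=True, trans="T")


class GaussianLMM:
    """Gaussian linear mixed model sampled by blocked Gibbs.

    Parameters
    ----------
    y : observations (n,)
    X : fixed-effects design (n, p); include the intercept column explicitly
    fixed_names : labels for the columns of X
    effects : random-effect blocks (GroupEffect / DenseEffect)
    beta_prior_mean, beta_prior_sd : independent normal priors on beta
        (scalar or length-p arrays)
    sigma_prior_sd : half-normal prior sd of the residual scale
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        fixed_names: Sequence[str],
        effects: Sequence[GroupEffect | DenseEffect] = (),
        beta_prior_mean=0.0,
        beta_prior_sd=10.0,
        sigma_prior_sd: float = 1.0,
        likelihood: bool = True,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        self.n, self.p = self.X.shape
        self.fixed_names = list(fixed_names)
        if len(self.fixed_names) != self.p:
            raise ValueError("fixed_names length must match X columns")
        self.effects = list(effects)
        self.beta_prior_mean = np.broadcast_to(
            np.asarray(beta_prior_mean, dtype=float), (self.p,)
        ).copy()
        self.beta_prior_sd = np.broadcast_to(
            np.asarray(beta_prior_sd, dtype=float), (self.p,)
        ).copy()
        if np.any(self.beta_prior_sd <= 0) or sigma_prior_sd <= 0:
            raise ValueError("prior scales must be positive")
        self.sigma_prior_sd = float(sigma_prior_sd)
        # likelihood=False turns the data term off: sampler then draws from
        # the prior, used as a correctness smoke test.
        self.likelihood = likelihood
        self._XtX = self.X.T @ self.X
        # intercept-mean relabeling moves (below) need an all-ones column 0
        self._has_intercept = bool(np.all(self.X[:, 0] == 1.0))
        self._precompute()

    def _precompute(self):
        self._eff_pre = []
        self._obs_level_k = None
        for k, eff in enumerate(self.effects):
            if isinstance(eff, GroupEffect):
                counts = np.bincount(eff.codes, minlength=eff.n_levels).astype(float)
                self._eff_pre.append(("group", counts))
                # an effect with exactly one observation per level is only
                # identified jointly with the residual: flag it for the
                # collapsed (tau, sigma) update
                if (
                    self._obs_level_k is None
                    and eff.n_levels == self.n
                    and np.all(counts == 1.0)
                ):
                    self._obs_level_k = k
            else:
                Z = np.asarray(eff.Z, dtype=float)
                self._eff_pre.append(("dense", Z.T @ Z))

    def _collapsed_tau_sigma(self, r, tau, sigma, prior_tau_sd, rng, n_steps=10):
        """Random-walk MH on (log tau, log sigma) with the observation-level
        effect integrated out: r_i ~ N(0, tau^2 + sigma^2) marginally."""
        ss = float(r @ r)
        n = len(r)

        def logp(lt, ls):
            t2, s2 = np.exp(2 * lt), np.exp(2 * ls)
            v = t2 + s2
            return (
                -0.5 * n * np.log(v)
                - 0.5 * ss / v
                - 0.5 * t2 / prior_tau_sd**2
                - 0.5 * s2 / self.sigma_prior_sd**2
                + lt
                + ls
            )

        lt, ls = np.log(max(tau, _SCALE_FLOOR)), np.log(max(sigma, _SCALE_FLOOR))
        lp = logp(lt, ls)
        for _ in range(n_steps):
            lt_n = lt + 0.3 * rng.standard_normal()
            ls_n = ls + 0.3 * rng.standard_normal()
            lp_n = logp(lt_n, ls_n)
            if np.log(rng.random()) < lp_n - lp:
                lt, ls, lp = lt_n, ls_n, lp_n
        return float(np.exp(lt)), float(np.exp(ls))

    def _run_chain(self, n_draws: int, burn_in: int, rng: np.random.Generator):
        n, p = self.n, self.p
        kept = n_draws - burn_in
        beta = self.beta_prior_mean.copy()
        sigma = max(float(np.std(self.y)), 0.1)
        taus = [0.5 * e.scale_prior_sd for e in self.effects]
        us = [
            np.zeros(e.n_levels if isinstance(e, GroupEffect) else e.Z.shape[1])
            for e in self.effects
        ]
        contribs = [np.zeros(n) for _ in self.effects]
        out_beta = np.empty((kept, p))
        out_sigma = np.empty(kept)
        out_tau = np.empty((kept, len(self.effects)))
        out_u = [np.empty((kept, len(u))) for u in us]

        prior_prec_beta = 1.0 / self.beta_prior_sd**2
        like = self.likelihood

        for it in range(n_draws):
            inv_s2 = 1.0 / sigma**2
            # --- beta block
            resid = self.y - sum(contribs) if self.effects else self.y
            prec = np.diag(prior_prec_beta).copy()
            lin = prior_prec_beta * self.beta_prior_mean
            if like:
                prec += self._XtX * inv_s2
                lin = lin + self.X.T @ resid * inv_s2
            beta = _draw_mvn_from_precision(prec, lin, rng)
            fx = self.X @ beta

            # --- random-effect blocks
            for k, eff in enumerate(self.effects):
                other = fx.copy()
                for j, c in enumerate(contribs):
                    if j != k:
                        other += c
                r_k = self.y - other
                tau = max(taus[k], _SCALE_FLOOR)
                kind, pre = self._eff_pre[k]
                if kind == "group":
                    counts = pre
                    prec_j = 1.0 / tau**2 + (counts * inv_s2 if like else 0.0)
                    lin_j = (
                        np.bincount(eff.codes, weights=r_k, minlength=eff.n_levels)
                        * inv_s2
                        if like
                        else np.zeros(eff.n_levels)
                    )
                    mean_j = lin_j / prec_j
                    us[k] = mean_j + rng.standard_normal(eff.n_levels) / np.sqrt(
                        prec_j
                    )
                    contribs[k] = us[k][eff.codes]
                else:
                    q = pre.shape[0]
                    prec_m = np.eye(q) / tau**2
                    lin_v = np.zeros(q)
                    if like:
                        prec_m += pre * inv_s2
                        lin_v = eff.Z.T @ r_k * inv_s2
                    us[k] = _draw_mvn_from_precision(prec_m, lin_v, rng)
                    contribs[k] = eff.Z @ us[k]
                if isinstance(eff, GroupEffect) and self._has_intercept and like:
                    # generalized-Gibbs sweep: shift the block mean into the
                    # intercept (likelihood-invariant; c drawn from its exact
                    # conditional under the priors), removing the additive
                    # redundancy that otherwise stalls mixing
                    q = eff.n_levels
                    prec_c = 1.0 / self.beta_prior_sd[0] ** 2 + q / tau**2
                    mean_c = (
                        (self.beta_prior_mean[0] - beta[0]) / self.beta_prior_sd[0] ** 2
                        + us[k].sum() / tau**2
                    ) / prec_c
                    c = mean_c + rng.standard_normal() / np.sqrt(prec_c)
                    us[k] -= c
                    beta[0] += c
                    fx = fx + c
                    r_k = r_k - c
                    contribs[k] = us[k][eff.codes]
                taus[k] = _slice_sample_log_scale(
                    taus[k],
                    float(us[k] @ us[k]),
                    len(us[k]),
                    eff.scale_prior_sd,
                    rng,
                )
                if like:
                    # ASIS interweaving: rescale in the non-centered
                    # parameterization (z = u / tau fixed, tau re-drawn from
                    # its conjugate regression conditional) to break the
                    # tau-u funnel
                    z = us[k] / max(taus[k], _SCALE_FLOOR)
                    xvec = z[eff.codes] if isinstance(eff, GroupEffect) else eff.Z @ z
                    xx = float(xvec @ xvec)
                    if xx > 0:
                        prec_w = xx * inv_s2 + 1.0 / eff.scale_prior_sd**2
                        mean_w = (float(xvec @ r_k) * inv_s2) / prec_w
                        w = mean_w + rng.standard_normal() / np.sqrt(prec_w)
                        taus[k] = max(abs(w), _SCALE_FLOOR)
                        us[k] = w * z
                        contribs[k] = (
                            us[k][eff.codes]
                            if isinstance(eff, GroupEffect)
                            else eff.Z @ us[k]
                        )

            # --- residual scale
            if like:
                resid_full = self.y - fx - sum(contribs) if self.effects else self.y - fx
                sigma = _slice_sample_log_scale(
                    sigma, float(resid_full @ resid_full), n, self.sigma_prior_sd, rng
                )
            else:
                sigma = abs(rng.standard_normal()) * self.sigma_prior_sd

            if like and self._obs_level_k is not None:
                k = self._obs_level_k
                eff = self.effects[k]
                other = fx.copy()
                for j, c in enumerate(contribs):
                    if j != k:
                        other += c
                r = self.y - other  # = u_k + eps observation-wise
                taus[k], sigma = self._collapsed_tau_sigma(
                    r, taus[k], sigma, eff.scale_prior_sd, rng
                )
                t2, s2 = taus[k] ** 2, sigma**2
                shrink = t2 / (t2 + s2)
                cond_sd = np.sqrt(t2 * s2 / (t2 + s2))
                u_new = shrink * r + cond_sd * rng.standard_normal(self.n)
                us[k] = np.empty(eff.n_levels)
                us[k][eff.codes] = u_new
                contribs[k] = u_new

            if it >= burn_in:
                j = it - burn_in
                out_beta[j] = beta
                out_sigma[j] = sigma
                out_tau[j] = taus
                for k in range(len(self.effects)):
                    out_u[k][j] = us[k]
        return out_beta, out_sigma, out_tau, out_u

    def sample(
        self,
        n_draws: int = 2000,
        burn_in: int = 500,
        n_chains: int = 2,
        seed: int = 0,
    ) -> PosteriorDraws:
        """Run ``n_chains`` independent chains of ``n_draws`` iterations each,
        discarding ``burn_in``, and return labelled draws."""
        if not (n_draws > burn_in >= 0):
            raise ValueError("need n_draws > burn_in >= 0")
        if n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")
        ss = np.random.SeedSequence(seed)
        chains = [self._run_chain(n_draws, burn_in, np.random.default_rng(s))
                  for s in ss.spawn(n_chains)]
        params: dict[str, np.ndarray] = {}
        coords: dict[str, Sequence] = {}
        params["beta"] = np.stack([c[0] for c in chains])
        coords["beta"] = self.fixed_names
        params["sigma"] = np.stack([c[1] for c in chains])
        if self.effects:
            tau = np.stack([c[2] for c in chains])
            for k, eff in enumerate(self.effects):
                params[f"tau_{eff.name}"] = tau[:, :, k]
                params[f"u_{eff.name}"] = np.stack([c[3][k] for c in chains])
                if eff.labels is not None:
                    coords[f"u_{eff.name}"] = list(eff.labels)
        draws = PosteriorDraws(params=params, coords=coords)
        draws.flag_convergence()
        return draws
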