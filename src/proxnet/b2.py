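"""The b2 model: Bayesian dyadic logistic regression for undirected binary
contact networks.

The b2 model is the undirected, unweighted reduction of the multilevel p2
model for social networks: reciprocity parameters, dyadic predictors and
network-level random effects are dropped, and each actor's sender and
receiver effects collapse into a single random effect.  For an eligible dyad
(i, j) the edge indicator is

    y_ij ~ Bernoulli(p_ij),
    logit(p_ij) = mu + sum_k gamma_k * (x_ik + x_jk) + A_i + A_j,
    A_i ~ Normal(0, sigma_a^2),

where ``mu`` is the density intercept, ``x_ik`` are actor-level covariates
(for an intervention comparison, a condition dummy), ``gamma_k`` their
effects on the log-odds scale, and ``A_i`` a latent per-actor contact
propensity shared across all of the actor's dyads.  Because an actor
covariate enters through both endpoints, a condition dummy shifts a
within-condition dyad's log-odds by ``2 * gamma``; the reported odds ratio
is ``exp(gamma)``, the per-actor convention.

Estimation is by Metropolis-within-Gibbs MCMC: random-walk proposals for
``mu``, each ``gamma_k`` and each ``A_i`` (with proposal scales adapted
during burn-in to a 20-50% acceptance rate and frozen afterwards, which
preserves detailed balance for the recorded draws), and a conjugate
inverse-gamma draw for ``sigma_a^2`` given the actor effects.  Priors are
the conventional diffuse choices for the p2 family: Normal(0, 10^2) on
``mu`` and each ``gamma_k``, Inverse-Gamma(0.001, 0.001) on ``sigma_a^2``.

The fixed effects are only weakly identified against linear combinations of
the actor effects (``mu`` against their overall mean, a ``gamma_k`` against
the covariate-weighted mean), so each sweep ends with *translation* moves
along those likelihood-invariant directions — e.g. ``mu + 2d, A_i - d`` —
accepted on the prior ratio alone.  They leave every dyad's log-odds
untouched, so they are exact Metropolis moves that remove the slow random
walk between the intercept / covariate effects and the random-effect means.

The posterior mean of ``exp(gamma_k)`` is reported as the odds-ratio point
estimate with a central 95% posterior percentile interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from .network import ContactNetwork

logger = logging.getLogger(__name__)

_ADAPT_WINDOW = 50
_ACC_LOW, _ACC_HIGH = 0.20, 0.50


@dataclass(frozen=True)
class B2Spec:
    """Priors and MCMC settings for :class:`B2Model`.

    ``prior_sd_fixed`` is the SD of the Normal(0, sd^2) priors on ``mu`` and
    each ``gamma_k``; ``prior_a``/``prior_b`` are the shape and scale of the
    Inverse-Gamma prior on ``sigma_a^2``.  ``n_iter`` counts post-burn-in
    sweeps per chain.  ``fix_sigma_a`` pins the actor-effect SD at a known
    value (0 gives the plain dyadic logistic regression, used for oracle
    checks); ``None`` (default) samples it.
    """

    prior_sd_fixed: float = 10.0
    prior_a: float = 0.001
    prior_b: float = 0.001
    n_chains: int = 4
    n_burnin: int = 2000
    n_iter: int = 10000
    thin: int = 1
    seed: int = 0
    fix_sigma_a: float | None = None
    store_actor_effects: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burnin, self.n_iter, self.thin) <= 0:
            raise ValueError("chain, burn-in, iteration and thinning counts must be positive")
        if self.prior_sd_fixed <= 0 or self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if self.fix_sigma_a is not None and self.fix_sigma_a < 0:
            raise ValueError("fix_sigma_a must be non-negative")


@dataclass(frozen=True)
class ORSummary:
    """Odds-ratio summary for one covariate: posterior mean of exp(gamma)
    with a central 95% credible interval."""

    covariate: str
    or_point: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:
        return (
            f"OR = {self.or_point:.2f}, "
            f"95% Credible Interval (CI) [{self.ci_low:.2f}, {self.ci_high:.2f}]"
        )


@dataclass(frozen=True)
class MLEResult:
    mu: float
    gamma: np.ndarray
    converged: bool
    n_iter: int


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class B2Model:
    """Dyadic contact-network model with actor covariates and actor random
    effects (the b2 model).

    Parameters
    ----------
    network : ContactNetwork
        Undirected binary network; only dyads flagged eligible in
        ``network.dyad_mask`` enter the likelihood, so structurally excluded
        pairs (e.g. cross-condition dyads in a stacked comparison network)
        carry no information.
    spec : B2Spec, optional
        Priors and sampler settings.

    Examples
    --------
    >>> model = B2Model(combined, B2Spec(n_chains=2, seed=7))
    >>> results = model.fit()
    >>> print(results.summarize_or("condition"))
    """

    def __init__(self, network: ContactNetwork, spec: B2Spec | None = None):
        if network.n_actors < 2 or network.n_eligible_dyads < 1:
            raise ValueError("network must have at least 2 actors and 1 eligible dyad")
        X = network.covariates.to_numpy(dtype=float)
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        self.network = network
        self.spec = spec or B2Spec()
        self.covariate_names = list(network.covariates.columns)

        iu, ju = np.nonzero(np.triu(network.dyad_mask, k=1))
        self._i_idx, self._j_idx = iu, ju
        self._y = network.adjacency[iu, ju].astype(float)
        self._X = X
        # dyad-level design for each covariate: x_i + x_j
        self._dx = [X[iu, k] + X[ju, k] for k in range(X.shape[1])]
        n = network.n_actors
        self._dyads_of = [
            np.flatnonzero((iu == i) | (ju == i)) for i in range(n)
        ]
        n_edges = self._y.sum()
        if n_edges == 0 or n_edges == len(self._y):
            warnings.warn(
                "network has no edges or all edges: the density intercept is "
                "weakly identified", UserWarning, stacklevel=2,
            )

    # -- sampling -----------------------------------------------------------

    def fit(self) -> "B2Results":
        """Run the Metropolis-within-Gibbs sampler and return the posterior."""
        spec = self.spec
        seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
        chains = [self._run_chain(np.random.default_rng(s)) for s in seeds]
        stack = lambda key: np.stack([c[key] for c in chains])  # noqa: E731
        actor = stack("A") if spec.store_actor_effects else None
        return B2Results(
            model=self,
            mu=stack("mu"),
            gamma=stack("gamma"),
            sigma_a=stack("sigma_a"),
            actor_effects=actor,
            acceptance={k: float(np.mean([c["acc"][k] for c in chains]))
                        for k in chains[0]["acc"]},
        )

    def _run_chain(self, rng: np.random.Generator) -> dict:
        spec = self.spec
        y, i_idx, j_idx = self._y, self._i_idx, self._j_idx
        dx = self._dx
        n = self.network.n_actors
        k = len(dx)
        D = len(y)

        fixed_sigma = spec.fix_sigma_a
        sample_A = not (fixed_sigma is not None and fixed_sigma == 0.0)

        # over-dispersed start: jitter around the empirical density intercept
        dens = (y.sum() + 1.0) / (D + 2.0)
        mu = float(np.log(dens / (1 - dens)) + rng.normal(0, 0.5))
        gamma = rng.normal(0, 0.1, size=k)
        A = np.zeros(n)
        sigma2 = float(fixed_sigma**2) if fixed_sigma is not None else 0.5

        eta = mu + A[i_idx] + A[j_idx]
        for kk in range(k):
            eta = eta + gamma[kk] * dx[kk]
        sp_sum = float(_softplus(eta).sum())

        y_sum = float(y.sum())
        ydx = [float((y * dx[kk]).sum()) for kk in range(k)]
        y_loc = [float(y[loc].sum()) for loc in self._dyads_of]
        prior_var = spec.prior_sd_fixed**2

        s_mu, s_gamma, s_A = 0.5, np.full(k, 0.5), 0.5
        s_tr = np.full(k + 1, 0.3)
        acc = {"mu": 0, "gamma": 0, "A": 0, "shift": 0}
        att = {"mu": 0, "gamma": 0, "A": 0, "shift": 0}
        win_acc = {"mu": 0, "gamma": np.zeros(k), "A": 0, "shift": np.zeros(k + 1)}
        win_att = {"mu": 0, "gamma": np.zeros(k), "A": 0, "shift": np.zeros(k + 1)}

        n_keep = spec.n_iter // spec.thin
        out_mu = np.empty(n_keep)
        out_gamma = np.empty((n_keep, k))
        out_sigma = np.empty(n_keep)
        out_A = np.empty((n_keep, n)) if spec.store_actor_effects else None
        kept = 0

        total = spec.n_burnin + spec.n_iter
        for sweep in range(total):
            burn = sweep < spec.n_burnin

            # intercept
            eps = rng.normal(0, s_mu)
            sp_prop = float(_softplus(eta + eps).sum())
            dll = eps * y_sum - (sp_prop - sp_sum)
            dll += (mu**2 - (mu + eps) ** 2) / (2 * prior_var)
            att["mu"] += 1
            win_att["mu"] += 1
            if np.log(rng.uniform()) < dll:
                mu += eps
                eta = eta + eps
                sp_sum = sp_prop
                acc["mu"] += 1
                win_acc["mu"] += 1

            # covariate effects
            for kk in range(k):
                eps = rng.normal(0, s_gamma[kk])
                eta_prop = eta + eps * dx[kk]
                sp_prop = float(_softplus(eta_prop).sum())
                dll = eps * ydx[kk] - (sp_prop - sp_sum)
                dll += (gamma[kk] ** 2 - (gamma[kk] + eps) ** 2) / (2 * prior_var)
                att["gamma"] += 1
                win_att["gamma"][kk] += 1
                if np.log(rng.uniform()) < dll:
                    gamma[kk] += eps
                    eta = eta_prop
                    sp_sum = sp_prop
                    acc["gamma"] += 1
                    win_acc["gamma"][kk] += 1

            # actor random effects (single-site, local likelihood)
            if sample_A:
                log_u = np.log(rng.uniform(size=n))
                eps_all = rng.normal(0, s_A, size=n)
                for i in range(n):
                    loc = self._dyads_of[i]
                    eps = eps_all[i]
                    eta_loc = eta[loc]
                    sp_old = _softplus(eta_loc)
                    sp_new = _softplus(eta_loc + eps)
                    d_sp = float(sp_new.sum() - sp_old.sum())
                    dll = eps * y_loc[i] - d_sp
                    dll += (A[i] ** 2 - (A[i] + eps) ** 2) / (2 * sigma2)
                    att["A"] += 1
                    win_att["A"] += 1
                    if log_u[i] < dll:
                        A[i] += eps
                        eta[loc] = eta_loc + eps
                        sp_sum += d_sp
                        acc["A"] += 1
                        win_acc["A"] += 1

                # conjugate inverse-gamma update of the actor variance
                if fixed_sigma is None:
                    shape = spec.prior_a + 0.5 * n
                    rate = spec.prior_b + 0.5 * float(A @ A)
                    sigma2 = rate / rng.gamma(shape)

                # translation moves along likelihood-invariant directions:
                # (mu, A) -> (mu + 2d, A - d) and, per covariate,
                # (gamma_k, A) -> (gamma_k + d, A - d * x_k); eta is
                # unchanged, acceptance depends on the priors only
                if sigma2 > 0:
                    d = rng.normal(0, s_tr[0])
                    dll = -float(((A - d) ** 2 - A**2).sum()) / (2 * sigma2)
                    dll += (mu**2 - (mu + 2 * d) ** 2) / (2 * prior_var)
                    att["shift"] += 1
                    win_att["shift"][0] += 1
                    if np.log(rng.uniform()) < dll:
                        A -= d
                        mu += 2 * d
                        acc["shift"] += 1
                        win_acc["shift"][0] += 1
                    for kk in range(k):
                        xk = self._X[:, kk]
                        d = rng.normal(0, s_tr[kk + 1])
                        dll = -float(((A - d * xk) ** 2 - A**2).sum()) / (2 * sigma2)
                        dll += (gamma[kk] ** 2 - (gamma[kk] + d) ** 2) / (2 * prior_var)
                        att["shift"] += 1
                        win_att["shift"][kk + 1] += 1
                        if np.log(rng.uniform()) < dll:
                            A -= d * xk
                            gamma[kk] += d
                            acc["shift"] += 1
                            win_acc["shift"][kk + 1] += 1

            # adapt proposal scales during burn-in only
            if burn and (sweep + 1) % _ADAPT_WINDOW == 0:
                s_mu = _adapt(s_mu, win_acc["mu"], win_att["mu"])
                for kk in range(k):
                    s_gamma[kk] = _adapt(s_gamma[kk], win_acc["gamma"][kk], win_att["gamma"][kk])
                if win_att["A"]:
                    s_A = _adapt(s_A, win_acc["A"], win_att["A"])
                for kk in range(k + 1):
                    if win_att["shift"][kk]:
                        s_tr[kk] = _adapt(s_tr[kk], win_acc["shift"][kk], win_att["shift"][kk])
                win_acc = {"mu": 0, "gamma": np.zeros(k), "A": 0, "shift": np.zeros(k + 1)}
                win_att = {"mu": 0, "gamma": np.zeros(k), "A": 0, "shift": np.zeros(k + 1)}

            if not burn and (sweep - spec.n_burnin + 1) % spec.thin == 0:
                out_mu[kept] = mu
                out_gamma[kept] = gamma
                out_sigma[kept] = np.sqrt(sigma2)
                if out_A is not None:
                    out_A[kept] = A
                kept += 1

            if not np.isfinite(sp_sum):
                raise FloatingPointError("non-finite likelihood during sampling")

        rates = {kk: (acc[kk] / att[kk] if att[kk] else np.nan) for kk in acc}
        return {"mu": out_mu, "gamma": out_gamma, "sigma_a": out_sigma,
                "A": out_A, "acc": rates}


def _adapt(scale: float, accepted: float, attempted: float) -> float:
    rate = accepted / attempted if attempted else 0.0
    if rate < _ACC_LOW:
        return scale * 0.7
    if rate > _ACC_HIGH:
        return scale * 1.4
    return scale


class B2Results:
    """Posterior draws and summaries from a fitted :class:`B2Model`.

    Draw arrays are shaped ``(n_chains, n_draws)`` (plus a trailing covariate
    or actor axis).  ``acceptance`` holds mean Metropolis acceptance rates
    per parameter block.
    """

    def __init__(self, model, mu, gamma, sigma_a, actor_effects, acceptance):
        self.model = model
        self.mu = mu
        self.gamma = gamma
        self.sigma_a = sigma_a
        self.actor_effects = actor_effects
        self.acceptance = acceptance
        self.covariate_names = model.covariate_names

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def _gamma_draws(self, covariate: str) -> np.ndarray:
        try:
            k = self.covariate_names.index(covariate)
        except ValueError:
            raise KeyError(f"unknown covariate {covariate!r}") from None
        return self.gamma[:, :, k]

    def posterior_mean(self, parameter: str) -> float:
        if parameter == "mu":
            return float(self.mu.mean())
        if parameter == "sigma_a":
            return float(self.sigma_a.mean())
        return float(self._gamma_draws(parameter).mean())

    def summarize_or(self, covariate: str) -> ORSummary:
        """Odds ratio for an actor covariate: posterior mean of
        ``exp(gamma)`` with central 95% percentile interval."""
        draws = np.exp(self._gamma_draws(covariate).ravel())
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return ORSummary(covariate, float(draws.mean()), float(lo), float(hi))

    def odds_ratios(self) -> pd.DataFrame:
        rows = [self.summarize_or(c) for c in self.covariate_names]
        return pd.DataFrame(
            {
                "covariate": [r.covariate for r in rows],
                "or_point": [r.or_point for r in rows],
                "ci_low": [r.ci_low for r in rows],
                "ci_high": [r.ci_high for r in rows],
            }
        )

    def _scalar_draws(self) -> dict[str, np.ndarray]:
        draws = {"mu": self.mu, "sigma_a": self.sigma_a}
        for k, name in enumerate(self.covariate_names):
            draws[f"gamma[{name}]"] = self.gamma[:, :, k]
        return draws

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and effective sample size per scalar parameter.

        R-hat needs at least two chains and is reported as NaN otherwise;
        values above 1.05 are logged as convergence warnings.
        """
        rows = []
        for name, d in self._scalar_draws().items():
            ess = float(az.ess(az.convert_to_dataset(d))["x"].values)
            if self.n_chains >= 2:
                rhat = float(az.rhat(az.convert_to_dataset(d))["x"].values)
            else:
                rhat = float("nan")
            if np.isfinite(rhat) and rhat > 1.05:
                logger.warning("diagnostics: R-hat for %s is %.3f (> 1.05)", name, rhat)
            rows.append((name, rhat, ess))
        return pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws table: chain, iter, parameter, value."""
        frames = []
        for name, d in self._scalar_draws().items():
            c, n = d.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "iter": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": d.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Text summary: posterior means, SDs, 95% intervals, diagnostics,
        and odds ratios in the two-decimal reporting style."""
        diag = self.diagnostics().set_index("parameter")
        lines = [
            "b2 dyadic contact-network model",
            f"actors: {self.model.network.n_actors}   "
            f"eligible dyads: {self.model.network.n_eligible_dyads}   "
            f"edges: {self.model.network.n_edges}",
            f"chains: {self.n_chains}   draws/chain: {self.n_draws}",
            "",
            f"{'parameter':<22}{'mean':>9}{'sd':>9}{'2.5%':>9}{'97.5%':>9}{'rhat':>7}{'ess':>8}",
        ]
        for name, d in self._scalar_draws().items():
            flat = d.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rhat, ess = diag.loc[name, "rhat"], diag.loc[name, "ess"]
            lines.append(
                f"{name:<22}{flat.mean():>9.3f}{flat.std(ddof=1):>9.3f}"
                f"{lo:>9.3f}{hi:>9.3f}{rhat:>7.3f}{ess:>8.0f}"
            )
        if self.covariate_names:
            lines.append("")
            for c in self.covariate_names:
                lines.append(f"{c}: {self.summarize_or(c)}")
        return "\n".join(lines)


def fit_b2(network: ContactNetwork, spec: B2Spec | None = None) -> B2Results:
    """Fit the b2 model; convenience wrapper around ``B2Model(...).fit()``."""
    return B2Model(network, spec).fit()


def summarize_or(posterior: B2Results, covariate: str) -> ORSummary:
    return posterior.summarize_or(covariate)


def diagnostics(posterior: B2Results) -> pd.DataFrame:
    return posterior.diagnostics()


def logistic_mle_oracle(network: ContactNetwork, tol: float = 1e-8, max_iter: int = 50) -> MLEResult:
    """Maximum-likelihood fit of the no-random-effects dyadic logistic model.

    With ``sigma_a = 0`` the b2 model reduces to plain logistic regression of
    the edge indicators on the dyadic design ``(1, x_i + x_j)``; this Newton
    solver provides an independent reference for that limit.  Convergence is
    declared when the gradient norm drops below ``tol``; separation (diverging
    coefficients or a singular Hessian) is reported via ``converged=False``.
    """
    iu, ju = np.nonzero(np.triu(network.dyad_mask, k=1))
    y = network.adjacency[iu, ju].astype(float)
    X = network.covariates.to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(y))] + [X[iu, k] + X[ju, k] for k in range(X.shape[1])])
    beta = np.zeros(Z.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(Z @ beta)
        grad = Z.T @ (y - p)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        hess = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.any(np.abs(beta) > 30):
            break
    if not converged:
        warnings.warn("logistic MLE did not converge (possible separation)",
                      UserWarning, stacklevel=2)
    return MLEResult(mu=float(beta[0]), gamma=beta[1:].copy(), converged=converged, n_iter=it)
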