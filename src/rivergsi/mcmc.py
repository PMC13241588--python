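"""A small gradient-based MCMC engine (Hamiltonian Monte Carlo).

Both hierarchical models in this package (the zero-inflated beta contribution
model and the zero-inflated Dirichlet composition model) expose a joint
log-posterior with analytic gradients; this module samples them with HMC using
dual-averaging step-size adaptation and a diagonal mass matrix estimated
during warmup.  Trajectory lengths are jittered uniformly to avoid resonance.

Split-R-hat and effective sample sizes are computed with arviz on the draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMCResult", "hmc_sample", "rhat_max", "ess_min"]


@dataclass
class HMCResult:
    draws: np.ndarray  # (chains, draws, dim)
    accept_rate: float
    step_sizes: list[float]
    divergences: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _find_initial_step(logp_grad, x, inv_mass, rng, start=0.1):
    """Crude variant of the usual heuristic: scale the step until a single
    leapfrog step gives an acceptance probability near 0.5."""
    eps = start
    lp, grad = logp_grad(x)
    for _ in range(30):
        p = rng.standard_normal(x.size) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(p**2 * inv_mass)
        p1 = p + 0.5 * eps * grad
        x1 = x + eps * inv_mass * p1
        lp1, g1 = logp_grad(x1)
        p1 = p1 + 0.5 * eps * g1
        h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
        dh = h1 - h0
        if not np.isfinite(dh):
            eps *= 0.5
            continue
        if dh > np.log(0.5):
            if dh < np.log(0.95):
                return eps
            eps *= 2.0
        else:
            eps *= 0.5
    return eps


def _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        lp, grad = logp_grad(x)
        if not np.all(np.isfinite(grad)) or not np.isfinite(lp):
            return x, p, lp, grad, False
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, lp, grad, True


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
    n_chains: int = 2,
    target_accept: float = 0.8,
    max_leapfrog: int = 24,
    init_jitter: float = 0.5,
) -> HMCResult:
    """Sample ``n_chains`` independent HMC chains.

    ``logp_grad(x)`` must return ``(log posterior, gradient)``.  ``x0`` is a
    starting point on the unconstrained scale; chains are initialised from it
    with independent N(0, init_jitter^2) perturbations.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    all_draws = np.empty((n_chains, n_draws, dim))
    accepts, divergences, step_sizes = [], 0, []

    # dual-averaging constants (Hoffman & Gelman 2014)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    for chain in range(n_chains):
        x = x0 + init_jitter * rng.standard_normal(dim)
        inv_mass = np.ones(dim)
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            x = x0.copy()
            lp, grad = logp_grad(x)
        eps = _find_initial_step(logp_grad, x, inv_mass, rng)
        mu_da, log_eps_bar, h_bar = np.log(10 * eps), 0.0, 0.0
        window = (int(0.10 * n_warmup), int(0.60 * n_warmup))
        wsamples = []

        for it in range(n_warmup + n_draws):
            adapting = it < n_warmup
            n_steps = int(rng.integers(1, max_leapfrog + 1))
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = lp - 0.5 * np.sum(p**2 * inv_mass)
            x1, p1, lp1, grad1, ok = _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass)
            if ok:
                h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
                dh = h1 - h0
                alpha = min(1.0, np.exp(min(dh, 0.0)))
                if dh < -1000:
                    divergences += int(not adapting)
                    alpha = 0.0
            else:
                alpha = 0.0
            if rng.random() < alpha:
                x, lp, grad = x1, lp1, grad1
            if adapting:
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
                log_eps = mu_da - np.sqrt(m) / gamma * h_bar
                eta = m**-kappa
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                eps = np.exp(log_eps)
                if window[0] <= it < window[1]:
                    wsamples.append(x.copy())
                if it == window[1] - 1 and len(wsamples) > 10:
                    var = np.var(np.asarray(wsamples), axis=0)
                    inv_mass = np.clip(var, 1e-6, None)
                    # re-initialise step-size adaptation for the new metric
                    eps = _find_initial_step(logp_grad, x, inv_mass, rng)
                    mu_da, log_eps_bar, h_bar = np.log(10 * eps), 0.0, 0.0
                if it == n_warmup - 1:
                    eps = np.exp(log_eps_bar)
            else:
                accepts.append(alpha)
                all_draws[chain, it - n_warmup] = x
        step_sizes.append(float(eps))

    return HMCResult(
        draws=all_draws,
        accept_rate=float(np.mean(accepts)) if accepts else float("nan"),
        step_sizes=step_sizes,
        divergences=divergences,
    )


def _to_idata(named_draws: dict[str, np.ndarray]):
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.from_dict(posterior=named_draws)


def rhat_max(named_draws: dict[str, np.ndarray]) -> float:
    """Largest split-R-hat over all named parameters.

    Each value in ``named_draws`` has shape (chains, draws, ...).
    """
    import arviz as az

    idata = _to_idata(named_draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(idata)
    return float(max(np.nanmax(np.atleast_1d(r[v].values)) for v in r.data_vars))


def ess_min(named_draws: dict[str, np.ndarray]) -> float:
    import arviz as az

    idata = _to_idata(named_draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = az.ess(idata)
    return float(min(np.nanmin(np.atleast_1d(e[v].values)) for v in e.data_vars))
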