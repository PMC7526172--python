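"""Vectorized Hamiltonian Monte Carlo for the GLMM posteriors.

All chains advance in lockstep as rows of a (chains, dim) state matrix, so
one leapfrog step costs a single vectorized gradient evaluation.  Warmup
adapts a scalar step size by dual averaging (Nesterov-style, targeting a
mean Metropolis acceptance across chains) and a diagonal mass matrix from
the sample variance of a central warmup window.  Sampling uses a jittered
trajectory length to break periodic resonances.

The target densities here (Poisson log-link / binomial logit GLMMs with
Gaussian priors and non-centered random intercepts) are smooth and close to
log-concave, which is what makes this comparatively simple scheme reliable;
convergence is nevertheless always checked downstream with split-R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

Potential = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class HMCResult:
    draws: np.ndarray        # (chains, kept iterations, dim)
    accept_rate: np.ndarray  # per chain, sampling phase only
    step_size: float
    inv_mass: np.ndarray     # diagonal of M^{-1} (posterior variance estimate)


def _leapfrog(potential: Potential, q, p, grad, eps: float, n_steps: int, inv_mass):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * p * inv_mass
        logp, grad = potential(q)
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_initial_step(potential: Potential, q, logp, grad, inv_mass, rng) -> float:
    """Heuristic of Hoffman & Gelman: double/halve until accept crosses 1/2."""
    eps = 0.1 / max(1.0, q.shape[1]) ** 0.25
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    for _ in range(50):
        q1, p1, logp1, _ = _leapfrog(potential, q, p, grad, eps, 1, inv_mass)
        dh = (logp1 - 0.5 * np.sum(p1 * p1 * inv_mass, axis=1)) - (
            logp - 0.5 * np.sum(p * p * inv_mass, axis=1)
        )
        a = float(np.exp(np.clip(np.nanmean(dh), -50, 50)))
        if not np.isfinite(a):
            a = 0.0
        if 1.0 / 3.0 < a < 3.0:  # acceptance within (0.25, 0.75)-ish band
            break
        eps = eps * 2.0 if a > 1.0 else eps * 0.5
    return eps


def sample_hmc(
    potential: Potential,
    init: np.ndarray,
    iterations: int,
    warmup: int,
    seed: int,
    target_accept: float = 0.8,
    trajectory_length: float = 1.2,
    max_leapfrog: int = 64,
    init_inv_mass: np.ndarray | None = None,
) -> HMCResult:
    """Run ``init.shape[0]`` chains for ``iterations`` steps, keep post-warmup.

    ``potential`` maps a (chains, dim) position matrix to (log density,
    gradient); densities need only be known up to a constant.
    ``init_inv_mass`` seeds the diagonal inverse mass matrix (a per-dimension
    posterior variance guess, e.g. from Fisher information at the starting
    point); warmup refines it.  Without it, heterogeneous parameter scales
    can make the adaptation windows far too short.
    """
    if not (0 < warmup < iterations):
        raise ValueError("need 0 < warmup < iterations")
    rng = np.random.default_rng(seed)
    q = np.array(init, dtype=float)
    n_chains, dim = q.shape
    logp, grad = potential(q)
    if not np.all(np.isfinite(logp)):
        raise ValueError("initial position has non-finite log density")

    if init_inv_mass is None:
        inv_mass = np.ones(dim)
    else:
        inv_mass = np.clip(np.asarray(init_inv_mass, dtype=float), 1e-8, 1e8)
    eps = _find_initial_step(potential, q, logp, grad, inv_mass, rng)

    # dual averaging state (re-initialized after the mass-matrix update)
    def fresh_da(eps0: float):
        return {"mu": np.log(10.0 * eps0), "log_eps_bar": np.log(eps0), "h": 0.0, "t": 0}

    da = fresh_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    # two mass-adaptation windows: a rough estimate early, refined once the
    # sampler moves at roughly the right scale (guards against freezing a
    # variance estimated from barely-moving early chains)
    windows = [
        (int(warmup * 0.15), int(warmup * 0.45)),
        (int(warmup * 0.50), int(warmup * 0.90)),
    ]
    window: list[np.ndarray] = []

    kept = np.empty((n_chains, iterations - warmup, dim))
    n_accept = np.zeros(n_chains)

    for it in range(iterations):
        adapting = it < warmup
        eps_it = eps if adapting else eps * rng.uniform(0.8, 1.2)
        n_steps = int(np.clip(round(trajectory_length / eps_it), 1, max_leapfrog))

        p0 = rng.standard_normal((n_chains, dim)) / np.sqrt(inv_mass)
        q1, p1, logp1, grad1 = _leapfrog(potential, q, p0, grad, eps_it, n_steps, inv_mass)
        ke0 = 0.5 * np.sum(p0 * p0 * inv_mass, axis=1)
        ke1 = 0.5 * np.sum(p1 * p1 * inv_mass, axis=1)
        dh = (logp1 - ke1) - (logp - ke0)
        dh = np.where(np.isfinite(dh), dh, -np.inf)
        accept_prob = np.exp(np.minimum(dh, 0.0))
        acc = rng.random(n_chains) < accept_prob
        q[acc] = q1[acc]
        logp[acc] = logp1[acc]
        grad[acc] = grad1[acc]

        if adapting:
            # dual averaging on the chain-mean acceptance statistic
            da["t"] += 1
            eta = 1.0 / (da["t"] + t0)
            da["h"] = (1 - eta) * da["h"] + eta * (target_accept - float(np.mean(accept_prob)))
            log_eps = da["mu"] - np.sqrt(da["t"]) / gamma * da["h"]
            w = da["t"] ** (-kappa)
            da["log_eps_bar"] = w * log_eps + (1 - w) * da["log_eps_bar"]
            eps = float(np.exp(log_eps))
            in_window = any(lo <= it < hi for lo, hi in windows)
            if in_window:
                window.append(q.copy())
            if any(it == hi - 1 for _, hi in windows) and len(window) >= 10:
                pool = np.concatenate(window, axis=0)  # chains pooled
                n_w = pool.shape[0]
                var = pool.var(axis=0, ddof=1)
                # regularize toward the current mass (Stan-style shrinkage)
                w = n_w / (n_w + 5.0)
                inv_mass = np.clip(w * var + (1 - w) * inv_mass, 1e-8, 1e8)
                window.clear()
                eps = _find_initial_step(potential, q, logp, grad, inv_mass, rng)
                da = fresh_da(eps)
            if it == warmup - 1:
                eps = float(np.exp(da["log_eps_bar"]))
        else:
            kept[:, it - warmup, :] = q
            n_accept += acc

    return HMCResult(
        draws=kept,
        accept_rate=n_accept / max(1, iterations - warmup),
        step_size=eps,
        inv_mass=inv_mass,
    )
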