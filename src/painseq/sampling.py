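"""Hamiltonian Monte Carlo with warmup adaptation.

A gradient-based sampler in the Stan mould, sized for the hierarchical
posteriors in this package (tens to ~100 dimensions, cheap analytic
gradients): leapfrog integration with a jittered number of steps, dual
averaging of the step size towards a target acceptance statistic, and
diagonal mass-matrix estimation over expanding warmup windows.

The sampler is deterministic given its seed; chains are seeded independently
via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainResult", "hmc_chain", "sample_chains"]


@dataclass
class ChainResult:
    draws: np.ndarray            # (n_draws, dim)
    logp: np.ndarray             # (n_draws,)
    accept_rate: float
    divergences: int
    step_size: float
    inv_mass: np.ndarray = field(repr=False, default=None)


def _leapfrog(x, p, grad, step, n_steps, logp_grad, inv_mass):
    """Standard leapfrog; returns (x, p, logp, grad, diverged)."""
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        x = x + step * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, -np.inf, grad, True
        if i < n_steps - 1:
            p = p + step * grad
    p = p + 0.5 * step * grad
    return x, p, logp, grad, False


def hmc_chain(logp_grad, x0, n_warmup, n_draws, rng,
              target_accept: float = 0.8, max_leapfrog: int = 32,
              init_step: float = 0.1) -> ChainResult:
    """Run one HMC chain.

    ``logp_grad(x) -> (logp, grad)`` on the unconstrained scale.  Warmup
    adapts the step size throughout and re-estimates the diagonal mass
    matrix twice (at 50% and 90% of warmup) from the preceding window,
    restarting dual averaging after each mass update.  Transitions whose
    Hamiltonian error exceeds 1000 count as divergent and are rejected.
    """
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    logp, grad = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    # dual averaging state (Hoffman & Gelman 2014 defaults)
    def _reset_da(step):
        return {"mu": np.log(10.0 * step), "log_step": np.log(step),
                "log_step_bar": 0.0, "h_bar": 0.0, "m": 0}

    da = _reset_da(init_step)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    step = init_step

    mass_updates = {int(0.5 * n_warmup), int(0.9 * n_warmup)} if n_warmup >= 20 else set()
    window_start = int(0.15 * n_warmup)
    window = []

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    n_accept = 0.0
    divergences = 0
    total_iters = n_warmup + n_draws

    for it in range(total_iters):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        h0 = -logp + 0.5 * np.sum(inv_mass * p0 * p0)
        x1, p1, logp1, grad1, diverged = _leapfrog(
            x, p0, grad, step, n_steps, logp_grad, inv_mass)
        if diverged:
            accept_prob = 0.0
        else:
            h1 = -logp1 + 0.5 * np.sum(inv_mass * p1 * p1)
            delta_h = h0 - h1
            if delta_h < -1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, np.exp(min(delta_h, 0.0)))
                if np.log(rng.uniform()) < delta_h:
                    x, logp, grad = x1, logp1, grad1
        if diverged and not warming:
            divergences += 1

        if warming:
            # dual averaging step-size update
            da["m"] += 1
            m = da["m"]
            eta = 1.0 / (m + t0)
            da["h_bar"] = (1.0 - eta) * da["h_bar"] + eta * (target_accept - accept_prob)
            da["log_step"] = da["mu"] - np.sqrt(m) / gamma * da["h_bar"]
            w = m ** (-kappa)
            da["log_step_bar"] = w * da["log_step"] + (1.0 - w) * da["log_step_bar"]
            step = float(np.exp(da["log_step"]))

            if it >= window_start:
                window.append(x.copy())
            if (it + 1) in mass_updates and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0)
                n = len(window)
                # regularise towards unit mass as Stan does
                inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-10)
                window = []
                step = float(np.exp(da["log_step_bar"]))
                da = _reset_da(max(step, 1e-8))
        else:
            if it == n_warmup and n_warmup > 0:
                pass
            n_accept += accept_prob
            draws[it - n_warmup] = x
            logps[it - n_warmup] = logp

        if it + 1 == n_warmup and n_warmup > 0:
            step = float(np.exp(da["log_step_bar"]))

    return ChainResult(
        draws=draws, logp=logps,
        accept_rate=float(n_accept / max(n_draws, 1)),
        divergences=divergences, step_size=step, inv_mass=inv_mass,
    )


def sample_chains(logp_grad, dim, n_chains, n_warmup, n_draws, seed,
                  init_fn=None, **hmc_kwargs):
    """Run ``n_chains`` independent HMC chains.

    ``init_fn(rng) -> x0`` supplies overdispersed starting points (default:
    N(0, 0.5) on every coordinate).  Returns (draws (chains, draws, dim),
    list of :class:`ChainResult`).
    """
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = np.empty((n_chains, n_draws, dim))
    results = []
    for c, sub in enumerate(seqs):
        rng = np.random.default_rng(sub)
        x0 = init_fn(rng) if init_fn is not None else 0.5 * rng.standard_normal(dim)
        res = hmc_chain(logp_grad, x0, n_warmup, n_draws, rng, **hmc_kwargs)
        all_draws[c] = res.draws
        results.append(res)
    return all_draws, results
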