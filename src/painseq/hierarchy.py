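"""Non-centred hierarchical parametrisation shared by all five models.

Every native parameter ``theta_ij`` (subject i, parameter j) is expressed as

    theta_ij = link_j(mu_j + tau_j * eta_ij)

with group location ``mu_j ~ N(0, 1)``, group scale ``tau_j ~
half-Student-t(3, 0, 1)`` and standard-Normal subject offsets ``eta_ij``.
Links map the unconstrained scale onto each parameter's support:

* ``unit``  — a logistic approximation to the standard-Normal CDF, for
  parameters in (0, 1) (learning rate alpha, perceptual weight gamma);
* ``pos``   — exp, for strictly positive scale-like parameters
  (xi, s, v, w0, epsilon, C);
* ``scale50`` — multiplication by 50, for response-scale locations (E0, R),
  turning the N(0, 1) group prior into a wide N(0, 50^2) on the 0-100 scale.

The sampler works on the unconstrained vector ``x = [mu, log tau, eta]``;
the half-t prior on tau carries the log-link Jacobian.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["PARAM_TABLE", "ParamSpec", "HierarchicalSpec", "phi_approx"]

_RESPONSE_SCALE = 50.0


def phi_approx(x):
    """Logistic approximation to the standard-Normal CDF."""
    x = np.asarray(x, dtype=float)
    arg = np.clip(0.07056 * x ** 3 + 1.5976 * x, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(-arg))


def _phi_approx_deriv(x):
    p = phi_approx(x)
    return p * (1.0 - p) * (0.21168 * x ** 2 + 1.5976)


_LINKS = {
    "unit": (phi_approx, _phi_approx_deriv),
    "pos": (np.exp, np.exp),
    "scale50": (lambda x: _RESPONSE_SCALE * np.asarray(x, dtype=float),
                lambda x: np.full_like(np.asarray(x, dtype=float), _RESPONSE_SCALE)),
}


class ParamSpec:
    """One native parameter: its name and link."""

    __slots__ = ("name", "link")

    def __init__(self, name: str, link: str):
        if link not in _LINKS:
            raise ValueError(f"unknown link {link!r}")
        self.name = name
        self.link = link

    def __repr__(self):
        return f"ParamSpec({self.name!r}, {self.link!r})"


#: native parameter order per model; must match painseq._kernels
PARAM_TABLE: dict[str, list[ParamSpec]] = {
    "rl": [ParamSpec("alpha", "unit"), ParamSpec("xi", "pos"),
           ParamSpec("E0", "scale50"), ParamSpec("C", "pos")],
    "erl": [ParamSpec("alpha", "unit"), ParamSpec("xi", "pos"),
            ParamSpec("E0", "scale50"), ParamSpec("C", "pos"),
            ParamSpec("gamma", "unit")],
    "kf": [ParamSpec("s", "pos"), ParamSpec("v", "pos"), ParamSpec("xi", "pos"),
           ParamSpec("E0", "scale50"), ParamSpec("w0", "pos"), ParamSpec("C", "pos")],
    "ekf": [ParamSpec("s", "pos"), ParamSpec("v", "pos"), ParamSpec("xi", "pos"),
            ParamSpec("E0", "scale50"), ParamSpec("w0", "pos"), ParamSpec("C", "pos"),
            ParamSpec("eps", "pos")],
    "random": [ParamSpec("R", "scale50"), ParamSpec("xi", "pos"),
               ParamSpec("C", "pos")],
}

_HALF_T_CONST = (math.log(2.0) + math.lgamma(2.0) - math.lgamma(1.5)
                 - 0.5 * math.log(3.0 * math.pi))


def _log_half_t3(tau):
    """log density of half-Student-t(3, 0, 1)."""
    return _HALF_T_CONST - 2.0 * np.log1p(tau ** 2 / 3.0)


class HierarchicalSpec:
    """Packing/unpacking and log-prior machinery for one model's hierarchy.

    The unconstrained vector is ``[mu (P), log tau (P), eta (ns*P)]`` with
    ``eta`` stored subject-major.
    """

    def __init__(self, model_id: str, n_subjects: int):
        if model_id not in PARAM_TABLE:
            raise ValueError(f"unknown model_id {model_id!r}")
        if n_subjects < 2:
            raise ValueError("hierarchical fitting needs >= 2 subjects")
        self.model_id = model_id
        self.params = PARAM_TABLE[model_id]
        self.n_subjects = n_subjects
        self.n_params = len(self.params)
        self.dim = 2 * self.n_params + n_subjects * self.n_params

    # ---- layout -----------------------------------------------------
    def unpack(self, x: np.ndarray):
        P, ns = self.n_params, self.n_subjects
        mu = x[:P]
        lam = x[P:2 * P]
        eta = x[2 * P:].reshape(ns, P)
        return mu, lam, eta

    def pack(self, mu, lam, eta) -> np.ndarray:
        return np.concatenate([np.ravel(mu), np.ravel(lam), np.ravel(eta)])

    @property
    def names(self) -> list[str]:
        """Flat parameter names matching the unconstrained layout."""
        out = [f"mu[{p.name}]" for p in self.params]
        out += [f"log_tau[{p.name}]" for p in self.params]
        for i in range(self.n_subjects):
            out += [f"eta[{p.name},{i}]" for p in self.params]
        return out

    # ---- transforms -------------------------------------------------
    def natives(self, x: np.ndarray) -> np.ndarray:
        """Native per-subject parameters theta (ns, P) for one draw."""
        mu, lam, eta = self.unpack(x)
        z = mu + np.exp(lam) * eta
        theta = np.empty_like(z)
        for j, p in enumerate(self.params):
            theta[:, j] = _LINKS[p.link][0](z[:, j])
        return theta

    def group_location_native(self, mu: np.ndarray) -> np.ndarray:
        """Group location mapped through each parameter's link."""
        return np.array([_LINKS[p.link][0](mu[j]) for j, p in enumerate(self.params)])

    # ---- log posterior ----------------------------------------------
    def logp_and_grad(self, x: np.ndarray, loglik_grad_fn):
        """Log posterior density and gradient on the unconstrained scale.

        ``loglik_grad_fn(theta (ns, P)) -> (ll, dll/dtheta (ns, P))``.
        """
        P = self.n_params
        mu, lam, eta = self.unpack(x)
        if np.any(np.abs(lam) > 300.0):
            return -np.inf, np.zeros_like(x)
        tau = np.exp(lam)
        z = mu + tau * eta
        # far outside any plausible region the exp links under/overflow and
        # the likelihood kernels would divide by zero; treat as -inf density
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) > 300.0):
            return -np.inf, np.zeros_like(x)

        theta = np.empty_like(z)
        dlink = np.empty_like(z)
        for j, p in enumerate(self.params):
            f, fprime = _LINKS[p.link]
            theta[:, j] = f(z[:, j])
            dlink[:, j] = fprime(z[:, j])

        ll, g_theta = loglik_grad_fn(theta)
        g_z = g_theta * dlink

        logp = (ll
                - 0.5 * np.sum(mu ** 2)
                + np.sum(_log_half_t3(tau) + lam)       # + log-link Jacobian
                - 0.5 * np.sum(eta ** 2))

        g_mu = g_z.sum(axis=0) - mu
        # d/d lam [log half-t(tau) + lam] = -4 tau^2/(3+tau^2) + 1
        g_lam = (g_z * eta).sum(axis=0) * tau + 1.0 - 4.0 * tau ** 2 / (3.0 + tau ** 2)
        g_eta = g_z * tau - eta
        grad = np.empty_like(x)
        grad[:P] = g_mu
        grad[P:2 * P] = g_lam
        grad[2 * P:] = g_eta.ravel()
        return logp, grad
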