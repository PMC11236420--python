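"""Compiled per-trial likelihood kernels with analytic parameter gradients.

Each observer model gets one per-subject kernel that runs the belief
recursion forward while propagating the tangents (forward-mode derivatives)
of the trial-wise response mean with respect to the model's native
parameters.  The Gaussian response likelihood and its gradient are assembled
in the same pass, so one call yields the subject's log-likelihood, its
gradient in native-parameter space, and the pointwise per-trial
log-likelihood needed for LOO.

Native parameter order (must match ``painseq.hierarchy.PARAM_TABLE``):

    rl      [alpha, xi, E0, C]
    erl     [alpha, xi, E0, C, gamma]
    kf      [s, v, xi, E0, w0, C]
    ekf     [s, v, xi, E0, w0, C, eps]
    random  [R, xi, C]

Derivative bookkeeping (shared by all kernels): with response r, mean mu,
sd = xi * exp((1 - c) / C) and z = (r - mu) / sd,

    d ll / d mu = z / sd
    d ll / d xi = (z^2 - 1) / xi
    d ll / d C  = (z^2 - 1) * (-(1 - c) / C^2)
"""

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _rl_subject(theta, inputs, resp, conf, is_pred, answered, pointwise, grad):
    alpha, xi, E0, C = theta[0], theta[1], theta[2], theta[3]
    E = E0
    dEa = 0.0   # dE/dalpha
    dE0 = 1.0   # dE/dE0
    ll = 0.0
    T = inputs.shape[0]
    for t in range(T):
        N = inputs[t]
        delta = N - E
        E_next = E + alpha * delta
        dEa_next = (1.0 - alpha) * dEa + delta
        dE0_next = (1.0 - alpha) * dE0
        if is_pred[t]:
            mu = E_next
            dmu_a, dmu_E0 = dEa_next, dE0_next
        else:
            mu = N
            dmu_a, dmu_E0 = 0.0, 0.0
        if answered[t]:
            k = (1.0 - conf[t]) / C
            sd = xi * np.exp(k)
            z = (resp[t] - mu) / sd
            lt = -0.5 * LOG2PI - np.log(sd) - 0.5 * z * z
            pointwise[t] = lt
            ll += lt
            dmu = z / sd
            zz1 = z * z - 1.0
            grad[0] += dmu * dmu_a
            grad[1] += zz1 / xi
            grad[2] += dmu * dmu_E0
            grad[3] += zz1 * (-k / C)
        else:
            pointwise[t] = 0.0
        E, dEa, dE0 = E_next, dEa_next, dE0_next
    return ll


@njit(cache=True)
def _erl_subject(theta, inputs, resp, conf, is_pred, answered, pointwise, grad):
    alpha, xi, E0, C, gamma = theta[0], theta[1], theta[2], theta[3], theta[4]
    E = E0
    dEa = 0.0
    dE0 = 1.0
    dEg = 0.0   # dE/dgamma
    ll = 0.0
    T = inputs.shape[0]
    for t in range(T):
        N = inputs[t]
        P = (1.0 - gamma) * N + gamma * E
        dPa = gamma * dEa
        dPE0 = gamma * dE0
        dPg = (E - N) + gamma * dEg
        shrink = 1.0 - alpha * (1.0 - gamma)
        E_next = E + alpha * (P - E)
        dEa_next = shrink * dEa + (P - E)
        dE0_next = shrink * dE0
        dEg_next = shrink * dEg + alpha * (E - N)
        if is_pred[t]:
            mu, dmu_a, dmu_E0, dmu_g = E_next, dEa_next, dE0_next, dEg_next
        else:
            mu, dmu_a, dmu_E0, dmu_g = P, dPa, dPE0, dPg
        if answered[t]:
            k = (1.0 - conf[t]) / C
            sd = xi * np.exp(k)
            z = (resp[t] - mu) / sd
            lt = -0.5 * LOG2PI - np.log(sd) - 0.5 * z * z
            pointwise[t] = lt
            ll += lt
            dmu = z / sd
            zz1 = z * z - 1.0
            grad[0] += dmu * dmu_a
            grad[1] += zz1 / xi
            grad[2] += dmu * dmu_E0
            grad[3] += zz1 * (-k / C)
            grad[4] += dmu * dmu_g
        else:
            pointwise[t] = 0.0
        E, dEa, dE0, dEg = E_next, dEa_next, dE0_next, dEg_next
    return ll


@njit(cache=True)
def _kf_subject(theta, inputs, resp, conf, is_pred, answered, pointwise, grad):
    s, v, xi, E0, w0, C = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    s2 = s * s
    m = E0
    w2 = w0 * w0
    # tangents of (m, w2) wrt (s, v, E0, w0)
    dm = np.zeros(4)
    dw = np.zeros(4)
    dm[2] = 1.0
    dw[3] = 2.0 * w0
    ll = 0.0
    T = inputs.shape[0]
    for t in range(T):
        N = inputs[t]
        denom = w2 + s2
        gain = w2 / denom
        # d gain / dx = (s2 * dw - w2 * ds2) / denom^2
        dgain = np.empty(4)
        for j in range(4):
            ds2 = 2.0 * s if j == 0 else 0.0
            dgain[j] = (s2 * dw[j] - w2 * ds2) / (denom * denom)
        err = N - m
        m_next = m + gain * err
        w2_next = w2 * (1.0 - gain) + v * v
        dm_next = np.empty(4)
        dw_next = np.empty(4)
        for j in range(4):
            dm_next[j] = dm[j] * (1.0 - gain) + dgain[j] * err
            dw_next[j] = dw[j] * (1.0 - gain) - w2 * dgain[j]
        dw_next[1] += 2.0 * v
        if answered[t]:
            k = (1.0 - conf[t]) / C
            sd = xi * np.exp(k)
            if is_pred[t]:
                mu = m_next
                z = (resp[t] - mu) / sd
                dmu = z / sd
                grad[0] += dmu * dm_next[0]
                grad[1] += dmu * dm_next[1]
                grad[3] += dmu * dm_next[2]
                grad[4] += dmu * dm_next[3]
            else:
                mu = N
                z = (resp[t] - mu) / sd
            lt = -0.5 * LOG2PI - np.log(sd) - 0.5 * z * z
            pointwise[t] = lt
            ll += lt
            zz1 = z * z - 1.0
            grad[2] += zz1 / xi
            grad[5] += zz1 * (-k / C)
        else:
            pointwise[t] = 0.0
        m, w2 = m_next, w2_next
        dm, dw = dm_next, dw_next
    return ll


@njit(cache=True)
def _ekf_subject(theta, inputs, resp, conf, is_pred, answered, pointwise, grad):
    s, v, xi, E0, w0, C, eps = (theta[0], theta[1], theta[2], theta[3],
                                theta[4], theta[5], theta[6])
    s2 = s * s
    e2 = eps * eps
    m = E0
    w2 = w0 * w0
    # tangents of (m, w2) wrt (s, v, E0, w0, eps)
    dm = np.zeros(5)
    dw = np.zeros(5)
    dm[2] = 1.0
    dw[3] = 2.0 * w0
    ll = 0.0
    T = inputs.shape[0]
    for t in range(T):
        N = inputs[t]
        D = e2 + s2 + w2
        gamma = e2 / D
        gain = w2 / D
        dgamma = np.empty(5)
        dgain = np.empty(5)
        for j in range(5):
            ds2 = 2.0 * s if j == 0 else 0.0
            de2 = 2.0 * eps if j == 4 else 0.0
            dD = ds2 + de2 + dw[j]
            dgamma[j] = (de2 * D - e2 * dD) / (D * D)
            dgain[j] = (dw[j] * D - w2 * dD) / (D * D)
        err = N - m
        P = gamma * m + (1.0 - gamma) * N
        m_next = m + gain * err
        w2_next = w2 * (1.0 - gain) + v * v
        dP = np.empty(5)
        dm_next = np.empty(5)
        dw_next = np.empty(5)
        for j in range(5):
            dP[j] = dgamma[j] * (m - N) + gamma * dm[j]
            dm_next[j] = dm[j] * (1.0 - gain) + dgain[j] * err
            dw_next[j] = dw[j] * (1.0 - gain) - w2 * dgain[j]
        dw_next[1] += 2.0 * v
        if answered[t]:
            k = (1.0 - conf[t]) / C
            sd = xi * np.exp(k)
            if is_pred[t]:
                mu = m_next
                dmu_vec = dm_next
            else:
                mu = P
                dmu_vec = dP
            z = (resp[t] - mu) / sd
            lt = -0.5 * LOG2PI - np.log(sd) - 0.5 * z * z
            pointwise[t] = lt
            ll += lt
            dmu = z / sd
            zz1 = z * z - 1.0
            grad[0] += dmu * dmu_vec[0]
            grad[1] += dmu * dmu_vec[1]
            grad[2] += zz1 / xi
            grad[3] += dmu * dmu_vec[2]
            grad[4] += dmu * dmu_vec[3]
            grad[5] += zz1 * (-k / C)
            grad[6] += dmu * dmu_vec[4]
        else:
            pointwise[t] = 0.0
        m, w2 = m_next, w2_next
        dm, dw = dm_next, dw_next
    return ll


@njit(cache=True)
def _random_subject(theta, inputs, resp, conf, is_pred, answered, pointwise, grad):
    R, xi, C = theta[0], theta[1], theta[2]
    ll = 0.0
    T = inputs.shape[0]
    for t in range(T):
        if answered[t]:
            k = (1.0 - conf[t]) / C
            sd = xi * np.exp(k)
            z = (resp[t] - R) / sd
            lt = -0.5 * LOG2PI - np.log(sd) - 0.5 * z * z
            pointwise[t] = lt
            ll += lt
            zz1 = z * z - 1.0
            grad[0] += z / sd
            grad[1] += zz1 / xi
            grad[2] += zz1 * (-k / C)
        else:
            pointwise[t] = 0.0
    return ll


def _make_driver(subject_kernel):
    @njit(cache=True)
    def driver(theta, inputs, resp, conf, is_pred, answered):
        ns, P = theta.shape
        T = inputs.shape[1]
        grads = np.zeros((ns, P))
        pointwise = np.zeros((ns, T))
        total = 0.0
        for i in range(ns):
            total += subject_kernel(theta[i], inputs[i], resp[i], conf[i],
                                    is_pred[i], answered[i], pointwise[i], grads[i])
        return total, grads, pointwise
    return driver


#: model_id -> driver(theta (ns,P), inputs/resp/conf (ns,T) float64,
#:                    is_pred/answered (ns,T) bool) -> (ll, grads, pointwise)
DRIVERS = {
    "rl": _make_driver(_rl_subject),
    "erl": _make_driver(_erl_subject),
    "kf": _make_driver(_kf_subject),
    "ekf": _make_driver(_ekf_subject),
    "random": _make_driver(_random_subject),
}
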