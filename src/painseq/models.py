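"""The five confidence-weighted observer models: RL, eRL, KF, eKF, random.

All five share the response model: a rating is Gaussian around the model's
trial-wise mean with standard deviation ``xi * exp((1 - c_t) / C)``, so low
confidence ``c_t`` inflates response noise and the scaling factor ``C``
controls how strongly.

*   **RL** — Rescorla-Wagner delta rule: expectation ``E_{t+1} = E_t +
    alpha * (N_t - E_t)``; perception reports the input itself.
*   **eRL** — expectation-weighted RL: perceived pain is the convex blend
    ``P_t = (1-gamma) N_t + gamma E_t`` and the prediction error is taken
    with respect to ``P_t``.
*   **KF** — Kalman filter tracking a latent mean that drifts with
    volatility ``v`` and is observed with stochasticity ``s``; the Kalman
    gain ``alpha_t = w_t^2 / (w_t^2 + s^2)`` is a trial-wise learning rate.
*   **eKF** — Kalman filter in which the input is itself an imperfect cue
    for pain (subjective noise ``epsilon``), which makes perception an
    expectation-weighted blend with weight
    ``gamma_t = epsilon^2 / (epsilon^2 + s^2 + w_t^2)``.
*   **random** — reports a constant ``R``; the no-learning baseline.

State updates always use the objective input ``N_t`` and run on every trial;
the likelihood is evaluated against the perception response on perception
trials and against the post-update prediction on prediction trials.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

__all__ = [
    "MODEL_IDS",
    "RLParams",
    "ERLParams",
    "KFParams",
    "EKFParams",
    "RandomParams",
    "BeliefState",
    "params_class",
    "confidence_noise_scale",
    "rl_step",
    "kf_step",
    "trial_loglik",
    "run_model",
    "simulate_responses",
]

MODEL_IDS = ("rl", "erl", "kf", "ekf", "random")


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass
class RLParams:
    """Rescorla-Wagner observer: learning rate, response noise, initial
    expectation and confidence scaling."""

    learning_rate: float        # alpha in [0, 1]
    response_noise: float       # xi > 0, response-scale units
    initial_expectation: float  # E0, response-scale units
    confidence_scaling: float   # C > 0

    model_id = "rl"

    def __post_init__(self):
        if not 0 <= self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in [0, 1]")
        _check_positive(response_noise=self.response_noise,
                        confidence_scaling=self.confidence_scaling)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass
class ERLParams(RLParams):
    """RL plus the perceptual weight gamma of expectation in reported pain."""

    perception_weight: float = 0.0   # gamma in [0, 1]

    model_id = "erl"

    def __post_init__(self):
        super().__post_init__()
        if not 0 <= self.perception_weight <= 1:
            raise ValueError("perception_weight must lie in [0, 1]")


@dataclass
class KFParams:
    """Kalman-filter observer."""

    stochasticity: float        # s > 0, response-scale units
    volatility: float           # v > 0, response-scale units
    response_noise: float       # xi > 0
    initial_expectation: float  # E0 (= m_1)
    initial_uncertainty: float  # w0 > 0 (sd; the filter tracks w^2)
    confidence_scaling: float   # C > 0

    model_id = "kf"

    def __post_init__(self):
        _check_positive(stochasticity=self.stochasticity,
                        response_noise=self.response_noise,
                        initial_uncertainty=self.initial_uncertainty,
                        confidence_scaling=self.confidence_scaling)
        # v = 0 is the stationary boundary (no drift): the filter reduces to
        # conjugate-Gaussian updating, used to validate the recursion
        if self.volatility < 0:
            raise ValueError("volatility must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass
class EKFParams(KFParams):
    """KF plus subjective noise epsilon: the input is an imperfect cue."""

    subjective_noise: float = 0.0   # epsilon >= 0

    model_id = "ekf"

    def __post_init__(self):
        super().__post_init__()
        if self.subjective_noise < 0:
            raise ValueError("subjective_noise must be >= 0")


@dataclass
class RandomParams:
    """Baseline observer answering a constant value R."""

    constant_response: float    # R, response-scale units
    response_noise: float       # xi > 0
    confidence_scaling: float   # C > 0

    model_id = "random"

    def __post_init__(self):
        _check_positive(response_noise=self.response_noise,
                        confidence_scaling=self.confidence_scaling)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


_PARAMS_CLASS = {"rl": RLParams, "erl": ERLParams, "kf": KFParams,
                 "ekf": EKFParams, "random": RandomParams}


def params_class(model_id: str):
    """Parameter dataclass for ``model_id``."""
    try:
        return _PARAMS_CLASS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}") from None


@dataclass
class BeliefState:
    """Belief carried across trials: expectation ``m_t`` and, for the Kalman
    models, latent-state uncertainty ``w_t^2``."""

    expectation: float
    uncertainty: float | None = None   # w_t^2 (variance), KF/eKF only
    trial: int = 0

    def __post_init__(self):
        if self.uncertainty is not None and not self.uncertainty > 0:
            raise ValueError("uncertainty w^2 must be > 0")


def confidence_noise_scale(xi: float, C: float, confidence) -> np.ndarray | float:
    """Response-noise sd ``xi * exp((1 - c) / C)`` for confidence ``c``.

    Full confidence leaves the noise at ``xi``; as ``C`` grows the influence
    of confidence vanishes.
    """
    _check_positive(xi=xi, C=C)
    c = np.asarray(confidence, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("confidence must lie in [0, 1]")
    out = xi * np.exp((1.0 - c) / C)
    return float(out) if out.ndim == 0 else out


def rl_step(state: BeliefState, stimulus: float,
            params: RLParams) -> tuple[float, BeliefState]:
    """One RL/eRL trial: returns (perceived pain P_t, updated state)."""
    E = state.expectation
    if isinstance(params, ERLParams):
        gamma = params.perception_weight
        percept = (1.0 - gamma) * stimulus + gamma * E
        delta = percept - E
    else:
        percept = stimulus
        delta = stimulus - E
    new = BeliefState(expectation=E + params.learning_rate * delta, trial=state.trial + 1)
    return percept, new


def kf_step(state: BeliefState, stimulus: float,
            params: KFParams) -> tuple[float, BeliefState]:
    """One KF/eKF trial: returns (perceived pain P_t, updated state)."""
    if state.uncertainty is None or not state.uncertainty > 0:
        raise ValueError("KF step requires a positive uncertainty w^2")
    m, w2 = state.expectation, state.uncertainty
    s2 = params.stochasticity ** 2
    if isinstance(params, EKFParams):
        e2 = params.subjective_noise ** 2
        gamma_t = e2 / (e2 + s2 + w2)
        gain = w2 / (e2 + w2 + s2)
        percept = gamma_t * m + (1.0 - gamma_t) * stimulus
    else:
        gain = w2 / (w2 + s2)
        percept = stimulus
    m_next = m + gain * (stimulus - m)
    w2_next = w2 * (1.0 - gain) + params.volatility ** 2
    return percept, BeliefState(expectation=m_next, uncertainty=w2_next, trial=state.trial + 1)


def trial_loglik(response: float, mean: float, xi: float, C: float,
                 confidence: float) -> float:
    """Gaussian log-density of one rating given its model mean.

    The sd is the confidence-scaled response noise; the 0-100 rating scale is
    modelled without truncation.  A missing response (NaN) contributes 0.
    """
    if response is None or np.isnan(response):
        return 0.0
    sd = confidence_noise_scale(xi, C, confidence)
    return float(stats.norm.logpdf(response, loc=mean, scale=sd))


def _initial_state(model_id: str, params) -> BeliefState:
    if model_id in ("kf", "ekf"):
        return BeliefState(expectation=params.initial_expectation,
                           uncertainty=params.initial_uncertainty ** 2)
    if model_id in ("rl", "erl"):
        return BeliefState(expectation=params.initial_expectation)
    return BeliefState(expectation=params.constant_response)


def run_model(model_id: str, params, inputs, schedule, confidences,
              responses=None) -> dict:
    """Run one observer over a transformed input sequence.

    Parameters
    ----------
    inputs : array of transformed stimulus intensities ``N_t`` (0-100 scale)
    schedule : :class:`~painseq.sequences.TrialSchedule` or sequence of
        ``{"perception", "prediction"}`` labels
    confidences : per-trial confidence ratings in [0, 1]
    responses : optional per-trial ratings; NaN marks an unanswered trial
        (excluded from the likelihood, state still updates)

    Returns
    -------
    dict with per-trial arrays ``perception_mean`` (P_t), ``prediction_mean``
    (E_{t+1}), ``response_mean`` (the likelihood mean for the question asked),
    ``response_sd``, ``loglik`` and the scalar ``total_loglik``.
    """
    cls = params_class(model_id)
    if not isinstance(params, cls):
        raise TypeError(f"params must be {cls.__name__} for model {model_id!r}")
    labels = getattr(schedule, "response_type", schedule)
    inputs = np.asarray(inputs, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    n = len(inputs)
    if len(labels) != n or len(confidences) != n:
        raise ValueError("inputs, schedule and confidences must have equal length")
    if responses is None:
        responses = np.full(n, np.nan)
    responses = np.asarray(responses, dtype=float)
    if len(responses) != n:
        raise ValueError("responses length mismatch")

    xi, C = params.response_noise, params.confidence_scaling
    state = _initial_state(model_id, params)
    percept = np.empty(n)
    predict = np.empty(n)
    for t in range(n):
        if model_id == "random":
            p = params.constant_response
            state = BeliefState(expectation=p, trial=t + 1)
        elif model_id in ("rl", "erl"):
            p, state = rl_step(state, inputs[t], params)
        else:
            p, state = kf_step(state, inputs[t], params)
        percept[t] = p
        predict[t] = state.expectation   # E_{t+1}, after updating on N_t

    is_pred = np.asarray([lab == "prediction" for lab in labels])
    mean = np.where(is_pred, predict, percept)
    sd = confidence_noise_scale(xi, C, confidences)
    sd = np.broadcast_to(sd, mean.shape)
    answered = ~np.isnan(responses)
    ll = np.zeros(n)
    ll[answered] = stats.norm.logpdf(responses[answered], loc=mean[answered],
                                     scale=sd[answered])
    return {
        "perception_mean": percept,
        "prediction_mean": predict,
        "response_mean": mean,
        "response_sd": np.asarray(sd, dtype=float).copy(),
        "loglik": ll,
        "answered": answered,
        "total_loglik": float(ll.sum()),
    }


def simulate_responses(model_id: str, params, inputs, schedule, confidences,
                       seed: int | None = None) -> dict:
    """Simulate ratings from an observer: draws each response from its
    trial-wise Gaussian.  Returns the :func:`run_model` dict plus
    ``response`` and ``seed``."""
    out = run_model(model_id, params, inputs, schedule, confidences)
    rng = np.random.default_rng(seed)
    out["response"] = rng.normal(out["response_mean"], out["response_sd"])
    out["seed"] = seed
    return out
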