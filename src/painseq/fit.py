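"""Hierarchical Bayesian estimation of observer-model parameters.

The entry point is :class:`HierarchicalObserverModel`, a statsmodels-style
model object built from trial-level data for one sequence condition.  Its
:meth:`~HierarchicalObserverModel.fit` runs gradient-based MCMC (see
:mod:`painseq.sampling`) on the non-centred hierarchy of
:mod:`painseq.hierarchy` and returns a :class:`PosteriorFit` results object
carrying posterior draws, convergence diagnostics and the pointwise
log-likelihood matrix that model comparison consumes.

Fits are per condition: group-level means get N(0,1) priors, group scales
half-Student-t(3,0,1), subject offsets N(0,1), and the likelihood jointly
covers the perception and prediction responses of every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import arviz as az

from ._kernels import DRIVERS
from .hierarchy import HierarchicalSpec, PARAM_TABLE
from .sampling import sample_chains

__all__ = [
    "SamplerConfig",
    "HierarchicalObserverModel",
    "PosteriorFit",
    "build_model",
    "sample_posterior",
    "diagnostics",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.  Defaults are the full-scale settings (4 chains,
    6000 warmup + 6000 sampling draws); :meth:`desk_scale` gives the reduced
    configuration used throughout the test-bench studies."""

    chains: int = 4
    warmup: int = 6000
    draws: int = 6000
    max_leapfrog: int = 32      # leapfrog steps are jittered on {1..max}
    target_accept: float = 0.8
    seed: int | None = None

    @classmethod
    def desk_scale(cls, seed: int | None = None, **overrides) -> "SamplerConfig":
        return cls(chains=4, warmup=1000, draws=1000, seed=seed, **overrides)

    def with_seed(self, seed: int) -> "SamplerConfig":
        return replace(self, seed=seed)


def build_model(model_id: str, n_subjects: int) -> HierarchicalSpec:
    """Hierarchical specification (links, packing, priors) for one model."""
    return HierarchicalSpec(model_id, n_subjects)


class HierarchicalObserverModel:
    """One observer model, one condition, all subjects.

    Parameters
    ----------
    inputs, responses, confidences : arrays (n_subjects, n_trials)
        Transformed stimulus intensities, ratings (NaN = unanswered) and
        confidence ratings in [0, 1].
    is_prediction : bool array (n_subjects, n_trials)
        True where the prediction question was asked.
    model : one of {"rl", "erl", "kf", "ekf", "random"}
    """

    def __init__(self, inputs, responses, confidences, is_prediction,
                 model: str = "ekf", participants=None, condition: str | None = None):
        if model not in PARAM_TABLE:
            raise ValueError(f"unknown model {model!r}")
        self.model_id = model
        self.inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        self.responses = np.atleast_2d(np.asarray(responses, dtype=float))
        self.confidences = np.atleast_2d(np.asarray(confidences, dtype=float))
        self.is_prediction = np.atleast_2d(np.asarray(is_prediction, dtype=bool))
        shapes = {a.shape for a in (self.inputs, self.responses,
                                    self.confidences, self.is_prediction)}
        if len(shapes) != 1:
            raise ValueError("inputs, responses, confidences and is_prediction "
                             "must share one (n_subjects, n_trials) shape")
        if not np.isfinite(self.inputs).all():
            raise ValueError("inputs must be finite on every trial")
        conf = self.confidences
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidence ratings must lie in [0, 1]")
        self.answered = np.isfinite(self.responses)
        self.n_subjects, self.n_trials = self.inputs.shape
        if self.n_subjects < 2:
            raise ValueError("hierarchical fitting needs data from >= 2 subjects")
        self.participants = (list(participants) if participants is not None
                             else list(range(self.n_subjects)))
        self.condition = condition
        self.spec = HierarchicalSpec(model, self.n_subjects)
        self._driver = DRIVERS[model]
        # numba wants contiguous float/bool arrays and NaN-free responses
        self._resp = np.where(self.answered, self.responses, 0.0)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model: str = "ekf",
                       condition: str | None = None) -> "HierarchicalObserverModel":
        """Build from long-format trial data with columns ``participant,
        condition, trial, input, response_type, response, confidence``."""
        df = data.copy()
        if condition is not None:
            df = df[df["condition"] == condition]
            if df.empty:
                raise ValueError(f"no rows for condition {condition!r}")
        elif df["condition"].nunique() > 1:
            raise ValueError("data spans several conditions; pass condition=...")
        df = df.sort_values(["participant", "trial"])
        counts = df.groupby("participant").size()
        if counts.nunique() != 1:
            raise ValueError("all participants must have the same trial count")
        participants = list(counts.index)
        shape = (len(participants), int(counts.iloc[0]))
        def pivot(col):
            return df[col].to_numpy().reshape(shape)
        return cls(
            inputs=pivot("input"),
            responses=pivot("response"),
            confidences=pivot("confidence"),
            is_prediction=pivot("response_type") == "prediction",
            model=model,
            participants=participants,
            condition=condition if condition is not None else df["condition"].iloc[0],
        )

    # ------------------------------------------------------------------
    def loglik_and_grad(self, theta: np.ndarray):
        """Joint data log-likelihood and gradient for native parameters
        ``theta`` of shape (n_subjects, n_params)."""
        ll, grads, _ = self._driver(np.ascontiguousarray(theta, dtype=float),
                                    self.inputs, self._resp, self.confidences,
                                    self.is_prediction, self.answered)
        return ll, grads

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log-likelihood (n_subjects, n_trials); unanswered
        trials hold 0."""
        _, _, pw = self._driver(np.ascontiguousarray(theta, dtype=float),
                                self.inputs, self._resp, self.confidences,
                                self.is_prediction, self.answered)
        return pw

    def logp_and_grad(self, x: np.ndarray):
        """Unconstrained log posterior density and gradient."""
        return self.spec.logp_and_grad(x, self.loglik_and_grad)

    def fit(self, config: SamplerConfig | None = None, **overrides) -> "PosteriorFit":
        """Sample the posterior; returns a :class:`PosteriorFit`."""
        if config is None:
            config = SamplerConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        draws, chain_stats = sample_chains(
            self.logp_and_grad, self.spec.dim,
            n_chains=config.chains, n_warmup=config.warmup, n_draws=config.draws,
            seed=config.seed, target_accept=config.target_accept,
            max_leapfrog=config.max_leapfrog,
        )
        return PosteriorFit(self, config, draws, chain_stats)


class PosteriorFit:
    """Results object: posterior draws plus diagnostics for one model x
    condition fit.

    Attributes of note: :attr:`idata` (ArviZ ``InferenceData`` with a
    ``log_likelihood`` group pointwise over answered trials),
    :meth:`summary`, :meth:`diagnostics`, :attr:`max_rhat`,
    :attr:`converged`, :attr:`theta_mean`.
    """

    def __init__(self, model: HierarchicalObserverModel, config: SamplerConfig,
                 draws: np.ndarray, chain_stats):
        self.model = model
        self.model_id = model.model_id
        self.condition = model.condition
        self.config = config
        self.draws = draws          # (chains, draws, dim) unconstrained
        self.chain_stats = chain_stats
        self._idata = None
        self._diagnostics = None

    # ---- derived quantities ------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.model.spec.params]

    def theta_draws(self) -> np.ndarray:
        """Native per-subject parameters, shape (chains, draws, ns, P)."""
        spec = self.model.spec
        C, D, _ = self.draws.shape
        out = np.empty((C, D, spec.n_subjects, spec.n_params))
        for c in range(C):
            for d in range(D):
                out[c, d] = spec.natives(self.draws[c, d])
        return out

    @property
    def theta_mean(self) -> np.ndarray:
        """Posterior-mean native parameters per subject (ns, P)."""
        return self.theta_draws().mean(axis=(0, 1))

    def _build_idata(self) -> az.InferenceData:
        spec = self.model.spec
        C, D, _ = self.draws.shape
        P, ns = spec.n_params, spec.n_subjects
        mu = self.draws[:, :, :P]
        tau = np.exp(self.draws[:, :, P:2 * P])
        theta = self.theta_draws()
        posterior = {}
        group_loc = np.empty((C, D, P))
        for c in range(C):
            for d in range(D):
                group_loc[c, d] = spec.group_location_native(mu[c, d])
        for j, name in enumerate(self.param_names):
            posterior[f"mu_{name}"] = mu[:, :, j]
            posterior[f"tau_{name}"] = tau[:, :, j]
            posterior[f"{name}_group"] = group_loc[:, :, j]
            posterior[name] = theta[:, :, :, j]

        answered = self.model.answered
        pw = np.empty((C, D, int(answered.sum())))
        for c in range(C):
            for d in range(D):
                pw[c, d] = self.model.pointwise_loglik(theta[c, d])[answered]
        coords = {"subject": self.model.participants,
                  "obs_id": np.arange(pw.shape[2])}
        dims = {name: ["subject"] for name in self.param_names}
        idata = az.from_dict(posterior=posterior,
                             log_likelihood={"resp": pw},
                             coords=coords,
                             dims={**dims, "resp": ["obs_id"]})
        return idata

    @property
    def idata(self) -> az.InferenceData:
        if self._idata is None:
            self._idata = self._build_idata()
        return self._idata

    # ---- diagnostics --------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and rank-normalised bulk/tail ESS for every
        unconstrained parameter, including non-centred offsets."""
        if self._diagnostics is None:
            self._diagnostics = diagnostics(self.draws, self.model.spec.names)
        return self._diagnostics

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics()["rhat"].max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD

    @property
    def n_divergences(self) -> int:
        return int(sum(r.divergences for r in self.chain_stats))

    # ---- presentation -------------------------------------------------
    def summary(self, kind: str = "group") -> pd.DataFrame:
        """Posterior summary table.

        ``kind="group"`` (default) summarises the link-transformed group
        locations and group scales; ``kind="subject"`` the per-subject
        native parameters.
        """
        if kind == "group":
            names = [f"{n}_group" for n in self.param_names] + \
                    [f"tau_{n}" for n in self.param_names]
        elif kind == "subject":
            names = self.param_names
        else:
            raise ValueError("kind must be 'group' or 'subject'")
        return az.summary(self.idata, var_names=names, round_to=4)

    def group_location_draws(self, name: str) -> np.ndarray:
        """Merged-across-chains draws of a link-transformed group location,
        for between-condition HDI contrasts."""
        return np.asarray(self.idata.posterior[f"{name}_group"]).reshape(-1)

    def plot_trace(self, var_names=None):
        return az.plot_trace(self.idata, var_names=var_names or
                             [f"{n}_group" for n in self.param_names])

    def __repr__(self):
        return (f"<PosteriorFit {self.model_id} condition={self.condition!r} "
                f"chains={self.config.chains} draws={self.config.draws} "
                f"max_rhat={self.max_rhat:.3f}>")


def sample_posterior(model: HierarchicalObserverModel,
                     config: SamplerConfig) -> PosteriorFit:
    """Functional wrapper around :meth:`HierarchicalObserverModel.fit`."""
    return model.fit(config)


def diagnostics(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Convergence table from raw draws of shape (chains, draws, dim)."""
    draws = np.asarray(draws)
    if draws.ndim != 3:
        raise ValueError("draws must have shape (chains, draws, dim)")
    if draws.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains")
    if draws.shape[2] != len(names):
        raise ValueError("names must match the parameter dimension")
    data = {name: draws[:, :, k] for k, name in enumerate(names)}
    ds = az.convert_to_dataset(data)
    rhat = az.rhat(ds)
    ess_bulk = az.ess(ds, method="bulk")
    ess_tail = az.ess(ds, method="tail")
    table = pd.DataFrame({
        "rhat": [float(rhat[n]) for n in names],
        "ess_bulk": [float(ess_bulk[n]) for n in names],
        "ess_tail": [float(ess_tail[n]) for n in names],
    }, index=names)
    table.attrs["converged"] = bool(table["rhat"].max() < RHAT_THRESHOLD)
    return table
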