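"""Generation of noxious-input sequences under a 2x2 volatility x stochasticity design.

A sequence is a series of *chunks*: runs of trials sharing one latent mean
intensity.  Volatility is manipulated through the mean chunk length ``L``
(short chunks = a fast-drifting environment), stochasticity through the
trial-to-trial observation variance ``sigma2`` around the chunk mean.  Trial
values are drawn on a continuous scale and discretised to the integer
intensity levels 1..13 actually deliverable by a thermal stimulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConditionSpec",
    "Sequence",
    "TrialSchedule",
    "make_condition",
    "generate_sequence",
    "generate_schedule",
]

_LEVELS = ("low", "high")

#: mean chunk length (trials) per volatility level
CHUNK_LENGTH = {"high": 15, "low": 25}
#: observation variance (intensity levels squared) per stochasticity level
OBS_VARIANCE = {"high": 1.75, "low": 0.25}


@dataclass(frozen=True)
class ConditionSpec:
    """Parameters of the generative process for one sequence condition."""

    volatility_level: str
    stochasticity_level: str
    mean_chunk_length: int          # L, trials
    length_jitter: int = 3          # a, trials; l ~ U{L-a, .., L+a}
    observation_variance: float = 0.25   # sigma^2, intensity levels^2
    mean_lower: float = 3.5         # uniform support of chunk means
    mean_upper: float = 10.5
    min_mean_separation: float = 2.0
    intensity_min: int = 1
    intensity_max: int = 13
    n_trials: int = 80

    @property
    def label(self) -> str:
        return f"vol_{self.volatility_level}-stoch_{self.stochasticity_level}"

    def validate(self) -> None:
        if self.volatility_level not in _LEVELS or self.stochasticity_level not in _LEVELS:
            raise ValueError("volatility/stochasticity levels must be 'low' or 'high'")
        if self.min_mean_separation > (self.mean_upper - self.mean_lower):
            raise ValueError(
                "min_mean_separation exceeds the chunk-mean support width; "
                "no second chunk mean could ever be drawn"
            )
        if self.mean_chunk_length - self.length_jitter < 1:
            raise ValueError("length jitter allows non-positive chunk lengths")
        if self.observation_variance < 0:
            raise ValueError("observation variance must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Sequence:
    """One generated 80-trial condition block.

    ``pre_discretisation_values`` are the accepted continuous draws (after any
    out-of-range redraws), kept so the generative variance can be audited.
    """

    intensities: np.ndarray              # int levels, shape (n_trials,)
    chunk_means: np.ndarray              # I_k, real levels
    chunk_lengths: np.ndarray            # l_k, trials (last chunk truncated)
    chunk_index: np.ndarray              # per-trial chunk id
    pre_discretisation_values: np.ndarray
    condition: ConditionSpec
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def trial_chunk_means(self) -> np.ndarray:
        """Chunk mean of every trial, shape (n_trials,)."""
        return self.chunk_means[self.chunk_index]

    def plot(self, ax=None):
        """Plot discretised intensities with the underlying chunk means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = np.arange(1, len(self) + 1)
        ax.step(t, self.trial_chunk_means, where="mid", color="C1", label="chunk mean")
        ax.plot(t, self.intensities, "o", ms=3, color="C0", label="intensity")
        ax.set(xlabel="trial", ylabel="intensity level", title=self.condition.label)
        ax.legend(frameon=False)
        return ax


@dataclass
class TrialSchedule:
    """Which question (perception vs prediction) is asked after each trial."""

    response_type: list[str] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.response_type)

    @property
    def is_prediction(self) -> np.ndarray:
        return np.asarray([r == "prediction" for r in self.response_type])


def make_condition(volatility_level: str, stochasticity_level: str, **overrides) -> ConditionSpec:
    """Build the :class:`ConditionSpec` for one cell of the 2x2 design.

    ``L=15`` (high volatility) or ``25`` (low); ``sigma^2=1.75`` (high
    stochasticity) or ``0.25`` (low).  Keyword overrides replace any default.
    """
    if volatility_level not in _LEVELS:
        raise ValueError(f"unknown volatility level {volatility_level!r}")
    if stochasticity_level not in _LEVELS:
        raise ValueError(f"unknown stochasticity level {stochasticity_level!r}")
    spec = ConditionSpec(
        volatility_level=volatility_level,
        stochasticity_level=stochasticity_level,
        mean_chunk_length=overrides.pop("mean_chunk_length", CHUNK_LENGTH[volatility_level]),
        observation_variance=overrides.pop("observation_variance", OBS_VARIANCE[stochasticity_level]),
        **overrides,
    )
    spec.validate()
    return spec


def _draw_chunk_mean(rng: np.random.Generator, spec: ConditionSpec, previous: float | None) -> float:
    """Rejection-sample a chunk mean at least ``min_mean_separation`` from its predecessor."""
    while True:
        mean = rng.uniform(spec.mean_lower, spec.mean_upper)
        if previous is None or abs(mean - previous) >= spec.min_mean_separation:
            return mean


def generate_sequence(spec: ConditionSpec, seed: int | None = None) -> Sequence:
    """Generate one sequence under ``spec``.

    Chunk means ~ U(mean_lower, mean_upper) with consecutive means at least
    ``min_mean_separation`` apart; chunk lengths ~ U{L-a,..,L+a}; trial values
    ~ N(chunk mean, sigma^2), rounded to the nearest integer level, with any
    value rounding outside [intensity_min, intensity_max] discarded and
    redrawn.  Chunks are drawn until they cover ``n_trials``; the final chunk
    is truncated to fit.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    chunk_means: list[float] = []
    chunk_lengths: list[int] = []
    total = 0
    while total < spec.n_trials:
        mean = _draw_chunk_mean(rng, spec, chunk_means[-1] if chunk_means else None)
        length = int(rng.integers(spec.mean_chunk_length - spec.length_jitter,
                                  spec.mean_chunk_length + spec.length_jitter + 1))
        chunk_means.append(mean)
        chunk_lengths.append(length)
        total += length
    # truncate the final chunk so the trial count is exact
    chunk_lengths[-1] -= total - spec.n_trials

    sd = np.sqrt(spec.observation_variance)
    chunk_index = np.repeat(np.arange(len(chunk_means)), chunk_lengths)
    trial_means = np.asarray(chunk_means)[chunk_index]

    values = rng.normal(trial_means, sd)
    rounded = np.rint(values)
    # redraw individual trials whose rounded value leaves the valid range
    bad = (rounded < spec.intensity_min) | (rounded > spec.intensity_max)
    while bad.any():
        values[bad] = rng.normal(trial_means[bad], sd)
        rounded = np.rint(values)
        bad = (rounded < spec.intensity_min) | (rounded > spec.intensity_max)

    return Sequence(
        intensities=rounded.astype(int),
        chunk_means=np.asarray(chunk_means),
        chunk_lengths=np.asarray(chunk_lengths),
        chunk_index=chunk_index,
        pre_discretisation_values=values,
        condition=spec,
        seed=seed,
    )


def generate_schedule(n_trials: int = 80, seed: int | None = None) -> TrialSchedule:
    """Randomise the question order: exactly ``n_trials/2`` perception and
    ``n_trials/2`` prediction ratings."""
    if n_trials % 2:
        raise ValueError("n_trials must be even to balance perception/prediction")
    rng = np.random.default_rng(seed)
    labels = np.array(["perception", "prediction"]).repeat(n_trials // 2)
    rng.shuffle(labels)
    return TrialSchedule(response_type=list(labels), seed=seed)
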