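"""Recovery-study building blocks: transform sampling, confidence
simulation, category mapping, confusion-matrix bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painseq.recovery import (CoefficientDistribution, ConfusionMatrix,
                              sample_transform_coefficients,
                              simulate_confidence, categorise_recovery,
                              draw_individual_parameters, simulate_dataset,
                              parameter_recovery, model_recovery)
from painseq.fit import SamplerConfig


def test_degenerate_coefficient_distribution():
    dist = CoefficientDistribution(slope_sd=0.0, intercept_sd=0.0)
    assert dist.degenerate
    trs = sample_transform_coefficients(dist, 5, seed=0)
    assert all(t.slope == 5.0 and t.intercept == 15.0 for t in trs)


def test_coefficient_sampling_moments_and_positivity():
    dist = CoefficientDistribution(slope_mean=5.0, slope_sd=1.0,
                                   intercept_mean=15.0, intercept_sd=5.0)
    trs = sample_transform_coefficients(dist, 10_000, seed=1)
    slopes = np.array([t.slope for t in trs])
    inters = np.array([t.intercept for t in trs])
    assert np.all(slopes > 0)
    assert slopes.mean() == pytest.approx(5.0, abs=0.05)
    assert inters.mean() == pytest.approx(15.0, abs=0.2)


def test_confidence_construction_extremes():
    up = np.arange(40.0)                      # strictly monotone
    conf = simulate_confidence(up, window=10)
    assert np.all(conf > 0.95)
    alt = np.tile([20.0, 80.0], 20)           # perfectly alternating
    conf = simulate_confidence(alt, window=10)
    assert np.all(conf < 0.05)
    const = np.full(30, 50.0)
    assert np.allclose(simulate_confidence(const, window=10), 0.5)
    with pytest.raises(ValueError):
        simulate_confidence(up, window=2)


def test_confidence_matches_bruteforce_autocorrelation(rng):
    x = rng.uniform(0, 100, 60)
    w = 12
    conf = simulate_confidence(x, window=w)
    for t in range(w - 1, 60):
        win = x[t - w + 1:t + 1]
        r = stats.pearsonr(win[:-1], win[1:])[0]
        assert conf[t] == pytest.approx((r + 1) / 2, abs=1e-10)
    assert np.all(conf[:w - 1] == conf[w - 1])
    assert np.all((conf >= 0) & (conf <= 1))


@pytest.mark.parametrize("r,cat", [
    (0.3, "poor"), (0.49, "poor"), (0.6, "fair"), (0.8, "good"),
    (0.95, "excellent"), (float("nan"), "poor"),
])
def test_recovery_categories(r, cat):
    assert categorise_recovery(r) == cat


def test_individual_parameter_draws_respect_supports(rng):
    theta = draw_individual_parameters("ekf", 500, seed=0)
    assert theta.shape == (500, 7)
    assert np.all(theta[:, [0, 1, 2, 4, 5, 6]] > 0)   # s v xi w0 C eps


def test_simulated_dataset_layout():
    sim = simulate_dataset("rl", n_subjects=4, seed=9)
    df = sim["data"]
    assert set(df.columns) == {"participant", "condition", "trial", "input",
                               "response_type", "response", "confidence"}
    assert df.groupby("participant").size().eq(80).all()
    counts = df.groupby(["participant", "response_type"]).size()
    assert counts.eq(40).all()                 # 40 + 40 questions each
    assert df["confidence"].between(0, 1).all()
    assert sim["theta"].shape == (4, 4)
    # reproducibility end to end
    again = simulate_dataset("rl", n_subjects=4, seed=9)
    pd.testing.assert_frame_equal(df, again["data"])


def test_recovery_requires_enough_subjects():
    with pytest.raises(ValueError):
        parameter_recovery("rl", n_subjects=4, seed=0)


def test_parameter_recovery_reproducible_and_order_invariant():
    cfg = SamplerConfig(chains=2, warmup=150, draws=150, seed=2)
    rep1 = parameter_recovery("random", n_subjects=8, seed=5, sampler_config=cfg)
    rep2 = parameter_recovery("random", n_subjects=8, seed=5, sampler_config=cfg)
    assert rep1.r == rep2.r
    assert rep1.category == rep2.category
    # Pearson r is invariant to relabelling subjects
    perm = np.random.default_rng(0).permutation(8)
    r_perm = stats.pearsonr(rep1.theta_true[perm, 0], rep1.theta_est[perm, 0])[0]
    assert r_perm == pytest.approx(rep1.r["R"], abs=1e-12)


def test_shuffled_estimates_decorrelate(rng):
    """Destroying the pairing drives r towards 0 ('poor')."""
    true = rng.uniform(0, 1, 200)
    est = true + rng.normal(0, 0.01, 200)
    assert categorise_recovery(stats.pearsonr(true, est)[0]) == "excellent"
    shuffled = rng.permutation(est)
    assert abs(stats.pearsonr(true, shuffled)[0]) < 0.2


def test_confusion_matrix_bookkeeping():
    counts = pd.DataFrame([[2.0, 0.0], [0.5, 1.5]],
                          index=["a", "b"], columns=["a", "b"])
    cm = ConfusionMatrix(counts=counts, n_per_model=2, ties=1)
    assert cm.counts.sum(axis=1).eq(2.0).all()
    assert cm.diagonally_modal
    norm = cm.normalised()
    assert np.allclose(norm.sum(axis=1), 1.0)
    off = ConfusionMatrix(counts=pd.DataFrame([[0.0, 2.0], [0.0, 2.0]],
                                              index=["a", "b"], columns=["a", "b"]),
                          n_per_model=2)
    assert not off.diagonally_modal


def test_single_model_recovery_degenerate():
    """M = 1: the confusion 'matrix' is a 1x1 tally of its datasets."""
    cm = model_recovery(model_ids=["random"], n_datasets_per_model=2,
                        n_subjects=3, seed=1,
                        sampler_config=SamplerConfig(chains=2, warmup=120,
                                                     draws=120, seed=2))
    assert cm.counts.shape == (1, 1)
    assert cm.counts.iloc[0, 0] == 2.0
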