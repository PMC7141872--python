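"""Ensemble composition, prediction statistics and calibration."""

import numpy as np
import pytest

from ensgrad.ensemble import (
    EnsembleModel,
    calibration_report,
    compare_single_vs_ensemble,
    fit_ensemble,
    predict_ensemble,
)
from ensgrad.models import TrainingConfig, build_architecture


def test_canonical_composition_is_architectures_times_subsets(small_ensemble):
    assert len(small_ensemble) == 4  # 2 architectures x 2 subsets here
    assert small_ensemble.architecture_counts() == {"Seq_32_32": 2, "Seq_32x1_16": 2}


def test_fit_rejects_tiny_datasets(campaign):
    with pytest.raises(ValueError, match="observations"):
        fit_ensemble(campaign["x"][:5], campaign["y"][:5], campaign["labels"][:5],
                     architectures=["Seq_32_32"], n_subsets=1)


def test_prediction_statistics_hand_example():
    # three members scoring {1, 2, 3}: mean 2, sample variance 1,
    # upper95 = 2 + 1.96*1 = 3.96
    class Fixed:
        def __init__(self, value):
            self.value = value
            self.spec = type("S", (), {"name": "fixed", "n_outputs": 1})()

        def predict(self, x):
            return np.full((len(x), 1), self.value)

    ens = EnsembleModel(members=[Fixed(1.0), Fixed(2.0), Fixed(3.0)])
    (pred,) = predict_ensemble(ens, np.zeros((1, 20, 20)))
    assert pred.mean == pytest.approx(2.0)
    assert pred.variance == pytest.approx(1.0)
    assert pred.upper95 == pytest.approx(3.96)

    zeros = EnsembleModel(members=[Fixed(0.0)] * 3)
    (p0,) = predict_ensemble(zeros, np.zeros((1, 20, 20)))
    assert p0.mean == p0.variance == p0.upper95 == 0.0


def test_singleton_ensemble_variance_is_zero(campaign):
    ens = fit_ensemble(campaign["x"], campaign["y"], campaign["labels"],
                       architectures=["Seq_32_32"], n_subsets=1,
                       cfg=TrainingConfig(max_epochs=3, seed=11))
    preds = predict_ensemble(ens, campaign["x"][:5])
    assert all(p.variance == 0.0 and p.upper95 == p.mean for p in preds)


def test_upper_bound_monotone_in_variance():
    base = np.zeros((1, 20, 20))

    class Noisy:
        def __init__(self, v):
            self.v = v
            self.spec = type("S", (), {"name": "n", "n_outputs": 1})()

        def predict(self, x):
            return np.full((len(x), 1), self.v)

    narrow = predict_ensemble(EnsembleModel([Noisy(-0.1), Noisy(0.1)]), base)[0]
    wide = predict_ensemble(EnsembleModel([Noisy(-1.0), Noisy(1.0)]), base)[0]
    assert narrow.mean == wide.mean == 0.0
    assert wide.upper95 > narrow.upper95


def test_ensemble_mse_bounded_by_average_member_mse(small_ensemble, campaign):
    # Jensen: mean-prediction squared error <= average member squared error
    table = compare_single_vs_ensemble(small_ensemble, campaign["x"], campaign["y"])
    members = table.drop("ensemble_mean")
    assert table.loc["ensemble_mean", "mse"] <= members["mse"].mean() + 1e-12


def test_compare_single_member_rows_match(campaign):
    ens = fit_ensemble(campaign["x"], campaign["y"], campaign["labels"],
                       architectures=["Seq_32_32"], n_subsets=1,
                       cfg=TrainingConfig(max_epochs=3, seed=12))
    table = compare_single_vs_ensemble(ens, campaign["x"][:100], campaign["y"][:100])
    assert np.allclose(table.iloc[0].to_numpy(), table.loc["ensemble_mean"].to_numpy())


def test_calibration_flags_degenerate_ensemble(campaign):
    class Fixed:
        spec = type("S", (), {"name": "f", "n_outputs": 1})()

        def predict(self, x):
            return np.zeros((len(x), 1))

    ens = EnsembleModel(members=[Fixed(), Fixed()])
    report = calibration_report(ens, campaign["x"][:60], campaign["y"][:60])
    assert report["degenerate"]


def test_calibration_positive_for_constructed_noise_structure(rng):
    # members = truth + noise whose scale varies by input: binned MSE must
    # rise with binned variance and the rank correlation must be positive
    n = 400
    truth = rng.normal(size=n)
    sigma = np.where(np.arange(n) < n // 2, 0.05, 0.6)

    class NoisyOracle:
        def __init__(self, seed):
            self.noise = np.random.default_rng(seed).normal(size=n) * sigma
            self.spec = type("S", (), {"name": "o", "n_outputs": 1})()

        def predict(self, x):
            return (truth + self.noise)[: len(x), None]

    ens = EnsembleModel(members=[NoisyOracle(s) for s in range(8)])
    x_dummy = np.zeros((n, 20, 20))
    report = calibration_report(ens, x_dummy, truth)
    assert report["rank_correlation"] > 0.3
    table = report["table"]
    assert table["mse"].iloc[-1] > table["mse"].iloc[0]


def test_calibration_requires_enough_examples(small_ensemble, campaign):
    with pytest.raises(ValueError, match="50"):
        calibration_report(small_ensemble, campaign["x"][:10], campaign["y"][:10])


def test_ensemble_checkpoint_roundtrip(tmp_path, small_ensemble, campaign):
    small_ensemble.save(tmp_path / "ens")
    loaded = EnsembleModel.load(tmp_path / "ens")
    a = predict_ensemble(small_ensemble, campaign["x"][:4])
    b = predict_ensemble(loaded, campaign["x"][:4])
    assert np.allclose([p.mean for p in a], [p.mean for p in b])
    assert np.allclose([p.variance for p in a], [p.variance for p in b])
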