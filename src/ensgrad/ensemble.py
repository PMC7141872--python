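"""Ensembles of enrichment predictors: mean, variance and confidence bounds.

The canonical configuration trains each of the six architectures on three
random 80% subsamples of the observations (distinct seeds), giving 18
members.  The ensemble prediction is the arithmetic mean of the member
regression scores; the across-member sample variance is the uncertainty
estimate, and ``upper95 = mean + 1.96 * sd`` is the pessimistic score used
for off-target rejection.  The across-member variance of a singleton
ensemble is defined as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ensgrad.models import (
    ARCHITECTURES,
    TrainedModel,
    TrainingConfig,
    build_architecture,
    build_multioutput,
    train_model,
)
from ensgrad.sequences import encode_batch

#: z-score of the default confidence upper bound.
Z_UPPER = 1.96

#: Fraction of observations in each random training subsample.
SUBSET_FRACTION = 0.8


@dataclass
class EnsembleModel:
    members: list[TrainedModel]
    subset_assignments: dict[int, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def architecture_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.spec.name] = counts.get(m.spec.name, 0) + 1
        return counts

    def member_scores(self, x, output_index: int = 0) -> np.ndarray:
        """(n_members, n_inputs) regression scores."""
        if not isinstance(x, np.ndarray):
            x = encode_batch(list(x))
        if x.ndim == 2:
            x = x[None]
        return np.stack([m.predict(x)[:, output_index] for m in self.members])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"n_members": len(self.members), "members": []}
        for i, m in enumerate(self.members):
            fname = f"member_{i:02d}_{m.spec.name}.npz"
            m.save(directory / fname)
            manifest["members"].append(
                {"file": fname, "architecture": m.spec.name,
                 "subset": self.subset_assignments.get(i, {})}
            )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        members = [TrainedModel.load(directory / e["file"]) for e in manifest["members"]]
        assignments = {i: e.get("subset", {}) for i, e in enumerate(manifest["members"])}
        return cls(members=members, subset_assignments=assignments)


@dataclass
class EnsemblePrediction:
    mean: float
    variance: float
    upper95: float
    per_member: np.ndarray


def fit_ensemble(
    x,
    y_reg: np.ndarray,
    y_label: np.ndarray | None = None,
    architectures: Sequence[str] | None = None,
    n_subsets: int = 3,
    cfg: TrainingConfig = TrainingConfig(),
    n_targets: int | None = None,
) -> EnsembleModel:
    """Train architectures x subsets members on random 80% subsamples.

    Each subset is drawn once (without replacement) and shared across
    architectures, so every architecture appears exactly ``n_subsets``
    times.  Member seeds are all distinct, derived from ``cfg.seed``.
    With ``n_targets`` set, multi-output (per-target regression) members
    are built instead of the dual-head model and ``y_reg`` is (n, T).
    """
    if architectures is None:
        architectures = list(ARCHITECTURES)
    if not isinstance(x, np.ndarray):
        x = encode_batch(list(x))
    y_reg = np.asarray(y_reg, dtype=np.float64)
    n = len(x)
    if n < 10 * n_subsets:
        raise ValueError(f"need at least {10 * n_subsets} observations, got {n}")

    rng = np.random.default_rng(cfg.seed)
    subset_size = max(int(round(n * SUBSET_FRACTION)), 1)
    subsets = [np.sort(rng.choice(n, size=subset_size, replace=False)) for _ in range(n_subsets)]

    members: list[TrainedModel] = []
    assignments: dict[int, dict] = {}
    for a_i, name in enumerate(architectures):
        for s_i, idx in enumerate(subsets):
            member_seed = cfg.seed + 1000 * a_i + 100 * s_i + 1
            if n_targets is None:
                model = build_architecture(name, seed=member_seed)
            else:
                model = build_multioutput(name, n_targets, seed=member_seed)
            member_cfg = TrainingConfig(
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                max_epochs=cfg.max_epochs,
                patience=cfg.patience,
                val_fraction=cfg.val_fraction,
                regression_weight=cfg.regression_weight,
                classification_weight=cfg.classification_weight,
                seed=member_seed,
            )
            try:
                train_model(
                    model,
                    x[idx],
                    y_reg[idx],
                    None if y_label is None else np.asarray(y_label)[idx],
                    member_cfg,
                )
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(
                    f"training failed for member {name}/subset{s_i}: {exc}"
                ) from exc
            model.metadata["subset_id"] = s_i
            members.append(model)
            assignments[len(members) - 1] = {"architecture": name, "subset_id": s_i,
                                             "seed": member_seed}
    return EnsembleModel(members=members, subset_assignments=assignments)


def predict_ensemble(
    ensemble: EnsembleModel, x, output_index: int = 0, z: float = Z_UPPER
) -> list[EnsemblePrediction]:
    """Mean / sample-variance / upper-bound predictions per input."""
    scores = ensemble.member_scores(x, output_index)  # (m, n)
    mean = scores.mean(axis=0)
    if scores.shape[0] > 1:
        var = scores.var(axis=0, ddof=1)
    else:
        var = np.zeros_like(mean)
    upper = mean + z * np.sqrt(var)
    return [
        EnsemblePrediction(float(mean[i]), float(var[i]), float(upper[i]), scores[:, i])
        for i in range(scores.shape[1])
    ]


def prediction_frame(predictions: Sequence[EnsemblePrediction],
                     sequences: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate predictions (mean, variance, upper95, per-member columns)."""
    rows = {
        "mean": [p.mean for p in predictions],
        "variance": [p.variance for p in predictions],
        "upper95": [p.upper95 for p in predictions],
    }
    n_members = len(predictions[0].per_member) if predictions else 0
    for j in range(n_members):
        rows[f"member_{j:02d}"] = [p.per_member[j] for p in predictions]
    idx = pd.Index(sequences, name="sequence") if sequences is not None else None
    return pd.DataFrame(rows, index=idx)


def calibration_report(
    ensemble: EnsembleModel, x, y_true: np.ndarray, n_bins: int = 10
) -> dict:
    """Does ensemble variance track squared error?

    Bins test examples by prediction-variance decile and reports the mean
    squared error per bin plus the Spearman rank correlation between
    per-example variance and squared error.  A well-calibrated ensemble
    shows rising error with rising variance (positive correlation).
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    if len(y_true) < 50:
        raise ValueError(f"need at least 50 labeled examples, got {len(y_true)}")
    preds = predict_ensemble(ensemble, x)
    mean = np.array([p.mean for p in preds])
    var = np.array([p.variance for p in preds])
    sq_err = (mean - y_true) ** 2

    degenerate = bool(np.allclose(var, var[0]))
    if degenerate:
        rho, pval = 0.0, 1.0
        table = pd.DataFrame({"variance": [float(var.mean())], "mse": [float(sq_err.mean())],
                              "n": [len(var)]})
    else:
        rho, pval = stats.spearmanr(var, sq_err)
        edges = np.quantile(var, np.linspace(0, 1, n_bins + 1))
        bins = np.clip(np.searchsorted(edges, var, side="right") - 1, 0, n_bins - 1)
        table = (
            pd.DataFrame({"bin": bins, "variance": var, "mse": sq_err})
            .groupby("bin")
            .agg(variance=("variance", "mean"), mse=("mse", "mean"), n=("mse", "size"))
            .reset_index(drop=True)
        )
    return {
        "table": table,
        "rank_correlation": float(rho),
        "p_value": float(pval),
        "degenerate": degenerate,
    }


def compare_single_vs_ensemble(
    ensemble: EnsembleModel, x, y_true: np.ndarray
) -> pd.DataFrame:
    """Pearson r, R^2 and MSE for every member and for the ensemble mean.

    The ensemble-mean MSE is algebraically at most the average member MSE
    on any batch; empirically it usually beats every single member.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    if len(y_true) == 0:
        raise ValueError("empty labeled batch")
    scores = ensemble.member_scores(x)
    rows = []

    def metrics(pred: np.ndarray) -> dict:
        resid = pred - y_true
        mse = float(np.mean(resid**2))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        if np.std(pred) > 0 and np.std(y_true) > 0:
            r = float(stats.pearsonr(pred, y_true)[0])
        else:
            r = np.nan
        return {"pearson_r": r, "r2": r2, "mse": mse}

    for i, m in enumerate(ensemble.members):
        rows.append({"model": f"member_{i:02d}_{m.spec.name}", **metrics(scores[i])})
    rows.append({"model": "ensemble_mean", **metrics(scores.mean(axis=0))})
    return pd.DataFrame(rows).set_index("model")
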