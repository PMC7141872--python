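"""Gradient-ascent sequence design on the relaxed one-hot input (Ens-Grad).

Starting from a seed sequence's one-hot encoding, the optimizer takes
``k`` plain gradient-ascent steps of size ``lambda`` on the unconstrained
relaxed matrix, then projects back to a discrete sequence by per-position
argmax, scores the projection, and repeats.  A run terminates when the
projected score has failed to improve on the best for ``patience``
consecutive projections (default 10), or at a safety cap.  Design is
substitution-only: positions beyond the seed length stay frozen, so
proposals preserve seed length.  Residue channels outside the allowed set
(by default all residues except cysteine and asparagine, which are
liabilities for manufacturability and stability) receive zero gradient and
are excluded from projection, so no proposal ever introduces them.

Candidate libraries are assembled with a two-step voting-thresholding
rule: a candidate survives when at least ``vote_rule`` ensemble members
score it strictly above its own seed, and surviving candidates are kept by
descending ensemble mean above a score threshold, up to a budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from ensgrad.ensemble import EnsembleModel, Z_UPPER
from ensgrad.models import TrainedModel
from ensgrad.sequences import ALPHABET, Alphabet, MAX_POSITIONS, encode_batch, encode_onehot

#: Residues never proposed by design (liabilities), excluded by default.
DISALLOWED_RESIDUES = "CN"

#: Seed-selection thresholds: keep sequences with non-negative
#: round-2-to-round-3 enrichment or final-round frequency above this.
SEED_FREQUENCY_THRESHOLD = 5e-5


class Objective(Protocol):
    """Differentiable score over batches of relaxed matrices."""

    def value(self, x: np.ndarray) -> np.ndarray:
        """(n, 20, 20) -> (n,) scores."""
        ...

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """(n, 20, 20) -> (n, 20, 20) d(score)/d(input)."""
        ...


class ModelObjective:
    """A single model's regression output as the ascent objective."""

    def __init__(self, model: TrainedModel, output_index: int = 0):
        self.model = model
        self.output_index = output_index

    def value(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)[:, self.output_index]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.model.network.input_gradient(x, self.output_index)


class EnsembleMeanObjective:
    """Mean of the member regression outputs as the ascent objective."""

    def __init__(self, ensemble: EnsembleModel, output_index: int = 0):
        self.ensemble = ensemble
        self.output_index = output_index

    def value(self, x: np.ndarray) -> np.ndarray:
        return self.ensemble.member_scores(x, self.output_index).mean(axis=0)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        grads = [
            m.network.input_gradient(x, self.output_index)
            for m in self.ensemble.members
        ]
        return np.mean(grads, axis=0)


class LinearObjective:
    """Separable linear landscape sum(W * X); exact optimum is known."""

    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=np.float64)

    def value(self, x: np.ndarray) -> np.ndarray:
        return np.einsum("npc,pc->n", x, self.weights)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.weights, x.shape).copy()


@dataclass
class OptimizerConfig:
    step_size: float = 0.5
    projection_interval: int = 5
    patience: int = 10
    max_iterations: int = 1000
    allowed_residues: str = "".join(
        r for r in ALPHABET.residues if r not in DISALLOWED_RESIDUES
    )
    frozen_positions: frozenset[int] = frozenset()
    # renormalize each occupied position onto the probability simplex after
    # every gradient step (off by default: the relaxation is unconstrained)
    simplex_renormalize: bool = False

    def __post_init__(self) -> None:
        if self.step_size < 0:
            raise ValueError("step_size must be non-negative")
        if self.projection_interval < 1 or self.patience < 1 or self.max_iterations < 1:
            raise ValueError("projection_interval, patience, max_iterations must be >= 1")
        if not self.allowed_residues:
            raise ValueError("allowed_residues must be non-empty")


@dataclass
class OptimizationTrace:
    seed: str
    iterations: list[tuple[int, str, float]] = field(default_factory=list)
    best: tuple[str, float] = ("", -np.inf)
    termination_reason: str = ""


@dataclass
class DesignCandidate:
    sequence: str
    seed: str
    edit_distance: int
    per_member: np.ndarray
    votes: int = 0
    mean: float = 0.0
    variance: float = 0.0
    upper95: float = 0.0
    accepted: bool = False


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def select_seeds(
    records: pd.DataFrame,
    enrichment_col: str = "enrichment",
    freq_col: str = "freq_to",
    freq_threshold: float = SEED_FREQUENCY_THRESHOLD,
) -> list[str]:
    """Seed rule: non-negative enrichment OR final-round frequency above 5e-5.

    ``records`` is the ``compute_enrichment`` output (sequence index,
    enrichment and later-round frequency columns).  Order is preserved and
    duplicates dropped.  The frequency clause is a strict inequality.
    """
    for col in (enrichment_col, freq_col):
        if col not in records.columns:
            raise KeyError(f"records missing required column {col!r}")
    keep = (records[enrichment_col] >= 0) | (records[freq_col] > freq_threshold)
    seen: set[str] = set()
    out: list[str] = []
    for s in records.index[keep]:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _channel_indices(residues: str, alphabet: Alphabet = ALPHABET) -> np.ndarray:
    return np.array(sorted(alphabet.index_of(r) for r in residues), dtype=int)


def _project(
    x: np.ndarray,
    seeds: Sequence[str],
    allowed: np.ndarray,
    frozen: frozenset[int],
    alphabet: Alphabet = ALPHABET,
) -> list[str]:
    """Per-position argmax restricted to allowed channels; frozen positions
    keep the seed residue; padding positions are ignored."""
    masked = np.full_like(x, -np.inf)
    masked[:, :, allowed] = x[:, :, allowed]
    arg = np.argmax(masked, axis=2)  # ties -> lowest channel index
    out = []
    for i, seed in enumerate(seeds):
        chars = []
        for p in range(len(seed)):
            if p in frozen:
                chars.append(seed[p])
            else:
                chars.append(alphabet.residues[arg[i, p]])
        out.append("".join(chars))
    return out


def _optimize_batch(
    seeds: Sequence[str],
    objective: Objective,
    cfg: OptimizerConfig,
    record_traces: bool = True,
) -> list[OptimizationTrace]:
    """Vectorized gradient ascent over a batch of seeds (shared objective)."""
    n = len(seeds)
    x = encode_batch(list(seeds))
    allowed = _channel_indices(cfg.allowed_residues)

    # gradient mask: zero at padding positions, frozen positions and
    # disallowed channels
    mask = np.zeros_like(x)
    mask[:, :, allowed] = 1.0
    for i, seed in enumerate(seeds):
        mask[i, len(seed):, :] = 0.0
        for p in cfg.frozen_positions:
            if p < MAX_POSITIONS:
                mask[i, p, :] = 0.0

    traces = [OptimizationTrace(seed=s) for s in seeds]
    init_scores = objective.value(x)
    for i, t in enumerate(traces):
        t.best = (seeds[i], float(init_scores[i]))

    stall = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    iters = 0
    while iters < cfg.max_iterations and active.any():
        steps = min(cfg.projection_interval, cfg.max_iterations - iters)
        for _ in range(steps):
            grad = objective.gradient(x)
            if not np.all(np.isfinite(grad)):
                bad = int(np.argwhere(~np.isfinite(grad))[0][0])
                raise RuntimeError(
                    f"non-finite gradient during optimization of seed "
                    f"{seeds[bad]!r} at iteration {iters}"
                )
            x[active] += cfg.step_size * (grad * mask)[active]
            if cfg.simplex_renormalize:
                clipped = np.clip(x, 0.0, None) * (mask > 0)
                sums = clipped.sum(axis=2, keepdims=True)
                np.divide(clipped, sums, out=clipped, where=sums > 0)
                occupied = mask.any(axis=2, keepdims=True)
                x = np.where(occupied, clipped, x)
        iters += steps

        projected = _project(x, seeds, allowed, cfg.frozen_positions)
        scores = objective.value(encode_batch(projected))
        for i in np.nonzero(active)[0]:
            seq_i, score_i = projected[i], float(scores[i])
            if record_traces:
                traces[i].iterations.append((iters, seq_i, score_i))
            if score_i > traces[i].best[1]:
                traces[i].best = (seq_i, score_i)
                stall[i] = 0
            else:
                stall[i] += 1
                if stall[i] >= cfg.patience:
                    traces[i].termination_reason = "patience"
                    active[i] = False
    for t in traces:
        if not t.termination_reason:
            t.termination_reason = "max_iterations"
    return traces


def optimize_seed(
    seed: str, objective: Objective, cfg: OptimizerConfig = OptimizerConfig()
) -> OptimizationTrace:
    """Run gradient ascent from a single seed; returns the full trace."""
    return _optimize_batch([seed], objective, cfg)[0]


def score_candidates(
    candidates: Sequence[tuple[str, str]],
    ensemble: EnsembleModel,
    output_index: int = 0,
) -> list[DesignCandidate]:
    """Score (sequence, seed) pairs with every ensemble member."""
    if not candidates:
        return []
    seqs = [c[0] for c in candidates]
    seeds = [c[1] for c in candidates]
    unique_seeds = list(dict.fromkeys(seeds))
    seed_scores = ensemble.member_scores(unique_seeds, output_index)
    seed_col = {s: seed_scores[:, i] for i, s in enumerate(unique_seeds)}
    cand_scores = ensemble.member_scores(seqs, output_index)

    out = []
    for i, (seq, seed) in enumerate(candidates):
        per = cand_scores[:, i]
        votes = int(np.sum(per > seed_col[seed]))
        mean = float(per.mean())
        var = float(per.var(ddof=1)) if len(per) > 1 else 0.0
        out.append(
            DesignCandidate(
                sequence=seq,
                seed=seed,
                edit_distance=hamming(seq, seed),
                per_member=per,
                votes=votes,
                mean=mean,
                variance=var,
                upper95=mean + Z_UPPER * np.sqrt(var),
            )
        )
    return out


def vote_and_threshold(
    candidates: Sequence[DesignCandidate],
    vote_rule: int,
    score_threshold: float,
    budget: int,
) -> list[DesignCandidate]:
    """Two-step selection: member voting, then mean-score thresholding.

    Step 1 keeps candidates whose ``votes`` (members scoring the candidate
    strictly above its own seed) reach ``vote_rule``.  Step 2 keeps
    survivors with ensemble mean >= ``score_threshold``, sorted by
    descending mean (ties broken lexicographically by sequence), truncated
    to ``budget``.
    """
    if budget <= 0:
        raise ValueError(f"budget must be positive, got {budget}")
    survivors = [c for c in candidates if c.votes >= vote_rule]
    survivors = [c for c in survivors if c.mean >= score_threshold]
    survivors.sort(key=lambda c: (-c.mean, c.sequence))
    accepted = survivors[:budget]
    for c in accepted:
        c.accepted = True
    return accepted


#: Default step-size / projection-interval grid: the cross product of
#: lambda in {0.1, 0.5, 1.0} and k in {1, 5, 10}.
DEFAULT_GRID: tuple[tuple[float, int], ...] = tuple(
    (lam, k) for lam in (0.1, 0.5, 1.0) for k in (1, 5, 10)
)


def propose_library(
    seeds: Sequence[str],
    ensemble: EnsembleModel,
    grid: Sequence[tuple[float, int]] = DEFAULT_GRID,
    budget: int = 500,
    vote_rule: int | None = None,
    score_threshold: float = 0.0,
    base_cfg: OptimizerConfig = OptimizerConfig(),
    objective_mode: str = "mean",
    max_iterations: int | None = None,
) -> list[DesignCandidate]:
    """Full Ens-Grad design run: optimize, pool, deduplicate, vote, threshold.

    Runs gradient ascent from every seed under every (step size,
    projection interval) setting of the grid — against the ensemble mean
    (default) or against each member separately (``objective_mode=
    "members"``) — pools the best projected sequences, drops duplicates
    and seed-identical proposals, scores the pool with every member and
    applies ``vote_and_threshold``.  ``vote_rule`` defaults to a strict
    majority of the ensemble.
    """
    if not seeds:
        return []
    if vote_rule is None:
        vote_rule = len(ensemble) // 2 + 1
    if objective_mode == "mean":
        objectives: list[Objective] = [EnsembleMeanObjective(ensemble)]
    elif objective_mode == "members":
        objectives = [ModelObjective(m) for m in ensemble.members]
    else:
        raise ValueError(f"unknown objective_mode {objective_mode!r}")

    seed_set = set(seeds)
    pooled: dict[str, str] = {}  # proposal -> seed (first occurrence)
    for lam, k in grid:
        cfg = OptimizerConfig(
            step_size=lam,
            projection_interval=k,
            patience=base_cfg.patience,
            max_iterations=max_iterations or base_cfg.max_iterations,
            allowed_residues=base_cfg.allowed_residues,
            frozen_positions=base_cfg.frozen_positions,
        )
        for obj in objectives:
            traces = _optimize_batch(list(seeds), obj, cfg, record_traces=False)
            for t in traces:
                best_seq = t.best[0]
                if best_seq not in seed_set and best_seq not in pooled:
                    pooled[best_seq] = t.seed

    candidates = score_candidates([(s, pooled[s]) for s in pooled], ensemble)
    return vote_and_threshold(candidates, vote_rule, score_threshold, budget)


def candidate_frame(candidates: Sequence[DesignCandidate]) -> pd.DataFrame:
    """Tabulate design candidates for CSV output."""
    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in candidates],
            "seed": [c.seed for c in candidates],
            "edit_distance": [c.edit_distance for c in candidates],
            "votes": [c.votes for c in candidates],
            "mean": [c.mean for c in candidates],
            "variance": [c.variance for c in candidates],
            "upper95": [c.upper95 for c in candidates],
            "accepted": [c.accepted for c in candidates],
        }
    ).set_index("sequence")
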