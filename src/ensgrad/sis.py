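"""Sufficient Input Subsets: minimal position sets that justify a score.

A sufficient input subset (SIS) of a sequence is a set of positions whose
residues alone — all other positions masked out — keep the model's
predicted enrichment at or above a threshold (0.4 log10 units by
default).  Subsets are found by backward selection: repeatedly mask the
position whose removal hurts the prediction least, then take the minimal
suffix of the removal order that restores the threshold, and prune it so
that removing any single remaining position drops the prediction below
the threshold.  Masking uses the all-zero column, identical to the
encoder's padding semantics; disjoint additional subsets are extracted by
re-running on the residual masked input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ensgrad.sequences import ALPHABET, Alphabet, encode_onehot

#: Default prediction threshold (log10 enrichment units).
SIS_THRESHOLD = 0.4

BatchScorer = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SufficientSubset:
    sequence: str
    positions: frozenset[int]
    threshold: float
    masked_prediction: float

    @property
    def residues(self) -> dict[int, str]:
        return {p: self.sequence[p] for p in sorted(self.positions)}


def _as_scorer(objective) -> BatchScorer:
    if hasattr(objective, "value"):
        return objective.value
    return objective


def _masked_input(
    x_full: np.ndarray, positions: Sequence[frozenset[int] | set[int]],
    mask_column: np.ndarray,
) -> np.ndarray:
    """Batch of inputs with ONLY the given positions unmasked, per entry."""
    out = np.broadcast_to(mask_column, x_full.shape).copy()
    batch = np.stack([out] * len(positions))
    for i, pos in enumerate(positions):
        for p in pos:
            batch[i, p] = x_full[p]
    return batch


def find_sis(
    objective,
    seq: str,
    threshold: float = SIS_THRESHOLD,
    mask_column: np.ndarray | None = None,
    max_subsets: int = 10,
    alphabet: Alphabet = ALPHABET,
) -> list[SufficientSubset]:
    """All disjoint sufficient input subsets of ``seq``, strongest first.

    ``objective`` is any batch scorer over (n, 20, 20) matrices (an
    optimizer ``Objective`` works directly).  Returns an empty list when
    even the fully unmasked sequence scores below the threshold.
    """
    scorer = _as_scorer(objective)
    x_full = encode_onehot(seq, alphabet)
    if mask_column is None:
        mask_column = np.zeros(len(alphabet))
    mask_column = np.asarray(mask_column, dtype=np.float64)

    def f(position_sets: Sequence[set[int] | frozenset[int]]) -> np.ndarray:
        return scorer(_masked_input(x_full, position_sets, mask_column))

    if float(f([set(range(len(seq)))])[0]) < threshold:
        return []

    subsets: list[SufficientSubset] = []
    available = set(range(len(seq)))
    while available and len(subsets) < max_subsets:
        if float(f([available])[0]) < threshold:
            break
        # backward selection over the available positions
        remaining = set(available)
        removal_order: list[int] = []
        while remaining:
            candidates = sorted(remaining)
            scores = f([remaining - {p} for p in candidates])
            p_best = candidates[int(np.argmax(scores))]
            remaining.remove(p_best)
            removal_order.append(p_best)
        # minimal suffix of the removal order restoring the threshold
        subset: set[int] = set()
        for p in reversed(removal_order):
            subset.add(p)
            if float(f([subset])[0]) >= threshold:
                break
        # prune to greedy minimality
        changed = True
        while changed and len(subset) > 1:
            changed = False
            for p in sorted(subset):
                trial = subset - {p}
                if trial and float(f([trial])[0]) >= threshold:
                    subset = trial
                    changed = True
                    break
        pred = float(f([subset])[0])
        if pred < threshold:
            break
        subsets.append(
            SufficientSubset(
                sequence=seq,
                positions=frozenset(subset),
                threshold=threshold,
                masked_prediction=pred,
            )
        )
        available -= subset
    subsets.sort(key=lambda s: -s.masked_prediction)
    return subsets


def sis_frequency_logo(
    subsets: Sequence[SufficientSubset], alphabet: Alphabet = ALPHABET
) -> pd.DataFrame:
    """Per-position residue frequencies restricted to SIS-member residues.

    Counts each subset's residues at its positions only, then normalizes
    per position; rows are positions, columns residues.  All underlying
    sequences must share one length.  The matrix is directly renderable as
    a sequence logo.
    """
    if not subsets:
        raise ValueError("no subsets given")
    lengths = {len(s.sequence) for s in subsets}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths {sorted(lengths)}; logos need one length")
    length = lengths.pop()
    counts = np.zeros((length, len(alphabet)))
    for s in subsets:
        for p in s.positions:
            counts[p, alphabet.index_of(s.sequence[p])] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return pd.DataFrame(freq, columns=list(alphabet.residues),
                        index=pd.RangeIndex(length, name="position"))
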