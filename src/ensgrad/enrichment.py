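"""Per-round frequencies and round-to-round log10 enrichment.

Enrichment of a sequence between panning rounds is the log10 ratio of its
frequency in the later round to its frequency in the earlier round.  A
positive value indicates selection for binding; the sign doubles as the
classification label.  Frequencies are always computed on the unfiltered
per-round totals so that filtering never changes a surviving sequence's
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RoundCountTable:
    """Sequence read counts per panning round.

    ``counts`` is a DataFrame indexed by sequence with one integer column
    per round identifier (e.g. R1, R2, R3), in panning order.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def rounds(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_mapping(
        cls, counts: Mapping[str, Sequence[int]], rounds: Sequence[str]
    ) -> "RoundCountTable":
        df = pd.DataFrame.from_dict(dict(counts), orient="index", columns=list(rounds))
        df.index.name = "sequence"
        return cls(df.astype(np.int64))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RoundCountTable":
        """Read ``sequence<TAB>count_R1<TAB>count_R2...`` with a header row."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected sequence column plus round columns")
        df = df.set_index(df.columns[0])
        df.index.name = "sequence"
        df.columns = [c.removeprefix("count_") for c in df.columns]
        try:
            df = df.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-integer count: {exc}") from exc
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.columns = [f"count_{c}" for c in out.columns]
        out.to_csv(path, sep="\t", index_label="sequence")


@dataclass(frozen=True)
class FilterPolicy:
    """Denoising rules applied before computing enrichment.

    ``min_count_from`` — required read count in the earlier round (drop
    sequences below it).  ``absent_policy`` — what to do with sequences
    that vanish in the later round: ``"pseudo"`` substitutes
    ``pseudo_count`` reads there (keeping negatively enriched sequences
    finite), ``"drop"`` removes them.
    """

    min_count_from: int = 1
    absent_policy: Literal["pseudo", "drop"] = "pseudo"
    pseudo_count: float = 1.0


@dataclass
class EnrichmentRecord:
    sequence: str
    freq: dict[str, float] = field(default_factory=dict)
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    label: dict[tuple[str, str], bool] = field(default_factory=dict)


def compute_frequencies(table: RoundCountTable) -> pd.DataFrame:
    """Per-round sequence frequencies: count / round total.

    Raises if any round total is zero (frequencies undefined).
    """
    totals = table.totals
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in round(s): {list(zero.index)}")
    return table.counts / totals


def compute_enrichment(
    table: RoundCountTable,
    from_round: str,
    to_round: str,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """log10 round-to-round enrichment for sequences passing the policy.

    Returns a DataFrame indexed by sequence with columns ``freq_from``,
    ``freq_to``, ``enrichment`` and boolean ``label`` (positive
    enrichment).  Zero later-round counts are handled per the policy and
    never yield NaN or -inf.
    """
    for r in (from_round, to_round):
        if r not in table.rounds:
            raise KeyError(f"round {r!r} not in table rounds {table.rounds}")
    freqs = compute_frequencies(table)
    counts_from = table.counts[from_round]
    counts_to = table.counts[to_round]

    keep = counts_from >= max(policy.min_count_from, 1)
    if policy.absent_policy == "drop":
        keep &= counts_to > 0
    sub_from = counts_from[keep]
    sub_to = counts_to[keep].astype(np.float64)
    if policy.absent_policy == "pseudo":
        sub_to = sub_to.where(sub_to > 0, policy.pseudo_count)

    total_from = float(table.totals[from_round])
    total_to = float(table.totals[to_round])
    freq_from = sub_from / total_from
    freq_to = sub_to / total_to
    enr = np.log10(freq_to / freq_from)
    out = pd.DataFrame(
        {
            "freq_from": freq_from,
            "freq_to": freqs.loc[keep, to_round],
            "enrichment": enr,
            "label": enr > 0,
        }
    )
    out.index.name = "sequence"
    return out


def replicate_consistency(
    a: pd.DataFrame | Mapping[str, float], b: pd.DataFrame | Mapping[str, float]
) -> dict:
    """Pearson correlation of enrichment between two replicates.

    Accepts the ``compute_enrichment`` output (or any sequence->enrichment
    mapping) for each replicate and correlates over the shared sequences.
    """
    sa = a["enrichment"] if isinstance(a, pd.DataFrame) else pd.Series(dict(a))
    sb = b["enrichment"] if isinstance(b, pd.DataFrame) else pd.Series(dict(b))
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sequences; need at least 3")
    r, p = stats.pearsonr(sa.loc[shared], sb.loc[shared])
    return {"pearson_r": float(r), "p_value": float(p), "n_shared": int(len(shared))}
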