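"""Binder-class labels across targets and off-target counter-selection.

Classes follow the sign table of the panning campaigns: a sequence is a
*target-specific* binder when its round-2-to-round-3 enrichment is
positive for the focal target and non-positive for every off-target; an
*Fc binder* when enrichment is positive for every Fc-containing target but
non-positive for the Fc-free one; *non-specific* when it binds the focal
target and at least one off-target; otherwise a *non-binder*.  Exactly
zero enrichment counts as non-positive throughout.

The filter rejects a design candidate when the multi-output ensemble's
95% confidence upper bound on predicted enrichment is positive for ANY
off-target — a pessimistic rule that trades a little recall on specific
binders for strong rejection of cross-reactive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ensgrad.ensemble import EnsembleModel, predict_ensemble


@dataclass(frozen=True)
class BinderLabel:
    binder_class: str  # target_specific | non_specific | fc_binder | non_binder
    evidence: dict[str, bool]  # target -> positive-enrichment sign


def label_binders(
    per_target_enrichment: Mapping[str, float],
    focal_target: str,
    fc_targets: Sequence[str] = (),
    fc_free_target: str | None = None,
) -> BinderLabel:
    """Classify a sequence from its per-target enrichment signs."""
    if focal_target not in per_target_enrichment:
        raise KeyError(f"missing enrichment for focal target {focal_target!r}")
    signs = {t: bool(v > 0) for t, v in per_target_enrichment.items()}

    fc_set = set(fc_targets) | {focal_target}
    is_fc_binder = (
        fc_free_target is not None
        and all(signs.get(t, False) for t in fc_set)
        and not signs.get(fc_free_target, False)
    )
    off_targets = [t for t in signs if t not in (focal_target, fc_free_target)]
    if is_fc_binder:
        cls = "fc_binder"
    elif signs[focal_target] and not any(signs[t] for t in off_targets):
        cls = "target_specific"
    elif signs[focal_target]:
        cls = "non_specific"
    else:
        cls = "non_binder"
    return BinderLabel(binder_class=cls, evidence=signs)


def filter_nonspecific(
    candidates: Sequence[str],
    offtarget_ensemble: EnsembleModel,
    offtarget_names: Sequence[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Reject candidates whose off-target upper bound is positive anywhere.

    ``offtarget_ensemble`` is a multi-output ensemble with one regression
    output per off-target.  Returns (kept sequences, rejection records);
    each rejection names the triggering target(s) and their upper bounds.
    """
    candidates = list(candidates)
    if not candidates:
        return [], []
    n_outputs = offtarget_ensemble.members[0].spec.n_outputs
    if offtarget_names is None:
        offtarget_names = [f"offtarget_{j}" for j in range(n_outputs)]
    if len(offtarget_names) != n_outputs:
        raise ValueError(
            f"{len(offtarget_names)} names for {n_outputs} ensemble outputs"
        )

    uppers = np.stack(
        [
            [p.upper95 for p in predict_ensemble(offtarget_ensemble, candidates, output_index=j)]
            for j in range(n_outputs)
        ],
        axis=1,
    )  # (n_candidates, n_offtargets)

    kept: list[str] = []
    rejected: list[dict] = []
    for i, seq in enumerate(candidates):
        triggering = [offtarget_names[j] for j in range(n_outputs) if uppers[i, j] > 0]
        if triggering:
            rejected.append(
                {
                    "sequence": seq,
                    "triggering_targets": triggering,
                    "upper95": {offtarget_names[j]: float(uppers[i, j]) for j in range(n_outputs)},
                }
            )
        else:
            kept.append(seq)
    return kept, rejected
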