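"""Shared fixtures: one small simulated campaign and models trained on it.

The heavier fixtures are session-scoped so the expensive work (panning
simulation, ensemble training) happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ensgrad.enrichment import compute_enrichment
from ensgrad.ensemble import fit_ensemble
from ensgrad.models import TrainingConfig, build_architecture, train_model
from ensgrad.sequences import encode_batch
from ensgrad.simulate import AffinityLandscape, sample_library, simulate_rounds


@pytest.fixture(scope="session")
def campaign():
    """A small simulated 3-round panning campaign with ground truth."""
    landscape = AffinityLandscape.random(seed=7)
    library = sample_library(1200, seed=8)
    run = simulate_rounds(library, landscape, beta=1.0, depth=60_000,
                          n_rounds=3, seed=9)
    records = compute_enrichment(run.table, "R2", "R3")
    seqs = list(records.index)
    return {
        "landscape": landscape,
        "library": library,
        "run": run,
        "records": records,
        "sequences": seqs,
        "x": encode_batch(seqs),
        "y": records["enrichment"].to_numpy(),
        "labels": records["label"].to_numpy(),
        "truth": landscape.score_batch(seqs),
    }


@pytest.fixture(scope="session")
def small_model(campaign):
    """One quickly trained dense model on the campaign data."""
    model = build_architecture("Seq_32_32", seed=1)
    train_model(model, campaign["x"], campaign["y"], campaign["labels"],
                TrainingConfig(max_epochs=40, seed=2))
    return model


@pytest.fixture(scope="session")
def small_ensemble(campaign):
    """A 2-architecture x 2-subset ensemble, trained briefly."""
    return fit_ensemble(
        campaign["x"], campaign["y"], campaign["labels"],
        architectures=["Seq_32_32", "Seq_32x1_16"], n_subsets=2,
        cfg=TrainingConfig(max_epochs=15, seed=3),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
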