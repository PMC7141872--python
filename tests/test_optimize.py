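"""Seed selection, gradient ascent and voting-thresholding."""

import numpy as np
import pandas as pd
import pytest

from ensgrad.optimize import (
    DesignCandidate,
    LinearObjective,
    OptimizerConfig,
    _channel_indices,
    optimize_seed,
    propose_library,
    select_seeds,
    vote_and_threshold,
)
from ensgrad.sequences import ALPHABET


def _records(rows):
    df = pd.DataFrame(rows, columns=["sequence", "enrichment", "freq_to"])
    return df.set_index("sequence")


class TestSelectSeeds:
    def test_boundary_cases_of_the_selection_rule(self):
        records = _records([
            ("AAAAAAAAAA", 0.0, 1e-6),    # kept: enrichment non-negative
            ("CCCCCCCCCC", -0.5, 6e-5),   # kept: frequency clause
            ("DDDDDDDDDD", -0.5, 5e-5),   # rejected: frequency not strictly above
            ("EEEEEEEEEE", -0.01, 4e-5),  # rejected on both clauses
        ])
        assert select_seeds(records) == ["AAAAAAAAAA", "CCCCCCCCCC"]

    def test_order_preserved_duplicates_removed(self):
        records = _records([
            ("GGGGGGGGGG", 0.2, 0.0),
            ("AAAAAAAAAA", 0.1, 0.0),
            ("GGGGGGGGGG", 0.3, 0.0),
        ])
        assert select_seeds(records) == ["GGGGGGGGGG", "AAAAAAAAAA"]

    def test_missing_columns_raise(self):
        with pytest.raises(KeyError, match="freq_to"):
            select_seeds(pd.DataFrame({"enrichment": [1.0]}, index=["AAAAAAAAAA"]))


class TestOptimizeSeed:
    def test_zero_step_size_returns_seed(self, rng):
        w = rng.normal(size=(20, 20))
        trace = optimize_seed("ACDEFGHIKL", LinearObjective(w),
                              OptimizerConfig(step_size=0.0, projection_interval=1))
        assert trace.best[0] == "ACDEFGHIKL"
        assert trace.termination_reason == "patience"

    def test_constant_objective_terminates_by_patience(self):
        class Constant:
            def value(self, x):
                return np.zeros(len(x))

            def gradient(self, x):
                return np.zeros_like(x)

        trace = optimize_seed("ACDEFGHIKL", Constant(), OptimizerConfig())
        assert trace.best[0] == "ACDEFGHIKL"
        assert trace.termination_reason == "patience"

    @pytest.mark.parametrize("instance", range(15))
    def test_recovers_separable_linear_optimum(self, instance):
        rng = np.random.default_rng(instance)
        w = rng.normal(size=(20, 20))
        length = int(rng.integers(10, 19))
        seed = "".join(rng.choice(list(ALPHABET.residues), size=length))
        cfg = OptimizerConfig(step_size=5.0, projection_interval=200,
                              max_iterations=5000)
        allowed = _channel_indices(cfg.allowed_residues)
        trace = optimize_seed(seed, LinearObjective(w), cfg)
        oracle = "".join(
            ALPHABET.residues[allowed[np.argmax(w[p, allowed])]]
            for p in range(length)
        )
        assert trace.best[0] == oracle

    def test_best_score_never_below_seed_score(self, rng):
        w = rng.normal(size=(20, 20))
        obj = LinearObjective(w)
        seed = "ACDEFGHIKLMQ"
        trace = optimize_seed(seed, obj, OptimizerConfig(max_iterations=100))
        from ensgrad.sequences import encode_batch
        assert trace.best[1] >= float(obj.value(encode_batch([seed]))[0])

    def test_no_disallowed_residues_and_length_preserved(self):
        w = np.zeros((20, 20))
        # make cysteine and asparagine maximally attractive everywhere
        w[:, ALPHABET.index_of("C")] = 10.0
        w[:, ALPHABET.index_of("N")] = 9.0
        w[:, ALPHABET.index_of("W")] = 1.0
        cfg = OptimizerConfig(step_size=1.0, projection_interval=1,
                              max_iterations=200)
        trace = optimize_seed("ADDEFGHIKL", LinearObjective(w), cfg)
        assert len(trace.best[0]) == 10
        assert trace.best[0] == "W" * 10  # best *allowed* channel everywhere

        # a seed already carrying cysteine keeps it only in itself: every
        # projected proposal avoids the disallowed channels
        trace_c = optimize_seed("ACDEFGHIKL", LinearObjective(w), cfg)
        for _, proposal, _ in trace_c.iterations:
            assert "C" not in proposal and "N" not in proposal

    def test_frozen_positions_keep_seed_residue(self):
        w = np.zeros((20, 20))
        w[:, ALPHABET.index_of("W")] = 5.0
        seed = "ACDEFGHIKL"
        cfg = OptimizerConfig(step_size=1.0, projection_interval=1,
                              max_iterations=100, frozen_positions=frozenset({0, 3}))
        trace = optimize_seed(seed, LinearObjective(w), cfg)
        best = trace.best[0]
        assert best[0] == "A" and best[3] == "E"
        assert set(best[1:3]) | set(best[4:]) == {"W"}

    def test_simplex_mode_improves_on_seed(self, rng):
        w = rng.normal(size=(20, 20))
        obj = LinearObjective(w)
        cfg = OptimizerConfig(step_size=0.5, projection_interval=5,
                              max_iterations=200, simplex_renormalize=True)
        trace = optimize_seed("ACDEFGHIKL", obj, cfg)
        from ensgrad.sequences import encode_batch
        assert trace.best[1] >= float(obj.value(encode_batch(["ACDEFGHIKL"]))[0])
        assert trace.termination_reason in ("patience", "max_iterations")

    def test_best_is_max_over_recorded_projections(self, rng):
        w = rng.normal(size=(20, 20))
        trace = optimize_seed("ACDEFGHIKLMQ", LinearObjective(w),
                              OptimizerConfig(max_iterations=80))
        recorded = [s for _, _, s in trace.iterations]
        if recorded:
            assert trace.best[1] >= max(recorded) - 1e-12


class TestVoteAndThreshold:
    def _candidate(self, seq, votes, mean):
        return DesignCandidate(sequence=seq, seed="A" * len(seq), edit_distance=1,
                               per_member=np.zeros(3), votes=votes, mean=mean)

    def test_rejects_unanimous_worsening(self):
        c = self._candidate("CCCCCCCCCC", votes=0, mean=99.0)
        assert vote_and_threshold([c], vote_rule=1, score_threshold=0.0, budget=10) == []

    def test_accepts_unanimous_improvement_above_threshold(self):
        c = self._candidate("CCCCCCCCCC", votes=3, mean=0.5)
        out = vote_and_threshold([c], vote_rule=3, score_threshold=0.0, budget=10)
        assert out == [c] and c.accepted

    def test_matches_exhaustive_filter_then_sort(self, rng):
        cands = []
        for i in range(20):
            seq = "".join(rng.choice(list(ALPHABET.residues), size=10))
            cands.append(self._candidate(seq, votes=int(rng.integers(0, 4)),
                                         mean=float(rng.normal())))
        vote_rule, thr, budget = 2, 0.0, 5
        got = vote_and_threshold(list(cands), vote_rule, thr, budget)
        oracle = sorted(
            [c for c in cands if c.votes >= vote_rule and c.mean >= thr],
            key=lambda c: (-c.mean, c.sequence),
        )[:budget]
        assert [c.sequence for c in got] == [c.sequence for c in oracle]

    def test_budget_must_be_positive(self):
        with pytest.raises(ValueError, match="budget"):
            vote_and_threshold([], 1, 0.0, 0)


class TestProposeLibrary:
    def test_empty_seed_list_gives_empty_library(self, small_ensemble):
        assert propose_library([], small_ensemble) == []

    def test_design_pipeline_properties(self, small_ensemble, campaign):
        seeds = campaign["sequences"][:10]
        accepted = propose_library(seeds, small_ensemble, grid=((0.5, 5),),
                                   budget=50, max_iterations=30,
                                   score_threshold=-np.inf, vote_rule=1)
        for c in accepted:
            assert len(c.sequence) == len(c.seed)
            assert "C" not in c.sequence and "N" not in c.sequence
            assert c.sequence not in set(seeds)
            assert c.votes >= 1
            assert c.accepted
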