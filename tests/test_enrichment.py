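"""Frequencies, log10 enrichment and the filter policy."""

import numpy as np
import pandas as pd
import pytest

from ensgrad.enrichment import (
    FilterPolicy,
    RoundCountTable,
    compute_enrichment,
    compute_frequencies,
    replicate_consistency,
)


@pytest.fixture()
def toy_table():
    # 6 sequences, mixed enrichment directions, hand-checkable totals
    counts = {
        "AAAAAAAAAA": [50, 100],
        "CCCCCCCCCC": [100, 100],
        "DDDDDDDDDD": [200, 50],
        "EEEEEEEEEE": [400, 600],
        "FFFFFFFFFF": [250, 150],
        "GGGGGGGGGG": [0, 0],
    }
    return RoundCountTable.from_mapping(counts, ["R2", "R3"])


def test_frequencies_match_hand_division(toy_table):
    freqs = compute_frequencies(toy_table)
    assert freqs.loc["AAAAAAAAAA", "R2"] == pytest.approx(50 / 1000)
    assert freqs.loc["GGGGGGGGGG", "R3"] == 0.0
    assert freqs.sum(axis=0).tolist() == pytest.approx([1.0, 1.0])


def test_zero_total_round_raises():
    t = RoundCountTable.from_mapping({"AAAAAAAAAA": [5, 0]}, ["R1", "R2"])
    with pytest.raises(ValueError, match="zero total"):
        compute_frequencies(t)


def test_enrichment_matches_hand_arithmetic(toy_table):
    rec = compute_enrichment(toy_table, "R2", "R3")
    # totals: R2=1000, R3=1000 -> enrichment = log10(c3/c2)
    assert rec.loc["AAAAAAAAAA", "enrichment"] == pytest.approx(np.log10(2))
    assert rec.loc["CCCCCCCCCC", "enrichment"] == pytest.approx(0.0)
    assert rec.loc["DDDDDDDDDD", "enrichment"] == pytest.approx(np.log10(0.25))
    assert bool(rec.loc["AAAAAAAAAA", "label"]) is True
    assert bool(rec.loc["CCCCCCCCCC", "label"]) is False  # 0 is non-positive
    assert "GGGGGGGGGG" not in rec.index  # absent from earlier round


def test_absent_policy_pseudo_vs_drop():
    t = RoundCountTable.from_mapping(
        {"AAAAAAAAAA": [10, 0], "CCCCCCCCCC": [10, 20]}, ["R2", "R3"]
    )
    pseudo = compute_enrichment(t, "R2", "R3", FilterPolicy(absent_policy="pseudo"))
    assert pseudo.loc["AAAAAAAAAA", "enrichment"] == pytest.approx(np.log10(0.1))
    assert np.isfinite(pseudo["enrichment"]).all()
    dropped = compute_enrichment(t, "R2", "R3", FilterPolicy(absent_policy="drop"))
    assert list(dropped.index) == ["CCCCCCCCCC"]


def test_enrichment_antisymmetric_under_round_swap(toy_table):
    fwd = compute_enrichment(toy_table, "R2", "R3", FilterPolicy(absent_policy="drop"))
    rev = compute_enrichment(toy_table, "R3", "R2", FilterPolicy(absent_policy="drop"))
    shared = fwd.index.intersection(rev.index)
    assert np.allclose(fwd.loc[shared, "enrichment"], -rev.loc[shared, "enrichment"])


def test_enrichment_scale_invariant(toy_table):
    scaled = RoundCountTable(toy_table.counts * 7)
    a = compute_enrichment(toy_table, "R2", "R3", FilterPolicy(absent_policy="drop"))
    b = compute_enrichment(scaled, "R2", "R3", FilterPolicy(absent_policy="drop"))
    assert np.allclose(a["enrichment"], b["enrichment"])


def test_missing_round_raises(toy_table):
    with pytest.raises(KeyError):
        compute_enrichment(toy_table, "R1", "R3")


def test_replicate_consistency_limits():
    a = pd.DataFrame({"enrichment": [0.1, -0.2, 0.5, 0.9]},
                     index=["s1", "s2", "s3", "s4"])
    same = replicate_consistency(a, a)
    assert same["pearson_r"] == pytest.approx(1.0)
    assert same["n_shared"] == 4
    neg = a.copy()
    neg["enrichment"] *= -1
    assert replicate_consistency(a, neg)["pearson_r"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="shared"):
        replicate_consistency(a.iloc[:2], a.iloc[:2])


def test_tsv_roundtrip(tmp_path, toy_table):
    path = tmp_path / "counts.tsv"
    toy_table.write_tsv(path)
    loaded = RoundCountTable.read_tsv(path)
    pd.testing.assert_frame_equal(loaded.counts, toy_table.counts)


def test_malformed_tsv_raises(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sequence\tcount_R1\nAAAA\tnotanumber\n")
    with pytest.raises(ValueError, match="non-integer"):
        RoundCountTable.read_tsv(path)
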