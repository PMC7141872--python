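"""Self-contained simulator benchmarks exercising the full pipeline.

Each function builds its own synthetic panning data with the bundled
generator, runs one stage of the method end to end, and returns plain
numbers.  They stand in for campaign-scale evaluations: real-data metrics
need the original sequencing data, whereas these run on one CPU in
minutes against a known ground-truth landscape.  Problem sizes are chosen
so a full sweep stays comfortably inside a coffee break; the methods note
documents them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ensgrad.enrichment import compute_enrichment
from ensgrad.ensemble import (
    calibration_report,
    compare_single_vs_ensemble,
    fit_ensemble,
)
from ensgrad.models import (
    ARCHITECTURES,
    TrainingConfig,
    build_architecture,
    count_parameters,
    train_model,
)
from ensgrad.optimize import (
    LinearObjective,
    OptimizerConfig,
    _channel_indices,
    optimize_seed,
    propose_library,
    select_seeds,
)
from ensgrad.sequences import ALPHABET, encode_batch
from ensgrad.simulate import AffinityLandscape, sample_library, simulate_rounds
from ensgrad.sis import find_sis
from ensgrad.specificity import filter_nonspecific

#: Reference parameter totals of the six canonical architectures.
EXPECTED_PARAMETER_COUNTS = {
    "Seq_32_32": 13954,
    "Seq_32x1_16": 8402,
    "Seq_32x2_16": 18706,
    "Seq_64x1_16": 16754,
    "Seq_32x1_16_filt3": 7122,
    "Seq_embed_32x1_16": 13082,
}


def table1_parameter_counts() -> dict[str, int]:
    """Build every canonical architecture and count trainable parameters."""
    return {name: count_parameters(build_architecture(name)) for name in ARCHITECTURES}


def _campaign(seed: int, n: int, depth: int, beta: float):
    """Simulate one campaign and split enrichment records 80/20."""
    landscape = AffinityLandscape.random(seed=seed)
    library = sample_library(n, seed=seed + 1)
    run = simulate_rounds(library, landscape, beta=beta, depth=depth,
                          n_rounds=3, seed=seed + 2)
    records = compute_enrichment(run.table, "R2", "R3")
    seqs = list(records.index)
    y = records["enrichment"].to_numpy()
    labels = records["label"].to_numpy()
    truth = landscape.score_batch(seqs)
    rng = np.random.default_rng(seed + 3)
    perm = rng.permutation(len(seqs))
    cut = int(0.8 * len(perm))
    return {
        "landscape": landscape,
        "run": run,
        "records": records,
        "sequences": seqs,
        "x": encode_batch(seqs),
        "y": y,
        "labels": labels,
        "truth": truth,
        "train_idx": perm[:cut],
        "test_idx": perm[cut:],
    }


def heldout_truth_correlation(
    seed: int = 0, n: int = 5000, depth: int = 100_000, beta: float = 1.0,
    architecture: str = "Seq_32_32",
) -> dict:
    """Train one model on simulated enrichment; Pearson r of its held-out
    predictions against the true landscape values."""
    c = _campaign(seed, n, depth, beta)
    tr, te = c["train_idx"], c["test_idx"]
    model = build_architecture(architecture, seed=seed + 10)
    train_model(model, c["x"][tr], c["y"][tr], c["labels"][tr],
                TrainingConfig(seed=seed + 11))
    pred = model.predict_enrichment(c["x"][te])
    r_truth = float(stats.pearsonr(pred, c["truth"][te])[0])
    r_observed = float(stats.pearsonr(pred, c["y"][te])[0])
    return {"pearson_r_truth": r_truth, "pearson_r_observed": r_observed,
            "n": int(len(te))}


def null_auroc(
    seed: int = 0, n: int = 3000, depth: int = 100_000, beta: float = 1.0,
    architecture: str = "Seq_32_32",
) -> dict:
    """Label-shuffled control: train on permuted targets, AUROC on the
    held-out true signs should sit at chance."""
    c = _campaign(seed, n, depth, beta)
    tr, te = c["train_idx"], c["test_idx"]
    rng = np.random.default_rng(seed + 20)
    y_shuf = c["y"].copy()
    lab_shuf = c["labels"].copy()
    perm = rng.permutation(len(y_shuf))
    y_shuf, lab_shuf = y_shuf[perm], lab_shuf[perm]
    model = build_architecture(architecture, seed=seed + 21)
    train_model(model, c["x"][tr], y_shuf[tr], lab_shuf[tr],
                TrainingConfig(seed=seed + 22))
    logits = model.predict(c["x"][te])[:, 1]
    return {"auroc": float(roc_auc_score(c["labels"][te], logits)),
            "n": int(len(te))}


def ensemble_benchmark(
    seed: int = 0, n: int = 2000, depth: int = 100_000, beta: float = 1.0,
    n_reps: int = 10, max_epochs: int = 60,
) -> dict:
    """Repeated ensemble-vs-members comparison plus calibration.

    For each repetition: fresh landscape/library/panning, an 18-member
    ensemble, then held-out ensemble MSE vs the best and average member
    MSE, and the variance-vs-error rank correlation.
    """
    reps = []
    for rep in range(n_reps):
        rep_seed = seed + 1000 * rep
        c = _campaign(rep_seed, n, depth, beta)
        tr, te = c["train_idx"], c["test_idx"]
        ens = fit_ensemble(
            c["x"][tr], c["y"][tr], c["labels"][tr],
            cfg=TrainingConfig(seed=rep_seed + 30, max_epochs=max_epochs),
        )
        table = compare_single_vs_ensemble(ens, c["x"][te], c["y"][te])
        ens_mse = float(table.loc["ensemble_mean", "mse"])
        member_mse = table.drop("ensemble_mean")["mse"]
        cal = calibration_report(ens, c["x"][te], c["y"][te])
        reps.append({
            "ensemble_mse": ens_mse,
            "min_member_mse": float(member_mse.min()),
            "avg_member_mse": float(member_mse.mean()),
            "beats_min_member": bool(ens_mse <= member_mse.min()),
            "beats_avg_member": bool(ens_mse <= member_mse.mean()),
            "calibration_rho": float(cal["rank_correlation"]),
        })
    return {
        "reps": reps,
        "wins_vs_min_member": int(sum(r["beats_min_member"] for r in reps)),
        "wins_vs_avg_member": int(sum(r["beats_avg_member"] for r in reps)),
        "n_reps": n_reps,
        "n": n,
    }


def calibration_benchmark(
    seed: int = 0, n_train: int = 2000, n_test: int = 2000,
    depth: int = 100_000, beta: float = 1.0, max_epochs: int = 60,
) -> dict:
    """Variance-vs-error calibration on a large held-out test set.

    One campaign sized so the held-out split has ``n_test`` sequences;
    heteroscedasticity comes from the count noise itself (rare sequences
    carry noisier enrichment estimates).
    """
    n = n_train + n_test + 500  # head-room for filtered sequences
    c = _campaign(seed, n, depth, beta)
    all_idx = np.concatenate([c["train_idx"], c["test_idx"]])
    tr, te = all_idx[:n_train], all_idx[n_train : n_train + n_test]
    ens = fit_ensemble(c["x"][tr], c["y"][tr], c["labels"][tr],
                       cfg=TrainingConfig(seed=seed + 50, max_epochs=max_epochs))
    cal = calibration_report(ens, c["x"][te], c["y"][te])
    return {"rank_correlation": float(cal["rank_correlation"]),
            "p_value": float(cal["p_value"]), "n_test": int(len(te))}


def design_lift(
    seed: int = 0, n: int = 2000, depth: int = 100_000, beta: float = 1.0,
    n_seeds: int = 200, budget: int = 500, max_epochs: int = 60,
    max_iterations: int = 60,
) -> dict:
    """Full design run: does gradient ascent beat the seeds on the true
    landscape?  One-sided rank-sum p of proposals vs seeds plus best-vs-best.
    """
    c = _campaign(seed, n, depth, beta)
    tr = c["train_idx"]
    ens = fit_ensemble(c["x"][tr], c["y"][tr], c["labels"][tr],
                       cfg=TrainingConfig(seed=seed + 40, max_epochs=max_epochs))
    seed_pool = select_seeds(c["records"])
    seeds = seed_pool[:n_seeds]
    accepted = propose_library(
        seeds, ens, grid=((0.5, 5), (1.0, 10)), budget=budget,
        max_iterations=max_iterations,
    )
    landscape = c["landscape"]
    prop_truth = landscape.score_batch([cand.sequence for cand in accepted])
    seed_truth = landscape.score_batch(seeds)
    _, p = stats.mannwhitneyu(prop_truth, seed_truth, alternative="greater")
    return {
        "n_proposals": int(len(accepted)),
        "n_seeds": int(len(seeds)),
        "mean_shift": float(prop_truth.mean() - seed_truth.mean()),
        "rank_sum_p": float(p),
        "best_proposal": float(prop_truth.max()),
        "best_seed": float(seed_truth.max()),
        "best_improved": bool(prop_truth.max() > seed_truth.max()),
    }


def optimizer_oracle(seed: int = 0, n_instances: int = 100) -> dict:
    """Separable linear landscapes: gradient ascent must recover the
    per-position argmax optimum, and every trace must terminate within
    patience of its last improvement."""
    cfg = OptimizerConfig(step_size=5.0, projection_interval=200,
                          max_iterations=5000)
    allowed = _channel_indices(cfg.allowed_residues)
    recovered = terminated = clean = 0
    for i in range(n_instances):
        rng = np.random.default_rng(seed + i)
        weights = rng.normal(size=(20, 20))
        length = int(rng.integers(10, 19))
        start = "".join(rng.choice(list(ALPHABET.residues), size=length))
        trace = optimize_seed(start, LinearObjective(weights), cfg)
        optimum = "".join(
            ALPHABET.residues[allowed[np.argmax(weights[p, allowed])]]
            for p in range(length)
        )
        recovered += trace.best[0] == optimum
        terminated += trace.termination_reason == "patience"
        clean += all(ch not in "CN" for ch in trace.best[0])
    return {
        "recovered": int(recovered),
        "patience_terminated": int(terminated),
        "no_disallowed_residues": int(clean),
        "n_instances": n_instances,
    }


class _SeparableMaskObjective:
    """Position-presence objective: unmasked position p contributes c_p."""

    def __init__(self, contributions: np.ndarray):
        self.contributions = contributions

    def value(self, x: np.ndarray) -> np.ndarray:
        present = x.sum(axis=2) > 0
        L = len(self.contributions)
        return (present[:, :L] * self.contributions).sum(axis=1)


def sis_oracle(seed: int = 0, n_instances: int = 100, threshold: float = 0.4) -> dict:
    """Random separable objectives: every emitted subset must be sufficient
    and greedy-minimal, and the family must contain a subset matching the
    brute-force minimum cardinality."""
    valid = matched = evaluated = 0
    for i in range(n_instances):
        rng = np.random.default_rng(seed + 500 + i)
        length = int(rng.integers(10, 13))
        contrib = rng.normal(0, 0.25, size=length)
        contrib[rng.choice(length, size=2, replace=False)] += 0.35
        seq = "".join(rng.choice(list(ALPHABET.residues), size=length))
        subsets = find_sis(_SeparableMaskObjective(contrib), seq, threshold=threshold)
        if contrib.sum() < threshold:
            continue  # no subset exists; find_sis returns empty, not scored
        evaluated += 1
        ok = all(
            contrib[sorted(s.positions)].sum() >= threshold
            and all(
                contrib[[p for p in s.positions if p != q]].sum() < threshold
                for q in s.positions
            )
            for s in subsets
        ) and len(subsets) > 0
        valid += ok
        brute_k = next(
            k for k in range(length + 1)
            if any(contrib[list(c)].sum() >= threshold
                   for c in combinations(range(length), k))
        )
        matched += bool(subsets) and min(len(s.positions) for s in subsets) == brute_k
    return {"valid": int(valid), "brute_force_matched": int(matched),
            "evaluated": int(evaluated)}


def _expected_log_enrichment(
    landscape: AffinityLandscape, pool: list[str], beta: float,
    query_scores: np.ndarray, from_round: int = 2, to_round: int = 3,
) -> np.ndarray:
    """Infinite-depth round-to-round enrichment of trace-level spike-ins.

    Propagates the pool's expected frequencies through selection and
    returns log10 of each query sequence's frequency ratio between the
    two rounds; a spiked-in sequence at negligible frequency enriches by
    (beta*s - ln Z) / ln 10 with Z the pool's selection normalizer.
    """
    scores = landscape.score_batch(pool)
    p = np.full(len(pool), 1.0 / len(pool))  # round 1 = unselected library
    z = []
    for _ in range(to_round - 1):
        w = p * np.exp(beta * scores)
        z.append(w.sum())  # z[r-1]: normalizer of the round r -> r+1 step
        p = w / w.sum()
    log_z = np.sum(np.log(z[from_round - 1 : to_round - 1]))
    return (beta * query_scores - log_z) / np.log(10.0)


def specificity_benchmark(
    seed: int = 0, n: int = 6000, depth: int = 100_000, beta: float = 1.0,
    n_candidates: int = 500, cross_margin: float = 0.2,
    specific_margin: float = 0.5, max_epochs: int = 60,
) -> dict:
    """Counter-selection on two off-target landscapes.

    Simulates panning of one library against two off-targets and trains a
    6-member multi-output ensemble on the observed enrichments.  Candidate
    sequences are planted by rejection-sampling fresh library draws
    against the noise-free selection model: cross-reactive candidates have
    infinite-depth enrichment above ``cross_margin`` for at least one
    off-target, specific candidates below ``-specific_margin`` for both.
    The specific margin is wider because the pessimistic upper-bound rule
    is *designed* to reject borderline negatives within roughly two member
    standard deviations of zero; a planted specific candidate must sit
    decisively outside that band.  None of the planted candidates is seen
    in training.  Reports the fraction of cross-reactive candidates
    rejected and specific candidates kept.
    """
    land_a = AffinityLandscape.random(seed=seed + 60)
    land_b = AffinityLandscape.random(seed=seed + 61)
    library = sample_library(n, seed=seed + 62)
    run_a = simulate_rounds(library, land_a, beta=beta, depth=depth, seed=seed + 63)
    run_b = simulate_rounds(library, land_b, beta=beta, depth=depth, seed=seed + 64)
    rec_a = compute_enrichment(run_a.table, "R2", "R3")
    rec_b = compute_enrichment(run_b.table, "R2", "R3")

    pool = list(library)
    joint = pd.DataFrame(index=pd.Index(pool, name="sequence"))
    joint["a"] = rec_a["enrichment"]
    joint["b"] = rec_b["enrichment"]
    joint = joint[~(joint["a"].isna() & joint["b"].isna())]
    train_seqs = list(joint.index)
    ens = fit_ensemble(
        train_seqs, joint[["a", "b"]].to_numpy(), None, n_subsets=1, n_targets=2,
        cfg=TrainingConfig(seed=seed + 66, max_epochs=max_epochs),
    )

    # plant candidates from fresh library draws, classified by the
    # noise-free selection model (margins in log10 units)
    half = n_candidates // 2
    cross_seqs: list[str] = []
    spec_seqs: list[str] = []
    seen = set(train_seqs)
    batch_seed = seed + 70
    while (len(cross_seqs) < half or len(spec_seqs) < half) and batch_seed < seed + 170:
        fresh = [s for s in sample_library(20_000, seed=batch_seed) if s not in seen]
        seen.update(fresh)
        e_a = _expected_log_enrichment(land_a, pool, beta, land_a.score_batch(fresh))
        e_b = _expected_log_enrichment(land_b, pool, beta, land_b.score_batch(fresh))
        for s, ea, eb in zip(fresh, e_a, e_b):
            if (ea > cross_margin or eb > cross_margin) and len(cross_seqs) < half:
                cross_seqs.append(s)
            elif (ea < -specific_margin and eb < -specific_margin
                  and len(spec_seqs) < half):
                spec_seqs.append(s)
        batch_seed += 1
    _, rejected_cross = filter_nonspecific(cross_seqs, ens, ["a", "b"])
    kept_spec, _ = filter_nonspecific(spec_seqs, ens, ["a", "b"])
    return {
        "n_cross_reactive": int(len(cross_seqs)),
        "n_specific": int(len(spec_seqs)),
        "cross_reactive_rejected_frac": float(len(rejected_cross) / max(len(cross_seqs), 1)),
        "specific_kept_frac": float(len(kept_spec) / max(len(spec_seqs), 1)),
    }
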