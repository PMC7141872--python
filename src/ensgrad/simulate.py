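"""Synthetic phage-panning data with a known ground-truth landscape.

The simulator supplies what real campaigns cannot at desk scale: a
randomized CDR-H3 library (uniform residues, lengths 10-18), a
ground-truth sequence-affinity landscape, and multi-round affinity
selection.  Each round reweights sequence abundance by
``exp(beta * landscape(s))`` (softmax selection at inverse temperature
``beta``) and then draws a multinomial sample of the configured
sequencing depth, so count noise scales realistically with frequency.
``beta = 0`` is the mock-panning null: no systematic enrichment, only
resampling noise.  Replicates re-draw the final round under an
independently perturbed landscape (perturbation scale ``sigma_rep``),
emulating biological replicate noise on top of sampling noise.

The landscape is additive per position/residue with optional pairwise
motif bonuses; its defaults (10% nonzero weights of scale 0.5, two
pairwise motifs) give round-to-round enrichments spanning roughly +/-2
log10, the dynamic range a real campaign shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ensgrad.enrichment import RoundCountTable
from ensgrad.sequences import ALPHABET, Alphabet, MAX_POSITIONS

#: Supported library lengths.
LIBRARY_LENGTHS = tuple(range(10, 19))


@dataclass
class AffinityLandscape:
    """Ground-truth additive sequence-affinity oracle.

    ``weights[p, c]`` is the contribution of residue channel ``c`` at
    position ``p``; ``motifs`` are ((pos_a, res_a), (pos_b, res_b), bonus)
    pairwise terms awarded when both residues are present.
    """

    weights: np.ndarray
    motifs: list[tuple[tuple[int, str], tuple[int, str], float]] = field(default_factory=list)
    intercept: float = 0.0
    alphabet: Alphabet = field(default_factory=lambda: ALPHABET)

    @classmethod
    def random(
        cls,
        seed: int,
        sparsity: float = 0.1,
        scale: float = 0.5,
        n_motifs: int = 2,
        motif_bonus: float = 1.0,
    ) -> "AffinityLandscape":
        """Sparse random landscape: ``sparsity`` of weights nonzero."""
        rng = np.random.default_rng(seed)
        w = rng.normal(0.0, scale, size=(MAX_POSITIONS, len(ALPHABET)))
        w *= rng.random(w.shape) < sparsity
        motifs = []
        for _ in range(n_motifs):
            # motif positions within the shortest library length
            p1, p2 = rng.choice(min(LIBRARY_LENGTHS), size=2, replace=False)
            r1, r2 = rng.choice(list(ALPHABET.residues), size=2)
            motifs.append(((int(p1), str(r1)), (int(p2), str(r2)), motif_bonus))
        return cls(weights=w, motifs=motifs)

    def score(self, seq: str) -> float:
        s = self.intercept
        for i, ch in enumerate(seq):
            s += self.weights[i, self.alphabet.index_of(ch)]
        for (p1, r1), (p2, r2), bonus in self.motifs:
            if p1 < len(seq) and p2 < len(seq) and seq[p1] == r1 and seq[p2] == r2:
                s += bonus
        return float(s)

    def score_batch(self, seqs: Sequence[str]) -> np.ndarray:
        return np.array([self.score(s) for s in seqs])


@dataclass
class PanningRun:
    library: dict[str, int]
    table: RoundCountTable  # columns R1..Rn over the library universe
    beta: float
    depth: int
    seed: int

    @property
    def rounds(self) -> list[str]:
        return self.table.rounds


def sample_library(
    n_sequences: int,
    seed: int,
    lengths: Sequence[int] | None = None,
    length_probs: Sequence[float] | None = None,
) -> dict[str, int]:
    """Draw an i.i.d. uniform-residue library; collisions merge counts."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if lengths is None:
        lengths = LIBRARY_LENGTHS
    for L in lengths:
        if L not in LIBRARY_LENGTHS:
            raise ValueError(f"unsupported library length {L}; allowed {LIBRARY_LENGTHS}")
    rng = np.random.default_rng(seed)
    drawn_lengths = rng.choice(list(lengths), size=n_sequences, p=length_probs)
    residues = np.array(list(ALPHABET.residues))
    library: dict[str, int] = {}
    for L in drawn_lengths:
        seq = "".join(rng.choice(residues, size=int(L)))
        library[seq] = library.get(seq, 0) + 1
    return library


def simulate_rounds(
    library: Mapping[str, int],
    landscape: AffinityLandscape,
    beta: float,
    depth: int,
    n_rounds: int = 3,
    seed: int = 0,
    select_first_round: bool = False,
) -> PanningRun:
    """Multi-round selection: reweight by exp(beta*score), sample to depth.

    Round r counts are a multinomial draw of size ``depth`` from
    probabilities proportional to ``counts_{r-1} * exp(beta * score)``.
    Round 1 is by default the *unselected* starting pool (a pure
    depth-``depth`` resampling of the library): it plays the role of the
    first observed sequence pool, and selection acts from round 2 onward.
    Set ``select_first_round`` to apply selection in round 1 as well.
    Every round's counts sum to exactly ``depth``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = list(library)
    counts = np.array([library[s] for s in seqs], dtype=np.float64)
    fitness = np.exp(beta * landscape.score_batch(seqs))

    columns = {}
    for r in range(1, n_rounds + 1):
        w = counts * fitness if (select_first_round or r > 1) else counts
        p = w / w.sum()
        counts = rng.multinomial(depth, p).astype(np.float64)
        columns[f"R{r}"] = counts.astype(np.int64)
    df = pd.DataFrame(columns, index=pd.Index(seqs, name="sequence"))
    return PanningRun(library=dict(library), table=RoundCountTable(df),
                      beta=beta, depth=depth, seed=seed)


def make_replicates(
    run: PanningRun,
    landscape: AffinityLandscape,
    sigma_rep: float,
    seed: int = 0,
) -> tuple[RoundCountTable, RoundCountTable]:
    """Two final-round re-draws under independently perturbed landscapes.

    Each replicate perturbs every sequence's landscape value with
    independent Gaussian noise of scale ``sigma_rep``, reweights the
    penultimate round's counts and re-draws the final round's multinomial.
    ``sigma_rep = 0`` gives replicates differing by sampling noise only.
    """
    if sigma_rep < 0:
        raise ValueError("sigma_rep must be >= 0")
    rng = np.random.default_rng(seed)
    rounds = run.rounds
    if len(rounds) < 2:
        raise ValueError("need at least two rounds to form replicates")
    prev, last = rounds[-2], rounds[-1]
    seqs = list(run.table.counts.index)
    base_scores = landscape.score_batch(seqs)
    prev_counts = run.table.counts[prev].to_numpy(dtype=np.float64)

    tables = []
    for _ in range(2):
        scores = base_scores + rng.normal(0.0, sigma_rep, size=len(seqs))
        w = prev_counts * np.exp(run.beta * scores)
        p = w / w.sum()
        new_last = rng.multinomial(run.depth, p).astype(np.int64)
        df = run.table.counts.copy()
        df[last] = new_last
        tables.append(RoundCountTable(df))
    return tables[0], tables[1]


def write_ground_truth(path: str | Path, landscape: AffinityLandscape,
                       seqs: Sequence[str]) -> None:
    """CSV of (sequence, true landscape value) for evaluation harnesses."""
    pd.DataFrame(
        {"landscape_value": landscape.score_batch(seqs)},
        index=pd.Index(seqs, name="sequence"),
    ).to_csv(path)
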