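# ensgrad

Machine-learning design of antibody CDR-H3 sequences from phage-display
panning data.

Phage panning physically selects binders from a randomized antibody
library, but it only *samples* sequence space — it produces no model that
says where better binders lie. `ensgrad` closes that gap: it learns
round-to-round enrichment, the log10 ratio of a sequence's frequency
between consecutive panning rounds

```
E(s) = log10( freq_R3(s) / freq_R2(s) )
```

from NGS count tables with an ensemble of small neural networks, then
*designs* improved CDR-H3 loops by gradient ascent on a relaxed one-hot
encoding of the sequence: holding the trained weights fixed, gradients are
back-propagated all the way to the input, the continuous input is updated
in steps of size λ, and every k steps it is projected back to a discrete
sequence by per-position argmax. An 18-model ensemble (6 architectures ×
3 data subsamples) provides mean predictions, variance-based uncertainty
and a pessimistic `mean + 1.96·sd` upper bound used to reject candidates
predicted to bind off-targets. Sufficient input subsets — minimal position
sets whose residues alone keep the predicted enrichment above 0.4 —
explain what the model considers load-bearing. Designs never introduce
cysteine or asparagine and preserve seed length.

A bundled panning simulator (uniform library, softmax selection
`∝ exp(β·score)` under a known ground-truth landscape, multinomial
sequencing depth, replicate noise) makes the whole pipeline testable
without any experimental data — and lets designs be scored against the
true landscape, which no real campaign can do.

Intended users: computational antibody/protein engineers working with
phage- or yeast-display NGS data, and method developers who need a
controlled benchmark for sequence-design pipelines.

## Worked example

`examples/03_design_sequences.py` — simulate a campaign, train the
ensemble, design sequences, and score them against the (known) truth:

```
$ python examples/03_design_sequences.py
100 seeds -> 186 accepted designs
true landscape value: seeds mean +0.025, designs mean +2.260
one-sided rank-sum p = 1.78e-43; best design +3.789 vs best seed +1.733
top design: SWSPKKEDQTTFTQIILI (from seed IWSEMFEMCYCICAPNNH, 15 substitutions, 18/18 votes)
```

The designs' mean true affinity rises ~2.2 log10 units above the seeds,
the best design clearly beats the best sequence the "experiment" ever
observed, and every ensemble member scores the top design above its seed
(18/18 votes). The other scripts in `examples/` walk through enrichment
computation, ensemble uncertainty and calibration, off-target filtering,
and sufficient-input-subset interpretation.

Real campaigns are consumed the same way: a TSV with
`sequence<TAB>count_R1<TAB>count_R2<TAB>count_R3` per row replaces the
simulator (see `ensgrad enrich --help`).

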