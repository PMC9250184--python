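# methylbn

Consensus Bayesian-network analysis of binarized methylation count data.

Given a sample × feature table of non-negative integer methylation counts
plus a binary treatment column, the pipeline:

1. **discretizes** counts into binary methylation states (0 stays 0, any
   positive count becomes 1) and carries the condition through as a variable;
2. **screens** all variable pairs with chi-square contingency tests and
   blocks both directions of every pair with p ≥ 0.25 (no evidence of
   dependence) from the structure search;
3. **searches** for high-scoring DAG structures with batches of 100
   random-start tabu searches maximizing the BDe (Bayesian Dirichlet
   equivalent) score, honouring the blocklist;
4. **averages** each batch into per-arc probabilities using softmax weights
   over BDe log-scores, classifies arc probabilities into high/low clusters
   with a two-component Gaussian mixture (EM), and selects arcs with
   probability ≥ 0.5 and classification uncertainty ≤ 0.01;
5. **builds a consensus** from the arcs selected in *all* of 50 independent
   repetitions, weighted by their averaged probabilities; and
6. **extracts the Markov blanket** (parents, children, spouses) of the
   condition node from the consensus network.

A first-class synthetic-data module generates ground-truth networks and
zero-inflated count matrices (state 0 → count 0; state 1 → positive count
≤ 39 by default) so that every stage is testable without external data.

## CLI

```bash
# simulate a study-shaped dataset (60 features, 46 samples)
methylbn simulate --n-features 60 --n-samples 46 --seed 1 \
    --out counts.tsv --truth-edges truth.tsv

# full pipeline with one master seed
methylbn run --input counts.tsv --outdir out/ --seed 1

# or stage by stage
methylbn discretize counts.tsv --out binary.tsv
methylbn filter counts.tsv --pvalues-out pvalues.tsv --blocklist-out blocklist.tsv
methylbn search --data binary.tsv --blocklist blocklist.tsv --seed 1 \
    --edges-out batch_edges.tsv --scores-out batch_scores.tsv
methylbn average --edges batch_edges.tsv --scores batch_scores.tsv \
    --data binary.tsv --out arcs.tsv
methylbn consensus --data binary.tsv --blocklist blocklist.tsv --seed 1 \
    --n-reps 50 --n-searches 100 --out consensus_arcs.tsv
methylbn mb consensus_arcs.tsv --target Treatment
```

`run` writes `binary.tsv`, `pvalues.tsv`, `blocklist.tsv`, per-repetition arc
tables, `consensus_arcs.tsv` (columns `arc`, `from`, `to`,
`Average.Probability`), GraphML/DOT exports with probability bands
(0.90–1.00, 0.80–0.89, 0.70–0.79, 0.60–0.69) as edge attributes,
`markov_blanket.json`, and a `provenance.json` recording every effective
setting and seed.  The master seed fully determines every output byte.
A YAML config file may supply defaults (`--config`); CLI flags win.

## Input dialect

Tab-delimited, header row of feature names plus `Treatment`
(0 = control, 1 = stress), one row per individual, integer counts.  An
optional leading `Sample` column holds sample identifiers.
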