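# promscreen

In-silico screening of **high-expression, mutation-resistant promoter
sequences** for synthetic biology.

Synthetic core promoters drive heterologous expression in hosts like
*Saccharomyces cerevisiae*, but point mutations accumulating over long
cultivations can erode their strength. `promscreen` asks, before any wet-lab
work: *which strong promoters keep their strength as substitutions
accumulate?* It couples three pieces:

1. **A sequence→expression predictor.** Any model satisfying the
   `predict(sequences) -> values` contract plugs in. The built-in
   desk-scale surrogate is ridge regression on overlapping k-mer counts
   (k = 4 by default): for an 80 bp promoter *s* with feature vector
   *x(s) ∈ ℕ^{4^k}* it fits *ŷ = xᵀβ + b* with penalty λ chosen by
   leave-one-out GCV. Fine-tuned transformer predictors enter through
   `external_predictor_adapter`.
2. **A neutral base-mutation model.** Each "generation" draws
   *m ~ U{1,2,3}* substitutions at distinct uniform sites, each to a
   uniform alternative base — no hotspots, no selection. Lineages of G
   generations (default 100) are simulated per founder on independent,
   founder-keyed RNG substreams.
3. **A trajectory screen.** Founder cohorts (e.g. the top 1000 candidates
   by predicted expression) are mutated, their predicted expression
   trajectories summarized (start, volatility, largest early rise/drop,
   net large-step balance), k-means-clustered into three behavior classes —
   *resistant*, *declining*, *volatile* — and the resistant, high-expression
   candidates ranked and exported.

Because the empirical 30M-sequence training corpus is external, the package
ships a **synthetic fitness landscape** module: an additive motif model
(baseline + Σ motif-weight × occurrence + Gaussian noise) that generates
datasets with the statistical quirks of the real data (measurement noise,
integer-valued single-dish contamination) and **plants ground-truth
robustness classes** so the whole screen is testable offline.

Evaluation uses the standard trio — Pearson correlation (PCC), mean squared
error (MSE) and the coefficient of determination R² = 1 − SS_res/SS_tot
(negative when a model underperforms the mean) — plus a sample-size-ladder
protocol: train at increasing subsample sizes, evaluate on one fixed test
set.

## Worked example

`examples/04_robustness_screen.py` plants 10 promoters of each robustness
class in a known landscape, mutates each founder for 100 generations
(1–3 substitutions per generation), predicts expression along every lineage
with the ground-truth landscape, clusters and selects:

```
recovered cluster sizes: {'resistant': 10, 'declining': 10, 'volatile': 10}
label agreement with planted classes: 30/30
selected mutation-resistant promoters (ranked): ['founder_3', 'founder_4', 'founder_2', 'founder_8', 'founder_0']
generation-100 expression mode: -0.066667 3.133333 28
```

All 30 planted classes are recovered exactly; the ranked selection is a
subset of the planted-resistant founders that additionally passed the
high-final / low-drop quantile thresholds. The density line says that by
generation 100, 28 of 30 trajectories sit in the lowest expression bin —
under sustained neutral mutation (~2.5 substitutions per site) *every*
promoter eventually relaxes to background, which is why the screen
classifies by trajectory *shape* rather than final level alone.

`examples/02_ladder_benchmark.py` shows the ladder protocol on noisy
synthetic data (PCC 0.748 → 0.980 → 0.985 for 100 → 1K → 10K training
samples), and `examples/03_mutation_lineages.py` shows founder identity
decaying toward the random-sequence Hamming distance (~60 of 80) within
100 generations.

## Command line

The same stages are available as a thin CLI driven by one YAML config
(see `promscreen --help`):

```bash
promscreen simulate-data --config pipeline.yaml   # dataset + landscape + filter
promscreen benchmark     --config pipeline.yaml   # ladder report (train_size, pcc, mse, r2)
promscreen screen        --config pipeline.yaml   # report + density + selected FASTA
```

Each run writes a manifest (config hash, per-stage seeds, version); reruns
with the same config and seed are byte-identical.

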