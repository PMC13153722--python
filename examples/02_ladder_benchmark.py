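"""Benchmark the k-mer ridge surrogate at a ladder of training-set sizes.

Trains at 100 / 1,000 / 10,000 samples drawn from one pool and evaluates
every model on the same fixed test set — the protocol used to compare
predictors as training data grows.
"""

from promscreen import SampleLadder, make_landscape, run_ladder_benchmark, sample_dataset
from promscreen.landscape import LandscapeConfig

landscape = make_landscape(LandscapeConfig(noise_sd=0.5), seed=3)
pool = sample_dataset(landscape, n=12000, seed=4)
test = sample_dataset(landscape, n=2000, seed=5)

bench = run_ladder_benchmark(pool, test, SampleLadder(sizes=(100, 1000, 10000), seed=6))
print(bench.to_frame().to_string(index=False))
# PCC/R2 rise and MSE falls with training size; the residual gap to PCC=1
# is the measurement-noise ceiling, not model error.
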