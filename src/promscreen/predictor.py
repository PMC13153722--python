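"""Sequence-to-expression prediction, evaluation metrics and ladder benchmarking.

The desk-scale surrogate is ridge-penalized linear regression on overlapping
k-mer counts (k = 4 by default, matching the tokenization that worked best
for the transformer models this surrogate stands in for). On data generated
by an additive 4-mer landscape the surrogate is well-specified and recovers
the landscape essentially exactly; it is deterministic, trains in seconds on
a laptop, and is "a predictor good enough to drive the screen". Fine-tuned
transformer predictors (or any external model) plug in through
:func:`external_predictor_adapter` instead.

Metrics follow the usual conventions: sample Pearson correlation, mean
squared error, and the coefficient of determination about the observed mean
(which can be negative for a poor model). All metrics are computed on raw
expression values. Undefined cases (constant vectors) raise rather than
returning NaN, so a degenerate ladder row cannot silently corrupt a report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.metrics import mean_squared_error as _sk_mse
from sklearn.metrics import r2_score as _sk_r2

from .landscape import FitnessLandscape, SampleLadder, draw_sample_ladder
from .sequence import PromoterRecord, kmer_count_matrix

__all__ = [
    "PredictorModel",
    "KmerRidgeModel",
    "ExternalPredictorModel",
    "MetricReport",
    "LadderBenchmark",
    "fit_kmer_ridge",
    "external_predictor_adapter",
    "oracle_predictor",
    "pearson_cc",
    "mean_squared_error",
    "r_squared",
    "evaluate",
    "run_ladder_benchmark",
    "save_model",
    "load_model",
    "DEFAULT_RIDGE_GRID",
]

#: fixed, deterministic penalty grid searched by leave-one-out GCV when no
#: explicit ridge penalty is supplied
DEFAULT_RIDGE_GRID = tuple(float(a) for a in np.logspace(-4, 4, 17))

#: tag identifying the k-mer feature ordering used by serialized models
FEATURE_ORDER_TAG = "lexicographic-ACGT"


class PredictorModel(Protocol):
    """Anything mapping a batch of sequences to one finite value each."""

    def predict(self, sequences: Sequence[str]) -> np.ndarray: ...


@dataclass
class KmerRidgeModel:
    """Fitted ridge regression on overlapping k-mer count features."""

    k: int
    coef: np.ndarray
    intercept: float
    penalty: float
    kind: str = "kmer_ridge"

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        """Predicted expression per sequence, order-preserving."""
        if len(sequences) == 0:
            return np.zeros(0, dtype=float)
        X = kmer_count_matrix(list(sequences), self.k)
        return X @ self.coef + self.intercept


@dataclass
class ExternalPredictorModel:
    """Adapter wrapping an arbitrary batch callable behind the predict contract."""

    fn: Callable[[Sequence[str]], Sequence[float]]
    kind: str = "external"

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        out = np.asarray(self.fn(list(sequences)), dtype=float)
        if out.shape != (len(sequences),):
            raise ValueError(
                f"external predictor returned shape {out.shape} for "
                f"{len(sequences)} sequences"
            )
        if len(sequences) and not np.all(np.isfinite(out)):
            raise ValueError("external predictor returned non-finite values")
        return out


def fit_kmer_ridge(
    train: Sequence[PromoterRecord],
    k: int = 4,
    ridge_penalty: float | None = None,
    seed: int = 0,
) -> KmerRidgeModel:
    """Fit the k-mer ridge surrogate.

    With ``ridge_penalty=None`` the penalty is chosen by efficient
    leave-one-out generalized cross-validation over :data:`DEFAULT_RIDGE_GRID`
    (deterministic, so two fits on the same data give identical models).
    ``seed`` is accepted for interface uniformity; the fit itself is
    deterministic.
    """
    if len(train) == 0:
        raise ValueError("training set must be non-empty")
    X = kmer_count_matrix([r.sequence for r in train], k)
    y = np.array([r.expression for r in train], dtype=float)
    if ridge_penalty is None:
        est = RidgeCV(alphas=DEFAULT_RIDGE_GRID).fit(X, y)
        penalty = float(est.alpha_)
    else:
        if ridge_penalty <= 0:
            raise ValueError("ridge_penalty must be positive")
        est = Ridge(alpha=float(ridge_penalty), solver="svd").fit(X, y)
        penalty = float(ridge_penalty)
    return KmerRidgeModel(
        k=k, coef=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_), penalty=penalty,
    )


def external_predictor_adapter(
    fn: Callable[[Sequence[str]], Sequence[float]],
) -> ExternalPredictorModel:
    """Wrap ``fn`` (sequences -> floats) behind the predict contract.

    Output length and finiteness are validated on every call.
    """
    return ExternalPredictorModel(fn=fn)


def oracle_predictor(ls: FitnessLandscape) -> ExternalPredictorModel:
    """Predictor returning the landscape's noiseless ground-truth expression."""
    return external_predictor_adapter(lambda seqs: [ls.score(s) for s in seqs])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    return x, y


def pearson_cc(x, y) -> float:
    """Sample Pearson correlation; raises on constant input instead of NaN."""
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise ValueError("pearson_cc requires vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_cc is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mean_squared_error(x, y) -> float:
    """Mean squared difference between two equal-length vectors."""
    x, y = _as_pair(x, y)
    if x.size == 0:
        raise ValueError("mean_squared_error requires non-empty vectors")
    return float(_sk_mse(x, y))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot about the observed mean.

    May be negative when predictions do worse than the observed mean.
    """
    observed, predicted = _as_pair(observed, predicted)
    if observed.size < 2 or np.ptp(observed) == 0:
        raise ValueError("r_squared requires a non-constant observed vector")
    return float(_sk_r2(observed, predicted))


@dataclass(frozen=True)
class MetricReport:
    """PCC / MSE / R² of one model evaluation."""

    pcc: float
    mse: float
    r2: float


def evaluate(observed, predicted) -> MetricReport:
    """All three metrics of ``predicted`` against ``observed``."""
    return MetricReport(
        pcc=pearson_cc(observed, predicted),
        mse=mean_squared_error(observed, predicted),
        r2=r_squared(observed, predicted),
    )


# ---------------------------------------------------------------------------
# Sample-size-ladder benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LadderBenchmark:
    """Per-training-size metrics against one fixed test set."""

    rows: tuple[tuple[int, MetricReport], ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"train_size": size, "pcc": m.pcc, "mse": m.mse, "r2": m.r2}
                for size, m in self.rows
            ],
            columns=["train_size", "pcc", "mse", "r2"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_ladder_benchmark(
    pool: Sequence[PromoterRecord],
    test: Sequence[PromoterRecord],
    ladder: SampleLadder,
    trainer: Callable[[Sequence[PromoterRecord], int], PredictorModel] | None = None,
) -> LadderBenchmark:
    """Train at each ladder size on a subsample of ``pool``; evaluate on ``test``.

    The test set is identical across rows. The caller is responsible for
    keeping ``pool`` and ``test`` disjoint. Trainer failures are re-raised
    annotated with the offending ladder size.
    """
    if trainer is None:
        trainer = lambda records, seed: fit_kmer_ridge(records, seed=seed)
    observed = np.array([r.expression for r in test], dtype=float)
    test_seqs = [r.sequence for r in test]
    rows = []
    for size, subset in zip(ladder.sizes, draw_sample_ladder(pool, ladder)):
        try:
            model = trainer(subset, ladder.seed)
            predicted = model.predict(test_seqs)
            rows.append((size, evaluate(observed, predicted)))
        except Exception as exc:
            raise RuntimeError(f"ladder benchmark failed at train_size={size}: {exc}") from exc
    return LadderBenchmark(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Model serialization (flat text)
# ---------------------------------------------------------------------------


def save_model(model: KmerRidgeModel, path) -> None:
    """Serialize a fitted surrogate to a flat text file."""
    with open(path, "w") as fh:
        fh.write(f"kind\t{model.kind}\n")
        fh.write(f"k\t{model.k}\n")
        fh.write(f"feature_order\t{FEATURE_ORDER_TAG}\n")
        fh.write(f"penalty\t{model.penalty!r}\n")
        fh.write(f"intercept\t{model.intercept!r}\n")
        for c in model.coef:
            fh.write(f"{float(c)!r}\n")


def load_model(path) -> KmerRidgeModel:
    """Load a surrogate serialized by :func:`save_model`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header = dict(ln.split("\t", 1) for ln in lines[:5])
    if header.get("feature_order") != FEATURE_ORDER_TAG:
        raise ValueError(f"unsupported feature order {header.get('feature_order')!r}")
    k = int(header["k"])
    coef = np.array([float(ln) for ln in lines[5:]], dtype=float)
    if coef.size != 4**k:
        raise ValueError(f"expected {4**k} coefficients for k={k}, found {coef.size}")
    return KmerRidgeModel(
        k=k,
        coef=coef,
        intercept=float(header["intercept"]),
        penalty=float(header["penalty"]),
        kind=header.get("kind", "kmer_ridge"),
    )
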