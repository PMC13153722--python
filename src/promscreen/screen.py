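"""Robustness screen: expression trajectories, features, clustering, selection.

The screen turns mutation lineages into predicted-expression trajectories,
summarizes each trajectory with a small feature vector, clusters the cohort
into three behavior classes — mutation-resistant, declining, and volatile —
and ranks the resistant, high-expression candidates.

A note on feature choice. Under the default mutation pressure (1–3
substitutions per generation for 100 generations on an 80 bp sequence,
about 2.5 hits per site in total) every lineage's sequence is essentially
randomized, so all trajectories relax toward the landscape's background
expression and the *final* value alone carries little class information.
What survives is the shape of the relaxation: mutation-resistant promoters
lose expression in many small steps (redundant weak sites), declining
promoters collapse in one large step (a single strong site), and volatile
promoters jump both down and up (strong sites destroyed and created). The
default clustering features therefore include the largest single-step rise
and drop alongside the classic level statistics.

Step features are computed over an early window (the first ~30% of
generations) as well as the full trajectory: late in the walk, drifted
background sequence occasionally creates and destroys strong sites of its
own ("flicker"), which injects large steps into every class; early on, the
planted architecture dominates and the step signature is clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .mutation import LineageTrajectory
from .predictor import PredictorModel

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryMatrix",
    "TrajectoryFeatures",
    "ClusterResult",
    "RobustnessReport",
    "expression_trajectories",
    "trajectory_features",
    "features_to_frame",
    "cluster_trajectories",
    "select_resistant",
    "top_n_by_prediction",
    "trajectory_density_summary",
    "build_report",
    "plot_trajectory_fan",
    "DEFAULT_CLUSTER_FEATURES",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = ("resistant", "declining", "volatile")

#: trajectory features used for clustering (standardized before k-means)
DEFAULT_CLUSTER_FEATURES = (
    "start",
    "volatility",
    "max_rise_early",
    "max_drop_early",
    "large_step_balance",
)

#: magnitude-like features compressed with log1p before standardization, so
#: the 2-vs-8 distinction (weak vs strong site) is not drowned by 8-vs-24
#: spread among already-large steps
LOG_COMPRESSED_FEATURES = frozenset(
    {"volatility", "volatility_early", "max_rise", "max_drop_step",
     "max_rise_early", "max_drop_early"}
)

#: fraction of the trajectory treated as the "early" window for step features
EARLY_WINDOW_FRACTION = 0.3

#: single-generation steps at least this large (expression units) count as
#: strong-site events in ``large_step_balance``; set between the weak-site
#: and strong-site effect sizes of the landscape under study
LARGE_STEP_THRESHOLD = 5.0


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Predicted expression per founder (rows) and generation (columns)."""

    values: np.ndarray  # shape (n_founders, generations + 1)
    founder_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("trajectory matrix must be 2-D")
        if values.shape[0] != len(self.founder_ids):
            raise ValueError("founder_ids length must match matrix rows")
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory matrix contains non-finite entries")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "founder_ids", tuple(self.founder_ids))

    @property
    def n_founders(self) -> int:
        return self.values.shape[0]

    @property
    def generations(self) -> int:
        return self.values.shape[1] - 1


def expression_trajectories(
    model: PredictorModel, cohort: Sequence[LineageTrajectory]
) -> TrajectoryMatrix:
    """Predict every generation of every lineage in one batched call.

    Entry (i, g) is the model's prediction for lineage i at generation g;
    batched evaluation equals sequence-by-sequence evaluation because
    prediction is deterministic given fitted state.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    n_cols = {len(t.sequences) for t in cohort}
    if len(n_cols) != 1:
        raise ValueError("all lineages must have the same number of generations")
    width = n_cols.pop()
    flat = [seq for traj in cohort for seq in traj.sequences]
    values = np.asarray(model.predict(flat), dtype=float).reshape(len(cohort), width)
    return TrajectoryMatrix(
        values=values, founder_ids=tuple(t.founder_id for t in cohort)
    )


@dataclass(frozen=True)
class TrajectoryFeatures:
    """Per-founder summary of one expression trajectory.

    ``volatility`` is the mean absolute successive difference; ``max_rise``
    and ``max_drop_step`` are the largest single-generation increase and
    decrease (0 when the trajectory never moves in that direction). The
    ``*_early`` variants restrict to the early window of the trajectory,
    where the founder's own site architecture, not background drift,
    determines the steps. ``large_step_balance`` is the summed magnitude of
    large downward steps minus large upward ones — the founder's net loss
    of strong-site content, invariant to a strong site being destroyed,
    rebuilt and destroyed again.
    """

    founder_id: str
    start: float
    final: float
    mean: float
    sd: float
    min: float
    max: float
    net_drop: float
    volatility: float
    max_rise: float
    max_drop_step: float
    volatility_early: float
    max_rise_early: float
    max_drop_early: float
    large_step_balance: float


def _step_stats(diffs: np.ndarray) -> tuple[float, float, float]:
    if diffs.size == 0:
        return 0.0, 0.0, 0.0
    return (
        float(np.abs(diffs).mean()),
        float(max(diffs.max(), 0.0)),
        float(max(-diffs.min(), 0.0)),
    )


def trajectory_features(
    tm: TrajectoryMatrix,
    early_fraction: float = EARLY_WINDOW_FRACTION,
    large_step_threshold: float = LARGE_STEP_THRESHOLD,
) -> list[TrajectoryFeatures]:
    """Compute features row-wise; deterministic."""
    if not 0.0 < early_fraction <= 1.0:
        raise ValueError("early_fraction must lie in (0, 1]")
    n_steps = tm.values.shape[1] - 1
    early_steps = max(1, int(round(early_fraction * n_steps))) if n_steps else 0
    out = []
    for fid, row in zip(tm.founder_ids, tm.values):
        diffs = np.diff(row)
        volatility, max_rise, max_drop = _step_stats(diffs)
        vol_early, rise_early, drop_early = _step_stats(diffs[:early_steps])
        large = diffs[np.abs(diffs) >= large_step_threshold]
        out.append(
            TrajectoryFeatures(
                founder_id=fid,
                start=float(row[0]),
                final=float(row[-1]),
                mean=float(row.mean()),
                sd=float(row.std(ddof=0)),
                min=float(row.min()),
                max=float(row.max()),
                net_drop=float(row[0] - row[-1]),
                volatility=volatility,
                max_rise=max_rise,
                max_drop_step=max_drop,
                volatility_early=vol_early,
                max_rise_early=rise_early,
                max_drop_early=drop_early,
                large_step_balance=float(-large.sum()) if large.size else 0.0,
            )
        )
    return out


def features_to_frame(features: Sequence[TrajectoryFeatures]) -> pd.DataFrame:
    cols = [f.name for f in fields(TrajectoryFeatures)]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in features], columns=cols)


@dataclass(frozen=True)
class ClusterResult:
    """k-means labels plus the deterministic semantic class mapping."""

    labels: tuple[str, ...]  # semantic label per founder (order of input)
    raw_labels: tuple[int, ...]  # k-means cluster index per founder
    mapping: dict[int, str]  # cluster index -> semantic label


def cluster_trajectories(
    features: Sequence[TrajectoryFeatures],
    n_clusters: int = 3,
    seed: int = 0,
    feature_names: Sequence[str] = DEFAULT_CLUSTER_FEATURES,
) -> ClusterResult:
    """k-means over standardized trajectory features + semantic relabeling.

    Magnitude-like features are log1p-compressed, then all features are
    standardized; a feature that is (numerically) constant across the
    cohort is left centred at zero rather than noise-amplified, so e.g. a
    common starting level simply drops out.

    With the default ``n_clusters=3`` the clusters are mapped to behavior
    classes deterministically:

    * **resistant** — the cluster with the highest mean resilience score,
      starting level minus largest early single-step drop: promoters that
      hold expression without large collapses;
    * **declining** — of the remainder, the cluster with the higher mean
      ``large_step_balance`` (net permanent loss of strong sites), mean
      early ``max_rise`` breaking ties (a rebound marks volatility);
    * **volatile** — the last cluster.

    Remaining ties break to the lower cluster index. For ``n_clusters != 3``
    generic ``cluster_<i>`` labels are returned.
    """
    if len(features) < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} founders to form {n_clusters} clusters, "
            f"got {len(features)}"
        )
    frame = features_to_frame(features)
    missing = set(feature_names) - set(frame.columns)
    if missing:
        raise ValueError(f"unknown clustering features: {sorted(missing)}")
    X = frame[list(feature_names)].to_numpy(dtype=float)
    for j, name in enumerate(feature_names):
        if name in LOG_COMPRESSED_FEATURES:
            X[:, j] = np.log1p(np.maximum(X[:, j], 0.0))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd < 1e-12 * np.maximum(1.0, np.abs(mu)), 1.0, sd)
    X = (X - mu) / sd
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed))
    raw = km.fit_predict(X)

    if n_clusters != 3:
        mapping = {i: f"cluster_{i}" for i in range(n_clusters)}
    else:
        mapping = _semantic_mapping(frame, raw)
    labels = tuple(mapping[int(r)] for r in raw)
    return ClusterResult(labels=labels, raw_labels=tuple(int(r) for r in raw), mapping=mapping)


def _semantic_mapping(frame: pd.DataFrame, raw: np.ndarray) -> dict[int, str]:
    stats = frame.assign(
        cluster=raw, resilience=frame["start"] - frame["max_drop_early"]
    ).groupby("cluster")[["resilience", "large_step_balance", "max_rise_early"]].mean()
    # holds its starting level without large collapses -> resistant
    resistant = int(
        stats["resilience"].round(12).sort_values(ascending=False, kind="stable").index[0]
    )
    rest = [int(i) for i in stats.index if int(i) != resistant]
    # permanent strong-site loss -> declining; rebounds mark volatility
    rest_stats = stats.loc[rest].sort_values(
        ["large_step_balance", "max_rise_early"],
        ascending=[False, True], kind="stable",
    )
    declining = int(rest_stats.index[0])
    volatile = int(rest_stats.index[1])
    return {resistant: "resistant", volatile: "volatile", declining: "declining"}


@dataclass(frozen=True)
class RobustnessReport:
    """Features, cluster label and resistant-rank for every founder."""

    features: tuple[TrajectoryFeatures, ...]
    clusters: ClusterResult
    selected: tuple[str, ...]  # resistant founder ids, ranked

    def to_frame(self) -> pd.DataFrame:
        frame = features_to_frame(self.features)
        frame["cluster"] = list(self.clusters.labels)
        rank = {fid: i + 1 for i, fid in enumerate(self.selected)}
        frame["rank"] = [rank.get(fid, 0) for fid in frame["founder_id"]]
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_resistant(
    features: Sequence[TrajectoryFeatures],
    labels: Sequence[str],
    min_final_quantile: float = 0.5,
    max_drop_quantile: float = 0.25,
) -> list[str]:
    """Rank resistant-labeled founders passing final/drop quantile filters.

    Thresholds are quantiles of the cohort's own distributions: a candidate
    must have ``final`` at or above the ``min_final_quantile`` quantile of
    all finals and ``net_drop`` at or below the ``max_drop_quantile``
    quantile of all drops. Ranking is by descending final, then descending
    mean, then founder id — a deterministic total order. An empty selection
    is returned (and logged), not an error.
    """
    for q in (min_final_quantile, max_drop_quantile):
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile thresholds must lie in [0, 1]")
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    finals = np.array([f.final for f in features])
    drops = np.array([f.net_drop for f in features])
    final_thr = float(np.quantile(finals, min_final_quantile))
    drop_thr = float(np.quantile(drops, max_drop_quantile))
    candidates = [
        f
        for f, label in zip(features, labels)
        if label == "resistant" and f.final >= final_thr and f.net_drop <= drop_thr
    ]
    if not candidates:
        logger.info("select_resistant: no founder passed the selection thresholds")
    candidates.sort(key=lambda f: (-f.final, -f.mean, f.founder_id))
    return [f.founder_id for f in candidates]


def build_report(
    tm: TrajectoryMatrix,
    n_clusters: int = 3,
    seed: int = 0,
    feature_names: Sequence[str] = DEFAULT_CLUSTER_FEATURES,
    min_final_quantile: float = 0.5,
    max_drop_quantile: float = 0.25,
) -> RobustnessReport:
    """Feature extraction, clustering and selection in one step."""
    feats = trajectory_features(tm)
    clusters = cluster_trajectories(
        feats, n_clusters=n_clusters, seed=seed, feature_names=feature_names
    )
    selected = select_resistant(
        feats,
        clusters.labels,
        min_final_quantile=min_final_quantile,
        max_drop_quantile=max_drop_quantile,
    )
    return RobustnessReport(
        features=tuple(feats), clusters=clusters, selected=tuple(selected)
    )


def top_n_by_prediction(
    model: PredictorModel, candidates: Sequence[str], n: int = 1000
) -> list[str]:
    """The ``n`` candidates with highest predicted expression, ties by input order."""
    if n > len(candidates):
        raise ValueError(f"n={n} exceeds candidate pool of {len(candidates)}")
    predictions = np.asarray(model.predict(list(candidates)), dtype=float)
    order = np.argsort(-predictions, kind="stable")
    return [candidates[i] for i in order[:n]]


def trajectory_density_summary(tm: TrajectoryMatrix, n_bins: int = 20) -> pd.DataFrame:
    """Per-generation histogram of trajectory values over a shared global range.

    A reproducible numeric stand-in for the trajectory-fan density plot:
    for each generation, counts of trajectories per expression bin; the bin
    grid is global so columns are comparable. Counts per generation sum to
    the number of founders.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = float(tm.values.min())
    hi = float(tm.values.max())
    if lo == hi:
        raise ValueError("degenerate (zero-width) global expression range")
    edges = np.linspace(lo, hi, n_bins + 1)
    rows = []
    for g in range(tm.values.shape[1]):
        counts, _ = np.histogram(tm.values[:, g], bins=edges)
        for b in range(n_bins):
            rows.append(
                {
                    "generation": g,
                    "bin_low": float(edges[b]),
                    "bin_high": float(edges[b + 1]),
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows, columns=["generation", "bin_low", "bin_high", "count"])


def plot_trajectory_fan(tm: TrajectoryMatrix, labels: Sequence[str] | None, path) -> None:
    """Optional trajectory-fan figure, one panel per behavior class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if labels is None:
        labels = ["all"] * tm.n_founders
    classes = sorted(set(labels))
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 3), sharey=True)
    if len(classes) == 1:
        axes = [axes]
    gens = np.arange(tm.values.shape[1])
    for ax, cls in zip(axes, classes):
        for row, label in zip(tm.values, labels):
            if label == cls:
                ax.plot(gens, row, color="tab:red", alpha=0.15, lw=0.8)
        ax.set_title(cls)
        ax.set_xlabel("generation")
    axes[0].set_ylabel("predicted expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
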