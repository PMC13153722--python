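"""Neutral base-mutation model: random point substitutions along lineages.

Each "generation" is one mutation iteration, not a culture passage: a count
m is drawn uniformly from {min..max} (1–3 by default), m distinct sites are
chosen uniformly, and each mutated site receives a base drawn uniformly
from the three alternatives. There is no transition/transversion bias, no
hotspots and no selection — mutation is purely random; screening happens
post hoc on the predicted expression trajectories.

Reproducibility: each founder's lineage runs on its own RNG substream keyed
on (seed, founder sequence digest, duplicate index), so cohort results do
not depend on founder ordering or on how work is scheduled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence import ALPHABET, normalize_sequence

__all__ = [
    "MutationConfig",
    "LineageTrajectory",
    "mutate_one_generation",
    "simulate_lineage",
    "simulate_cohort",
    "trajectories_to_fasta_records",
    "trajectories_to_frame",
]


@dataclass(frozen=True)
class MutationConfig:
    """Parameters of the per-generation substitution process.

    ``mutation_count_weights``, when given, replaces the uniform draw over
    {min..max} with the supplied probabilities. ``distinct_sites=False``
    switches site choice to with-replacement (a generation may then hit one
    site twice, so the per-step Hamming distance can fall below the drawn
    count).
    """

    min_mutations: int = 1
    max_mutations: int = 3
    generations: int = 100
    seed: int = 0
    distinct_sites: bool = True
    mutation_count_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_mutations <= self.max_mutations:
            raise ValueError(
                f"require 1 <= min_mutations <= max_mutations, got "
                f"[{self.min_mutations}, {self.max_mutations}]"
            )
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.mutation_count_weights is not None:
            weights = tuple(float(w) for w in self.mutation_count_weights)
            n = self.max_mutations - self.min_mutations + 1
            if len(weights) != n or any(w < 0 for w in weights) or sum(weights) <= 0:
                raise ValueError(
                    f"mutation_count_weights must be {n} non-negative values"
                )
            object.__setattr__(self, "mutation_count_weights", weights)


@dataclass(frozen=True)
class LineageTrajectory:
    """Sequence series over generations; index 0 is the founder."""

    founder_id: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences in a lineage must have equal length")

    @property
    def founder(self) -> str:
        return self.sequences[0]

    @property
    def generations(self) -> int:
        return len(self.sequences) - 1


def _draw_count(cfg: MutationConfig, rng: np.random.Generator) -> int:
    if cfg.mutation_count_weights is None:
        return int(rng.integers(cfg.min_mutations, cfg.max_mutations + 1))
    weights = np.asarray(cfg.mutation_count_weights, dtype=float)
    counts = np.arange(cfg.min_mutations, cfg.max_mutations + 1)
    return int(rng.choice(counts, p=weights / weights.sum()))


def mutate_one_generation(
    seq: str, cfg: MutationConfig, rng: np.random.Generator
) -> str:
    """Apply one generation of random substitutions; the input is unmodified.

    Substituted sites always change base (the new base is uniform over the
    three alternatives), so with distinct sites the per-step Hamming
    distance equals the drawn mutation count.
    """
    seq = normalize_sequence(seq)
    if len(seq) < cfg.max_mutations:
        raise ValueError(
            f"sequence length {len(seq)} shorter than max_mutations {cfg.max_mutations}"
        )
    m = _draw_count(cfg, rng)
    positions = rng.choice(len(seq), size=m, replace=not cfg.distinct_sites)
    out = list(seq)
    for pos in np.atleast_1d(positions):
        current = out[pos]
        alternatives = [b for b in ALPHABET if b != current]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def simulate_lineage(
    founder: str,
    cfg: MutationConfig,
    rng: np.random.Generator,
    founder_id: str = "founder",
) -> LineageTrajectory:
    """Simulate ``cfg.generations`` mutation iterations from ``founder``."""
    founder = normalize_sequence(founder)
    sequences = [founder]
    for _ in range(cfg.generations):
        sequences.append(mutate_one_generation(sequences[-1], cfg, rng))
    return LineageTrajectory(founder_id=founder_id, sequences=tuple(sequences))


def _founder_substream(cfg: MutationConfig, founder: str, occurrence: int) -> np.random.Generator:
    digest = hashlib.sha256(founder.encode("ascii")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), key, int(occurrence)])
    )


def simulate_cohort(
    founders: Sequence[str],
    cfg: MutationConfig,
    founder_ids: Sequence[str] | None = None,
) -> list[LineageTrajectory]:
    """One independent lineage per founder, on per-founder RNG substreams.

    A founder's trajectory depends only on (seed, its sequence, its
    duplicate index among identical founders), so reordering the input
    reorders but never changes the per-founder results.
    """
    if len(founders) == 0:
        raise ValueError("founder list must be non-empty")
    if founder_ids is None:
        founder_ids = [f"founder_{i}" for i in range(len(founders))]
    if len(founder_ids) != len(founders):
        raise ValueError("founder_ids length must match founders")
    seen: dict[str, int] = {}
    trajectories = []
    for founder, fid in zip(founders, founder_ids):
        founder = normalize_sequence(founder)
        occurrence = seen.get(founder, 0)
        seen[founder] = occurrence + 1
        rng = _founder_substream(cfg, founder, occurrence)
        trajectories.append(simulate_lineage(founder, cfg, rng, founder_id=fid))
    return trajectories


def trajectories_to_fasta_records(
    cohort: Iterable[LineageTrajectory],
) -> list[tuple[str, str]]:
    """Flatten a cohort to (``founderID_gN``, sequence) FASTA records."""
    records = []
    for traj in cohort:
        for g, seq in enumerate(traj.sequences):
            records.append((f"{traj.founder_id}_g{g}", seq))
    return records


def trajectories_to_frame(cohort: Iterable[LineageTrajectory]):
    """Cohort as a tidy DataFrame with founder, generation and sequence."""
    import pandas as pd

    rows = [
        {"founder": traj.founder_id, "generation": g, "sequence": seq}
        for traj in cohort
        for g, seq in enumerate(traj.sequences)
    ]
    return pd.DataFrame(rows, columns=["founder", "generation", "sequence"])
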