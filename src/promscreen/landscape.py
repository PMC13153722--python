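"""Synthetic promoter/expression data with a known ground-truth fitness landscape.

The landscape is additive over exact motif occurrences: expression is a
baseline plus, for every overlapping occurrence of every motif, the motif's
weight times an optional per-position multiplier, plus Gaussian measurement
noise. This is the simplest family in which mutation-resistant, declining
and volatile promoter classes can be constructed and audited by brute-force
single-mutant scans; it is a test oracle, not a biological claim.

The module also emulates two artifacts of the real training data that the
screening pipeline must tolerate: continuous measurement noise, and a
contaminating subpopulation whose expression values are exact integers
(single-dish measurements in the source data), which the pipeline removes
before training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .sequence import ALPHABET, PromoterRecord, normalize_sequence

__all__ = [
    "FitnessLandscape",
    "LandscapeConfig",
    "SampleLadder",
    "PlantedCohort",
    "make_landscape",
    "sample_dataset",
    "filter_integer_expression",
    "draw_sample_ladder",
    "plant_cohort",
    "random_sequence",
    "INTEGER_TOLERANCE",
    "CLASS_RESISTANT",
    "CLASS_DECLINING",
    "CLASS_VOLATILE",
]

#: |y - round(y)| at or below this marks an expression value as integer-like.
#: Values survive text round-trips, so the tolerance is well above float64
#: round-off but far below any plausible genuine fractional part.
INTEGER_TOLERANCE = 1e-9

CLASS_RESISTANT = "resistant"
CLASS_DECLINING = "declining"
CLASS_VOLATILE = "volatile"


@dataclass(frozen=True)
class FitnessLandscape:
    """Additive motif landscape mapping sequences to expression.

    Parameters
    ----------
    motifs
        ``(pattern, weight)`` pairs; patterns are 4–8 nt over ACGT. Weights
        may be negative (repressive sites). At least one weight must be
        nonzero.
    baseline
        Expression of a sequence with no motif occurrences (expression units).
    position_weights
        Optional per-start-position multipliers applied to occurrences by
        their 0-based start coordinate; positions beyond the array use 1.0.
    noise_sd
        Standard deviation of additive Gaussian measurement noise
        (expression units). With ``noise_sd=0`` the landscape is
        deterministic.
    """

    motifs: tuple[tuple[str, float], ...]
    baseline: float = 0.0
    position_weights: tuple[float, ...] | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        motifs = tuple((normalize_sequence(p), float(w)) for p, w in self.motifs)
        if not motifs:
            raise ValueError("landscape requires at least one motif")
        for pattern, _ in motifs:
            if not 4 <= len(pattern) <= 8:
                raise ValueError(f"motif length must be 4-8 nt, got {pattern!r}")
        if all(w == 0.0 for _, w in motifs):
            raise ValueError("at least one motif must have nonzero weight")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "motifs", motifs)
        if self.position_weights is not None:
            object.__setattr__(
                self, "position_weights", tuple(float(w) for w in self.position_weights)
            )

    def _multiplier(self, pos: int) -> float:
        if self.position_weights is None or pos >= len(self.position_weights):
            return 1.0
        return self.position_weights[pos]

    def score(self, seq: str) -> float:
        """Noiseless expression of ``seq`` (baseline + weighted occurrences)."""
        seq = normalize_sequence(seq)
        total = self.baseline
        for pattern, weight in self.motifs:
            k = len(pattern)
            for pos in range(len(seq) - k + 1):
                if seq[pos : pos + k] == pattern:
                    total += weight * self._multiplier(pos)
        return total

    def true_expression(self, seq: str, rng: np.random.Generator | None = None) -> float:
        """Expression of ``seq`` with one measurement-noise draw from ``rng``."""
        value = self.score(seq)
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            value += float(rng.normal(0.0, self.noise_sd))
        return value

    def with_noise(self, noise_sd: float) -> "FitnessLandscape":
        """Copy of this landscape with a different measurement-noise level."""
        return replace(self, noise_sd=float(noise_sd))

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "baseline": float(self.baseline),
            "noise_sd": float(self.noise_sd),
            "motifs": [{"pattern": p, "weight": float(w)} for p, w in self.motifs],
            "position_weights": (
                list(self.position_weights) if self.position_weights is not None else None
            ),
        }
        with open(path, "w") as handle:
            yaml.safe_dump(doc, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FitnessLandscape":
        with open(path) as handle:
            doc = yaml.safe_load(handle)
        return cls(
            motifs=tuple((m["pattern"], float(m["weight"])) for m in doc["motifs"]),
            baseline=float(doc.get("baseline", 0.0)),
            position_weights=doc.get("position_weights"),
            noise_sd=float(doc.get("noise_sd", 0.0)),
        )


@dataclass(frozen=True)
class LandscapeConfig:
    """Ranges from which :func:`make_landscape` draws a random landscape.

    The default motif length of 4 makes the landscape exactly linear in
    overlapping 4-mer counts, i.e. well-specified for the surrogate
    predictor; longer motifs exercise model misspecification.
    """

    n_motifs: tuple[int, int] = (3, 8)
    motif_length: tuple[int, int] = (4, 4)
    weight_range: tuple[float, float] = (0.5, 3.0)
    baseline: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.n_motifs
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid motif count range {self.n_motifs}")
        llo, lhi = self.motif_length
        if not (4 <= llo <= lhi <= 8):
            raise ValueError(f"motif length range must lie in 4-8, got {self.motif_length}")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence of ``length``."""
    return "".join(rng.choice(list(ALPHABET), size=length))


def make_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> FitnessLandscape:
    """Draw a reproducible random landscape from ``config`` ranges."""
    config = config or LandscapeConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6C616E64]))
    n = int(rng.integers(config.n_motifs[0], config.n_motifs[1] + 1))
    motifs: list[tuple[str, float]] = []
    seen: set[str] = set()
    while len(motifs) < n:
        length = int(rng.integers(config.motif_length[0], config.motif_length[1] + 1))
        pattern = random_sequence(length, rng)
        if pattern in seen:
            continue
        seen.add(pattern)
        weight = float(rng.uniform(*config.weight_range))
        motifs.append((pattern, weight))
    return FitnessLandscape(
        motifs=tuple(motifs),
        baseline=config.baseline,
        noise_sd=config.noise_sd,
    )


def sample_dataset(
    ls: FitnessLandscape,
    n: int,
    seq_length: int = 80,
    integer_contamination_rate: float = 0.0,
    seed: int = 0,
) -> list[PromoterRecord]:
    """Draw ``n`` uniform-random sequences with (noisy) landscape expression.

    A Bernoulli(``integer_contamination_rate``) subset of records has its
    expression rounded to the nearest integer, emulating the single-dish
    integer artifact of the source dataset.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= integer_contamination_rate <= 1.0:
        raise ValueError("integer_contamination_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x64617461]))
    records: list[PromoterRecord] = []
    for _ in range(n):
        seq = random_sequence(seq_length, rng)
        value = ls.score(seq)
        if ls.noise_sd > 0:
            value += float(rng.normal(0.0, ls.noise_sd))
        if integer_contamination_rate > 0 and rng.random() < integer_contamination_rate:
            value = float(round(value))
        records.append(PromoterRecord(seq, value))
    return records


def filter_integer_expression(
    records: Iterable[PromoterRecord], tolerance: float = INTEGER_TOLERANCE
) -> list[PromoterRecord]:
    """Drop records whose expression is an exact integer; preserves order.

    Integer-valued expression marks measurements taken in only a single
    culture dish in the source data and carries large error.
    """
    return [
        rec for rec in records if abs(rec.expression - round(rec.expression)) > tolerance
    ]


@dataclass(frozen=True)
class SampleLadder:
    """Strictly increasing training-set sizes drawn from one pool.

    Mirrors the protocol of training at e.g. 300 / 3K / 30K / ... samples
    and evaluating every model on the same fixed test set.
    """

    sizes: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes or any(s <= 0 for s in sizes):
            raise ValueError("ladder sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ladder sizes must be strictly increasing")
        object.__setattr__(self, "sizes", sizes)


def draw_sample_ladder(
    records: Sequence[PromoterRecord], ladder: SampleLadder
) -> list[list[PromoterRecord]]:
    """One uniform without-replacement subsample per ladder size.

    Draws are independent across sizes (subsets need not nest), matching a
    plain "randomly selected" protocol.
    """
    pool = list(records)
    if max(ladder.sizes) > len(pool):
        raise ValueError(
            f"ladder size {max(ladder.sizes)} exceeds pool of {len(pool)} records"
        )
    datasets = []
    for i, size in enumerate(ladder.sizes):
        rng = np.random.default_rng(np.random.SeedSequence([int(ladder.seed), 0x6C616464, i]))
        idx = rng.choice(len(pool), size=size, replace=False)
        datasets.append([pool[j] for j in idx])
    return datasets


# ---------------------------------------------------------------------------
# Planted robustness cohort
# ---------------------------------------------------------------------------

#: weight of each small (resistant-class) motif copy, expression units
_SMALL_WEIGHT = 2.0
#: weight of each large-effect motif, expression units
_LARGE_WEIGHT = 8.0
#: weight of the volatile class's level-restoring medium sites; three copies
#: restore the common +8 start, and single-site coincidences distort the
#: large-step balance by at most one medium weight
_MEDIUM_WEIGHT = 8.0 / 3.0
_BASELINE = 1.0
#: all planted classes start at exactly _BASELINE + 8.0
START_BAND = (_BASELINE + 8.0 - 0.5, _BASELINE + 8.0 + 0.5)


@dataclass(frozen=True)
class PlantedCohort:
    """Sequences with ground-truth robustness classes assigned by construction.

    Classes are defined by how the planted motif architecture responds to
    point mutations, not by any simulation outcome, so they can serve as
    ground truth for cluster-recovery tests.
    """

    records: tuple[tuple[str, str], ...]  # (sequence, class label)

    @property
    def sequences(self) -> list[str]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.records]

    def by_class(self, label: str) -> list[str]:
        return [seq for seq, cls in self.records if cls == label]


def _draw_patterns(rng: np.random.Generator) -> dict[str, list[str]]:
    """Draw the class motif patterns with cross-talk guards.

    Small motifs are 4-mers (exactly representable by k=4 surrogate
    features); large-effect motifs are 8-mers, long enough that drifting
    backgrounds almost never create a spurious copy (expected equilibrium
    occupancy ~1e-3 per sequence). Large patterns are pairwise far apart
    and never contain a small pattern, so destroying one motif cannot
    silently alter another class's signal.
    """
    while True:
        small = []
        while len(small) < 2:
            p = random_sequence(4, rng)
            if p not in small:
                small.append(p)
        large = []
        while len(large) < 3:
            p = random_sequence(8, rng)
            if any(s in p for s in small):
                continue
            if any(sum(a != b for a, b in zip(p, q)) < 3 for q in large):
                continue
            large.append(p)
        while True:
            m = random_sequence(6, rng)
            if any(s in m for s in small):
                continue
            if any(m in p for p in large):
                continue
            return {"small": small, "large": large, "med": m}


def _occurrences(seq: str, pattern: str) -> list[int]:
    k = len(pattern)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == pattern]


def _near_occurrences(seq: str, pattern: str) -> list[int]:
    """Start positions of windows within Hamming distance 1 of ``pattern``."""
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        if sum(a != b for a, b in zip(seq[i : i + k], pattern)) <= 1:
            out.append(i)
    return out


def _plant(
    background: str, placements: list[tuple[int, str]]
) -> str:
    seq = list(background)
    for pos, pattern in placements:
        seq[pos : pos + len(pattern)] = pattern
    return "".join(seq)


def _spread_positions(
    seq_length: int, widths: Sequence[int], rng: np.random.Generator, guard: int = 2
) -> list[int]:
    """Random non-overlapping start positions for sites of ``widths`` (``guard`` nt gaps).

    Slack beyond the minimal packing is distributed uniformly over the n+1
    inter-site gaps, so placement is uniform over valid configurations and
    never needs rejection. Site order along the sequence is randomized.
    """
    n = len(widths)
    order = rng.permutation(n)
    slack = seq_length - int(sum(widths)) - (n - 1) * guard
    if slack < 0:
        raise ValueError(f"sequence length {seq_length} too short for planted motifs")
    extras = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    positions = [0] * n
    cursor = 0
    for slot, site in enumerate(order):
        cursor += int(extras[slot])
        positions[site] = cursor
        cursor += int(widths[site]) + guard
    return positions


def _mutate_at(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1 :]


def plant_cohort(
    seq_length: int = 80,
    n_per_class: int = 20,
    seed: int = 0,
) -> tuple[FitnessLandscape, PlantedCohort]:
    """Construct a landscape plus resistant / declining / volatile sequences.

    All classes start at exactly ``baseline + 8`` expression units:

    * **resistant** — four copies of small-weight (2.0) 4-mer motifs; any
      single substitution moves expression by at most one copy's weight,
      a quarter of the total motif contribution, so expression degrades in
      small steps.
    * **declining** — exactly one large-weight (8.0) 8-mer; its first hit
      collapses expression to baseline and the neutral walk essentially
      never rebuilds an 8-mer.
    * **volatile** — two large-weight activator copies balanced against two
      planted copies of a large *negative*-weight repressor, three 6-mer
      medium-weight sites restoring the starting level, and two near-miss
      activator sites one substitution away from the activator
      motif. Losing a repressor (or completing a near-miss) jumps
      expression up by the large weight; losing an activator copy drops it
      by the same amount, so trajectories swing both ways, and the net
      large-step balance over a long walk is ~0 (equal strong content of
      both signs), unlike a declining promoter whose balance equals its
      lost activator weight.

    Backgrounds are rejection-sampled so that, at generation 0, each
    sequence carries exactly its planted motif content: no stray small-motif
    occurrences and no windows within Hamming distance 1 of any large motif
    (other than the intended near-miss sites).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if seq_length < 60:
        raise ValueError("seq_length must be >= 60 to host the planted motif copies")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x706C6E74]))
    patterns = _draw_patterns(rng)
    r1, r2 = patterns["small"]
    d_motif, v_act, v_rep = patterns["large"]
    v_med = patterns["med"]

    motifs = (
        (r1, _SMALL_WEIGHT),
        (r2, _SMALL_WEIGHT),
        (d_motif, _LARGE_WEIGHT),
        (v_act, _LARGE_WEIGHT),
        (v_rep, -_LARGE_WEIGHT),
        (v_med, _MEDIUM_WEIGHT),
    )
    ls = FitnessLandscape(motifs=motifs, baseline=_BASELINE, noise_sd=0.0)
    all_patterns = [r1, r2, d_motif, v_act, v_rep, v_med]
    large_patterns = [d_motif, v_act, v_rep, v_med]

    def clean_background() -> str:
        return random_sequence(seq_length, rng)

    def valid(seq: str, expected: dict[str, int], allowed_near: dict[str, int]) -> bool:
        for p in all_patterns:
            if len(_occurrences(seq, p)) != expected.get(p, 0):
                return False
        for p in large_patterns:
            # near-miss windows include exact occurrences
            n_near = len(_near_occurrences(seq, p))
            if n_near != expected.get(p, 0) + allowed_near.get(p, 0):
                return False
        return True

    def build(placements_for, expected, allowed_near) -> str:
        for _ in range(2000):
            seq = _plant(clean_background(), placements_for())
            if valid(seq, expected, allowed_near):
                return seq
        raise RuntimeError("failed to construct a clean planted sequence")

    records: list[tuple[str, str]] = []

    for _ in range(n_per_class):
        # resistant: 2 copies each of the two small motifs
        def resistant_placements() -> list[tuple[int, str]]:
            sites = [r1, r1, r2, r2]
            pos = _spread_positions(seq_length, [4] * 4, rng)
            return list(zip(pos, sites))

        records.append(
            (build(resistant_placements, {r1: 2, r2: 2}, {}), CLASS_RESISTANT)
        )

    for _ in range(n_per_class):
        # declining: a single large activator
        def declining_placements() -> list[tuple[int, str]]:
            pos = _spread_positions(seq_length, [8], rng)
            return [(pos[0], d_motif)]

        records.append(
            (build(declining_placements, {d_motif: 1}, {}), CLASS_DECLINING)
        )

    for _ in range(n_per_class):
        # volatile: 2 activators + 2 repressors + 3 medium sites + 2
        # near-miss activator sites; strong content of both signs is
        # balanced, with the medium sites restoring the common start level.
        def volatile_placements() -> list[tuple[int, str]]:
            sites = [
                v_act, v_act, v_rep, v_rep, v_med, v_med, v_med,
                _near_miss(v_act, rng), _near_miss(v_act, rng),
            ]
            pos = _spread_positions(
                seq_length, [len(s) for s in sites], rng, guard=1
            )
            return list(zip(pos, sites))

        records.append(
            (
                build(
                    volatile_placements,
                    {v_act: 2, v_rep: 2, v_med: 3},
                    {v_act: 2},
                ),
                CLASS_VOLATILE,
            )
        )

    cohort = PlantedCohort(records=tuple(records))
    for seq, _ in records:
        assert abs(ls.score(seq) - (_BASELINE + 8.0)) < 1e-9
    return ls, cohort


def _near_miss(pattern: str, rng: np.random.Generator) -> str:
    """A copy of ``pattern`` with one random position substituted."""
    pos = int(rng.integers(len(pattern)))
    current = pattern[pos]
    choices = [b for b in ALPHABET if b != current]
    return _mutate_at(pattern, pos, choices[int(rng.integers(3))])
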