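"""DNA sequence primitives, k-mer featurization, construct assembly and file I/O.

Sequences are plain Python strings over the uppercase alphabet ``ACGT``.
Ambiguity codes (including ``N``) are rejected rather than randomized: both
the mutation model and the k-mer features are defined only over the four
canonical bases, and silently resolving ambiguous bases would make results
depend on an undocumented coin flip.

k-mer indices are fixed lexicographic (``AAAA`` < ... < ``TTTT``) so that
feature positions are reproducible across runs and serialized models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "ALPHABET",
    "BASE_INDEX",
    "PromoterRecord",
    "ConstructLayout",
    "normalize_sequence",
    "hamming_distance",
    "kmer_count_vector",
    "kmer_count_matrix",
    "kmer_index",
    "assemble_construct",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_expression_table",
]


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence paired with its expression value.

    ``expression`` is on the dataset's own (arbitrary) scale and must be
    finite.
    """

    sequence: str
    expression: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if not math.isfinite(self.expression):
            raise ValueError(f"expression must be finite, got {self.expression!r}")


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and validate it contains only A/C/G/T.

    Raises ``ValueError`` for empty input or any non-ACGT character,
    including IUPAC ambiguity codes.
    """
    if not isinstance(raw, str):
        raise TypeError(f"sequence must be a string, got {type(raw).__name__}")
    if not raw:
        raise ValueError("sequence must be non-empty")
    seq = raw.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT characters: {sorted(bad)!r}"
        )
    return seq


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which equal-length sequences ``a``/``b`` differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Integer-encode a sequence (A=0, C=1, G=2, T=3)."""
    return np.frombuffer(
        seq.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8
    ).astype(np.int64)


_ENCODE_TABLE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer (leftmost base most significant)."""
    idx = 0
    for base in normalize_sequence(kmer):
        idx = idx * 4 + BASE_INDEX[base]
    return idx


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic codes of all overlapping k-windows of one encoded row."""
    n_win = codes.shape[-1] - k + 1
    out = np.zeros(codes.shape[:-1] + (n_win,), dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[..., j : j + n_win]
    return out


def kmer_count_vector(seq: str, k: int) -> np.ndarray:
    """Counts of all overlapping k-mers of ``seq`` in lexicographic order.

    The returned vector has length ``4**k`` and sums to ``len(seq) - k + 1``.
    """
    seq = normalize_sequence(seq)
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    codes = _window_codes(encode(seq), k)
    return np.bincount(codes, minlength=4**k).astype(np.int64)


def kmer_count_matrix(seqs: Sequence[str], k: int) -> np.ndarray:
    """Stacked ``kmer_count_vector`` rows for equal-length sequences.

    Vectorized over sequences; used by the surrogate predictor where the
    per-sequence loop would dominate fitting time.
    """
    if len(seqs) == 0:
        return np.zeros((0, 4**k), dtype=np.int64)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        # fall back to per-row featurization for ragged batches
        return np.stack([kmer_count_vector(s, k) for s in seqs])
    codes = np.stack([encode(normalize_sequence(s)) for s in seqs])
    if k > codes.shape[1]:
        raise ValueError(f"k={k} exceeds sequence length {codes.shape[1]}")
    win = _window_codes(codes, k)
    n, n_win = win.shape
    flat = win + (np.arange(n)[:, None] * 4**k)
    counts = np.bincount(flat.ravel(), minlength=n * 4**k)
    return counts.reshape(n, 4**k).astype(np.int64)


@dataclass(frozen=True)
class ConstructLayout:
    """Layout of the reporter construct hosting an 80 bp variable insert.

    The insert sits between constant poly-T (pT) and poly-A (pA) elements,
    themselves flanked by constant scaffold sequence. The TSS-relative labels
    (insert spanning −170..−90 upstream of the presumed transcription start
    site) are carried as metadata only; within the assembled construct the
    insert window is addressed 0-based half-open via ``insert_offset``.
    """

    upstream_scaffold: str = ""
    pt_element: str = ""
    insert_slot_length: int = 80
    pa_element: str = ""
    downstream_scaffold: str = ""
    insert_start_relative_to_tss: int = -170
    insert_end_relative_to_tss: int = -90

    def __post_init__(self) -> None:
        if self.insert_slot_length < 1:
            raise ValueError("insert_slot_length must be positive")
        for name in ("upstream_scaffold", "pt_element", "pa_element", "downstream_scaffold"):
            value = getattr(self, name)
            if value:
                object.__setattr__(self, name, normalize_sequence(value))
        span = self.insert_end_relative_to_tss - self.insert_start_relative_to_tss
        if span != self.insert_slot_length:
            raise ValueError(
                f"TSS-relative labels span {span} nt but insert_slot_length is "
                f"{self.insert_slot_length} (half-open convention)"
            )

    @property
    def insert_offset(self) -> int:
        """0-based start of the insert window within the assembled construct."""
        return len(self.upstream_scaffold) + len(self.pt_element)

    @property
    def total_length(self) -> int:
        return (
            len(self.upstream_scaffold)
            + len(self.pt_element)
            + self.insert_slot_length
            + len(self.pa_element)
            + len(self.downstream_scaffold)
        )


def assemble_construct(layout: ConstructLayout, insert: str) -> str:
    """Embed ``insert`` into ``layout``: upstream + pT + insert + pA + downstream."""
    insert = normalize_sequence(insert)
    if len(insert) != layout.insert_slot_length:
        raise ValueError(
            f"insert length {len(insert)} != slot length {layout.insert_slot_length}"
        )
    return (
        layout.upstream_scaffold
        + layout.pt_element
        + insert
        + layout.pa_element
        + layout.downstream_scaffold
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs, normalized to ACGT."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapped at ``width`` columns."""
    seq_records = [
        SeqRecord(Seq(normalize_sequence(seq)), id=str(name), description="")
        for name, seq in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_expression_table(path, header: bool | None = None) -> list[PromoterRecord]:
    """Read a two-column sequence/expression TSV into ``PromoterRecord`` rows.

    The layout follows the reference training file: one sequence, a tab, and
    one floating-point expression value per line, no header by default. With
    ``header=None`` a header line is auto-detected by a non-numeric second
    field on line 1 whose first field is not itself a DNA sequence (a DNA
    first field with a malformed value is a data error, not a header).
    Ragged rows and non-numeric expression fields raise.
    """
    records: list[PromoterRecord] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        return records
    start = 0
    if header is True:
        start = 1
    elif header is None:
        fields = lines[0].split("\t")
        if (
            len(fields) >= 2
            and not _is_float(fields[1])
            and not set(fields[0].upper()) <= set(ALPHABET)
        ):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        seq, value = fields
        if not _is_float(value):
            raise ValueError(f"{path}:{lineno}: non-numeric expression {value!r}")
        records.append(PromoterRecord(seq, float(value)))
    return records


def write_expression_table(records: Iterable[PromoterRecord], path, header: bool = False) -> None:
    """Write records as two-column TSV; floats use shortest round-trip repr."""
    with open(path, "w") as handle:
        if header:
            handle.write("sequence\texpression\n")
        for rec in records:
            handle.write(f"{rec.sequence}\t{rec.expression!r}\n")
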