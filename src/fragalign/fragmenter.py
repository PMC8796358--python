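"""Simulate fragmentary sequence datasets from a reference alignment.

Fragmentation mimics reads/contigs from incomplete assembly: a chosen
fraction of sequences is replaced by a contiguous substring whose length is
drawn from a normal distribution.  Two standard conditions:

* high fragmentation (HF): 50% of sequences fragmented, length ~
  Normal(0.25 * median length, sd 60);
* low fragmentation (LF): 25% fragmented, Normal(0.5 * median, sd 60).

Operating on the reference alignment (masking removed residues with gaps)
keeps the true homologies of the surviving residues, so fragmented datasets
remain scorable against their truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence as TypingSequence

import numpy as np

from .msa_core import GAP, Alignment, Sequence


@dataclass(frozen=True)
class FragmentationProfile:
    """Parameters of the fragmentation simulator.

    fraction_fragmentary and length_ratio are in (0, 1]; length_sd is in
    residues.  The two named conditions are exposed as
    :meth:`high` (0.5 / 0.25) and :meth:`low` (0.25 / 0.5), both sd 60.
    """

    fraction_fragmentary: float
    length_ratio: float
    length_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_fragmentary <= 1.0:
            raise ValueError("fraction_fragmentary must be in (0, 1]")
        if not 0.0 < self.length_ratio <= 1.0:
            raise ValueError("length_ratio must be in (0, 1]")
        if self.length_sd < 0:
            raise ValueError("length_sd must be non-negative")

    @classmethod
    def high(cls, seed: int = 0) -> "FragmentationProfile":
        return cls(0.5, 0.25, 60.0, seed)

    @classmethod
    def low(cls, seed: int = 0) -> "FragmentationProfile":
        return cls(0.25, 0.5, 60.0, seed)

    @classmethod
    def named(cls, name: str, seed: int = 0) -> "FragmentationProfile":
        key = name.upper()
        if key == "HF":
            return cls.high(seed)
        if key == "LF":
            return cls.low(seed)
        raise ValueError(f"unknown profile {name!r} (expected HF or LF)")

    def with_seed(self, seed: int) -> "FragmentationProfile":
        return replace(self, seed=seed)


@dataclass
class FragmentRecord:
    id: str
    is_fragment: bool
    original_length: int
    fragment_length: int
    start: int  # ungapped start index; -1 for untouched rows


@dataclass
class FragmentationResult:
    alignment: Alignment            # fragmented truth (same columns as input minus all-gap)
    sequences: list[Sequence]       # ungapped rows: the pipeline input
    records: list[FragmentRecord] = field(default_factory=list)
    seed: int = 0

    @property
    def fragment_ids(self) -> set[str]:
        return {r.id for r in self.records if r.is_fragment}


def median_length(seqs: TypingSequence[Sequence]) -> float:
    """Sample median of ungapped sequence lengths (even count: midpoint mean)."""
    if not seqs:
        raise ValueError("median of an empty collection")
    return float(np.median([len(s) for s in seqs]))


def count_fragments(n: int, profile: FragmentationProfile) -> int:
    """Number of sequences to fragment: floor(n * fraction_fragmentary)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return math.floor(n * profile.fraction_fragmentary)


def sample_fragment_length(
    median: float,
    source_length: int,
    profile: FragmentationProfile,
    rng: np.random.Generator,
) -> int:
    """Draw a fragment length ~ round(Normal(length_ratio * median, sd)).

    Draws outside [1, source_length) are rejected and redrawn, so a
    fragment is always a proper, non-empty substring of its source.  A
    length-1 source is returned whole.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if source_length < 1:
        raise ValueError("source_length must be >= 1")
    if source_length == 1:
        return 1
    mean = profile.length_ratio * median
    while True:
        value = int(round(rng.normal(mean, profile.length_sd)))
        if 1 <= value < source_length:
            return value


def make_fragment(
    row: str, length: int, rng: np.random.Generator, start: int | None = None
) -> tuple[str, int]:
    """Mask a gapped row down to a contiguous ungapped substring.

    The fragment keeps its residues in their original columns; residues
    outside the chosen window become gaps.  ``start`` (an ungapped index)
    may be forced for testing; otherwise it is uniform over valid starts.
    Returns the masked row and the start used.
    """
    ungapped_len = len(row) - row.count(GAP)
    if not 1 <= length <= ungapped_len:
        raise ValueError(
            f"fragment length {length} out of range [1, {ungapped_len}]"
        )
    if start is None:
        start = int(rng.integers(0, ungapped_len - length + 1))
    elif not 0 <= start <= ungapped_len - length:
        raise ValueError("start out of range")
    out = []
    k = 0
    for ch in row:
        if ch == GAP:
            out.append(GAP)
        else:
            out.append(ch if start <= k < start + length else GAP)
            k += 1
    return "".join(out), start


def fragment_alignment(
    ref: Alignment, profile: FragmentationProfile
) -> FragmentationResult:
    """Fragment a reference alignment under an HF/LF-style profile.

    Exactly ``count_fragments(n, profile)`` rows, chosen uniformly without
    replacement, are shortened; all-gap columns are then dropped.  Fully
    deterministic given ``profile.seed``.
    """
    if ref.n_rows < 2:
        raise ValueError("need at least 2 rows to fragment")
    rng = np.random.default_rng(profile.seed)
    ids = list(ref.rows)
    n_frag = count_fragments(len(ids), profile)
    chosen = set(
        rng.choice(len(ids), size=n_frag, replace=False).tolist()
    ) if n_frag else set()
    med = median_length(ref.sequences())
    rows: dict[str, str] = {}
    records: list[FragmentRecord] = []
    for idx, rid in enumerate(ids):
        row = ref.rows[rid]
        orig_len = len(row) - row.count(GAP)
        if idx in chosen:
            frag_len = sample_fragment_length(med, orig_len, profile, rng)
            masked, start = make_fragment(row, frag_len, rng)
            rows[rid] = masked
            records.append(FragmentRecord(rid, True, orig_len, frag_len, start))
        else:
            rows[rid] = row
            records.append(FragmentRecord(rid, False, orig_len, orig_len, -1))
    fragged = Alignment(rows, ref.insertion_columns).drop_all_gap_columns()
    seqs = fragged.sequences()
    return FragmentationResult(fragged, seqs, records, profile.seed)
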