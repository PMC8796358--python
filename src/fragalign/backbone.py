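"""Backbone selection: pick full-length sequences and sample the backbone.

The two-stage strategy aligns a *backbone* of (generally) full-length
sequences first, then places everything else onto it.  Full-length status
is either declared (simulated data, where fragment ids are known) or
inferred as all sequences within 25% of the median sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from .fragmenter import median_length
from .msa_core import Sequence


@dataclass(frozen=True)
class BackboneConfig:
    backbone_size: int = 1000
    length_band: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_size < 1:
            raise ValueError("backbone_size must be >= 1")
        if not 0.0 < self.length_band < 1.0:
            raise ValueError("length_band must be in (0, 1)")


def select_full_length(
    seqs: TypingSequence[Sequence], band: float = 0.25
) -> set[str]:
    """Ids of sequences within ``band`` of the median length (inclusive)."""
    med = median_length(seqs)
    lo, hi = (1.0 - band) * med, (1.0 + band) * med
    return {s.id for s in seqs if lo <= len(s) <= hi}


def sample_backbone(full_ids: Iterable[str], config: BackboneConfig) -> set[str]:
    """Uniform random subset of at most ``backbone_size`` full-length ids.

    Deterministic given the config seed; id order does not matter (ids are
    sorted before sampling).
    """
    ids = sorted(full_ids)
    if not ids:
        raise ValueError("no full-length sequences to sample from")
    if len(ids) <= config.backbone_size:
        return set(ids)
    rng = np.random.default_rng(config.seed)
    pick = rng.choice(len(ids), size=config.backbone_size, replace=False)
    return {ids[i] for i in pick}


def split_dataset(
    seqs: TypingSequence[Sequence],
    known_fragment_ids: set[str] | None = None,
    config: BackboneConfig = BackboneConfig(),
) -> tuple[set[str], set[str]]:
    """Partition sequence ids into (backbone, queries).

    When fragment ids are declared (simulated data) the full-length set is
    simply their complement; otherwise the median-band rule decides.  The
    backbone is a random sample of the full-length set; every other id,
    full-length or not, becomes a query.
    """
    all_ids = {s.id for s in seqs}
    if known_fragment_ids is not None:
        unknown = known_fragment_ids - all_ids
        if unknown:
            raise KeyError(f"declared fragment ids not in dataset: {sorted(unknown)}")
        full = all_ids - known_fragment_ids
    else:
        full = select_full_length(seqs, config.length_band)
    if not full:
        raise ValueError("no full-length sequences: backbone would be empty")
    bb = sample_backbone(full, config)
    return bb, all_ids - bb
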