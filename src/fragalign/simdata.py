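"""Synthetic benchmark generator: tree + sequence evolution with a true alignment.

Sequences evolve down a pure-birth (Yule) tree under Jukes–Cantor
substitutions plus a Poisson indel process with geometric indel lengths.
Residue homology is tracked through global column bookkeeping, so the leaf
sequences come with their exact true alignment — the reference against
which estimated alignments are scored.  Combined with the fragmenter this
yields complete, fully deterministic benchmark bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .backbone import BackboneConfig, split_dataset
from .fragmenter import FragmentationProfile, FragmentationResult, fragment_alignment
from .msa_core import GAP, Alignment, Sequence

_RESIDUES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 100
    root_length: int = 1000
    substitution_rate: float = 0.05   # expected substitutions / site / unit branch length
    indel_rate: float = 0.01          # expected indel events / site / unit branch length
    indel_length_mean: float = 3.0    # geometric length distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")


def yule_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Pure-birth tree with ``n_taxa`` leaves and exponential branch lengths.

    Each extant lineage splits at rate 1; waiting times between speciations
    are Exp(1/k) with k the number of extant lineages.  Tips are named
    s0001, s0002, ... in creation order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    root.length = None
    first, second = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([first, second])
    active = [first, second]
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / k)
        for node in active:
            node.length += dt
        idx = int(rng.integers(0, k))
        parent = active.pop(idx)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(kids)
        active.extend(kids)
    dt = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += dt
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"s{i:04d}"
    return root


@dataclass
class _LineageState:
    # residues as parallel lists: global column ids and residue codes
    cols: list[int]
    codes: list[int]


def _evolve_branch(
    state: _LineageState,
    t: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    order: list[int],
    next_col: list[int],
) -> _LineageState:
    cols = list(state.cols)
    codes = list(state.codes)
    # Jukes-Cantor substitutions
    if config.substitution_rate > 0 and t > 0 and cols:
        p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * config.substitution_rate * t))
        hits = np.flatnonzero(rng.random(len(codes)) < p)
        for h in hits:
            codes[h] = (codes[h] + int(rng.integers(1, 4))) % 4
    # indels
    if config.indel_rate > 0 and t > 0 and cols:
        n_events = rng.poisson(config.indel_rate * t * len(cols))
        for _ in range(n_events):
            L = len(cols)
            if L == 0:
                break
            size = int(rng.geometric(1.0 / config.indel_length_mean))
            if rng.random() < 0.5:  # deletion
                start = int(rng.integers(0, L))
                del cols[start : start + size]
                del codes[start : start + size]
            else:  # insertion
                pos = int(rng.integers(0, L + 1))
                new_ids = list(range(next_col[0], next_col[0] + size))
                next_col[0] += size
                if pos == 0:
                    anchor_at = order.index(cols[0])
                else:
                    anchor_at = order.index(cols[pos - 1]) + 1
                order[anchor_at:anchor_at] = new_ids
                cols[pos:pos] = new_ids
                codes[pos:pos] = [int(r) for r in rng.integers(0, 4, size=size)]
    return _LineageState(cols, codes)


def evolve(
    tree: TreeNode, config: SimulationConfig
) -> tuple[Alignment, list[Sequence]]:
    """Evolve sequences down a tree; return (true alignment, leaf sequences).

    The root sequence is i.i.d. uniform over {A,C,G,T}.  Substitutions are
    Jukes–Cantor with per-site change probability derived from the branch
    length; indel events are Poisson in (rate x branch length x sequence
    length) with geometric lengths and uniform positions.  Homology is
    exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    L = config.root_length
    order = list(range(L))
    next_col = [L]
    root_state = _LineageState(
        cols=list(range(L)),
        codes=[int(r) for r in rng.integers(0, 4, size=L)],
    )
    leaf_states: dict[str, _LineageState] = {}

    def recurse(node: TreeNode, state: _LineageState) -> None:
        for child in node.children:
            t = child.length or 0.0
            child_state = _evolve_branch(state, t, config, rng, order, next_col)
            if child.is_tip():
                if not child_state.cols:
                    raise RuntimeError(
                        f"lineage {child.name} lost its entire sequence; "
                        "lower the indel rate"
                    )
                leaf_states[child.name] = child_state
            else:
                recurse(child, child_state)

    recurse(tree, root_state)
    names = [t.name for t in tree.tips()]
    global_pos = {c: i for i, c in enumerate(order)}
    used_cols = sorted(
        {c for st in leaf_states.values() for c in st.cols},
        key=global_pos.__getitem__,
    )
    col_pos = {c: i for i, c in enumerate(used_cols)}
    width = len(used_cols)
    rows: dict[str, str] = {}
    for name in names:
        st = leaf_states[name]
        out = [GAP] * width
        for c, code in zip(st.cols, st.codes):
            out[col_pos[c]] = _RESIDUES[code]
        rows[name] = "".join(out)
    aln = Alignment(rows)
    return aln, aln.sequences()


@dataclass
class BenchmarkBundle:
    """Everything needed to run and score the pipeline on one replicate."""

    true_alignment: Alignment          # pre-fragmentation truth
    fragmented_truth: Alignment        # truth restricted to surviving residues
    sequences: list[Sequence]          # pipeline input (fragments included)
    fragment_ids: set[str]
    backbone_ids: set[str]
    query_ids: set[str]
    metadata: dict = field(default_factory=dict)


def make_benchmark(
    config: SimulationConfig,
    profile: FragmentationProfile,
    backbone_config: BackboneConfig | None = None,
) -> BenchmarkBundle:
    """Simulate, fragment, and split one benchmark replicate deterministically."""
    tree = yule_tree(config.n_taxa, config.seed)
    true_aln, _ = evolve(tree, config)
    frag: FragmentationResult = fragment_alignment(true_aln, profile)
    backbone_config = backbone_config or BackboneConfig(seed=profile.seed)
    bb_ids, query_ids = split_dataset(
        frag.sequences, known_fragment_ids=frag.fragment_ids, config=backbone_config
    )
    return BenchmarkBundle(
        true_alignment=true_aln,
        fragmented_truth=frag.alignment,
        sequences=frag.sequences,
        fragment_ids=frag.fragment_ids,
        backbone_ids=bb_ids,
        query_ids=query_ids,
        metadata={
            "sim_seed": config.seed,
            "frag_seed": profile.seed,
            "n_taxa": config.n_taxa,
            "root_length": config.root_length,
            "fraction_fragmentary": profile.fraction_fragmentary,
            "length_ratio": profile.length_ratio,
        },
    )
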