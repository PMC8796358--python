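"""Ensemble-of-profile-HMMs placement of query sequences onto a backbone.

The backbone alignment is hierarchically decomposed (via its tree) into
nested subsets; a profile HMM is trained on each subset's sub-alignment;
each query is Viterbi-aligned against every ensemble member, assigned to
the best-scoring one, and its residues are mapped back to backbone columns
through that HMM's match states.  All placements are then transitively
merged: backbone columns are preserved verbatim and insert-state residues
go into extra columns flagged non-homologous.

The structural contract of the two-stage design: restricting the final
alignment to the backbone ids (and dropping insertion columns) reproduces
the backbone alignment byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
from skbio import TreeNode

from .dc_aligner import _centroid_edge_split, nj_tree
from .evaluate import encode_alignment, p_distance_matrix
from .msa_core import (
    GAP,
    Alignment,
    AlignmentError,
    Sequence,
    restrict_alignment,
)

LOG_QUARTER = np.log2(0.25)
_RES_INDEX = {b: i for i, b in enumerate("ACGT")}
NEG_INF = -np.inf


@dataclass(frozen=True)
class EnsembleConfig:
    min_subset_size: int = 10
    keep_all_levels: bool = True
    pseudocount: float = 1.0
    match_column_threshold: float = 0.5  # max gap fraction for a match column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_subset_size < 1:
            raise ValueError("min_subset_size must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not 0.0 < self.match_column_threshold <= 1.0:
            raise ValueError("match_column_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# Backbone tree and hierarchical decomposition
# ---------------------------------------------------------------------------


def backbone_tree(backbone_aln: Alignment) -> TreeNode:
    """Neighbor-joining tree on p-distances of the backbone alignment."""
    if backbone_aln.n_rows < 2:
        raise ValueError("need at least 2 backbone rows")
    d = p_distance_matrix(backbone_aln)
    return nj_tree(d, list(backbone_aln.rows))


def hierarchical_decompose(
    tree: TreeNode, config: EnsembleConfig
) -> list[frozenset[str]]:
    """Nested subsets from recursive centroid-edge splits.

    Every intermediate set is retained (that is what makes it an ensemble:
    a query can match a broad, shallow model or a narrow, deep one).
    Result ordered by (size descending, smallest member id).
    """
    all_tips = frozenset(t.name for t in tree.tips())
    sets: list[frozenset[str]] = []

    def recurse(subtree: TreeNode, members: frozenset[str]) -> None:
        sets.append(members)
        if len(members) <= config.min_subset_size:
            return
        left, right = _centroid_edge_split(subtree)
        for part in (left, right):
            fpart = frozenset(part)
            if len(fpart) == 1:
                sets.append(fpart)
            else:
                recurse(subtree.shear(sorted(fpart)), fpart)

    recurse(tree, all_tips)
    return sorted(sets, key=lambda s: (-len(s), min(s)))


# ---------------------------------------------------------------------------
# Profile HMM
# ---------------------------------------------------------------------------


@dataclass
class ProfileHMM:
    """Match/insert/delete profile HMM over {A,C,G,T}.

    Layer j runs 0..K with M_0 = begin and M_{K+1} = end.  Transition
    arrays are indexed by source layer; illegal transitions (into the
    nonexistent D_{K+1}) carry probability 0.  ``column_map`` sends match
    state j (1-based) to its backbone alignment column.
    """

    match_count: int
    match_emissions: np.ndarray      # (K, 4) probabilities
    log_match_emissions: np.ndarray  # (K, 4) log2
    t: dict[str, np.ndarray]         # 'MM','MI','MD','IM','II','ID','DM','DI','DD'
    log_t: dict[str, np.ndarray]
    column_map: list[int]
    source_subset: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        K = self.match_count
        if K < 1:
            raise ValueError("need at least one match state")
        if len(self.column_map) != K:
            raise ValueError("column_map length must equal match_count")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column_map must be strictly increasing")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")
        for src in "MID":
            out = sum(
                self.t[src + dst] for dst in "MID"
            )
            lo = 1 if src == "D" else 0
            if not np.allclose(out[lo:], 1.0, atol=1e-9):
                raise ValueError(f"{src}-state transitions must sum to 1")


def build_profile_hmm(
    sub_alignment: Alignment,
    config: EnsembleConfig = EnsembleConfig(),
    column_indices: TypingSequence[int] | None = None,
    source_subset: frozenset[str] | None = None,
) -> ProfileHMM:
    """Train a profile HMM on a sub-alignment.

    Match columns are those with gap fraction <= ``match_column_threshold``
    (boundary inclusive).  Emissions use add-``pseudocount`` smoothing over
    the 4 residues; insert emissions are the uniform background.
    Transitions are counted from each row's observed state path, smoothed
    with the same pseudocount over the legal successors.

    ``column_indices`` maps sub-alignment columns to the coordinates the
    HMM should report (the backbone alignment's columns); default identity.
    """
    aln = sub_alignment
    if column_indices is None:
        column_indices = list(range(aln.n_columns))
    if len(column_indices) != aln.n_columns:
        raise ValueError("column_indices length must equal alignment width")
    codes = encode_alignment(aln)
    n_rows = codes.shape[0]
    gap_frac = (codes < 0).sum(axis=0) / n_rows
    is_match = gap_frac <= config.match_column_threshold
    match_cols = np.flatnonzero(is_match)
    K = match_cols.size
    if K == 0:
        raise AlignmentError("no columns qualify as match states")
    pc = config.pseudocount

    # emissions
    emis = np.full((K, 4), pc)
    for k, col in enumerate(match_cols):
        for r in range(4):
            emis[k, r] += (codes[:, col] == r).sum()
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts from observed state paths
    counts = {key: np.zeros(K + 1) for key in
              ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")}
    match_index_of_col = np.cumsum(is_match)  # col -> number of match cols up to incl.
    for row in codes:
        prev = ("M", 0)  # begin
        for col in range(aln.n_columns):
            c = row[col]
            if is_match[col]:
                j = int(match_index_of_col[col])
                state = ("M", j) if c >= 0 else ("D", j)
            else:
                if c < 0:
                    continue
                j = int(match_index_of_col[col])  # inserts anchor after match j
                state = ("I", j)
            counts[prev[0] + state[0]][prev[1]] += 1
            prev = state
        counts[prev[0] + "M"][prev[1]] += 1  # -> end

    t: dict[str, np.ndarray] = {}
    for src in "MID":
        cm = counts[src + "M"] + pc
        ci = counts[src + "I"] + pc
        cd = counts[src + "D"] + pc
        cd[K] = 0.0  # no D_{K+1}
        total = cm + ci + cd
        total[total == 0] = 1.0
        t[src + "M"] = cm / total
        t[src + "I"] = ci / total
        t[src + "D"] = cd / total
    with np.errstate(divide="ignore"):
        log_t = {k: np.log2(v) for k, v in t.items()}
        log_emis = np.log2(emis)
    return ProfileHMM(
        match_count=K,
        match_emissions=emis,
        log_match_emissions=log_emis,
        t=t,
        log_t=log_t,
        column_map=[int(column_indices[c]) for c in match_cols],
        source_subset=source_subset
        if source_subset is not None
        else frozenset(aln.rows),
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

StatePath = list[tuple[str, int]]


def viterbi(hmm: ProfileHMM, query: Sequence) -> tuple[float, StatePath]:
    """Best log-odds path score (bits) and its state path.

    Score is log2 P(path, query | hmm) - log2 P(query | null) with a
    uniform i.i.d. null, so match emissions contribute log2(e/0.25),
    insert emissions 0, and transitions log2 t.
    """
    x = [_RES_INDEX.get(ch, -1) for ch in query.residues]
    if any(c < 0 for c in x):
        raise ValueError(
            f"query {query.id!r} contains non-ACGT characters; clean the dataset first"
        )
    n = len(x)
    K = hmm.match_count
    lt = hmm.log_t
    le = hmm.log_match_emissions - LOG_QUARTER  # (K,4) log-odds
    VM = np.full((n + 1, K + 1), NEG_INF)
    VI = np.full((n + 1, K + 1), NEG_INF)
    VD = np.full((n + 1, K + 1), NEG_INF)
    VM[0, 0] = 0.0
    # D-chain along layers uses a running max with cumulative log tDD.
    cum_dd = np.concatenate([[0.0], np.cumsum(lt["DD"][1:K])])  # index j-1 -> sum
    for i in range(0, n + 1):
        if i > 0:
            emis_row = le[:, x[i - 1]]
            VM[i, 1:] = emis_row + np.maximum.reduce([
                VM[i - 1, :-1] + lt["MM"][:-1],
                VI[i - 1, :-1] + lt["IM"][:-1],
                VD[i - 1, :-1] + lt["DM"][:-1],
            ])
            VI[i] = np.maximum.reduce([
                VM[i - 1] + lt["MI"],
                VI[i - 1] + lt["II"],
                VD[i - 1] + lt["DI"],
            ])
        # VD[i, j] = cum_dd[j-1] + max_{k<j} (base[k] - cum_dd[k])
        base = np.maximum(VM[i, :K] + lt["MD"][:K], VI[i, :K] + lt["ID"][:K])
        with np.errstate(invalid="ignore"):
            VD[i, 1:] = cum_dd + np.maximum.accumulate(base - cum_dd)
    score = max(
        VM[n, K] + lt["MM"][K],
        VI[n, K] + lt["IM"][K],
        VD[n, K] + lt["DM"][K],
    )
    # traceback
    tol = 1e-9
    end_cands = (
        ("M", VM[n, K] + lt["MM"][K]),
        ("I", VI[n, K] + lt["IM"][K]),
        ("D", VD[n, K] + lt["DM"][K]),
    )
    state = next(s for s, v in end_cands if v >= score - tol)
    i, j = n, K
    path: StatePath = []
    V = {"M": VM, "I": VI, "D": VD}
    while not (state == "M" and j == 0 and i == 0):
        path.append((state, j))
        cur = V[state][i, j]
        if state == "M":
            target = cur - le[j - 1, x[i - 1]]
            cands = (
                ("M", VM[i - 1, j - 1] + lt["MM"][j - 1]),
                ("I", VI[i - 1, j - 1] + lt["IM"][j - 1]),
                ("D", VD[i - 1, j - 1] + lt["DM"][j - 1]),
            )
            i, j = i - 1, j - 1
        elif state == "I":
            target = cur
            cands = (
                ("M", VM[i - 1, j] + lt["MI"][j]),
                ("I", VI[i - 1, j] + lt["II"][j]),
                ("D", VD[i - 1, j] + lt["DI"][j]),
            )
            i = i - 1
        else:
            target = cur
            cands = (
                ("M", VM[i, j - 1] + lt["MD"][j - 1]),
                ("I", VI[i, j - 1] + lt["ID"][j - 1]),
                ("D", VD[i, j - 1] + lt["DD"][j - 1]),
            )
            j = j - 1
        state = next(
            (s for s, v in cands if v >= target - max(tol, abs(target) * 1e-12)),
            None,
        )
        if state is None:  # pragma: no cover
            raise RuntimeError("viterbi traceback inconsistency")
    path.reverse()
    return float(score), path


# ---------------------------------------------------------------------------
# Query assignment and placement
# ---------------------------------------------------------------------------


@dataclass
class QueryPlacement:
    """Residue-level map of one query onto the backbone coordinate system.

    ``residue_map[k]`` is either ``('M', backbone_column)`` or
    ``('I', anchor_column, ordinal)`` where the anchor is the backbone
    column of the preceding match state (-1 for insertions before the
    first match column).
    """

    query_id: str
    hmm_index: int
    score: float
    residues: str
    residue_map: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        match_cols = [e[1] for e in self.residue_map if e[0] == "M"]
        if any(b <= a for a, b in zip(match_cols, match_cols[1:])):
            raise ValueError("mapped backbone columns must strictly increase")
        if len(self.residue_map) != len(self.residues):
            raise ValueError("every residue must be mapped exactly once")

    def insertions_at(self) -> dict[int, int]:
        """anchor column -> number of inserted residues there."""
        out: dict[int, int] = {}
        for entry in self.residue_map:
            if entry[0] == "I":
                out[entry[1]] = out.get(entry[1], 0) + 1
        return out


def assign_query(
    ensemble: TypingSequence[ProfileHMM], query: Sequence
) -> tuple[int, float]:
    """Index and score of the best-scoring ensemble member (ties: earliest)."""
    if not ensemble:
        raise ValueError("empty ensemble")
    best_idx, best_score = 0, NEG_INF
    for idx, hmm in enumerate(ensemble):
        score, _ = viterbi(hmm, query)
        if score > best_score:
            best_idx, best_score = idx, score
    return best_idx, float(best_score)


def place_query(
    hmm: ProfileHMM, query: Sequence, hmm_index: int = 0
) -> QueryPlacement:
    """Viterbi-align a query and convert the path to a residue map."""
    score, path = viterbi(hmm, query)
    residue_map: list[tuple] = []
    last_match_col = -1
    ins_ordinal = 0
    for state, j in path:
        if state == "M":
            col = hmm.column_map[j - 1]
            residue_map.append(("M", col))
            last_match_col = col
            ins_ordinal = 0
        elif state == "I":
            residue_map.append(("I", last_match_col, ins_ordinal))
            ins_ordinal += 1
        # D states consume no query residue
    return QueryPlacement(query.id, hmm_index, score, query.residues, residue_map)


def transitive_merge(
    backbone_aln: Alignment, placements: TypingSequence[QueryPlacement]
) -> Alignment:
    """Merge query placements into the backbone alignment.

    Backbone columns are kept verbatim and in order.  At every anchor, each
    query's inserted residues get their own fresh columns (insertions of
    different queries at the same anchor are deliberately NOT aligned to
    each other: an insert state asserts no homology).  Insertion columns
    are flagged and later written lowercase.
    """
    W = backbone_aln.n_columns
    for p in placements:
        for entry in p.residue_map:
            col = entry[1]
            if not -1 <= col < W:
                raise ValueError(
                    f"placement of {p.query_id!r} references column {col} "
                    f"outside the backbone (width {W})"
                )
    if any(p.query_id in backbone_aln.rows for p in placements):
        raise ValueError("query id collides with a backbone id")
    # width of the insertion block after each anchor (-1 = before column 0)
    ins_width = {a: 0 for a in range(-1, W)}
    # per (query, anchor): offset of that query's run inside the block
    run_offset: dict[tuple[str, int], int] = {}
    for p in placements:
        for anchor, count in sorted(p.insertions_at().items()):
            run_offset[(p.query_id, anchor)] = ins_width[anchor]
            ins_width[anchor] += count
    # output layout: [ins block -1][col 0][ins block 0][col 1]...
    col_pos: list[int] = []
    pos = ins_width[-1]
    ins_start = {-1: 0}
    for c in range(W):
        col_pos.append(pos)
        pos += 1
        ins_start[c] = pos
        pos += ins_width[c]
    total = pos
    insertion_columns = {
        ins_start[a] + k for a in range(-1, W) for k in range(ins_width[a])
    }
    rows: dict[str, str] = {}
    for rid, row in backbone_aln.rows.items():
        out = [GAP] * total
        for c, ch in enumerate(row):
            out[col_pos[c]] = ch
        rows[rid] = "".join(out)
    for p in placements:
        out = [GAP] * total
        for ch, entry in zip(p.residues, p.residue_map):
            if entry[0] == "M":
                out[col_pos[entry[1]]] = ch
            else:
                _, anchor, ordinal = entry
                out[ins_start[anchor] + run_offset[(p.query_id, anchor)] + ordinal] = ch
        rows[p.query_id] = "".join(out)
    old_ins = {col_pos[c] for c in backbone_aln.insertion_columns}
    return Alignment(rows, insertion_columns | old_ins)


# ---------------------------------------------------------------------------
# Full second stage
# ---------------------------------------------------------------------------


def build_ensemble(
    backbone_aln: Alignment,
    config: EnsembleConfig = EnsembleConfig(),
    tree: TreeNode | None = None,
) -> list[ProfileHMM]:
    """Hierarchically decompose the backbone and train one HMM per subset."""
    if tree is None:
        if backbone_aln.n_rows == 1:
            subsets = [frozenset(backbone_aln.rows)]
        else:
            tree = backbone_tree(backbone_aln)
            subsets = hierarchical_decompose(tree, config)
    else:
        subsets = hierarchical_decompose(tree, config)
    ensemble: list[ProfileHMM] = []
    for subset in subsets:
        sub_rows = {i: backbone_aln.rows[i] for i in backbone_aln.rows if i in subset}
        sub = Alignment(sub_rows)
        mat = sub.to_matrix()
        kept = np.flatnonzero((mat != GAP.encode()).any(axis=0)).tolist()
        sub = sub.keep_columns(kept)
        ensemble.append(
            build_profile_hmm(sub, config, column_indices=kept, source_subset=subset)
        )
    return ensemble


def add_queries(
    backbone_aln: Alignment,
    queries: TypingSequence[Sequence],
    config: EnsembleConfig = EnsembleConfig(),
    tree: TreeNode | None = None,
) -> Alignment:
    """Place every query onto the backbone via its best ensemble HMM."""
    if not queries:
        return backbone_aln
    overlap = {q.id for q in queries} & set(backbone_aln.rows)
    if overlap:
        raise ValueError(f"query ids overlap backbone ids: {sorted(overlap)}")
    ensemble = build_ensemble(backbone_aln, config, tree)
    placements = []
    for q in queries:
        idx, _ = assign_query(ensemble, q)
        placements.append(place_query(ensemble[idx], q, idx))
    final = transitive_merge(backbone_aln, placements)
    _check_backbone_preservation(final, backbone_aln)
    return final


class BackbonePreservationError(RuntimeError):
    pass


def _check_backbone_preservation(final: Alignment, backbone_aln: Alignment) -> None:
    back = restrict_alignment(final, backbone_aln.rows)
    if {i: back.rows[i] for i in backbone_aln.rows} != backbone_aln.rows:
        raise BackbonePreservationError(
            "final alignment does not preserve the backbone alignment"
        )
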