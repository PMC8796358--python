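"""Divide-and-conquer backbone aligner with graph-clustering merge.

Pipeline: k-mer distances -> neighbor-joining guide tree -> centroid-edge
decomposition into subsets -> progressive profile alignment per subset ->
support alignments spanning the subsets -> weighted alignment graph over
subset columns -> Markov clustering (MCL) -> legality/ordering resolution
into one merged alignment.

The merge never rewrites a subset alignment: each output column contains at
most one column per subset and every subset's internal column order is
preserved, so restricting the merged result to one subset's rows (and
dropping all-gap columns) reproduces that subset's alignment exactly.
"""

from __future__ import annotations

import heapq
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .msa_core import GAP, Alignment, Sequence, parse_newick

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Distances and guide trees
# ---------------------------------------------------------------------------


def _kmer_counts(residues: str, k: int) -> Counter:
    if len(residues) < k:
        # short sequence: fall back to its own full-length word
        return Counter([residues])
    return Counter(residues[i : i + k] for i in range(len(residues) - k + 1))


def kmer_distance_matrix(
    seqs: TypingSequence[Sequence], k: int = 8
) -> np.ndarray:
    """Pairwise 1 - cosine similarity of k-mer count vectors."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    counts = [_kmer_counts(s.residues, k) for s in seqs]
    norms = [np.sqrt(sum(v * v for v in c.values())) for c in counts]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = counts[i], counts[j]
            if len(b) < len(a):
                a, b = b, a
            dot = sum(v * b[kmer] for kmer, v in a.items() if kmer in b)
            sim = dot / (norms[i] * norms[j]) if norms[i] and norms[j] else 0.0
            d[i, j] = d[j, i] = max(0.0, 1.0 - sim)
    return d


def nj_tree(dist: np.ndarray, labels: TypingSequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Two labels yield the trivial single-edge tree; additive matrices are
    recovered exactly (standard NJ guarantee).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or dist.shape[0] != len(labels):
        raise ValueError("matrix/label shape mismatch")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) == 1:
        return parse_newick(f"({labels[0]}:0.0);")
    if len(labels) == 2:
        return parse_newick(f"({labels[0]}:0.0,{labels[1]}:{dist[0, 1]});")
    dm = DistanceMatrix(dist, list(labels))
    return _skbio_nj(dm)


@dataclass(frozen=True)
class SubsetDecomposition:
    subsets: list[frozenset[str]]
    max_subset_size: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.subsets:
            if not s:
                raise ValueError("empty subset")
            if seen & s:
                raise ValueError("subsets are not disjoint")
            seen |= s


def _centroid_edge_split(
    tree: TreeNode,
) -> tuple[set[str], set[str]]:
    """Split leaves at the centroid edge (most balanced bipartition).

    Ties go to the first edge found in a preorder traversal.
    """
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    best_node, best_score = None, None
    # leaf counts per clade, computed once
    counts: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        counts[id(node)] = (
            1 if node.is_tip() else sum(counts[id(c)] for c in node.children)
        )
    for node in tree.preorder(include_self=False):
        c = counts[id(node)]
        if c == 0 or c == n:
            continue
        score = abs(2 * c - n)
        if best_score is None or score < best_score:
            best_node, best_score = node, score
    side = {t.name for t in best_node.tips()} if not best_node.is_tip() else {
        best_node.name
    }
    return side, set(tips) - side


def centroid_decompose(tree: TreeNode, max_size: int) -> SubsetDecomposition:
    """Recursively split at centroid edges until every part has <= max_size leaves."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    result: list[frozenset[str]] = []

    def recurse(subtree: TreeNode) -> None:
        tips = sorted(t.name for t in subtree.tips())
        if len(tips) <= max_size:
            result.append(frozenset(tips))
            return
        left, right = _centroid_edge_split(subtree)
        for part in (left, right):
            if len(part) == 1:
                result.append(frozenset(part))
            else:
                recurse(subtree.shear(sorted(part)))

    recurse(tree)
    return SubsetDecomposition(result, max_size)


# ---------------------------------------------------------------------------
# Progressive profile-profile alignment (affine gaps, Gotoh)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scoring:
    """Per-sequence-pair alignment scoring.

    ``gap_extend`` is the cost of one residue aligned against a gap (per
    sequence pair); ``gap_open`` is the total cost of the FIRST residue of
    a gap run (classic affine convention), so the opening surcharge is
    ``gap_open - gap_extend``.  Profile columns are scored as expected
    per-pair values over residue/gap frequencies, and the cost of gapping
    a whole column scales with that column's residue occupancy — this
    keeps the dynamic program's objective consistent with the sum-of-pairs
    score it optimizes (a constant-cost gap would underprice splitting
    occupied columns apart).
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -2.0

    @property
    def open_surcharge(self) -> float:
        return self.gap_open - self.gap_extend


_RES_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def _profile_counts(aln: Alignment) -> np.ndarray:
    """Column residue counts, shape (n_columns, 4) over A,C,G,T."""
    mat = aln.to_matrix()
    return np.stack(
        [(mat == b).sum(axis=0) for b in _RES_BYTES], axis=1
    ).astype(float)


def _profile(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Residue frequencies (n_columns, 4) and per-column occupancy."""
    freqs = _profile_counts(aln) / aln.n_rows
    return freqs, freqs.sum(axis=1)


def _column_scores(
    f1: np.ndarray, occ1: np.ndarray, f2: np.ndarray, occ2: np.ndarray, sc: Scoring
) -> np.ndarray:
    """Expected per-pair score for every column pair of two profiles.

    Residue-residue pairs score match/mismatch; residue-gap pairs (one row
    occupied, the other already gapped) score gap_extend.
    """
    matches = f1 @ f2.T
    totals = occ1[:, None] * occ2[None, :]
    res_gap = (
        occ1[:, None] * (1.0 - occ2)[None, :]
        + (1.0 - occ1)[:, None] * occ2[None, :]
    )
    return (
        sc.match * matches
        + sc.mismatch * (totals - matches)
        + sc.gap_extend * res_gap
    )


def _gotoh(
    S: np.ndarray, gx: np.ndarray, gy: np.ndarray, go: float
) -> tuple[float, list[str]]:
    """Affine DP with position-specific gap-extension costs.

    ``gx[i]`` / ``gy[j]`` is the cost of consuming column i of the first
    (resp. j of the second) profile against a gap; ``go`` is the constant
    opening surcharge added on entering a gap run.  Returns the optimal
    score and the edit path as ops: 'D' consume both, 'U' consume a
    first-profile column, 'L' a second-profile column.  Ties prefer D,
    then U, then L (deterministic).
    """
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG_INF)
    X = np.full((m + 1, n + 1), NEG_INF)  # gap in second profile (consume row i)
    Y = np.full((m + 1, n + 1), NEG_INF)  # gap in first profile (consume col j)
    M[0, 0] = 0.0
    cumx = np.concatenate([[0.0], np.cumsum(gx)])
    cumy = np.concatenate([[0.0], np.cumsum(gy)])
    if m >= 1:
        X[1:, 0] = go + cumx[1:]
    if n >= 1:
        Y[0, 1:] = go + cumy[1:]
    for i in range(1, m + 1):
        diag_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1] + diag_best
        X[i] = gx[i - 1] + np.maximum(np.maximum(M[i - 1], Y[i - 1]) + go, X[i - 1])
        # within-row recurrence via running max:
        #   Y[i,j] = max_{k<j} max(M[i,k], X[i,k]) + go + (cumy[j] - cumy[k])
        base = np.maximum(M[i, :-1], X[i, :-1]) + go - cumy[:-1]
        Y[i, 1:] = cumy[1:] + np.maximum.accumulate(base)
        Y[i, 0] = NEG_INF
    # traceback
    i, j = m, n
    state = max(
        (("M", M[m, n]), ("X", X[m, n]), ("Y", Y[m, n])), key=lambda t: t[1]
    )[0]
    score = max(M[m, n], X[m, n], Y[m, n])
    ops: list[str] = []
    tol = 1e-6  # traceback equality slack; fp association differs between paths
    while i > 0 or j > 0:
        if state == "M":
            ops.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            cands = (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]), ("Y", Y[i - 1, j - 1]))
            state = _pick(cands, target, tol)
            i, j = i - 1, j - 1
        elif state == "X":
            ops.append("U")
            target = X[i, j] - gx[i - 1]
            cands = (
                ("M", M[i - 1, j] + go),
                ("X", X[i - 1, j]),
                ("Y", Y[i - 1, j] + go),
            )
            state = _pick(cands, target, tol)
            i -= 1
        else:  # Y
            ops.append("L")
            target = Y[i, j] - gy[j - 1]
            cands = (
                ("M", M[i, j - 1] + go),
                ("X", X[i, j - 1] + go),
                ("Y", Y[i, j - 1]),
            )
            state = _pick(cands, target, tol)
            j -= 1
    ops.reverse()
    return float(score), ops


def _pick(cands, target: float, tol: float) -> str:
    for name, val in cands:
        if val >= target - tol:
            return name
    raise RuntimeError("traceback inconsistency")  # pragma: no cover


def _merge_alignments(a: Alignment, b: Alignment, sc: Scoring) -> Alignment:
    """Merge two alignments by profile-profile affine alignment."""
    f1, occ1 = _profile(a)
    f2, occ2 = _profile(b)
    S = _column_scores(f1, occ1, f2, occ2, sc)
    _, ops = _gotoh(S, sc.gap_extend * occ1, sc.gap_extend * occ2, sc.open_surcharge)
    rows: dict[str, str] = {}
    a_cols = [op != "L" for op in ops]  # a advances on D/U
    b_cols = [op != "U" for op in ops]
    for rid, row in a.rows.items():
        it = iter(row)
        rows[rid] = "".join(next(it) if adv else GAP for adv in a_cols)
    for rid, row in b.rows.items():
        it = iter(row)
        rows[rid] = "".join(next(it) if adv else GAP for adv in b_cols)
    return Alignment(rows)


def pairwise_align(
    x: Sequence, y: Sequence, scoring: Scoring = Scoring()
) -> tuple[float, Alignment]:
    """Optimal affine-gap global alignment of two sequences."""
    a = Alignment({x.id: x.residues})
    b = Alignment({y.id: y.residues})
    f1, occ1 = _profile(a)
    f2, occ2 = _profile(b)
    S = _column_scores(f1, occ1, f2, occ2, scoring)
    score, ops = _gotoh(
        S, scoring.gap_extend * occ1, scoring.gap_extend * occ2, scoring.open_surcharge
    )
    merged = _merge_alignments(a, b, scoring)
    return score, merged


def progressive_align(
    seqs: TypingSequence[Sequence],
    guide: TreeNode,
    scoring: Scoring = Scoring(),
) -> Alignment:
    """Progressive profile-profile alignment up a guide tree.

    Children of each internal node are merged left to right in tree order,
    so the result is deterministic for a fixed guide tree.
    """
    by_id = {s.id: s for s in seqs}
    tip_names = {t.name for t in guide.tips()}
    if tip_names != set(by_id):
        raise ValueError("guide tree leaves do not match sequence ids")

    def recurse(node: TreeNode) -> Alignment:
        if node.is_tip():
            s = by_id[node.name]
            return Alignment({s.id: s.residues})
        parts = [recurse(c) for c in node.children]
        acc = parts[0]
        for part in parts[1:]:
            acc = _merge_alignments(acc, part, scoring)
        return acc

    merged = recurse(guide)
    # restore input row order
    return Alignment({s.id: merged.rows[s.id] for s in seqs})


def align_unaligned(
    seqs: TypingSequence[Sequence],
    scoring: Scoring = Scoring(),
    k: int = 8,
) -> Alignment:
    """One-stage alignment: k-mer NJ guide tree + progressive alignment."""
    if len(seqs) == 1:
        return Alignment({seqs[0].id: seqs[0].residues})
    tree = nj_tree(kmer_distance_matrix(seqs, k), [s.id for s in seqs])
    return progressive_align(seqs, tree, scoring)


# ---------------------------------------------------------------------------
# Alignment graph, MCL, merge resolution
# ---------------------------------------------------------------------------


@dataclass
class MergeConfig:
    inflation: float = 2.0
    support_count: int = 3
    support_sample_size: int = 10
    max_mcl_iterations: int = 100
    convergence_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.support_count < 1 or self.support_sample_size < 1:
            raise ValueError("support counts must be positive")


Node = tuple[int, int]  # (subset index, column index)


@dataclass
class AlignmentGraph:
    """Weighted graph over subset-alignment columns.

    Nodes are (subset, column) pairs; an edge weight counts how many
    residue pairs from the two columns co-occur in support-alignment
    columns.  Columns of the same subset are never adjacent.
    """

    nodes: list[Node]
    edges: dict[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for pair, w in self.edges.items():
            u, v = tuple(pair)
            if u[0] == v[0]:
                raise ValueError(f"within-subset edge {u}-{v}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not a node: {pair}")
            if w < 1:
                raise ValueError("edge weights must be >= 1")

    def add_edge(self, u: Node, v: Node, w: int = 1) -> None:
        key = frozenset((u, v))
        self.edges[key] = self.edges.get(key, 0) + w

    def weight(self, u: Node, v: Node) -> int:
        return self.edges.get(frozenset((u, v)), 0)


def build_support_alignments(
    subset_alignments: TypingSequence[Alignment],
    config: MergeConfig,
    scoring: Scoring = Scoring(),
) -> list[Alignment]:
    """Cross-subset helper alignments used to weight the alignment graph.

    Each support alignment takes ``support_sample_size`` sequences from
    every subset (all of them if the subset is smaller) and aligns their
    ungapped sequences from scratch, so its columns relate columns of
    different subsets.
    """
    if len(subset_alignments) < 2:
        raise ValueError("need at least 2 subset alignments")
    rng = np.random.default_rng(config.seed)
    supports = []
    for _ in range(config.support_count):
        chosen: list[Sequence] = []
        for aln in subset_alignments:
            ids = sorted(aln.rows)
            if len(ids) > config.support_sample_size:
                idx = rng.choice(
                    len(ids), size=config.support_sample_size, replace=False
                )
                ids = [ids[i] for i in sorted(idx)]
            chosen.extend(Sequence(i, aln.ungapped(i)) for i in ids)
        supports.append(align_unaligned(chosen, scoring))
    return supports


def _residue_to_column_maps(
    subset_alignments: TypingSequence[Alignment],
) -> dict[tuple[str, int], Node]:
    """(sequence id, ungapped index) -> (subset, column)."""
    out: dict[tuple[str, int], Node] = {}
    for s_idx, aln in enumerate(subset_alignments):
        for rid, row in aln.rows.items():
            k = 0
            for col, ch in enumerate(row):
                if ch != GAP:
                    out[(rid, k)] = (s_idx, col)
                    k += 1
    return out


def build_alignment_graph(
    subset_alignments: TypingSequence[Alignment],
    supports: TypingSequence[Alignment],
) -> AlignmentGraph:
    """Count cross-subset residue co-occurrences in support columns."""
    nodes: list[Node] = [
        (s, c)
        for s, aln in enumerate(subset_alignments)
        for c in range(aln.n_columns)
    ]
    graph = AlignmentGraph(nodes)
    res_map = _residue_to_column_maps(subset_alignments)
    for support in supports:
        counters = {rid: 0 for rid in support.rows}
        for col in range(support.n_columns):
            present: list[Node] = []
            for rid, row in support.rows.items():
                if row[col] != GAP:
                    node = res_map.get((rid, counters[rid]))
                    if node is not None:
                        present.append(node)
                    counters[rid] += 1
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    u, v = present[i], present[j]
                    if u[0] != v[0]:
                        graph.add_edge(u, v, 1)
    return graph


def mcl(graph: AlignmentGraph, config: MergeConfig) -> list[set[Node]]:
    """Markov clustering of the alignment graph.

    Self-loops are set to each node's maximum incident weight (at least 1),
    columns are normalized to a stochastic matrix, and expansion (matrix
    squaring) alternates with inflation (entrywise power + renormalization)
    until the matrix stabilizes.  Clusters are the connected components of
    the converged matrix's support.
    """
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    max_w = np.ones(n)
    rows_i, cols_i, vals = [], [], []
    for pair, w in graph.edges.items():
        u, v = tuple(pair)
        iu, iv = index[u], index[v]
        rows_i += [iu, iv]
        cols_i += [iv, iu]
        vals += [float(w), float(w)]
        max_w[iu] = max(max_w[iu], w)
        max_w[iv] = max(max_w[iv], w)
    rows_i += list(range(n))
    cols_i += list(range(n))
    vals += max_w.tolist()
    A = sparse.csr_matrix((vals, (rows_i, cols_i)), shape=(n, n))

    def normalize(m: sparse.csr_matrix) -> sparse.csr_matrix:
        sums = np.asarray(m.sum(axis=0)).ravel()
        sums[sums == 0] = 1.0
        return m @ sparse.diags(1.0 / sums)

    A = normalize(A).tocsr()
    for _ in range(config.max_mcl_iterations):
        expanded = (A @ A).tocsr()
        expanded.data **= config.inflation
        expanded.data[expanded.data < 1e-12] = 0.0
        expanded.eliminate_zeros()
        new = normalize(expanded).tocsr()
        delta = abs(new - A)
        change = delta.max() if delta.nnz else 0.0
        A = new
        if change < config.convergence_tol:
            break
    support = (A + A.T) > 1e-6
    n_comp, labels = csgraph.connected_components(support, directed=False)
    clusters: list[set[Node]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        clusters[lab].add(node)
    return [c for c in clusters if c]


def _intra_weight(node: Node, cluster: set[Node], graph: AlignmentGraph | None) -> float:
    if graph is None:
        return 0.0
    return float(sum(graph.weight(node, other) for other in cluster if other != node))


def resolve_and_merge(
    clusters: list[set[Node]],
    subset_alignments: TypingSequence[Alignment],
    graph: AlignmentGraph | None = None,
) -> Alignment:
    """Turn column clusters into one legal merged alignment.

    Legality: a cluster may keep at most one column per subset; extra
    columns are evicted to singleton clusters, keeping the column with the
    highest total intra-cluster edge weight (ties: the lower column index
    stays).  Ordering: the precedence digraph induced by each subset's
    column order must be acyclic; while a cycle exists, the weakest-attached
    column on the cycle is evicted to a singleton.  A deterministic
    topological sort then fixes the output column order.
    """
    expected = {
        (s, c)
        for s, aln in enumerate(subset_alignments)
        for c in range(aln.n_columns)
    }
    covered = set().union(*clusters) if clusters else set()
    if covered != expected:
        missing = expected - covered
        extra = covered - expected
        raise ValueError(
            f"clusters do not cover the subset columns exactly "
            f"(missing {len(missing)}, extra {len(extra)})"
        )
    work = [set(c) for c in clusters]

    # --- legality: one column per subset per cluster
    final: list[set[Node]] = []
    for cluster in work:
        by_subset: dict[int, list[Node]] = defaultdict(list)
        for node in cluster:
            by_subset[node[0]].append(node)
        keep: set[Node] = set()
        evicted: list[Node] = []
        for _, cols in by_subset.items():
            if len(cols) == 1:
                keep.add(cols[0])
            else:
                best = max(
                    cols,
                    key=lambda nd: (_intra_weight(nd, cluster, graph), -nd[1]),
                )
                keep.add(best)
                evicted.extend(c for c in cols if c != best)
        final.append(keep)
        final.extend({e} for e in sorted(evicted))

    # --- ordering: break precedence cycles by evicting weak columns
    def build_digraph(cls: list[set[Node]]) -> nx.DiGraph:
        owner: dict[Node, int] = {}
        for ci, cluster in enumerate(cls):
            for node in cluster:
                owner[node] = ci
        g = nx.DiGraph()
        g.add_nodes_from(range(len(cls)))
        for s_idx, aln in enumerate(subset_alignments):
            for col in range(aln.n_columns - 1):
                u = owner[(s_idx, col)]
                v = owner[(s_idx, col + 1)]
                if u != v:
                    g.add_edge(u, v)
        return g

    while True:
        dig = build_digraph(final)
        try:
            cycle = nx.find_cycle(dig)
        except nx.NetworkXNoCycle:
            break
        cycle_clusters = {u for u, _ in cycle}
        candidates: list[tuple[float, Node, int]] = []
        for ci in cycle_clusters:
            if len(final[ci]) > 1:
                for node in final[ci]:
                    candidates.append(
                        (_intra_weight(node, final[ci], graph), node, ci)
                    )
        if not candidates:  # pragma: no cover - cannot arise from chains alone
            raise RuntimeError("cyclic precedence among singleton clusters")
        _, node, ci = min(candidates, key=lambda t: (t[0], t[1]))
        final[ci] = final[ci] - {node}
        final.append({node})

    # --- deterministic topological order
    dig = build_digraph(final)
    key = [min(c) for c in final]
    indeg = dict(dig.in_degree())
    ready = [(key[ci], ci) for ci in dig.nodes if indeg[ci] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        _, ci = heapq.heappop(ready)
        order.append(ci)
        for succ in dig.successors(ci):
            indeg[succ] -= 1
            if indeg[succ] == 0:
                heapq.heappush(ready, (key[succ], succ))
    if len(order) != len(final):
        raise RuntimeError("precedence digraph still cyclic after resolution")

    # --- emit merged columns
    col_of: dict[Node, int] = {}
    for out_col, ci in enumerate(order):
        for node in final[ci]:
            col_of[node] = out_col
    total = len(order)
    rows: dict[str, str] = {}
    for s_idx, aln in enumerate(subset_alignments):
        placement = [col_of[(s_idx, c)] for c in range(aln.n_columns)]
        for rid, row in aln.rows.items():
            out = [GAP] * total
            for c, ch in enumerate(row):
                if ch != GAP:
                    out[placement[c]] = ch
            rows[rid] = "".join(out)
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Top-level backbone alignment
# ---------------------------------------------------------------------------


class MergeInvariantError(RuntimeError):
    """The merged alignment failed to preserve a subset alignment."""


def _check_subset_preservation(
    merged: Alignment, subset_alignments: TypingSequence[Alignment]
) -> None:
    from .msa_core import restrict_alignment

    for aln in subset_alignments:
        back = restrict_alignment(merged, aln.rows)
        ordered = Alignment({rid: back.rows[rid] for rid in aln.rows})
        if ordered.rows != aln.rows:
            raise MergeInvariantError(
                "merged alignment does not preserve a subset alignment"
            )


def align_backbone(
    seqs: TypingSequence[Sequence],
    max_subset_size: int = 50,
    merge_config: MergeConfig | None = None,
    scoring: Scoring = Scoring(),
    k: int = 8,
) -> Alignment:
    """Full divide-and-conquer alignment of the backbone sequences."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Alignment({seqs[0].id: seqs[0].residues})
    merge_config = merge_config or MergeConfig()
    dist = kmer_distance_matrix(seqs, k)
    labels = [s.id for s in seqs]
    tree = nj_tree(dist, labels)
    if len(seqs) <= max_subset_size:
        return progressive_align(seqs, tree, scoring)
    decomp = centroid_decompose(tree, max_subset_size)
    by_id = {s.id: s for s in seqs}
    index = {lab: i for i, lab in enumerate(labels)}
    subset_alignments: list[Alignment] = []
    for subset in decomp.subsets:
        ids = sorted(subset)
        if len(ids) == 1:
            subset_alignments.append(
                Alignment({ids[0]: by_id[ids[0]].residues})
            )
            continue
        sub_idx = [index[i] for i in ids]
        sub_dist = dist[np.ix_(sub_idx, sub_idx)]
        sub_tree = nj_tree(sub_dist, ids)
        subset_alignments.append(
            progressive_align([by_id[i] for i in ids], sub_tree, scoring)
        )
    supports = build_support_alignments(subset_alignments, merge_config, scoring)
    graph = build_alignment_graph(subset_alignments, supports)
    clusters = mcl(graph, merge_config)
    merged = resolve_and_merge(clusters, subset_alignments, graph)
    _check_subset_preservation(merged, subset_alignments)
    return Alignment({s.id: merged.rows[s.id] for s in seqs})
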