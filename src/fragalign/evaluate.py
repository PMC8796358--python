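"""Alignment error (SPFN/SPFP) and dataset statistics.

An alignment is represented by its set of pairwise residue homologies:
two residues are homologous iff they share a (non-insertion) column.
Comparing an estimated alignment to a reference then gives

* SPFN — fraction of reference pairs the estimate fails to recover,
* SPFP — fraction of estimated pairs absent from the reference,

and their mean, the average alignment error.  Both metrics are computed by
column-wise counting (equivalent to, but much faster than, materializing
the pair sets; the explicit construction lives in
:func:`fragalign.msa_core.homology_pairs` and is used as the test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .msa_core import GAP, Alignment


_RES_INDEX = {b: i for i, b in enumerate("ACGT")}


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Rows as int8 codes: 0..3 for A,C,G,T; -1 for gaps/other."""
    mat = aln.to_matrix()
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for ch, i in _RES_INDEX.items():
        codes[mat == ch.encode()] = i
    return codes


@dataclass(frozen=True)
class ErrorReport:
    spfn: float
    spfp: float

    @property
    def avg_error(self) -> float:
        return (self.spfn + self.spfp) / 2.0


@dataclass(frozen=True)
class DatasetStats:
    n_sequences: int
    avg_p_distance: float
    max_p_distance: float
    percent_gaps: float
    avg_seq_length: float
    alignment_length: int


# ---------------------------------------------------------------------------
# SPFN / SPFP
# ---------------------------------------------------------------------------


def _check_comparable(reference: Alignment, estimated: Alignment) -> None:
    if set(reference.rows) != set(estimated.rows):
        raise ValueError("reference and estimated alignments have different ids")
    for rid in reference.rows:
        if reference.ungapped(rid) != estimated.ungapped(rid):
            raise ValueError(
                f"ungapped sequence of {rid!r} differs between alignments"
            )


def _pair_count(aln: Alignment) -> int:
    """Number of homologous pairs: sum over non-insertion columns of C(m, 2)."""
    mat = aln.to_matrix()
    m = (mat != GAP.encode()).sum(axis=0).astype(np.int64)
    if aln.insertion_columns:
        keep = np.ones(aln.n_columns, dtype=bool)
        keep[list(aln.insertion_columns)] = False
        m = m[keep]
    return int((m * (m - 1) // 2).sum())


def _shared_pair_count(reference: Alignment, estimated: Alignment) -> int:
    """Pairs homologous in both alignments, by grouping estimated-column
    residues by their reference column."""
    ids = list(reference.rows)
    # reference column of each residue, per row; -1 if the residue sits in
    # an insertion column of the reference (excluded from its pair set)
    ref_ins = reference.insertion_columns
    ref_col_of: dict[str, np.ndarray] = {}
    for rid in ids:
        row = reference.rows[rid]
        cols = np.fromiter(
            (c for c, ch in enumerate(row) if ch != GAP), dtype=np.int64
        )
        if ref_ins:
            mask = np.isin(cols, list(ref_ins))
            cols = np.where(mask, -1, cols)
        ref_col_of[rid] = cols
    est_ins = estimated.insertion_columns
    # per estimated column, group present residues by reference column
    width = estimated.n_columns
    # build matrix of reference columns aligned to the estimated layout
    ref_mat = np.full((len(ids), width), -1, dtype=np.int64)
    for r, rid in enumerate(ids):
        row = estimated.rows[rid]
        pos = np.fromiter(
            (c for c, ch in enumerate(row) if ch != GAP), dtype=np.int64
        )
        ref_mat[r, pos] = ref_col_of[rid]
    shared = 0
    for c in range(width):
        if c in est_ins:
            continue
        col = ref_mat[:, c]
        col = col[col >= 0]
        if col.size < 2:
            continue
        _, counts = np.unique(col, return_counts=True)
        shared += int((counts * (counts - 1) // 2).sum())
    return shared


def spfn(reference: Alignment, estimated: Alignment) -> float:
    """Fraction of reference homologies missing from the estimate."""
    _check_comparable(reference, estimated)
    ref_n = _pair_count(reference)
    if ref_n == 0:
        return 0.0
    shared = _shared_pair_count(reference, estimated)
    return (ref_n - shared) / ref_n


def spfp(reference: Alignment, estimated: Alignment) -> float:
    """Fraction of estimated homologies absent from the reference."""
    _check_comparable(reference, estimated)
    est_n = _pair_count(estimated)
    if est_n == 0:
        return 0.0
    shared = _shared_pair_count(reference, estimated)
    return (est_n - shared) / est_n


def error_report(reference: Alignment, estimated: Alignment) -> ErrorReport:
    return ErrorReport(spfn(reference, estimated), spfp(reference, estimated))


# ---------------------------------------------------------------------------
# Dataset statistics
# ---------------------------------------------------------------------------


def p_distance(row_i: str, row_j: str) -> float:
    """Fraction of differing sites among columns where both rows hold residues."""
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal length")
    comparable = 0
    diff = 0
    for a, b in zip(row_i, row_j):
        if a != GAP and b != GAP:
            comparable += 1
            if a != b:
                diff += 1
    return diff / comparable if comparable else 0.0


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """All pairwise p-distances; incomparable pairs get the max observed."""
    codes = encode_alignment(aln)
    n = codes.shape[0]
    d = np.zeros((n, n))
    incomparable: list[tuple[int, int]] = []
    for i in range(n - 1):
        both = (codes[i] >= 0) & (codes[i + 1 :] >= 0)
        comp = both.sum(axis=1)
        diff = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        vals = np.where(comp > 0, diff / np.maximum(comp, 1), -1.0)
        for off, v in enumerate(vals):
            j = i + 1 + off
            if v < 0:
                incomparable.append((i, j))
            else:
                d[i, j] = d[j, i] = v
    if incomparable:
        dmax = d.max()
        for i, j in incomparable:
            d[i, j] = d[j, i] = dmax
    return d


def percent_gaps(aln: Alignment) -> float:
    mat = aln.to_matrix()
    return float((mat == GAP.encode()).mean())


def dataset_stats(
    aln: Alignment, pair_sample: int | None = None, seed: int = 0
) -> DatasetStats:
    """Summary statistics of an alignment.

    p-distances use all row pairs, or a seeded uniform sample of
    ``pair_sample`` pairs when there are more pairs than that.
    """
    n = aln.n_rows
    lengths = [len(aln.ungapped(i)) for i in aln.rows]
    n_pairs = n * (n - 1) // 2
    if n < 2:
        avg_p = max_p = 0.0
    elif pair_sample is None or n_pairs <= pair_sample:
        d = p_distance_matrix(aln)
        iu = np.triu_indices(n, k=1)
        avg_p = float(d[iu].mean())
        max_p = float(d[iu].max())
    else:
        rng = np.random.default_rng(seed)
        rows = list(aln.rows.values())
        vals = []
        seen: set[tuple[int, int]] = set()
        while len(vals) < pair_sample:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            vals.append(p_distance(rows[key[0]], rows[key[1]]))
        avg_p = float(np.mean(vals))
        max_p = float(np.max(vals))
    return DatasetStats(
        n_sequences=n,
        avg_p_distance=avg_p,
        max_p_distance=max_p,
        percent_gaps=percent_gaps(aln),
        avg_seq_length=float(np.mean(lengths)),
        alignment_length=aln.n_columns,
    )


def pearson_r(xs, ys) -> float:
    """Sample Pearson correlation; errors on zero variance or length < 2."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 2:
        raise ValueError("need two equal-length lists with >= 2 entries")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(xs, ys).statistic)
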