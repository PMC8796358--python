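"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (nested loops, exhaustive
enumeration): they restate the definitions directly and stay independent
of the implementation paths they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from fragalign.msa_core import GAP, Alignment, Sequence


# ---------------------------------------------------------------------------
# Brute-force homology-pair oracle
# ---------------------------------------------------------------------------


def brute_force_pairs(rows: dict[str, str], insertion_columns=frozenset()) -> set:
    """All homologous residue pairs by direct column x row-pair enumeration."""
    ids = list(rows)
    width = len(next(iter(rows.values())))
    pairs = set()
    for col in range(width):
        if col in insertion_columns:
            continue
        present = []
        for rid in ids:
            if rows[rid][col] != GAP:
                k = len(rows[rid][:col].replace(GAP, ""))
                present.append((rid, k))
        for a, b in combinations(present, 2):
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def brute_force_spfn_spfp(ref: Alignment, est: Alignment) -> tuple[float, float]:
    rp = brute_force_pairs(ref.rows, ref.insertion_columns)
    ep = brute_force_pairs(est.rows, est.insertion_columns)
    fn = len(rp - ep) / len(rp) if rp else 0.0
    fp = len(ep - rp) / len(ep) if ep else 0.0
    return fn, fp


# ---------------------------------------------------------------------------
# Exhaustive affine-gap pairwise alignment oracle
# ---------------------------------------------------------------------------


def _all_monotone_paths(m: int, n: int):
    """Yield all global alignment op strings over {'D','U','L'}."""
    stack = [(0, 0, [])]
    while stack:
        i, j, ops = stack.pop()
        if i == m and j == n:
            yield ops
            continue
        if i < m and j < n:
            stack.append((i + 1, j + 1, ops + ["D"]))
        if i < m:
            stack.append((i + 1, j, ops + ["U"]))
        if j < n:
            stack.append((i, j + 1, ops + ["L"]))


def exhaustive_affine_score(
    x: str, y: str, match=2.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-2.0
) -> float:
    """Optimal global affine-gap score by scoring every possible alignment.

    gap_open is the total cost of the first residue of a gap run and
    gap_extend the cost of each subsequent one.
    """
    best = -math.inf
    for ops in _all_monotone_paths(len(x), len(y)):
        score = 0.0
        i = j = 0
        prev = None
        for op in ops:
            if op == "D":
                score += match if x[i] == y[j] else mismatch
                i += 1
                j += 1
            else:
                score += gap_extend if prev == op else gap_open
                if op == "U":
                    i += 1
                else:
                    j += 1
            prev = op
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# Exhaustive Viterbi path-enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_viterbi_score(hmm, residues: str) -> float:
    """Best log-odds path score by enumerating every legal state path."""
    from fragalign.ehmm import _RES_INDEX, LOG_QUARTER

    x = [_RES_INDEX[ch] for ch in residues]
    n = len(x)
    K = hmm.match_count
    lt = hmm.log_t
    le = hmm.log_match_emissions - LOG_QUARTER
    best = [-math.inf]

    def step(state: str, j: int, i: int, score: float) -> None:
        # end transition (M_{K+1}) only from layer K with all residues used
        if j == K and i == n:
            best[0] = max(best[0], score + lt[state + "M"][j])
        # M_{j+1}
        if j < K and i < n:
            step("M", j + 1, i + 1, score + lt[state + "M"][j] + le[j, x[i]])
        # I_j
        if i < n:
            step("I", j, i + 1, score + lt[state + "I"][j])
        # D_{j+1}
        if j < K:
            step("D", j + 1, i, score + lt[state + "D"][j])

    step("M", 0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Random data generators
# ---------------------------------------------------------------------------


def random_sequences(rng: np.random.Generator, n: int, min_len=3, max_len=20):
    out = []
    for i in range(n):
        k = int(rng.integers(min_len, max_len + 1))
        out.append(
            Sequence(f"s{i}", "".join("ACGT"[c] for c in rng.integers(0, 4, k)))
        )
    return out


def random_gapped_layout(rng: np.random.Generator, seqs, max_width=20) -> Alignment:
    """Scatter each sequence's residues over random columns of a shared grid."""
    longest = max(len(s) for s in seqs)
    width = int(rng.integers(longest, max(longest + 1, max_width + 1)))
    rows = {}
    for s in seqs:
        pos = sorted(rng.choice(width, size=len(s), replace=False).tolist())
        row = [GAP] * width
        for ch, p in zip(s.residues, pos):
            row[p] = ch
        rows[s.id] = "".join(row)
    return Alignment(rows).drop_all_gap_columns()


def random_alignment_pair(rng: np.random.Generator, max_rows=6, max_cols=20):
    """Two random alignments of the same underlying sequences."""
    n = int(rng.integers(2, max_rows + 1))
    seqs = random_sequences(rng, n, min_len=1, max_len=max(2, max_cols // 2))
    return (
        random_gapped_layout(rng, seqs, max_cols),
        random_gapped_layout(rng, seqs, max_cols),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
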