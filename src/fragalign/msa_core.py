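"""Core data model: sequences, gapped alignments, homology pairs, trees, and I/O.

The universal currency between pipeline stages is the :class:`Alignment`,
a rectangular gapped matrix keyed by sequence id.  Columns may carry an
*insertion* flag: residues in flagged columns were placed by an HMM insert
state and are not asserted homologous to one another; such columns are
written in lowercase and are excluded from homology-pair extraction.

Trees are scikit-bio ``TreeNode`` objects throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from skbio import TreeNode

GAP = "-"
ALPHABET = "ACGT"
_VALID_RESIDUES = frozenset(ALPHABET)


class FastaError(ValueError):
    """Raised for malformed FASTA input (carries a line number when known)."""


class AlignmentError(ValueError):
    """Raised when an alignment violates its structural invariants."""


@dataclass(frozen=True)
class Sequence:
    """An unaligned nucleotide sequence.

    Residues are uppercase over {A, C, G, T} plus (possibly) ambiguity
    codes that survive until :func:`clean_dataset` removes the sequence.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues:
            raise ValueError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """A rectangular gapped alignment: ordered map id -> gapped row.

    Parameters
    ----------
    rows
        Mapping from sequence id to gapped row string; all rows must have
        equal length.  Row order is preserved.
    insertion_columns
        0-based indices of columns whose residues are non-homologous by
        construction (HMM insert states).  Written lowercase on output and
        excluded from homology pairs.
    """

    def __init__(
        self,
        rows: Mapping[str, str],
        insertion_columns: Iterable[int] = (),
    ) -> None:
        if not rows:
            raise AlignmentError("alignment must contain at least one row")
        self.rows: dict[str, str] = dict(rows)
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        self.n_columns: int = lengths.pop()
        if self.n_columns == 0:
            raise AlignmentError("alignment has zero columns")
        self.insertion_columns: frozenset[int] = frozenset(insertion_columns)
        bad = [c for c in self.insertion_columns if not 0 <= c < self.n_columns]
        if bad:
            raise AlignmentError(f"insertion column indices out of range: {bad}")

    # -- basic views -------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def sequences(self) -> list[Sequence]:
        """The ungapped rows as unaligned sequences (row order preserved)."""
        return [Sequence(i, self.ungapped(i)) for i in self.rows]

    def to_matrix(self) -> np.ndarray:
        """The alignment as a 2D array of single-byte strings."""
        flat = "".join(self.rows.values())
        arr = np.frombuffer(flat.encode("ascii"), dtype="S1")
        return arr.reshape(self.n_rows, self.n_columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.rows == other.rows
            and self.insertion_columns == other.insertion_columns
        )

    def __repr__(self) -> str:
        return f"<Alignment {self.n_rows}x{self.n_columns}>"

    # -- column surgery ----------------------------------------------------

    def keep_columns(self, cols: Iterable[int]) -> "Alignment":
        """A new alignment containing only the given columns, in order."""
        cols = list(cols)
        new_rows = {
            i: "".join(r[c] for c in cols) for i, r in self.rows.items()
        }
        old_ins = self.insertion_columns
        new_ins = {k for k, c in enumerate(cols) if c in old_ins}
        return Alignment(new_rows, new_ins)

    def drop_all_gap_columns(self) -> "Alignment":
        mat = self.to_matrix()
        keep = np.flatnonzero((mat != GAP.encode()).any(axis=0))
        if keep.size == self.n_columns:
            return self
        if keep.size == 0:
            raise AlignmentError("all columns are gap-only")
        return self.keep_columns(keep.tolist())

    def drop_insertion_columns(self) -> "Alignment":
        keep = [c for c in range(self.n_columns) if c not in self.insertion_columns]
        if not keep:
            raise AlignmentError("alignment has only insertion columns")
        return self.keep_columns(keep)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_WRAP = 60


def _normalize(residue_line: str) -> str:
    return residue_line.replace(".", GAP).replace("U", "T").replace("u", "t")


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA records, preserving case (needed for insertion flags)."""
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, "".join(chunks)))
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FastaError(f"empty record id at line {lineno}")
                chunks = []
            else:
                if current_id is None:
                    raise FastaError(
                        f"sequence data before first header at line {lineno}"
                    )
                if ">" in line:
                    raise FastaError(f"stray '>' inside record at line {lineno}")
                chunks.append(_normalize(line))
    if current_id is not None:
        records.append((current_id, "".join(chunks)))
    if not records:
        raise FastaError("no FASTA records found")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise FastaError(f"duplicate sequence id {rid!r}")
        seen.add(rid)
    return records


def read_fasta(path: str | Path, aligned: bool = False):
    """Read a FASTA file.

    With ``aligned=False`` returns a list of :class:`Sequence` (gaps are an
    error); with ``aligned=True`` returns an :class:`Alignment`, inferring
    insertion columns from lowercase residues.  'U' is normalized to 'T'
    and '.' to '-' on the way in.
    """
    records = _parse_fasta(path)
    if not aligned:
        seqs = []
        for rid, body in records:
            body = body.upper()
            if GAP in body:
                raise FastaError(
                    f"record {rid!r} contains gaps but aligned=False"
                )
            seqs.append(Sequence(rid, body))
        return seqs
    lengths = {len(body) for _, body in records}
    if len(lengths) != 1:
        raise FastaError(
            f"aligned FASTA has ragged row lengths: {sorted(lengths)}"
        )
    insertion: set[int] = set()
    for _, body in records:
        for col, ch in enumerate(body):
            if ch.islower():
                insertion.add(col)
    rows = {rid: body.upper() for rid, body in records}
    return Alignment(rows, insertion)


def _wrap(body: str) -> str:
    return "\n".join(body[i : i + _WRAP] for i in range(0, len(body), _WRAP))


def write_fasta(data, path: str | Path) -> None:
    """Write sequences or an alignment as FASTA, 60 characters per line.

    Insertion columns of an alignment are written lowercase so the flag
    round-trips through :func:`read_fasta`.
    """
    if isinstance(data, Alignment):
        ins = data.insertion_columns
        items = []
        for rid, row in data.rows.items():
            if ins:
                row = "".join(
                    ch.lower() if c in ins else ch for c, ch in enumerate(row)
                )
            items.append((rid, row))
    else:
        data = list(data)
        if not data:
            raise ValueError("refusing to write an empty sequence collection")
        items = [(s.id, s.residues) for s in data]
    with open(path, "w") as fh:
        for rid, body in items:
            fh.write(f">{rid}\n{_wrap(body)}\n")


# ---------------------------------------------------------------------------
# Dataset cleaning and homology pairs
# ---------------------------------------------------------------------------


def clean_dataset(aln: Alignment) -> Alignment:
    """Drop every row containing ambiguity codes or no residues at all.

    A row survives iff its ungapped residues are all in {A,C,G,T} and it
    has at least one residue.  Columns left entirely gapped by row removal
    are dropped.  Raises if nothing survives.
    """
    keep = {}
    for rid, row in aln.rows.items():
        residues = row.replace(GAP, "")
        if residues and set(residues) <= _VALID_RESIDUES:
            keep[rid] = row
    if not keep:
        raise AlignmentError("cleaning removed every sequence")
    ins = {c for c in aln.insertion_columns}
    return Alignment(keep, ins & set(range(aln.n_columns))).drop_all_gap_columns()


def homology_pairs(aln: Alignment) -> set:
    """The set of homologous residue pairs implied by an alignment.

    For every non-insertion column, every unordered pair of rows that both
    hold a residue there contributes one pair ``((id_i, k_i), (id_j, k_j))``
    where ``k`` is the 0-based ungapped residue index.  Pairs are stored
    with the two endpoints sorted so the set is canonical.
    """
    pairs: set = set()
    counters = {rid: 0 for rid in aln.rows}
    ids = list(aln.rows)
    row_strs = [aln.rows[i] for i in ids]
    for col in range(aln.n_columns):
        present = []
        for rid, row in zip(ids, row_strs):
            if row[col] != GAP:
                present.append((rid, counters[rid]))
                counters[rid] += 1
        if col in aln.insertion_columns:
            continue
        for a, b in combinations(present, 2):
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def restrict_alignment(aln: Alignment, ids: Iterable[str]) -> Alignment:
    """Restrict to a subset of rows, dropping columns that become all-gap."""
    ids = set(ids)
    unknown = ids - set(aln.rows)
    if unknown:
        raise KeyError(f"unknown sequence ids: {sorted(unknown)}")
    rows = {rid: row for rid, row in aln.rows.items() if rid in ids}
    return Alignment(rows, aln.insertion_columns).drop_all_gap_columns()


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


class NewickError(ValueError):
    pass


def read_newick(path: str | Path) -> TreeNode:
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sniffer chatter on bad input
            return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own hierarchy
        raise NewickError(f"cannot parse newick file {path}: {exc}") from exc


def parse_newick(text: str) -> TreeNode:
    try:
        return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:
        raise NewickError(f"cannot parse newick string: {exc}") from exc


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
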