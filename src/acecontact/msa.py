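"""Query-anchored multiple sequence alignments and subfamily pruning.

An :class:`Msa` keeps every residue-pair computation downstream in *query
coordinates*: ``column_map[c]`` gives, for alignment column ``c``, the
0-based index of the query residue occupying that column (or ``-1`` where
the query has a gap).  Pruning by identity to the query (QID) produces the
nested subfamily alignments at the heart of alternative contact
enhancement: higher thresholds keep sequences increasingly identical to
the query, exposing subfamily-specific couplings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class MsaFormatError(ValueError):
    """Raised when an alignment file does not parse under its format."""


class QueryLookupError(KeyError):
    """Raised when the query label is absent or ambiguous."""


@dataclass(frozen=True)
class Msa:
    """A query-anchored alignment.

    Parameters
    ----------
    rows
        ``(depth, n_columns)`` array of single uppercase characters
        (20 amino acids plus ``-``).
    labels
        Per-row identifiers.
    query_index
        Row index of the query sequence.
    column_map
        Per-column 0-based query residue index; ``-1`` where the query
        row holds a gap.
    """

    rows: np.ndarray
    labels: tuple[str, ...]
    query_index: int
    column_map: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype="<U1")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "column_map", np.asarray(self.column_map, dtype=np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))
        if rows.ndim != 2:
            raise ValueError("rows must be a 2-D character array")
        if len(self.labels) != rows.shape[0]:
            raise ValueError("labels and rows disagree on depth")
        if not 0 <= self.query_index < rows.shape[0]:
            raise ValueError("query_index out of range")
        if self.column_map.shape != (rows.shape[1],):
            raise ValueError("column_map length must equal the number of columns")
        mapped = self.column_map[self.column_map >= 0]
        if mapped.size and np.any(np.diff(mapped) <= 0):
            raise ValueError("column_map must be strictly increasing over non-gap query columns")

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[str],
        labels: Sequence[str],
        query_index: int = 0,
    ) -> "Msa":
        """Build an Msa from aligned strings, deriving column_map from the query."""
        arr = _rows_to_array(rows)
        query = arr[query_index]
        column_map = np.full(arr.shape[1], -1, dtype=np.int64)
        column_map[query != GAP] = np.arange(int((query != GAP).sum()))
        return cls(arr, tuple(labels), query_index, column_map)

    @property
    def depth(self) -> int:
        return self.rows.shape[0]

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    @property
    def query_row(self) -> np.ndarray:
        return self.rows[self.query_index]

    @property
    def query_length(self) -> int:
        """Number of query residues represented in the alignment."""
        return int((self.column_map >= 0).sum())

    def query_sequence(self) -> str:
        """Ungapped query sequence over the retained columns."""
        return "".join(self.query_row[self.column_map >= 0])

    def row_strings(self) -> list[str]:
        return ["".join(r) for r in self.rows]


@dataclass(frozen=True)
class NestedMsas:
    """The superfamily alignment plus its QID-pruned subfamilies.

    ``subfamilies`` holds ``(qid_threshold_percent, Msa)`` with duplicate
    row sets (thresholds crossing no additional sequence) collapsed to the
    lowest threshold producing each distinct alignment.
    """

    superfamily: Msa
    subfamilies: tuple[tuple[int, Msa], ...]
    thresholds: tuple[int, ...]

    def all_msas(self) -> list[tuple[int, Msa]]:
        """Superfamily (threshold 0) followed by the distinct subfamilies."""
        return [(0, self.superfamily), *self.subfamilies]


def _rows_to_array(rows: Iterable[str]) -> np.ndarray:
    rows = [r.upper().replace(".", GAP) for r in rows]
    if not rows:
        raise MsaFormatError("alignment has no sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MsaFormatError(f"rows have unequal lengths: {sorted(lengths)}")
    return np.array([list(r) for r in rows], dtype="<U1")


def _find_query(labels: Sequence[str], query_label: str | None) -> int:
    if query_label is None:
        return 0
    hits = [i for i, lab in enumerate(labels) if lab == query_label]
    if len(hits) != 1:
        raise QueryLookupError(
            f"query label {query_label!r} matched {len(hits)} rows (need exactly 1)"
        )
    return hits[0]


def _read_a3m(path: Path) -> tuple[list[str], list[str]]:
    labels: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
                labels.append(line[1:].split()[0] if len(line) > 1 else "")
            elif line:
                if not labels:
                    raise MsaFormatError("A3M sequence data before first header")
                current.append(line)
    if current:
        seqs.append("".join(current))
    if len(labels) != len(seqs):
        raise MsaFormatError("A3M header/sequence count mismatch")
    # Lowercase letters are insertions relative to the query coordinate
    # system and are deleted; '.' and '-' both read as gaps.
    seqs = ["".join(ch for ch in s if not ch.islower()) for s in seqs]
    return labels, seqs


def read_msa(path: str | Path, format: str = "fasta", query_label: str | None = None) -> Msa:
    """Read an alignment (FASTA, A3M or Stockholm) into query coordinates.

    The query row defaults to the first sequence; pass ``query_label`` to
    select it by identifier (must match exactly one row).
    """
    path = Path(path)
    if format == "a3m":
        labels, seqs = _read_a3m(path)
    elif format in ("fasta", "stockholm"):
        try:
            aln = AlignIO.read(str(path), format)
        except ValueError as exc:
            raise MsaFormatError(f"cannot parse {path} as {format}: {exc}") from exc
        labels = [rec.id for rec in aln]
        seqs = [str(rec.seq) for rec in aln]
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not labels:
        raise MsaFormatError(f"{path} contains no sequences")
    qidx = _find_query(labels, query_label)
    try:
        return Msa.from_rows(seqs, labels, qidx)
    except MsaFormatError:
        raise
    except ValueError as exc:
        raise MsaFormatError(str(exc)) from exc


def write_msa(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment; A3M output carries no insert states (plain aligned)."""
    path = Path(path)
    if format in ("fasta", "a3m"):
        with open(path, "w") as fh:
            for label, row in zip(msa.labels, msa.row_strings()):
                fh.write(f">{label}\n{row}\n")
    elif format == "stockholm":
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(msa.labels, msa.row_strings())
        ]
        AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def qid_to_query(msa: Msa) -> np.ndarray:
    """Per-row identity to the query (QID).

    Identity is the fraction of columns, among those where the query is
    non-gap, where the row carries the same residue as the query (gaps in
    the row never match).  The query row scores 1.0.
    """
    qcols = msa.column_map >= 0
    query = msa.query_row[qcols]
    sub = msa.rows[:, qcols]
    matches = (sub == query[None, :]) & (sub != GAP)
    n_query_cols = int(qcols.sum())
    if n_query_cols == 0:
        raise ValueError("query row is all gaps")
    return matches.sum(axis=1) / n_query_cols


def prune_by_qid(msa: Msa, threshold_percent: float) -> Msa:
    """Keep rows with QID >= threshold_percent/100; the query always survives."""
    if not 0 <= threshold_percent <= 100:
        raise ValueError("threshold must be in [0, 100]")
    qid = qid_to_query(msa)
    keep = qid >= threshold_percent / 100.0
    keep[msa.query_index] = True
    return _take_rows(msa, np.flatnonzero(keep))


def _take_rows(msa: Msa, row_idx: np.ndarray) -> Msa:
    row_idx = np.asarray(row_idx)
    new_query = int(np.searchsorted(row_idx, msa.query_index))
    return Msa(
        msa.rows[row_idx],
        tuple(msa.labels[i] for i in row_idx),
        new_query,
        msa.column_map.copy(),
    )


def make_nested_msas(msa: Msa, thresholds: Sequence[int] = tuple(range(1, 51))) -> NestedMsas:
    """Prune at each QID threshold (default 1–50% in steps of 1%).

    Thresholds yielding identical row sets are collapsed to one entry (the
    lowest such threshold); a threshold retaining the full superfamily is
    collapsed into the superfamily itself.
    """
    thresholds = tuple(sorted(thresholds))
    qid = qid_to_query(msa)
    seen: set[frozenset[int]] = {frozenset(range(msa.depth))}
    subfamilies: list[tuple[int, Msa]] = []
    for t in thresholds:
        keep = qid >= t / 100.0
        keep[msa.query_index] = True
        key = frozenset(np.flatnonzero(keep).tolist())
        if key in seen:
            continue
        seen.add(key)
        subfamilies.append((t, _take_rows(msa, np.flatnonzero(keep))))
    return NestedMsas(msa, tuple(subfamilies), thresholds)


def filter_gaps(msa: Msa, seq_gap_max: float = 0.25, col_gap_max: float = 0.75) -> Msa:
    """Remove gappy rows, then gappy columns.

    Rows (never the query) with gap fraction > ``seq_gap_max`` are removed
    first; columns with gap fraction > ``col_gap_max`` over the remaining
    rows are then removed.  The order matters and is part of the contract:
    row removal changes the per-column gap statistics.
    """
    gaps = msa.rows == GAP
    row_frac = gaps.mean(axis=1)
    keep_rows = row_frac <= seq_gap_max
    keep_rows[msa.query_index] = True
    row_idx = np.flatnonzero(keep_rows)
    col_frac = gaps[row_idx].mean(axis=0)
    keep_cols = col_frac <= col_gap_max
    new_query = int(np.searchsorted(row_idx, msa.query_index))
    return Msa(
        msa.rows[np.ix_(row_idx, np.flatnonzero(keep_cols))],
        tuple(msa.labels[i] for i in row_idx),
        new_query,
        msa.column_map[keep_cols],
    )


def depth_sufficient(msa: Msa, query_length: int | None = None) -> bool:
    """True iff the alignment is deep enough for coevolutionary analysis.

    The rule is depth >= 5 x query length; shallower alignments give
    couplings too noisy to interpret.
    """
    if query_length is None:
        query_length = msa.query_length
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    return msa.depth >= 5 * query_length


def mask_columns_to_alanine(
    msa: Msa, query_positions: Iterable[int], keep_query: bool = True
) -> Msa:
    """Mutate the listed query columns to alanine in every non-query row.

    This weakens the coevolutionary signal carried by those columns (used
    to suppress a dominant fold's couplings) while leaving the query
    sequence itself intact when ``keep_query``.  Gaps are preserved.
    """
    positions = sorted(set(int(p) for p in query_positions))
    cols = []
    present = {int(q): c for c, q in enumerate(msa.column_map) if q >= 0}
    for p in positions:
        if p not in present:
            raise IndexError(f"query position {p} not present in column_map")
        cols.append(present[p])
    if not cols:
        return msa
    rows = msa.rows.copy()
    target = rows[:, cols]
    target[target != GAP] = "A"
    rows[:, cols] = target
    if keep_query:
        rows[msa.query_index] = msa.query_row
    return dataclasses.replace(msa, rows=rows)
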