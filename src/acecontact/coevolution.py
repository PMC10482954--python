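"""Per-alignment residue-pair coupling scores.

The package does not reimplement Potts-model or language-model inference;
those run externally and their score files are imported with
:func:`load_external_scores`.  A built-in stand-in scorer,
:func:`score_mi_apc` (mutual information with average-product correction),
provides a self-contained coupling signal with the same interface so the
whole enhancement pipeline can run without external tools.

Every run is normalized to z-scores over its own scored pairs before
superposition, so runs from alignments of very different depths are
comparable.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import GAP, Msa

#: 20 amino acids plus the gap symbol, treated as a 21st state.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + GAP


class InsufficientDataError(ValueError):
    """Raised when an alignment is too shallow to score."""


class ScoreParseError(ValueError):
    """Raised on malformed external score files; names the offending line."""


@dataclass(frozen=True)
class PredictionRun:
    """Residue-pair scores from one (alignment, method) combination.

    Pair indices ``i < j`` are 0-based query residue indices.  ``z`` is
    ``None`` until :func:`zscore_run` has been applied.
    """

    method_tag: str
    msa_depth: int
    i: np.ndarray
    j: np.ndarray
    raw: np.ndarray
    z: np.ndarray | None = None
    depth_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "i", np.asarray(self.i, dtype=np.int64))
        object.__setattr__(self, "j", np.asarray(self.j, dtype=np.int64))
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=np.float64))
        if self.z is not None:
            object.__setattr__(self, "z", np.asarray(self.z, dtype=np.float64))
        if not (self.i.shape == self.j.shape == self.raw.shape):
            raise ValueError("i, j and raw must have equal shapes")
        if np.any(self.i >= self.j):
            raise ValueError("pairs must satisfy i < j")
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must lie in (0, 1]")

    @property
    def n_pairs(self) -> int:
        return int(self.i.size)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def to_frame(self) -> pd.DataFrame:
        data = {"i": self.i, "j": self.j, "raw": self.raw}
        if self.z is not None:
            data["z"] = self.z
        return pd.DataFrame(data)


def _encode(msa: Msa) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode the query-mapped columns; unknown residues count as gaps."""
    mapped = msa.column_map >= 0
    sub = np.ascontiguousarray(msa.rows[:, mapped])
    lut = np.full(128, ALPHABET.index(GAP), dtype=np.int64)
    for k, aa in enumerate(ALPHABET):
        lut[ord(aa)] = k
    codes = lut[sub.view(np.uint32).reshape(sub.shape) % 128]
    return codes, msa.column_map[mapped]


def mi_matrix(msa: Msa, pseudocount: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mutual information between all query-mapped column pairs.

    Joint frequencies use an additive pseudocount spread over the 21x21
    cells, ``f_ab(x,y) = (n_ab(x,y) + pc/441) / (N + pc)``, with marginals
    taken as the row/column sums of the smoothed joint so the MI
    decomposition stays internally consistent.

    Returns ``(M, qpos)``: the symmetric C x C MI matrix over mapped
    columns and the query residue index of each column.
    """
    codes, qpos = _encode(msa)
    n_rows, n_cols = codes.shape
    if n_rows < 2:
        raise InsufficientDataError("need at least 2 sequences to score couplings")
    q = len(ALPHABET)
    lam = pseudocount / (q * q)
    denom = n_rows + pseudocount

    marg = np.zeros((n_cols, q))
    for c in range(n_cols):
        marg[c] = np.bincount(codes[:, c], minlength=q)
    fmarg = (marg + lam * q) / denom
    log_fmarg = np.log(fmarg)

    a_idx, b_idx = np.triu_indices(n_cols, k=1)
    n_pairs = a_idx.size
    joint = np.empty((n_pairs, q * q))
    for p in range(n_pairs):
        joint[p] = np.bincount(codes[:, a_idx[p]] * q + codes[:, b_idx[p]], minlength=q * q)
    fj = (joint + lam) / denom
    log_outer = (log_fmarg[a_idx][:, :, None] + log_fmarg[b_idx][:, None, :]).reshape(
        n_pairs, q * q
    )
    mi = np.einsum("pc,pc->p", fj, np.log(fj) - log_outer)

    mat = np.zeros((n_cols, n_cols))
    mat[a_idx, b_idx] = mi
    mat[b_idx, a_idx] = mi
    return mat, qpos


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: ``S(a,b) = MI(a,b) - m_a m_b / m``.

    ``m_a`` is the mean coupling of column ``a`` over all other columns and
    ``m`` the grand mean; the correction suppresses entropic and
    phylogenetic bias concentrated in individual columns.
    """
    n = mi.shape[0]
    if n < 2:
        return mi - mi
    col_mean = mi.sum(axis=1) / (n - 1)
    grand = mi[np.triu_indices(n, k=1)].mean()
    if grand == 0:
        return mi.copy()
    corr = mi - np.outer(col_mean, col_mean) / grand
    np.fill_diagonal(corr, 0.0)
    return corr


def score_mi_apc(
    msa: Msa, min_separation: int = 6, pseudocount: float = 1.0
) -> PredictionRun:
    """Stand-in coupling scorer: APC-corrected mutual information.

    Reports every query-coordinate pair with sequence separation
    ``j - i >= min_separation``.  The gap symbol participates as a 21st
    state and sequences are unweighted, keeping the score a deterministic
    function of the alignment.
    """
    mat, qpos = mi_matrix(msa, pseudocount)
    corr = apc_correct(mat)
    a_idx, b_idx = np.triu_indices(len(qpos), k=1)
    qi, qj = qpos[a_idx], qpos[b_idx]
    keep = qj - qi >= min_separation
    return PredictionRun(
        method_tag="mi-apc",
        msa_depth=msa.depth,
        i=qi[keep],
        j=qj[keep],
        raw=corr[a_idx[keep], b_idx[keep]],
    )


def zscore_run(run: PredictionRun) -> PredictionRun:
    """Standardize raw scores to mean 0, population standard deviation 1."""
    if run.n_pairs < 2:
        raise InsufficientDataError("need at least 2 scored pairs to z-score")
    std = run.raw.std()
    if std == 0:
        warnings.warn(
            f"run {run.method_tag!r}: zero score variance, all z-scores set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        z = np.zeros_like(run.raw)
    else:
        z = (run.raw - run.raw.mean()) / std
    return dataclasses.replace(run, z=z)


def truncate_run(run: PredictionRun, cap: int) -> PredictionRun:
    """Keep a run's top-``cap`` pairs by z-score (the per-run retention step).

    Ties break deterministically by lower ``i`` then lower ``j``.  Pairs
    outside the cap are dropped entirely — in the downstream superposition
    an absent pair simply contributes nothing for this run.
    """
    if run.z is None:
        run = zscore_run(run)
    if run.n_pairs <= cap:
        return run
    order = np.lexsort((run.j, run.i, -run.z))[:cap]
    keep = np.sort(order)
    return dataclasses.replace(
        run, i=run.i[keep], j=run.j[keep], raw=run.raw[keep], z=run.z[keep]
    )


def _parse_pair_list(path: Path) -> tuple[bool, list[tuple[int, int, float]]]:
    one_based = False
    triples: list[tuple[int, int, float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].lstrip().startswith("#"):
        token = lines[0].lstrip("# \t").strip().lower()
        if token == "one_based":
            one_based = True
        elif token != "zero_based":
            raise ScoreParseError(
                f"{path}:1: header must declare 'zero_based' or 'one_based', got {token!r}"
            )
        start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ScoreParseError(f"{path}:{ln}: expected 'i j score', got {line.strip()!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
            s = float(parts[2])
        except ValueError as exc:
            raise ScoreParseError(f"{path}:{ln}: non-numeric field: {exc}") from exc
        triples.append((i, j, s))
    return one_based, triples


def load_external_scores(
    path: str | Path,
    format: str,
    msa: Msa,
    min_separation: int = 6,
    method_tag: str | None = None,
) -> PredictionRun:
    """Import coupling scores produced by an external inference engine.

    ``pair_list`` files carry a ``# zero_based`` / ``# one_based`` header
    followed by ``i j score`` lines; ``matrix`` files are an L x L numeric
    grid over query residues (L = mapped query length).  Symmetric entries
    are averaged, indices mapped to 0-based query coordinates, and pairs
    closer than ``min_separation`` dropped.
    """
    path = Path(path)
    L = msa.query_length
    scores: dict[tuple[int, int], list[float]] = {}
    if format == "pair_list":
        one_based, triples = _parse_pair_list(path)
        off = 1 if one_based else 0
        for ln, (i, j, s) in enumerate(triples, start=1):
            i, j = i - off, j - off
            if not (0 <= i < L and 0 <= j < L):
                raise ScoreParseError(
                    f"{path}: pair ({i},{j}) out of range for query length {L}"
                )
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            scores.setdefault(key, []).append(s)
    elif format == "matrix":
        rows: list[list[float]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                try:
                    rows.append([float(tok) for tok in line.split()])
                except ValueError as exc:
                    raise ScoreParseError(f"{path}:{ln}: non-numeric cell: {exc}") from exc
        mat = np.array(rows, dtype=float) if rows and len({len(r) for r in rows}) == 1 else None
        if mat is None or mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            shape = None if mat is None else mat.shape
            raise ScoreParseError(f"{path}: ragged or non-square matrix (shape {shape})")
        if mat.shape[0] != L:
            raise ScoreParseError(
                f"{path}: matrix dimension {mat.shape[0]} does not match query length {L}"
            )
        for i in range(L):
            for j in range(i + 1, L):
                scores[(i, j)] = [mat[i, j], mat[j, i]]
    else:
        raise ValueError(f"unknown score format {format!r}")

    pairs = sorted(scores)
    i_arr = np.array([p[0] for p in pairs], dtype=np.int64)
    j_arr = np.array([p[1] for p in pairs], dtype=np.int64)
    raw = np.array([float(np.mean(scores[p])) for p in pairs])
    keep = j_arr - i_arr >= min_separation
    return PredictionRun(
        method_tag=method_tag or f"external-{format}",
        msa_depth=msa.depth,
        i=i_arr[keep],
        j=j_arr[keep],
        raw=raw[keep],
    )


def write_run(run: PredictionRun, path: str | Path) -> None:
    """Write a run as a zero-based pair list (round-trips through the loader)."""
    with open(path, "w") as fh:
        fh.write("# zero_based\n")
        for i, j, s in zip(run.i, run.j, run.raw):
            fh.write(f"{i}\t{j}\t{float(s)!r}\n")
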