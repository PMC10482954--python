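"""Blind fold-switch calling from two independently predicted structures.

Two structure predictors (an MSA-conditioned one and a single-sequence
language model) each produce a model of the same sequence.  If their
secondary structures diverge over a sustained region and coevolved
contacts support the uniquely folded regions of *both* models, the
protein is called a fold switcher (Category 1).  If the models agree but
a substantial coevolutionary signal remains that neither model explains,
the protein is flagged Category 2 (with a caveat: multimeric interfaces
can mimic such signal).  Everything else is a single folder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import FilteredPredictions, overlap_mask
from .structures import CategorizedPredictions, DualFoldMap

Pair = tuple[int, int]
Span = tuple[int, int]

#: DSSP 8-state to 3-state collapse: 3-10/alpha/pi helices -> H,
#: strand/bridge -> E, everything else (turn, bend, PPII, coil) -> C.
_SS8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", " ": "C", "-": "C", "C": "C", "P": "C", "~": "C",
}


class SsParseError(ValueError):
    """Raised on characters outside the DSSP secondary-structure alphabet."""


def simplify_ss(eight_state: str) -> str:
    """Collapse a DSSP 8-state string to 3 states over {H, E, C}."""
    out = []
    for k, ch in enumerate(eight_state):
        try:
            out.append(_SS8_TO_3[ch])
        except KeyError:
            raise SsParseError(
                f"unknown secondary-structure code {ch!r} at position {k}"
            ) from None
    return "".join(out)


def read_dssp(path: str | Path) -> dict[str, str]:
    """Read per-chain 8-state secondary structure from a classic DSSP file."""
    path = Path(path)
    chains: dict[str, list[str]] = {}
    in_data = False
    with open(path) as fh:
        for line in fh:
            if not in_data:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_data = True
                continue
            if len(line) < 17:
                continue
            if line[13] == "!":  # chain break
                continue
            chain = line[11].strip() or "A"
            chains.setdefault(chain, []).append(line[16] if line[16] != " " else " ")
    if not chains:
        raise SsParseError(f"{path}: no residue records found (is this DSSP output?)")
    return {c: "".join(ss) for c, ss in chains.items()}


def find_divergent_regions(
    ss_a: str, ss_b: str, min_len: int = 15, min_frac: float = 0.5
) -> list[Span]:
    """Sustained alpha <-> beta disagreements between two 3-state strings.

    A position diverges iff one string has H and the other E there.  Any
    window of length >= ``min_len`` whose divergence density is
    >= ``min_frac`` marks all of its positions; maximal merged runs of
    marked positions are returned as inclusive (start, end) spans.
    """
    if len(ss_a) != len(ss_b):
        raise ValueError(
            f"secondary-structure strings differ in length ({len(ss_a)} vs {len(ss_b)})"
        )
    n = len(ss_a)
    if n == 0:
        return []
    a = np.frombuffer(ss_a.encode(), dtype="S1")
    b = np.frombuffer(ss_b.encode(), dtype="S1")
    diff = ((a == b"H") & (b == b"E")) | ((a == b"E") & (b == b"H"))
    csum = np.concatenate([[0], np.cumsum(diff)])
    marked = np.zeros(n, dtype=bool)
    for w in range(min_len, n + 1):
        window_counts = csum[w:] - csum[:-w]
        hits = np.flatnonzero(window_counts >= min_frac * w)
        for s in hits:
            marked[s : s + w] = True
    spans: list[Span] = []
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return spans
    start = prev = int(idx[0])
    for k in idx[1:]:
        k = int(k)
        if k != prev + 1:
            spans.append((start, prev))
            start = k
        prev = k
    spans.append((start, prev))
    return spans


def corroborate(
    dualmap: DualFoldMap,
    filtered: FilteredPredictions,
    tol: int = 2,
    min_cluster: int = 3,
) -> dict[str, int]:
    """Per predicted structure: how many contact clusters support its unique fold.

    A cluster (size >= ``min_cluster``) supports a structure when at least
    one member falls within the +/-tol box of that structure's unique
    contacts (interchain included).  A structure is corroborated iff it
    has at least one supporting cluster; identical predictions have empty
    unique sets, hence zero corroboration by definition.
    """
    counts: dict[str, int] = {}
    for fold in dualmap.source_ids:
        ref = dualmap.fold_reference(fold)
        n = 0
        for cluster in filtered.clusters:
            if len(cluster) < min_cluster:
                continue
            if len(ref) and overlap_mask(cluster, ref, tol).any():
                n += 1
        counts[fold] = n
    return counts


def alternative_signal_clusters(
    filtered: FilteredPredictions,
    dualmap: DualFoldMap,
    tol: int = 2,
    min_size: int = 5,
    min_separation: float = 6.0,
) -> list[np.ndarray]:
    """Clusters unexplained by either predicted structure.

    Operationalizes "substantial alternative signal": a cluster of at
    least ``min_size`` pairs, mean sequence separation at least
    ``min_separation`` (excluding near-diagonal smears), none of whose
    members overlap any contact of either predicted structure within
    +/-tol.  Deliberately conservative; multimeric interfaces can still
    produce such clusters, which is why Category 2 calls carry a flag.
    """
    all_ref = dualmap.all_contacts()
    out = []
    for cluster in filtered.clusters:
        if len(cluster) < min_size:
            continue
        if np.mean(cluster[:, 1] - cluster[:, 0]) < min_separation:
            continue
        if len(all_ref) and overlap_mask(cluster, all_ref, tol).any():
            continue
        out.append(cluster)
    return out


@dataclass(frozen=True)
class BlindCall:
    """Outcome of the blind classification.

    category1 — predictions diverge and coevolution corroborates both;
    category2 — predictions agree but unexplained coevolutionary signal
    for an alternative conformation persists; single_fold — coevolutionary
    evidence for one conformation only.
    """

    category: str
    divergent_regions: tuple[Span, ...]
    corroboration: Mapping[str, int]
    n_alternative_signal_clusters: int
    flags: tuple[str, ...] = ()


def classify_blind(
    ss_a: str,
    ss_b: str,
    corroboration: Mapping[str, int],
    alt_signal_clusters: Sequence,
    min_len: int = 15,
    min_frac: float = 0.5,
) -> BlindCall:
    """Apply the Category 1 / Category 2 / single-fold decision rule.

    Divergence with both structures corroborated is Category 1.  When the
    two predictions diverge but only one is corroborated, the call is
    still Category 1 but flagged low-confidence (a partially supported
    switch).  Without divergence, persisting unexplained signal gives
    Category 2 (flagged: could be a multimer interface).  Otherwise the
    protein is called a single folder.
    """
    divergent = tuple(find_divergent_regions(ss_a, ss_b, min_len, min_frac))
    supported = [fold for fold, n in corroboration.items() if n >= 1]
    flags: list[str] = []
    if divergent and len(supported) == 2:
        category = "category1"
    elif divergent and len(supported) == 1:
        category = "category1"
        flags.append("low_confidence_single_corroboration")
    elif not divergent and len(alt_signal_clusters) >= 1:
        category = "category2"
        flags.append("possible_multimer_interface")
    else:
        category = "single_fold"
    return BlindCall(
        category=category,
        divergent_regions=divergent,
        corroboration=dict(corroboration),
        n_alternative_signal_clusters=len(alt_signal_clusters),
        flags=tuple(flags),
    )


def dominant_only_positions(categorized: CategorizedPredictions) -> set[int]:
    """Query positions in at least one dominant pair and no alternative pair.

    These are the columns masked to alanine to weaken the dominant fold's
    coevolutionary signal; positions participating in contacts of both
    folds are left untouched.
    """
    dom_pos = {p for pair in categorized.dominant for p in pair}
    alt_pos = {p for pair in categorized.alternative for p in pair}
    return dom_pos - alt_pos
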