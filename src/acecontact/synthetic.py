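"""Synthetic protein families with planted dual-fold couplings.

The generator emulates the evolutionary scenario the pipeline targets: a
diverse superfamily in which *dominant-fold* residue pairs coevolve in
every sequence, plus a high-identity clade (the fold-switching
subfamily) in which additional *alternative-fold* pairs coevolve.

Each planted pair is realized as a two-state column pair: both columns
draw their symbols from a fixed 2x2 table in every row, but only rows in
the pair's active stratum (all rows for dominant pairs, clade rows for
alternative pairs) draw the two symbols jointly; other rows draw them
independently.  Marginal column frequencies are therefore identical in
and out of the clade, so the alternative signal visible to a whole-
superfamily analysis is only the modest joint-frequency excess
contributed by the clade — the signal becomes strong only once pruning
isolates the clade, which is exactly the behavior the enhancement
pipeline is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .msa import Msa
from .structures import DualFoldMap

Pair = tuple[int, int]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _default_dominant() -> tuple[Pair, ...]:
    return tuple([(10 + k, 40 + k) for k in range(4)] + [(55 + k, 80 + k) for k in range(4)])


def _default_alternative() -> tuple[Pair, ...]:
    return tuple([(20 + k, 70 + k) for k in range(4)] + [(30 + k, 90 + k) for k in range(4)])


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted family.

    Planted pairs are laid out (by default) as two diagonal 4-contact
    clusters per category, mimicking the locally dense stripes of real
    contact maps — the density-based denoiser is only meaningful on
    spatially clustered signal.  Identities are expectations, not exact
    row properties.
    """

    L: int = 100
    n_super: int = 2000
    clade_fraction: float = 0.15
    dominant_pairs: tuple[Pair, ...] = field(default_factory=_default_dominant)
    alternative_pairs: tuple[Pair, ...] = field(default_factory=_default_alternative)
    coupling_strength: float = 0.9
    background_identity: float = 0.35
    clade_identity: float = 0.75
    min_separation: int = 6
    seed: int = 7

    def validate(self) -> None:
        if not 0 < self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in (0, 1]")
        if not self.clade_identity > self.background_identity:
            raise ValueError("clade_identity must exceed background_identity")
        if self.n_super < 5 * self.L:
            raise ValueError("n_super must be at least 5*L for a usable superfamily")
        planted = self.dominant_pairs + self.alternative_pairs
        cols = [c for p in planted for c in p]
        if len(set(planted)) != len(planted):
            raise ValueError("planted pair sets must be disjoint")
        if len(set(cols)) != len(cols):
            raise ValueError("planted pairs must not share columns")
        for i, j in planted:
            if not 0 <= i < j < self.L:
                raise ValueError(f"planted pair ({i},{j}) outside [0, L)")
            if j - i < self.min_separation:
                raise ValueError(f"planted pair ({i},{j}) closer than min_separation")


def default_spec(seed: int = 7) -> SyntheticSpec:
    return SyntheticSpec(seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: pair sets, clade membership, coupling tables."""

    dominant_pairs: tuple[Pair, ...]
    alternative_pairs: tuple[Pair, ...]
    clade_rows: tuple[int, ...]
    tables: dict[Pair, tuple[tuple[str, str], tuple[str, str]]]
    query: str


def generate_family(spec: SyntheticSpec) -> tuple[Msa, GroundTruth]:
    """Generate the superfamily alignment and its planted ground truth.

    Deterministic given ``spec.seed``.  Row 0 is the query (a clade
    member by construction); the following ``clade_fraction * n_super``
    rows form the high-identity clade.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, n = spec.L, spec.n_super
    aa = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")

    query = rng.integers(0, 20, size=L)
    n_clade = max(1, round(spec.clade_fraction * n))
    clade_rows = tuple(range(0, n_clade + 1))  # query row included

    codes = np.empty((n, L), dtype=np.int64)
    codes[0] = query
    ident = np.full(n, spec.background_identity)
    ident[1 : n_clade + 1] = spec.clade_identity
    body = slice(1, n)
    match = rng.random((n - 1, L)) < ident[body, None]
    mutated = (query[None, :] + 1 + rng.integers(0, 19, size=(n - 1, L))) % 20
    codes[body] = np.where(match, query[None, :], mutated)

    # Planted two-state column pairs.
    tables: dict[Pair, tuple[tuple[str, str], tuple[str, str]]] = {}
    planted = [(p, True) for p in spec.dominant_pairs] + [
        (p, False) for p in spec.alternative_pairs
    ]
    clade_mask = np.zeros(n, dtype=bool)
    clade_mask[list(clade_rows)] = True
    for (ci, cj), is_dominant in planted:
        xi = rng.choice(20, size=2, replace=False)
        yj = rng.choice(20, size=2, replace=False)
        tables[(ci, cj)] = (
            (AA20[xi[0]], AA20[yj[0]]),
            (AA20[xi[1]], AA20[yj[1]]),
        )
        active = np.ones(n, dtype=bool) if is_dominant else clade_mask.copy()
        coupled = active & (rng.random(n) < spec.coupling_strength)
        state = rng.integers(0, 2, size=n)
        x_ind = rng.integers(0, 2, size=n)
        y_ind = rng.integers(0, 2, size=n)
        codes[:, ci] = np.where(coupled, xi[state], xi[x_ind])
        codes[:, cj] = np.where(coupled, yj[state], yj[y_ind])
        # the query sits in coupled state 0
        codes[0, ci], codes[0, cj] = xi[0], yj[0]

    rows = aa[codes]
    labels = ["query"] + [
        (f"clade_{r:05d}" if clade_mask[r] else f"bg_{r:05d}") for r in range(1, n)
    ]
    msa = Msa.from_rows(["".join(r) for r in rows], labels, query_index=0)
    truth = GroundTruth(
        dominant_pairs=tuple(spec.dominant_pairs),
        alternative_pairs=tuple(spec.alternative_pairs),
        clade_rows=clade_rows,
        tables=tables,
        query="".join(aa[query]),
    )
    return msa, truth


def truth_dual_fold_map(truth: GroundTruth, L: int) -> DualFoldMap:
    """Dual-fold map whose folds are the planted dominant/alternative sets."""
    dom = frozenset(truth.dominant_pairs)
    alt = frozenset(truth.alternative_pairs)
    return DualFoldMap(
        source_ids=("dominant_fold", "alternative_fold"),
        unique={"dominant_fold": dom, "alternative_fold": alt},
        common=frozenset(),
        interchain={"dominant_fold": frozenset(), "alternative_fold": frozenset()},
        L=L,
    )


def generate_toy_dualfold(
    L: int,
    n_dominant: int,
    n_alternative: int,
    n_common: int,
    seed: int = 0,
    min_separation: int = 2,
) -> DualFoldMap:
    """Random disjoint contact sets with the requested category sizes.

    Contact *sets* are emitted directly (no 3-D realization is attempted);
    use them to exercise categorization and statistics.
    """
    rng = np.random.default_rng(seed)
    candidates = [(i, j) for i in range(L) for j in range(i + min_separation, L)]
    need = n_dominant + n_alternative + n_common
    if need > len(candidates):
        raise ValueError(
            f"cannot place {need} contacts with separation >= {min_separation} in L={L}"
        )
    chosen = rng.choice(len(candidates), size=need, replace=False)
    pairs = [candidates[k] for k in chosen]
    dom = frozenset(pairs[:n_dominant])
    alt = frozenset(pairs[n_dominant : n_dominant + n_alternative])
    common = frozenset(pairs[n_dominant + n_alternative :])
    return DualFoldMap(
        source_ids=("fold_a", "fold_b"),
        unique={"fold_a": dom, "fold_b": alt},
        common=common,
        interchain={"fold_a": frozenset(), "fold_b": frozenset()},
        L=L,
    )


@dataclass(frozen=True)
class BlindScenario:
    """Inputs for a blind fold-switch call with known ground truth.

    Emulates the post-filtering composition of real enhanced-contact
    output — dense clusters sitting on structural contacts plus sparse
    scattered noise — together with the two predicted structures' contact
    maps and secondary-structure strings.
    """

    is_fold_switcher: bool
    dualmap: DualFoldMap
    ss_a: str
    ss_b: str
    points: np.ndarray  # unfiltered predicted pairs (clusters + scatter)


def _random_stripes(
    rng: np.random.Generator,
    L: int,
    n_stripes: int,
    stripe_len: int,
    min_separation: int,
    exclude: set[Pair],
) -> list[Pair]:
    """Diagonal contact stripes like helix/strand packing seams."""
    pairs: list[Pair] = []
    attempts = 0
    while len(pairs) < n_stripes * stripe_len and attempts < 1000:
        attempts += 1
        i0 = int(rng.integers(0, L - 2 * stripe_len - min_separation - 1))
        j0 = int(rng.integers(i0 + min_separation + stripe_len, L - stripe_len + 1))
        stripe = [(i0 + k, j0 + k) for k in range(stripe_len)]
        near = {
            (i + di, j + dj)
            for i, j in stripe
            for di in range(-4, 5)
            for dj in range(-4, 5)
        }
        if near & (set(pairs) | exclude):
            continue
        pairs.extend(stripe)
    return pairs


def generate_blind_scenario(
    fold_switcher: bool,
    L: int = 100,
    n_stripes: int = 4,
    stripe_len: int = 5,
    n_noise: int = 60,
    seed: int = 0,
) -> BlindScenario:
    """A blind-call scenario: predicted structures, SS strings, contact cloud.

    Single folders get two identical predicted structures (empty unique
    sets, identical secondary structure) and a contact cloud on fold-A
    contacts only.  Fold switchers get two structures with distinct
    contact stripes, a 20-residue alpha/beta divergence, and clusters on
    both folds' unique contacts.  Scattered noise is sparse, as after
    density filtering of realistic predictions.
    """
    rng = np.random.default_rng(seed)
    min_sep = 6
    fold_a = _random_stripes(rng, L, n_stripes, stripe_len, min_sep, set())
    fold_b = (
        _random_stripes(rng, L, n_stripes, stripe_len, min_sep, set(fold_a))
        if fold_switcher
        else list(fold_a)
    )
    common = frozenset(fold_a) & frozenset(fold_b)
    dualmap = DualFoldMap(
        source_ids=("pred_a", "pred_b"),
        unique={
            "pred_a": frozenset(fold_a) - common,
            "pred_b": frozenset(fold_b) - common,
        },
        common=common,
        interchain={"pred_a": frozenset(), "pred_b": frozenset()},
        L=L,
    )
    ss_a = list("C" * L)
    ss_b = list("C" * L)
    start = int(rng.integers(10, L - 30))
    for k in range(start, start + 20):
        ss_a[k] = "H"
        ss_b[k] = "E" if fold_switcher else "H"

    cloud = list(fold_a)
    if fold_switcher:
        cloud += fold_b
    seen = set(cloud)
    candidates = [
        (i, j) for i in range(L) for j in range(i + min_sep, L) if (i, j) not in seen
    ]
    picks = rng.choice(len(candidates), size=min(n_noise, len(candidates)), replace=False)
    cloud += [candidates[k] for k in picks]
    points = np.array(sorted(set(cloud)), dtype=np.int64)
    return BlindScenario(fold_switcher, dualmap, "".join(ss_a), "".join(ss_b), points)


#: Backbone-only template used to fabricate tiny coordinate files for the
#: structure-parser path; clearly synthetic, not a real protein.
def toy_pdb_string(
    ca_coords: Sequence[Sequence[float]], seq: str, chain_id: str = "A"
) -> str:
    """A minimal synthetic PDB (one CA heavy atom per residue)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    if len(ca_coords) != len(seq):
        raise ValueError("need one CA coordinate per residue")
    lines = []
    for k, ((x, y, z), aa) in enumerate(zip(ca_coords, seq), start=1):
        lines.append(
            f"ATOM  {k:5d}  CA  {three[aa]} {chain_id}{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
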