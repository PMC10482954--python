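"""Experimental contact maps and dual-fold categorization.

Contacts are residue pairs whose closest heavy atoms lie within 8 A
(intrachain) or 10 A (interchain).  Two conformations of the same
sequence give a dual-fold map: contacts unique to each fold, contacts
common to both, and each fold's interchain contacts.  Predicted pairs
are then categorized against that map with a +/-2 residue tolerance; the
fold overlapping most predictions from the deepest alignment is labeled
"dominant" (a bookkeeping convention with no energetic meaning).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .core import FilteredPredictions, overlap_mask

Pair = tuple[int, int]


@dataclass(frozen=True)
class ChainData:
    chain_id: str
    seq: str
    # per-residue (n_atoms, 3) heavy-atom coordinate arrays
    coords: tuple[np.ndarray, ...]
    to_query: np.ndarray | None = None  # per-residue query index, -1 unmapped


@dataclass(frozen=True)
class Structure:
    source_id: str
    chains: tuple[ChainData, ...]

    def chain(self, chain_id: str) -> ChainData:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


class StructureContentError(ValueError):
    """Raised when a coordinate file holds no usable protein chain."""


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def parse_structure(
    path: str | Path, format: str | None = None, model: int = 1, source_id: str | None = None
) -> Structure:
    """Read a PDB or mmCIF file into per-chain residues and heavy atoms.

    Hydrogens and waters are excluded; where alternate locations exist the
    highest-occupancy atom is kept; residues without heavy atoms are
    dropped.
    """
    path = Path(path)
    if format == "pdb":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    elif format in ("mmcif", "cif"):
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    elif format is None:
        st = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}")
    st.setup_entities()
    if model > len(st):
        raise StructureContentError(f"{path}: model {model} not present")
    mdl = st[model - 1]

    chains: list[ChainData] = []
    for chain in mdl:
        seq: list[str] = []
        coords: list[np.ndarray] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            best: dict[str, tuple[float, gemmi.Atom]] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev[0]:
                    best[atom.name] = (atom.occ, atom)
            if not best:
                continue
            xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for _, a in best.values()])
            seq.append(_one_letter(res.name))
            coords.append(xyz)
        if coords:
            chains.append(ChainData(chain.name, "".join(seq), tuple(coords)))
    if not chains:
        raise StructureContentError(f"{path}: no protein chain with heavy atoms")
    return Structure(source_id or path.stem, tuple(chains))


# Documented alignment constants for mapping structure chains onto the
# query: match +1, mismatch 0, gap open -5, extend -1, global mode.
_ALN_MATCH, _ALN_MISMATCH, _ALN_OPEN, _ALN_EXTEND = 1.0, 0.0, -5.0, -1.0


class ChainMappingError(ValueError):
    """Raised when a chain cannot be credibly aligned to the query."""


def map_to_query(structure: Structure, query_seq: str, min_identity: float = 0.15) -> Structure:
    """Globally align each chain sequence to the query and record the mapping.

    Chains aligning with identity below ``min_identity`` (over the chain
    length) are rejected: they are almost certainly not the protein the
    predictions describe.
    """
    if not query_seq:
        raise ValueError("query sequence must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _ALN_MATCH
    aligner.mismatch_score = _ALN_MISMATCH
    aligner.open_gap_score = _ALN_OPEN
    aligner.extend_gap_score = _ALN_EXTEND

    mapped_chains = []
    for chain in structure.chains:
        aln = aligner.align(chain.seq, query_seq)[0]
        to_query = np.full(len(chain.seq), -1, dtype=np.int64)
        n_ident = 0
        for (cs, ce), (qs, qe) in zip(*aln.aligned):
            for k in range(ce - cs):
                to_query[cs + k] = qs + k
                if chain.seq[cs + k] == query_seq[qs + k]:
                    n_ident += 1
        identity = n_ident / len(chain.seq)
        if identity < min_identity:
            warnings.warn(
                f"chain {chain.chain_id}: alignment identity {identity:.2f} below "
                f"{min_identity}; refusing to map (likely the wrong chain)",
                RuntimeWarning,
                stacklevel=2,
            )
            raise ChainMappingError(
                f"chain {chain.chain_id} aligns to the query with identity "
                f"{identity:.2f} < {min_identity}"
            )
        mapped_chains.append(dataclasses.replace(chain, to_query=to_query))
    return dataclasses.replace(structure, chains=tuple(mapped_chains))


@dataclass(frozen=True)
class ContactMap:
    """Experimental contacts in query coordinates for one conformation."""

    source_id: str
    intra: frozenset[Pair]
    inter: frozenset[Pair]
    L: int


def _chain_atom_table(chain: ChainData) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy atoms of query-mapped residues; returns (coords, query_idx)."""
    if chain.to_query is None:
        raise ValueError("structure must be mapped to the query first")
    coords, owner = [], []
    for r, xyz in enumerate(chain.coords):
        q = int(chain.to_query[r])
        if q < 0:
            continue
        coords.append(xyz)
        owner.append(np.full(len(xyz), q, dtype=np.int64))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=np.int64)
    return np.concatenate(coords), np.concatenate(owner)


def contact_map(
    structure: Structure,
    intra_cutoff: float = 8.0,
    inter_cutoff: float = 10.0,
    min_separation: int = 1,
) -> ContactMap:
    """Minimum heavy-atom distance contacts, intra at 8 A and inter at 10 A.

    Interchain contacts of an oligomer are reported in query coordinates
    like everything else (both chains map onto the same query), kept in a
    separate set.
    """
    intra: set[Pair] = set()
    inter: set[Pair] = set()
    tables = [_chain_atom_table(c) for c in structure.chains]
    L = 0
    for coords, owner in tables:
        if len(owner):
            L = max(L, int(owner.max()) + 1)
    for coords, owner in tables:
        if len(coords) == 0:
            continue
        tree = cKDTree(coords)
        for a, b in tree.query_pairs(intra_cutoff):
            qi, qj = int(owner[a]), int(owner[b])
            if qi == qj:
                continue
            lo, hi = min(qi, qj), max(qi, qj)
            if hi - lo >= min_separation:
                intra.add((lo, hi))
    for x in range(len(tables)):
        cx, ox = tables[x]
        if len(cx) == 0:
            continue
        tx = cKDTree(cx)
        for y in range(x + 1, len(tables)):
            cy, oy = tables[y]
            if len(cy) == 0:
                continue
            ty = cKDTree(cy)
            for a, neighbors in enumerate(tx.query_ball_tree(ty, inter_cutoff)):
                for b in neighbors:
                    qi, qj = int(ox[a]), int(oy[b])
                    if qi == qj:
                        continue
                    inter.add((min(qi, qj), max(qi, qj)))
    return ContactMap(structure.source_id, frozenset(intra), frozenset(inter), L)


@dataclass(frozen=True)
class DualFoldMap:
    """Contacts unique to each fold, common to both, and interchain per fold.

    The common set is the exact pair intersection of the two intrachain
    maps; the +/-2 tolerance applies only when predictions are compared
    against the map, not between the two experimental maps themselves.
    """

    source_ids: tuple[str, str]
    unique: Mapping[str, frozenset[Pair]]
    common: frozenset[Pair]
    interchain: Mapping[str, frozenset[Pair]]
    L: int
    dominant_id: str | None = None

    @property
    def dominant_unique(self) -> frozenset[Pair]:
        return self.unique[self._require_dominant()]

    @property
    def alternative_unique(self) -> frozenset[Pair]:
        return self.unique[self.alternative_id]

    @property
    def alternative_id(self) -> str:
        dom = self._require_dominant()
        return next(s for s in self.source_ids if s != dom)

    def _require_dominant(self) -> str:
        if self.dominant_id is None:
            raise ValueError("dominant fold not determined yet")
        return self.dominant_id

    def fold_reference(self, fold_id: str) -> frozenset[Pair]:
        """Unique contacts of a fold including its interchain contacts."""
        return self.unique[fold_id] | self.interchain[fold_id]

    def all_contacts(self) -> frozenset[Pair]:
        out: frozenset[Pair] = self.common
        for s in self.source_ids:
            out = out | self.unique[s] | self.interchain[s]
        return out

    def with_dominant(self, fold_id: str) -> "DualFoldMap":
        if fold_id not in self.source_ids:
            raise ValueError(f"{fold_id!r} is not one of {self.source_ids}")
        return dataclasses.replace(self, dominant_id=fold_id)


def build_dual_fold_map(map_a: ContactMap, map_b: ContactMap) -> DualFoldMap:
    """Partition two conformations' contacts into unique/common sets."""
    if map_a.source_id == map_b.source_id:
        raise ValueError("the two conformations need distinct source ids")
    common = map_a.intra & map_b.intra
    return DualFoldMap(
        source_ids=(map_a.source_id, map_b.source_id),
        unique={
            map_a.source_id: frozenset(map_a.intra - common),
            map_b.source_id: frozenset(map_b.intra - common),
        },
        common=frozenset(common),
        interchain={
            map_a.source_id: frozenset(map_a.inter),
            map_b.source_id: frozenset(map_b.inter),
        },
        L=max(map_a.L, map_b.L),
    )


def determine_dominant(
    dualmap: DualFoldMap, deepest_run_pairs: Iterable[Pair], tol: int = 2
) -> str:
    """The dominant fold overlaps more deep-alignment predictions.

    Overlap is counted over each fold's unique contacts (interchain
    included) within the +/-tol box.  Ties go to the first fold with a
    warning.
    """
    pts = np.asarray(sorted(set((int(a), int(b)) for a, b in deepest_run_pairs)))
    counts = []
    for fold in dualmap.source_ids:
        ref = dualmap.fold_reference(fold)
        counts.append(int(overlap_mask(pts, ref, tol).sum()) if len(pts) else 0)
    if counts[0] == counts[1]:
        warnings.warn(
            "both folds overlap the deep-alignment predictions equally; "
            f"labeling {dualmap.source_ids[0]!r} dominant by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return dualmap.source_ids[0]
    return dualmap.source_ids[int(np.argmax(counts))]


@dataclass(frozen=True)
class CategorizedPredictions:
    """Filtered predictions partitioned by what they match in the dual-fold map.

    Precedence when tolerance boxes overlap several sets is
    common > dominant > alternative > unobserved: a pair consistent with
    both folds carries no fold-discriminating information and must not
    inflate either unique count.
    """

    dominant: frozenset[Pair]
    alternative: frozenset[Pair]
    common: frozenset[Pair]
    unobserved: frozenset[Pair]
    dominant_fold_id: str

    @property
    def total(self) -> int:
        return (
            len(self.dominant) + len(self.alternative) + len(self.common) + len(self.unobserved)
        )

    def as_dict(self) -> dict[str, frozenset[Pair]]:
        return {
            "dominant": self.dominant,
            "alternative": self.alternative,
            "common": self.common,
            "unobserved": self.unobserved,
        }


def categorize_predictions(
    filtered: FilteredPredictions | Iterable[Pair],
    dualmap: DualFoldMap,
    tol: int = 2,
) -> CategorizedPredictions:
    """Assign each filtered pair to common/dominant/alternative/unobserved."""
    if isinstance(filtered, FilteredPredictions):
        pts = filtered.kept_points()
    else:
        pts = np.asarray(sorted(set((int(a), int(b)) for a, b in filtered))).reshape(-1, 2)
    dom = dualmap._require_dominant()
    alt = dualmap.alternative_id
    in_common = overlap_mask(pts, dualmap.common, tol)
    in_dom = overlap_mask(pts, dualmap.fold_reference(dom), tol)
    in_alt = overlap_mask(pts, dualmap.fold_reference(alt), tol)

    pairs = [(int(a), int(b)) for a, b in pts]
    common_set, dom_set, alt_set, unobs = set(), set(), set(), set()
    for p, c, d, a in zip(pairs, in_common, in_dom, in_alt):
        if c:
            common_set.add(p)
        elif d:
            dom_set.add(p)
        elif a:
            alt_set.add(p)
        else:
            unobs.add(p)
    return CategorizedPredictions(
        dominant=frozenset(dom_set),
        alternative=frozenset(alt_set),
        common=frozenset(common_set),
        unobserved=frozenset(unobs),
        dominant_fold_id=dom,
    )


def write_categorized_tsv(cat: CategorizedPredictions, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tcategory\tfold\n")
        for name, pairs in cat.as_dict().items():
            fold = cat.dominant_fold_id if name == "dominant" else ""
            for i, j in sorted(pairs):
                fh.write(f"{i}\t{j}\t{name}\t{fold}\n")


def plot_dual_fold_map(
    dualmap: DualFoldMap,
    predictions: Iterable[Pair] | None = None,
    path: str | Path | None = None,
):
    """Asymmetric dual-fold contact map: fold A upper triangle, fold B lower.

    Common contacts appear on both sides of the diagonal; predictions (if
    given) are drawn in the upper triangle.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    id_a, id_b = dualmap.source_ids
    for (i, j) in dualmap.unique[id_a]:
        ax.plot(j, i, "o", color="0.8", ms=3)
    for (i, j) in dualmap.unique[id_b]:
        ax.plot(i, j, "o", color="0.1", ms=3)
    for (i, j) in dualmap.common:
        ax.plot(j, i, "o", color="0.5", ms=3)
        ax.plot(i, j, "o", color="0.5", ms=3)
    for fold, marker_side in ((id_a, True), (id_b, False)):
        for (i, j) in dualmap.interchain[fold]:
            x, y = (j, i) if marker_side else (i, j)
            ax.plot(x, y, "o", color="0.8" if marker_side else "0.1", ms=1.5)
    if predictions is not None:
        pts = np.asarray(list(predictions)).reshape(-1, 2)
        if len(pts):
            ax.plot(pts[:, 1], pts[:, 0], "o", color="teal", ms=2, alpha=0.7)
    ax.plot([0, dualmap.L], [0, dualmap.L], "-", color="0.6", lw=0.5)
    ax.set_xlim(0, dualmap.L)
    ax.set_ylim(dualmap.L, 0)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(f"{id_a} (upper) vs {id_b} (lower)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
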