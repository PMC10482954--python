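"""Superposition of coevolution runs and density-based denoising.

All runs from the nested alignments (superfamily plus every pruned
subfamily) are superimposed on a single contact map: each residue pair's
z-scores are averaged over the runs that scored it, and the top
``15L/2`` pairs by mean z-score are retained.  The retained pairs are
then clustered in the 2-D contact-map plane; the sparsest points are
noise and are discarded.  The clustering radius ``eps`` is chosen from a
receiver-operating-characteristic table against experimental (or
predicted) reference contacts, subject to the constraint that filtering
may not return fewer contacts than the plain deep-alignment run.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from .coevolution import PredictionRun, truncate_run, zscore_run
from .msa import Msa, NestedMsas, depth_sufficient, filter_gaps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Superposition:
    """Pairs pooled across runs with averaged z-scores.

    ``retained`` indexes the top-``cap`` pairs by ``mean_z`` (ties broken
    by higher support, then lower ``i``, then lower ``j``).
    """

    i: np.ndarray
    j: np.ndarray
    mean_z: np.ndarray
    support: np.ndarray
    shallowest_fraction: np.ndarray
    L: int
    cap: int
    retained: np.ndarray  # index array into the pair arrays

    @property
    def retained_points(self) -> np.ndarray:
        """(n, 2) array of retained (i, j) pairs, in retention order."""
        return np.column_stack([self.i[self.retained], self.j[self.retained]])

    def retained_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.retained_points}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "i": self.i,
                "j": self.j,
                "mean_z": self.mean_z,
                "support": self.support,
                "shallowest_fraction": self.shallowest_fraction,
            }
        )
        df["retained"] = False
        df.loc[self.retained, "retained"] = True
        return df


@dataclass(frozen=True)
class FilteredPredictions:
    """DBSCAN output: dense clusters of predicted pairs plus discarded noise."""

    clusters: tuple[np.ndarray, ...]
    noise: np.ndarray
    eps: float
    min_samples: int

    def kept_points(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(self.clusters, axis=0)

    def kept_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.kept_points()}

    @property
    def n_kept(self) -> int:
        return sum(len(c) for c in self.clusters)


def retention_cap(L: int) -> int:
    """Number of superposed pairs retained: floor(15 L / 2)."""
    return (15 * L) // 2


def superpose_runs(
    runs: Sequence[PredictionRun], L: int, cap: int | None = None
) -> Superposition:
    """Average z-scores per pair over the runs that scored it.

    A pair absent from a run contributes nothing for that run (absence is
    not a zero score: subfamily-only couplings would otherwise be
    systematically punished by the deep runs that cannot see them).
    """
    if not runs:
        raise ValueError("superpose_runs requires at least one run")
    if cap is None:
        cap = retention_cap(L)
    frames = []
    for run in runs:
        if run.z is None:
            run = zscore_run(run)
        frames.append(
            pd.DataFrame(
                {"i": run.i, "j": run.j, "z": run.z, "frac": run.depth_fraction}
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    agg = (
        pooled.groupby(["i", "j"], sort=True)
        .agg(mean_z=("z", "mean"), support=("z", "size"), shallowest=("frac", "min"))
        .reset_index()
    )
    order = np.lexsort(
        (agg["j"].to_numpy(), agg["i"].to_numpy(), -agg["support"].to_numpy(), -agg["mean_z"].to_numpy())
    )
    retained = np.sort(order[: min(cap, len(order))])
    return Superposition(
        i=agg["i"].to_numpy(),
        j=agg["j"].to_numpy(),
        mean_z=agg["mean_z"].to_numpy(),
        support=agg["support"].to_numpy(np.int64),
        shallowest_fraction=agg["shallowest"].to_numpy(),
        L=L,
        cap=cap,
        retained=retained,
    )


def dbscan_filter(
    pairs: np.ndarray | Iterable[tuple[int, int]],
    eps: float,
    min_samples: int = 3,
) -> FilteredPredictions:
    """Density-based clustering of contact-map points; sparse points are noise.

    Points are (i, j) coordinates on the half-plane i < j under Euclidean
    distance.  A core point has at least ``min_samples`` points (itself
    included) within ``eps``; clusters are the connected components of
    core points, and each non-core point within ``eps`` of a core point
    joins the cluster of its first core neighbor in input order (a
    deterministic border-assignment rule).  Remaining points are noise.
    """
    pts = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs)
    pts = pts.reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("dbscan_filter requires at least one point")
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = len(pts)
    nn = NearestNeighbors(radius=eps).fit(pts)
    neigh = nn.radius_neighbors(pts, return_distance=False)
    is_core = np.array([len(a) >= min_samples for a in neigh])

    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in np.flatnonzero(is_core):
        for b in neigh[a]:
            if is_core[b]:
                ra, rb = find(a), find(int(b))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    labels = np.full(n, -1, dtype=np.int64)
    for a in np.flatnonzero(is_core):
        labels[a] = find(a)
    for a in np.flatnonzero(~is_core):
        core_neigh = [int(b) for b in sorted(neigh[a]) if is_core[b]]
        if core_neigh:
            labels[a] = find(core_neigh[0])

    clusters = []
    for root in sorted(set(labels[labels >= 0].tolist())):
        clusters.append(pts[labels == root])
    return FilteredPredictions(
        clusters=tuple(clusters),
        noise=pts[labels < 0],
        eps=float(eps),
        min_samples=min_samples,
    )


def overlap_mask(
    points: np.ndarray, reference: Iterable[tuple[int, int]], tol: int = 2
) -> np.ndarray:
    """Boolean mask: point within a +/-tol Chebyshev box of any reference pair."""
    points = np.asarray(points).reshape(-1, 2)
    ref = np.asarray(sorted(set((int(a), int(b)) for a, b in reference)))
    if len(ref) == 0 or len(points) == 0:
        return np.zeros(len(points), dtype=bool)
    tree = cKDTree(ref)
    dist, _ = tree.query(points, k=1, p=np.inf)
    return dist <= tol


def eps_roc_table(
    pairs: np.ndarray,
    reference_contacts: Iterable[tuple[int, int]],
    eps_grid: Sequence[float],
    tol: int = 2,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-eps true/false positive counts of the DBSCAN-filtered pairs."""
    ref = list(reference_contacts)
    records = []
    for eps in eps_grid:
        filt = dbscan_filter(pairs, eps, min_samples)
        kept = filt.kept_points()
        tp = int(overlap_mask(kept, ref, tol).sum()) if len(kept) else 0
        records.append(
            {"eps": float(eps), "tp": tp, "fp": len(kept) - tp, "total": len(kept)}
        )
    return pd.DataFrame.from_records(records)


def optimize_eps(
    pairs: np.ndarray,
    reference_contacts: Iterable[tuple[int, int]],
    eps_grid: Sequence[float] = tuple(range(1, 16)),
    tol: int = 2,
    baseline_count: int = 0,
    baseline_tp: int = 0,
    min_samples: int = 3,
) -> float:
    """Choose the DBSCAN radius from the ROC first-derivative rule.

    Walking the eps grid upward, the marginal slope dTP/dFP from the
    previous grid value measures whether growing the radius admits mostly
    true positives (slope > 1) or mostly false positives (slope < 1).
    The chosen eps is the largest one whose incoming slope exceeds 1
    while the next step's slope falls below 1.  Filtering may not be so
    stringent that it returns fewer contacts than the plain
    deep-alignment run: both the total (``baseline_count``) and the
    correct contacts (``baseline_tp``, within the +/-tol box of the
    reference) of that run are protected; a violating eps is relaxed to
    the smallest grid value meeting both.
    """
    eps_grid = list(eps_grid)
    if not eps_grid:
        raise ValueError("eps grid must not be empty")
    if any(b <= a for a, b in zip(eps_grid, eps_grid[1:])):
        raise ValueError("eps grid must be strictly increasing")
    table = eps_roc_table(pairs, reference_contacts, eps_grid, tol, min_samples)
    logger.debug("eps ROC table:\n%s", table.to_string(index=False))
    tp = table["tp"].to_numpy()
    fp = table["fp"].to_numpy()
    total = table["total"].to_numpy()

    def slope(k: int) -> float:
        dtp, dfp = tp[k] - tp[k - 1], fp[k] - fp[k - 1]
        if dfp <= 0:
            # no extra false positives: an infinite slope if true positives
            # were gained, a worthless step (slope 0) if nothing was gained
            return math.inf if dtp > 0 else 0.0
        return dtp / dfp

    ok = (total >= baseline_count) & (tp >= baseline_tp)
    chosen = None
    for k in range(len(eps_grid) - 2, 0, -1):
        if slope(k) > 1 and slope(k + 1) < 1:
            chosen = k
            break
    if chosen is not None and ok[chosen]:
        return float(eps_grid[chosen])
    meets = np.flatnonzero(ok)
    if len(meets):
        return float(eps_grid[int(meets[0])])
    warnings.warn(
        "no eps on the grid preserves the deep-alignment baseline; "
        "falling back to the largest grid value",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(eps_grid[-1])


@dataclass(frozen=True)
class AceResult:
    """Full enhancement output plus the deep-alignment-only baseline."""

    superposition: Superposition
    filtered: FilteredPredictions
    eps: float
    superfamily_superposition: Superposition
    superfamily_filtered: FilteredPredictions
    runs: tuple[dict, ...]


def run_ace(
    nested_msas: NestedMsas,
    scorers: Sequence[Callable[[Msa], PredictionRun]],
    reference_contacts: Iterable[tuple[int, int]],
    eps_grid: Sequence[float] = tuple(range(1, 16)),
    tol: int = 2,
    min_samples: int = 3,
    seq_gap_max: float = 0.25,
    col_gap_max: float = 0.75,
) -> AceResult:
    """Score every nested alignment, superpose, and denoise.

    Each run keeps its top-3L/2 pairs (the usual per-run retention), the
    superposition keeps the top-15L/2 by mean z-score, and the retained
    pairs are density-filtered at the ROC-chosen eps.
    ``reference_contacts`` are the experimental (or predicted-structure)
    contacts used only to pick the clustering radius; categorization
    happens downstream.  The superfamily-only baseline is the 3L/2-pair
    superposition of the deep-alignment runs, filtered with its own
    ROC-chosen radius.
    """
    super_filtered_msa = filter_gaps(nested_msas.superfamily, seq_gap_max, col_gap_max)
    L = super_filtered_msa.query_length
    if not depth_sufficient(super_filtered_msa, L):
        raise InsufficientDepthError(
            f"superfamily alignment depth {super_filtered_msa.depth} is below "
            f"5*L = {5 * L}; couplings would be too noisy to interpret"
        )
    super_depth = super_filtered_msa.depth

    all_runs: list[PredictionRun] = []
    superfamily_runs: list[PredictionRun] = []
    run_meta: list[dict] = []
    for threshold, msa in nested_msas.all_msas():
        fmsa = (
            super_filtered_msa
            if threshold == 0
            else filter_gaps(msa, seq_gap_max, col_gap_max)
        )
        if fmsa.depth < 2:
            continue
        frac = min(1.0, fmsa.depth / super_depth)
        for scorer in scorers:
            run = truncate_run(zscore_run(scorer(fmsa)), (3 * L) // 2)
            run = PredictionRun(
                method_tag=run.method_tag,
                msa_depth=run.msa_depth,
                i=run.i,
                j=run.j,
                raw=run.raw,
                z=run.z,
                depth_fraction=frac,
            )
            all_runs.append(run)
            if threshold == 0:
                superfamily_runs.append(run)
            run_meta.append(
                {
                    "qid_threshold": threshold,
                    "method_tag": run.method_tag,
                    "depth": fmsa.depth,
                    "depth_fraction": frac,
                }
            )

    superposition = superpose_runs(all_runs, L)
    superfamily_sup = superpose_runs(superfamily_runs, L, cap=(3 * L) // 2)
    baseline_count = len(superfamily_sup.retained)

    reference = list(reference_contacts)
    baseline_tp = int(
        overlap_mask(superfamily_sup.retained_points, reference, tol).sum()
    )
    eps = optimize_eps(
        superposition.retained_points,
        reference,
        eps_grid,
        tol=tol,
        baseline_count=baseline_count,
        baseline_tp=baseline_tp,
        min_samples=min_samples,
    )
    filtered = dbscan_filter(superposition.retained_points, eps, min_samples)

    eps_base = optimize_eps(
        superfamily_sup.retained_points,
        reference,
        eps_grid,
        tol=tol,
        baseline_count=0,
        min_samples=min_samples,
    )
    superfamily_filtered = dbscan_filter(
        superfamily_sup.retained_points, eps_base, min_samples
    )
    return AceResult(
        superposition=superposition,
        filtered=filtered,
        eps=eps,
        superfamily_superposition=superfamily_sup,
        superfamily_filtered=superfamily_filtered,
        runs=tuple(run_meta),
    )


class InsufficientDepthError(ValueError):
    """Superfamily alignment too shallow (< 5 x query length)."""
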