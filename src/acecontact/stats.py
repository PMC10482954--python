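"""Significance and enhancement statistics.

The central test asks: given how many correct and incorrect contacts the
deep superfamily alignment already produced, how surprising is the batch
of additional correct contacts contributed by the subfamily alignments?
The null model is drawing the subfamily batch at random from the
remaining contact space, which gives a one-tailed hypergeometric tail
probability evaluated in log space.

A depth-binned profile locates where enhancement comes from: correct
contacts are accumulated from deep to shallow alignments into bins of
the depth fraction (shallowest depth / superfamily depth), and each
family's cumulative counts are z-scored across bins so families with
very different raw contact counts can be pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

Pair = tuple[int, int]

#: Lower edges of the 20 depth-fraction bins.
DEPTH_BINS = tuple(np.round(np.arange(20) * 0.05, 2))


@dataclass(frozen=True)
class HypergeomCounts:
    """Count table for the subfamily-enrichment test.

    ``n_exp`` — unique experimental contacts pooled from both
    conformations; ``n_pred_super`` / ``n_noise_super`` — unique correct /
    incorrect predictions from the superfamily alignment alone;
    ``n_pred_sub`` / ``n_noise_sub`` — unique correct / incorrect
    predictions contributed by the subfamily alignments beyond the
    superfamily's; ``L`` — maximum experimental sequence length, so the
    noise space is ``L**2 - n_exp``.  The ``*_total`` denominators default
    to ``n_exp`` and ``n_noise`` but may be overridden.
    """

    n_exp: int
    n_pred_super: int
    n_pred_sub: int
    n_noise_super: int
    n_noise_sub: int
    L: int
    n_exp_total: int | None = None
    n_noise_total: int | None = None

    @property
    def n_noise(self) -> int:
        return self.L**2 - self.n_exp

    @property
    def exp_total(self) -> int:
        return self.n_exp if self.n_exp_total is None else self.n_exp_total

    @property
    def noise_total(self) -> int:
        return self.n_noise if self.n_noise_total is None else self.n_noise_total

    def validate(self) -> None:
        fields = {
            "n_exp": self.n_exp,
            "n_pred_super": self.n_pred_super,
            "n_pred_sub": self.n_pred_sub,
            "n_noise_super": self.n_noise_super,
            "n_noise_sub": self.n_noise_sub,
            "L": self.L,
        }
        for name, v in fields.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_pred_super > self.n_exp:
            raise ValueError("n_pred_super cannot exceed n_exp")
        if self.n_noise < 0:
            raise ValueError("L**2 must be at least n_exp")
        if self.n_noise_super > self.n_noise:
            raise ValueError("n_noise_super cannot exceed the noise space")


def _log_comb(n: float, k: float) -> float:
    if k < 0 or k > n or n < 0:
        return -math.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_pvalue(counts: HypergeomCounts) -> float:
    """One-tailed hypergeometric tail probability of the subfamily gains.

    Evaluates

        sum_{i=0}^{Nn_sub}  C(Ne - Np_sup, Np_sub + i) * C(Nn - Nn_sup, Nn_sub - i)
                            / C((Ne_tot - Np_sup) + (Nn_tot - Nn_sup), Np_sub + Nn_sub)

    in log space via log-gamma; terms with impossible binomial arguments
    contribute zero.  Returns a probability in (0, 1].
    """
    counts.validate()
    top_exp = counts.n_exp - counts.n_pred_super
    top_noise = counts.n_noise - counts.n_noise_super
    draw = counts.n_pred_sub + counts.n_noise_sub
    log_denom = _log_comb(
        (counts.exp_total - counts.n_pred_super) + (counts.noise_total - counts.n_noise_super),
        draw,
    )
    if not math.isfinite(log_denom):
        raise ValueError("denominator binomial coefficient is undefined for these counts")
    log_terms = []
    for i in range(counts.n_noise_sub + 1):
        t = _log_comb(top_exp, counts.n_pred_sub + i) + _log_comb(
            top_noise, counts.n_noise_sub - i
        )
        if math.isfinite(t):
            log_terms.append(t)
    if not log_terms:
        return 0.0 if draw > 0 else 1.0
    m = max(log_terms)
    log_p = m + math.log(sum(math.exp(t - m) for t in log_terms)) - log_denom
    return min(1.0, math.exp(log_p))


def epps_singleton(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sample Epps-Singleton test (empirical characteristic functions).

    Evaluation points t = (0.4, 0.8) scaled by the pooled semi-interquartile
    range, with the standard small-sample correction; returns
    ``(statistic, p)`` from the chi-squared reference distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 observations")
    pooled_iqr = sps.iqr(np.concatenate([a, b]))
    if pooled_iqr == 0:
        raise ValueError("degenerate samples: pooled interquartile range is zero")
    res = sps.epps_singleton_2samp(a, b, t=(0.4, 0.8))
    return float(res.statistic), float(res.pvalue)


def nondominant_fraction(categorized) -> float:
    """Fraction of predictions not matching the dominant fold or common set.

    For single-fold proteins the alternative set is empty by construction,
    so this reduces to the unobserved (noise) fraction.
    """
    cats = _category_sets(categorized)
    total = sum(len(v) for v in cats.values())
    if total == 0:
        raise ValueError("nondominant_fraction undefined for zero predictions")
    return (len(cats["alternative"]) + len(cats["unobserved"])) / total


def amplification(count_super_only: int, count_ace: int) -> float:
    """Percent increase of ACE over the superfamily-only count."""
    if count_super_only < 1:
        raise ValueError("amplification undefined for a zero baseline")
    return 100.0 * (count_ace - count_super_only) / count_super_only


def depth_bin(msa_depth: int, superfamily_depth: int) -> float:
    """Lower edge of the 0.05-wide depth-fraction bin; capped at 0.95.

    E.g. 19,050 of 20,000 sequences -> 0.95; 999 of 20,000 -> 0.00; a full
    fraction of 1.0 also maps to the 0.95 bin.
    """
    if not 0 < msa_depth <= superfamily_depth:
        raise ValueError("need 0 < msa_depth <= superfamily_depth")
    idx = min(int(20 * msa_depth / superfamily_depth), 19)
    return idx / 20.0


def _category_sets(categorized) -> dict[str, frozenset[Pair]]:
    if isinstance(categorized, Mapping):
        return {k: frozenset(categorized.get(k, ())) for k in
                ("dominant", "alternative", "common", "unobserved")}
    return categorized.as_dict()


@dataclass(frozen=True)
class EnhancementProfile:
    """Per-family cumulative contact counts and z-scores by depth bin."""

    bins: tuple[float, ...]
    cumulative_counts: Mapping[str, np.ndarray]
    z_scores: Mapping[str, np.ndarray]


def enhancement_profile(
    per_msa_categorized: Sequence,
    depths: Sequence[int],
    superfamily_depth: int,
    categories: Sequence[str] = ("dominant", "alternative", "common"),
) -> EnhancementProfile:
    """Cumulative correct contacts by depth-fraction bin, z-scored over bins.

    The cumulative count at bin ``b`` is the union of each category's
    contacts over all alignments whose depth fraction is at least ``b``;
    bin 0.0 therefore includes every alignment and counts never decrease
    toward shallower bins.
    """
    if len(per_msa_categorized) != len(depths):
        raise ValueError("per_msa_categorized and depths must be parallel")
    assigned = {depth_bin(d, superfamily_depth) for d in depths}
    if len(assigned) < 2:
        raise ValueError(
            "enhancement profile needs alignments in at least 2 distinct depth bins"
        )
    fracs = np.array([d / superfamily_depth for d in depths])
    counts: dict[str, np.ndarray] = {}
    zs: dict[str, np.ndarray] = {}
    for cat in categories:
        per_bin = []
        for b in DEPTH_BINS:
            pool: set[Pair] = set()
            for cats, f in zip(per_msa_categorized, fracs):
                if f >= b:
                    pool |= set(_category_sets(cats)[cat])
            per_bin.append(len(pool))
        arr = np.array(per_bin, dtype=float)
        std = arr.std()
        zs[cat] = np.zeros_like(arr) if std == 0 else (arr - arr.mean()) / std
        counts[cat] = arr
    return EnhancementProfile(DEPTH_BINS, counts, zs)


def profile_medians(
    profiles: Iterable[EnhancementProfile], category: str = "alternative"
) -> np.ndarray:
    """Per-bin median z-score across families."""
    stack = np.stack([np.asarray(p.z_scores[category]) for p in profiles])
    return np.median(stack, axis=0)
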