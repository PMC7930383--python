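"""Within-sample (alpha) diversity calculators and group comparisons.

Calculators follow the mothur conventions: Shannon entropy in nats, Simpson
as the unbiased dominance estimator sum n_i(n_i-1)/(N(N-1)), Good's coverage
1 - singletons/N. No rarefaction is applied; calculators run on raw counts
(sequencing depth is a simulation control instead).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._perm import ENUMERATION_LIMIT, all_label_assignments, n_assignments, two_group_masks
from .results import GroupComparisonResult
from .tables import AbundanceTable, SampleMetadata

METRICS = ("observed_otus", "shannon", "simpson", "goods_coverage")


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 0).any() or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def observed_richness(counts) -> int:
    """Number of taxa with count > 0 (the observed-OTUs metric)."""
    return int((_as_counts(counts) > 0).sum())


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Unbiased Simpson dominance D = sum n_i(n_i-1) / (N(N-1)).

    1 - D is the associated diversity. Requires total N >= 2.
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if total < 2:
        raise ValueError("Simpson estimator requires total count >= 2")
    return float((arr * (arr - 1)).sum() / (total * (total - 1)))


def goods_coverage(counts) -> float:
    """Good's coverage C = 1 - F1/N, F1 = number of singleton taxa."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    return float(1 - (arr == 1).sum() / total)


_CALCULATORS = {
    "observed_otus": observed_richness,
    "shannon": shannon,
    "simpson": simpson,
    "goods_coverage": goods_coverage,
}


def alpha_diversity(table: AbundanceTable,
                    metrics: Iterable[str] = METRICS) -> pd.DataFrame:
    """Per-sample diversity table (samples x metrics)."""
    metrics = list(metrics)
    unknown = [m for m in metrics if m not in _CALCULATORS]
    if unknown:
        raise ValueError(f"unknown metrics: {unknown}")
    out = {m: [ _CALCULATORS[m](row) for row in table.data.to_numpy()]
           for m in metrics}
    return pd.DataFrame(out, index=table.sample_ids)


def _kruskal_h(rank_sums: np.ndarray, sizes: np.ndarray, n: int,
               tie_term: float) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * (rank_sums ** 2 / sizes).sum(axis=-1) - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else h


def compare_groups(values: pd.Series, metadata: SampleMetadata,
                   n_perm: int = 999, seed: int = 0,
                   alternative: str = "two-sided") -> GroupComparisonResult:
    """Rank-based group comparison of a per-sample diversity vector.

    Two groups: Wilcoxon rank-sum (midranks); three or more: Kruskal-Wallis
    H with tie correction. The p-value is by full enumeration of label
    assignments when their number is at most 20,000, otherwise by ``n_perm``
    seeded label permutations with the plus-one estimator. ``alternative``
    applies to the two-group case ("two-sided", "greater", "less", with
    "greater" meaning the first group's ranks are high).
    """
    groups = metadata.groups(list(values.index))
    labels = pd.unique(groups)
    sizes = np.array([(groups == g).sum() for g in labels])
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = [g for g, s in zip(labels, sizes) if s < 2]
        raise ValueError(f"groups with < 2 samples: {small}")
    x = values.to_numpy(dtype=float)
    n = len(x)
    ranks = rankdata(x)  # midranks
    label_list = list(labels)
    codes = np.array([label_list.index(g) for g in groups])

    total = n_assignments(sizes)
    rng = np.random.default_rng(seed)

    if len(labels) == 2:
        n1 = sizes[0]
        w_obs = ranks[codes == 0].sum()
        mu = n1 * (n + 1) / 2.0

        def pval(w_star: np.ndarray, denom: int, exact: bool) -> float:
            if alternative == "two-sided":
                hits = (np.abs(w_star - mu) >= np.abs(w_obs - mu) - 1e-12).sum()
            elif alternative == "greater":
                hits = (w_star >= w_obs - 1e-12).sum()
            elif alternative == "less":
                hits = (w_star <= w_obs + 1e-12).sum()
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            return hits / denom if exact else (hits + 1) / (denom + 1)

        if total <= ENUMERATION_LIMIT:
            masks = two_group_masks(n, int(n1))
            w_star = masks @ ranks
            p = pval(w_star, total, exact=True)
            return GroupComparisonResult("wilcoxon_W", float(w_obs), p, total,
                                         exact=True, seed=seed)
        w_star = np.array([rng.permutation(ranks)[:n1].sum()
                           for _ in range(n_perm)])
        p = pval(w_star, n_perm, exact=False)
        return GroupComparisonResult("wilcoxon_W", float(w_obs), p, n_perm,
                                     exact=False, seed=seed)

    # Kruskal-Wallis, one-sided on H
    _, counts = np.unique(x, return_counts=True)
    tie_term = 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))

    def h_of(code_matrix: np.ndarray) -> np.ndarray:
        rs = np.stack([(code_matrix == g) @ ranks for g in range(len(labels))],
                      axis=-1)
        return _kruskal_h(rs, sizes, n, tie_term)

    h_obs = float(h_of(codes[None, :])[0])
    if total <= ENUMERATION_LIMIT:
        mats = all_label_assignments(codes)
        h_star = h_of(mats)
        p = float((h_star >= h_obs - 1e-12).sum() / total)
        return GroupComparisonResult("kruskal_H", h_obs, p, total,
                                     exact=True, seed=seed)
    h_star = np.empty(n_perm)
    for b in range(n_perm):
        h_star[b] = h_of(rng.permutation(codes)[None, :])[0]
    p = float(((h_star >= h_obs - 1e-12).sum() + 1) / (n_perm + 1))
    return GroupComparisonResult("kruskal_H", h_obs, p, n_perm,
                                 exact=False, seed=seed)
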