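"""Between-sample dissimilarities, ordination and matrix permutation tests.

Implements Bray-Curtis, unweighted/weighted UniFrac (the weighted variant
normalized by default), classical PCoA (Gower double-centering, negative
eigenvalues reported and their axes dropped), rank-based ANOSIM and the
Mantel test. Permutation p-values use seeded generators with the plus-one
estimator; ANOSIM switches to full enumeration for small designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._perm import ENUMERATION_LIMIT, all_label_assignments, n_assignments
from .results import GroupComparisonResult
from .tables import AbundanceTable, PhyloTree, RelativeAbundanceTable, SampleMetadata


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative dissimilarity")
        self.values = (v + v.T) / 2
        np.fill_diagonal(self.values, 0.0)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray           # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    has_negative_eigenvalues: bool


def bray_curtis(table: RelativeAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|a_i-b_i| / sum(a_i+b_i)."""
    x = table.data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(tot > 0, diff / np.where(tot == 0, 1, tot), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


def _branch_incidence(tree: PhyloTree, taxa: list):
    """Branches (non-root nodes) x taxa incidence and branch lengths."""
    col = {t: j for j, t in enumerate(taxa)}
    rows, lengths = [], []
    for node in tree.tree.postorder(include_self=False):
        row = np.zeros(len(taxa), dtype=bool)
        for tip in node.tips(include_self=True):
            if tip.name in col:
                row[col[tip.name]] = True
        rows.append(row)
        lengths.append(node.length or 0.0)
    return np.array(rows), np.array(lengths)


def unifrac(table: AbundanceTable, tree: PhyloTree, weighted: bool = False,
            normalized: bool = True) -> DistanceMatrix:
    """Phylogenetic UniFrac distance between all sample pairs.

    Unweighted: fraction of observed branch length unique to one of the two
    samples. Weighted: sum over branches of length x |A_b - B_b| where A_b
    is the fraction of the sample's reads descending from the branch; when
    ``normalized``, divided by sum length x (A_b + B_b).
    """
    counts = table.data.to_numpy(dtype=float)
    taxa = table.taxon_ids
    present = counts.sum(axis=0) > 0
    missing = [t for t, p in zip(taxa, present) if p and t not in set(tree.leaf_names)]
    if missing:
        raise ValueError(f"taxa with nonzero counts absent from tree: {missing}")
    incidence, lengths = _branch_incidence(tree, taxa)

    n = counts.shape[0]
    d = np.zeros((n, n))
    if weighted:
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero-total sample in weighted UniFrac")
        rel = counts / totals[:, None]
        branch_frac = rel @ incidence.T  # samples x branches
        for i in range(n):
            for j in range(i + 1, n):
                num = (lengths * np.abs(branch_frac[i] - branch_frac[j])).sum()
                if normalized:
                    den = (lengths * (branch_frac[i] + branch_frac[j])).sum()
                    d[i, j] = d[j, i] = num / den if den > 0 else 0.0
                else:
                    d[i, j] = d[j, i] = num
    else:
        presence = (counts > 0) @ incidence.T > 0  # samples x branches
        for i in range(n):
            for j in range(i + 1, n):
                either = presence[i] | presence[j]
                unique = presence[i] ^ presence[j]
                den = lengths[either].sum()
                d[i, j] = d[j, i] = lengths[unique].sum() / den if den > 0 else 0.0
    return DistanceMatrix(table.sample_ids, d)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, and keeps axes with positive
    eigenvalues; negative eigenvalues are reported but contribute no axes
    and are excluded from the explained-proportion numerator.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval).max(initial=0), 0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{k + 1}" for k in range(int(pos.sum()))]
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.ids, columns=axes),
        eigenvalues=eigval,
        proportion_explained=prop,
        has_negative_eigenvalues=bool((eigval < -1e-12 * max(abs(eigval).max(initial=0), 1)).any()),
    )


def anosim(dm: DistanceMatrix, metadata: SampleMetadata, n_perm: int = 999,
           seed: int = 0) -> GroupComparisonResult:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with midranks. One-sided p (large R) by full enumeration of label
    assignments when at most 20,000 exist, else by seeded permutation with
    the plus-one estimator.
    """
    groups = metadata.groups(dm.ids).to_numpy()
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("ANOSIM requires at least 2 groups")
    sizes = np.array([(groups == g).sum() for g in labels])
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 samples")
    codes = np.array([labels.index(g) for g in groups])
    n = len(codes)
    iu0, iu1 = np.triu_indices(n, k=1)
    ranks = rankdata(dm.condensed())
    denom = n * (n - 1) / 4.0

    def r_stat(code_matrix: np.ndarray) -> np.ndarray:
        within = code_matrix[:, iu0] == code_matrix[:, iu1]
        n_within = within.sum(axis=1)
        n_between = within.shape[1] - n_within
        sum_within = (ranks[None, :] * within).sum(axis=1)
        mean_within = sum_within / n_within
        mean_between = (ranks.sum() - sum_within) / n_between
        return (mean_between - mean_within) / denom

    r_obs = float(r_stat(codes[None, :])[0])
    total = n_assignments(sizes)
    if total <= ENUMERATION_LIMIT:
        mats = all_label_assignments(codes)
        r_star = r_stat(mats)
        p = float((r_star >= r_obs - 1e-12).sum() / total)
        return GroupComparisonResult("anosim_R", r_obs, p, total, exact=True,
                                     seed=seed)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(codes) for _ in range(n_perm)])
    r_star = r_stat(perms)
    p = float(((r_star >= r_obs - 1e-12).sum() + 1) / (n_perm + 1))
    return GroupComparisonResult("anosim_R", r_obs, p, n_perm, exact=False,
                                 seed=seed)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           method: str = "pearson", alternative: str = "two-sided",
           seed: int = 0) -> GroupComparisonResult:
    """Mantel correlation between two distance matrices.

    Correlates strictly-upper-triangle entries (midranked for Spearman) and
    permutes the sample order of ``d2`` jointly over rows and columns.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share sample ids and order")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    n = len(d1.ids)
    iu0, iu1 = np.triu_indices(n, k=1)
    x = d1.condensed()
    if method == "spearman":
        x = rankdata(x)
    y_full = d2.values.copy()

    def corr(y: np.ndarray) -> float:
        yy = rankdata(y) if method == "spearman" else y
        if x.std() == 0 or yy.std() == 0:
            return np.nan
        return float(np.corrcoef(x, yy)[0, 1])

    r_obs = corr(y_full[iu0, iu1])
    if np.isnan(r_obs):
        return GroupComparisonResult("mantel_r", 0.0, 1.0, 0, exact=False,
                                     seed=seed, degenerate=True)
    rng = np.random.default_rng(seed)
    r_star = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)
        r_star[b] = corr(y_full[np.ix_(idx, idx)][iu0, iu1])
    if alternative == "two-sided":
        hits = (np.abs(r_star) >= abs(r_obs) - 1e-12).sum()
    elif alternative == "greater":
        hits = (r_star >= r_obs - 1e-12).sum()
    elif alternative == "less":
        hits = (r_star <= r_obs + 1e-12).sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float((hits + 1) / (n_perm + 1))
    return GroupComparisonResult("mantel_r", r_obs, p, n_perm, exact=False,
                                 seed=seed)


def covariate_mantel(dm: DistanceMatrix, x: pd.Series, n_perm: int = 999,
                     method: str = "pearson", seed: int = 0,
                     alternative: str = "two-sided") -> GroupComparisonResult:
    """Mantel test of a per-sample scalar against a distance matrix.

    Builds the covariate distance |x_i - x_j| and delegates to
    :func:`mantel` (e.g. dysbiosis-score or single-taxon abundance versus
    UniFrac structure). A constant covariate is degenerate: r = 0, p = 1.
    """
    missing = [s for s in dm.ids if s not in x.index]
    if missing:
        raise ValueError(f"covariate missing for samples: {missing}")
    v = x.loc[dm.ids].to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError("covariate contains missing values")
    dx = np.abs(v[:, None] - v[None, :])
    d2 = DistanceMatrix(dm.ids, dx)
    return mantel(dm, d2, n_perm=n_perm, method=method, seed=seed,
                  alternative=alternative)
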