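"""The microbial dysbiosis index (MDI) and its downstream statistics.

MDI(sample) = log10( (sum of relative abundances of disease-increased
genera + eps) / (sum of disease-decreased genera + eps) ): a single scalar
summarizing how far a community has shifted toward the tumor-associated
configuration. Higher values indicate dysbiosis; the pseudocount eps keeps
the score finite when one side of the signature is absent.

Discrimination is quantified by the rank (Mann-Whitney) AUC with a seeded
stratified-bootstrap percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, rankdata, spearmanr
from sklearn.metrics import roc_curve

from .beta import DistanceMatrix, covariate_mantel
from .difftaxa import MdiSignature
from .results import GroupComparisonResult
from .tables import RelativeAbundanceTable, SampleMetadata


@dataclass
class MdiResult:
    """Per-sample MDI values (log10 units) plus provenance."""

    values: pd.Series
    pseudocount: float
    signature: MdiSignature
    missing_increased: list = field(default_factory=list)
    missing_decreased: list = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("MDI values must be finite")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: str
    n_boot: int
    seed: int
    ci_method: str = "stratified bootstrap percentile"

    def __post_init__(self):
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


def mdi(table: RelativeAbundanceTable, signature: MdiSignature,
        pseudocount: Optional[float] = None) -> MdiResult:
    """Compute the MDI for every sample of a genus-level table.

    ``pseudocount`` defaults to half the smallest nonzero relative
    abundance in the table. Signature genera absent from the table
    contribute zero and are recorded on the result.
    """
    cols = set(table.data.columns)
    inc = sorted(signature.increased & cols)
    dec = sorted(signature.decreased & cols)
    if not inc and not dec:
        raise ValueError("no signature genus present in the table")
    if pseudocount is None:
        nz = table.data.to_numpy(dtype=float)
        nz = nz[nz > 0]
        if nz.size == 0:
            raise ValueError("table has no nonzero abundances")
        pseudocount = float(nz.min() / 2)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    inc_sum = table.data[inc].sum(axis=1) if inc else pd.Series(0.0, index=table.data.index)
    dec_sum = table.data[dec].sum(axis=1) if dec else pd.Series(0.0, index=table.data.index)
    # difference of logs, so swapping the sets negates the score exactly
    values = np.log10(inc_sum + pseudocount) - np.log10(dec_sum + pseudocount)
    return MdiResult(
        values=values.rename("mdi"),
        pseudocount=pseudocount,
        signature=signature,
        missing_increased=sorted(signature.increased - cols),
        missing_decreased=sorted(signature.decreased - cols),
    )


def auc_rank(scores: Sequence[float], labels: Sequence,
             positive_label="T") -> float:
    """Rank AUC via the Mann-Whitney identity.

    AUC = (number of positive-negative pairs with score_pos > score_neg,
    ties counting one half) / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    r = rankdata(s)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_with_ci(scores: pd.Series, metadata_or_labels, positive_label="T",
                n_boot: int = 2000, seed: int = 0) -> RocResult:
    """ROC operating points, rank AUC, bootstrap CI and a Mann-Whitney p.

    The CI is the 2.5/97.5 percentile of AUCs over ``n_boot`` seeded
    stratified bootstrap resamples (classes resampled separately, so every
    replicate keeps both classes). The p-value tests AUC != 0.5.
    """
    if isinstance(metadata_or_labels, SampleMetadata):
        labels = metadata_or_labels.groups(list(scores.index)).to_numpy()
    else:
        labels = np.asarray(metadata_or_labels)
    s = scores.to_numpy(dtype=float)
    pos = labels == positive_label
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each class needs at least 3 samples")

    auc = auc_rank(s, labels, positive_label)
    fpr, tpr, thr = roc_curve(pos.astype(int), s)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(pos), np.flatnonzero(~pos)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        boot[b] = auc_rank(s[idx], pos[idx], positive_label=True)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    p = float(mannwhitneyu(s[pos], s[~pos], alternative="two-sided").pvalue)
    return RocResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi), p_value=p,
        thresholds=thr, sensitivity=tpr, specificity=1 - fpr,
        positive_label=str(positive_label), n_boot=n_boot, seed=seed,
    )


def correlate_mdi_alpha(mdi_result: MdiResult, alpha_values: pd.Series,
                        method: str = "pearson", n_perm: int = 999,
                        seed: int = 0) -> GroupComparisonResult:
    """Correlation between MDI and an alpha-diversity vector (e.g. observed
    OTUs), with a seeded two-sided permutation p-value."""
    x = mdi_result.values
    if list(x.index) != list(alpha_values.index):
        alpha_values = alpha_values.loc[x.index]
    a = x.to_numpy(dtype=float)
    b = alpha_values.to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return GroupComparisonResult(f"{method}_r", 0.0, 1.0, 0, seed=seed,
                                     degenerate=True)
    fn = pearsonr if method == "pearson" else spearmanr
    r_obs = float(fn(a, b).statistic)
    rng = np.random.default_rng(seed)
    r_star = np.array([float(fn(a, rng.permutation(b)).statistic)
                       for _ in range(n_perm)])
    hits = (np.abs(r_star) >= abs(r_obs) - 1e-12).sum()
    return GroupComparisonResult(f"{method}_r", r_obs,
                                 float((hits + 1) / (n_perm + 1)), n_perm,
                                 seed=seed)


def mdi_vs_beta(mdi_result: MdiResult, dm: DistanceMatrix,
                n_perm: int = 999, seed: int = 0) -> GroupComparisonResult:
    """Mantel test of |MDI_i - MDI_j| against a beta-diversity matrix."""
    return covariate_mantel(dm, mdi_result.values, n_perm=n_perm, seed=seed,
                            alternative="two-sided")
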