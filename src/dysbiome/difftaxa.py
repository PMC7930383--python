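"""Differential-abundance testing and biomarker selection.

Two routes mirror the common 16S practice for a two-group contrast:

* a Metastats-style test — Welch t-statistic on relative abundances with a
  permutation p-value, falling back to Fisher's exact test on pooled counts
  for sparse taxa (prevalence below 25% in both groups), with
  Benjamini-Hochberg q-values over all taxa;
* a deterministic single-feature LDA effect size (the LEfSe selection rule:
  Kruskal-Wallis screen at p < 0.05, then a log10 effect on abundances
  rescaled to one million per sample, biomarkers kept when the effect
  exceeds 3). The cited tool's per-class bootstrap and subclass logic are
  deliberately omitted: with one two-class contrast the discriminant is
  one-dimensional and the calibrated effect reduces to the absolute
  difference of scaled group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, kruskal, pearsonr, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .results import GroupComparisonResult
from .tables import AbundanceTable, RelativeAbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class DiffAbundanceRecord:
    taxon_id: str
    mean: Dict[str, float]
    variance: Dict[str, float]
    statistic: float
    p_value: float
    q_value: Optional[float] = None
    lda_score: Optional[float] = None
    direction: Optional[str] = None   # group in which enriched
    test: str = "welch_permutation"


@dataclass(frozen=True)
class MdiSignature:
    """Disjoint genus sets defining the microbial dysbiosis index."""

    increased: frozenset
    decreased: frozenset

    def __post_init__(self):
        inc, dec = frozenset(self.increased), frozenset(self.decreased)
        object.__setattr__(self, "increased", inc)
        object.__setattr__(self, "decreased", dec)
        if not inc or not dec:
            raise ValueError("both signature sets must be non-empty")
        if inc & dec:
            raise ValueError(f"signature sets overlap: {sorted(inc & dec)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"genus": g, "direction": "increased"} for g in sorted(self.increased)]
        rows += [{"genus": g, "direction": "decreased"} for g in sorted(self.decreased)]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MdiSignature":
        inc = df.loc[df["direction"] == "increased", "genus"]
        dec = df.loc[df["direction"] == "decreased", "genus"]
        return cls(frozenset(inc), frozenset(dec))


#: Genera depleted in tumors in the ESCC discovery cohort.
_ESCC_DECREASED = (
    "Acinetobacter", "Blastomonas", "Klebsiella", "Pseudomonas",
    "Lactococcus", "Thermus", "Anoxybacillus", "Geobacillus",
)
#: Genera enriched in tumors ("Non-Fusobacterium Fusobacteria" is the
#: phylum-level remainder after removing the genus Fusobacterium).
_ESCC_INCREASED = (
    "Campylobacter", "Fusobacterium", "Non-Fusobacterium_Fusobacteria",
    "Parvimonas", "Peptostreptococcus", "Selenomonas", "Streptococcus",
    "Veillonella", "Prevotella", "Treponema", "Capnocytophaga",
)


def escc_signature() -> MdiSignature:
    """The fixed 19-genus ESCC dysbiosis signature (8 decreased, 11 increased)."""
    return MdiSignature(increased=frozenset(_ESCC_INCREASED),
                        decreased=frozenset(_ESCC_DECREASED))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _two_group_codes(metadata: SampleMetadata, sample_ids: list):
    groups = metadata.groups(sample_ids)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, found {labels}")
    codes = (groups.to_numpy() == labels[1]).astype(int)
    return labels, codes


def _welch_t(x: np.ndarray, g0: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over taxa columns for boolean group masks."""
    n0, n1 = g0.sum(), g1.sum()
    m0, m1 = x[g0].mean(axis=0), x[g1].mean(axis=0)
    v0 = x[g0].var(axis=0, ddof=1)
    v1 = x[g1].var(axis=0, ddof=1)
    se = np.sqrt(v0 / n0 + v1 / n1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m0 - m1) / np.where(se == 0, 1, se), 0.0)
    return t


def metastats_test(table: AbundanceTable, metadata: SampleMetadata,
                   n_perm: int = 1000, sparse_fraction: float = 0.25,
                   seed: int = 0) -> List[DiffAbundanceRecord]:
    """Metastats-style two-group differential abundance test.

    Non-sparse taxa: Welch t on relative abundances, permutation p with the
    plus-one estimator. Sparse taxa (nonzero in fewer than
    ``sparse_fraction`` of samples in both groups): two-sided Fisher exact
    test on pooled taxon counts versus pooled remaining reads. All-zero
    taxa are excluded with a log message; q-values are BH over all tested
    taxa.
    """
    table = table.drop_zero_taxa()
    labels, codes = _two_group_codes(metadata, table.sample_ids)
    g0, g1 = codes == 0, codes == 1
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = table.data.to_numpy(dtype=float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    taxa = table.taxon_ids

    prev0 = (counts[g0] > 0).mean(axis=0)
    prev1 = (counts[g1] > 0).mean(axis=0)
    sparse = (prev0 < sparse_fraction) & (prev1 < sparse_fraction)

    t_obs = _welch_t(rel, g0, g1)
    rng = np.random.default_rng(seed)
    dense_idx = np.flatnonzero(~sparse)
    p = np.ones(len(taxa))
    if dense_idx.size:
        exceed = np.zeros(dense_idx.size)
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            t_star = _welch_t(rel[:, dense_idx], perm == 0, perm == 1)
            exceed += np.abs(t_star) >= np.abs(t_obs[dense_idx]) - 1e-12
        p[dense_idx] = (exceed + 1) / (n_perm + 1)

    pooled0 = counts[g0].sum(axis=0)
    pooled1 = counts[g1].sum(axis=0)
    tot0, tot1 = counts[g0].sum(), counts[g1].sum()
    for i in np.flatnonzero(sparse):
        tab = [[pooled0[i], tot0 - pooled0[i]], [pooled1[i], tot1 - pooled1[i]]]
        p[i] = fisher_exact(np.asarray(tab, dtype=np.int64), alternative="two-sided")[1]

    q = bh_fdr(p)
    records = []
    for i, t in enumerate(taxa):
        m0, m1 = rel[g0, i].mean(), rel[g1, i].mean()
        records.append(DiffAbundanceRecord(
            taxon_id=t,
            mean={labels[0]: float(m0), labels[1]: float(m1)},
            variance={labels[0]: float(rel[g0, i].var(ddof=1)),
                      labels[1]: float(rel[g1, i].var(ddof=1))},
            statistic=float(t_obs[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            direction=labels[0] if m0 >= m1 else labels[1],
            test="fisher_exact" if sparse[i] else "welch_permutation",
        ))
    return records


def lda_effect_size(table: RelativeAbundanceTable, metadata: SampleMetadata,
                    scale: float = 1e6) -> List[DiffAbundanceRecord]:
    """Deterministic single-feature LDA effect size per taxon.

    Abundances are rescaled to sum to ``scale`` per sample. Each taxon
    carries a Kruskal-Wallis screen p-value and the effect
    log10(max(|scaled group-mean difference|, 1)): for a one-dimensional
    two-class discriminant the calibrated abundance difference reduces to
    the absolute difference of scaled group means (any ridge added to the
    pooled variance cancels from the calibrated effect). The p < 0.05
    screen is applied at selection time by :func:`lefse_select`.
    """
    labels, codes = _two_group_codes(metadata, table.sample_ids)
    g0, g1 = codes == 0, codes == 1
    if g0.sum() < 3 or g1.sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    x = table.data.to_numpy(dtype=float) * scale
    records = []
    for i, t in enumerate(table.taxon_ids):
        a, b = x[g0, i], x[g1, i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            kw_p = 1.0
        else:
            kw_p = float(kruskal(a, b).pvalue)
        diff = abs(a.mean() - b.mean())
        score = float(np.log10(max(diff, 1.0)))
        records.append(DiffAbundanceRecord(
            taxon_id=t,
            mean={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
            variance={labels[0]: float(a.var(ddof=1)), labels[1]: float(b.var(ddof=1))},
            statistic=score,
            p_value=kw_p,
            lda_score=score,
            direction=labels[0] if a.mean() >= b.mean() else labels[1],
            test="lda_effect_size",
        ))
    return records


def lefse_select(records: Iterable[DiffAbundanceRecord],
                 p_threshold: float = 0.05,
                 lda_threshold: float = 3.0) -> List[DiffAbundanceRecord]:
    """Biomarkers: p < ``p_threshold`` and LDA score > ``lda_threshold``."""
    out = []
    for r in records:
        if r.lda_score is None:
            raise ValueError(f"record {r.taxon_id} lacks an LDA score")
        if r.p_value < p_threshold and r.lda_score > lda_threshold:
            out.append(r)
    return out


def derive_signature(biomarkers: Iterable[DiffAbundanceRecord],
                     tumor_group: str = "T") -> MdiSignature:
    """Signature from selected biomarkers: increased = enriched in the
    tumor group, decreased = enriched in the other group."""
    inc, dec = set(), set()
    for r in biomarkers:
        (inc if r.direction == tumor_group else dec).add(r.taxon_id)
    if not inc or not dec:
        raise ValueError("both enriched and depleted biomarkers are required "
                         "for a dysbiosis signature")
    return MdiSignature(increased=frozenset(inc), decreased=frozenset(dec))


def correlate_taxa(table: RelativeAbundanceTable, taxon_a: str, taxon_b: str,
                   method: str = "spearman", n_perm: int = 999,
                   seed: int = 0) -> GroupComparisonResult:
    """Correlation of two taxa's relative abundances across samples, with a
    seeded two-sided permutation p-value."""
    for t in (taxon_a, taxon_b):
        if t not in table.data.columns:
            raise ValueError(f"taxon {t!r} not in table")
    a = table.data[taxon_a].to_numpy(dtype=float)
    b = table.data[taxon_b].to_numpy(dtype=float)

    def corr(x, y):
        if x.std() == 0 or y.std() == 0:
            return np.nan
        if method == "spearman":
            return float(spearmanr(x, y).statistic)
        if method == "pearson":
            return float(pearsonr(x, y).statistic)
        raise ValueError(f"unknown method {method!r}")

    r_obs = corr(a, b)
    if np.isnan(r_obs):
        return GroupComparisonResult(f"{method}_r", 0.0, 1.0, 0, seed=seed,
                                     degenerate=True)
    rng = np.random.default_rng(seed)
    r_star = np.array([corr(a, rng.permutation(b)) for _ in range(n_perm)])
    hits = (np.abs(r_star) >= abs(r_obs) - 1e-12).sum()
    return GroupComparisonResult(f"{method}_r", r_obs,
                                 float((hits + 1) / (n_perm + 1)), n_perm,
                                 seed=seed)


def records_to_frame(records: Iterable[DiffAbundanceRecord]) -> pd.DataFrame:
    """Flat table of differential-abundance records (diff.tsv schema)."""
    rows = []
    for r in records:
        groups = sorted(r.mean)
        row = {"taxon": r.taxon_id}
        for g in groups:
            row[f"mean_{g}"] = r.mean[g]
        row.update(stat=r.statistic, p=r.p_value, q=r.q_value,
                   lda=r.lda_score, direction=r.direction, test=r.test)
        rows.append(row)
    return pd.DataFrame(rows)
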