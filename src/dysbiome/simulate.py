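"""Synthetic ESCC-like 16S cohort generator.

Generates genus-level count tables, sample metadata and a phylogeny for a
two/three-group esophageal cohort (PN = physiologically normal, PreT =
pre-cancer, T = tumor) under a Dirichlet-multinomial noise model:

* per-sample sequencing depth ~ negative binomial;
* a per-sample Bernoulli presence mask thins taxa (richness deficit in T);
* sample fractions ~ Dirichlet(concentration x group profile restricted to
  present taxa); counts ~ Multinomial(depth, fractions).

Group composition shifts are multiplicative fold-changes on the baseline
(PN) expected profile, re-closed to sum to one. The default configuration
is calibrated so that the cohort-size-weighted overall expected phylum
means hit the dominant-phyla percentages reported for ESCC/PN esophageal
mucosa (Fusobacteria 7.43, Actinobacteria 0.70, Bacteroidetes 28.93,
Firmicutes 35.76, Proteobacteria 23.21, Spirochetes 1.57, Thermi 1.91; an
unassigned remainder of 0.49 closes the composition), with tumor-group
enrichment of Fusobacteria/Bacteroidetes/Spirochetes, depletion of
Proteobacteria/Thermi, and a genus layer carrying the 19-genus dysbiosis
signature.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables import RANKS, AbundanceTable, PhyloTree, SampleMetadata

#: (genus, phylum, overall target mean fraction, tumor fold-change)
#: Fold > 1: enriched in tumors; fold < 1: depleted. Fillers are neutral.
_GENUS_SPEC = [
    # Firmicutes (0.3576 total)
    ("Streptococcus", "Firmicutes", 0.12, 3.0),
    ("Veillonella", "Firmicutes", 0.05, 3.0),
    ("Parvimonas", "Firmicutes", 0.02, 3.0),
    ("Peptostreptococcus", "Firmicutes", 0.02, 3.0),
    ("Selenomonas", "Firmicutes", 0.02, 3.0),
    ("Lactococcus", "Firmicutes", 0.02, 0.3),
    ("Anoxybacillus", "Firmicutes", 0.01, 0.3),
    ("Geobacillus", "Firmicutes", 0.01, 0.3),
    *[(f"Firmicutes_genus_{i:02d}", "Firmicutes", 0.0876 / 6, 1.0) for i in range(1, 7)],
    # Bacteroidetes (0.2893)
    ("Prevotella", "Bacteroidetes", 0.18, 3.0),
    ("Capnocytophaga", "Bacteroidetes", 0.03, 3.0),
    *[(f"Bacteroidetes_genus_{i:02d}", "Bacteroidetes", 0.0793 / 8, 1.0) for i in range(1, 9)],
    # Proteobacteria (0.2321)
    ("Klebsiella", "Proteobacteria", 0.08, 0.3),
    ("Pseudomonas", "Proteobacteria", 0.05, 0.3),
    ("Acinetobacter", "Proteobacteria", 0.04, 0.3),
    ("Blastomonas", "Proteobacteria", 0.01, 0.3),
    ("Campylobacter", "Proteobacteria", 0.012, 3.0),
    *[(f"Proteobacteria_genus_{i:02d}", "Proteobacteria", 0.0401 / 7, 1.0) for i in range(1, 8)],
    # Fusobacteria (0.0743)
    ("Fusobacterium", "Fusobacteria", 0.06, 3.0),
    ("Non-Fusobacterium_Fusobacteria", "Fusobacteria", 0.0143, 3.0),
    # Thermi (0.0191)
    ("Thermus", "Thermi", 0.015, 0.3),
    ("Thermi_genus_01", "Thermi", 0.0041, 1.0),
    # Spirochetes (0.0157)
    ("Treponema", "Spirochetes", 0.0147, 3.0),
    ("Spirochetes_genus_01", "Spirochetes", 0.001, 1.0),
    # Actinobacteria (0.007)
    *[(f"Actinobacteria_genus_{i:02d}", "Actinobacteria", 0.007 / 5, 1.0) for i in range(1, 6)],
    # unassigned remainder closing the composition to 1 (0.0049)
    *[(f"Unassigned_genus_{i:02d}", None, 0.0049 / 3, 1.0) for i in range(1, 4)],
]

_BASELINE_CACHE: dict = {}

#: The seven phyla with printed overall mean percentages.
PRINTED_PHYLUM_MEANS = {
    "Fusobacteria": 0.0743,
    "Actinobacteria": 0.0070,
    "Bacteroidetes": 0.2893,
    "Firmicutes": 0.3576,
    "Proteobacteria": 0.2321,
    "Spirochetes": 0.0157,
    "Thermi": 0.0191,
}


def _closure(x: pd.Series) -> pd.Series:
    return x / x.sum()


def _mask_closure_expectation(q: np.ndarray, r: float,
                              n_big: int = 8) -> np.ndarray:
    """Expected composition after Bernoulli(r) presence masking + closure.

    Masking taxa and renormalizing inflates the surviving taxa, so
    E[q_i z_i / sum_j q_j z_j] != q_i for r < 1. Computed by exact
    enumeration over the presence patterns of the ``n_big`` largest taxa,
    with a second-order delta correction for the near-constant sum of the
    remaining small taxa; the result is re-closed to sum to one.
    """
    q = np.asarray(q, dtype=float)
    n = q.size
    if r >= 1:
        return q.copy()
    big = np.argsort(q)[::-1][: min(n_big, n)]
    is_small = np.ones(n, dtype=bool)
    is_small[big] = False
    small_sum = q[is_small].sum()
    small_sq = (q[is_small] ** 2).sum()
    k = big.size
    bits = (np.arange(2 ** k)[:, None] >> np.arange(k)) & 1  # patterns x big
    probs = np.prod(np.where(bits == 1, r, 1 - r), axis=1)
    sums = bits @ q[big]
    pos = {idx: j for j, idx in enumerate(big)}

    out = np.empty(n)
    for i in range(n):
        if is_small[i]:
            mu = r * (small_sum - q[i])
            var = r * (1 - r) * (small_sq - q[i] ** 2)
            c = q[i] + sums + mu
            out[i] = r * q[i] * float(probs @ ((1 / c) * (1 + var / c ** 2)))
        else:
            j = pos[i]
            rows = bits[:, j] == 0  # presence patterns of the other big taxa
            pr = probs[rows] / (1 - r)
            mu = r * small_sum
            var = r * (1 - r) * small_sq
            c = q[i] + sums[rows] + mu
            out[i] = r * q[i] * float(pr @ ((1 / c) * (1 + var / c ** 2)))
    return out / out.sum()


@dataclass
class CohortSimulationConfig:
    """Everything needed to draw a cohort; same seed, same cohort."""

    n_per_group: Dict[str, int]
    baseline_profile: pd.Series          # taxon -> expected PN fraction, sums to 1
    group_effects: Dict[str, pd.Series]  # group -> per-taxon fold-change
    richness_retention: Dict[str, float]
    lineages: dict                       # taxon -> 7-tuple over RANKS
    depth_mean: float = 40410.0
    depth_dispersion: float = 11.1       # negative-binomial size; CV ~ 0.30
    concentration: float = 50.0          # Dirichlet scale; smaller = noisier
    seed: int = 0

    def __post_init__(self):
        if abs(self.baseline_profile.sum() - 1) > 1e-9:
            raise ValueError("baseline_profile must sum to 1")
        if (self.baseline_profile <= 0).any():
            raise ValueError("baseline_profile entries must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g}] must be >= 1")
            if g not in self.group_effects:
                raise ValueError(f"group {g!r} missing from group_effects")
            if g not in self.richness_retention:
                raise ValueError(f"group {g!r} missing from richness_retention")
        for g, f in self.group_effects.items():
            if (np.asarray(f) <= 0).any():
                raise ValueError(f"fold-changes for {g!r} must be > 0")
        for g, r in self.richness_retention.items():
            if not (0 < r <= 1):
                raise ValueError(f"richness_retention[{g}] must be in (0, 1]")

    @property
    def taxon_ids(self) -> list:
        return list(self.baseline_profile.index)

    def pre_mask_profile(self, group: str) -> pd.Series:
        """Group composition before presence masking (Dirichlet center)."""
        return _closure(self.baseline_profile * self.group_effects[group])

    def expected_profile(self, group: str) -> pd.Series:
        """Realized expected composition of one group: the pre-mask profile
        corrected for the inflation that masking + closure causes."""
        q = self.pre_mask_profile(group)
        corrected = _mask_closure_expectation(
            q.to_numpy(), self.richness_retention[group])
        return pd.Series(corrected, index=q.index)

    def overall_expected_profile(self) -> pd.Series:
        """Group-size-weighted mean of the per-group expected profiles."""
        total = sum(self.n_per_group.values())
        out = sum((n / total) * self.expected_profile(g)
                  for g, n in self.n_per_group.items())
        return out

    def truth_frame(self) -> pd.DataFrame:
        """Per-group expected fractions plus the log2 fold parameters."""
        rows = {g: self.expected_profile(g) for g in self.n_per_group}
        df = pd.DataFrame(rows).T
        df.index.name = "group"
        return df


@dataclass
class SimulatedCohort:
    table: AbundanceTable
    metadata: SampleMetadata
    tree: PhyloTree
    truth: pd.DataFrame
    config: CohortSimulationConfig

    def __post_init__(self):
        if self.table.sample_ids != self.metadata.sample_ids:
            raise ValueError("table and metadata sample ids differ")
        if set(self.table.taxon_ids) - set(self.tree.leaf_names):
            raise ValueError("table taxa missing from tree")


def _lineage_for(genus: str, phylum: Optional[str]) -> tuple:
    lin = [None] * len(RANKS)
    lin[0] = "Bacteria"
    lin[RANKS.index("phylum")] = phylum
    lin[RANKS.index("genus")] = genus
    return tuple(lin)


def _solve_baseline(target: pd.Series, effects: Dict[str, pd.Series],
                    weights: Dict[str, float], retention: Dict[str, float],
                    tol: float = 1e-13, max_iter: int = 5000) -> pd.Series:
    """Find the baseline profile whose weighted per-group realized expected
    means (including the mask-closure correction) equal ``target``
    (multiplicative fixed-point iteration)."""
    idx = target.index

    def realized(b: pd.Series, g: str) -> pd.Series:
        q = _closure(b * effects[g])
        return pd.Series(_mask_closure_expectation(q.to_numpy(), retention[g]),
                         index=idx)

    b = target.copy()
    for _ in range(max_iter):
        overall = sum(w * realized(b, g) for g, w in weights.items())
        if np.max(np.abs(overall - target)) < tol:
            break
        b = _closure(b * target / overall)
    else:
        raise RuntimeError("baseline calibration did not converge")
    return b


def default_escc_config(seed: int = 0,
                        n_per_group: Optional[Dict[str, int]] = None,
                        depth_mean: float = 40410.0) -> CohortSimulationConfig:
    """Default two-group configuration emulating the ESCC discovery cohort.

    PN = 11 and T = 18 samples by default; the weighted overall expected
    phylum means equal the printed dominant-phyla values exactly, tumor
    effects raise Fusobacteria/Bacteroidetes/Spirochetes genera and lower
    Proteobacteria/Thermi genera, and all 19 signature genera are present.
    """
    if n_per_group is None:
        n_per_group = {"PN": 11, "T": 18}
    taxa = [g for g, _, _, _ in _GENUS_SPEC]
    target = pd.Series({g: m for g, _, m, _ in _GENUS_SPEC}, index=taxa)
    target = target / target.sum()  # exact closure of the designed means
    fold_t = pd.Series({g: f for g, _, _, f in _GENUS_SPEC}, index=taxa)
    effects = {
        "PN": pd.Series(1.0, index=taxa),
        "T": fold_t,
        "PreT": np.sqrt(fold_t * 1.0),  # geometric midpoint of PN and T
    }
    unknown = set(n_per_group) - set(effects)
    if unknown:
        raise ValueError(f"groups missing from group_effects: {sorted(unknown)}")
    retention = {"PN": 0.95, "T": 0.80, "PreT": 0.875}
    total = sum(n_per_group.values())
    weights = {g: n / total for g, n in n_per_group.items()}
    cache_key = tuple(sorted(n_per_group.items()))
    if cache_key not in _BASELINE_CACHE:
        _BASELINE_CACHE[cache_key] = _solve_baseline(target, effects, weights,
                                                     retention)
    baseline = _BASELINE_CACHE[cache_key].copy()
    lineages = {g: _lineage_for(g, p) for g, p, _, _ in _GENUS_SPEC}
    return CohortSimulationConfig(
        n_per_group=dict(n_per_group),
        baseline_profile=baseline,
        group_effects=effects,
        richness_retention=retention,
        lineages=lineages,
        depth_mean=depth_mean,
        seed=seed,
    )


def null_config(seed: int = 0,
                n_per_group: Optional[Dict[str, int]] = None) -> CohortSimulationConfig:
    """A no-effect configuration (all folds 1, equal retention) for
    calibration studies: every downstream test should behave as under H0."""
    cfg = default_escc_config(seed=seed, n_per_group=n_per_group)
    ones = pd.Series(1.0, index=cfg.taxon_ids)
    cfg.group_effects = {g: ones.copy() for g in cfg.group_effects}
    cfg.richness_retention = {g: 0.95 for g in cfg.richness_retention}
    # with no effects the baseline is the overall target composition itself
    target = pd.Series({g: m for g, _, m, _ in _GENUS_SPEC})
    cfg.baseline_profile = target / target.sum()
    return cfg


def _sample_rng(seed: int, sample_id: str, stream: int = 0) -> np.random.Generator:
    # named substream per sample: draws do not depend on group ordering
    key = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, stream)))


def simulate_cohort(config: CohortSimulationConfig) -> SimulatedCohort:
    """Draw one cohort; bit-identical for identical configs and seeds."""
    taxa = config.taxon_ids
    n_taxa = len(taxa)
    rows, meta_rows, sample_ids = [], [], []
    for group in config.n_per_group:
        profile = config.pre_mask_profile(group).to_numpy()
        retention = config.richness_retention[group]
        for i in range(1, config.n_per_group[group] + 1):
            sid = f"{group}_{i:03d}"
            rng = _sample_rng(config.seed, sid)
            r = config.depth_dispersion
            p = r / (r + config.depth_mean)
            depth = 0
            while depth == 0:
                depth = int(rng.negative_binomial(r, p))
            mask = rng.random(n_taxa) < retention
            if not mask.any():
                mask[int(np.argmax(profile))] = True
            alpha = config.concentration * profile[mask] / profile[mask].sum()
            fractions = rng.dirichlet(alpha)
            counts = np.zeros(n_taxa, dtype=np.int64)
            counts[mask] = rng.multinomial(depth, fractions)
            rows.append(counts)
            sample_ids.append(sid)
            mrng = _sample_rng(config.seed, sid, stream=1)
            age_mean = {"PN": 45.0, "PreT": 52.0, "T": 60.0}.get(group, 50.0)
            meta_rows.append({
                "sample_id": sid,
                "group": group,
                "age": float(np.round(np.clip(mrng.normal(age_mean, 8.0), 25, 85), 1)),
                "sex": "male" if mrng.random() < 0.6 else "female",
                "stage": ("I II III IV".split()[int(mrng.integers(4))]
                          if group == "T" else "unknown"),
            })

    data = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=taxa)
    table = AbundanceTable(data, dict(config.lineages))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    phyla = {t: config.lineages[t][RANKS.index("phylum")] for t in taxa}
    tree_seed = int(np.random.SeedSequence(config.seed, spawn_key=(0, 99)).generate_state(1)[0] % (2 ** 31))
    tree = simulate_tree(taxa, seed=tree_seed, phyla=phyla)
    return SimulatedCohort(table, metadata, tree, config.truth_frame(), config)


def simulate_tree(taxon_ids: Sequence[str], seed: int,
                  phyla: Optional[Dict[str, Optional[str]]] = None) -> PhyloTree:
    """Random rooted binary tree over ``taxon_ids``.

    Built by sequential random joins with Exponential(1) branch lengths;
    when ``phyla`` is given, taxa of the same phylum coalesce before any
    cross-phylum join, so each phylum's genera form a clade.
    """
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    if phyla is None:
        phyla = {t: None for t in taxon_ids}

    def _join_all(nodes):
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = TreeNode(length=float(rng.exponential(1.0)))
            parent.extend([nodes[i], nodes[j]])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        return nodes[0]

    cluster_order, clusters = [], {}
    for t in taxon_ids:
        key = phyla.get(t)
        if key not in clusters:
            clusters[key] = []
            cluster_order.append(key)
        clusters[key].append(TreeNode(name=t, length=float(rng.exponential(1.0))))

    roots = [_join_all(clusters[k]) for k in cluster_order]
    root = _join_all(roots) if len(roots) > 1 else roots[0]
    root.length = None
    return PhyloTree(root)
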