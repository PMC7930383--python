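"""End-to-end orchestration of the dysbiosis analysis.

One call reproduces the figure-level statistics on simulated or user data:
alpha diversity and group tests, UniFrac/PCoA/ANOSIM, differential taxa,
signature -> MDI -> correlations -> ROC. A single seed is expanded into
named per-stage substreams, so adding a stage never perturbs the draws of
earlier stages; the same config and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .alpha import METRICS, alpha_diversity, compare_groups
from .beta import DistanceMatrix, anosim, pcoa, unifrac
from .difftaxa import (MdiSignature, derive_signature, escc_signature,
                       lda_effect_size, lefse_select, metastats_test,
                       records_to_frame)
from .mdi import correlate_mdi_alpha, mdi, mdi_vs_beta, roc_with_ci
from .simulate import CohortSimulationConfig, default_escc_config, simulate_cohort
from .tables import (AbundanceTable, PhyloTree, SampleMetadata,
                     read_abundance_table, read_metadata, read_tree,
                     write_abundance_table, write_metadata, write_tree)

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("alpha.tsv", "dist_unweighted.tsv", "dist_weighted.tsv",
                "pcoa.tsv", "diff.tsv", "signature.tsv", "mdi.tsv",
                "roc.json", "run_log.json")


@dataclass
class PipelineConfig:
    """Exactly one of (table/metadata/tree paths, simulation) must be set."""

    seed: int
    out_dir: Path
    table_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    tree_path: Optional[Path] = None
    simulation: Optional[CohortSimulationConfig] = None
    rank: str = "genus"
    signature_source: str = "escc"      # "escc" or "derive"
    n_perm: int = 999
    metastats_perm: int = 1000
    n_boot: int = 2000

    def __post_init__(self):
        has_paths = self.table_path is not None
        if has_paths and (self.metadata_path is None or self.tree_path is None):
            raise ValueError("table_path requires metadata_path and tree_path")
        if has_paths == (self.simulation is not None):
            raise ValueError("provide exactly one of input paths or a "
                             "simulation config")
        if self.signature_source not in ("escc", "derive"):
            raise ValueError("signature_source must be 'escc' or 'derive'")
        self.out_dir = Path(self.out_dir)


def _stage_seed(seed: int, name: str) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format="%.12g", index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the result bundle as a dict and writes
    the standard files into ``config.out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": __version__, "seed": config.seed,
                 "parameters": {"rank": config.rank,
                                "signature_source": config.signature_source,
                                "n_perm": config.n_perm,
                                "metastats_perm": config.metastats_perm,
                                "n_boot": config.n_boot},
                 "stages": {}}
    bundle: dict = {}
    stage = "load"
    try:
        # (1) load or simulate the cohort
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=_stage_seed(config.seed, "simulate"))
            cohort = simulate_cohort(sim_cfg)
            table, metadata, tree = cohort.table, cohort.metadata, cohort.tree
            write_abundance_table(table, out / "table.tsv")
            write_metadata(metadata, out / "metadata.tsv")
            write_tree(tree, out / "tree.nwk")
            _write_tsv(cohort.truth, out / "truth.tsv")
            log["stages"]["simulate"] = {"seed": sim_cfg.seed,
                                         "n_samples": len(table.sample_ids),
                                         "n_taxa": len(table.taxon_ids)}
        else:
            table = read_abundance_table(config.table_path)
            metadata = read_metadata(config.metadata_path)
            tree = read_tree(config.tree_path)
            log["stages"]["load"] = {"table": str(config.table_path)}

        groups = metadata.groups(table.sample_ids)
        two_group = metadata.frame.loc[
            [s for s in table.sample_ids if groups[s] in ("PN", "T")]]
        pn_t_meta = SampleMetadata(two_group.copy())

        # (2) rank aggregation
        stage = "aggregate"
        genus = table.aggregate_at_rank(config.rank).drop_zero_taxa()
        genus_rel = genus.to_relative()

        # (3) alpha diversity + group tests
        stage = "alpha"
        adiv = alpha_diversity(table)
        _write_tsv(adiv, out / "alpha.tsv", index_label="sample_id")
        alpha_tests = {}
        for metric in METRICS:
            res = compare_groups(adiv[metric], metadata,
                                 n_perm=config.n_perm,
                                 seed=_stage_seed(config.seed, f"alpha:{metric}"))
            alpha_tests[metric] = {"statistic": res.statistic_name,
                                   "value": res.statistic, "p": res.p_value,
                                   "exact": res.exact}
        log["stages"]["alpha"] = alpha_tests

        # (4) beta diversity: UniFrac, PCoA, ANOSIM
        stage = "beta"
        work = table.drop_zero_taxa()
        dists = {"unweighted": unifrac(work, tree, weighted=False),
                 "weighted": unifrac(work, tree, weighted=True)}
        beta_log = {}
        pcoa_frames = []
        for name, dm in dists.items():
            dm.write(out / f"dist_{name}.tsv")
            ord_res = pcoa(dm)
            coords = ord_res.coordinates.iloc[:, :2].copy()
            coords.columns = [f"{name}_{c}" for c in coords.columns]
            pcoa_frames.append(coords)
            res = anosim(dm, metadata, n_perm=config.n_perm,
                         seed=_stage_seed(config.seed, f"anosim:{name}"))
            beta_log[name] = {
                "anosim_R": res.statistic, "p": res.p_value, "exact": res.exact,
                "pcoa_prop_explained": [float(x) for x in
                                        ord_res.proportion_explained[:2]],
                "negative_eigenvalues": ord_res.has_negative_eigenvalues}
        _write_tsv(pd.concat(pcoa_frames, axis=1), out / "pcoa.tsv",
                   index_label="sample_id")
        log["stages"]["beta"] = beta_log

        # (5) differential taxa on the PN-vs-T contrast
        stage = "difftaxa"
        genus_pt = genus.filter_samples(pn_t_meta, lambda r: True).drop_zero_taxa()
        meta_records = metastats_test(genus_pt, pn_t_meta,
                                      n_perm=config.metastats_perm,
                                      seed=_stage_seed(config.seed, "metastats"))
        lefse_records = lda_effect_size(genus_pt.to_relative(), pn_t_meta)
        diff = records_to_frame(meta_records).merge(
            records_to_frame(lefse_records)[["taxon", "lda"]], on="taxon",
            how="left", suffixes=("", "_lefse"))
        _write_tsv(diff.set_index("taxon"), out / "diff.tsv")
        biomarkers = lefse_select(lefse_records)
        log["stages"]["difftaxa"] = {"n_taxa": len(meta_records),
                                     "n_biomarkers": len(biomarkers)}

        # (6) signature -> MDI -> correlations -> ROC
        stage = "mdi"
        if config.signature_source == "escc":
            signature = escc_signature()
        else:
            signature = derive_signature(biomarkers)
        signature.to_frame().to_csv(out / "signature.tsv", sep="\t", index=False)
        rel_pt = genus_pt.to_relative()
        mdi_res = mdi(rel_pt, signature)
        _write_tsv(mdi_res.values.to_frame(), out / "mdi.tsv",
                   index_label="sample_id")
        richness = adiv.loc[mdi_res.values.index, "observed_otus"]
        corr_alpha = correlate_mdi_alpha(
            mdi_res, richness, seed=_stage_seed(config.seed, "mdi_alpha"))
        dm_w = dists["weighted"]
        keep = [i for i, s in enumerate(dm_w.ids) if s in set(mdi_res.values.index)]
        dm_pt = DistanceMatrix([dm_w.ids[i] for i in keep],
                               dm_w.values[np.ix_(keep, keep)])
        corr_beta = mdi_vs_beta(mdi_res, dm_pt, n_perm=config.n_perm,
                                seed=_stage_seed(config.seed, "mdi_beta"))
        roc = roc_with_ci(mdi_res.values, pn_t_meta, positive_label="T",
                          n_boot=config.n_boot,
                          seed=_stage_seed(config.seed, "roc"))
        roc_payload = {
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "p_value": roc.p_value, "positive_label": roc.positive_label,
            "ci_method": roc.ci_method, "n_boot": roc.n_boot,
            "pseudocount": mdi_res.pseudocount,
            "missing_signature_genera": {
                "increased": mdi_res.missing_increased,
                "decreased": mdi_res.missing_decreased},
            "mdi_vs_observed_otus": {"r": corr_alpha.statistic,
                                     "p": corr_alpha.p_value},
            "mdi_vs_weighted_unifrac": {"mantel_r": corr_beta.statistic,
                                        "p": corr_beta.p_value},
        }
        (out / "roc.json").write_text(json.dumps(roc_payload, indent=2,
                                                 sort_keys=True) + "\n")
        log["stages"]["mdi"] = {"signature_size": [len(signature.increased),
                                                   len(signature.decreased)],
                                "auc": roc.auc}
        bundle.update(table=table, metadata=metadata, tree=tree,
                      alpha=adiv, distances=dists, diff=diff,
                      signature=signature, mdi=mdi_res, roc=roc,
                      mdi_vs_alpha=corr_alpha, mdi_vs_beta=corr_beta,
                      anosim=beta_log, alpha_tests=alpha_tests)
    except Exception as exc:  # annotate the failing stage, keep partial output
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True)
                                      + "\n")
    bundle["run_log"] = log
    return bundle


def summarize(out_dir) -> str:
    """Markdown report with the headline numbers of a finished bundle."""
    out = Path(out_dir)
    for f in ("run_log.json", "roc.json"):
        if not (out / f).exists():
            raise FileNotFoundError(f"missing {f} in {out}")
    log = json.loads((out / "run_log.json").read_text())
    roc = json.loads((out / "roc.json").read_text())
    lines = ["# Dysbiosis analysis summary", ""]
    beta_sig = False
    for name, entry in log["stages"].get("beta", {}).items():
        lines.append(f"- ANOSIM ({name} UniFrac): R = {entry['anosim_R']:.4f}, "
                     f"p = {entry['p']:.4g}")
        beta_sig = beta_sig or entry["p"] <= 0.05
    lines.append(f"- MDI ROC: AUC = {roc['auc']:.4f} "
                 f"(95% CI {roc['ci_low']:.4f}-{roc['ci_high']:.4f}, "
                 f"p = {roc['p_value']:.4g})")
    ra = roc["mdi_vs_observed_otus"]
    lines.append(f"- MDI vs observed OTUs: r = {ra['r']:.4f}, p = {ra['p']:.4g}")
    rb = roc["mdi_vs_weighted_unifrac"]
    lines.append(f"- MDI vs weighted UniFrac (Mantel): r = {rb['mantel_r']:.4f}, "
                 f"p = {rb['p']:.4g}")
    auc_informative = not (roc["ci_low"] <= 0.5 <= roc["ci_high"])
    if not beta_sig and not auc_informative:
        lines.append("")
        lines.append("No significant dysbiosis detected: group structure and "
                     "MDI discrimination are consistent with the null.")
    if (out / "signature.tsv").exists():
        sig = pd.read_csv(out / "signature.tsv", sep="\t")
        inc = (sig["direction"] == "increased").sum()
        dec = (sig["direction"] == "decreased").sum()
        lines.append("")
        lines.append(f"Signature: {inc} increased / {dec} decreased genera.")
    return "\n".join(lines) + "\n"
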