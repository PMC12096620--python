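"""End-to-end orchestration of the two analysis pipelines.

IHC4 pipeline:  QC → 0–15 normalization → ER/PR/HER2 binning and per-core
histoscores + Ki67 positivity → graph clustering of cell co-expression →
per-case alpha/beta diversity → subtype comparisons.

Immune pipeline: QC → Z-score normalization → control-based thresholds →
gating → patch composition → niche phenotyping → per-core phenotype
fractions → subtype comparisons.

Every intermediate table is written to the output directory as CSV with a
provenance header; the run refuses to overwrite an existing directory
unless forced.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, diversity, panels, patches, preprocess, scoring, stats, synthetic
from .errors import ConfigError
from .io import RunConfig, read_cell_table, read_table, write_table

log = logging.getLogger(__name__)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run both pipelines and return the output directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.force:
        raise ConfigError(f"output directory {out} exists; pass force=True/--force to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    chash = cfg.config_hash()
    cfg.to_yaml(out / "config.yaml")

    if cfg.simulate:
        spec = synthetic.CohortSpec(
            n_cases=cfg.n_cases,
            regions_per_case_range=cfg.regions_per_case_range,
            cells_per_core_range=cfg.cells_per_core_range,
            seed=cfg.seed,
        )
        tables, metadata, truth = synthetic.simulate_cohort(spec)
        ihc4_raw, immune_raw = tables[panels.IHC4], tables[panels.IMMUNE]
        write_table(truth.ihc4, out / "ground_truth_ihc4.csv", chash, cfg.seed)
        write_table(truth.immune, out / "ground_truth_immune.csv", chash, cfg.seed)
    else:
        ihc4_raw = read_cell_table(cfg.ihc4_cells, panel=panels.IHC4)
        immune_raw = read_cell_table(cfg.immune_cells, panel=panels.IMMUNE)
        metadata = read_table(cfg.metadata)
    write_table(metadata, out / "core_metadata.csv", chash, cfg.seed)

    ihc4_outputs = run_ihc4_pipeline(ihc4_raw, metadata, cfg)
    for name, df in ihc4_outputs.items():
        write_table(df, out / f"{name}.csv", chash, cfg.seed)

    immune_outputs = run_immune_pipeline(immune_raw, metadata, cfg)
    for name, df in immune_outputs.items():
        write_table(df, out / f"{name}.csv", chash, cfg.seed)

    log.info("pipeline complete: %s", out)
    return out


def run_ihc4_pipeline(cells: pd.DataFrame, metadata: pd.DataFrame,
                      cfg: RunConfig) -> dict[str, pd.DataFrame]:
    stage = "ihc4/qc+normalize"
    try:
        ncfg = preprocess.NormalizationConfig(panel=panels.IHC4)
        kept = preprocess.qc_filter(cells, ncfg)
        normed, _ = preprocess.normalize(kept, ncfg)

        stage = "ihc4/scoring"
        for marker in ("ER", "PR", "HER2"):
            normed = scoring.bin_cells(normed, scoring.scheme_for(marker))
        score_rows = []
        for core_id in metadata["core_id"]:
            if core_id not in set(normed["core_id"]):
                continue
            for marker in ("ER", "PR", "HER2"):
                r = scoring.histoscore(normed, scoring.scheme_for(marker), core_id)
                score_rows.append({"core_id": core_id, "marker": marker,
                                   "histoscore": r.histoscore, "n_cells": r.n_cells,
                                   **{f"pct_{k}": v for k, v in r.category_percent.items()}})
            score_rows.append({"core_id": core_id, "marker": "Ki67",
                               "histoscore": np.nan,
                               "n_cells": int((normed["core_id"] == core_id).sum()),
                               "pct_positive": scoring.ki67_positivity(normed, core_id)})
        scores = pd.DataFrame(score_rows)

        stage = "ihc4/clustering"
        feat_cols = [panels.norm_col(m) for m in panels.IHC4_MARKERS]
        feats = normed[feat_cols].to_numpy(dtype=float)
        n = len(feats)
        if cfg.k_scan:
            _, result = clustering.select_k(
                feats, clustering.ClusteringConfig(K=min(cfg.cluster_k_cells, n - 1),
                                                   K_scan=cfg.k_scan, seed=cfg.seed),
                feature_names=feat_cols)
        else:
            result = clustering.cluster_features(
                feats, clustering.ClusteringConfig(K=min(cfg.cluster_k_cells, n - 1),
                                                   seed=cfg.seed),
                feature_names=feat_cols)
        normed["cluster"] = result.labels
        centroids = result.centroids.copy()
        centroids["n"] = result.sizes["n"]
        centroids["percent"] = result.sizes["percent"]

        stage = "ihc4/diversity"
        per_case, per_core = diversity.cohort_diversity(normed, metadata, "cluster")

        stage = "ihc4/comparisons"
        comparisons = _subtype_comparisons(scores, per_case, metadata)
        return {"cells_ihc4": normed, "scores_ihc4": scores,
                "cluster_centroids_ihc4": centroids.reset_index(),
                "diversity_cases": per_case, "diversity_cores": per_core,
                "comparisons_ihc4": comparisons}
    except Exception:
        log.error("IHC4 pipeline failed at stage %s", stage)
        raise


def run_immune_pipeline(cells: pd.DataFrame, metadata: pd.DataFrame,
                        cfg: RunConfig) -> dict[str, pd.DataFrame]:
    stage = "immune/qc+normalize"
    try:
        ncfg = preprocess.NormalizationConfig(panel=panels.IMMUNE)
        kept = preprocess.qc_filter(cells, ncfg)
        normed, nstats = preprocess.normalize(kept, ncfg)

        stage = "immune/thresholds+gating"
        control, _ = synthetic.simulate_tonsil_control(seed=cfg.seed + 1)
        log2_ctrl = control.copy()
        for m in panels.GATED_IMMUNE_MARKERS:
            log2_ctrl[m] = np.log2(control[m] + 1.0)
        raw_thr = scoring.estimate_thresholds(log2_ctrl, panels.GATED_IMMUNE_MARKERS)
        thr = {m: nstats.transform_log2(m, t) for m, t in raw_thr.items()}
        gated = scoring.gate_immune(normed, scoring.GatingConfig(thresholds=thr))

        stage = "immune/patches"
        pcfg = patches.PatchConfig(patch_px=cfg.patch_px, pixel_size_um=cfg.pixel_size_um)
        patch_table = patches.assign_patches(gated, pcfg)
        filtered = patches.filter_patches(patch_table, pcfg)

        stage = "immune/phenotyping"
        k = min(cfg.cluster_k_patches, max(1, len(filtered) - 1))
        phenotyped, _, _ = patches.phenotype_patches(
            filtered, clustering.ClusteringConfig(K=k, seed=cfg.seed),
            n_phenotypes=cfg.n_phenotypes)
        fracs = patches.phenotype_fractions(phenotyped)

        stage = "immune/comparisons"
        comparisons = _phenotype_comparisons(fracs, metadata)
        return {"cells_immune": gated, "patches_immune": phenotyped,
                "phenotype_fractions": fracs, "comparisons_immune": comparisons}
    except Exception:
        log.error("Immune pipeline failed at stage %s", stage)
        raise


def _case_subtype(metadata: pd.DataFrame) -> pd.Series:
    """Dominant subtype per case (most frequent call; ties alphabetical)."""
    return metadata.groupby("case_id")["subtype"].agg(
        lambda s: s.value_counts().sort_index().idxmax())


def _subtype_comparisons(scores: pd.DataFrame, per_case: pd.DataFrame,
                         metadata: pd.DataFrame) -> pd.DataFrame:
    rows = []
    core_subtype = metadata.set_index("core_id")["subtype"]
    for marker in ("ER", "PR", "HER2"):
        sub = scores.loc[scores["marker"] == marker].copy()
        sub["subtype"] = sub["core_id"].map(core_subtype)
        rows.append(_anova_row(f"{marker}_histoscore_by_subtype",
                               sub["histoscore"], sub["subtype"]))
    ki = scores.loc[scores["marker"] == "Ki67"].copy()
    ki["subtype"] = ki["core_id"].map(core_subtype)
    rows.append(_anova_row("Ki67_pct_by_subtype", ki["pct_positive"], ki["subtype"]))
    case_subtype = _case_subtype(metadata)
    pc = per_case.copy()
    pc["subtype"] = pc["case_id"].map(case_subtype)
    rows.append(_anova_row("alpha_by_subtype", pc["alpha"], pc["subtype"]))
    beta = pc.dropna(subset=["beta"])
    rows.append(_anova_row("beta_by_subtype", beta["beta"], beta["subtype"]))
    return pd.DataFrame(rows)


def _phenotype_comparisons(fracs: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    rows = []
    core_subtype = metadata.set_index("core_id")["subtype"]
    merged = fracs.copy()
    merged["subtype"] = merged["core_id"].map(core_subtype)
    for col in fracs.columns:
        if col == "core_id":
            continue
        rows.append(_anova_row(f"patch_fraction[{col}]_by_subtype",
                               merged[col], merged["subtype"]))
    return pd.DataFrame(rows)


def _anova_row(feature: str, values: pd.Series, groups: pd.Series) -> dict:
    mask = values.notna() & groups.notna()
    v, g = values[mask].to_numpy(float), groups[mask].to_numpy()
    uniq = pd.unique(g)
    if len(uniq) < 2 or any((g == u).sum() < 2 for u in uniq):
        return {"feature": feature, "test": "anova", "groups": len(uniq),
                "statistic": np.nan, "p_value": np.nan}
    f, p = stats.compare_groups(v, g, "anova")
    return {"feature": feature, "test": "anova", "groups": len(uniq),
            "statistic": f, "p_value": p}
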