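"""Grid-based spatial patch analysis of the immune panel.

Each core image is divided into square patches (default 150 px, i.e.
48.75 μm at 0.325 μm/px). The composition of each patch — the fractions of
cancer-epithelial (CK8/18+) and nine immune lineage phenotypes among its
cells — is the feature vector for niche discovery: patches are clustered
(PhenoGraph-style, K = 30 by default), the fine clusters are aggregated into
a small number of spatial phenotypes, and each core is summarized by the
fraction of its patches assigned to each phenotype.

Sparse patches (fewer than 5 cells) and poorly covered cores (fewer than 10
surviving patches) are excluded before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import clustering, panels
from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

COMPOSITION_COLUMNS = [f"frac {c}" for c in panels.CELL_CLASSES]


@dataclass(frozen=True)
class PatchConfig:
    """Patch grid geometry and the sparsity filters.

    ``denominator`` controls the composition fractions: ``"all"`` divides by
    every cell in the patch (so fractions over the ten classes sum to ≤ 1
    because unclassified cells count toward the denominator), while
    ``"classified"`` divides by classified cells only.
    """

    patch_px: int = 150
    pixel_size_um: float = 0.325
    min_cells_per_patch: int = 5
    min_patches_per_core: int = 10
    denominator: str = "all"

    def __post_init__(self) -> None:
        if self.patch_px < 1:
            raise ValidationError(f"patch_px must be >= 1, got {self.patch_px}")
        if self.pixel_size_um <= 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.denominator not in ("all", "classified"):
            raise ValidationError("denominator must be 'all' or 'classified'")

    @property
    def patch_side_um(self) -> float:
        """Physical patch side length in μm."""
        return self.patch_px * self.pixel_size_um


def assign_patches(cells: pd.DataFrame, cfg: PatchConfig | None = None) -> pd.DataFrame:
    """Grid the cells of every core into patches and compute compositions.

    The grid is anchored at each core's bounding-box minimum; a cell at
    (x, y) falls into patch (floor((x−x0)/s), floor((y−y0)/s)) with
    half-open intervals. Returns one row per non-empty patch with the cell
    count and the ten composition fractions (unfiltered).
    """
    cfg = cfg or PatchConfig()
    for col in ("core_id", "x", "y", scoring_phenotype_col()):
        if col not in cells.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    if len(cells) == 0:
        return _empty_patch_table()
    df = cells[["core_id", "x", "y", scoring_phenotype_col()]].copy()
    x0 = df.groupby("core_id")["x"].transform("min")
    y0 = df.groupby("core_id")["y"].transform("min")
    df["i"] = np.floor((df["x"] - x0) / cfg.patch_px).astype(int)
    df["j"] = np.floor((df["y"] - y0) / cfg.patch_px).astype(int)

    pheno = df[scoring_phenotype_col()]
    grp = df.groupby(["core_id", "i", "j"], sort=True)
    n_cells = grp.size().rename("n_cells")
    counts = (df.assign(_p=pheno)
                .pivot_table(index=["core_id", "i", "j"], columns="_p",
                             aggfunc="size", fill_value=0))
    for c in panels.CELL_CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    classified = counts[panels.CELL_CLASSES].sum(axis=1)
    denom = n_cells if cfg.denominator == "all" else classified
    out = pd.DataFrame({"n_cells": n_cells})
    for c in panels.CELL_CLASSES:
        out[f"frac {c}"] = np.where(denom > 0, counts[c] / denom.replace(0, 1), 0.0)
    return out.reset_index()


def scoring_phenotype_col() -> str:
    from .scoring import PHENOTYPE_COL
    return PHENOTYPE_COL


def _empty_patch_table() -> pd.DataFrame:
    cols = ["core_id", "i", "j", "n_cells"] + COMPOSITION_COLUMNS
    return pd.DataFrame({c: pd.Series(dtype=object if c == "core_id" else float)
                         for c in cols})


def filter_patches(patch_table: pd.DataFrame, cfg: PatchConfig | None = None) -> pd.DataFrame:
    """Drop sparse patches, then drop cores left with too few patches."""
    cfg = cfg or PatchConfig()
    kept = patch_table.loc[patch_table["n_cells"] >= cfg.min_cells_per_patch]
    n_dropped = len(patch_table) - len(kept)
    per_core = kept.groupby("core_id").size()
    good_cores = per_core.index[per_core >= cfg.min_patches_per_core]
    out = kept.loc[kept["core_id"].isin(good_cores)].reset_index(drop=True)
    log.info("filter_patches: dropped %d sparse patches and %d cores",
             n_dropped, per_core.size - len(good_cores))
    return out


def phenotype_patches(
    patch_table: pd.DataFrame,
    cluster_cfg: clustering.ClusteringConfig | None = None,
    n_phenotypes: int = 8,
) -> tuple[pd.DataFrame, clustering.ClusterResult, clustering.MergeResult]:
    """Cluster patch compositions and aggregate into spatial phenotypes.

    Returns the patch table with ``patch_cluster`` and ``phenotype`` columns
    appended, plus the fine clustering and merge results.
    """
    cluster_cfg = cluster_cfg or clustering.ClusteringConfig(K=clustering.K_PATCHES)
    n = len(patch_table)
    if n <= cluster_cfg.K:
        raise ValidationError(
            f"only {n} patches for K={cluster_cfg.K}; use a smaller K")
    feats = patch_table[COMPOSITION_COLUMNS].to_numpy(dtype=float)
    result = clustering.cluster_features(feats, cluster_cfg,
                                         feature_names=panels.CELL_CLASSES)
    n_groups = min(n_phenotypes, result.n_clusters)
    if n_groups < n_phenotypes:
        log.warning("only %d fine clusters; merging to %d phenotypes instead of %d",
                    result.n_clusters, n_groups, n_phenotypes)
    merge = clustering.merge_clusters(result, n_groups)
    out = patch_table.copy()
    out["patch_cluster"] = result.labels
    group = np.array([merge.merge_map[c] for c in result.labels])
    out["phenotype"] = [merge.group_names[g] for g in group]
    return out, result, merge


def phenotype_fractions(patch_table: pd.DataFrame) -> pd.DataFrame:
    """Per-core fraction of patches carrying each spatial phenotype.

    Fractions are over the surviving (filtered) patches of the core and sum
    to 1 per core.
    """
    if "phenotype" not in patch_table.columns:
        raise SchemaError("patch table has no 'phenotype' column; run phenotype_patches")
    counts = (patch_table.pivot_table(index="core_id", columns="phenotype",
                                      aggfunc="size", fill_value=0))
    fracs = counts.div(counts.sum(axis=1), axis=0)
    fracs.columns.name = None
    return fracs.reset_index()


def with_patch_config(cfg: PatchConfig, **kwargs) -> PatchConfig:
    return replace(cfg, **kwargs)
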