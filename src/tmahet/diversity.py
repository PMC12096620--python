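"""Alpha/beta decomposition of cell-cluster diversity via Rao's quadratic
entropy.

Each TMA core is a "community" whose "species" are the cell cluster groups;
with the identity dissimilarity (d_ij = 1 − δ_ij, no phylogenetic tree) Rao's
quadratic entropy of a composition p reduces to the Simpson diversity index

    alpha = 1 − Σ_i p_i² .

For a case with several cores, alpha diversity is the (cell-count-weighted)
mean of per-core Simpson indices — intra-core heterogeneity — and total
diversity is the Simpson index of the pooled composition. Beta diversity,
the among-core (intra-tumoral) component, is their difference:

    beta = total − alpha ≥ 0 .

The pairwise among-community dissimilarity D_kl = 1 − Σ_i p_ki p_li is also
reported, since "average among-community diversity" admits both readings;
the additive decomposition is the headline value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

CELL_COUNT = "cell_count"
EQUAL = "equal"


@dataclass
class CompositionVector:
    """Cluster-composition of one community (core)."""

    community_id: str
    proportions: np.ndarray
    n_cells: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValidationError(f"community {self.community_id}: proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"community {self.community_id}: proportions sum to {p.sum():.12f}, not 1")
        if self.n_cells < 1:
            raise ValidationError(f"community {self.community_id}: n_cells must be >= 1")
        self.proportions = p


@dataclass
class DiversityResult:
    alpha_per_community: dict[str, float]
    alpha: float
    total: float
    beta: float
    pairwise: pd.DataFrame


def simpson_alpha(comp: CompositionVector) -> float:
    """Simpson diversity 1 − Σ p_i² of one community."""
    return float(1.0 - (comp.proportions ** 2).sum())


def rao_decomposition(communities: list[CompositionVector],
                      weights: str = CELL_COUNT) -> DiversityResult:
    """Additive alpha/total/beta decomposition over a set of communities.

    ``weights='cell_count'`` (default) weights communities by their cell
    counts both in the mean alpha and in the pooled composition, so the
    decomposition is exactly the cell-level Simpson partition and beta ≥ 0.
    ``weights='equal'`` treats every community equally.
    """
    if len(communities) == 0:
        raise ValidationError("at least one community required")
    k = len(communities[0].proportions)
    if any(len(c.proportions) != k for c in communities):
        raise ValidationError("communities must share one species space")
    if weights == CELL_COUNT:
        w = np.array([c.n_cells for c in communities], dtype=float)
    elif weights == EQUAL:
        w = np.ones(len(communities))
    else:
        raise ValidationError(f"weights must be '{CELL_COUNT}' or '{EQUAL}', got {weights!r}")
    w = w / w.sum()

    alphas = {c.community_id: simpson_alpha(c) for c in communities}
    alpha = float(sum(wi * alphas[c.community_id] for wi, c in zip(w, communities)))
    pooled = np.sum([wi * c.proportions for wi, c in zip(w, communities)], axis=0)
    total = float(1.0 - (pooled ** 2).sum())
    beta = total - alpha

    ids = [c.community_id for c in communities]
    P = np.vstack([c.proportions for c in communities])
    D = 1.0 - P @ P.T
    pairwise = pd.DataFrame(D, index=ids, columns=ids)
    return DiversityResult(alpha_per_community=alphas, alpha=alpha,
                           total=total, beta=beta, pairwise=pairwise)


def compositions_from_labels(cells: pd.DataFrame, label_col: str,
                             species: list | None = None) -> list[CompositionVector]:
    """Build per-core composition vectors over the global label set."""
    if species is None:
        species = sorted(pd.unique(cells[label_col]))
    out = []
    for core_id, sub in cells.groupby("core_id", sort=True):
        counts = sub[label_col].value_counts()
        p = np.array([counts.get(s, 0) for s in species], dtype=float)
        out.append(CompositionVector(str(core_id), p / p.sum(), n_cells=len(sub)))
    return out


def cohort_diversity(cells: pd.DataFrame, metadata: pd.DataFrame,
                     label_col: str = "cluster",
                     weights: str = CELL_COUNT) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case alpha (intra-core) and beta (intra-tumoral) heterogeneity.

    Every analysed cell must carry ``label_col`` and a core id present in
    ``metadata``. Cases with a single analysed core report beta as missing
    (NaN), not zero. Returns ``(per_case, per_core)`` tables.
    """
    if label_col not in cells.columns:
        raise ValidationError(f"cells are missing the {label_col!r} label column")
    species = sorted(pd.unique(cells[label_col]))
    core_to_case = metadata.set_index("core_id")["case_id"]
    case_rows, core_rows = [], []
    for case_id, case_meta in metadata.groupby("case_id", sort=True):
        core_ids = [c for c in case_meta["core_id"] if c in set(cells["core_id"])]
        sub = cells.loc[cells["core_id"].isin(core_ids)]
        if len(sub) == 0:
            continue
        comps = compositions_from_labels(sub, label_col, species)
        res = rao_decomposition(comps, weights=weights)
        for cid, a in res.alpha_per_community.items():
            core_rows.append({"case_id": case_id, "core_id": cid, "alpha": a})
        case_rows.append({
            "case_id": case_id, "n_cores": len(comps), "alpha": res.alpha,
            "total": res.total if len(comps) >= 2 else res.alpha,
            "beta": res.beta if len(comps) >= 2 else np.nan,
            "mean_pairwise_D": (float(res.pairwise.to_numpy()[
                np.triu_indices(len(comps), k=1)].mean()) if len(comps) >= 2 else np.nan),
        })
    per_case = pd.DataFrame(case_rows)
    per_core = pd.DataFrame(core_rows)
    if not per_core.empty:
        per_core["case_id"] = per_core["core_id"].map(core_to_case).fillna(per_core["case_id"])
    return per_case, per_core
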