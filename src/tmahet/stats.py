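"""Cohort-level labels and group comparisons.

A case whose analysed regions carry more than one molecular subtype call is
molecularly *polytypic*; otherwise *monotypic*. Group comparisons mirror the
analysis conventions of per-core TMA studies: classic one-way fixed-effects
ANOVA on per-core values (cores treated as independent), the two-sample
Wilcoxon rank-sum test (exact for small samples), and Pearson/Spearman
correlations. Raw p-values are reported; an optional Benjamini–Hochberg
adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

MONOTYPIC = "monotypic"
POLYTYPIC = "polytypic"


@dataclass
class CohortSummary:
    n_cases: int
    n_polytypic: int
    percent_polytypic: float
    category_percent: dict[str, dict[str, float]]


def classify_typy(metadata: pd.DataFrame,
                  clinical: pd.DataFrame | None = None) -> tuple[pd.DataFrame, CohortSummary]:
    """Label each case monotypic/polytypic and summarize the cohort.

    ``metadata`` needs ``case_id`` and per-core ``subtype`` columns; cases
    with no analysed core are excluded. ``clinical`` may add per-case
    categorical columns (e.g. IHC category, grade) whose percentage
    breakdowns are included in the summary.
    """
    if metadata["subtype"].isna().any():
        raise ValidationError("every analysed core needs a subtype call")
    rows = []
    for case_id, sub in metadata.groupby("case_id", sort=True):
        calls = sorted(set(sub["subtype"]))
        rows.append({"case_id": case_id, "n_regions": len(sub),
                     "subtype_calls": "|".join(calls),
                     "typy": POLYTYPIC if len(calls) >= 2 else MONOTYPIC})
    labels = pd.DataFrame(rows)
    n = len(labels)
    n_poly = int((labels["typy"] == POLYTYPIC).sum())
    cats: dict[str, dict[str, float]] = {
        "typy": {POLYTYPIC: 100.0 * n_poly / n, MONOTYPIC: 100.0 * (n - n_poly) / n}
    }
    if clinical is not None:
        merged = labels.merge(clinical, on="case_id", how="left")
        for col in clinical.columns:
            if col == "case_id":
                continue
            vc = merged[col].value_counts()
            cats[col] = {str(k): 100.0 * v / n for k, v in vc.items()}
    summary = CohortSummary(n_cases=n, n_polytypic=n_poly,
                            percent_polytypic=100.0 * n_poly / n,
                            category_percent=cats)
    return labels, summary


def compare_groups(values: np.ndarray, groups: np.ndarray,
                   test: str = "anova") -> tuple[float, float]:
    """One-way ANOVA or two-sample Wilcoxon rank-sum across groups.

    Returns (statistic, p-value). The rank-sum test is exact for combined
    n ≤ 20 and uses the tie-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    ok = ~np.isnan(values)  # missing values do not count toward a group
    samples = [values[(groups == g) & ok] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("every group needs at least one value")
    if test == "anova":
        if len(samples) < 2:
            raise ValidationError("ANOVA needs at least 2 groups")
        res = sps.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        if len(samples) != 2:
            raise ValidationError(f"rank-sum test needs exactly 2 groups, got {len(samples)}")
        a, b = samples
        method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"test must be 'anova' or 'wilcoxon', got {test!r}")


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation of paired values (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; comparisons default to raw p)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = ranked
    return out
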