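"""Clinical-style scoring of normalized intensities.

Three quantifications are implemented on the 0–15 range-normalized IHC4
scale:

* intensity binning of ER/PR (negative, 1+, 2+, 3+) and HER2 (0, 1+, 2+, 3+),
* the per-core histoscore H = 3·(%3+) + 2·(%2+) + (%1+), range 0–300,
* Ki67 positivity (% of cancer cells with normalized Ki67 > 0).

On the Z-scored Immune scale, cells are gated into one cancer (CK8/18+) and
nine immune lineage phenotypes by binary marker thresholds; thresholds can
be estimated from an on-slide tonsil control via the valley between the two
modes of each marker's intensity distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from . import panels
from .errors import ConfigError, SchemaError, ValidationError

log = logging.getLogger(__name__)

NEGATIVE = "negative"
CATEGORY_COL = "{marker}_bin"
PHENOTYPE_COL = "phenotype"


@dataclass(frozen=True)
class BinScheme:
    """Ordered intensity categories on the 0–15 normalized scale.

    ``edges`` lists ``(label, lower, upper, lower_inclusive, upper_inclusive)``
    tuples that must partition the marker's value range.
    """

    marker: str
    edges: tuple[tuple[str, float, float, bool, bool], ...]

    def __post_init__(self) -> None:
        los = [e[1] for e in self.edges]
        if los != sorted(los):
            raise ValidationError(f"bin scheme for {self.marker}: edges must be increasing")

    def assign(self, values: np.ndarray) -> np.ndarray:
        out = np.full(len(values), None, dtype=object)
        for label, lo, hi, lo_inc, hi_inc in self.edges:
            above = values >= lo if lo_inc else values > lo
            below = values <= hi if hi_inc else values < hi
            sel = above & below & (out == None)  # noqa: E711  — first matching bin wins
            out[sel] = label
        return out


#: ER/PR: negative at exactly 0; 1+ on (0, 7); 2+ on [7, 12]; 3+ on (12, 15]
ER_PR_SCHEME = BinScheme(
    marker="ER",
    edges=(
        (NEGATIVE, 0.0, 0.0, True, True),
        ("1+", 0.0, 7.0, False, False),
        ("2+", 7.0, 12.0, True, True),
        ("3+", 12.0, 15.0, False, True),
    ),
)

#: HER2: 0 on [0, 5]; 1+ on (5, 10]; 2+ on (10, 13); 3+ on [13, 15]
#: (the printed 2+/3+ ranges overlap at 13; 13 is scored 3+ by convention)
HER2_SCHEME = BinScheme(
    marker="HER2",
    edges=(
        ("0", 0.0, 5.0, True, True),
        ("1+", 5.0, 10.0, False, True),
        ("2+", 10.0, 13.0, False, False),
        ("3+", 13.0, 15.0, True, True),
    ),
)

POSITIVE_BINS = ("1+", "2+", "3+")
BIN_WEIGHTS = {"3+": 3.0, "2+": 2.0, "1+": 1.0}


def scheme_for(marker: str) -> BinScheme:
    if marker == "HER2":
        return dataclasses_replace_marker(HER2_SCHEME, marker)
    return dataclasses_replace_marker(ER_PR_SCHEME, marker)


def dataclasses_replace_marker(scheme: BinScheme, marker: str) -> BinScheme:
    return BinScheme(marker=marker, edges=scheme.edges)


def bin_cells(cells: pd.DataFrame, scheme: BinScheme) -> pd.DataFrame:
    """Assign each cell one intensity category for ``scheme.marker``.

    Operates on the ``<marker>_norm`` column, which must lie in [0, 15].
    """
    col = panels.norm_col(scheme.marker)
    if col not in cells.columns:
        raise SchemaError(f"cell table is missing normalized column {col!r}")
    vals = cells[col].to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 15).any():
        raise ValidationError(
            f"{col} has values outside [0, 15]; run range normalization first")
    out = cells.copy()
    labels = scheme.assign(vals)
    if (labels == None).any():  # noqa: E711
        raise ValidationError(f"bin scheme for {scheme.marker} does not cover all values")
    out[CATEGORY_COL.format(marker=scheme.marker)] = labels
    return out


@dataclass
class ScoreResult:
    """Histoscore of one marker in one core."""

    core_id: str
    marker: str
    histoscore: float
    category_percent: dict[str, float]
    n_cells: int


def histoscore(cells: pd.DataFrame, scheme: BinScheme, core_id: str) -> ScoreResult:
    """H = 3·(%3+) + 2·(%2+) + (%1+) over the binned cells of one core."""
    col = CATEGORY_COL.format(marker=scheme.marker)
    sub = cells.loc[cells["core_id"] == core_id]
    if len(sub) == 0:
        raise ValidationError(f"core {core_id}: no scored cells")
    if col not in sub.columns:
        raise SchemaError(f"cells are not binned for {scheme.marker} (missing {col!r})")
    counts = sub[col].value_counts()
    pct = {label: 100.0 * counts.get(label, 0) / len(sub)
           for label, *_ in scheme.edges}
    h = sum(BIN_WEIGHTS.get(label, 0.0) * p for label, p in pct.items())
    return ScoreResult(core_id=core_id, marker=scheme.marker, histoscore=h,
                       category_percent=pct, n_cells=len(sub))


def ki67_positivity(cells: pd.DataFrame, core_id: str,
                    cancer_mask: pd.Series | None = None) -> float:
    """Percentage of cancer cells with normalized Ki67 > 0 in one core.

    ``cancer_mask`` selects the cancer (CK8/18+) cells; if omitted, all cells
    of the core are treated as cancer cells.
    """
    sub = cells.loc[cells["core_id"] == core_id]
    if cancer_mask is not None:
        sub = sub.loc[cancer_mask.reindex(sub.index, fill_value=False)]
    if len(sub) == 0:
        raise ValidationError(f"core {core_id}: no cancer cells for Ki67 positivity")
    vals = sub[panels.norm_col("Ki67")].to_numpy(dtype=float)
    return 100.0 * float((vals > 0).sum()) / len(sub)


# ---------------------------------------------------------------------------
# immune gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    @property
    def n_constrained(self) -> int:
        return len(self.positive) + len(self.negative)


def default_gates() -> list[Gate]:
    """The cancer gate plus nine immune lineage gates.

    Most-specific-first resolution is applied downstream; FoxP3 is measured
    but not constrained by any default gate.
    """
    return [
        Gate("CD3+/CD8+/PD1+", ("CD3", "CD8", "PD1")),
        Gate("CD3+/CD8-/PD1+", ("CD3", "PD1"), ("CD8",)),
        Gate("CD3+/CD8+", ("CD3", "CD8"), ("PD1",)),
        Gate("CD3+/CD8-", ("CD3",), ("CD8", "PD1")),
        Gate("CD68+/CD163+", ("CD68", "CD163")),
        Gate("CD68+/PDL1+", ("CD68", "PDL1"), ("CD163",)),
        Gate("CD163+/PDL1+", ("CD163", "PDL1"), ("CD68",)),
        Gate("CD68+", ("CD68",), ("CD163", "PDL1")),
        Gate("CD163+", ("CD163",), ("CD68", "PDL1")),
        Gate("CK+", (panels.CK,)),
    ]


@dataclass
class GatingConfig:
    """Binary thresholds (Z-score units) and the ordered gate list."""

    thresholds: dict[str, float] = field(default_factory=dict)
    gates: list[Gate] = field(default_factory=default_gates)
    default_threshold: float = 0.0

    def threshold_for(self, marker: str) -> float:
        return self.thresholds.get(marker, self.default_threshold)

    def ordered_gates(self) -> list[Gate]:
        """Most-specific-first: by number of constrained markers, descending;
        ties keep listed order."""
        order = sorted(range(len(self.gates)),
                       key=lambda i: (-self.gates[i].n_constrained, i))
        out = [self.gates[i] for i in order]
        labels = [g.label for g in out]
        if len(set(labels)) != len(labels):
            raise ConfigError("gate labels must be unique")
        return out


def gate_immune(cells: pd.DataFrame, cfg: GatingConfig | None = None) -> pd.DataFrame:
    """Assign each cell exactly one phenotype label.

    Thresholding is applied to the Z-normalized marker columns; the first
    satisfied gate in most-specific-first order wins and unmatched cells are
    labelled ``other``.
    """
    cfg = cfg or GatingConfig()
    out = cells.copy()
    markers = sorted({m for g in cfg.gates for m in (*g.positive, *g.negative)})
    pos: dict[str, np.ndarray] = {}
    for m in markers:
        col = panels.norm_col(m)
        if col not in out.columns:
            raise SchemaError(f"cell table is missing normalized column {col!r}")
        pos[m] = out[col].to_numpy(dtype=float) > cfg.threshold_for(m)
    labels = np.full(len(out), panels.OTHER, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for gate in cfg.ordered_gates():
        sel = unassigned.copy()
        for m in gate.positive:
            sel &= pos[m]
        for m in gate.negative:
            sel &= ~pos[m]
        labels[sel] = gate.label
        unassigned &= ~sel
    out[PHENOTYPE_COL] = labels
    return out


# ---------------------------------------------------------------------------
# threshold estimation from control tissue
# ---------------------------------------------------------------------------

def estimate_thresholds(
    control: pd.DataFrame,
    markers: list[str],
    manual: dict[str, float] | None = None,
    fallback: float = 0.0,
    grid_size: int = 512,
) -> dict[str, float]:
    """Per-marker thresholds at the density valley of a bimodal control.

    Operates on whatever scale the given columns carry (log2 or Z-score);
    the returned threshold is on that same scale. A Gaussian KDE is evaluated
    on a grid and the threshold placed at the density minimum between the two
    most prominent modes. Markers with an effectively unimodal control fall
    back to ``fallback`` with a warning. ``manual`` entries are returned
    verbatim without estimation.
    """
    manual = manual or {}
    out: dict[str, float] = {}
    for m in markers:
        if m in manual:
            out[m] = manual[m]
            continue
        if m not in control.columns:
            raise SchemaError(f"control table is missing marker column {m!r}")
        vals = control[m].to_numpy(dtype=float)
        kde = gaussian_kde(vals)
        grid = np.linspace(vals.min(), vals.max(), grid_size)
        dens = kde(grid)
        peaks, props = find_peaks(dens, prominence=0.05 * dens.max())
        if len(peaks) < 2:
            log.warning("marker %s: control distribution unimodal; using fallback %.3f",
                        m, fallback)
            out[m] = fallback
            continue
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        lo, hi = int(top2.min()), int(top2.max())
        valley = lo + int(np.argmin(dens[lo:hi + 1]))
        out[m] = float(grid[valley])
        log.info("marker %s: valley threshold %.3f", m, out[m])
    return out
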