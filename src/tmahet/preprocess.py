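"""QC filtering and intensity normalization of raw single-cell tables.

Cells with a DAPI signal below 1000 raw units are treated as damaged nuclei
and removed. Marker intensities are then log2-transformed and normalized:
min–max scaled onto a 0–15 range for the IHC4 panel (the scale on which the
histoscore bin thresholds are defined), or Z-scored for the Immune panel
(the scale on which gating thresholds are defined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panels
from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

RANGE_0_15 = "range_0_15"
ZSCORE = "zscore"

#: default normalization mode per panel
DEFAULT_MODE = {panels.IHC4: RANGE_0_15, panels.IMMUNE: ZSCORE}


@dataclass(frozen=True)
class NormalizationConfig:
    """Normalization settings for one panel.

    ``mode`` defaults to the panel convention (0–15 range for IHC4, Z-score
    for Immune). ``log_offset`` is added before log2 so raw zeros stay
    finite. ``percentile_clip`` optionally winsorizes the log2 values at the
    (p, 100−p) percentiles before range scaling, for robustness to outliers;
    it is off (0) by default. ``per_core`` switches scaling scope from
    global-per-marker (default) to per core.
    """

    panel: str = panels.IHC4
    mode: str | None = None
    log_offset: float = 1.0
    dapi_min: float = 1000.0
    percentile_clip: float = 0.0
    per_core: bool = False

    def __post_init__(self) -> None:
        if self.panel not in panels.PANEL_MARKERS:
            raise ValidationError(f"panel must be one of {sorted(panels.PANEL_MARKERS)}")
        if self.mode is not None and self.mode not in (RANGE_0_15, ZSCORE):
            raise ValidationError(f"mode must be {RANGE_0_15!r} or {ZSCORE!r}, got {self.mode!r}")
        if self.log_offset < 0:
            raise ValidationError(f"log_offset must be >= 0, got {self.log_offset}")
        if not (0.0 <= self.percentile_clip < 50.0):
            raise ValidationError("percentile_clip must lie in [0, 50)")

    @property
    def effective_mode(self) -> str:
        return self.mode if self.mode is not None else DEFAULT_MODE[self.panel]


def qc_filter(cells: pd.DataFrame, cfg: NormalizationConfig | None = None) -> pd.DataFrame:
    """Drop cells whose DAPI intensity is below the damaged-nucleus cutoff.

    Strictly-below: a cell exactly at the cutoff is retained. The number of
    removed cells is logged.
    """
    cfg = cfg or NormalizationConfig()
    if panels.DAPI not in cells.columns:
        raise SchemaError(f"cell table is missing required column {panels.DAPI!r}")
    dapi = pd.to_numeric(cells[panels.DAPI], errors="coerce")
    if dapi.isna().any() or (dapi < 0).any():
        raise SchemaError("DAPI column must be numeric and non-negative")
    keep = dapi >= cfg.dapi_min
    n_removed = int((~keep).sum())
    log.info("qc_filter: removed %d of %d cells (DAPI < %g)", n_removed, len(cells), cfg.dapi_min)
    return cells.loc[keep].reset_index(drop=True)


@dataclass
class NormalizationStats:
    """Per-marker transform parameters, recorded so external values (e.g.
    control-tissue thresholds) can be mapped onto the normalized scale."""

    mode: str
    log_offset: float
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    # range_0_15: (log2 min, log2 max); zscore: (mean, sd) of log2 values

    def transform_log2(self, marker: str, value: float) -> float:
        """Map a log2 raw-intensity value onto the normalized scale."""
        a, b = self.params[marker]
        if self.mode == RANGE_0_15:
            return 15.0 * (value - a) / (b - a)
        return (value - a) / b


def normalize(
    cells: pd.DataFrame,
    cfg: NormalizationConfig | None = None,
    markers: list[str] | None = None,
) -> tuple[pd.DataFrame, NormalizationStats]:
    """log2-transform and scale marker intensities; raw columns are kept.

    Returns the table with ``<marker>_norm`` columns appended and the fitted
    :class:`NormalizationStats`. Scaling is global per marker across all
    cells in the run unless ``cfg.per_core`` is set.
    """
    cfg = cfg or NormalizationConfig()
    markers = panels.PANEL_MARKERS[cfg.panel] if markers is None else markers
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise SchemaError(f"cell table is missing marker columns {missing}")
    out = cells.copy()
    stats = NormalizationStats(mode=cfg.effective_mode, log_offset=cfg.log_offset)

    def _scale(log2_vals: np.ndarray, marker: str) -> np.ndarray:
        if cfg.percentile_clip > 0:
            lo, hi = np.percentile(log2_vals, [cfg.percentile_clip, 100 - cfg.percentile_clip])
            log2_vals = np.clip(log2_vals, lo, hi)
        if cfg.effective_mode == RANGE_0_15:
            mn, mx = float(log2_vals.min()), float(log2_vals.max())
            if mx == mn:
                log.warning("marker %s is constant; range-normalized values set to 0", marker)
                stats.params[marker] = (mn, mn + 1.0)
                return np.zeros_like(log2_vals)
            stats.params[marker] = (mn, mx)
            # clip so the [0, 15] bound holds exactly despite rounding
            return np.clip(15.0 * (log2_vals - mn) / (mx - mn), 0.0, 15.0)
        mean, sd = float(log2_vals.mean()), float(log2_vals.std(ddof=0))
        if sd == 0.0:
            raise ValidationError(f"marker {marker} is constant; Z-score undefined")
        stats.params[marker] = (mean, sd)
        return (log2_vals - mean) / sd

    for m in markers:
        raw = pd.to_numeric(out[m], errors="coerce").to_numpy(dtype=float)
        if np.isnan(raw).any() or (raw < 0).any():
            raise SchemaError(f"marker {m} has negative or non-numeric raw intensities")
        log2_vals = np.log2(raw + cfg.log_offset)
        if cfg.per_core:
            vals = np.empty_like(log2_vals)
            for _, idx in out.groupby("core_id").indices.items():
                vals[idx] = _scale(log2_vals[idx], m)
        else:
            vals = _scale(log2_vals, m)
        out[panels.norm_col(m)] = vals
    return out, stats
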