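"""Table I/O, schema validation and run configuration.

All tables are plain CSV/TSV with a header. Output CSVs carry a provenance
comment line (``# tmahet …``) recording the config hash and seed; readers
skip ``#`` comment lines, so round trips are lossless.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import panels
from .errors import ConfigError, SchemaError


def sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = ""
        for line in fh:
            if not line.startswith("#"):
                sample = line
                break
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_cell_table(path: str | Path, panel: str | None = None,
                    require_normalized: bool = False) -> pd.DataFrame:
    """Read and validate a per-cell table (CSV or TSV, auto-detected).

    With ``panel`` given, the panel's required columns are enforced and
    intensity columns are checked numeric (the error names the first bad
    row). Unknown columns are preserved as passthrough.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sniff_delimiter(path), comment="#")
    if panel is not None:
        cols = panels.required_columns(panel)
        if require_normalized:
            cols = cols + [panels.norm_col(m) for m in panels.PANEL_MARKERS[panel]]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing required column(s) {missing}")
        for m in [panels.DAPI] + panels.PANEL_MARKERS[panel]:
            vals = pd.to_numeric(df[m], errors="coerce")
            if vals.isna().any():
                row = int(vals.index[vals.isna()][0]) + 2  # +header +1-based
                raise SchemaError(f"{path.name}: non-numeric {m} intensity at line {row}")
            df[m] = vals
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=sniff_delimiter(path), comment="#")


def write_table(df: pd.DataFrame, path: str | Path,
                config_hash: str = "none", seed: int | None = None) -> None:
    """Write a CSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# tmahet config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (both panels).

    Either a simulated cohort (``simulate=True``, the default) or paths to
    existing cell/metadata tables.
    """

    out_dir: str = "tmahet_out"
    seed: int = 0
    simulate: bool = True
    ihc4_cells: str | None = None
    immune_cells: str | None = None
    metadata: str | None = None
    n_cases: int = 3
    regions_per_case_range: tuple[int, int] = (2, 4)
    cells_per_core_range: tuple[int, int] = (250, 450)
    cluster_k_cells: int = 100
    cluster_k_patches: int = 30
    k_scan: tuple[int, ...] | None = None
    n_phenotypes: int = 8
    patch_px: int = 150
    pixel_size_um: float = 0.325
    log_level: str = "INFO"
    force: bool = False
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("ihc4_cells", "immune_cells", "metadata"):
                if getattr(self, name) is None:
                    raise ConfigError(f"simulate=False requires {name} to be set")
        if self.cluster_k_cells < 1 or self.cluster_k_patches < 1:
            raise ConfigError("cluster K values must be >= 1")
        if self.patch_px < 1:
            raise ConfigError("patch_px must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regions_per_case_range", "cells_per_core_range", "k_scan"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        # hash only analysis-relevant fields: same settings => same hash,
        # wherever the run is written and however verbose it is
        skip = {"force", "out_dir", "log_level"}
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items() if k not in skip}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
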