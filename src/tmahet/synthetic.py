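"""Synthetic multi-region TMA cohorts with full ground truth.

The study design being emulated: whole-mount processed lumpectomies, each
sampled at 2–9 cored regions; every core imaged with two multiplexed panels
(IHC4 and Immune) and exported as a per-cell intensity table. The generator
produces those tables together with a ground-truth record of every cell's
archetype (IHC4 panel), lineage gate label and spatial niche (Immune panel),
so each downstream stage can be validated against known truth.

Model summary
-------------
* Raw intensities are log-normal per marker per cell population (intensities
  are positive, analysed on log2 scale) and clipped to the 16-bit range
  [0, 65535].
* DAPI is drawn from a mixture: a configurable fraction of cells falls below
  the damaged-nucleus QC cutoff of 1000 raw units.
* A case's molecular subtype drives both the mixture weights over cancer-cell
  archetypes (IHC4 panel) and the weights over immune niches (Immune panel);
  by default Luminal A cores are enriched for T-cell-rich niches.
* Cells live inside a circular core footprint. Immune-panel cells are placed
  in isotropic Gaussian niche blobs with Poisson counts; out-of-footprint
  draws are radially clipped to the core boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panels
from .errors import ValidationError

INTENSITY_MAX = 65535.0  # 16-bit camera scale


# ---------------------------------------------------------------------------
# specification objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Sampling design of a synthetic lumpectomy cohort.

    Parameters
    ----------
    n_cases:
        Number of lumpectomy cases.
    regions_per_case_range:
        Inclusive range of cored regions per case; must lie within [2, 9],
        the sampling depth of the emulated design.
    cells_per_core_range:
        Inclusive range of segmented cells per core (per panel).
    subtype_weights:
        Sampling probabilities of the four molecular subtypes for the
        dominant subtype of a case.
    polytypic_fraction:
        Probability that a case is molecularly polytypic, i.e. its regions
        carry more than one subtype call.
    dapi_low_fraction:
        Fraction of cells whose DAPI intensity is drawn below the QC cutoff
        (simulating damaged nuclei that the DAPI filter must remove).
    other_cell_fraction:
        Immune panel only: fraction of cells that belong to none of the ten
        gated classes (stromal/unclassified cells).
    core_radius_px:
        Radius of the circular core footprint, in pixels.
    pixel_size_um:
        Physical pixel size used to convert niche blob radii from μm.
    seed:
        Fully determines the generated cohort.
    """

    n_cases: int = 8
    regions_per_case_range: tuple[int, int] = (2, 5)
    cells_per_core_range: tuple[int, int] = (600, 1200)
    subtype_weights: dict[str, float] = field(
        default_factory=lambda: {"LumA": 0.40, "LumB": 0.28, "HER2E": 0.08, "Basal": 0.24}
    )
    polytypic_fraction: float = 0.342
    dapi_low_fraction: float = 0.10
    other_cell_fraction: float = 0.05
    core_radius_px: float = 450.0
    pixel_size_um: float = 0.325
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.regions_per_case_range
        if not (2 <= lo <= hi <= 9):
            raise ValidationError(
                f"regions_per_case_range must lie within [2, 9], got {self.regions_per_case_range}"
            )
        clo, chi = self.cells_per_core_range
        if not (1 <= clo <= chi):
            raise ValidationError(f"cells_per_core_range invalid: {self.cells_per_core_range}")
        if self.n_cases < 1:
            raise ValidationError(f"n_cases must be >= 1, got {self.n_cases}")
        if set(self.subtype_weights) != set(panels.SUBTYPES):
            raise ValidationError(
                f"subtype_weights must cover {panels.SUBTYPES}, got {sorted(self.subtype_weights)}"
            )
        w = np.array([self.subtype_weights[s] for s in panels.SUBTYPES], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("subtype_weights must be a probability vector summing to 1")
        for name in ("polytypic_fraction", "dapi_low_fraction", "other_cell_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ArchetypeSpec:
    """A cancer-cell population with a log-normal marker intensity profile.

    ``marker_log_means``/``marker_log_sds`` are in log2 raw-intensity units;
    ``prevalence_by_subtype`` gives non-negative mixture weights per molecular
    subtype (normalized per core at draw time).
    """

    name: str
    marker_log_means: dict[str, float]
    marker_log_sds: dict[str, float]
    prevalence_by_subtype: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.marker_log_sds) != set(self.marker_log_means):
            raise ValidationError(f"archetype {self.name}: marker_log_sds keys must match marker_log_means")
        if any(s <= 0 for s in self.marker_log_sds.values()):
            raise ValidationError(f"archetype {self.name}: marker_log_sds must be > 0")
        if any(w < 0 for w in self.prevalence_by_subtype.values()):
            raise ValidationError(f"archetype {self.name}: prevalence_by_subtype must be >= 0")


@dataclass(frozen=True)
class NicheSpec:
    """A recurring local immune/cancer composition pattern.

    ``composition`` is a probability vector over the ten gated cell classes
    (:data:`tmahet.panels.CELL_CLASSES`); ``spatial_blob_radius`` is the
    Gaussian sigma of the niche blob, in μm.
    """

    niche_label: str
    composition: dict[str, float]
    spatial_blob_radius: float = 55.0
    weight_by_subtype: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in panels.SUBTYPES}
    )

    def __post_init__(self) -> None:
        if set(self.composition) - set(panels.CELL_CLASSES):
            raise ValidationError(
                f"niche {self.niche_label}: composition has unknown classes "
                f"{sorted(set(self.composition) - set(panels.CELL_CLASSES))}"
            )
        vals = np.array(list(self.composition.values()), dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"niche {self.niche_label}: composition must sum to 1 (got {vals.sum():.6f})"
            )
        if self.spatial_blob_radius <= 0:
            raise ValidationError(f"niche {self.niche_label}: spatial_blob_radius must be > 0")


@dataclass
class GroundTruth:
    """Per-cell and per-core truth emitted alongside the simulated tables."""

    ihc4: pd.DataFrame       # cell_id, core_id, archetype
    immune: pd.DataFrame     # cell_id, core_id, cell_class, niche
    core_composition: pd.DataFrame  # core_id x archetype fraction (IHC4 panel)


# ---------------------------------------------------------------------------
# default populations
# ---------------------------------------------------------------------------

def default_archetypes(n: int = 5, log_sd: float = 0.35) -> list[ArchetypeSpec]:
    """Five well-separated cancer-cell archetypes spanning the IHC4 space.

    Centroid separations are >= 5 pooled SDs at the default ``log_sd`` so
    graph clustering is expected to recover them exactly.
    """
    profiles = [
        ("ER+PR+_quiescent", {"ER": 12.0, "PR": 12.0, "HER2": 8.0, "Ki67": 6.0, panels.CK: 11.0},
         {"LumA": 0.55, "LumB": 0.15, "HER2E": 0.05, "Basal": 0.02}),
        ("ER+_proliferative", {"ER": 12.0, "PR": 7.0, "HER2": 8.5, "Ki67": 11.0, panels.CK: 11.0},
         {"LumA": 0.10, "LumB": 0.50, "HER2E": 0.10, "Basal": 0.03}),
        ("HER2_high", {"ER": 7.0, "PR": 6.5, "HER2": 12.5, "Ki67": 10.0, panels.CK: 11.0},
         {"LumA": 0.05, "LumB": 0.10, "HER2E": 0.60, "Basal": 0.05}),
        ("basal_like", {"ER": 6.0, "PR": 6.0, "HER2": 7.0, "Ki67": 11.5, panels.CK: 12.0},
         {"LumA": 0.02, "LumB": 0.05, "HER2E": 0.10, "Basal": 0.70}),
        ("luminal_low", {"ER": 9.0, "PR": 9.5, "HER2": 9.5, "Ki67": 8.0, panels.CK: 10.0},
         {"LumA": 0.28, "LumB": 0.20, "HER2E": 0.15, "Basal": 0.20}),
    ]
    specs = [
        ArchetypeSpec(name, means, {m: log_sd for m in means}, prev)
        for name, means, prev in profiles[:n]
    ]
    if len(specs) < n:
        raise ValidationError(f"n must be <= {len(profiles)} default archetypes, got {n}")
    return specs


def default_niches() -> list[NicheSpec]:
    """The eight immune spatial phenotypes the patch analysis should recover.

    They span immune-cold (cancer only; cancer with sparse macrophages) to
    immune-hot (CD68++, CD163++, CD3++, overall immune rich) plus a
    PDL1-expressing-macrophage niche. Luminal A gets a higher T-cell-rich
    niche weight so subtype contrasts are testable end to end.
    """
    base = {s: 1.0 for s in panels.SUBTYPES}
    luma_cd3 = {"LumA": 3.0, "LumB": 0.6, "HER2E": 1.0, "Basal": 1.2}
    return [
        NicheSpec("cancer only",
                  {"CK+": 0.97, "CD3+/CD8-": 0.01, "CD68+": 0.01, "CD163+": 0.01},
                  weight_by_subtype=dict(base)),
        NicheSpec("cancer-CD68",
                  {"CK+": 0.75, "CD68+": 0.20, "CD68+/CD163+": 0.03, "CD3+/CD8-": 0.02},
                  weight_by_subtype=dict(base)),
        NicheSpec("cancer-CD163",
                  {"CK+": 0.75, "CD163+": 0.20, "CD68+/CD163+": 0.03, "CD3+/CD8-": 0.02},
                  weight_by_subtype={"LumA": 0.8, "LumB": 1.6, "HER2E": 1.0, "Basal": 1.0}),
        NicheSpec("CD68++",
                  {"CK+": 0.25, "CD68+": 0.55, "CD68+/CD163+": 0.10, "CD68+/PDL1+": 0.05,
                   "CD163+": 0.05},
                  weight_by_subtype=dict(base)),
        NicheSpec("CD163++",
                  {"CK+": 0.25, "CD163+": 0.55, "CD68+/CD163+": 0.10, "CD163+/PDL1+": 0.05,
                   "CD68+": 0.05},
                  weight_by_subtype=dict(base)),
        NicheSpec("CD3++",
                  {"CK+": 0.25, "CD3+/CD8-": 0.35, "CD3+/CD8+": 0.25, "CD3+/CD8+/PD1+": 0.08,
                   "CD3+/CD8-/PD1+": 0.07},
                  weight_by_subtype=luma_cd3),
        NicheSpec("Immune rich",
                  {"CK+": 0.10, "CD3+/CD8-": 0.15, "CD3+/CD8+": 0.15, "CD68+": 0.15,
                   "CD163+": 0.15, "CD68+/CD163+": 0.10, "CD68+/PDL1+": 0.05,
                   "CD163+/PDL1+": 0.05, "CD3+/CD8+/PD1+": 0.05, "CD3+/CD8-/PD1+": 0.05},
                  weight_by_subtype=dict(base)),
        NicheSpec("PDL1-macrophage",
                  {"CK+": 0.30, "CD68+/PDL1+": 0.30, "CD163+/PDL1+": 0.25, "CD68+": 0.05,
                   "CD163+": 0.05, "CD68+/CD163+": 0.05},
                  weight_by_subtype=dict(base)),
    ]


# which immune markers are positive for each gated cell class
_CLASS_POSITIVE = {
    "CK+": {panels.CK},
    "CD3+/CD8-": {"CD3"},
    "CD3+/CD8+": {"CD3", "CD8"},
    "CD68+": {"CD68"},
    "CD163+": {"CD163"},
    "CD68+/CD163+": {"CD68", "CD163"},
    "CD68+/PDL1+": {"CD68", "PDL1"},
    "CD163+/PDL1+": {"CD163", "PDL1"},
    "CD3+/CD8+/PD1+": {"CD3", "CD8", "PD1"},
    "CD3+/CD8-/PD1+": {"CD3", "PD1"},
    panels.OTHER: set(),
}

# log2 intensity means for marker-positive / marker-negative immune cells;
# 4 log2-unit separation at sd 0.5 keeps gate error well below 1%
IMMUNE_POS_LOG_MEAN = 11.0
IMMUNE_NEG_LOG_MEAN = 7.0
IMMUNE_LOG_SD = 0.5


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _draw_dapi(rng: np.random.Generator, n: int, low_fraction: float) -> np.ndarray:
    """DAPI mixture: damaged nuclei below 1000, intact well above."""
    low = rng.random(n) < low_fraction
    out = 1000.0 + 3000.0 * 2.0 ** rng.normal(0.0, 0.4, size=n)
    out[low] = rng.uniform(100.0, 1000.0, size=int(low.sum()))  # upper bound exclusive
    return out


def simulate_archetype_cells(
    n_cells: int,
    archetypes: list[ArchetypeSpec] | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    dapi_low_fraction: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a flat pool of IHC4-panel cells from an archetype mixture.

    Returns the raw intensity table (IHC4 markers + DAPI) and the integer
    archetype index of every cell. Used by :func:`simulate_cohort` and
    directly by clustering-recovery checks.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if len(archetypes) < 1:
        raise ValidationError("at least one archetype required")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = np.full(len(archetypes), 1.0 / len(archetypes))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(len(archetypes), size=n_cells, p=weights)
    cols: dict[str, np.ndarray] = {}
    markers = list(archetypes[0].marker_log_means)
    for m in markers:
        mu = np.array([a.marker_log_means[m] for a in archetypes])[labels]
        sd = np.array([a.marker_log_sds[m] for a in archetypes])[labels]
        cols[m] = np.clip(2.0 ** rng.normal(mu, sd), 0.0, INTENSITY_MAX)
    cols[panels.DAPI] = _draw_dapi(rng, n_cells, dapi_low_fraction)
    return pd.DataFrame(cols), labels


def _positions_uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + radius


def _clip_to_disk(xy: np.ndarray, radius: float) -> np.ndarray:
    """Radially project points outside the core footprint onto its boundary."""
    centered = xy - radius
    r = np.linalg.norm(centered, axis=1)
    out = r > radius
    if out.any():
        centered[out] *= (radius / r[out])[:, None] * 0.999
    return centered + radius


def _blob_centers(rng: np.random.Generator, n_blobs: int, radius: float,
                  min_sep: float) -> np.ndarray:
    """Sequential rejection sampling of blob centers with a soft minimum gap."""
    centers: list[np.ndarray] = []
    for _ in range(n_blobs):
        best = None
        for _attempt in range(40):
            cand = _positions_uniform_disk(rng, 1, radius * 0.85 + 0.15 * radius)[0]
            if not centers:
                best = cand
                break
            d = min(np.linalg.norm(cand - c) for c in centers)
            if d >= min_sep:
                best = cand
                break
            if best is None or d > min(np.linalg.norm(best - c) for c in centers):
                best = cand
        centers.append(best)
    return np.array(centers)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    spec: CohortSpec,
    archetypes: list[ArchetypeSpec] | None = None,
    niches: list[NicheSpec] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate a multi-region cohort for both panels.

    Returns ``(cell_tables, core_metadata, ground_truth)`` where
    ``cell_tables`` maps panel name to a raw cell table. Polytypic cases are
    drawn with probability ``spec.polytypic_fraction`` and are guaranteed at
    least two distinct subtype calls among their cores.
    """
    archetypes = default_archetypes() if archetypes is None else archetypes
    niches = default_niches() if niches is None else niches
    if len(archetypes) < 2:
        raise ValidationError("at least 2 archetypes required")
    if len(niches) < 1:
        raise ValidationError("at least 1 niche required")
    rng = np.random.default_rng(spec.seed)

    subtype_p = np.array([spec.subtype_weights[s] for s in panels.SUBTYPES])
    meta_rows = []
    ihc4_parts, immune_parts = [], []
    truth_ihc4, truth_immune, truth_comp = [], [], []

    for ci in range(spec.n_cases):
        case_id = f"L{ci + 1:02d}"
        n_regions = int(rng.integers(spec.regions_per_case_range[0],
                                     spec.regions_per_case_range[1] + 1))
        main = panels.SUBTYPES[rng.choice(len(panels.SUBTYPES), p=subtype_p)]
        polytypic = rng.random() < spec.polytypic_fraction
        calls = [main] * n_regions
        if polytypic:
            others = [s for s in panels.SUBTYPES if s != main]
            second = others[rng.choice(len(others))]
            n_second = int(rng.integers(1, n_regions))  # 1 .. n_regions-1
            idx = rng.choice(n_regions, size=n_second, replace=False)
            for k in idx:
                calls[k] = second

        for ri in range(n_regions):
            core_id = f"{case_id}_R{ri + 1}"
            subtype = calls[ri]
            n_cells = int(rng.integers(spec.cells_per_core_range[0],
                                       spec.cells_per_core_range[1] + 1))
            meta_rows.append({"case_id": case_id, "core_id": core_id,
                              "region": ri + 1, "subtype": subtype})

            ihc4_df, arch_idx = _simulate_ihc4_core(rng, spec, archetypes, subtype,
                                                    n_cells, case_id, core_id)
            ihc4_parts.append(ihc4_df)
            truth_ihc4.append(pd.DataFrame({
                "cell_id": ihc4_df["cell_id"], "core_id": core_id,
                "archetype": [archetypes[k].name for k in arch_idx]}))
            frac = np.bincount(arch_idx, minlength=len(archetypes)) / n_cells
            truth_comp.append({"core_id": core_id,
                               **{archetypes[k].name: frac[k] for k in range(len(archetypes))}})

            imm_df, imm_truth = _simulate_immune_core(rng, spec, niches, subtype,
                                                      n_cells, case_id, core_id)
            immune_parts.append(imm_df)
            truth_immune.append(imm_truth)

    tables = {panels.IHC4: pd.concat(ihc4_parts, ignore_index=True),
              panels.IMMUNE: pd.concat(immune_parts, ignore_index=True)}
    metadata = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        ihc4=pd.concat(truth_ihc4, ignore_index=True),
        immune=pd.concat(truth_immune, ignore_index=True),
        core_composition=pd.DataFrame(truth_comp).fillna(0.0),
    )
    return tables, metadata, truth


def _simulate_ihc4_core(rng, spec, archetypes, subtype, n_cells, case_id, core_id):
    prev = np.array([a.prevalence_by_subtype.get(subtype, 0.0) for a in archetypes])
    if prev.sum() <= 0:
        prev = np.full(len(archetypes), 1.0)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    df, arch_idx = simulate_archetype_cells(
        n_cells, archetypes, prev, seed=sub_seed, dapi_low_fraction=spec.dapi_low_fraction)
    xy = _positions_uniform_disk(np.random.default_rng(sub_seed + 1), n_cells,
                                 spec.core_radius_px)
    df.insert(0, "cell_id", [f"{core_id}_I{i}" for i in range(n_cells)])
    df.insert(1, "case_id", case_id)
    df.insert(2, "core_id", core_id)
    df.insert(3, "x", xy[:, 0])
    df.insert(4, "y", xy[:, 1])
    df.insert(5, "area", rng.normal(120.0, 20.0, n_cells).clip(min=30.0))
    return df, arch_idx


def _simulate_immune_core(rng, spec, niches, subtype, n_cells, case_id, core_id):
    radius = spec.core_radius_px
    blob_r_px = np.array([n.spatial_blob_radius / spec.pixel_size_um for n in niches])
    mean_blob_r = float(blob_r_px.mean())
    n_blobs = max(3, int(round((np.pi * radius**2) / (np.pi * (2.0 * mean_blob_r) ** 2))))
    weights = np.array([n.weight_by_subtype.get(subtype, 1.0) for n in niches], dtype=float)
    weights = weights / weights.sum()
    blob_niche = rng.choice(len(niches), size=n_blobs, p=weights)
    centers = _blob_centers(rng, n_blobs, radius, min_sep=2.2 * mean_blob_r)

    counts = rng.poisson(n_cells / n_blobs, size=n_blobs)
    counts[-1] += max(0, n_cells - int(counts.sum()))  # keep totals near target
    rows_xy, niche_lab, class_lab = [], [], []
    for b in range(n_blobs):
        nb = int(counts[b])
        if nb == 0:
            continue
        niche = niches[blob_niche[b]]
        xy = centers[b] + rng.normal(0.0, blob_r_px[blob_niche[b]] * 0.6, size=(nb, 2))
        rows_xy.append(_clip_to_disk(xy, radius))
        classes = list(niche.composition)
        p = np.array(list(niche.composition.values()))
        drawn = rng.choice(len(classes), size=nb, p=p / p.sum())
        lab = np.array([classes[k] for k in drawn], dtype=object)
        lab[rng.random(nb) < spec.other_cell_fraction] = panels.OTHER
        class_lab.append(lab)
        niche_lab.extend([niche.niche_label] * nb)
    xy = np.vstack(rows_xy)
    classes = np.concatenate(class_lab)
    n = len(classes)

    cols: dict[str, np.ndarray] = {}
    for m in panels.IMMUNE_MARKERS:
        pos = np.array([m in _CLASS_POSITIVE[c] for c in classes])
        mu = np.where(pos, IMMUNE_POS_LOG_MEAN, IMMUNE_NEG_LOG_MEAN)
        cols[m] = np.clip(2.0 ** rng.normal(mu, IMMUNE_LOG_SD), 0.0, INTENSITY_MAX)
    cols[panels.DAPI] = _draw_dapi(rng, n, spec.dapi_low_fraction)

    df = pd.DataFrame(cols)
    df.insert(0, "cell_id", [f"{core_id}_M{i}" for i in range(n)])
    df.insert(1, "case_id", case_id)
    df.insert(2, "core_id", core_id)
    df.insert(3, "x", xy[:, 0])
    df.insert(4, "y", xy[:, 1])
    df.insert(5, "area", rng.normal(100.0, 15.0, n).clip(min=30.0))
    truth = pd.DataFrame({"cell_id": df["cell_id"], "core_id": core_id,
                          "cell_class": classes, "niche": niche_lab})
    return df, truth


# ---------------------------------------------------------------------------
# tonsil control
# ---------------------------------------------------------------------------

def simulate_tonsil_control(
    seed: int,
    n_cells: int = 2000,
    markers: list[str] | None = None,
    mixing_fraction: float = 0.5,
    separation: float = 4.0,
    neg_log_mean: float = IMMUNE_NEG_LOG_MEAN,
    log_sd: float = IMMUNE_LOG_SD,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """On-slide positive control tissue with bimodal immune marker intensities.

    Each marker mixes a negative mode at ``neg_log_mean`` and a positive mode
    ``separation`` log2 units above it, with ``mixing_fraction`` of cells
    positive. Returns the raw table and the true log2 midpoint per marker,
    against which valley-threshold estimation can be validated.
    """
    if n_cells < 100:
        raise ValidationError(f"n_cells must be >= 100 for a usable control, got {n_cells}")
    if markers is None:
        markers = list(panels.GATED_IMMUNE_MARKERS)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    midpoints: dict[str, float] = {}
    for m in markers:
        pos = rng.random(n_cells) < mixing_fraction
        mu = np.where(pos, neg_log_mean + separation, neg_log_mean)
        cols[m] = np.clip(2.0 ** rng.normal(mu, log_sd), 0.0, INTENSITY_MAX)
        midpoints[m] = neg_log_mean + separation / 2.0
    cols[panels.DAPI] = _draw_dapi(rng, n_cells, 0.0)
    df = pd.DataFrame(cols)
    df.insert(0, "cell_id", [f"tonsil_{i}" for i in range(n_cells)])
    return df, midpoints


# ---------------------------------------------------------------------------
# fixed reference cohort description (synthetic)
# ---------------------------------------------------------------------------

def reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A fixed, synthetic 38-case cohort description for worked examples.

    Built programmatically to match the published clinical summary of the
    motivating whole-mount lumpectomy study: 13 of 38 cases molecularly
    polytypic (ten mixing Luminal A and Luminal B calls, one involving
    HER2-enriched, two involving basal-like), monotypic cases split
    10 LumA / 7 LumB / 2 HER2E / 6 Basal; 27 cases HR+/HER2− by clinical
    IHC and 23 of grade I/II. Splits the summary does not pin down (the
    HER2+/TNBC breakdown of the remaining 11 cases; grade I vs II within
    the 23) are arbitrary synthetic choices.

    Returns ``(core_metadata, case_clinical)``: per-region subtype calls and
    per-case clinical labels.
    """
    rows = []

    def add(case_idx: int, calls: list[str]) -> None:
        case_id = f"L{case_idx:02d}"
        for ri, s in enumerate(calls, start=1):
            rows.append({"case_id": case_id, "core_id": f"{case_id}_R{ri}",
                         "region": ri, "subtype": s})

    idx = 1
    for _ in range(10):
        add(idx, ["LumA", "LumA", "LumA"][: 2 + idx % 2]); idx += 1
    for _ in range(7):
        add(idx, ["LumB", "LumB"]); idx += 1
    for _ in range(2):
        add(idx, ["HER2E", "HER2E", "HER2E"]); idx += 1
    for _ in range(6):
        add(idx, ["Basal", "Basal"]); idx += 1
    for _ in range(10):                      # polytypic LumA/LumB mixes
        add(idx, ["LumA", "LumB", "LumA"][: 2 + idx % 2]); idx += 1
    add(idx, ["HER2E", "Basal"]); idx += 1   # polytypic involving HER2E
    add(idx, ["Basal", "LumB"]); idx += 1    # polytypic involving Basal
    add(idx, ["Basal", "LumA", "Basal"]); idx += 1
    metadata = pd.DataFrame(rows)

    case_ids = [f"L{i:02d}" for i in range(1, 39)]
    # 27 HR+/HER2-; of the rest: 3 HER2+, 8 TNBC (synthetic split); the last
    # three polytypic cases mirror one HER2+ and two TNBC polytypic cancers
    ihc_cat = (["HR+/HER2-"] * 17 + ["HER2+"] * 2 + ["TNBC"] * 6
               + ["HR+/HER2-"] * 10 + ["HER2+"] * 1 + ["TNBC"] * 2)
    # 23 grade I/II (8 + 15), 15 grade III (synthetic split)
    grade = (["I"] * 8 + ["II"] * 15 + ["III"] * 15)
    clinical = pd.DataFrame({"case_id": case_ids, "ihc_category": ihc_cat, "grade": grade})
    return metadata, clinical
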