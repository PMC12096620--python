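# Methods

This note documents the models and procedures implemented in `tmahet`, the
defaults chosen where the design was genuinely open, and what the synthetic
data do and do not demonstrate.

## Data model

The pipeline consumes per-cell tables (CSV/TSV): cell id, case id, core id,
x/y pixel coordinates, cell area, and raw fluorescence intensities on a
16-bit linear scale, one table per panel (IHC4: ER, PR, HER2, Ki67, CK8/18;
Immune: CD3, CD8, CD68, CD163, FoxP3, PD1, PDL1, Ki67, CK8/18; DAPI in
both). Per-core metadata carry the case id and a molecular subtype call
(Luminal A / Luminal B / HER2-enriched / Basal-like) per cored region.
Coordinates are 0-based pixels; physical conversion uses per-panel pixel
size (0.293 μm MxIF, 0.325 μm Cell DIVE) held in configuration, not
hard-coded into operations.

## QC and normalization

Cells with raw DAPI < 1000 are removed as damaged nuclei; the boundary
value 1000 is retained (strict inequality). Intensities are transformed
`x → log2(x + 1)` (the offset keeps raw zeros finite; its value is a
config knob) and then scaled per marker:

* IHC4: min–max onto [0, 15] ("range normalization"). Scope is global per
  marker across all cores of a run — histoscores are compared across cores
  and must share a scale. Per-core scope and percentile winsorization are
  available as options but off by default; whether the original protocol
  scaled globally or robustly is not something we claim fidelity to.
* Immune: Z-score (mean 0, SD 1) per marker. A constant marker is an error
  under Z-scoring and maps to all-zeros with a warning under range scaling.

Normalization records per-marker transform parameters so externally derived
log2 thresholds (e.g. from control tissue) can be mapped onto the
normalized scale.

## Scoring

ER/PR bins on the 0–15 scale: negative = {0}, 1+ = (0, 7), 2+ = [7, 12],
3+ = (12, 15]. HER2: 0 = [0, 5], 1+ = (5, 10], 2+ = (10, 13),
3+ = [13, 15]; the 2+/3+ definitions meet at 13, which is scored 3+ by
documented convention. Per core,

    H = 3·(%3+) + 2·(%2+) + 1·(%1+) ∈ [0, 300].

Ki67 positivity is the percentage of cancer cells with normalized Ki67
strictly greater than 0, mirroring the clinical convention that any nuclear
staining counts. The cancer-cell denominator is CK8/18-gated when a gate is
supplied and all cells of the core otherwise.

Immune gating applies binary per-marker thresholds (Z units) and resolves
cells most-specific-first: gates are ordered by the number of constrained
markers, descending, ties keeping the listed order, so CD3+/CD8+/PD1+ wins
over CD3+/CD8+. Cells satisfying no gate are labelled `other` and excluded
from the nine phenotype counts. FoxP3 is measured but unconstrained by the
default gates. Thresholds are estimated from a bimodal on-slide control
(tonsil): a Gaussian KDE is evaluated on a 512-point grid and the threshold
placed at the density minimum between the two most prominent modes
(prominence ≥ 5% of the peak density); an effectively unimodal control
falls back to a configured manual threshold with a warning.

## Graph clustering

Features (normalized intensities for cells; composition vectors for
patches) are connected to their K nearest Euclidean neighbors (ties broken
by item index; exact O(n²) distances for n ≤ 2048, a KD-tree beyond).
Directed KNN edges are symmetrized by union and weighted by the Jaccard
index of the endpoints' neighbor sets; sets include the node itself, so
coincident mutual neighbors reach weight 1, and zero-Jaccard edges are
dropped. Defaults: K = 300 for cell co-expression, K = 30 for patch
composition. Communities come from Louvain modularity maximization
(igraph `community_multilevel`, RNG seeded for reproducibility); quality is
weighted Newman–Girvan modularity Q ∈ [−1, 1], cross-checked in tests
against igraph's own implementation and an exhaustive brute-force oracle.
Cluster ids are relabelled by descending size. Louvain's greedy sweep is
node-order dependent, so permuting input rows permutes the graph exactly
but may shift a few labels; tests assert graph equivariance exactly and
partition agreement approximately.

**K selection.** Modularity values computed on different KNN graphs are
not comparable: sparser graphs fragment into many near-perfect components
and their Q grows monotonically as K shrinks (measured Q = 0.94/0.88/0.82
at K = 2/5/10 on three planted Gaussian blobs whose correct 3-way partition
has Q ≈ 0.67 — and the effect is scale-invariant, so no degree of blob
separation avoids it). `select_k` therefore scores every candidate
partition on one common reference graph built at the largest scanned K and
keeps the maximizer, with ties resolved to the smallest K. On planted
blobs this recovers the true structure whenever the scan contains an
adequate K.

**Aggregation.** Fine clusters are merged by average-linkage hierarchical
clustering of their centroid vectors (Euclidean), cutting the tree at the
requested group count. Groups are auto-named from the dominant feature of
the size-weighted mean profile ("cancer only" for CK-dominated profiles,
"Immune rich" when no feature exceeds 0.25, "<feature> rich" otherwise),
with deterministic disambiguation of duplicates.

## Patch analysis

Each core is gridded into `patch_px` × `patch_px` squares (default 150 px =
48.75 μm at 0.325 μm/px), anchored at the core's bounding-box minimum with
half-open intervals; partial edge patches are retained. A patch's feature
vector is the fraction of its cells in each of the ten classes (CK+ plus
nine immune phenotypes). The denominator is all cells in the patch
including `other` by default — the ten fractions then sum to ≤ 1 — with a
classified-only denominator available in config. Patches with fewer than 5
cells are excluded, then cores with fewer than 10 surviving patches.
Compositions are clustered at K = 30 and merged to 8 spatial phenotypes by
default; 8 is a configuration parameter, not a discovered quantity. Patch
fractions are fed to clustering raw (not z-scored) so that absolute
composition differences drive the niches; a z-scoring flag exists.

## Diversity decomposition

With cluster composition p per core and the identity dissimilarity
(no phylogenetic/dissimilarity tree), Rao's quadratic entropy reduces to
the Simpson index `alpha_k = 1 − Σ_i p_ki²`. For each case, alpha is the
weighted mean of per-core alphas, total is the Simpson index of the pooled
composition, and beta = total − alpha. Weights default to per-core cell
counts, which makes the decomposition exactly the cell-level Simpson
partition and guarantees beta ≥ 0 (Jensen); equal weights are available.
The pairwise among-core matrix `D_kl = 1 − Σ_i p_ki p_li` is also reported
because "among-community diversity" admits that reading too; the additive
beta is the headline value. Cases with one analysed core report beta as
missing, never zero. The species space is the global cluster label set of
the run; absent clusters contribute p = 0.

## Group comparisons

One-way fixed-effects ANOVA on per-core values treats cores as independent
(case-level nesting is deliberately ignored, matching common TMA practice;
nested models are out of scope). The two-sample Wilcoxon rank-sum test is
exact for combined n ≤ 20 and tie-corrected normal beyond. Pearson and
Spearman correlations require n ≥ 3 and non-degenerate variance. Raw
p-values are reported; Benjamini–Hochberg adjustment is provided but off
by default.

## Synthetic cohorts

The generator emulates the sampling design: 2–9 cored regions per case,
subtype weights (default 0.40/0.28/0.08/0.24 for LumA/LumB/HER2E/Basal,
approximating the monotypic composition of the reference cohort),
a polytypic fraction (default 0.342) guaranteeing at least two distinct
subtype calls among a polytypic case's cores, and per-core cell counts
drawn uniformly from a configurable range.

* **IHC4 cells** are drawn from log-normal archetypes (log2 means/SDs per
  marker, clipped to [0, 65535]). The five defaults (ER+PR+ quiescent,
  ER+ proliferative, HER2-high, basal-like, luminal-low) have centroid
  separations ≥ 5 pooled SDs at SD 0.35, so clustering is expected to
  recover them exactly; subtype-dependent prevalences give cores of
  different subtype different mixtures.
* **Immune cells** are placed in isotropic Gaussian niche blobs (Poisson
  counts, radial clipping to the circular core footprint, blob centers
  rejection-sampled with a soft minimum gap). Each of the eight default
  niches is a 10-way composition over the gated classes — spanning
  immune-cold (cancer only, cancer-CD68, cancer-CD163) to immune-hot
  (CD68++, CD163++, CD3++, immune-rich) plus a PDL1-macrophage niche —
  and Luminal A cores carry a 3× weight on the T-cell-rich niche so
  subtype contrasts propagate to the patch analysis. Marker intensities
  are 4 log2 units apart between positive and negative cells at SD 0.5,
  yielding > 99% gate accuracy at the control-derived thresholds. A
  configurable fraction of cells (default 5%) is unclassified (`other`);
  a configurable fraction of DAPI draws (default 10%) falls below the QC
  cutoff to exercise the filter.
* **Tonsil control**: per-marker two-component log-normal mixture (default
  mixing 0.5, separation 4 log2 units) with the true midpoint recorded, so
  valley-threshold estimation is testable against truth.
* **Reference cohort description**: a fixed, programmatically built,
  synthetic 38-case table reproducing published cohort totals (13
  polytypic, of which ten mix LumA/LumB; monotypic 10/7/2/6 across
  subtypes; 27 HR+/HER2−; 23 grade I/II). Splits those totals do not pin
  down (HER2+/TNBC breakdown; grade I vs II) are arbitrary and do not
  affect any reported percentage.

What the synthetic data do *not* emulate: staining/bleaching artifacts,
segmentation errors, spatially varying illumination, continuous expression
gradients, correlated marker noise within cells, or realistic cell-density
inhomogeneity beyond blob structure. Passing recovery tests therefore shows
the pipeline is correct and well-calibrated under its own assumptions, not
that it would achieve the same accuracy on real tissue.

## Numerical conventions and problem sizes

Range-normalized values are clipped to [0, 15] so the bound holds exactly
under floating-point rounding. Probability-vector validation uses a 1e-9
tolerance; diversity oracle agreement is asserted at 1e-12. Distance ties
in KNN break by item index; modularity ties in the K scan break to the
smallest K. Recovery checks run at n = 3000 cells (K = 300) and a
10-case immune cohort (~700–1400 filtered patches, K = 30); the end-to-end
determinism check uses a 3-case cohort. These sizes were chosen to exercise
the defaults the pipeline ships with while keeping the full suite quick to
run.

## Known limitations

* Louvain (not Leiden) is used, matching the published PhenoGraph backend;
  partitions can be order-sensitive at the margins.
* The valley threshold assumes a clearly bimodal control; heavily skewed or
  multi-modal real controls may need manual thresholds.
* ANOVA on cores ignores within-case correlation; p-values on real
  multi-region data will be anti-conservative.
* Phenotype auto-naming is heuristic and intended for readability, not as
  a biological claim.
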