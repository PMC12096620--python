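# tmahet

Quantifying **intra-tumoral spatial heterogeneity** in breast cancer from
multiplexed-immunofluorescence (MxIF) single-cell tables.

Large breast cancers are spatially heterogeneous: biomarker expression,
cell-population composition and the immune microenvironment can differ
between regions of one tumor, with direct consequences for biopsy-based
diagnosis and treatment planning. `tmahet` implements an analysis pipeline
for the study design that makes this measurable — whole-mount processed
lumpectomies sampled at multiple tissue-microarray (TMA) cored regions per
case, each core imaged with two marker panels and exported as a per-cell
intensity table:

* **IHC4 panel** (ER, PR, HER2, Ki67, CK8/18 + DAPI): QC filtering (cells
  with DAPI < 1000 excluded), log2 + 0–15 range normalization, per-cell
  intensity binning and per-core **histoscores**
  `H = 3·(%3+) + 2·(%2+) + (%1+)` (range 0–300), Ki67 positivity,
  PhenoGraph-style KNN/Jaccard/Louvain clustering of marker co-expression,
  and an alpha/beta diversity decomposition of cluster composition.
* **Immune panel** (CD3, CD8, CD68, CD163, FoxP3, PD1, PDL1, Ki67, CK8/18 +
  DAPI): log2 + Z-score normalization, binary gating into a cancer (CK8/18+)
  and nine immune lineage phenotypes via thresholds estimated from an
  on-slide tonsil control, division of each core into 150 px (48.75 μm)
  image patches, clustering of patch composition vectors into spatial
  **immune niche phenotypes**, and per-core phenotype fractions.

Heterogeneity is quantified with Rao's quadratic entropy under the identity
dissimilarity, where it reduces to the Simpson index `1 − Σ p_i²`:
per-core **alpha** diversity (intra-core heterogeneity), pooled **total**
diversity per case, and their difference **beta** (intra-tumoral
heterogeneity), so that `total = alpha + beta` exactly.

Because per-cell cohort data of this kind are rarely public, the package
includes a first-class synthetic cohort generator with full ground truth
(cell archetypes, gate labels, spatial niches, subtype-dependent effects),
so every stage is testable end to end.

## Worked example

```python
import numpy as np
from tmahet import synthetic, stats, preprocess, scoring, clustering, diversity, panels

# cohort summary arithmetic on the bundled 38-case reference description
metadata, clinical = synthetic.reference_cohort()
labels, summary = stats.classify_typy(metadata, clinical)
print("cases:", summary.n_cases, "polytypic:", summary.n_polytypic,
      f"({summary.percent_polytypic:.1f}%)")

# a small synthetic cohort through the IHC4 pipeline
spec = synthetic.CohortSpec(n_cases=4, regions_per_case_range=(2, 3),
                            cells_per_core_range=(400, 600), seed=0)
tables, meta, truth = synthetic.simulate_cohort(spec)
ncfg = preprocess.NormalizationConfig(panel=panels.IHC4)
cells = preprocess.qc_filter(tables[panels.IHC4], ncfg)
normed, _ = preprocess.normalize(cells, ncfg)
normed = scoring.bin_cells(normed, scoring.scheme_for("ER"))
core = meta.loc[0, "core_id"]
r = scoring.histoscore(normed, scoring.scheme_for("ER"), core)
print(f"{core} ER H-score: {r.histoscore:.1f} (n={r.n_cells})")

feats = normed[[panels.norm_col(m) for m in panels.IHC4_MARKERS]].to_numpy()
res = clustering.cluster_features(feats, clustering.ClusteringConfig(K=200, seed=0))
print(f"clusters: {res.n_clusters}, modularity Q = {res.modularity:.3f}")
normed["cluster"] = res.labels
per_case, per_core = diversity.cohort_diversity(normed, meta)
print(per_case[["case_id", "n_cores", "alpha", "beta"]].round(4).to_string(index=False))
```

prints

```
cases: 38 polytypic: 13 (34.2%)
L01_R1 ER H-score: 138.9 (n=398)
clusters: 5, modularity Q = 0.795
case_id  n_cores  alpha   beta
    L01        3 0.5986 0.1298
    L02        2 0.6281 0.0001
    L03        3 0.6740 0.0016
    L04        3 0.4427 0.0002
```

The clustering recovers exactly the five cancer-cell archetypes planted by
the generator; `alpha` is the mean within-core Simpson diversity of cluster
composition and `beta` the among-core (intra-tumoral) component — case L01
was simulated with regions of discordant subtype, hence its larger beta.

A command-line interface mirrors the stages
(`tmahet simulate|preprocess|score|cluster|patches|diversity|compare|run-all`):

```sh
tmahet run-all --out out_dir --seed 1
```

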