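"""Patch gridding, composition, sparsity filters and niche phenotyping."""

import numpy as np
import pandas as pd
import pytest

from tmahet import clustering, panels, patches, preprocess, scoring, synthetic
from tmahet.errors import SchemaError, ValidationError


def _cells(coords, phenos, core="c1"):
    return pd.DataFrame({
        "core_id": core,
        "x": [c[0] for c in coords],
        "y": [c[1] for c in coords],
        scoring.PHENOTYPE_COL: phenos,
    })


class TestAssign:
    def test_half_open_grid(self):
        cells = _cells([(0, 0), (149, 149), (150, 0)], ["CK+"] * 3)
        out = patches.assign_patches(cells)
        assert set(zip(out["i"], out["j"])) == {(0, 0), (1, 0)}
        assert out.loc[(out["i"] == 0) & (out["j"] == 0), "n_cells"].iloc[0] == 2

    def test_composition_denominator_includes_other(self):
        coords = [(i, 0) for i in range(10)]
        phenos = ["CK+"] * 6 + ["CD3+/CD8-"] * 2 + ["other"] * 2
        out = patches.assign_patches(_cells(coords, phenos))
        row = out.iloc[0]
        assert row["frac CK+"] == pytest.approx(0.6)
        assert row["frac CD3+/CD8-"] == pytest.approx(0.2)
        assert sum(row[f"frac {c}"] for c in panels.CELL_CLASSES) == pytest.approx(0.8)

    def test_classified_denominator_option(self):
        coords = [(i, 0) for i in range(10)]
        phenos = ["CK+"] * 6 + ["CD3+/CD8-"] * 2 + ["other"] * 2
        cfg = patches.PatchConfig(denominator="classified")
        out = patches.assign_patches(_cells(coords, phenos), cfg)
        assert out.iloc[0]["frac CK+"] == pytest.approx(0.75)

    def test_empty_input_gives_empty_table(self):
        out = patches.assign_patches(_cells([], []))
        assert len(out) == 0

    def test_grid_anchored_at_bounding_box(self):
        # identical layouts offset by an arbitrary translation grid identically
        coords = [(10, 10), (170, 20), (40, 200)]
        a = patches.assign_patches(_cells(coords, ["CK+"] * 3))
        b = patches.assign_patches(_cells([(x + 731, y + 412) for x, y in coords],
                                          ["CK+"] * 3))
        pd.testing.assert_frame_equal(a, b)

    def test_cell_count_conserved(self, small_cohort):
        tables, _, truth = small_cohort
        cells = tables[panels.IMMUNE].merge(
            truth.immune[["cell_id", "cell_class"]], on="cell_id")
        cells[scoring.PHENOTYPE_COL] = cells["cell_class"]
        out = patches.assign_patches(cells)
        assert out["n_cells"].sum() == len(cells)

    def test_missing_phenotype_column_raises(self):
        with pytest.raises(SchemaError, match="phenotype"):
            patches.assign_patches(pd.DataFrame({"core_id": ["c"], "x": [0], "y": [0]}))


class TestFilter:
    def _table(self, counts, core="c1"):
        rows = [{"core_id": core, "i": k, "j": 0, "n_cells": c,
                 **{f"frac {cl}": 0.0 for cl in panels.CELL_CLASSES}}
                for k, c in enumerate(counts)]
        return pd.DataFrame(rows)

    def test_sparse_patches_dropped(self):
        cfg = patches.PatchConfig(min_patches_per_core=1)
        out = patches.filter_patches(self._table([4, 5, 6]), cfg)
        assert out["n_cells"].tolist() == [5, 6]

    def test_core_with_too_few_patches_dropped(self):
        out = patches.filter_patches(self._table([10] * 9))
        assert len(out) == 0

    def test_boundary_core_retained(self):
        out = patches.filter_patches(self._table([10] * 10))
        assert len(out) == 10

    def test_raising_min_cells_never_keeps_more(self):
        table = self._table(list(range(3, 30)))
        prev = len(patches.filter_patches(table, patches.PatchConfig(
            min_cells_per_patch=0, min_patches_per_core=1)))
        for mc in range(1, 25):
            cur = len(patches.filter_patches(table, patches.PatchConfig(
                min_cells_per_patch=mc, min_patches_per_core=1)))
            assert cur <= prev
            prev = cur


def test_patch_side_is_48_75_um_at_defaults():
    assert patches.PatchConfig().patch_side_um == 48.75


class TestPhenotyping:
    @pytest.fixture(scope="class")
    def gated_cohort(self):
        spec = synthetic.CohortSpec(n_cases=8, regions_per_case_range=(2, 3),
                                    cells_per_core_range=(700, 1000), seed=21)
        tables, metadata, truth = synthetic.simulate_cohort(spec)
        cells = tables[panels.IMMUNE].merge(
            truth.immune[["cell_id", "cell_class", "niche"]], on="cell_id")
        cells[scoring.PHENOTYPE_COL] = cells["cell_class"]  # true gates
        return cells, metadata, truth

    def test_known_niches_recovered(self, gated_cohort):
        cells, _, _ = gated_cohort
        pcfg = patches.PatchConfig()
        table = patches.filter_patches(patches.assign_patches(cells, pcfg), pcfg)
        phenotyped, result, merge = patches.phenotype_patches(
            table, clustering.ClusteringConfig(K=30, seed=5), n_phenotypes=8)
        assert merge.n_groups == 8
        # truth label of a patch: dominant niche among its cells
        x0 = cells.groupby("core_id")["x"].transform("min")
        y0 = cells.groupby("core_id")["y"].transform("min")
        cells = cells.assign(i=np.floor((cells["x"] - x0) / 150).astype(int),
                             j=np.floor((cells["y"] - y0) / 150).astype(int))
        dom = cells.groupby(["core_id", "i", "j"])["niche"].agg(
            lambda s: s.value_counts().sort_index().idxmax())
        keyed = phenotyped.set_index(["core_id", "i", "j"])
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(dom.loc[keyed.index], keyed["phenotype"])
        assert ari >= 0.8

    def test_deterministic(self, gated_cohort):
        cells, _, _ = gated_cohort
        pcfg = patches.PatchConfig()
        table = patches.filter_patches(patches.assign_patches(cells, pcfg), pcfg)
        a, _, _ = patches.phenotype_patches(table, clustering.ClusteringConfig(K=30, seed=5))
        b, _, _ = patches.phenotype_patches(table, clustering.ClusteringConfig(K=30, seed=5))
        assert a["phenotype"].tolist() == b["phenotype"].tolist()

    def test_too_few_patches_raises(self):
        rows = [{"core_id": "c1", "i": k, "j": 0, "n_cells": 10,
                 **{f"frac {cl}": 0.1 for cl in panels.CELL_CLASSES}}
                for k in range(10)]
        with pytest.raises(ValidationError, match="smaller K"):
            patches.phenotype_patches(pd.DataFrame(rows),
                                      clustering.ClusteringConfig(K=30))

    def test_luma_cores_richer_in_t_cell_patches(self, gated_cohort):
        # the generator enriches LumA for T-cell niches; the patch pipeline
        # must see the same contrast (directional end-to-end check)
        cells, metadata, _ = gated_cohort
        pcfg = patches.PatchConfig()
        table = patches.filter_patches(patches.assign_patches(cells, pcfg), pcfg)
        phenotyped, _, merge = patches.phenotype_patches(
            table, clustering.ClusteringConfig(K=30, seed=5), n_phenotypes=8)
        fracs = patches.phenotype_fractions(phenotyped)
        merged = fracs.merge(metadata[["core_id", "subtype"]], on="core_id")
        cd3_cols = [c for c in fracs.columns if "CD3" in c]
        assert cd3_cols, f"no CD3-dominant phenotype named among {list(fracs.columns)}"
        cd3 = merged[cd3_cols].sum(axis=1)
        luma = cd3[merged["subtype"] == "LumA"]
        lumb = cd3[merged["subtype"] == "LumB"]
        if len(luma) >= 2 and len(lumb) >= 2:
            assert luma.mean() > lumb.mean()


class TestFractions:
    def test_direct_count(self):
        table = pd.DataFrame({"core_id": ["c1"] * 10,
                              "phenotype": ["Immune rich"] * 4 + ["cancer only"] * 6})
        out = patches.phenotype_fractions(table)
        assert out.loc[0, "Immune rich"] == pytest.approx(0.4)

    def test_single_phenotype_is_one(self):
        table = pd.DataFrame({"core_id": ["c1"] * 5, "phenotype": ["cancer only"] * 5})
        out = patches.phenotype_fractions(table)
        assert out.loc[0, "cancer only"] == 1.0

    def test_fractions_sum_to_one_per_core(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "core_id": rng.choice(["a", "b", "c"], 60),
            "phenotype": rng.choice(["p1", "p2", "p3", "p4"], 60)})
        out = patches.phenotype_fractions(table).set_index("core_id")
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_requires_phenotype_column(self):
        with pytest.raises(SchemaError, match="phenotype"):
            patches.phenotype_fractions(pd.DataFrame({"core_id": ["c"]}))
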