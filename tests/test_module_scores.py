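"""Module registry, exclusivity filter and mean-log2 scoring."""

import numpy as np
import pytest

from gliameta import (
    GeneModule,
    default_modules,
    filter_exclusive,
    load_modules,
    score_all,
    score_module,
    target_level,
)
from conftest import make_dataset


def log2_ds(values, symbols, **kw):
    ds = make_dataset(values, symbols=symbols, **kw)
    return ds.to_log2()


class TestRegistry:
    def test_default_registry_shape(self):
        mods = default_modules()
        assert len(mods) == 11
        by_cat = {}
        for m in mods:
            by_cat.setdefault(m.category, []).append(m.name)
        assert len(by_cat["myeloid"]) == 3
        assert len(by_cat["activation"]) == 4
        assert len(by_cat["neuron_astro"]) == 4
        assert "Microglia" in by_cat["myeloid"]
        for m in mods:
            for sp in ("mouse", "rat", "human"):
                assert m.symbols_for(sp)

    def test_no_symbol_in_two_modules_of_same_category(self):
        mods = default_modules()
        for cat in ("myeloid", "activation", "neuron_astro"):
            seen = {}
            for m in (x for x in mods if x.category == cat):
                for k in m.keys_for("mouse"):
                    assert k not in seen, f"{k} in {m.name} and {seen.get(k)}"
                    seen[k] = m.name

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            GeneModule("Empty", "myeloid", {"mouse": []})

    def test_user_file_extends_registry(self, tmp_path):
        p = tmp_path / "mods.tsv"
        p.write_text("module\tcategory\tspecies\tsymbol\n"
                     "Custom\tactivation\tmouse\tFoo1\n"
                     "Custom\tactivation\tmouse\tBar2\n")
        mods = load_modules(p)
        assert [m.name for m in mods] == ["Custom"]
        assert mods[0].symbols_for("mouse") == ["Foo1", "Bar2"]

    def test_duplicate_module_name_rejected(self, tmp_path):
        p = tmp_path / "mods.json"
        p.write_text('[{"name": "M", "category": "myeloid",'
                     ' "symbols": {"mouse": ["A"]}},'
                     ' {"name": "M", "category": "myeloid",'
                     ' "symbols": {"mouse": ["B"]}}]')
        with pytest.raises(ValueError, match="duplicate"):
            load_modules(p)


class TestFilterExclusive:
    MOD = GeneModule("Microglia", "myeloid", {"mouse": ["A1", "B1", "C1"]})

    def test_flagged_gene_removed_and_logged(self):
        filtered, removals = filter_exclusive(
            [self.MOD], {"C1": {"astrocyte"}})
        assert filtered[0].symbols_for("mouse") == ["A1", "B1"]
        assert removals[0]["symbol"] == "C1"
        assert "astrocyte" in removals[0]["reason"]

    def test_no_flags_identity(self):
        filtered, removals = filter_exclusive([self.MOD], {})
        assert filtered[0].symbols_for("mouse") == ["A1", "B1", "C1"]
        assert removals == []

    def test_own_cell_type_does_not_remove(self):
        filtered, _ = filter_exclusive([self.MOD], {"A1": {"microglia"}})
        assert filtered[0].symbols_for("mouse") == ["A1", "B1", "C1"]

    def test_emptied_module_is_error(self):
        with pytest.raises(ValueError, match="Microglia"):
            filter_exclusive([self.MOD], {s: {"neuron"}
                                          for s in ("A1", "B1", "C1")})


class TestScoreModule:
    def test_two_gene_mean(self):
        ds = log2_ds([[3.0], [15.0]], ["A", "B"])  # log2 -> 2.0, 4.0
        mod = GeneModule("M", "myeloid", {"mouse": ["A", "B"]})
        assert score_module(ds, mod).dataset_mean == pytest.approx(3.0)

    def test_single_gene_identity(self):
        ds = log2_ds([[3.0, 7.0], [1.0, 1.0]], ["A", "B"])
        mod = GeneModule("M", "myeloid", {"mouse": ["A"]})
        ms = score_module(ds, mod)
        np.testing.assert_allclose(ms.per_sample, [2.0, 3.0])
        assert ms.dataset_mean == pytest.approx(2.5)

    def test_missing_gene_mean_over_present_with_coverage(self):
        # 4-gene module, one missing; present log2 values 1, 2, 3 -> mean 2.0
        ds = log2_ds([[1.0], [3.0], [7.0]], ["A", "B", "C"])
        mod = GeneModule("M", "myeloid", {"mouse": ["A", "B", "C", "D"]})
        ms = score_module(ds, mod)
        assert ms.dataset_mean == pytest.approx(2.0)
        assert ms.coverage == pytest.approx(0.75)
        assert not ms.low_coverage  # above the 0.5 default threshold

    def test_zero_present_genes_absent_not_zero(self):
        ds = log2_ds([[1.0]], ["X"])
        mod = GeneModule("M", "myeloid", {"mouse": ["A", "B"]})
        ms = score_module(ds, mod)
        assert ms.dataset_mean is None and ms.low_coverage

    def test_requires_log2(self):
        ds = make_dataset([[1.0]], symbols=["A"])
        mod = GeneModule("M", "myeloid", {"mouse": ["A"]})
        with pytest.raises(ValueError, match="log2"):
            score_module(ds, mod)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(size=(6, 3))
        symbols = [f"G{i}" for i in range(6)]
        ds = log2_ds(vals, symbols)
        mod = GeneModule("M", "myeloid", {"mouse": symbols[:4]})
        base = score_module(ds, mod).dataset_mean
        perm = rng.permutation(6)
        ds_p = log2_ds(vals[perm], [symbols[i] for i in perm])
        mod_p = GeneModule("M", "myeloid",
                           {"mouse": list(rng.permutation(symbols[:4]))})
        assert score_module(ds_p, mod_p).dataset_mean == pytest.approx(
            base, abs=1e-12)

    def test_adding_gene_at_mean_is_neutral(self):
        ds = log2_ds([[1.0], [3.0], [3.0]], ["A", "B", "C"])
        mod2 = GeneModule("M", "myeloid", {"mouse": ["A", "B"]})
        base = score_module(ds, mod2).dataset_mean  # (1+2)/2 = 1.5
        # gene C has log2 value 2.0 != mean; instead craft one at the mean
        ds2 = log2_ds([[1.0], [3.0], [2.0 ** 1.5 - 1.0]], ["A", "B", "C"])
        mod3 = GeneModule("M", "myeloid", {"mouse": ["A", "B", "C"]})
        assert score_module(ds2, mod3).dataset_mean == pytest.approx(
            base, abs=1e-12)


class TestScoreAll:
    def _collection(self, rng, n=3):
        symbols = ["Oprm1", "P2ry12", "Tmem119", "Gfap"]
        return [make_dataset(rng.lognormal(1, 0.5, size=(4, 2)),
                             symbols=symbols, dataset_id=f"D{i}")
                for i in range(n)]

    def test_table_shape_and_identity_cells(self):
        rng = np.random.default_rng(4)
        ds_list = self._collection(rng)
        single = GeneModule("Solo", "myeloid", {"mouse": ["P2ry12"]})
        pair = GeneModule("Astro", "neuron_astro", {"mouse": ["Gfap"]})
        table = score_all(ds_list, [single, pair], "Oprm1")
        assert table.dataset_scores.shape == (3, 3)  # 2 modules + target
        for ds in ds_list:
            got = table.dataset_scores.loc[ds.dataset_id, "Solo"]
            want = float(np.log2(1 + ds.values[1]).mean())
            assert got == pytest.approx(want, abs=1e-12)

    def test_target_column_matches_detection_value(self):
        rng = np.random.default_rng(8)
        ds_list = self._collection(rng)
        mod = GeneModule("M", "myeloid", {"mouse": ["Tmem119"]})
        table = score_all(ds_list, [mod], "Oprm1")
        for ds in ds_list:
            assert table.dataset_scores.loc[ds.dataset_id, "Oprm1"] == \
                pytest.approx(target_level(ds, "Oprm1"), abs=1e-12)

    def test_absent_target_cell_is_nan(self):
        ds = make_dataset([[1.0, 2.0]], symbols=["Gfap"], dataset_id="NoT")
        mod = GeneModule("Astro", "neuron_astro", {"mouse": ["Gfap"]})
        table = score_all([ds], [mod], "Oprm1")
        assert np.isnan(table.dataset_scores.loc["NoT", "Oprm1"])

    def test_dataset_mean_is_mean_of_sample_scores(self):
        rng = np.random.default_rng(12)
        ds_list = self._collection(rng, n=2)
        mod = GeneModule("Pair", "myeloid", {"mouse": ["P2ry12", "Tmem119"]})
        table = score_all(ds_list, [mod], "Oprm1")
        per = table.sample_scores
        for ds in ds_list:
            s = per[(per.dataset_id == ds.dataset_id) & (per.column == "Pair")]
            assert table.dataset_scores.loc[ds.dataset_id, "Pair"] == \
                pytest.approx(s.score.mean(), abs=1e-12)


def test_planted_microglia_shift_dominates():
    """With a +3 log2 Microglia shift the Microglia score tops every other
    module in nearly all generated datasets."""
    import logging
    from gliameta import SyntheticCollectionConfig, generate_collection
    logging.disable(logging.WARNING)
    try:
        mods = default_modules()
        cfg = SyntheticCollectionConfig(seed=77, n_datasets=40, n_genes=500)
        coll = generate_collection(cfg)
        wins = 0
        for ds in coll.datasets:
            ds2 = ds.to_log2()
            scores = {m.name: score_module(ds2, m).dataset_mean for m in mods}
            wins += max(scores, key=scores.get) == "Microglia"
        assert wins >= 38  # >= 95%
    finally:
        logging.disable(logging.NOTSET)
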