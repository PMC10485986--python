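import numpy as np
import pandas as pd
import pytest

from phylomorph import data_io
from phylomorph.data_io import (
    EcologyTable,
    LandmarkSet,
    Phylogeny,
    assign_primary_diet,
    filter_quantitative_diet,
    match_and_prune,
    normalize_name,
    read_landmark_file,
    write_landmark_csv,
    write_landmark_tps,
)
from phylomorph.errors import FormatError, ValidationError


def _tiny_eco(taxa, habitats=None, diets=None, records=None):
    n = len(taxa)
    return EcologyTable(
        taxa=list(taxa),
        habitat=habitats or ["terrestrial"] * n,
        primary_diet=diets or ["amphibians"] * n,
        n_diet_records=records,
    )


class TestTpsDialect:
    def test_minimal_block(self, tmp_path):
        f = tmp_path / "m.tps"
        f.write_text("LM3=2\n0 0 0\n1 0 0\nID=sp1\n")
        lm = read_landmark_file(f, format="tps")
        assert lm.taxa == ["sp1"]
        assert lm.n_landmarks == 2
        np.testing.assert_array_equal(lm.coords[0], [[0, 0, 0], [1, 0, 0]])

    def test_inconsistent_counts_names_taxon(self, tmp_path):
        f = tmp_path / "bad.tps"
        f.write_text("LM3=2\n0 0 0\n1 0 0\nID=sp1\nLM3=3\n0 0 0\n1 0 0\n2 0 0\nID=sp2\n")
        with pytest.raises(FormatError, match="sp2"):
            read_landmark_file(f, format="tps")

    def test_declared_count_mismatch(self, tmp_path):
        f = tmp_path / "bad.tps"
        f.write_text("LM3=3\n0 0 0\n1 0 0\nID=sp1\n")
        with pytest.raises(FormatError, match="sp1"):
            read_landmark_file(f, format="tps")

    def test_duplicate_taxon(self, tmp_path):
        f = tmp_path / "dup.tps"
        block = "LM3=1\n0 0 0\nID=sp1\n"
        f.write_text(block + block)
        with pytest.raises(FormatError, match="duplicate"):
            read_landmark_file(f, format="tps")

    def test_scale_line_warns_and_is_ignored(self, tmp_path):
        f = tmp_path / "s.tps"
        f.write_text("LM3=1\n1 2 3\nSCALE=0.01\nID=sp1\n")
        with pytest.warns(UserWarning, match="SCALE"):
            lm = read_landmark_file(f, format="tps")
        np.testing.assert_array_equal(lm.coords[0], [[1, 2, 3]])

    def test_roundtrip(self, tmp_path, rng):
        lm = LandmarkSet(
            taxa=["a", "b", "c"], coords=rng.standard_normal((3, 7, 3)) * 13.7
        )
        f = tmp_path / "rt.tps"
        write_landmark_tps(lm, f)
        back = read_landmark_file(f, format="tps")
        assert back.taxa == lm.taxa
        np.testing.assert_allclose(back.coords, lm.coords, atol=1e-12, rtol=0)


class TestCsvDialect:
    def test_73_landmark_wide_csv(self, tmp_path, rng):
        lm = LandmarkSet(
            taxa=["sp1", "sp2", "sp3"], coords=rng.standard_normal((3, 73, 3))
        )
        f = tmp_path / "w.csv"
        write_landmark_csv(lm, f)
        back = read_landmark_file(f, format="csv")
        assert back.n_taxa == 3
        assert back.n_landmarks == 73
        np.testing.assert_allclose(back.coords, lm.coords, atol=1e-12, rtol=0)

    def test_non_multiple_of_three_columns(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("taxon,x1,y1,z1,x2\nsp1,0,0,0,1\n")
        with pytest.raises(FormatError, match="multiple of 3"):
            read_landmark_file(f, format="csv")


class TestLandmarkSetInvariants:
    def test_nan_rejected(self):
        coords = np.zeros((2, 3, 3))
        coords[1, 2, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            LandmarkSet(taxa=["a", "b"], coords=coords)

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            LandmarkSet(taxa=["a", "a"], coords=np.zeros((2, 3, 3)))

    def test_partial_module_assignment_rejected(self):
        with pytest.raises(ValidationError, match="without a module"):
            LandmarkSet(
                taxa=["a"], coords=np.zeros((1, 3, 3)), module_of={0: "m1"}
            )

    def test_module_slice_isolates_landmarks(self, rng):
        module_of = {0: "m1", 1: "m1", 2: "m1", 3: "m2", 4: "m2", 5: "m2"}
        lm = LandmarkSet(
            taxa=["a", "b"],
            coords=rng.standard_normal((2, 6, 3)),
            module_of=module_of,
        )
        sl = lm.module_slice("m2")
        assert sl.n_landmarks == 3
        np.testing.assert_array_equal(sl.coords, lm.coords[:, 3:, :])


class TestPrimaryDietRule:
    def test_pure_diet(self):
        props = {c: 0.0 for c in data_io.DIET_CATEGORIES}
        props["amphibians"] = 1.0
        assert assign_primary_diet(props) == "amphibians"

    def test_rule_at_margin(self):
        assert assign_primary_diet({"fish": 0.51, "amphibians": 0.49}) == "fish"

    def test_exact_half_is_generalist(self):
        assert assign_primary_diet({"a": 0.5, "b": 0.5}) == "generalist"

    def test_boundary_grid_exhaustive(self):
        # independent restatement of the strict >50% rule on a 3-category grid
        step = 0.05
        grid = np.round(np.arange(0, 1 + step / 2, step), 10)
        for p1 in grid:
            for p2 in grid:
                p3 = round(1.0 - p1 - p2, 10)
                if p3 < 0:
                    continue
                props = {"a": p1, "b": p2, "c": p3}
                expected = "generalist"
                for cat, v in props.items():
                    if v > 0.5:
                        expected = cat
                assert assign_primary_diet(props) == expected

    def test_validation(self):
        with pytest.raises(ValidationError):
            assign_primary_diet({"a": 0.7, "b": 0.4})
        with pytest.raises(ValidationError):
            assign_primary_diet({"a": -0.1, "b": 1.1})


class TestDietRecordFilter:
    def test_strict_inequality(self):
        eco = _tiny_eco(["sp1", "sp2", "sp3"], records=np.array([11, 10, 200]))
        assert filter_quantitative_diet(eco, 10).taxa == ["sp1", "sp3"]

    def test_all_zero_records(self):
        eco = _tiny_eco(["sp1", "sp2"], records=np.zeros(2))
        assert filter_quantitative_diet(eco, 10).taxa == []

    def test_poisson_counts_match_recount_oracle(self, rng):
        counts = rng.poisson(12, size=160).astype(float)
        taxa = [f"s{i}" for i in range(160)]
        eco = _tiny_eco(taxa, records=counts)
        kept = filter_quantitative_diet(eco, 10)
        assert kept.n_taxa == int((counts > 10).sum())


class TestEcologyTable:
    def test_unknown_habitat_rejected(self):
        with pytest.raises(ValidationError, match="unknown habitat"):
            _tiny_eco(["a"], habitats=["pelagic"])

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            EcologyTable(
                taxa=["a"],
                habitat=["aquatic"],
                primary_diet=["fish"],
                diet_categories=("fish", "frogs"),
                diet_proportions=np.array([[0.6, 0.5]]),
            )

    def test_csv_roundtrip(self, tmp_path, rng):
        props = rng.dirichlet(np.ones(10), size=4)
        eco = EcologyTable(
            taxa=["a", "b", "c", "d"],
            habitat=["aquatic", "arboreal", "terrestrial", "cryptozoic"],
            primary_diet=["fish", "generalist", "mammals", "annelids"],
            diet_proportions=props,
            n_diet_records=np.array([3.0, 15.0, 40.0, 0.0]),
        )
        f = tmp_path / "eco.csv"
        data_io.write_ecology_csv(eco, f)
        back = data_io.read_ecology_csv(f)
        assert back.taxa == eco.taxa
        assert back.habitat == eco.habitat
        assert back.primary_diet == eco.primary_diet
        np.testing.assert_allclose(back.diet_proportions, props, atol=1e-12, rtol=0)


class TestMatchAndPrune:
    def _abc(self):
        lm = LandmarkSet(taxa=["a", "b", "c"], coords=np.random.default_rng(0).standard_normal((3, 4, 3)))
        eco = _tiny_eco(["a", "b", "c"])
        tree = Phylogeny.from_newick("((a:1,b:1):1,(d:1,x:1):1);", is_path=False)
        return lm, eco, tree

    def test_drop_report(self):
        lm = LandmarkSet(
            taxa=["a", "b", "c", "e"],
            coords=np.random.default_rng(0).standard_normal((4, 4, 3)),
        )
        eco = _tiny_eco(["a", "b", "c", "e"])
        tree = Phylogeny.from_newick(
            "((a:1,b:1):1,((c:0.5,e:0.5):0.5,d:1):1);", is_path=False
        )
        m = match_and_prune(lm, eco, tree)
        assert m.taxa == ["a", "b", "c", "e"]
        assert m.dropped["tree"] == ["d"]

    def test_intersection_too_small(self):
        lm, eco, tree = self._abc()
        with pytest.raises(ValidationError, match="at least 4"):
            match_and_prune(lm, eco, tree)

    def test_identity_keeps_all(self, small_dataset):
        phy, eco, lm = small_dataset
        m = match_and_prune(lm, eco, phy)
        assert m.n_taxa == lm.n_taxa
        assert all(not v for v in m.dropped.values())

    def test_name_normalization(self):
        assert normalize_name("Genus species") == normalize_name("genus_Species".lower())

    def test_random_intersection_matches_set_oracle(self, rng):
        from phylomorph.synthetic_data import simulate_tree

        phy = simulate_tree(160, seed=5)
        tips = phy.tip_labels
        tree_keep = sorted(rng.choice(tips, size=148, replace=False))
        pruned = phy.prune_to(tree_keep)
        lm_taxa = sorted(rng.choice(tips, size=120, replace=False))
        lm = LandmarkSet(
            taxa=lm_taxa, coords=rng.standard_normal((120, 4, 3))
        )
        eco = _tiny_eco(lm_taxa)
        expected = set(lm_taxa) & set(tree_keep)
        if len(expected) >= 4:
            m = match_and_prune(lm, eco, pruned)
            assert set(m.taxa) == expected

    def test_idempotent(self, matched):
        m2 = match_and_prune(matched.landmarks, matched.ecology, matched.phylogeny)
        assert m2.taxa == matched.taxa
        np.testing.assert_array_equal(m2.landmarks.coords, matched.landmarks.coords)

    def test_pruning_preserves_patristic_distances(self):
        from phylomorph.synthetic_data import simulate_tree

        phy = simulate_tree(30, seed=9)
        keep = phy.tip_labels[::2]

        def patristic(tree, pair):
            pdm = tree.tree.phylogenetic_distance_matrix()
            t1 = tree.tree.taxon_namespace.get_taxon(pair[0])
            t2 = tree.tree.taxon_namespace.get_taxon(pair[1])
            return pdm.patristic_distance(t1, t2)

        pruned = phy.prune_to(keep)
        for pair in [(keep[0], keep[1]), (keep[2], keep[10]), (keep[5], keep[14])]:
            assert patristic(phy, pair) == pytest.approx(patristic(pruned, pair), abs=1e-12)


class TestModuleAssignmentsFile:
    def test_yaml_roundtrip(self, tmp_path):
        module_of = {0: "m1", 1: "m1", 2: "m2"}
        f = tmp_path / "mods.yaml"
        data_io.write_module_assignments(module_of, f)
        assert data_io.read_module_assignments(f) == module_of

    def test_csv_roundtrip(self, tmp_path):
        module_of = {0: "m1", 1: "m2", 2: "m2"}
        f = tmp_path / "mods.csv"
        data_io.write_module_assignments(module_of, f)
        assert data_io.read_module_assignments(f) == module_of
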