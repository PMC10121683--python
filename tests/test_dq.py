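import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mhc2deconv.blosum import AMINO_ACIDS, BLOSUM50
from mhc2deconv.datasets import Sample
from mhc2deconv.dq import (
    PairingRuleTable,
    build_tree,
    category_means,
    classify_molecule,
    classify_pairing,
    contribution_analysis,
    coverage,
    enumerate_prevalent,
    extended_coverage,
    motif_logo_data,
    pseudo_distance,
    specificity_distance,
    weighted_frequency,
)


class TestClassifyPairing:
    @pytest.mark.parametrize(
        "dqa, dqb, expected",
        [
            ("DQA1*01:01", "DQB1*05:01", "cis"),
            ("DQA1*01:02", "DQB1*06:02", "cis"),
            ("DQA1*03:03", "DQB1*03:01", "cis"),
            ("DQA1*01:01", "DQB1*03:01", "trans_only"),
            ("DQA1*03:03", "DQB1*05:01", "trans_only"),
            ("DQA1*05:01", "DQB1*06:02", "trans_only"),
        ],
    )
    def test_haplotype_table(self, dqa, dqb, expected):
        assert classify_pairing(dqa, dqb) == expected

    def test_group01_pairs_exactly_with_05_06(self):
        for b in ("02", "03", "04", "05", "06"):
            expected = "cis" if b in ("05", "06") else "trans_only"
            assert classify_pairing("DQA1*01:01", f"DQB1*{b}:01") == expected

    def test_partition_of_all_group_pairs(self):
        for a, b in itertools.product(["01", "02", "03", "04", "05", "06"],
                                      ["02", "03", "04", "05", "06"]):
            cls = classify_pairing(f"DQA1*{a}:01", f"DQB1*{b}:01")
            assert cls in ("cis", "trans_only")

    def test_unparseable_name(self):
        with pytest.raises(ValueError):
            classify_pairing("DRB1*01:01", "DQB1*05:01")

    def test_combined_name_classification(self):
        assert classify_molecule("HLA-DQA1*01:01-DQB1*05:01") == "cis"

    def test_rule_table_round_trip(self, tmp_path):
        table = PairingRuleTable()
        path = tmp_path / "rules.tsv"
        table.write(path)
        assert PairingRuleTable.read(path) == table


class TestPseudoDistance:
    def test_identical_is_zero(self):
        p = "".join(AMINO_ACIDS[i % 20] for i in range(34))
        assert pseudo_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_toy_blosum_value(self):
        # "AA" vs "AV": s(A,B)=5+0, s(A,A)=10, s(B,B)=10 -> d = 1 - 5/10
        assert BLOSUM50[AMINO_ACIDS.index("A"), AMINO_ACIDS.index("V")] == 0.0
        assert pseudo_distance("AA", "AV") == pytest.approx(0.5)

    @given(st.data())
    def test_symmetry(self, data):
        a = data.draw(st.lists(st.sampled_from(AMINO_ACIDS), min_size=34, max_size=34))
        b = data.draw(st.lists(st.sampled_from(AMINO_ACIDS), min_size=34, max_size=34))
        pa, pb = "".join(a), "".join(b)
        assert pseudo_distance(pa, pb) == pytest.approx(pseudo_distance(pb, pa), abs=1e-12)

    def test_monotone_under_convergence(self, rng):
        """Making B equal to A one position at a time never increases d(A, B)."""
        a = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=34))
        b = list(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=34))
        prev = pseudo_distance(a, "".join(b))
        for pos in rng.permutation(34):
            b[pos] = a[pos]
            cur = pseudo_distance(a, "".join(b))
            assert cur <= prev + 1e-9
            prev = cur
        assert prev == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pseudo_distance("AA", "AAA")


class TestWeightedFrequency:
    def test_single_population(self):
        assert weighted_frequency([(0.07, 500)]) == pytest.approx(0.07)

    def test_capping_at_thousand(self):
        value = weighted_frequency([(0.1, 500), (0.3, 4000)])
        assert value == pytest.approx((0.1 * 500 + 0.3 * 1000) / 1500)

    def test_small_populations_dropped(self):
        assert weighted_frequency([(0.9, 99), (0.1, 100)]) == pytest.approx(0.1)

    def test_equal_frequencies_size_invariant(self):
        assert weighted_frequency([(0.2, 150), (0.2, 5000), (0.2, 100)]) == pytest.approx(0.2)

    def test_empty_undefined(self):
        assert weighted_frequency([]) is None
        assert weighted_frequency([(0.5, 50)]) is None


class TestEnumeratePrevalent:
    def test_included_above_threshold(self):
        out = enumerate_prevalent({"DQA1*01:01": 0.01}, {"DQB1*05:01": 0.02})
        assert out["molecule"].tolist() == ["DQA10101-DQB10501"]
        assert out.loc[0, "frequency"] == pytest.approx(2e-4)

    def test_boundary_is_strict(self):
        out = enumerate_prevalent({"DQA1*01:01": 0.01}, {"DQB1*05:01": 0.005})
        assert out.empty  # product exactly 0.00005

    def test_disallowed_pair_excluded(self):
        out = enumerate_prevalent({"DQA1*01:01": 0.5}, {"DQB1*03:01": 0.5})
        assert out.empty

    def test_sorted_by_frequency(self):
        out = enumerate_prevalent(
            {"DQA1*01:01": 0.01, "DQA1*01:02": 0.03},
            {"DQB1*05:01": 0.02, "DQB1*06:02": 0.01},
        )
        freqs = out["frequency"].tolist()
        assert freqs == sorted(freqs, reverse=True)

    def test_negative_frequency_error(self):
        with pytest.raises(ValueError):
            enumerate_prevalent({"DQA1*01:01": -0.1}, {"DQB1*05:01": 0.5})


def _ann(rows):
    return pd.DataFrame(rows, columns=["sample_id", "molecule", "is_trash", "target"])


class TestCoverage:
    def test_five_percent_gate(self):
        rows = [("CL1", "A", False, 1.0)] * 960 + [("CL1", "B", False, 1.0)] * 40
        report = coverage(_ann(rows))
        # B sits at 4% of 1000 -> contributes nothing
        assert "B" not in set(report["molecule"])
        assert report.set_index("molecule").loc["A", "count"] == 960

    def test_accumulation_across_lines(self):
        rows = [("CL1", "A", False, 1.0)] * 60 + [("CL2", "A", False, 1.0)] * 50
        report = coverage(_ann(rows))
        row = report.set_index("molecule").loc["A"]
        assert row["count"] == 110 and bool(row["covered"])

    def test_boundary_not_covered(self):
        rows = [("CL1", "A", False, 1.0)] * 99
        report = coverage(_ann(rows))
        assert not bool(report.set_index("molecule").loc["A", "covered"])

    def test_monotone_in_min_total(self):
        rows = [("CL1", "A", False, 1.0)] * 150 + [("CL2", "B", False, 1.0)] * 120
        loose = coverage(_ann(rows), min_total=100)
        tight = coverage(_ann(rows), min_total=130)
        covered_loose = set(loose.loc[loose["covered"], "molecule"])
        covered_tight = set(tight.loc[tight["covered"], "molecule"])
        assert covered_tight <= covered_loose

    def test_extended_coverage_superset(self):
        rows = [("CL1", "A", False, 1.0)] * 150
        report = coverage(_ann(rows))
        base = "".join(AMINO_ACIDS[i % 20] for i in range(34))
        near = "C" + base[1:]  # one conservative step away
        far = "W" * 34
        ext = extended_coverage(report, {"A": base, "B": near, "C": far})
        ext = ext.set_index("molecule")
        assert bool(ext.loc["A", "extended_covered"])  # covered => extended
        assert ext.loc["B", "extended_covered"] == (
            ext.loc["B", "distance_to_covered"] <= 0.025
        )
        assert not bool(ext.loc["C", "extended_covered"])


class TestContributionAnalysis:
    def _samples(self):
        return {
            "HET1": Sample(
                "HET1",
                (
                    "DQA10101-DQB10501",  # cis (SA)
                    "DQA10303-DQB10301",  # cis (MA)
                    "DQA10101-DQB10301",  # trans-only
                    "DQA10303-DQB10501",  # trans-only
                ),
            ),
            "HOM1": Sample("HOM1", ("DQA10101-DQB10501",)),
        }

    def test_small_dataset_excluded(self):
        rows = [("HET1", "DQA10101-DQB10501", False, 1.0)] * 99
        out = contribution_analysis(_ann(rows), self._samples(), ["DQA10101-DQB10501"])
        assert out.empty

    def test_homozygous_dataset_fraction_one(self):
        rows = [("HOM1", "DQA10101-DQB10501", False, 1.0)] * 150
        out = contribution_analysis(
            _ann(rows), self._samples(), ["DQA10101-DQB10501"], heterozygous_only=False
        )
        assert out.loc[0, "mean_fraction"] == pytest.approx(1.0)

    def test_categories_and_fractions(self):
        rows = (
            [("HET1", "DQA10101-DQB10501", False, 1.0)] * 70
            + [("HET1", "DQA10303-DQB10301", False, 1.0)] * 25
            + [("HET1", "DQA10101-DQB10301", False, 1.0)] * 5
        )
        out = contribution_analysis(_ann(rows), self._samples(), ["DQA10101-DQB10501"])
        by_mol = out.set_index("molecule")
        assert by_mol.loc["DQA10101-DQB10501", "category"] == "cis_SA"
        assert by_mol.loc["DQA10303-DQB10301", "category"] == "cis_MA"
        assert by_mol.loc["DQA10101-DQB10301", "category"] == "trans_only"
        assert by_mol.loc["DQA10101-DQB10501", "mean_fraction"] == pytest.approx(0.70)
        means = category_means(out)
        assert means["trans_only"] == pytest.approx(0.05 / 2, abs=0.03)


class TestBuildTree:
    def _additive_matrix(self):
        # tree ((a,b),(c,d)) with external branches 1 and internal branch 2
        names = ["a", "b", "c", "d"]
        mat = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        return pd.DataFrame(mat, index=names, columns=names)

    @staticmethod
    def _splits(newick):
        """Non-trivial splits of an unrooted tree, each normalized to the
        unordered {side, complement} pair (via dendropy)."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        taxa = frozenset(t.label for t in tree.taxon_namespace)
        splits = set()
        for bp in tree.bipartition_encoding:
            side = frozenset(t.label for t in bp.leafset_taxa(tree.taxon_namespace))
            if 1 < len(side) < len(taxa) - 1:
                splits.add(frozenset({side, taxa - side}))
        return splits

    def test_recovers_generating_topology(self):
        newick = build_tree(self._additive_matrix())
        expected = frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})
        assert self._splits(newick) == {expected}

    def test_leaf_order_permutation_invariance(self):
        dm = self._additive_matrix()
        order = ["c", "a", "d", "b"]
        permuted = dm.loc[order, order]
        assert self._splits(build_tree(dm)) == self._splits(build_tree(permuted))

    def test_three_taxa_closed_form(self):
        names = ["a", "b", "c"]
        mat = pd.DataFrame(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
            index=names,
            columns=names,
        )
        newick = build_tree(mat)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        # three-point formulas: la=(dab+dac-dbc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_no_negative_branch_lengths(self, rng):
        names = [f"m{i}" for i in range(6)]
        raw = rng.random((6, 6))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 0.0)
        newick = build_tree(pd.DataFrame(mat, index=names, columns=names))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert all(
            e.length is None or e.length >= 0 for e in tree.preorder_edge_iter()
        )

    def test_two_leaves_degenerate(self):
        mat = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        assert build_tree(mat) == "(a:0.2,b:0.2);"


class TestSelectRepresentatives:
    def test_priority_order(self):
        from mhc2deconv.dq import select_representatives

        pseudos = {
            "DQA10101-DQB10501": "A" * 34,  # covered
            "DQA10102-DQB10501": "A" * 34,  # preferred
            "DQA10103-DQB10501": "A" * 34,  # frequent
            "DQA10104-DQB10501": "A" * 34,
            "DQA10303-DQB10301": "C" * 34,  # unique sequence
        }
        reps = select_representatives(
            pseudos,
            covered=["DQA10101-DQB10501"],
            preferred=["DQA10102-DQB10501"],
            frequencies={"DQA10103-DQB10501": 0.2},
        )
        assert reps == {"DQA10101-DQB10501": "A" * 34, "DQA10303-DQB10301": "C" * 34}
        # without a covered molecule the preferred one wins, then frequency
        reps = select_representatives(
            pseudos, preferred=["DQA10102-DQB10501"],
            frequencies={"DQA10103-DQB10501": 0.2},
        )
        assert "DQA10102-DQB10501" in reps
        reps = select_representatives(pseudos, frequencies={"DQA10103-DQB10501": 0.2})
        assert "DQA10103-DQB10501" in reps

    def test_lexicographic_fallback(self):
        from mhc2deconv.dq import select_representatives

        reps = select_representatives(
            {"DQA10902-DQB10901": "D" * 34, "DQA10901-DQB10901": "D" * 34}
        )
        assert list(reps) == ["DQA10901-DQB10901"]


class TestSpecificityDistance:
    def test_symmetric_zero_diagonal(self, tiny_model, tiny_study):
        mols = sorted(tiny_study.pseudo_table.names())[:5]
        dist = specificity_distance(tiny_model, mols, tiny_study.proteome, n=500, seed=0)
        np.testing.assert_allclose(dist.values, dist.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dist.values), 0.0, atol=1e-12)

    def test_identical_pseudo_zero_distance(self, tiny_model, tiny_study):
        mol = tiny_study.sa_molecules[0]
        alias = "DQA19902-DQB19902"
        tiny_model.pseudo_table.add(alias, tiny_study.pseudo_table[mol])
        dist = specificity_distance(
            tiny_model, [mol, alias], tiny_study.proteome, n=400, seed=0
        )
        assert dist.iloc[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestMotifLogoData:
    def test_exact_core_count(self, tiny_model, tiny_study):
        pssm = motif_logo_data(
            tiny_model, tiny_study.sa_molecules[0], tiny_study.proteome, n=2000, seed=0
        )
        assert pssm.n_peptides == 20

    def test_deterministic(self, tiny_model, tiny_study):
        a = motif_logo_data(
            tiny_model, tiny_study.sa_molecules[0], tiny_study.proteome, n=2000, seed=4
        )
        b = motif_logo_data(
            tiny_model, tiny_study.sa_molecules[0], tiny_study.proteome, n=2000, seed=4
        )
        np.testing.assert_array_equal(a.freq, b.freq)

    def test_recovers_planted_motif(self, tiny_model, tiny_study):
        """The predicted logo of an SA-trained molecule correlates with its
        planted motif."""
        mol = tiny_study.sa_molecules[0]
        pssm = motif_logo_data(tiny_model, mol, tiny_study.proteome, n=5000, seed=1)
        planted = tiny_study.motifs[mol].matrix
        pcc = np.corrcoef(planted.reshape(-1), pssm.freq.reshape(-1))[0, 1]
        assert pcc > 0.8
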