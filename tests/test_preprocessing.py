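import numpy as np
import pytest

from tumortag import (
    AnnotationTable,
    ExpressionMatrix,
    align_features,
    balance_classes_per_domain,
    domain_partition,
    kfold_partition,
    normalize_cells,
    select_hvgs,
    split_train_val,
)

from conftest import random_annotations, random_counts


class TestNormalize:
    def test_hand_oracle(self):
        m = ExpressionMatrix([[1, 1, 2]], ["c1"], ["a", "b", "c"], "raw_counts")
        out = normalize_cells(m, 10_000)
        np.testing.assert_allclose(out.values[0], np.log1p([2500, 2500, 5000]))
        assert out.layer_tag == "normalized"

    def test_all_zero_gene_stays_zero(self, rng):
        m = random_counts(rng, 10, 5)
        m.values[:, 3] = 0
        out = normalize_cells(m)
        assert not out.values[:, 3].any()

    def test_zero_total_cell_listed(self):
        m = ExpressionMatrix([[0, 0], [1, 2]], ["dead", "ok"], ["a", "b"], "raw_counts")
        with pytest.raises(ValueError, match="dead"):
            normalize_cells(m)

    def test_expm1_row_sums_equal_scale_factor(self, rng):
        out = normalize_cells(random_counts(rng, 50, 30), 10_000)
        np.testing.assert_allclose(np.expm1(out.values).sum(axis=1), 10_000, rtol=1e-6)

    def test_matches_scanpy_normalize_total(self, rng):
        sc = pytest.importorskip("scanpy")
        ad = pytest.importorskip("anndata")
        m = random_counts(rng, 30, 20)
        adata = ad.AnnData(m.values.copy())
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        out = normalize_cells(m, 1e4)
        np.testing.assert_allclose(out.values, adata.X, rtol=1e-10)


class TestHvgs:
    def test_matches_brute_force_variance_sort(self, rng):
        m = normalize_cells(random_counts(rng, 50, 30))
        got = select_hvgs(m, 10)
        # brute-force oracle: python-loop variances, stable sort
        variances = []
        for j in range(m.n_genes):
            col = m.values[:, j]
            mu = sum(col) / len(col)
            variances.append(sum((x - mu) ** 2 for x in col) / len(col))
        order = sorted(range(m.n_genes), key=lambda j: (-variances[j], j))
        assert got == [m.gene_ids[j] for j in order[:10]]

    def test_toy_ranking(self):
        vals = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 2.0], [1.0, 2.0, 4.0]])
        m = ExpressionMatrix(vals, ["c1", "c2", "c3"], ["flat", "v1", "v4"], "normalized")
        assert select_hvgs(m, 2) == ["v4", "v1"]

    def test_full_selection_is_permutation(self, rng):
        m = normalize_cells(random_counts(rng, 20, 15))
        assert sorted(select_hvgs(m, 15)) == sorted(m.gene_ids)

    def test_tie_broken_by_input_order(self):
        vals = np.array([[0.0, 1.0, 1.0], [0.0, 2.0, 2.0]])
        m = ExpressionMatrix(vals, ["c1", "c2"], ["z", "first", "second"], "normalized")
        assert select_hvgs(m, 1) == ["first"]

    def test_too_many_requested(self, rng):
        m = normalize_cells(random_counts(rng, 10, 5))
        with pytest.raises(ValueError):
            select_hvgs(m, 6)


class TestBalance:
    def test_downsamples_majority_to_minority(self, rng):
        labels = np.array([1] * 100 + [0] * 300)
        ann = AnnotationTable(
            [f"c{i}" for i in range(400)], labels, ["liver"] * 400
        )
        out = balance_classes_per_domain(ann, seed=0)
        assert (out.labels == 1).sum() == 100 and (out.labels == 0).sum() == 100
        assert set(out.cell_ids) <= set(ann.cell_ids)

    def test_equal_counts_in_every_domain(self, rng):
        ann = random_annotations(rng, 200, 4)
        out = balance_classes_per_domain(ann, seed=1)
        for d, ix in domain_partition(out).items():
            labels = out.labels[ix]
            assert (labels == 1).sum() == (labels == 0).sum()

    def test_already_balanced_unchanged(self):
        ann = AnnotationTable(["a", "b", "c", "d"], [1, 0, 1, 0], ["t1"] * 4)
        out = balance_classes_per_domain(ann, seed=0)
        assert out.cell_ids == ann.cell_ids

    def test_missing_class_names_domain(self):
        ann = AnnotationTable(["a", "b"], [0, 0], ["kidney", "kidney"])
        with pytest.raises(ValueError, match="kidney"):
            balance_classes_per_domain(ann)

    def test_seeded_reproducibility(self, rng):
        ann = random_annotations(rng, 200, 3)
        a = balance_classes_per_domain(ann, seed=7)
        b = balance_classes_per_domain(ann, seed=7)
        assert a.cell_ids == b.cell_ids


class TestSplit:
    def _balanced(self, n_per_stratum=100):
        ids, labels, domains = [], [], []
        for d in ("liver", "lung"):
            for y in (0, 1):
                for i in range(n_per_stratum):
                    ids.append(f"{d}{y}_{i}")
                    labels.append(y)
                    domains.append(d)
        return AnnotationTable(ids, np.array(labels), domains)

    def test_four_to_one_per_stratum(self):
        ann = self._balanced(100)
        train, val = split_train_val(ann, 0.8, seed=0)
        assert len(train) == 320 and len(val) == 80
        for d in ("liver", "lung"):
            for y in (0, 1):
                n_tr = sum(1 for c in train if c.startswith(f"{d}{y}"))
                assert n_tr == 80
        assert not set(train) & set(val)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(self._balanced(10), 1.0, seed=0)

    def test_same_seed_identical(self):
        ann = self._balanced(25)
        assert split_train_val(ann, 0.8, 3) == split_train_val(ann, 0.8, 3)

    def test_singleton_stratum_goes_to_train_with_warning(self):
        ann = AnnotationTable(
            ["a", "b", "c", "d", "e"], [1, 0, 0, 1, 0], ["t", "t", "t", "u", "u"]
        )
        with pytest.warns(UserWarning, match="single cell"):
            train, val = split_train_val(ann, 0.8, seed=0)
        assert "a" in train and "d" in train


class TestKfold:
    def test_five_folds_disjoint_cover(self):
        ann = TestSplit()._balanced(25)  # 100 cells, 4 strata of 25
        folds = kfold_partition(ann, 5, seed=0)
        assert len(folds) == 5
        tests = [set(t) for _, t in folds]
        assert all(len(t) == 20 for t in tests)
        # brute-force disjointness oracle
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]
        assert set().union(*tests) == set(ann.cell_ids)
        for train, test in folds:
            assert not set(train) & set(test)

    def test_two_folds_of_two(self):
        ann = AnnotationTable(["a", "b", "c", "d"], [1, 1, 0, 0], ["t"] * 4)
        folds = kfold_partition(ann, 2, seed=0)
        assert all(len(t) == 2 for _, t in folds)

    def test_k_exceeding_smallest_stratum(self):
        ann = AnnotationTable(["a", "b", "c", "d"], [1, 1, 0, 0], ["t"] * 4)
        with pytest.raises(ValueError, match="stratum"):
            kfold_partition(ann, 3, seed=0)


class TestAlign:
    def _norm(self, rng, genes):
        m = random_counts(rng, 10, len(genes))
        m.gene_ids = list(genes)
        return normalize_cells(m)

    def test_permutation_invariance(self, rng):
        m = self._norm(rng, ["a", "b", "c", "d"])
        perm = m.subset_genes(["d", "b", "a", "c"])
        aligned, frac = align_features(perm, ["a", "b", "c", "d"])
        np.testing.assert_array_equal(aligned.values, m.values)
        assert frac == 0.0

    def test_missing_gene_zero_filled(self, rng):
        m = self._norm(rng, ["a", "b"])
        aligned, frac = align_features(m, ["a", "b", "zz"])
        assert not aligned.values[:, 2].any()
        assert frac == pytest.approx(1 / 3)

    def test_zero_overlap_rejected(self, rng):
        m = self._norm(rng, ["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            align_features(m, ["x", "y"])

    def test_majority_missing_warns_or_fails(self, rng):
        m = self._norm(rng, ["a"])
        with pytest.warns(UserWarning, match="zero-filled"):
            align_features(m, ["a", "x", "y"])
        with pytest.raises(ValueError):
            align_features(m, ["a", "x", "y"], hard_fail=True)
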