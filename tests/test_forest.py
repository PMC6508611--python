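import numpy as np
import pandas as pd
import pytest

from txscore import (
    AnnotationSet,
    FeatureTable,
    RFConfig,
    category_features,
    gene_features,
    pca_embed,
    rf_select,
    top_important,
)
from txscore.errors import DesignError
from conftest import make_study


FAST_RF = RFConfig(n_models=5, n_trees=60, mtry=3)


def _labelled_table(n_per_class=8, n_features=6, gap=4.0, noise=0.5, seed=0,
                    level="gene"):
    """Two-class table with a planted separation on every feature."""
    rng = np.random.default_rng(seed)
    samples, labels, cols = [], {}, []
    for cls, offset in (("x", 0.0), ("y", gap)):
        for i in range(n_per_class):
            s = f"{cls}{i}"
            samples.append(s)
            labels[s] = cls
            cols.append(offset + rng.normal(0, noise, n_features))
    values = pd.DataFrame(
        np.column_stack(cols), columns=samples,
        index=[f"f{i}" for i in range(n_features)],
    )
    return FeatureTable(level=level, values=values, labels=pd.Series(labels))


def _toy_study():
    rng = np.random.default_rng(3)
    samples = [f"s{i}" for i in range(4)]
    matrix = pd.DataFrame(
        rng.normal(6, 1, (5, 4)), index=[f"g{i}" for i in range(5)], columns=samples
    )
    design = {s: ("wt" if i < 2 else "tg") for i, s in enumerate(samples)}
    roles = {"wt": "healthy_control", "tg": "disease_control"}
    return make_study(matrix, design, roles)


class TestFeatureTables:
    def test_gene_features_are_expression_rows(self):
        study = _toy_study()
        table = gene_features(study, {"g1", "g3"})
        assert set(table.values.index) == {"g1", "g3"}
        np.testing.assert_allclose(table.values.loc["g1"], study.matrix.loc["g1"])

    def test_single_gene_category_equals_gene_row(self):
        study = _toy_study()
        annot = AnnotationSet(categories={"C": ("c", frozenset({"g2"}))})
        table = category_features(study, annot, {"g2"}, min_category_size=1)
        np.testing.assert_allclose(table.values.loc["C"], study.matrix.loc["g2"])

    def test_three_gene_category_is_row_mean(self):
        study = _toy_study()
        annot = AnnotationSet(categories={"C": ("c", frozenset({"g0", "g1", "g4"}))})
        table = category_features(study, annot, {"g0", "g1", "g4"},
                                  min_category_size=3)
        np.testing.assert_allclose(
            table.values.loc["C"],
            study.matrix.loc[["g0", "g1", "g4"]].mean(axis=0),
        )

    def test_category_outside_de_genes_absent(self):
        study = _toy_study()
        annot = AnnotationSet(
            categories={"IN": ("i", frozenset({"g0"})),
                        "OUT": ("o", frozenset({"g3"}))}
        )
        table = category_features(study, annot, {"g0"}, min_category_size=1)
        assert "OUT" not in table.values.index
        with pytest.raises(ValueError):
            category_features(study, annot, {"g2"}, min_category_size=1)


class TestRFSelect:
    def test_separable_classes_perfect(self):
        table = _labelled_table(gap=6.0, noise=0.3)
        result = rf_select(table, FAST_RF, seed=1)
        assert result.oob_error == 0.0
        assert result.test_accuracy == 1.0
        assert int(np.diag(result.confusion).sum()) == result.confusion.to_numpy().sum()

    def test_reproducible_given_seed(self):
        table = _labelled_table(gap=1.0, noise=1.0)
        r1 = rf_select(table, FAST_RF, seed=7)
        r2 = rf_select(table, FAST_RF, seed=7)
        assert r1.oob_errors == r2.oob_errors
        assert r1.model_index == r2.model_index
        pd.testing.assert_series_equal(r1.importances, r2.importances)

    def test_winner_oob_not_above_median(self):
        table = _labelled_table(gap=1.5, noise=1.2, seed=5)
        result = rf_select(table, RFConfig(n_models=9, n_trees=60, mtry=3), seed=2)
        assert result.oob_error <= float(np.median(result.oob_errors))

    def test_mtry_clamped_to_feature_count(self):
        table = _labelled_table(n_features=2, gap=5.0)
        result = rf_select(table, RFConfig(n_models=3, n_trees=40, mtry=10), seed=0)
        assert result.test_accuracy == 1.0

    def test_singleton_class_rejected(self):
        table = _labelled_table(n_per_class=4)
        labels = table.labels.copy()
        labels.iloc[0] = "lonely"
        bad = FeatureTable(level="gene", values=table.values, labels=labels)
        with pytest.raises(DesignError, match="lonely"):
            rf_select(bad, FAST_RF, seed=0)

    def test_confusion_row_sums_match_test_counts(self):
        table = _labelled_table(gap=2.0, noise=1.0, seed=8)
        result = rf_select(table, FAST_RF, seed=3)
        # stratified 70/30 on 8+8 samples -> 5 test samples, 2-3 per class
        row_sums = list(result.confusion.sum(axis=1))
        assert sum(row_sums) == 5
        assert all(n in (2, 3) for n in row_sums)

    def test_category_beats_gene_level_on_block_signal(self):
        # class signal spread over a 6-gene block, noise on 30 others:
        # averaging the block cancels noise, single genes do not
        rng = np.random.default_rng(12)
        n_per, n_noise = 7, 30
        samples, labels = [], {}
        block_rows, noise_rows = [], []
        for cls, offset in (("x", 0.0), ("y", 1.2)):
            for i in range(n_per):
                s = f"{cls}{i}"
                samples.append(s)
                labels[s] = cls
        n = len(samples)
        offsets = np.array([0.0] * n_per + [1.2] * n_per)
        block = offsets + rng.normal(0, 1.0, (6, n))
        noise = rng.normal(0, 1.0, (n_noise, n))
        values = pd.DataFrame(
            np.vstack([block, noise]), columns=samples,
            index=[f"b{i}" for i in range(6)] + [f"n{i}" for i in range(n_noise)],
        )
        labels = pd.Series(labels)
        gene_table = FeatureTable(level="gene", values=values, labels=labels)
        cat_values = pd.DataFrame(
            {"BLOCK": values.iloc[:6].mean(axis=0),
             "NOISE": values.iloc[6:].mean(axis=0)}
        ).T
        cat_table = FeatureTable(level="category", values=cat_values, labels=labels)
        rf = RFConfig(n_models=10, n_trees=100, mtry=2)
        acc_gene = rf_select(gene_table, rf, seed=4).test_accuracy
        acc_cat = rf_select(cat_table, rf, seed=4).test_accuracy
        assert acc_cat >= acc_gene


class TestTopImportant:
    def test_full_ranking_and_range_check(self):
        table = _labelled_table()
        result = rf_select(table, FAST_RF, seed=1)
        assert len(top_important(result, len(result.importances))) == 6
        with pytest.raises(ValueError):
            top_important(result, 7)

    def test_planted_informative_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            samples = [f"s{i}" for i in range(16)]
            labels = pd.Series(
                {s: ("x" if i < 8 else "y") for i, s in enumerate(samples)}
            )
            noise = rng.normal(0, 1, (9, 16))
            signal = np.r_[np.zeros(8), np.full(8, 5.0)] + rng.normal(0, 0.3, 16)
            values = pd.DataFrame(
                np.vstack([signal, noise]), columns=samples,
                index=["signal"] + [f"noise{i}" for i in range(9)],
            )
            table = FeatureTable(level="gene", values=values, labels=labels)
            result = rf_select(table, RFConfig(n_models=3, n_trees=80, mtry=3),
                               seed=seed)
            hits += top_important(result, 1)[0] == "signal"
        assert hits >= 9

    def test_dominant_feature_rank_stable_under_feature_permutation(self):
        # one feature carries all the class signal; permuting the feature
        # rows must not change which feature is ranked most important
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(16)]
        labels = pd.Series({s: ("x" if i < 8 else "y")
                            for i, s in enumerate(samples)})
        signal = np.r_[np.zeros(8), np.full(8, 6.0)] + rng.normal(0, 0.3, 16)
        noise = rng.normal(0, 1, (5, 16))
        values = pd.DataFrame(
            np.vstack([signal, noise]), columns=samples,
            index=["signal"] + [f"noise{i}" for i in range(5)],
        )
        table = FeatureTable(level="gene", values=values, labels=labels)
        permuted = FeatureTable(level="gene", values=values.iloc[::-1],
                                labels=labels)
        r1 = rf_select(table, FAST_RF, seed=5)
        r2 = rf_select(permuted, FAST_RF, seed=5)
        assert top_important(r1, 1) == top_important(r2, 1) == ["signal"]


class TestPCAEmbed:
    def test_rank_one_data_single_component(self, caplog):
        base = np.linspace(0, 1, 8)
        values = pd.DataFrame(
            np.outer([1.0, 2.0, -1.0], base),
            index=["f0", "f1", "f2"],
            columns=[f"s{i}" for i in range(8)],
        )
        labels = pd.Series({f"s{i}": "x" if i < 4 else "y" for i in range(8)})
        table = FeatureTable(level="gene", values=values, labels=labels)
        with caplog.at_level("WARNING"):
            coords, explained = pca_embed(table)
        assert coords.shape[1] == 2  # condition + PC1
        assert explained[0] == pytest.approx(1.0)

    def test_rotation_invariance_up_to_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (4, 12))
        x[0] += np.r_[np.zeros(6), np.full(6, 3.0)]
        values = pd.DataFrame(x, index=[f"f{i}" for i in range(4)],
                              columns=[f"s{i}" for i in range(12)])
        labels = pd.Series({f"s{i}": "x" if i < 6 else "y" for i in range(12)})
        table = FeatureTable(level="gene", values=values, labels=labels)
        coords, _ = pca_embed(table)
        # orthogonal rotation of the feature space
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = pd.DataFrame(q @ x, index=values.index, columns=values.columns)
        table_r = FeatureTable(level="gene", values=rotated, labels=labels)
        coords_r, _ = pca_embed(table_r)
        for pc in ("PC1", "PC2"):
            a, b = coords[pc].to_numpy(), coords_r[pc].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_planted_groups_separated_on_pc1(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.3, (5, 14))
        x[:, 7:] += 4.0
        values = pd.DataFrame(x, index=[f"f{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(14)])
        labels = pd.Series({f"s{i}": "x" if i < 7 else "y" for i in range(14)})
        table = FeatureTable(level="gene", values=values, labels=labels)
        coords, _ = pca_embed(table)
        a = coords.loc[labels == "x", "PC1"]
        b = coords.loc[labels == "y", "PC1"]
        assert a.max() < b.min() or b.max() < a.min()
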