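import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from meltstr import (
    ContractError,
    Genotype,
    accuracy,
    build_confusion,
    chance_rate,
    collapse_confusion,
    genotypes_near,
    load_reference_confusion,
    load_schemes,
    near_miss_rate,
    per_class_recall,
    subset_accuracy,
)
from meltstr.evaluation import ConfusionMatrix, GenoGroupScheme, evaluate_grouping_options

D5_HOMO = ["(11,11)", "(12,12)", "(13,13)"]
D5_HET = ["(10,11)", "(11,12)", "(11,13)", "(12,13)"]


@pytest.fixture(scope="module")
def d5_pca():
    return load_reference_confusion("confusion_d5s818_pca")


@pytest.fixture(scope="module")
def d5_lda():
    return load_reference_confusion("confusion_d5s818_lda")


@pytest.fixture(scope="module")
def d18_pca():
    return load_reference_confusion("confusion_d18s51_pca")


@pytest.fixture(scope="module")
def d18_lda():
    return load_reference_confusion("confusion_d18s51_lda")


class TestBuildConfusion:
    def test_perfect_predictions_diagonal(self):
        labels = ["a", "b", "c"]
        seq = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        cm = build_confusion(seq, seq, labels)
        assert cm.trace == 10
        assert cm.misclassified == 0
        np.testing.assert_array_equal(cm.counts, np.diag([4, 3, 3]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractError, match="label"):
            build_confusion(["a"], ["z"], ["a", "b"])

    def test_d5_lda_fixture_row_sums(self, d5_lda):
        # published design: 9-49 unknowns per genotype, 185 total
        sums = d5_lda.row_totals()
        assert d5_lda.total == 185
        assert sums.min() >= 9 and sums.max() <= 49

    def test_d18_pca_fixture_row_sums(self, d18_pca):
        # published design: 14-20 unknowns per genotype, 104 total
        assert d18_pca.total == 104
        sums = d18_pca.row_totals()
        assert sums.min() >= 14 and sums.max() <= 20


class TestAccuracy:
    def test_d5_lda_overall(self, d5_lda):
        assert d5_lda.trace == 109
        assert accuracy(d5_lda) == pytest.approx(109 / 185)
        assert round(100 * accuracy(d5_lda), 2) == 58.92

    def test_d18_lda_overall(self, d18_lda):
        assert round(100 * accuracy(d18_lda), 2) == 45.10

    def test_d18_pca_overall(self, d18_pca):
        assert round(100 * accuracy(d18_pca), 2) == 40.38

    def test_identity_matrix(self):
        cm = ConfusionMatrix(labels=list("abcde"), counts=np.diag([3, 1, 4, 1, 5]))
        assert accuracy(cm) == 1.0


class TestSubsetAccuracy:
    def test_d5_lda_homozygous_micro(self, d5_lda):
        assert round(100 * subset_accuracy(d5_lda, D5_HOMO, "micro"), 2) == 65.08

    def test_d5_lda_heterozygous_micro(self, d5_lda):
        assert round(100 * subset_accuracy(d5_lda, D5_HET, "micro"), 2) == 55.74

    def test_d5_pca_homozygous_macro(self, d5_pca):
        assert round(100 * subset_accuracy(d5_pca, D5_HOMO, "macro"), 2) == 39.58

    def test_d5_pca_heterozygous_macro(self, d5_pca):
        assert round(100 * subset_accuracy(d5_pca, D5_HET, "macro"), 2) == 20.18

    def test_full_subset_micro_equals_overall(self, d5_lda):
        assert subset_accuracy(d5_lda, d5_lda.labels, "micro") == pytest.approx(accuracy(d5_lda))

    def test_partition_micro_weighted_average_is_overall(self, d18_pca):
        homo_like = d18_pca.labels[:3]
        rest = d18_pca.labels[3:]
        totals = d18_pca.row_totals()
        w1 = totals[:3].sum()
        w2 = totals[3:].sum()
        combined = (
            w1 * subset_accuracy(d18_pca, homo_like, "micro")
            + w2 * subset_accuracy(d18_pca, rest, "micro")
        ) / (w1 + w2)
        assert combined == pytest.approx(accuracy(d18_pca), abs=1e-12)

    def test_empty_subset_rejected(self, d5_lda):
        with pytest.raises(ContractError):
            subset_accuracy(d5_lda, [], "micro")


class TestPerClassRecall:
    def test_d18_pca_12_16(self, d18_pca):
        rec = per_class_recall(d18_pca)["(12,16)"]
        assert rec == pytest.approx(8 / 14)
        assert round(100 * rec, 2) == 57.14

    def test_identity_all_ones(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.diag([2, 7]))
        assert per_class_recall(cm) == {"a": 1.0, "b": 1.0}

    def test_uniform_two_class(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.array([[1, 1], [1, 1]]))
        assert per_class_recall(cm) == {"a": 0.5, "b": 0.5}

    def test_zero_row_flagged_absent(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.array([[0, 0], [0, 3]]))
        assert per_class_recall(cm)["a"] is None


class TestNearMiss:
    @pytest.mark.parametrize(
        "g, p, expected",
        [
            (("(12,14)"), ("(12,15)"), True),
            (("(12,14)"), ("(13,16)"), False),
            (("(12,14)"), ("(13,14)"), True),
            (("(12,14)"), ("(12,16)"), False),
            (("(11,11)"), ("(11,12)"), True),
            (("(11,11)"), ("(12,12)"), False),
            (("(13,14)"), ("(14,15)"), False),
        ],
    )
    def test_predicate(self, g, p, expected):
        assert genotypes_near(Genotype.from_label(g), Genotype.from_label(p)) is expected

    @given(
        a=st.integers(8, 20), b=st.integers(8, 20), c=st.integers(8, 20), d=st.integers(8, 20)
    )
    def test_predicate_symmetric(self, a, b, c, d):
        g, p = Genotype(a, b), Genotype(c, d)
        assert genotypes_near(g, p) == genotypes_near(p, g)
        assert genotypes_near(g, g) is False

    def test_d18_pca_near_miss_rate(self, d18_pca):
        rate = near_miss_rate(d18_pca)
        assert rate == pytest.approx(25 / 62)
        assert round(100 * rate, 2) == 40.32

    def test_diagonal_matrix_undefined(self):
        cm = ConfusionMatrix(labels=["(11,11)", "(11,12)"], counts=np.diag([4, 4]))
        assert near_miss_rate(cm) is None


class TestCollapse:
    def test_d5_lda_option_a_brute_force(self, d5_lda):
        # oracle: sum the within/between-group cells of the printed matrix
        scheme = load_schemes("D5S818")["A"]
        expected = np.zeros((3, 3), dtype=int)
        order = list(scheme.group_order)
        for i, li in enumerate(d5_lda.labels):
            for j, lj in enumerate(d5_lda.labels):
                expected[order.index(scheme.mapping[li]), order.index(scheme.mapping[lj])] += (
                    d5_lda.counts[i, j]
                )
        collapsed = collapse_confusion(d5_lda, scheme)
        np.testing.assert_array_equal(collapsed.counts, expected)
        assert collapsed.total == 185
        assert collapsed.trace == 147
        assert accuracy(collapsed) == pytest.approx(147 / 185)

    def test_identity_scheme_is_noop(self, d18_lda):
        scheme = GenoGroupScheme.identity(d18_lda.labels)
        collapsed = collapse_confusion(d18_lda, scheme)
        np.testing.assert_array_equal(collapsed.counts, d18_lda.counts)

    def test_single_group_scheme_perfect(self, d18_pca):
        scheme = GenoGroupScheme(
            name="all", mapping={l: "G" for l in d18_pca.labels}, group_order=("G",)
        )
        collapsed = collapse_confusion(d18_pca, scheme)
        assert collapsed.counts.shape == (1, 1)
        assert accuracy(collapsed) == 1.0

    def test_unmapped_label_rejected(self, d5_lda):
        scheme = GenoGroupScheme(name="partial", mapping={"(10,11)": "G1"})
        with pytest.raises(ContractError, match="not mapped"):
            collapse_confusion(d5_lda, scheme)

    @given(
        counts=arrays(
            np.int64, (7, 7), elements=st.integers(0, 30)
        ).filter(lambda a: a.sum() > 0)
    )
    def test_collapse_conserves_and_never_hurts_all_schemes(self, counts):
        labels = ["(10,11)", "(11,11)", "(11,12)", "(11,13)", "(12,12)", "(12,13)", "(13,13)"]
        cm = ConfusionMatrix(labels=labels, counts=counts)
        for scheme in load_schemes("D5S818").values():
            collapsed = collapse_confusion(cm, scheme)
            assert collapsed.total == cm.total
            assert accuracy(collapsed) >= accuracy(cm)

    @given(
        counts=arrays(
            np.int64, (6, 6), elements=st.integers(0, 30)
        ).filter(lambda a: a.sum() > 0)
    )
    def test_collapse_properties_d18_schemes(self, counts):
        labels = ["(12,14)", "(12,15)", "(12,16)", "(13,14)", "(13,16)", "(14,15)"]
        cm = ConfusionMatrix(labels=labels, counts=counts)
        for scheme in load_schemes("D18S51").values():
            collapsed = collapse_confusion(cm, scheme)
            assert collapsed.total == cm.total
            assert accuracy(collapsed) >= accuracy(cm)


class TestChanceRate:
    def test_seven_genotypes(self):
        assert chance_rate(7) == pytest.approx(1 / 7)
        assert round(100 * chance_rate(7), 2) == 14.29

    def test_degenerate_and_small(self):
        assert chance_rate(1) == 1.0
        assert chance_rate(6) == pytest.approx(1 / 6)

    def test_invalid(self):
        with pytest.raises(ContractError):
            chance_rate(0)


class TestSchemeFixtures:
    def test_all_eleven_schemes_present(self):
        d5 = load_schemes("D5S818")
        d18 = load_schemes("D18S51")
        assert sorted(d5) == ["A", "B", "C", "F", "H", "J"]
        assert sorted(d18) == ["A", "C", "E", "F", "G"]

    def test_schemes_cover_panels_disjointly(self, d5_pca, d18_pca):
        for cm, schemes in ((d5_pca, load_schemes("D5S818")), (d18_pca, load_schemes("D18S51"))):
            for scheme in schemes.values():
                assert sorted(scheme.mapping) == sorted(cm.labels)  # exact cover

    def test_d5_option_a_groups(self):
        scheme = load_schemes("D5S818")["A"]
        assert scheme.mapping["(10,11)"] == "Group 1"
        assert scheme.mapping["(11,13)"] == "Group 1"
        assert scheme.mapping["(11,12)"] == "Group 2"
        assert scheme.mapping["(12,12)"] == "Group 2"
        assert {scheme.mapping[l] for l in ["(11,11)", "(12,13)", "(13,13)"]} == {"Group 3"}


class TestGroupingOptions:
    @staticmethod
    def _nearest_mean_classifier():
        def fit(X, labels):
            X = np.asarray(X, float)
            uniq = sorted(set(labels))
            means = {c: X[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) for c in uniq}
            return means

        def predict(model, X):
            X = np.asarray(X, float)
            labs = list(model)
            return [
                labs[int(np.argmin([np.linalg.norm(x - model[c]) for c in labs]))] for x in X
            ]

        return fit, predict

    @pytest.fixture()
    def toy_problem(self):
        rng = np.random.default_rng(3)
        labels = ["(10,11)", "(11,11)", "(11,12)", "(11,13)", "(12,12)", "(12,13)", "(13,13)"]
        centers = {l: rng.normal(0, 4, 2) for l in labels}
        tr_X, tr_y, te_X, te_y = [], [], [], []
        for l, c in centers.items():
            for _ in range(6):
                tr_X.append(c + rng.normal(0, 1.2, 2))
                tr_y.append(l)
            for _ in range(10):
                te_X.append(c + rng.normal(0, 1.2, 2))
                te_y.append(l)
        return np.array(tr_X), tr_y, np.array(te_X), te_y

    def test_collapse_never_below_ungrouped(self, toy_problem):
        fit, predict = self._nearest_mean_classifier()
        tr_X, tr_y, te_X, te_y = toy_problem
        model = fit(tr_X, tr_y)
        from meltstr.evaluation import build_confusion as bc

        base = accuracy(bc(te_y, predict(model, te_X), sorted(set(te_y))))
        results = evaluate_grouping_options(
            fit, predict, tr_X, tr_y, te_X, te_y,
            schemes=list(load_schemes("D5S818").values()), protocols=("collapse",),
        )
        assert all(r.accuracy >= base for r in results)

    def test_identity_scheme_collapse_reproduces_ungrouped(self, toy_problem):
        fit, predict = self._nearest_mean_classifier()
        tr_X, tr_y, te_X, te_y = toy_problem
        ident = GenoGroupScheme.identity(sorted(set(tr_y)))
        (res,) = evaluate_grouping_options(
            fit, predict, tr_X, tr_y, te_X, te_y, schemes=[ident], protocols=("collapse",)
        )
        model = fit(tr_X, tr_y)
        from meltstr.evaluation import build_confusion as bc

        base = accuracy(bc(te_y, predict(model, te_X), sorted(set(te_y))))
        assert res.accuracy == pytest.approx(base, abs=1e-12)

    def test_lda_grouping_on_simulated_panel(self, separable_dataset):
        from meltstr import features_from_curve
        from meltstr.evaluation import lda_fit_predict

        stds = [s for s in separable_dataset if s.role == "standard"]
        unks = [s for s in separable_dataset if s.role == "unknown"]
        tr_X = np.array([features_from_curve(s.curve, k=3).values for s in stds])
        te_X = np.array([features_from_curve(s.curve, k=3).values for s in unks])
        tr_y = [s.genotype.label for s in stds]
        te_y = [s.genotype.label for s in unks]
        fit, predict = lda_fit_predict()
        results = evaluate_grouping_options(
            fit, predict, tr_X, tr_y, te_X, te_y,
            schemes=[load_schemes("D5S818")["A"]], protocols=("collapse", "retrain"),
        )
        assert {r.protocol for r in results} == {"collapse", "retrain"}
        by_protocol = {r.protocol: r for r in results}
        for r in results:
            assert r.confusion.total == len(te_y)
            assert r.accuracy > 1 / 3  # well above the 3-group chance rate
        # collapsing an already-accurate genotype-level matrix cannot hurt it;
        # retraining on merged labels may (one Gaussian per multimodal group)
        model = fit(tr_X, tr_y)
        base = accuracy(build_confusion(te_y, predict(model, te_X), sorted(set(te_y))))
        assert by_protocol["collapse"].accuracy >= base

    def test_retrain_protocol_returns_group_matrices(self, toy_problem):
        fit, predict = self._nearest_mean_classifier()
        tr_X, tr_y, te_X, te_y = toy_problem
        results = evaluate_grouping_options(
            fit, predict, tr_X, tr_y, te_X, te_y,
            schemes=[load_schemes("D5S818")["A"]], protocols=("retrain",),
        )
        (res,) = results
        assert res.confusion.counts.shape == (3, 3)
        assert res.confusion.labels == ["Group 1", "Group 2", "Group 3"]
        assert res.confusion.total == len(te_y)
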