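import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from isoniche.data_io import PREY_CATEGORIES
from isoniche.diet_classifier import (
    balance_dataset,
    exact_shapley_small,
    shapley_importance,
    smote_oversample,
    tune_and_evaluate_rf,
)
from isoniche.synthetic_data import (
    DietClassSpec,
    DietSimSpec,
    PreyDistribution,
    generate_diet_dataset,
)
from conftest import SMALL_GRID


def _two_class_spec(n=100, p_hi=0.9, p_lo=0.05, prey="sipunculids"):
    """Two species differing only in one prey's occurrence probability."""
    classes = []
    for sp, p_occ in (("H_dipterurus", p_lo), ("N_entemedor", p_hi)):
        d = {q: PreyDistribution(0.5, 0.0, 0.6) for q in PREY_CATEGORIES}
        d[prey] = PreyDistribution(p_occ, 1.0, 0.6)
        classes.append(
            DietClassSpec(
                labels={
                    "species": sp, "sex": "female",
                    "stage": "adult", "season": "warm",
                },
                n=n,
                prey=d,
            )
        )
    return DietSimSpec(classes=classes)


@pytest.fixture(scope="module")
def separable_diet():
    return generate_diet_dataset(_two_class_spec(), seed=7)


@pytest.fixture(scope="module")
def tiny_forest(separable_diet):
    x = separable_diet[list(PREY_CATEGORIES)].to_numpy()
    y = (separable_diet["species"] == "N_entemedor").astype(int)
    return RandomForestClassifier(
        n_estimators=25, max_depth=3, random_state=0
    ).fit(x, y)


class TestBalancing:
    def test_undersample_and_smote_to_target(self, diet_table):
        sub = diet_table[diet_table["species"] == "H_dipterurus"]
        counts = sub["stage"].value_counts()
        assert counts["juvenile"] > 100 > counts["adult"]
        out = balance_dataset(sub, "stage", n_target=100, seed=1)
        assert out["stage"].value_counts().to_dict() == {
            "adult": 100, "juvenile": 100,
        }

    def test_already_balanced_unchanged(self, separable_diet):
        out = balance_dataset(separable_diet, "species", n_target=100, seed=2)
        assert len(out) == len(separable_diet)
        assert sorted(out["individual_id"]) == sorted(
            separable_diet["individual_id"]
        )

    def test_minority_too_small_for_k(self, separable_diet):
        tiny = pd.concat(
            [
                separable_diet[separable_diet["species"] == "N_entemedor"],
                separable_diet[separable_diet["species"] == "H_dipterurus"].head(3),
            ]
        )
        with pytest.raises(ValueError, match="smaller k"):
            balance_dataset(tiny, "species", n_target=50, k_neighbors=5, seed=0)

    def test_smote_points_within_minority_feature_bounds(self, rng):
        x = rng.random((30, len(PREY_CATEGORIES))) * 10
        synth = smote_oversample(x, n_new=200, k_neighbors=5, rng=rng)
        assert (synth >= x.min(axis=0) - 1e-12).all()
        assert (synth <= x.max(axis=0) + 1e-12).all()

    def test_balancing_preserves_schema(self, diet_table):
        sub = diet_table[diet_table["species"] == "H_dipterurus"]
        out = balance_dataset(sub, "stage", n_target=120, seed=3)
        assert list(out.columns) == list(sub.columns)
        assert (out[list(PREY_CATEGORIES)].to_numpy() >= 0).all()


class TestTuning:
    def test_separable_task_high_auc(self, separable_diet):
        rep = tune_and_evaluate_rf(
            separable_diet, "species", grid=SMALL_GRID, seed=0
        )
        assert rep.test_auc > 0.9
        assert rep.positive_class == "N_entemedor"

    def test_shuffled_labels_near_chance(self, separable_diet):
        rng = np.random.default_rng(0)
        aucs = []
        for s in range(10):
            d = separable_diet.copy()
            d["species"] = rng.permutation(d["species"].to_numpy())
            try:
                rep = tune_and_evaluate_rf(d, "species", grid=SMALL_GRID, seed=s)
            except ValueError:
                continue
            aucs.append(rep.test_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_too_few_rows_rejected(self, separable_diet):
        with pytest.raises(ValueError, match="20 rows"):
            tune_and_evaluate_rf(separable_diet.head(10), "species")

    def test_report_records_grid_choice(self, separable_diet):
        rep = tune_and_evaluate_rf(
            separable_diet, "species", grid=SMALL_GRID, seed=1
        )
        assert rep.n_estimators in SMALL_GRID["n_estimators"]
        assert rep.max_depth in SMALL_GRID["max_depth"]
        assert rep.cv_auc >= 0.0 and rep.test_auc <= 1.0


class TestShapley:
    def test_exact_single_feature_is_full_marginal(self):
        # with one feature the Shapley value is f(x) - mean background f
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        phi = exact_shapley_small(tree, np.array([3.0]), x)
        fx = tree.predict_proba([[3.0]])[0, 1]
        base = tree.predict_proba(x)[:, 1].mean()
        assert phi[0] == pytest.approx(fx - base, abs=1e-12)

    def test_exact_symmetry_for_duplicated_features(self, rng):
        # a model exactly symmetric in its two inputs must assign them
        # identical Shapley values (symmetry axiom)
        class SymmetricModel:
            def predict_proba(self, x):
                p = 1.0 / (1.0 + np.exp(-(x[:, 0] + x[:, 1])))
                return np.column_stack([1 - p, p])

        bg = rng.random((40, 2))
        phi = exact_shapley_small(
            SymmetricModel(), np.array([0.9, 0.9]), np.vstack([bg, bg[:, ::-1]])
        )
        assert phi[0] == pytest.approx(phi[1], abs=1e-10)

    def test_exact_two_feature_stump_hand_computed(self):
        # stump splits on feature 0 at 0.5 (feature 1 is uninformative);
        # f = 1 if x0 > 0.5 else 0, background x0 = (0, 0, 1, 1) -> E f = 0.5
        # v({}) = 0.5, v({0}) = 1, v({1}) = 0.5, v({0,1}) = 1 -> phi = (0.5, 0)
        x = np.array([[0.0, 5.0], [0.0, 7.0], [1.0, 6.0], [1.0, 8.0]])
        y = np.array([0, 0, 1, 1])
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        assert tree.tree_.feature[0] == 0
        phi = exact_shapley_small(tree, np.array([1.0, 7.0]), x)
        assert phi == pytest.approx([0.5, 0.0], abs=1e-12)

    def test_estimator_local_accuracy(self, tiny_forest, separable_diet):
        rows = separable_diet.head(3)
        imp = shapley_importance(
            tiny_forest, rows, n_samples=20, seed=0,
            background=separable_diet, max_background=30,
        )
        x = rows[list(PREY_CATEGORIES)].to_numpy()
        preds = tiny_forest.predict_proba(x)[:, 1]
        totals = imp.values.sum(axis=1).to_numpy() + imp.baseline
        assert np.allclose(totals, preds, atol=1e-6)

    def test_estimator_agrees_with_exact_oracle(self, tiny_forest, separable_diet):
        row = separable_diet.head(1)
        bg = separable_diet.head(25)
        imp = shapley_importance(
            tiny_forest, row, n_samples=100, seed=1,
            background=bg, max_background=25,
        )
        exact = exact_shapley_small(
            tiny_forest,
            row[list(PREY_CATEGORIES)].to_numpy()[0],
            bg[list(PREY_CATEGORIES)].to_numpy(),
        )
        est = imp.values.to_numpy()[0]
        se = np.maximum(imp.std_errors.to_numpy()[0], 1e-4)
        assert (np.abs(est - exact) <= 3 * se).all()

    def test_unused_feature_gets_zero_attribution(self, separable_diet):
        # forest trained on a single informative feature ignores the rest
        x = separable_diet[list(PREY_CATEGORIES)].to_numpy().copy()
        x[:, 1:] = 0.0
        y = (separable_diet["species"] == "N_entemedor").astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=2).fit(x, y)
        d = separable_diet.copy()
        d.loc[:, list(PREY_CATEGORIES)[1:]] = 0.0
        imp = shapley_importance(
            forest, d.head(2), n_samples=20, seed=3, background=d,
            max_background=20,
        )
        assert np.allclose(imp.values.to_numpy()[:, 1:], 0.0, atol=1e-12)

    def test_small_sample_budget_rejected(self, tiny_forest, separable_diet):
        with pytest.raises(ValueError, match="n_samples"):
            shapley_importance(tiny_forest, separable_diet.head(1), n_samples=5)

    def test_exact_guard_on_feature_count(self, tiny_forest):
        with pytest.raises(ValueError, match="12"):
            exact_shapley_small(tiny_forest, np.zeros(13), np.zeros((5, 13)))

    def test_global_ranking_identifies_discriminant_prey(
        self, tiny_forest, separable_diet
    ):
        imp = shapley_importance(
            tiny_forest, separable_diet.head(30), n_samples=20, seed=4,
            background=separable_diet, max_background=30,
        )
        assert imp.global_ranking().index[0] == "sipunculids"
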