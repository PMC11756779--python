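import numpy as np
import pandas as pd
import pytest
from scipy import stats

from syntharm.errors import ArgumentError
from syntharm.generators import (
    GeneratorSpec,
    exponential_mechanism,
    fit,
    fit_privbayes_conditionals,
    fit_privbayes_structure,
    mutual_information,
    sample,
    sample_bayesnet,
)
from syntharm.trial_data import FeatureSchema, TrialDataset


def exact_mi_2x2(joint):
    """Oracle: plug-in mutual information (bits) from an explicit 2x2 joint."""
    joint = np.asarray(joint, dtype=float)
    joint = joint / joint.sum()
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log2(joint[i, j] / (px[i] * py[j]))
    return mi


def categorical_dataset(columns: dict, categories: dict | None = None) -> TrialDataset:
    df = pd.DataFrame(columns)
    n = len(df)
    cats = categories or {}
    schema = [
        FeatureSchema(
            name=c,
            ftype="categorical",
            categories=tuple(cats.get(c, sorted(df[c].unique()))),
        )
        for c in df.columns
    ]
    schema += [
        FeatureSchema(name="arm", ftype="binary", categories=("c", "a"), role="arm"),
        FeatureSchema(name="time", ftype="categorical", categories=("t0", "t1"),
                      role="survival_time"),
        FeatureSchema(name="event", ftype="binary", categories=(0, 1),
                      role="event_indicator"),
    ]
    df["arm"] = "c"
    df["time"] = "t0"
    df["event"] = [0, 1] * (n // 2) + [0] * (n % 2)
    return TrialDataset(schema=schema, df=df)


class TestMutualInformation:
    def test_matches_exact_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 500)
        y = np.where(rng.uniform(size=500) < 0.8, x, 1 - x)
        joint = np.zeros((2, 2))
        for xi, yi in zip(x, y):
            joint[xi, yi] += 1
        assert mutual_information(x, y) == pytest.approx(exact_mi_2x2(joint), abs=1e-12)

    def test_independent_is_zero(self):
        x = np.repeat([0, 1], 50)
        y = np.tile([0, 1], 50)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)


class TestBaselines:
    def test_dummy_state_is_copy(self, small_cohort):
        g = fit(GeneratorSpec("dummy"), small_cohort, seed=0)
        pd.testing.assert_frame_equal(g.state.df, small_cohort.df)

    def test_dummy_full_size_replicates(self, small_cohort):
        g = fit(GeneratorSpec("dummy"), small_cohort, seed=0)
        out = sample(g, small_cohort.n_patients, seed=1)
        pd.testing.assert_frame_equal(out.df, small_cohort.df)

    def test_dummy_other_sizes_resample(self, small_cohort):
        g = fit(GeneratorSpec("dummy"), small_cohort, seed=0)
        out = sample(g, 50, seed=1)
        assert out.n_patients == 50

    def test_uniform_state_is_supports_only(self, small_cohort):
        g = fit(GeneratorSpec("uniform"), small_cohort, seed=0)
        assert set(g.state) == {f.name for f in small_cohort.schema}
        assert g.state["age"] == (small_cohort.df["age"].min(), small_cohort.df["age"].max())

    def test_uniform_binary_frequency(self, small_cohort):
        g = fit(GeneratorSpec("uniform"), small_cohort, seed=0)
        out = sample(g, 10_000, seed=2)
        freq = (out.df["bin_0"] == 1).mean()
        assert abs(freq - 0.5) < 0.015  # 3 binomial SEs at n=1e4

    def test_uniform_single_category_constant(self):
        d = categorical_dataset({"only": ["k"] * 10})
        g = fit(GeneratorSpec("uniform"), d, seed=0)
        out = sample(g, 25, seed=0)
        assert (out.df["only"] == "k").all()

    def test_independent_preserves_marginals(self, small_cohort):
        g = fit(GeneratorSpec("independent"), small_cohort, seed=0)
        out = sample(g, 20_000, seed=3)
        p_train = (small_cohort.df["bin_0"] == 1).mean()
        assert abs((out.df["bin_0"] == 1).mean() - p_train) < 0.02

    def test_sample_validates_n(self, small_cohort):
        g = fit(GeneratorSpec("dummy"), small_cohort, seed=0)
        with pytest.raises(ArgumentError):
            sample(g, 0, seed=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ArgumentError):
            GeneratorSpec("magic")


class TestPrivBayesStructure:
    def test_continuous_feature_rejected(self, small_cohort):
        with pytest.raises(ArgumentError, match="generalize"):
            fit(GeneratorSpec("privbayes"), small_cohort, seed=0)

    def test_k0_gives_independent_structure(self):
        rng = np.random.default_rng(1)
        d = categorical_dataset({"a": rng.integers(0, 2, 100), "b": rng.integers(0, 2, 100)})
        model = fit_privbayes_structure(d, k=0, epsilon_structure=1.0, seed=0)
        assert all(p == () for p in model.parents.values())

    def test_correlated_pair_linked_at_high_epsilon(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 400)
        c = rng.integers(0, 2, 400)
        d = categorical_dataset({"a": a, "b": a.copy(), "cc": c})
        for seed in range(5):
            model = fit_privbayes_structure(d, k=1, epsilon_structure=1e6, seed=seed)
            linked = ("a" in model.parents["b"]) or ("b" in model.parents["a"])
            assert linked

    def test_epsilon_zero_limit_uniform_choice(self):
        # with a fixed node order, the last node's parent choice must be
        # indistinguishable from uniform over its candidate sets
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 300)
        d = categorical_dataset(
            {"a": a, "b": a.copy(), "cc": rng.integers(0, 2, 300), "dd": rng.integers(0, 2, 300)}
        )
        order = ["a", "b", "cc", "time", "event", "arm", "dd"]
        candidates = [(), ("a",), ("b",), ("cc",), ("time",), ("event",), ("arm",)]
        counts = {c: 0 for c in candidates}
        for seed in range(200):
            model = fit_privbayes_structure(d, k=1, epsilon_structure=1e-9, seed=seed,
                                            order=order)
            counts[model.parents["dd"]] += 1
        observed = np.array(list(counts.values()))
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01

    def test_exponential_mechanism_maximizes_at_high_epsilon(self):
        rng = np.random.default_rng(0)
        picks = {exponential_mechanism([0.1, 0.9, 0.2], 1e9, 1.0, rng) for _ in range(20)}
        assert picks == {1}


class TestPrivBayesConditionals:
    def test_tables_match_empirical_at_high_epsilon(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 5000)
        b = np.where(rng.uniform(size=5000) < 0.9, a, 1 - a)
        d = categorical_dataset({"a": a, "b": b})
        model = fit_privbayes_structure(d, k=1, epsilon_structure=1e6, seed=0,
                                        order=["a", "b", "time", "event", "arm"])
        model = fit_privbayes_conditionals(d, model, epsilon_params=1e6, seed=1)
        emp = pd.crosstab(d.df["a"], d.df["b"], normalize="index")
        if model.parents["b"] == ("a",):
            for av in (0, 1):
                row = model.tables["b"][(av,)]
                np.testing.assert_allclose(row, emp.loc[av].to_numpy(), atol=0.01)

    def test_rows_sum_to_one_any_epsilon(self):
        rng = np.random.default_rng(5)
        d = categorical_dataset({"a": rng.integers(0, 3, 60), "b": rng.integers(0, 2, 60)},
                                categories={"a": (0, 1, 2), "b": (0, 1)})
        model = fit_privbayes_structure(d, k=2, epsilon_structure=0.5, seed=0)
        model = fit_privbayes_conditionals(d, model, epsilon_params=0.01, seed=1)
        for node, table in model.tables.items():
            for row in table.values():
                assert row.sum() == pytest.approx(1.0)
                assert (row >= 0).all()

    def test_unseen_parent_config_uniform(self):
        d = categorical_dataset({"a": [0] * 40, "b": [0, 1] * 20},
                                categories={"a": (0, 1), "b": (0, 1)})
        model = fit_privbayes_structure(d, k=1, epsilon_structure=1e6, seed=0,
                                        order=["a", "b", "time", "event", "arm"])
        model.parents["b"] = ("a",)  # force the dependency for the check
        model = fit_privbayes_conditionals(d, model, epsilon_params=1e9, seed=1)
        np.testing.assert_allclose(model.tables["b"][(1,)], [0.5, 0.5])


class TestBayesNetSampling:
    def _chain_model(self):
        from syntharm.generators import BayesNetModel

        model = BayesNetModel(
            order=["a", "b"],
            parents={"a": (), "b": ("a",)},
            categories={"a": (0, 1), "b": (0, 1)},
        )
        model.tables = {
            "a": {(): np.array([0.7, 0.3])},
            "b": {(0,): np.array([1.0, 0.0]), (1,): np.array([0.0, 1.0])},  # b = a
        }
        return model

    def test_deterministic_chain(self):
        df = sample_bayesnet(self._chain_model(), 500, seed=0)
        assert (df["a"] == df["b"]).all()

    def test_single_node_binomial_frequency(self):
        from syntharm.generators import BayesNetModel

        model = BayesNetModel(order=["a"], parents={"a": ()}, categories={"a": (0, 1)})
        model.tables = {"a": {(): np.array([0.7, 0.3])}}
        df = sample_bayesnet(model, 10_000, seed=1)
        assert abs((df["a"] == 1).mean() - 0.3) < 0.014  # 3 binomial SEs

    def test_independent_structure_low_mi(self):
        from syntharm.generators import BayesNetModel

        model = BayesNetModel(
            order=["a", "b"], parents={"a": (), "b": ()},
            categories={"a": (0, 1), "b": (0, 1)},
        )
        model.tables = {"a": {(): np.array([0.5, 0.5])}, "b": {(): np.array([0.5, 0.5])}}
        df = sample_bayesnet(model, 10_000, seed=2)
        assert mutual_information(df["a"], df["b"]) < 0.01

    def test_missing_table_rejected(self):
        model = self._chain_model()
        del model.tables["b"]
        with pytest.raises(ArgumentError):
            sample_bayesnet(model, 10, seed=0)


class TestPrivBayesEndToEnd:
    def test_epsilon_accounting(self):
        rng = np.random.default_rng(6)
        d = categorical_dataset({"a": rng.integers(0, 2, 100)})
        g = fit(GeneratorSpec("privbayes", {"epsilon": 4.0, "max_parents": 1}), d, seed=0)
        assert g.state.epsilon_total == pytest.approx(4.0)
        assert g.epsilon_spent == pytest.approx(4.0)

    def test_sample_validates_against_schema(self):
        rng = np.random.default_rng(7)
        d = categorical_dataset({"a": rng.integers(0, 2, 200), "b": rng.integers(0, 3, 200)},
                                categories={"a": (0, 1), "b": (0, 1, 2)})
        g = fit(GeneratorSpec("privbayes", {"epsilon": 10.0}), d, seed=1)
        out = sample(g, 150, seed=2)
        assert out.n_patients == 150
        out.validate()

    def test_fit_deterministic(self):
        rng = np.random.default_rng(8)
        d = categorical_dataset({"a": rng.integers(0, 2, 100)})
        s1 = sample(fit(GeneratorSpec("privbayes"), d, seed=5), 40, seed=9)
        s2 = sample(fit(GeneratorSpec("privbayes"), d, seed=5), 40, seed=9)
        pd.testing.assert_frame_equal(s1.df, s2.df)


class _ConstantPlugin:
    """Toy external generator used to exercise the plugin contract."""

    def fit(self, d, seed):
        self._row = d.df.iloc[[0]]

    def sample(self, n, seed):
        return pd.concat([self._row] * n, ignore_index=True)


def constant_plugin_factory():
    return _ConstantPlugin()


class TestExternalPlugin:
    def test_entry_point_resolution(self, small_cohort):
        spec = GeneratorSpec(
            "external",
            {"entry_point": f"{__name__}:constant_plugin_factory"},
        )
        g = fit(spec, small_cohort, seed=0)
        out = sample(g, 7, seed=0)
        assert out.n_patients == 7
        assert (out.df["age"] == small_cohort.df.loc[0, "age"]).all()

    def test_missing_entry_point_rejected(self, small_cohort):
        with pytest.raises(ArgumentError):
            fit(GeneratorSpec("external"), small_cohort, seed=0)
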