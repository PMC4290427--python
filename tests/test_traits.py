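import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from isolocal.errors import (
    ConfigError,
    DegenerateInputError,
    ImputationError,
    StandardizationError,
)
from isolocal.traits import (
    TraitDistanceMatrix,
    TraitTypeSpec,
    gower_matrix,
    impute_incomparable_pairs,
    mean_pairwise_distance,
    read_trait_table,
    restrict_to_community,
    standardize_quantitative,
    trait_apd,
    trait_uniqueness,
)

from .oracles import brute_gower


def random_mixed_table(seed: int, n_species=8, missing=0.25):
    """Random mixed-type trait table with injected missingness."""
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n_species)]
    n_quant = int(rng.integers(1, 4))
    n_ord = int(rng.integers(0, 3))
    n_nom = int(rng.integers(1, 4))
    data, kinds = {}, {}
    for j in range(n_quant):
        data[f"q{j}"] = rng.normal(5, 2, n_species)
        kinds[f"q{j}"] = "quantitative"
    for j in range(n_ord):
        data[f"o{j}"] = rng.integers(1, 5, n_species).astype(float)
        kinds[f"o{j}"] = "ordinal"
    for j in range(n_nom):
        data[f"c{j}"] = rng.choice(list("uvw"), n_species)
        kinds[f"c{j}"] = "nominal"
    table = pd.DataFrame(data, index=labels)
    mask = rng.random(table.shape) < missing
    table = table.mask(mask)
    return table, TraitTypeSpec(kinds, {k: False for k, v in kinds.items()
                                        if v == "quantitative"})


class TestStandardize:
    def test_divides_by_column_mean(self):
        table = pd.DataFrame({"a": [2.0, 4.0, np.nan]}, index=list("xyz"))
        spec = TraitTypeSpec({"a": "quantitative"})
        out = standardize_quantitative(table, spec)
        assert out["a"].tolist()[:2] == pytest.approx([2 / 3, 4 / 3])
        assert np.isnan(out["a"].iloc[2])

    def test_constant_column_becomes_ones(self):
        table = pd.DataFrame({"a": [5.0, 5.0]}, index=["x", "y"])
        out = standardize_quantitative(table, TraitTypeSpec({"a": "quantitative"}))
        assert out["a"].tolist() == [1.0, 1.0]

    def test_zero_mean_errors_naming_column(self):
        table = pd.DataFrame({"a": [0.0, 0.0]}, index=["x", "y"])
        with pytest.raises(StandardizationError, match="'a'"):
            standardize_quantitative(table, TraitTypeSpec({"a": "quantitative"}))

    def test_unflagged_column_untouched(self):
        table = pd.DataFrame({"a": [2.0, 4.0]}, index=["x", "y"])
        spec = TraitTypeSpec({"a": "quantitative"}, {"a": False})
        assert standardize_quantitative(table, spec)["a"].tolist() == [2.0, 4.0]


class TestGower:
    def test_worked_example(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        df = m.to_dataframe()
        assert df.loc["X", "Y"] == 0.5
        assert df.loc["Y", "Z"] == 0.5
        assert df.loc["X", "Z"] == 1.0

    def test_identical_rows_distance_zero(self):
        table = pd.DataFrame(
            {"a": [1.0, 1.0], "c": ["u", "u"]}, index=["x", "y"]
        )
        spec = TraitTypeSpec({"a": "quantitative", "c": "nominal"}, {"a": False})
        with pytest.warns(UserWarning, match="zero range"):
            m = gower_matrix(table, spec)
        assert m.values[0, 1] == 0.0

    def test_all_nominal_all_different_is_one(self):
        table = pd.DataFrame(
            {"c1": ["u", "v"], "c2": ["p", "q"], "c3": ["m", "n"]},
            index=["x", "y"],
        )
        spec = TraitTypeSpec({c: "nominal" for c in table.columns})
        assert gower_matrix(table, spec).values[0, 1] == 1.0

    def test_ordinal_uses_rank_scale(self):
        # values 1, 2, 100 -> ranks 1, 2, 3: equal spacing
        table = pd.DataFrame({"o": [1.0, 2.0, 100.0]}, index=list("xyz"))
        m = gower_matrix(table, TraitTypeSpec({"o": "ordinal"}))
        assert m.values[0, 1] == pytest.approx(0.5)
        assert m.values[1, 2] == pytest.approx(0.5)

    def test_single_species_degenerate(self):
        table = pd.DataFrame({"a": [1.0]}, index=["x"])
        with pytest.raises(DegenerateInputError):
            gower_matrix(table, TraitTypeSpec({"a": "quantitative"}))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        table, spec = random_mixed_table(seed, n_species=int(3 + seed % 10))
        m = gower_matrix(table, spec)
        expected = brute_gower(table, spec.kinds)
        for i, a in enumerate(m.labels):
            for j, b in enumerate(m.labels):
                e = expected[(a, b)]
                if e is None:
                    assert np.isnan(m.values[i, j])
                else:
                    assert m.values[i, j] == pytest.approx(e, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_range_symmetry_zero_diagonal(self, seed):
        table, spec = random_mixed_table(seed * 7 + 1, n_species=10, missing=0.3)
        m = gower_matrix(table, spec)
        vals = m.values
        finite = ~np.isnan(vals)
        assert ((vals[finite] >= 0) & (vals[finite] <= 1)).all()
        assert np.array_equal(vals, vals.T, equal_nan=True)
        assert (np.diag(vals) == 0).all()

    def test_fully_missing_column_changes_nothing(self):
        table, spec = random_mixed_table(5, n_species=6)
        m1 = gower_matrix(table, spec)
        table2 = table.copy()
        table2["extra"] = np.nan
        spec2 = TraitTypeSpec(
            dict(spec.kinds, extra="quantitative"),
            dict(spec.standardize, extra=False),
        )
        m2 = gower_matrix(table2, spec2)
        assert np.array_equal(m1.values, m2.values, equal_nan=True)


class TestImputation:
    def _matrix_with_incomparable(self):
        # three computable distances {0.5, 0.5, 1.0} and one incomparable pair
        values = np.array(
            [
                [0.0, 0.5, 0.5, np.nan],
                [0.5, 0.0, 1.0, 0.2],
                [0.5, 1.0, 0.0, 0.7],
                [np.nan, 0.2, 0.7, 0.0],
            ]
        )
        return TraitDistanceMatrix(
            list("wxyz"), values, np.zeros((4, 4), dtype=bool)
        )

    def test_median_fill_and_mask(self):
        m = impute_incomparable_pairs(self._matrix_with_incomparable())
        # median of {0.5, 0.5, 1.0, 0.2, 0.7} = 0.5
        assert m.values[0, 3] == 0.5 and m.values[3, 0] == 0.5
        assert m.imputed[0, 3] and m.imputed[3, 0]
        assert m.imputed.sum() == 2

    def test_no_incomparable_is_identity(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        m2 = impute_incomparable_pairs(m)
        assert np.array_equal(m.values, m2.values)
        assert not m2.imputed.any()

    def test_median_of_single_pair(self):
        values = np.array(
            [[0.0, 0.3, np.nan], [0.3, 0.0, np.nan], [np.nan, np.nan, 0.0]]
        )
        m = TraitDistanceMatrix(list("abc"), values, np.zeros((3, 3), bool))
        assert impute_incomparable_pairs(m).values[0, 2] == 0.3

    def test_no_computable_pairs_errors(self):
        values = np.full((2, 2), np.nan)
        np.fill_diagonal(values, 0.0)
        m = TraitDistanceMatrix(["a", "b"], values, np.zeros((2, 2), bool))
        with pytest.raises(ImputationError):
            impute_incomparable_pairs(m)


class TestTraitMetrics:
    def test_tu_worked_example(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        assert trait_uniqueness(m).to_dict() == {"X": 0.5, "Y": 0.5, "Z": 0.5}

    def test_tapd_worked_example(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        assert trait_apd(m).to_dict() == {"X": 0.75, "Y": 0.5, "Z": 0.75}

    def test_duplicated_species_gives_zero_tu(self):
        table = pd.DataFrame(
            {"a": [1.0, 1.0, 5.0], "c": ["u", "u", "v"]}, index=list("xyz")
        )
        spec = TraitTypeSpec({"a": "quantitative", "c": "nominal"}, {"a": False})
        tu = trait_uniqueness(gower_matrix(table, spec))
        assert tu["x"] == 0.0 and tu["y"] == 0.0

    def test_two_species(self):
        values = np.array([[0.0, 0.7], [0.7, 0.0]])
        m = TraitDistanceMatrix(["a", "b"], values, np.zeros((2, 2), bool))
        assert trait_uniqueness(m).tolist() == [0.7, 0.7]
        assert trait_apd(m).tolist() == [0.7, 0.7]
        assert mean_pairwise_distance(m) == 0.7

    def test_restrict_recomputes_local_scope(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        sub = restrict_to_community(m, ["X", "Z"], scope="c1")
        assert sub.scope == "c1"
        assert sub.values[0, 1] == 1.0
        assert trait_uniqueness(sub).to_dict() == {"X": 1.0, "Z": 1.0}
        # local TU equals min over the same global distances restricted to S
        full = m.to_dataframe()
        assert trait_uniqueness(sub)["X"] == full.loc["X", "Z"]

    def test_restrict_full_set_identity(self, xyz_traits):
        m = gower_matrix(*xyz_traits)
        sub = restrict_to_community(m, ["X", "Y", "Z"])
        assert np.array_equal(sub.values, m.values)


class TestIO:
    def test_csv_missing_codes(self, tmp_path):
        path = tmp_path / "traits.csv"
        path.write_text("species,mass,habitat\nX,1.0,forest\nY,NA,\n")
        table = read_trait_table(str(path))
        assert np.isnan(pd.to_numeric(table.loc["Y", "mass"]))
        assert pd.isna(table.loc["Y", "habitat"])

    def test_spec_file_roundtrip(self, tmp_path, xyz_traits):
        _, spec = xyz_traits
        path = tmp_path / "spec.json"
        spec.to_file(str(path))
        again = TraitTypeSpec.from_file(str(path))
        assert again.kinds == spec.kinds
        assert again.standardize == spec.standardize

    def test_spec_table_mismatch(self, xyz_traits):
        table, _ = xyz_traits
        bad = TraitTypeSpec({"mass": "quantitative"})
        with pytest.raises(ConfigError, match="habitat"):
            gower_matrix(table, bad)


@given(st.integers(min_value=0, max_value=10_000))
def test_gower_bounds_property(seed):
    """All computable Gower distances lie in [0, 1] with a zero diagonal,
    on arbitrary randomized mixed tables with missingness."""
    table, spec = random_mixed_table(seed, n_species=6, missing=0.35)
    vals = gower_matrix(table, spec).values
    finite = ~np.isnan(vals)
    assert ((vals[finite] >= -1e-12) & (vals[finite] <= 1 + 1e-12)).all()
    assert (np.diag(vals) == 0).all()
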