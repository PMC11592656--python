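import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldwcnn.clinical_io import (CellParseError, SchemaMismatchError,
                                ZeroVarianceError, denormalize, impute,
                                normalize, read_table, stratified_split,
                                write_arff, write_csv)
from ldwcnn.synthdata import generate, make_schema_preset

from conftest import table_from_arrays


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _mini_liver_csv(tmp_path, body):
    schema = make_schema_preset("liver")
    header = ",".join([m.name for m in schema.feature_meta] + [schema.label_column])
    p = tmp_path / "mini.csv"
    p.write_text(header + "\n" + body)
    return p, schema


def test_csv_missing_markers_become_missing_slots(tmp_path):
    row = "45,Male,1.0,0.3,200,25,20,6.8,3.8,1.0,1"
    qrow = "45,Male,?,0.3,200,25,20,6.8,3.8,1.0,2"
    p, schema = _mini_liver_csv(tmp_path, "\n".join([row, qrow, row]) + "\n")
    t = read_table(p, schema)
    assert t.n_rows == 3
    assert int(t.data.isna().sum().sum()) == 1
    assert t.labels.tolist() == [1, 0, 1]


def test_empty_file_is_an_error_not_an_empty_table(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    with pytest.raises(ValueError):
        read_table(p, make_schema_preset("liver"))


def test_schema_mismatch_names_the_offending_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("foo,bar\n1,2\n")
    with pytest.raises(SchemaMismatchError, match="foo"):
        read_table(p, make_schema_preset("liver"))


def test_unparseable_numeric_cell_reports_row_index(tmp_path):
    row = "45,Male,1.0,0.3,200,25,20,6.8,3.8,1.0,1"
    bad = "45,Male,oops,0.3,200,25,20,6.8,3.8,1.0,1"
    p, schema = _mini_liver_csv(tmp_path, "\n".join([row, bad]) + "\n")
    with pytest.raises(CellParseError, match="row 1"):
        read_table(p, schema)


def test_csv_round_trip_preserves_shape_labels_and_missingness(tmp_path):
    schema = make_schema_preset("kidney")
    t = generate(schema, 40, effect_size=1.0, missing_rate=0.1, seed=3)
    p = tmp_path / "kidney.csv"
    write_csv(t, p, label_column=schema.label_column)
    back = read_table(p, schema)
    assert back.n_rows == t.n_rows
    assert back.labels.tolist() == t.labels.tolist()
    assert int(back.data.isna().sum().sum()) == int(t.data.isna().sum().sum())


def test_arff_round_trip_on_mixed_type_table(tmp_path):
    schema = make_schema_preset("kidney")
    t = generate(schema, 30, effect_size=1.0, missing_rate=0.08, seed=5)
    p = tmp_path / "kidney.arff"
    write_arff(t, p, label_column=schema.label_column)
    back = read_table(p, schema)
    assert back.n_rows == 30
    assert back.labels.tolist() == t.labels.tolist()
    cont = [m.name for m in schema.feature_meta if m.kind == "continuous"]
    np.testing.assert_allclose(back.data[cont].to_numpy(float),
                               t.data[cont].to_numpy(float), rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def test_mean_and_mode_imputation():
    schema = make_schema_preset("liver")
    t = generate(schema, 20, effect_size=0.5, missing_rate=0.0, seed=1)
    t.data.loc[1, "tb"] = np.nan
    t.data.loc[2, "gender"] = np.nan
    out = impute(t)
    observed = t.data["tb"].drop(index=1).astype(float)
    assert out.data.loc[1, "tb"] == pytest.approx(observed.mean())
    assert out.data.loc[2, "gender"] == t.data["gender"].mode().iloc[0]
    assert not out.has_missing()


@pytest.mark.parametrize("column,values,expected", [
    ("cont", [1.0, np.nan, 3.0], [1.0, 2.0, 3.0]),
])
def test_continuous_impute_worked_example(column, values, expected):
    t = table_from_arrays(np.array(values)[:, None], [0, 0, 1])
    out = impute(t)
    assert out.data["f0"].tolist() == expected


def test_impute_is_idempotent_and_preserves_rows(liver_table):
    once = impute(liver_table)
    twice = impute(once)
    assert once.n_rows == liver_table.n_rows
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_drop_rows_strategy_removes_incomplete_rows(liver_table):
    out = impute(liver_table, "drop_rows")
    assert not out.has_missing()
    assert out.n_rows == int((~liver_table.data.isna().any(axis=1)).sum())


def test_entirely_missing_column_is_an_error():
    t = table_from_arrays(np.array([[1.0], [2.0]]), [0, 1])
    t.data["f0"] = np.nan
    with pytest.raises(ValueError, match="f0"):
        impute(t)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def test_two_point_normalisation_worked_example():
    train = table_from_arrays(np.array([[2.0], [4.0]]), [0, 1])
    params, (out,) = normalize(train)
    assert params.means["f0"] == pytest.approx(3.0)
    assert out.data["f0"].mean() == pytest.approx(0.0, abs=1e-12)


def test_params_fit_on_train_apply_identically_to_heldout():
    train = table_from_arrays(np.array([[1.0], [2.0], [6.0]]), [0, 1, 1])
    held = table_from_arrays(np.array([[1.0], [2.0], [6.0]]), [0, 0, 1])
    _, (tr, ho) = normalize(train, [held])
    np.testing.assert_allclose(tr.to_matrix(), ho.to_matrix())


def test_train_columns_standardised_and_roundtrip(liver_table):
    t = impute(liver_table)
    params, (out,) = normalize(t)
    cont = [m.name for m in t.feature_meta if m.kind == "continuous"]
    X = out.data[cont].to_numpy(float)
    np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-9)
    back = denormalize(out, params)
    np.testing.assert_allclose(back.data[cont].to_numpy(float),
                               t.data[cont].to_numpy(float), atol=1e-9)


def test_one_hot_columns_cover_training_categories(liver_table):
    t = impute(liver_table)
    _, (out,) = normalize(t)
    assert "gender=Male" in out.data.columns
    assert "gender=Female" in out.data.columns
    onehot = out.data[["gender=Male", "gender=Female"]].to_numpy()
    np.testing.assert_allclose(onehot.sum(axis=1), 1.0)


def test_zero_variance_column_raises_with_name():
    t = table_from_arrays(np.array([[1.0, 5.0], [2.0, 5.0]]), [0, 1])
    with pytest.raises(ZeroVarianceError, match="f1"):
        normalize(t)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def test_balanced_divisible_split_is_exact():
    rng = np.random.default_rng(0)
    t = table_from_arrays(rng.normal(size=(100, 3)), [0] * 50 + [1] * 50)
    b = stratified_split(t, (0.6, 0.2, 0.2), seed=11)
    assert (b.train.n_rows, b.validation.n_rows, b.test.n_rows) == (60, 20, 20)
    for part, n in ((b.train, 30), (b.validation, 10), (b.test, 10)):
        assert part.class_counts().tolist() == [n, n]


def test_same_seed_reproduces_identical_assignment(liver_table):
    t = impute(liver_table)
    b1 = stratified_split(t, seed=4)
    b2 = stratified_split(t, seed=4)
    for p1, p2 in ((b1.train, b2.train), (b1.test, b2.test)):
        pd.testing.assert_frame_equal(p1.data, p2.data)
        assert p1.labels.tolist() == p2.labels.tolist()


def test_bad_ratios_rejected(liver_table):
    with pytest.raises(ValueError):
        stratified_split(liver_table, (0.5, 0.5, 0.5), seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(30, 120), seed=st.integers(0, 10_000))
def test_split_partitions_table_with_stratification(n, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, size=n)
    y[:3] = [0, 1, 2]
    X = rng.normal(size=(n, 2))
    X[:, 0] = np.arange(n)  # row identity channel
    t = table_from_arrays(X, y, 3)
    b = stratified_split(t, (0.6, 0.2, 0.2), seed=seed)
    ids = np.concatenate([p.data["f0"].to_numpy() for p in
                          (b.train, b.validation, b.test)])
    assert sorted(ids.astype(int).tolist()) == list(range(n))
    for part, frac in ((b.train, 0.6), (b.validation, 0.2), (b.test, 0.2)):
        for k in range(3):
            expected = frac * (y == k).sum()
            assert abs(part.class_counts()[k] - expected) <= 1.0 + 1e-9


def test_rare_class_warns_and_lands_in_train():
    t = table_from_arrays(np.arange(22, dtype=float)[:, None],
                          [0] * 10 + [1] * 10 + [2] * 2, 3)
    with pytest.warns(UserWarning, match="< 3 rows"):
        b = stratified_split(t, (0.6, 0.2, 0.2), seed=0)
    assert b.train.class_counts()[2] == 2
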