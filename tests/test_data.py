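"""Ingestion, FFQ scoring, tertiles and the phenotype transform."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from acemod.data import (
    CompletenessError,
    DegenerateVarianceError,
    FFQ_CATEGORIES,
    HIGH_SUGAR_CUTPOINTS,
    SchemaError,
    StructuralError,
    UNHEALTHY_CUTPOINTS,
    UNHEALTHY_ITEMS,
    VocabularyError,
    assign_tertile,
    compose_food_score,
    default_ffq_mapping,
    ffq_to_servings,
    load_twin_table,
    transform_phenotype,
)

from conftest import make_twin_csv, twin_row


# ---------------------------------------------------------------------------
# FFQ conversion and food scores
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("category,expected", [
    ("never", 0.0),
    ("1-3 times/month", 2.0 / 30),
    ("1-2 times/week", 1.5 / 7),        # midpoint 1.5 per week
    ("3-4 times/week", 3.5 / 7),
    ("5-6 times/week", 5.5 / 7),
    ("1 time/day", 1.0),
    ("2 times/day", 2.0),
    ("3 times/day", 3.0),
])
def test_ffq_midpoint_convention(category, expected):
    assert ffq_to_servings(category) == pytest.approx(expected, abs=1e-12)


def test_ffq_category_canonicalization_and_monotonicity():
    # en-dash and stray whitespace are accepted
    assert ffq_to_servings("1–2 times/week") == pytest.approx(1.5 / 7)
    assert ffq_to_servings("  NEVER ") == 0.0
    with pytest.raises(VocabularyError):
        ffq_to_servings("sometimes")
    vals = [ffq_to_servings(c) for c in FFQ_CATEGORIES]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_compose_food_score_sums_item_set():
    items = {it: 0.0 for it in UNHEALTHY_ITEMS}
    assert compose_food_score(items, "unhealthy") == 0.0
    # the unhealthy list has 23 items
    items = {it: 0.2 for it in UNHEALTHY_ITEMS}
    assert compose_food_score(items, "unhealthy") == pytest.approx(4.6)
    sugar = {it: 0.0 for it in default_ffq_mapping().high_sugar_items}
    sugar["cookies"] = 1.0
    sugar["candy"] = 0.5
    assert compose_food_score(sugar, "high_sugar") == pytest.approx(1.5)


def test_compose_food_score_missing_item_is_error_and_permutation_invariant():
    items = {it: 0.1 for it in UNHEALTHY_ITEMS}
    items.pop("pizza")
    with pytest.raises(CompletenessError, match="pizza"):
        compose_food_score(items, "unhealthy")
    rng = np.random.default_rng(0)
    vals = {it: float(v) for it, v in
            zip(UNHEALTHY_ITEMS, rng.uniform(0, 1, len(UNHEALTHY_ITEMS)))}
    shuffled = dict(sorted(vals.items(), key=lambda kv: hash(kv[0])))
    assert compose_food_score(vals, "unhealthy") == compose_food_score(
        shuffled, "unhealthy")


@given(st.floats(min_value=0.0, max_value=20.0, allow_nan=False))
def test_tertile_boundary_closure(servings):
    lo, hi = HIGH_SUGAR_CUTPOINTS
    label = assign_tertile(servings, "high_sugar")
    if servings <= lo:
        assert label == "low"
    elif servings >= hi:
        assert label == "high"
    else:
        assert label == "middle"


def test_tertile_published_cutpoints():
    assert assign_tertile(1.0, "high_sugar") == "low"
    assert assign_tertile(4.5, "unhealthy") == "high"
    assert assign_tertile(1.56, cutpoints=HIGH_SUGAR_CUTPOINTS) == "low"
    assert assign_tertile(2.90, cutpoints=HIGH_SUGAR_CUTPOINTS) == "high"
    assert assign_tertile(2.61, cutpoints=UNHEALTHY_CUTPOINTS) == "low"
    with pytest.raises(ValueError):
        assign_tertile(-0.1, "unhealthy")


def test_empirical_tertiles_balance_on_continuous_scores():
    rng = np.random.default_rng(3)
    x = rng.lognormal(1.0, 0.5, size=3000)
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    labels = np.array([assign_tertile(v, cutpoints=(lo, hi)) for v in x])
    for lab in ("low", "middle", "high"):
        frac = np.mean(labels == lab)
        assert 0.30 <= frac <= 0.367


# ---------------------------------------------------------------------------
# Phenotype transform
# ---------------------------------------------------------------------------

def test_transform_two_point_symmetry():
    y, meta = transform_phenotype([0.0, math.e - 1.0])
    assert y == pytest.approx([-math.sqrt(0.5), math.sqrt(0.5)])
    assert np.std(y, ddof=1) == pytest.approx(1.0)
    assert meta.log_offset == 1.0


def test_transform_output_standardized_and_decorrelated():
    rng = np.random.default_rng(11)
    n = 1000
    age = rng.uniform(20, 47, n)
    sex = (rng.random(n) < 0.3).astype(float)
    lam = np.exp(0.3 + 0.02 * (age - 33))
    raw = rng.poisson(lam)
    y, meta = transform_phenotype(raw, age=age, sex=sex)
    assert abs(np.mean(y)) < 1e-8
    assert abs(np.std(y, ddof=1) - 1.0) < 1e-8
    assert abs(np.corrcoef(y, age)[0, 1]) < 0.02
    assert "age" in meta.covariate_coefs


def test_transform_invariant_to_affine_age_rescale():
    rng = np.random.default_rng(5)
    raw = rng.poisson(2.0, 400)
    age = rng.uniform(20, 47, 400)
    sex = (rng.random(400) < 0.5).astype(float)
    y1, _ = transform_phenotype(raw, age=age, sex=sex)
    y2, _ = transform_phenotype(raw, age=age / 10.0 + 3.0, sex=sex)
    np.testing.assert_allclose(y1, y2, atol=1e-8)


def test_transform_degenerate_and_invalid_inputs():
    with pytest.raises(DegenerateVarianceError):
        transform_phenotype([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        transform_phenotype([1.0, np.nan])
    # both orderings of standardization and residualization end standardized
    rng = np.random.default_rng(9)
    raw = rng.poisson(2.0, 200)
    age = rng.uniform(20, 47, 200)
    y, _ = transform_phenotype(raw, age=age, method="residualize_then_standardize")
    assert abs(np.mean(y)) < 1e-8 and abs(np.std(y, ddof=1) - 1.0) < 1e-8


# ---------------------------------------------------------------------------
# Loading and the dataset
# ---------------------------------------------------------------------------

def _complete_rows(n_pairs=3):
    rows = []
    for i in range(n_pairs):
        zyg = "MZ" if i % 2 == 0 else "DZ"
        rows.append(twin_row(f"p{i}", 1, zyg, ia=i, sugar=0.5 + i))
        rows.append(twin_row(f"p{i}", 2, zyg, ia=i + 1, sugar=1.0 + i))
    return rows


def test_load_complete_pairs(tmp_path):
    path = make_twin_csv(tmp_path / "t.csv", _complete_rows(3))
    ds = load_twin_table(path)
    assert ds.n_pairs == 3
    assert ds.load_report.pairs_dropped == 0
    counts = ds.zygosity_counts()
    assert counts["MZ"] + counts["DZ"] == 3


def test_load_drops_singleton_with_report(tmp_path):
    rows = _complete_rows(3) + [twin_row("lonely", 1)]
    path = make_twin_csv(tmp_path / "t.csv", rows)
    ds = load_twin_table(path)
    assert ds.n_pairs == 3
    assert ds.load_report.singletons_dropped == ["lonely"]


def test_load_vocabulary_canonicalization(tmp_path):
    rows = _complete_rows(2)
    rows[0]["zygosity"] = "mz "
    rows[1]["zygosity"] = " MZ"
    path = make_twin_csv(tmp_path / "t.csv", rows)
    ds = load_twin_table(path)
    assert set(ds.df["zygosity"]) <= {"MZ", "DZ"}

    rows[0]["zygosity"] = "XZ"
    path = make_twin_csv(tmp_path / "bad.csv", rows)
    with pytest.raises(StructuralError, match="XZ"):
        load_twin_table(path)


def test_load_errors(tmp_path):
    rows = _complete_rows(2)
    df = pd.DataFrame(rows).drop(columns=["zygosity"])
    p = tmp_path / "m.csv"
    df.to_csv(p, index=False)
    with pytest.raises(SchemaError, match="zygosity"):
        load_twin_table(p)

    rows = _complete_rows(2) + [twin_row("p0", 1)]  # p0 now has 3 rows
    path = make_twin_csv(tmp_path / "tri.csv", rows)
    with pytest.raises(StructuralError, match="p0"):
        load_twin_table(path)

    rows = _complete_rows(2)
    rows[2]["inattention_raw"] = "seven"
    path = make_twin_csv(tmp_path / "nn.csv", rows)
    with pytest.raises(ValueError, match="inattention_raw"):
        load_twin_table(path)


def test_load_with_schema_map(tmp_path):
    rows = _complete_rows(2)
    df = pd.DataFrame(rows).rename(columns={"pair_id": "fam", "zygosity": "zyg"})
    p = tmp_path / "s.csv"
    df.to_csv(p, index=False)
    ds = load_twin_table(p, schema={"pair_id": "fam", "zygosity": "zyg"})
    assert ds.n_pairs == 2


def test_roundtrip_csv_bit_identical(tmp_path, paper_cohort):
    ds, _ = paper_cohort
    out = tmp_path / "rt.csv"
    ds.to_csv(out)
    back = load_twin_table(out)
    for col in ("age", "inattention_raw", "sugar_servings", "unhealthy_servings"):
        a1, a2, _ = ds.pair_arrays(col)
        b1, b2, _ = back.pair_arrays(col)
        np.testing.assert_array_equal(a1, b1)
        np.testing.assert_array_equal(a2, b2)


def test_prepare_attaches_standardized_columns(tmp_path):
    rows = []
    rng = np.random.default_rng(2)
    for i in range(40):
        zyg = "MZ" if i % 2 else "DZ"
        for order in (1, 2):
            rows.append(twin_row(
                f"p{i}", order, zyg,
                sex="male" if rng.random() < 0.3 else "female",
                age=float(rng.uniform(20, 47)),
                ia=int(rng.poisson(2)), hi=int(rng.poisson(2)),
                sugar=float(rng.uniform(0, 6)), unhealthy=float(rng.uniform(0, 8))))
    path = make_twin_csv(tmp_path / "p.csv", rows)
    ds = load_twin_table(path).prepare()
    for col in ("y_inattention", "y_hyperactivity", "m_sugar", "m_unhealthy"):
        v = ds.df[col].to_numpy(float)
        assert abs(np.mean(v)) < 1e-8
        assert abs(np.std(v, ddof=1) - 1.0) < 1e-8
    assert set(ds.df["sugar_tertile"]) <= {"low", "middle", "high"}
    assert ds.tertile_cutpoints["unhealthy"] == UNHEALTHY_CUTPOINTS
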