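"""Unit tests for beep-level preprocessing: reading, validity filtering,
PA-factor derivation, scoring, and daily aggregation."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spiral_alt import esm
from spiral_alt.esm import (
    MOOD_ITEMS,
    DataError,
    SchemaError,
    aggregate_daily,
    baseline_period_means,
    cronbach_alpha,
    daily_to_wide,
    derive_pa_factor,
    filter_valid,
    read_esm_long,
    score_pa,
    score_pa_beep,
)

from conftest import exact_cov_sample, make_beep_df


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _write_csv(tmp_path, df):
    path = tmp_path / "beeps.csv"
    df.to_csv(path, index=False)
    return path


def test_read_well_formed_file_is_identity(tmp_path):
    df = make_beep_df([{"block": b} for b in (1, 2, 3)])
    out = read_esm_long(_write_csv(tmp_path, df))
    assert len(out) == 3
    assert out["happy"].tolist() == [4.0, 4.0, 4.0]
    assert out["block"].tolist() == [1, 2, 3]


def test_read_out_of_range_likert_becomes_missing_with_warning(tmp_path, caplog):
    df = make_beep_df([{"happy": 8}, {"block": 2, "happy": "junk"}, {"block": 3, "thought_pleasant": 0}])
    with caplog.at_level(logging.WARNING, logger="spiral_alt.esm"):
        out = read_esm_long(_write_csv(tmp_path, df))
    assert np.isnan(out.loc[0, "happy"])
    assert np.isnan(out.loc[1, "happy"])
    # the 1-7 scale treats a '0' rating as out of range, not as a recode
    assert np.isnan(out.loc[2, "thought_pleasant"])
    assert any("out-of-range" in r.message for r in caplog.records)


def test_read_duplicate_beep_key_is_error(tmp_path):
    df = make_beep_df([{}, {}])  # same (s1, pre, 1, 1) twice
    with pytest.raises(DataError, match="duplicate"):
        read_esm_long(_write_csv(tmp_path, df))


def test_read_missing_column_is_schema_error(tmp_path):
    df = make_beep_df([{}]).drop(columns=["happy"])
    with pytest.raises(SchemaError, match="happy"):
        read_esm_long(_write_csv(tmp_path, df))


def test_read_respects_schema_mapping(tmp_path):
    df = make_beep_df([{}]).rename(columns={"subject": "id"})
    path = _write_csv(tmp_path, df)
    with pytest.raises(SchemaError):
        read_esm_long(path)
    out = read_esm_long(path, schema={"subject": "id"})
    assert out["subject"].iloc[0] == "s1"


# ---------------------------------------------------------------------------
# validity filter
# ---------------------------------------------------------------------------


def test_filter_valid_boundary_and_counts():
    delays = [0, 5, 10, 15, 16, 20, 30, 3, 15, 14]
    df = make_beep_df([{"block": i + 1, "delay_min": d} for i, d in enumerate(delays)])
    out = filter_valid(df)
    assert len(out) == sum(d <= 15 for d in delays)  # 7 under the <= 15 rule
    assert 16 not in out["delay_min"].tolist()
    assert out["delay_min"].max() == 15  # inclusive boundary


def test_filter_valid_removes_never_completed():
    df = make_beep_df([{"delay_min": np.nan}, {"block": 2, "delay_min": 1.0}])
    out = filter_valid(df)
    assert len(out) == 1


@given(st.permutations(list(range(10))))
@settings(max_examples=25, deadline=None)
def test_filter_valid_idempotent_and_order_invariant(perm):
    delays = [0, 5, 10, 15, 16, 20, 30, 3, 15, 14]
    df = make_beep_df([{"block": i + 1, "delay_min": delays[i]} for i in perm])
    once = filter_valid(df)
    twice = filter_valid(once)
    pd.testing.assert_frame_equal(once, twice)
    assert sorted(once["block"]) == sorted(
        b + 1 for b in range(10) if delays[b] <= 15
    )


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------


def test_alpha_duplicated_columns_is_one():
    x = np.random.default_rng(0).normal(size=100)
    assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)


def test_alpha_independent_noise_is_near_zero():
    X = np.random.default_rng(1).normal(size=(10000, 5))
    assert abs(cronbach_alpha(X)) < 0.05


def test_alpha_equicorrelated_closed_form():
    # 3 items, pairwise correlation exactly 0.5, equal variances:
    # alpha = k*rbar / (1 + (k-1)*rbar) = 1.5/2 = 0.75
    C = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
    X = exact_cov_sample(C, n=60, seed=2)
    assert cronbach_alpha(X) == pytest.approx(0.75, abs=1e-10)


def test_alpha_zero_total_variance_errors():
    X = np.ones((10, 3))
    with pytest.raises(ValueError):
        cronbach_alpha(X)


# ---------------------------------------------------------------------------
# PA factor
# ---------------------------------------------------------------------------


def _loading_sim(true_loadings: dict[str, float], n=2000, seed=0) -> pd.DataFrame:
    """Beep table where each adjective = loading * factor + noise."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0, 1, n)
    rows = {it: lam * f + np.sqrt(max(1 - lam**2, 0.05)) * rng.normal(size=n) for it, lam in true_loadings.items()}
    df = pd.DataFrame(rows) + 4.0
    df["subject"] = "s1"
    df["condition"] = "control"
    df["period"] = "pre"
    df["day"] = 1
    df["block"] = 1
    df["delay_min"] = 0.0
    df["thought_pleasant"] = 4.0
    return df


def test_low_loading_item_excluded():
    truth = {it: 0.8 for it in MOOD_ITEMS}
    truth["relaxed"] = 0.3
    fdef = derive_pa_factor(_loading_sim(truth, n=2000, seed=3), MOOD_ITEMS)
    assert "relaxed" not in fdef.retained_items
    assert len(fdef.retained_items) == 7
    assert abs(fdef.loadings["relaxed"]) < 0.6


def test_collinear_items_all_retained_alpha_one():
    rng = np.random.default_rng(4)
    f = rng.normal(0, 1, 200)
    df = _loading_sim({it: 0.8 for it in MOOD_ITEMS}, n=200, seed=4)
    for it in MOOD_ITEMS:
        df[it] = f + 4.0  # perfectly collinear
    fdef = derive_pa_factor(df, MOOD_ITEMS)
    assert fdef.retained_items == MOOD_ITEMS
    assert fdef.alpha == pytest.approx(1.0)


def test_all_items_below_threshold_errors():
    df = _loading_sim({it: 0.1 for it in MOOD_ITEMS}, n=500, seed=5)
    with pytest.raises(ValueError, match="threshold"):
        derive_pa_factor(df, MOOD_ITEMS, threshold=0.99)


def test_factor_def_json_roundtrip(tmp_path):
    fdef = derive_pa_factor(_loading_sim({it: 0.8 for it in MOOD_ITEMS}, seed=6), MOOD_ITEMS)
    p = tmp_path / "factor.json"
    fdef.to_json(p)
    back = esm.PAFactorDef.from_json(p)
    assert back.retained_items == fdef.retained_items
    assert back.alpha == pytest.approx(fdef.alpha)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def seven_item_factor():
    retained = tuple(it for it in MOOD_ITEMS if it != "relaxed")
    return esm.PAFactorDef(
        candidate_items=MOOD_ITEMS,
        retained_items=retained,
        loadings={it: 0.8 for it in MOOD_ITEMS},
        alpha=0.89,
    )


def test_score_constant_and_arithmetic_mean(seven_item_factor):
    rec = {it: 4.0 for it in MOOD_ITEMS}
    assert score_pa_beep(rec, seven_item_factor) == pytest.approx(4.0)
    rec = dict(zip(seven_item_factor.retained_items, [1, 2, 3, 4, 5, 6, 7.0]))
    rec["relaxed"] = 7.0  # not retained; must not influence the score
    assert score_pa_beep(rec, seven_item_factor) == pytest.approx(4.0)


def test_score_min_items_rule(seven_item_factor):
    rec = {it: np.nan for it in MOOD_ITEMS}
    for it in seven_item_factor.retained_items[:3]:
        rec[it] = 5.0
    assert np.isnan(score_pa_beep(rec, seven_item_factor))
    rec[seven_item_factor.retained_items[3]] = 5.0
    assert score_pa_beep(rec, seven_item_factor) == pytest.approx(5.0)


@given(
    st.lists(st.integers(min_value=1, max_value=7), min_size=7, max_size=7),
)
@settings(max_examples=50, deadline=None)
def test_score_within_contributing_item_range(seven_item_factor, vals):
    rec = dict(zip(seven_item_factor.retained_items, map(float, vals)))
    rec["relaxed"] = 1.0
    s = score_pa_beep(rec, seven_item_factor)
    assert min(vals) <= s <= max(vals)


# ---------------------------------------------------------------------------
# daily aggregation
# ---------------------------------------------------------------------------


def test_aggregate_daily_means_and_missing_day(seven_item_factor):
    rows = [
        {"block": 1, "thought_pleasant": 3.0},
        {"block": 2, "thought_pleasant": 4.0},
        {"block": 3, "thought_pleasant": 5.0},
    ]
    df = make_beep_df(rows)
    daily = aggregate_daily(df, seven_item_factor)
    d1 = daily[(daily["day"] == 1) & (daily["period"] == "pre")].iloc[0]
    assert d1["pc"] == pytest.approx(4.0)
    assert d1["n_beeps"] == 3
    d2 = daily[(daily["day"] == 2) & (daily["period"] == "pre")].iloc[0]
    assert np.isnan(d2["pa"]) and np.isnan(d2["pc"])
    assert d2["n_beeps"] == 0
    # all six days present for both periods
    assert len(daily) == 12


def test_aggregate_daily_hand_computed_fixture(seven_item_factor):
    # six beeps on one day; two lack enough PA items -> PA mean over 4 beeps
    vals = [2.0, 3.0, 4.0, 5.0]
    rows = []
    for b, v in enumerate(vals, start=1):
        rows.append({"block": b, **{it: v for it in MOOD_ITEMS}, "thought_pleasant": v})
    for b in (5, 6):
        r = {"block": b, **{it: np.nan for it in MOOD_ITEMS}, "thought_pleasant": 7.0}
        rows.append(r)
    df = make_beep_df(rows)
    daily = aggregate_daily(df, seven_item_factor)
    d1 = daily[(daily["day"] == 1) & (daily["period"] == "pre")].iloc[0]
    assert d1["pa"] == pytest.approx(np.mean(vals))
    assert d1["pc"] == pytest.approx(np.mean(vals + [7.0, 7.0]))
    assert d1["n_pa"] == 4 and d1["n_pc"] == 6


def test_aggregate_daily_permutation_invariant(seven_item_factor):
    rng = np.random.default_rng(7)
    rows = [
        {"block": b, "day": d, **{it: float(rng.integers(1, 8)) for it in MOOD_ITEMS}}
        for d in (1, 2, 3)
        for b in range(1, 6)
    ]
    df = make_beep_df(rows)
    daily1 = aggregate_daily(df, seven_item_factor)
    daily2 = aggregate_daily(df.sample(frac=1, random_state=1).reset_index(drop=True), seven_item_factor)
    pd.testing.assert_frame_equal(daily1, daily2)


def test_baseline_period_means_missing_aware(seven_item_factor):
    daily = pd.DataFrame(
        {
            "subject": ["s1"] * 6,
            "condition": ["control"] * 6,
            "period": ["pre"] * 6,
            "day": range(1, 7),
            "pa": [2.0, np.nan, 4.0, np.nan, np.nan, np.nan],
            "pc": [np.nan] * 6,
        }
    )
    out = baseline_period_means(daily)
    assert out["pre_pa"].iloc[0] == pytest.approx(3.0)
    assert np.isnan(out["pre_pc"].iloc[0])


def test_daily_to_wide_layout(seven_item_factor):
    df = make_beep_df(
        [{"period": p, "day": d, "block": 1} for p in ("pre", "post") for d in (1, 2, 3, 4, 5, 6)]
    )
    daily = aggregate_daily(df, seven_item_factor)
    wide = daily_to_wide(daily, "post")
    assert list(wide.columns) == [f"pa_d{d}" for d in range(1, 7)] + [
        f"pc_d{d}" for d in range(1, 7)
    ] + ["condition"]
    assert wide.loc["s1", "pa_d3"] == pytest.approx(4.0)
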