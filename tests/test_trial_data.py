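"""Data model: I/O validation, standardization, arm summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bartcate import (
    default_schema,
    destandardize_value,
    generate_trial,
    load_trial_table,
    standardize_covariates,
    summarize_by_arm,
    write_trial_table,
)
from bartcate.trial_data import StandardizationParams, TrialDataset, destandardize_dataset

SCHEMA = default_schema()

HEADER = "id,arm,dawols90,mort90,age,limitations,resp_support,il6_inhibitor,dexa_3to4d,weight,diabetes,ihd_hf,copd,immunosuppression"


def _write(tmp_path, rows, name="trial.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


GOOD_ROWS = [
    "a,1,90,0,55,0,open,0,0,80,0,0,0,0",
    "b,0,10,1,70,0,imv,0,1,95,1,0,0,0",
    "c,1,45,NA,62,1,niv_cpap,1,0,70,0,1,0,1",
    "d,0,NA,0,48,0,open,0,0,110,0,0,1,0",
]


class TestLoad:
    def test_loads_records_and_missing_flags(self, tmp_path):
        ds = load_trial_table(_write(tmp_path, GOOD_ROWS))
        assert ds.n == 4
        assert int(ds.df["mort90"].isna().sum()) == 1
        assert int(ds.df["dawols90"].isna().sum()) == 1
        assert list(ds.df["resp_support"]) == ["open", "imv", "niv_cpap", "open"]

    @pytest.mark.parametrize(
        "bad_row, fragment",
        [
            ("e,1,91,0,55,0,open,0,0,80,0,0,0,0", "dawols90"),
            ("e,1,30,2,55,0,open,0,0,80,0,0,0,0", "mort90"),
            ("e,2,30,0,55,0,open,0,0,80,0,0,0,0", "arm"),
            ("e,1,30,0,NA,0,open,0,0,80,0,0,0,0", "age"),
            ("e,1,30,0,55,0,hfnc,0,0,80,0,0,0,0", "resp_support"),
            ("a,1,30,0,55,0,open,0,0,80,0,0,0,0", "id"),
        ],
    )
    def test_rejects_invalid_rows_naming_row_and_column(self, tmp_path, bad_row, fragment):
        with pytest.raises(ValueError) as exc:
            load_trial_table(_write(tmp_path, GOOD_ROWS + [bad_row]))
        msg = str(exc.value)
        assert fragment in msg
        assert "row" in msg

    def test_generator_output_round_trips(self, tmp_path, small_trial):
        path = tmp_path / "rt.csv"
        write_trial_table(small_trial, path)
        back = load_trial_table(path)
        assert back.n == small_trial.n
        pd.testing.assert_frame_equal(
            back.df.reset_index(drop=True), small_trial.df.reset_index(drop=True),
            check_dtype=False, check_categorical=False,
        )


class TestStandardize:
    def test_two_point_hand_computation(self):
        df = pd.DataFrame(
            {
                "id": ["a", "b"],
                "arm": [0, 1],
                "dawols90": pd.array([10, 20], dtype="Int64"),
                "mort90": pd.array([0, 0], dtype="Int64"),
                "age": [60.0, 70.0],
                "weight": [70.0, 90.0],
            }
        )
        for name in SCHEMA.names:
            if name not in df:
                df[name] = pd.Categorical(["open", "open"], categories=["open", "niv_cpap", "imv"]) \
                    if name == "resp_support" else 0.0
        ds = standardize_covariates(TrialDataset(schema=SCHEMA, df=df))
        # sd with n-1 denominator: sd({60,70}) = 10/sqrt(2), so values +/- 0.7071
        np.testing.assert_allclose(ds.df["age"].to_numpy(), [-0.70710678, 0.70710678])
        assert ds.std_params.center["age"] == 65.0

    def test_zero_variance_covariate_rejected(self, small_trial):
        ds = small_trial.copy()
        ds.df["weight"] = 80.0
        with pytest.raises(ValueError, match="weight"):
            standardize_covariates(ds)

    def test_round_trip_identity(self, small_trial):
        sds = standardize_covariates(small_trial)
        for name in SCHEMA.continuous:
            x = sds.df[name].to_numpy()
            assert abs(x.mean()) < 1e-10
            assert abs(x.std(ddof=1) - 1) < 1e-10
        back = destandardize_dataset(sds)
        for name in SCHEMA.continuous:
            np.testing.assert_allclose(
                back.df[name].to_numpy(), small_trial.df[name].to_numpy(), atol=1e-9
            )

    @given(
        center=st.floats(-100, 100),
        scale=st.floats(0.1, 50),
        x=st.floats(-5, 5),
    )
    def test_destandardize_is_affine(self, center, scale, x):
        params = StandardizationParams(center={"age": center}, scale={"age": scale})
        assert destandardize_value("age", x, params) == pytest.approx(x * scale + center)

    def test_destandardize_unknown_name(self):
        params = StandardizationParams(center={"age": 0.0}, scale={"age": 1.0})
        with pytest.raises(KeyError):
            destandardize_value("weight", 1.0, params)


def _dataset_from_counts(n1, deaths1, n0, deaths0, extra1=0, extra0=0):
    """Minimal dataset with prescribed mortality counts (extra = missing)."""
    rows = []
    rid = 0

    def add(arm, mort, k):
        nonlocal rid
        for _ in range(k):
            rows.append((f"r{rid}", arm, 45, mort))
            rid += 1

    add(1, 1, deaths1)
    add(1, 0, n1 - deaths1)
    add(1, None, extra1)
    add(0, 1, deaths0)
    add(0, 0, n0 - deaths0)
    add(0, None, extra0)
    df = pd.DataFrame(rows, columns=["id", "arm", "dawols90", "mort90"])
    df["dawols90"] = pd.array(df["dawols90"], dtype="Int64")
    df["mort90"] = pd.array(df["mort90"], dtype="Int64")
    for name in SCHEMA.names:
        if name == "resp_support":
            df[name] = pd.Categorical(["open"] * len(df), categories=["open", "niv_cpap", "imv"])
        elif name in ("age", "weight"):
            df[name] = np.linspace(40, 80, len(df))
        else:
            df[name] = 0.0
    return TrialDataset(schema=SCHEMA, df=df)


class TestSummaries:
    def test_mortality_percentages_from_trial_counts(self):
        # 157/490 deaths in the 12 mg/d arm, 180/478 in the 6 mg/d arm,
        # with 7 more 12 mg/d patients missing the outcome (497 randomized).
        ds = _dataset_from_counts(490, 157, 478, 180, extra1=7, extra0=7)
        s = summarize_by_arm(ds)
        assert s["12mg"]["mort90"] == {"deaths": 157, "total": 490, "pct": 32.0}
        assert s["6mg"]["mort90"]["pct"] == 37.7
        assert s["12mg"]["n"] == 497

    def test_binary_prevalence_percentage(self):
        ds = _dataset_from_counts(497, 100, 485, 100)
        ds.df.loc[ds.df["arm"] == 1, "diabetes"] = [1.0] * 135 + [0.0] * (497 - 135)
        s = summarize_by_arm(ds)
        assert s["12mg"]["diabetes"]["count"] == 135
        assert round(s["12mg"]["diabetes"]["pct"]) == 27

    def test_degenerate_weight_distribution(self):
        ds = _dataset_from_counts(20, 5, 20, 5)
        ds.df["weight"] = 80.0
        s = summarize_by_arm(ds)
        assert s["12mg"]["weight"] == {"median": 80.0, "q1": 80.0, "q3": 80.0}

    @given(seed=st.integers(0, 10_000))
    def test_percentages_match_direct_recount(self, seed):
        ds = generate_trial(60, seed=seed)
        s = summarize_by_arm(ds)
        df = ds.df
        for arm, label in ((1, "12mg"), (0, "6mg")):
            sub = df[df["arm"] == arm]
            cnt = int((sub["diabetes"] == 1).sum())
            assert s[label]["diabetes"]["count"] == cnt
            assert s[label]["diabetes"]["pct"] == round(100 * cnt / len(sub), 1)
            mort = sub["mort90"].dropna()
            assert s[label]["mort90"]["total"] == len(mort)
            assert s[label]["mort90"]["deaths"] == int(mort.sum())
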