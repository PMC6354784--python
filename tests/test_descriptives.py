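import numpy as np
import pandas as pd
import pytest

from trialmed import cell_means, mixed_anova, pearson_correlations, TrialTable
from trialmed.descriptives import CellMeansTable

from conftest import make_table


def _cells_df(values, groups=("patient", "control"), subj_per_group=2):
    """Long cell-means frame; values indexed [g][s][modality][level]."""
    rows = []
    for gi, g in enumerate(groups):
        for s in range(subj_per_group):
            for mi, m in enumerate(("pain", "touch")):
                for li, l in enumerate((1, 2, 3)):
                    rows.append({"subject_id": f"{g[0]}{s}", "group": g,
                                 "modality": m, "intensity_level": l,
                                 "rating": values[gi][s][mi][li],
                                 "rt_ms": values[gi][s][mi][li]})
    return pd.DataFrame(rows)


def _projection_ss(df, variable):
    """Brute-force oracle: sequential OLS projections with subject dummies."""
    y = df[variable].to_numpy(float)

    def dummies(*cols):
        key = df[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(float)

    terms = [
        ("intercept", np.ones((len(df), 1))),
        ("group", dummies("group")),
        ("subjects", dummies("subject_id")),
        ("modality", dummies("modality")),
        ("group:modality", dummies("group", "modality")),
        ("modality:subjects", dummies("subject_id", "modality")),
        ("intensity", dummies("intensity_level")),
        ("group:intensity", dummies("group", "intensity_level")),
        ("intensity:subjects", dummies("subject_id", "intensity_level")),
        ("modality:intensity", dummies("modality", "intensity_level")),
        ("group:modality:intensity", dummies("group", "modality", "intensity_level")),
    ]
    ss = {}
    X = np.zeros((len(df), 0))
    rss_prev = float(y @ y)
    for name, D in terms:
        X = np.hstack([X, D])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        ss[name] = rss_prev - rss
        rss_prev = rss
    ss["modality:intensity:subjects"] = rss_prev
    return ss


def test_cell_means_hand_computed_and_permutation_invariant():
    ratings = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0] * 2
    t = make_table({"rating": ratings,
                    "modality": ["pain"] * 6 + ["touch"] * 6,
                    "intensity_level": [1, 1, 2, 2, 3, 3] * 2}, n=12)
    cm = cell_means(t)
    got = cm.df.set_index(["modality", "intensity_level"])["rating"]
    assert got[("pain", 1)] == 15.0 and got[("pain", 3)] == 55.0
    shuffled = TrialTable(t.df.sample(frac=1, random_state=0).reset_index(drop=True))
    pd.testing.assert_frame_equal(cell_means(shuffled).df, cm.df)


def test_cell_means_drops_subject_with_empty_cell(small_preprocessed):
    df = small_preprocessed.df
    a_subject = df["subject_id"].iloc[0]
    mask = ~((df.subject_id == a_subject) & (df.modality == "pain")
             & (df.intensity_level == 1))
    cm = cell_means(TrialTable(df[mask].reset_index(drop=True)))
    assert a_subject in cm.dropped_subjects
    assert a_subject not in set(cm.df.subject_id)


def test_anova_no_signal_and_partition_identity():
    vals = [[[[50.0] * 3] * 2] * 2] * 2
    cm = CellMeansTable(_cells_df(vals))
    res = mixed_anova(cm, "rating")
    assert (res.table["ss"] < 1e-20).all()
    assert (res.table["F"] == 0).all()


@pytest.mark.parametrize("subj_per_group", [2, 4])
def test_anova_matches_projection_oracle(subj_per_group):
    rng = np.random.default_rng(subj_per_group)
    vals = rng.normal(50, 10, size=(2, subj_per_group, 2, 3)).tolist()
    df = _cells_df(vals, subj_per_group=subj_per_group)
    cm = CellMeansTable(df)
    res = mixed_anova(cm, "rating")
    oracle = _projection_ss(df, "rating")
    for _, row in res.table.iterrows():
        assert row["ss"] == pytest.approx(oracle[row["effect"]], abs=1e-9)
    for name, ss_err in res.error_ss.items():
        assert ss_err == pytest.approx(oracle[name], abs=1e-9)
    total = res.table["ss"].sum() + sum(res.error_ss.values())
    assert total == pytest.approx(res.ss_total, abs=1e-10)


def test_anova_unequal_group_sizes_partition_holds():
    rng = np.random.default_rng(5)
    rows = []
    for g, n in (("patient", 3), ("control", 5)):
        for s in range(n):
            for m in ("pain", "touch"):
                for l in (1, 2, 3):
                    rows.append({"subject_id": f"{g[0]}{s}", "group": g,
                                 "modality": m, "intensity_level": l,
                                 "rating": rng.normal(50, 8), "rt_ms": 400.0})
    df = pd.DataFrame(rows)
    res = mixed_anova(CellMeansTable(df), "rating")
    oracle = _projection_ss(df, "rating")
    for _, row in res.table.iterrows():
        assert row["ss"] == pytest.approx(oracle[row["effect"]], abs=1e-9)
    assert (res.table["ss"].sum() + sum(res.error_ss.values())
            == pytest.approx(res.ss_total, abs=1e-9))


def test_anova_f_invariant_to_affine_rescaling():
    rng = np.random.default_rng(9)
    vals = rng.normal(400, 30, size=(2, 3, 2, 3)).tolist()
    df = _cells_df(vals, subj_per_group=3)
    f1 = mixed_anova(CellMeansTable(df), "rating").table["F"].to_numpy()
    df2 = df.copy()
    df2["rating"] = 3.5 * df2["rating"] - 120.0
    f2 = mixed_anova(CellMeansTable(df2), "rating").table["F"].to_numpy()
    np.testing.assert_allclose(f1, f2, rtol=1e-9)


def test_anova_pure_group_shift_detected_only_as_group_effect():
    rng = np.random.default_rng(3)
    vals = rng.normal(0, 1, size=(2, 40, 2, 3))
    vals[0] += 5.0  # patients shifted
    df = _cells_df(vals.tolist(), subj_per_group=40)
    res = mixed_anova(CellMeansTable(df), "rating")
    tbl = res.table.set_index("effect")
    assert tbl.loc["group", "p"] < 1e-6
    assert (tbl.drop("group")["p"] > 0.01).all()


def test_gg_correction_reduces_df_but_not_f():
    rng = np.random.default_rng(11)
    vals = rng.normal(50, 5, size=(2, 6, 2, 3)).tolist()
    cm = CellMeansTable(_cells_df(vals, subj_per_group=6))
    plain = mixed_anova(cm, "rating")
    gg = mixed_anova(cm, "rating", gg_correction=True)
    np.testing.assert_allclose(plain.table["F"], gg.table["F"])
    idx = gg.table.set_index("effect")
    for eff in ("intensity", "modality:intensity"):
        row = idx.loc[eff]
        assert 0.5 <= row["gg_epsilon"] <= 1.0
        if row["F"] > 1.0:  # df shrinkage is conservative only above F = 1
            assert row["p_gg"] >= row["p"] - 1e-12
        assert 0.0 <= row["p_gg"] <= 1.0


def test_pearson_hand_example_and_errors():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
    r, p = pearson_correlations(x, y)
    # textbook formula
    rx = (x - x.mean()) / x.std()
    ry = (y - y.mean()) / y.std()
    assert r == pytest.approx(float((rx * ry).mean()))
    t = r * np.sqrt(3 / (1 - r**2))
    from scipy import stats
    assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))
    assert pearson_correlations(x, 2 * x + 1)[0] == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    big = rng.normal(size=5000)
    assert abs(pearson_correlations(big, rng.normal(size=5000))[0]) < 0.05
    with pytest.raises(ValueError, match="variance"):
        pearson_correlations(x, np.ones(5))
    with pytest.raises(ValueError):
        pearson_correlations(x[:2], y[:2])
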