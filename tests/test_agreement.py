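import numpy as np
import pandas as pd
import pytest

from l3comp import (
    LabelMask,
    agreement_report,
    bland_altman,
    bland_altman_plot,
    dice,
    dice_summary,
    icc_agreement,
    pearson,
)

from _oracles import (
    bland_altman_bruteforce,
    dice_bruteforce,
    icc_a1_bruteforce,
    pearson_bruteforce,
)


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_identity_disjoint_and_half_overlap():
    a = np.zeros((4, 4), dtype=bool)
    a[0, :4] = True
    assert dice(a, a) == 1.0
    b = np.zeros((4, 4), dtype=bool)
    b[2, :4] = True
    assert dice(a, b) == 0.0
    c = np.zeros((4, 4), dtype=bool)
    c[0, 2:4] = True
    c[1, 0:2] = True  # |A|=4, |B|=4, |A∩B|=2
    assert dice(a, c) == 0.5


def test_dice_both_empty_is_agreement_on_absence():
    e = np.zeros((3, 3), dtype=bool)
    assert dice(e, e) == 1.0


def test_dice_symmetry_and_bounds(rng):
    for _ in range(20):
        a = rng.random((8, 8)) < 0.4
        b = rng.random((8, 8)) < 0.4
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        assert d == pytest.approx(dice_bruteforce(a.tolist(), b.tolist()), abs=1e-12)


def test_dice_shape_mismatch_is_hard_error():
    with pytest.raises(ValueError, match="shape"):
        dice(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))


def test_dice_summary_two_point_statistics(small_case):
    t = small_case.truth
    flipped = t.labels.copy()
    sat = np.flatnonzero(flipped == 1)
    flipped.ravel()[sat[: len(sat) // 2]] = 5  # half the SAT relabelled
    half = LabelMask(labels=flipped)
    summary = dice_summary([(t, t), (t, half)], "SAT")
    d2 = dice(t, half, "SAT")
    assert summary.per_case_dice == (1.0, d2)
    assert summary.mean == pytest.approx((1.0 + d2) / 2)
    assert summary.sd == pytest.approx(np.std([1.0, d2], ddof=1))


def test_dice_summary_identical_pairs(small_case):
    t = small_case.truth
    s = dice_summary([(t, t)] * 3, "MUSCLE")
    assert s.mean == 1.0 and s.sd == 0.0


def test_dice_summary_empty_case_list_errors():
    with pytest.raises(ValueError):
        dice_summary([], "SAT")


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_duplicated_raters_is_one():
    a = np.array([3.0, 7.0, 1.0, 9.0, 5.0, 2.0])
    res = icc_agreement(np.column_stack([a, a]))
    assert res.estimate == pytest.approx(1.0)
    assert res.ci_lower <= res.estimate <= res.ci_upper


def test_icc_absolute_agreement_penalises_offset():
    a = np.array([3.0, 7.0, 1.0, 9.0, 5.0, 2.0])
    abs_res = icc_agreement(np.column_stack([a, a + 10]), form="absolute_agreement")
    con_res = icc_agreement(np.column_stack([a, a + 10]), form="consistency")
    assert abs_res.estimate < con_res.estimate
    assert con_res.estimate == pytest.approx(1.0)


def test_icc_matches_bruteforce_anova_on_toy_table():
    table = [[10.0, 11.0], [12.0, 13.5], [8.0, 7.5], [15.0, 15.5], [9.0, 10.0], [13.0, 12.0]]
    res = icc_agreement(np.asarray(table))
    assert res.estimate == pytest.approx(icc_a1_bruteforce(table), abs=1e-10)


def test_icc_matches_pingouin_reference():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    base = rng.normal(150, 40, size=12)
    y = np.column_stack([base + rng.normal(0, 8, 12), base + rng.normal(5, 8, 12)])
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["A", "B"], 12),
            "score": y.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    ref_row = ref.set_index("Type").loc["ICC(A,1)"]  # two-way absolute agreement, single
    res = icc_agreement(y)
    assert res.estimate == pytest.approx(ref_row["ICC"], abs=1e-8)
    assert res.ci_lower == pytest.approx(ref_row["CI95"][0], abs=0.01)
    assert res.ci_upper == pytest.approx(ref_row["CI95"][1], abs=0.01)


def test_icc_invariances(rng):
    y = rng.normal(100, 20, size=(10, 2))
    base = icc_agreement(y).estimate
    perm = rng.permutation(10)
    assert icc_agreement(y[perm]).estimate == pytest.approx(base, abs=1e-12)
    assert icc_agreement(y + 55.0).estimate == pytest.approx(base, abs=1e-9)


def test_icc_requires_three_subjects():
    with pytest.raises(ValueError, match="3"):
        icc_agreement(np.array([[1.0, 2.0], [3.0, 4.0]]))


def test_icc_zero_variance_degenerates_to_one_with_warning():
    with pytest.warns(UserWarning, match="zero total variance"):
        res = icc_agreement(np.full((5, 2), 7.0))
    assert (res.estimate, res.ci_lower, res.ci_upper) == (1.0, 1.0, 1.0)


def test_icc_incomplete_cases_excluded_with_warning():
    y = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0], [7.0, 7.5], [2.0, 2.5]])
    with pytest.warns(UserWarning, match="incomplete"):
        res = icc_agreement(y)
    assert res.n == 4


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_perfect_linear_relations():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r, p = pearson(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula(rng):
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    r, _ = pearson(x, y)
    assert r == pytest.approx(pearson_bruteforce(x.tolist(), y.tolist()), abs=1e-12)


def test_pearson_affine_invariance(rng):
    x, y = rng.normal(size=8), rng.normal(size=8)
    r0, _ = pearson(x, y)
    r1, _ = pearson(3 * x + 7, y)
    assert r1 == pytest.approx(r0, abs=1e-12)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError, match="variance"):
        pearson(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def test_bland_altman_constant_offset():
    b = np.array([10.0, 20.0, 30.0])
    res = bland_altman(b + 5, b)
    assert res.bias == 5.0
    assert res.sd_diff == 0.0
    assert (res.loa_lower, res.loa_upper) == (5.0, 5.0)


def test_bland_altman_matches_direct_formula(rng):
    a = rng.normal(100, 15, size=8)
    b = a + rng.normal(-2, 4, size=8)
    res = bland_altman(a, b)
    bias, sd, lo, hi = bland_altman_bruteforce(a.tolist(), b.tolist())
    assert res.bias == pytest.approx(bias, abs=1e-12)
    assert res.sd_diff == pytest.approx(sd, abs=1e-12)
    assert res.loa_lower == pytest.approx(lo, abs=1e-12)
    assert res.loa_upper == pytest.approx(hi, abs=1e-12)


def test_bland_altman_limits_symmetric_and_sign_convention(rng):
    a = rng.normal(size=6)
    b = rng.normal(size=6)
    res = bland_altman(a, b)
    assert res.loa_upper - res.bias == pytest.approx(res.bias - res.loa_lower, abs=1e-12)
    assert bland_altman(b, a).bias == pytest.approx(-res.bias, abs=1e-12)


def test_bland_altman_vat_limits_reconstruct_from_published_summary():
    # published VAT summary: bias −0.35 cm², upper limit 59.38 cm²; the
    # symmetric ±1.96·SD construction pins the lower limit
    bias, upper = -0.35, 59.38
    sd = (upper - bias) / 1.96
    diffs = np.array([bias - sd / np.sqrt(2), bias + sd / np.sqrt(2)])
    res = bland_altman(diffs, np.zeros(2))
    assert res.bias == pytest.approx(bias, abs=1e-12)
    assert res.loa_upper == pytest.approx(upper, abs=1e-9)
    assert res.loa_lower == pytest.approx(-60.08, abs=0.005)


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError):
        bland_altman(np.array([1.0]), np.array([2.0]))


def test_bland_altman_plot_writes_figure(tmp_path, rng):
    a = rng.normal(100, 10, size=12)
    b = a + rng.normal(0, 3, size=12)
    res = bland_altman(a, b)
    out = tmp_path / "ba.png"
    bland_altman_plot(res, a, b, out, tissue="SAT")
    assert out.stat().st_size > 0


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def _long_table(rng, n=8, tissues=("SAT", "VAT")):
    rows = []
    for t in tissues:
        base = rng.normal(150, 40, size=n)
        for i in range(n):
            rows.append({"subject_id": f"s{i}", "rater": "automated", "tissue": t,
                         "area_cm2": base[i] + rng.normal(0, 2)})
            rows.append({"subject_id": f"s{i}", "rater": "manual", "tissue": t,
                         "area_cm2": base[i] + rng.normal(0, 2)})
    return pd.DataFrame(rows)


def test_agreement_report_perfect_duplicates(rng):
    df = _long_table(rng)
    df = df.pivot_table(index=["subject_id", "tissue"], columns="rater",
                        values="area_cm2").reset_index()
    df["manual"] = df["automated"]
    long = df.melt(id_vars=["subject_id", "tissue"], var_name="rater", value_name="area_cm2")
    report = agreement_report(long, raters=("automated", "manual"))
    assert np.allclose(report["icc"], 1.0)
    assert np.allclose(report["pearson_r"], 1.0)
    assert (report["bias"] == 0.0).all()


def test_agreement_report_structure_and_ci_order(rng):
    report = agreement_report(_long_table(rng), raters=("automated", "manual"))
    assert set(report.index) == {"SAT", "VAT"}
    assert (report["icc_ci_lower"] <= report["icc"]).all()
    assert (report["icc"] <= report["icc_ci_upper"]).all()
    assert (report["loa_lower"] <= report["bias"]).all()


def test_agreement_report_single_tissue(rng):
    report = agreement_report(_long_table(rng, tissues=("MUSCLE",)),
                              raters=("automated", "manual"))
    assert list(report.index) == ["MUSCLE"]
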