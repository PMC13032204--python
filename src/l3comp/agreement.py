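"""Agreement statistics for method comparison of segmentations and areas.

Covers the standard validation battery for automated-vs-manual body
composition: spatial overlap (Dice), reliability (intraclass correlation
with 95% confidence intervals), linear association (Pearson) and
method-comparison bias (Bland–Altman bias ± 1.96·SD limits of agreement).

The ICC is computed from the mean squares of the two-way subjects × raters
layout.  The default form is two-way, absolute agreement, single measures
— ICC(A,1) in McGraw & Wong's notation — which penalises systematic rater
offsets and is the conventional choice for comparing single measurements
between two methods.  Consistency ICC(C,1) and the one-way ICC(1) are
available behind the ``form`` flag for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import LabelMask, _tissue_code

__all__ = [
    "DiceSummary",
    "ICCResult",
    "BlandAltmanResult",
    "dice",
    "dice_summary",
    "icc_agreement",
    "pearson",
    "bland_altman",
    "bland_altman_plot",
    "agreement_report",
]


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice(mask_a: LabelMask | np.ndarray, mask_b: LabelMask | np.ndarray,
         tissue: int | str | None = None) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) for one tissue label.

    Accepts label masks plus a tissue, or two boolean arrays directly.
    Two empty masks agree on absence and score 1.0.
    """
    if isinstance(mask_a, LabelMask):
        if tissue is None:
            raise ValueError("tissue label required for LabelMask inputs")
        a = mask_a.binary(tissue)
        b = mask_b.binary(tissue)
    else:
        a = np.asarray(mask_a, dtype=bool)
        b = np.asarray(mask_b, dtype=bool)
        if tissue is not None:
            raise ValueError("tissue label only applies to LabelMask inputs")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass(frozen=True)
class DiceSummary:
    """Per-case Dice values for one tissue with sample mean ± SD."""

    tissue: str
    per_case_dice: tuple
    mean: float
    sd: float
    n_both_empty: int = 0

    @property
    def n(self) -> int:
        return len(self.per_case_dice)


def dice_summary(cases, tissue: int | str) -> DiceSummary:
    """Summarise Dice over mask pairs: ``cases`` is a list of (A, B) masks."""
    if len(cases) == 0:
        raise ValueError("empty case list")
    code = _tissue_code(tissue)
    values, both_empty = [], 0
    for a, b in cases:
        values.append(dice(a, b, code))
        if isinstance(a, LabelMask) and not a.binary(code).any() and not b.binary(code).any():
            both_empty += 1
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else 0.0
    from .ct_io import TISSUE_NAMES

    return DiceSummary(
        tissue=TISSUE_NAMES[code],
        per_case_dice=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        sd=sd,
        n_both_empty=both_empty,
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with its 95% confidence interval."""

    estimate: float
    ci_lower: float
    ci_upper: float
    model: str
    n: int
    k: int


def _mean_squares(y: np.ndarray):
    """ANOVA mean squares of an n × k subjects-by-raters table."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def _as_table(pairs) -> np.ndarray:
    y = np.asarray(pairs, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected an n_subjects × k_raters table")
    if np.isnan(y).any():
        n_before = y.shape[0]
        y = y[~np.isnan(y).any(axis=1)]
        warnings.warn(
            f"excluding {n_before - y.shape[0]} incomplete case(s) from ICC",
            stacklevel=3,
        )
    return y


def icc_agreement(pairs, form: str = "absolute_agreement", alpha: float = 0.05) -> ICCResult:
    """ICC of an n × k subjects-by-raters table of single measurements.

    form = 'absolute_agreement' (default, ICC(A,1)), 'consistency'
    (ICC(C,1)) or 'one_way' (ICC(1)).  Confidence limits use the F-based
    method appropriate to each form.  All-identical values degenerate to an
    estimate of 1.0 with interval [1, 1] and a warning.
    """
    y = _as_table(pairs)
    n, k = y.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 raters, got {k}")

    if np.ptp(y) == 0:
        warnings.warn("zero total variance: ICC degenerates to 1.0", stacklevel=2)
        return ICCResult(1.0, 1.0, 1.0, _model_name(form, k), n, k)

    msr, msc, mse = _mean_squares(y)

    if form == "absolute_agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom if denom != 0 else 1.0
        lo, hi = _ci_absolute(est, msr, msc, mse, n, k, alpha)
    elif form == "consistency":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom != 0 else 1.0
        lo, hi = _ci_consistency(msr, mse, n, k, alpha)
    elif form == "one_way":
        # pool columns + error into within-subject variability
        msw = ((k - 1) * msc + (n - 1) * (k - 1) * mse) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        est = (msr - msw) / denom if denom != 0 else 1.0
        lo, hi = _ci_oneway(msr, msw, n, k, alpha)
    else:
        raise ValueError(f"unknown ICC form {form!r}")

    est = min(est, 1.0)
    lo = min(lo, est)
    hi = min(max(hi, est), 1.0)
    return ICCResult(float(est), float(lo), float(hi), _model_name(form, k), n, k)


def _model_name(form: str, k: int) -> str:
    return {
        "absolute_agreement": f"two-way, absolute agreement, single measures (k={k})",
        "consistency": f"two-way, consistency, single measures (k={k})",
        "one_way": f"one-way random, single measures (k={k})",
    }[form]


def _ci_absolute(est, msr, msc, mse, n, k, alpha):
    # McGraw & Wong F-based interval for ICC(A,1) via Satterthwaite df
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return est, est
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return lo, hi


def _ci_consistency(msr, mse, n, k, alpha):
    if mse == 0:
        return 1.0, 1.0
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return lo, hi


def _ci_oneway(msr, msw, n, k, alpha):
    if msw == 0:
        return 1.0, 1.0
    f_obs = msr / msw
    df1, df2 = n - 1, n * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return lo, hi


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one member; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference summary: bias and limits of agreement.

    Differences are method A − method B (automated − manual by convention,
    so a negative bias means the automated method underestimates).  The
    proportional-bias slope regresses differences on pair means.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    loa_multiplier: float = 1.96
    prop_bias_slope: float = float("nan")
    prop_bias_p: float = float("nan")


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman analysis of paired measurements (differences = a − b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (a + b) / 2
    slope, p = float("nan"), float("nan")
    if n >= 3 and means.std() > 0:
        reg = stats.linregress(means, d)
        slope, p = float(reg.slope), float(reg.pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - loa_multiplier * sd,
        loa_upper=bias + loa_multiplier * sd,
        n=n,
        loa_multiplier=loa_multiplier,
        prop_bias_slope=slope,
        prop_bias_p=p,
    )


def bland_altman_plot(result: BlandAltmanResult, a, b, path, tissue: str | None = None) -> None:
    """Scatter of difference vs pair mean with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    means = (a + b) / 2
    diffs = a - b

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=18, alpha=0.8, edgecolor="none")
    ax.axhline(result.bias, color="C3", lw=1.2, label=f"bias = {result.bias:.2f}")
    for loa, name in ((result.loa_lower, "lower LoA"), (result.loa_upper, "upper LoA")):
        ax.axhline(loa, color="C3", lw=1.0, ls="--", label=f"{name} = {loa:.2f}")
    title = "Bland–Altman" + (f" — {tissue}" if tissue else "")
    ax.set_title(title)
    ax.set_xlabel("mean of methods (cm²)")
    ax.set_ylabel("difference, automated − manual (cm²)")
    ax.legend(fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def agreement_report(
    measurements: pd.DataFrame,
    raters: tuple[str, str] | None = None,
    mask_pairs: dict | None = None,
    icc_form: str = "absolute_agreement",
    loa_multiplier: float = 1.96,
) -> pd.DataFrame:
    """Per-tissue agreement table: ICC (95% CI), Pearson, Bland–Altman, Dice.

    ``measurements`` is a long-format table (subject_id, rater, tissue,
    area_cm2) with exactly two raters of interest; ``raters`` fixes the
    (A, B) order for the difference sign, defaulting to sorted order.
    ``mask_pairs`` optionally maps tissue name → list of (mask_a, mask_b)
    for a Dice column.  Tissues whose statistics fail (too few pairs, zero
    variance) are reported with NaNs and a warning rather than aborting the
    whole report.
    """
    present = sorted(measurements["rater"].unique())
    if raters is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly 2 raters, found {present}")
        raters = (present[0], present[1])
    ra, rb = raters

    rows = []
    for tissue, grp in measurements.groupby("tissue", sort=True):
        wide = grp.pivot(index="subject_id", columns="rater", values="area_cm2")
        if ra not in wide.columns or rb not in wide.columns:
            warnings.warn(f"{tissue}: rater(s) missing, skipped", stacklevel=2)
            continue
        wide = wide[[ra, rb]].dropna()
        a = wide[ra].to_numpy()
        b = wide[rb].to_numpy()
        row = {"tissue": tissue, "n": len(wide)}
        try:
            icc = icc_agreement(np.column_stack([a, b]), form=icc_form)
            row.update(icc=icc.estimate, icc_ci_lower=icc.ci_lower, icc_ci_upper=icc.ci_upper)
        except ValueError as e:
            warnings.warn(f"{tissue}: ICC failed ({e})", stacklevel=2)
            row.update(icc=np.nan, icc_ci_lower=np.nan, icc_ci_upper=np.nan)
        try:
            r, p = pearson(a, b)
            row.update(pearson_r=r, pearson_p=p)
        except ValueError as e:
            warnings.warn(f"{tissue}: Pearson failed ({e})", stacklevel=2)
            row.update(pearson_r=np.nan, pearson_p=np.nan)
        try:
            ba = bland_altman(a, b, loa_multiplier=loa_multiplier)
            row.update(
                bias=ba.bias,
                sd_diff=ba.sd_diff,
                loa_lower=ba.loa_lower,
                loa_upper=ba.loa_upper,
                prop_bias_slope=ba.prop_bias_slope,
                prop_bias_p=ba.prop_bias_p,
            )
        except ValueError as e:
            warnings.warn(f"{tissue}: Bland–Altman failed ({e})", stacklevel=2)
            row.update(bias=np.nan, sd_diff=np.nan, loa_lower=np.nan, loa_upper=np.nan,
                       prop_bias_slope=np.nan, prop_bias_p=np.nan)
        if mask_pairs and tissue in mask_pairs:
            ds = dice_summary(mask_pairs[tissue], tissue)
            row.update(dice_mean=ds.mean, dice_sd=ds.sd)
        rows.append(row)
    if not rows:
        raise ValueError("no tissue could be analysed")
    return pd.DataFrame(rows).set_index("tissue")
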