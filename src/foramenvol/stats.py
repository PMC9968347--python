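"""Cohort and repeatability statistics.

Nonparametric tests matching the study design: a paired Wilcoxon signed-rank
test for the nucleotomy-vs-discoplasty volume change, Spearman rank
correlation between injected cement volume and the volume change, and
two-way mixed-effects absolute-agreement intraclass correlation (ICC) with
95% confidence intervals for inter- and intra-rater reliability.

Conventions (stated because they affect p-values): Wilcoxon drops zero
differences, uses mid-ranks with tie correction, switches from the exact
sign-pattern distribution to the continuity-corrected normal approximation
above n = 15; Spearman is Pearson on mid-ranks with the t approximation for
the p-value; ICC confidence intervals use the McGraw-Wong F-distribution
method (the two-way mixed and two-way random absolute-agreement models share
the same point estimates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RaterTable",
    "ICCResult",
    "wilcoxon_paired",
    "spearman",
    "icc_two_way_mixed_absolute",
    "cohort_analysis",
]


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------

EXACT_N_MAX = 15


def _exact_two_sided_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided p by enumeration of all sign patterns over the given ranks.

    Mid-ranks are multiples of 0.5, so doubled ranks are integers and the
    distribution of 2*W+ is a polynomial convolution over {0, r} factors.
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else 2 * counts[r:]
    n_patterns = 2.0 ** len(ranks)
    w2 = int(round(2.0 * w))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped (documented convention); |differences| are
    mid-ranked with tie correction.  For n <= 15 the p-value comes from exact
    enumeration of the 2^n sign patterns (valid under ties as well); larger
    samples use the normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D samples")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences (got {n})")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return w_plus, _exact_two_sided_p(w_plus, ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        warnings.warn("zero variance after tie correction; p = 1")
        return w_plus, 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation; returns (rho, two-sided p).

    Pearson correlation of mid-ranks; p-value from the t approximation with
    n - 2 degrees of freedom.  Ties are handled by mid-ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need equal-length 1D samples with n >= 4")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class RaterTable:
    """Subjects x rater-repetition measurement matrix (no missing cells)."""

    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater table must be 2D (subjects x raters)")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column labels must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater table must be complete (no missing cells)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RaterTable":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.columns)))


@dataclass
class ICCResult:
    """ICC point estimate with 95% CI and the ANOVA mean squares behind it."""

    icc: float
    ci_lower: float
    ci_upper: float
    model: str
    unit: str
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_raters: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.icc + 1e-12 and self.icc <= self.ci_upper + 1e-12):
            raise ValueError("CI must bracket the ICC estimate")
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


def icc_two_way_mixed_absolute(
    table, unit: str = "single", alpha: float = 0.05
) -> ICCResult:
    """Absolute-agreement ICC from a two-way (subjects x raters) layout.

    ``unit='single'`` gives the reliability of one measurement (McGraw-Wong
    A-1, the intra-rater model); ``unit='mean_of_k'`` the reliability of the
    mean over the k columns (A-k, the inter-rater model on averaged
    repetitions).  Confidence intervals use the F-distribution method with
    Satterthwaite degrees of freedom.
    """
    if unit not in ("single", "mean_of_k"):
        raise ValueError("unit must be 'single' or 'mean_of_k'")
    if isinstance(table, RaterTable):
        X = table.values
    elif isinstance(table, pd.DataFrame):
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D table with k >= 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("table must be complete (no missing cells)")
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n < 5:
        warnings.warn("fewer than 5 subjects: the confidence interval is unstable")
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("constant table: zero variance, ICC undefined")
    rm = X.mean(axis=1)
    cm = X.mean(axis=0)
    msr = k * float(((rm - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((cm - grand) ** 2).sum()) / (k - 1)
    mse = float(((X - rm[:, None] - cm[None, :] + grand) ** 2).sum()) / ((n - 1) * (k - 1))

    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0.0:
        # perfect within-subject agreement: estimate is exact
        lo1 = hi1 = icc_a1
    else:
        fj = msc / mse
        df2 = (n - 1) * (k - 1)
        a = k * icc_a1
        b = n * (1 + (k - 1) * icc_a1) - a
        vn = df2 * (a * fj + n * (1 + (k - 1) * icc_a1) - a) ** 2
        vd = (n - 1) * a**2 * fj**2 + (n * (1 + (k - 1) * icc_a1) - a) ** 2
        v = vn / vd
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    if unit == "single":
        icc, lo, hi = icc_a1, lo1, hi1
    else:
        icc = (msr - mse) / (msr + (msc - mse) / n)
        lo = lo1 * k / (1 + lo1 * (k - 1))
        hi = hi1 * k / (1 + hi1 * (k - 1))
    return ICCResult(
        icc=float(icc),
        ci_lower=float(min(lo, icc)),
        ci_upper=float(max(hi, icc)),
        model="two-way mixed, absolute agreement",
        unit=unit,
        msr=msr,
        msc=msc,
        mse=mse,
        n_subjects=n,
        k_raters=k,
    )


# ---------------------------------------------------------------------------
# cohort analysis
# ---------------------------------------------------------------------------


def cohort_analysis(records, alpha: float = 0.05) -> dict:
    """Cohort summary of per-specimen foramen measurements.

    ``records`` is a tidy table (DataFrame or list of dicts) with one row per
    specimen x motion and columns ``specimen, motion, v_nucleotomy,
    v_discoplasty`` plus optional ``cement_volume`` and ``level``.  Per motion
    the report gives mean +- SD of dV, the paired Wilcoxon test of
    V_nucleotomy vs V_discoplasty, and (when cement volumes are present) the
    Spearman correlation of cement volume with dV; spine levels get
    descriptive dV summaries only.
    """
    df = pd.DataFrame(records).copy()
    required = {"specimen", "motion", "v_nucleotomy", "v_discoplasty"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if "delta_v" not in df.columns:
        df["delta_v"] = df["v_discoplasty"] - df["v_nucleotomy"]
    report: dict = {"alpha": alpha, "per_motion": {}, "per_level": {}}
    for motion, grp in df.groupby("motion"):
        n = len(grp)
        if n < 5:
            raise ValueError(
                f"motion {motion!r}: {n} specimens is insufficient (need >= 5)"
            )
        w_stat, w_p = wilcoxon_paired(
            grp["v_discoplasty"].to_numpy(), grp["v_nucleotomy"].to_numpy()
        )
        entry = {
            "n": int(n),
            "delta_v_mean": float(grp["delta_v"].mean()),
            "delta_v_sd": float(grp["delta_v"].std(ddof=1)),
            "wilcoxon_statistic": w_stat,
            "wilcoxon_p": w_p,
            "significant": bool(w_p < alpha),
        }
        if "cement_volume" in grp.columns and grp["cement_volume"].notna().all():
            rho, s_p = spearman(
                grp["cement_volume"].to_numpy(), grp["delta_v"].to_numpy()
            )
            entry.update(
                spearman_rho=rho,
                spearman_p=s_p,
                spearman_significant=bool(s_p < alpha),
            )
        report["per_motion"][str(motion)] = entry
    if "level" in df.columns:
        for (motion, level), grp in df.groupby(["motion", "level"]):
            report["per_level"][f"{motion}/{level}"] = {
                "n": int(len(grp)),
                "delta_v_mean": float(grp["delta_v"].mean()),
                "delta_v_sd": float(grp["delta_v"].std(ddof=1)) if len(grp) > 1 else float("nan"),
            }
    return report
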