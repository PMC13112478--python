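"""Agreement and hypothesis-test statistics plus batch report generation.

Implements the agreement toolbox used to compare segmentation methods:
Bland-Altman bias and limits of agreement, two-way random-effects
absolute-agreement single-measure intraclass correlation ICC(2,1), the
standard error of measurement, paired tests with a Shapiro-Wilk normality
gate, and one-way repeated-measures ANOVA with Tukey HSD pairwise
comparisons.  ICC and RM-ANOVA are computed from explicit two-way ANOVA
mean squares so they can be verified against independent decompositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "PairedTestResult",
    "RMAnovaResult",
    "bland_altman",
    "icc_2_1",
    "sem_from_icc",
    "sem_residual",
    "paired_test",
    "rm_anova_tukey",
    "agreement",
    "batch_report",
]


@dataclass
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    icc: float
    sem: float
    sem_residual: float
    p_paired: float
    n: int
    flags: list[str] = field(default_factory=list)


def bland_altman(x, y) -> tuple[float, float, float]:
    """(bias, LOA low, LOA high) of paired differences d = x - y.

    LOA = bias +/- 1.96 x sample SD (n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1D arrays with n >= 2")
    d = x - y
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def _two_way_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of an n x k two-way layout without replication."""
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((ratings - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_2_1(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an n_subjects x k_raters table with no missing cells.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 table")
    if not np.isfinite(ratings).all():
        raise ValueError("ratings contain missing/non-finite cells")
    if np.allclose(ratings, ratings.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    n, k = ratings.shape
    ms_r, ms_c, ms_e = _two_way_mean_squares(ratings)
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def sem_from_icc(pooled_sd: float, icc: float) -> float:
    """Standard error of measurement: pooled SD x sqrt(1 - ICC)."""
    if pooled_sd < 0:
        raise ValueError("pooled_sd must be >= 0")
    if icc > 1:
        raise ValueError("icc must be <= 1")
    return pooled_sd * float(np.sqrt(1.0 - icc))


def sem_residual(ratings) -> float:
    """Alternative SEM convention: sqrt of the two-way residual mean square."""
    ratings = np.asarray(ratings, dtype=float)
    _, _, ms_e = _two_way_mean_squares(ratings)
    return float(np.sqrt(max(ms_e, 0.0)))


@dataclass
class PairedTestResult:
    p: float
    test: str                 # "t" or "wilcoxon"
    p_t: float | None
    p_wilcoxon: float | None
    shapiro_p: float | None
    flags: list[str] = field(default_factory=list)


def paired_test(x, y, normality_alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired comparison with a Shapiro-Wilk normality gate.

    Normal differences: paired Student's t.  Non-normal: the Wilcoxon
    signed-rank p is reported as primary, flagged, with the t p alongside.
    Zero-variance differences give p = 1 with a degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    d = x - y
    if np.allclose(d, d[0]):
        if np.allclose(d, 0.0):
            return PairedTestResult(1.0, "t", 1.0, None, None, ["degenerate: zero differences"])
        return PairedTestResult(1.0, "t", 1.0, None, None, ["degenerate: constant differences"])
    shapiro_p = float(stats.shapiro(d).pvalue)
    p_t = float(stats.ttest_rel(x, y).pvalue)
    if shapiro_p < normality_alpha:
        p_w = float(stats.wilcoxon(x, y).pvalue)
        return PairedTestResult(
            p_w, "wilcoxon", p_t, p_w, shapiro_p, ["non-normal differences (Shapiro-Wilk)"]
        )
    return PairedTestResult(p_t, "t", p_t, None, shapiro_p)


@dataclass
class RMAnovaResult:
    f: float
    p_global: float
    df_between: int
    df_error: int
    pairwise: pd.DataFrame  # columns: a, b, mean_diff, p, reject
    flags: list[str] = field(default_factory=list)


def rm_anova_tukey(values, alpha: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Tukey HSD pairwise comparisons.

    ``values`` is an n_subjects x m_methods complete table.  The F statistic
    uses the within-subject error term; Tukey HSD uses the same error mean
    square with the studentized range distribution at familywise ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("values must be an n>=2 by m>=2 table")
    if not np.isfinite(values).all():
        raise ValueError("values contain missing/non-finite cells")
    n, m = values.shape
    ms_subj, ms_meth, ms_err = _two_way_mean_squares(values)
    df_b, df_e = m - 1, (n - 1) * (m - 1)
    ss_meth = ms_meth * df_b
    flags: list[str] = []
    if np.isclose(ms_err, 0.0):
        flags.append("degenerate: zero error variance")
        if np.isclose(ss_meth, 0.0):
            f_stat, p_global = 0.0, 1.0
        else:
            f_stat, p_global = float("inf"), 0.0
    else:
        f_stat = ms_meth / ms_err
        p_global = float(stats.f.sf(f_stat, df_b, df_e))

    col_means = values.mean(axis=0)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            diff = float(col_means[i] - col_means[j])
            if np.isclose(ms_err, 0.0):
                p = 1.0 if np.isclose(diff, 0.0) else 0.0
            else:
                q = abs(diff) / np.sqrt(ms_err / n)
                p = float(stats.studentized_range.sf(q, m, df_e))
            rows.append({"a": i, "b": j, "mean_diff": diff, "p": p, "reject": p < alpha})
    return RMAnovaResult(f_stat, p_global, df_b, df_e, pd.DataFrame(rows), flags)


def agreement(x, y) -> AgreementResult:
    """Full agreement panel for one paired metric comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bias, lo, hi = bland_altman(x, y)
    ratings = np.column_stack([x, y])
    try:
        icc = icc_2_1(ratings)
    except ValueError:
        icc = float("nan")
    pooled_sd = float(np.concatenate([x, y]).std(ddof=1))
    sem = sem_from_icc(pooled_sd, icc) if np.isfinite(icc) else float("nan")
    if x.size >= 3:
        test = paired_test(x, y)
        p, flags = test.p, list(test.flags)
    else:
        p, flags = float("nan"), ["n < 3: no paired test"]
    return AgreementResult(bias, lo, hi, icc, sem, sem_residual(ratings), p, x.size, flags)


def batch_report(
    per_subject: pd.DataFrame,
    comparisons: list[dict],
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Build agreement and summary tables from per-subject metric rows.

    ``per_subject`` has one row per (subject_id, method) with metric columns;
    an optional ``group`` column marks healthy/HFpEF/HFrEF.  ``comparisons``
    entries are ``{"a": method, "b": method, "metric": column}``; subjects
    missing in either arm are listed and excluded pairwise.

    Returns (and optionally writes as CSV) three tables: per-comparison
    agreement, per-method mean +/- SD summaries, and LV-RV stroke-volume
    agreement restricted to healthy subjects.
    """
    agr_rows = []
    for comp in comparisons:
        a, b, metric = comp["a"], comp["b"], comp["metric"]
        ta = per_subject[per_subject["method"] == a].set_index("subject_id")[metric]
        tb = per_subject[per_subject["method"] == b].set_index("subject_id")[metric]
        common = sorted(set(ta.index) & set(tb.index))
        missing = sorted((set(ta.index) | set(tb.index)) - set(common))
        if len(common) < 2:
            raise ValueError(f"comparison {a} vs {b} on {metric}: fewer than 2 paired subjects")
        if missing:
            warnings.warn(f"{a} vs {b} on {metric}: excluded unpaired subjects {missing}")
        res = agreement(ta.loc[common].to_numpy(), tb.loc[common].to_numpy())
        agr_rows.append(
            {
                "method_a": a,
                "method_b": b,
                "metric": metric,
                "n": res.n,
                "bias": res.bias,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "icc": res.icc,
                "sem": res.sem,
                "sem_residual": res.sem_residual,
                "p_paired": res.p_paired,
                "excluded": ";".join(map(str, missing)),
            }
        )
    agreement_df = pd.DataFrame(agr_rows)

    metric_cols = [
        c for c in per_subject.columns
        if c not in ("subject_id", "method", "group", "cohort")
        and pd.api.types.is_numeric_dtype(per_subject[c])
    ]
    summary_df = (
        per_subject.groupby("method")[metric_cols]
        .agg(["mean", "std"])
        .round(6)
    )
    summary_df.columns = [f"{m}_{stat}" for m, stat in summary_df.columns]
    summary_df = summary_df.reset_index()

    sv_rows = []
    if {"sv_lv_ml", "sv_rv_ml"} <= set(per_subject.columns):
        healthy = per_subject
        if "group" in per_subject.columns:
            healthy = per_subject[per_subject["group"] == "healthy"]
        for method, sub in healthy.groupby("method"):
            if len(sub) >= 2:
                res = agreement(sub["sv_lv_ml"].to_numpy(), sub["sv_rv_ml"].to_numpy())
                sv_rows.append(
                    {
                        "method": method,
                        "n_healthy": res.n,
                        "bias_ml": res.bias,
                        "loa_low_ml": res.loa_low,
                        "loa_high_ml": res.loa_high,
                        "icc": res.icc,
                        "p_paired": res.p_paired,
                    }
                )
    sv_df = pd.DataFrame(sv_rows)

    tables = {"agreement": agreement_df, "summary": summary_df, "sv_agreement": sv_df}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return tables
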