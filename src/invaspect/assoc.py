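"""Association tests of a phenotype against a factor across a structured cohort.

A cohort of (tumor, organoid) observations with phenotype y and factor x is
split into tumor means (ȳ_t, x̄_t) and within-tumor deviations
(δy_ti = y_ti − ȳ_t, δx_ti = x_ti − x̄_t).  The between-tumor test regresses
ȳ on x̄ with an intercept (df = T − 2); the within-tumor test regresses δy
on δx *without* an intercept (the T tumor means are already absorbed,
df = N − T − 1).  Under the variance-components model the two tests are
statistically independent.

Extreme-tails designs rank organoids by y within each tumor and keep the
top/bottom fraction f (at least one organoid per tail; the median organoid
goes to the lower pool at f = 0.5 with odd group size).  The tails test is
an intercept regression of δy on δx in the selected subset; the pooled test
averages δx per tail per tumor and compares upper vs lower pool means with
a paired t test across tumors — shift-invariant in x, so pooling raw x_ti
gives identical results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedCohort",
    "TestResult",
    "TailAssignment",
    "split",
    "between_test",
    "within_test",
    "select_tails",
    "tails_test",
    "pooled_test",
]


@dataclass(frozen=True)
class TestResult:
    """Slope, fit quality and significance of one association test."""

    test: str
    beta_hat: float
    r_sq: float
    t_stat: float
    df: int
    p_value: float
    n_used: int
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairedCohort:
    """Filtered cohort with per-tumor means and deviations precomputed.

    ``table`` has columns tumor_id, organoid_id, y, x, ybar, xbar, dy, dx.
    """

    table: pd.DataFrame
    min_organoids: int
    n_tumors_dropped: int

    @property
    def n_tumors(self) -> int:
        return self.table["tumor_id"].nunique()

    @property
    def n_organoids(self) -> int:
        return len(self.table)

    def tumor_means(self) -> pd.DataFrame:
        return (self.table.groupby("tumor_id", sort=False)[["ybar", "xbar"]]
                .first().reset_index())


def split(cohort: pd.DataFrame, min_organoids: int = 5) -> PairedCohort:
    """Filter tumors by size and compute means/deviations.

    ``cohort`` must have columns tumor_id, organoid_id, y, x.  Tumors with
    fewer than ``min_organoids`` organoids are dropped; at least 2 tumors
    must survive.
    """
    required = {"tumor_id", "organoid_id", "y", "x"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    sizes = cohort.groupby("tumor_id")["organoid_id"].size()
    keep = sizes.index[sizes >= min_organoids]
    dropped = len(sizes) - len(keep)
    if len(keep) < 2:
        raise ValueError("fewer than 2 tumors pass the organoid-count filter")
    df = cohort[cohort["tumor_id"].isin(keep)].copy()
    grp = df.groupby("tumor_id", sort=False)
    df["ybar"] = grp["y"].transform("mean")
    df["xbar"] = grp["x"].transform("mean")
    df["dy"] = df["y"] - df["ybar"]
    df["dx"] = df["x"] - df["xbar"]
    return PairedCohort(table=df.reset_index(drop=True), min_organoids=min_organoids,
                        n_tumors_dropped=dropped)


def _intercept_ols(x: np.ndarray, y: np.ndarray, test: str) -> TestResult:
    if np.ptp(x) == 0:
        raise ValueError(f"{test}: zero variance in the regressor")
    fit = stats.linregress(x, y)
    df = len(x) - 2
    return TestResult(
        test=test,
        beta_hat=float(fit.slope),
        r_sq=float(fit.rvalue**2),
        t_stat=float(fit.slope / fit.stderr) if fit.stderr > 0 else math.inf,
        df=df,
        p_value=float(fit.pvalue),
        n_used=len(x),
        extra={"intercept": float(fit.intercept)},
    )


def between_test(cohort: PairedCohort) -> TestResult:
    """OLS of tumor-mean phenotype on tumor-mean factor, with intercept."""
    means = cohort.tumor_means()
    if len(means) < 3:
        raise ValueError("between-tumor test requires at least 3 tumors")
    return _intercept_ols(means["xbar"].to_numpy(), means["ybar"].to_numpy(), "between")


def within_test(cohort: PairedCohort) -> TestResult:
    """No-intercept OLS of phenotype deviations on factor deviations.

    The t test on the slope uses df = N − T − 1 (the T tumor means are
    estimated from the same data); the OLS-default df = N − 1 p-value is
    reported in ``extra`` for comparison.
    """
    dx = cohort.table["dx"].to_numpy()
    dy = cohort.table["dy"].to_numpy()
    n, t = len(dx), cohort.n_tumors
    df = n - t - 1
    if df < 1:
        raise ValueError("within-tumor test requires N − T − 1 >= 1")
    sxx = float(dx @ dx)
    if sxx == 0:
        raise ValueError("within: zero variance in factor deviations")
    beta = float(dx @ dy) / sxx
    resid = dy - beta * dx
    rss = float(resid @ resid)
    tss = float(dy @ dy)
    se = math.sqrt(rss / df / sxx)
    t_stat = beta / se if se > 0 else math.inf
    p = float(2 * stats.t.sf(abs(t_stat), df))
    df_ols = n - 1
    se_ols = math.sqrt(rss / df_ols / sxx)
    p_ols = float(2 * stats.t.sf(abs(beta / se_ols), df_ols))
    return TestResult(
        test="within",
        beta_hat=beta,
        r_sq=1.0 - rss / tss if tss > 0 else 0.0,
        t_stat=float(t_stat),
        df=df,
        p_value=p,
        n_used=n,
        extra={"df_ols": df_ols, "p_value_ols": p_ols},
    )


@dataclass(frozen=True)
class TailAssignment:
    """Per-organoid tail labels ('upper'/'lower'/'none') at pool fraction f."""

    labels: pd.Series  # aligned with the PairedCohort table index
    f: float
    tail_counts: pd.DataFrame  # per tumor: n, n_upper, n_lower


def select_tails(cohort: PairedCohort, f: float) -> TailAssignment:
    """Rank organoids by phenotype within each tumor and label the extreme tails.

    Tail size is ceil(N_t·f), ensuring at least one organoid per tail; when
    the two tails would overlap (odd N_t at f = 0.5) the lower pool keeps
    the median organoid and the upper pool shrinks.  Ties in y are broken by
    a stable sort on (y, organoid_id), so assignment is deterministic and
    invariant to monotone transforms of y.
    """
    if not 0 < f <= 0.5:
        raise ValueError("tail fraction must be in (0, 0.5]")
    table = cohort.table
    labels = pd.Series("none", index=table.index, dtype=object)
    counts = []
    for tumor, idx in table.groupby("tumor_id", sort=False).groups.items():
        sub = table.loc[idx].sort_values(["y", "organoid_id"], kind="stable")
        n_t = len(sub)
        k = math.ceil(n_t * f)
        k_lower = min(k, n_t)
        k_upper = min(k, n_t - k_lower)
        labels.loc[sub.index[:k_lower]] = "lower"
        if k_upper > 0:
            labels.loc[sub.index[-k_upper:]] = "upper"
        counts.append({"tumor_id": tumor, "n": n_t, "n_lower": k_lower, "n_upper": k_upper})
    return TailAssignment(labels=labels, f=f, tail_counts=pd.DataFrame(counts))


def tails_test(cohort: PairedCohort, tails: TailAssignment) -> TestResult:
    """Intercept OLS of δy on δx restricted to tail-member organoids."""
    in_tails = tails.labels.isin(["upper", "lower"])
    sub = cohort.table[in_tails]
    if len(sub) < 3:
        raise ValueError("tails test requires at least 3 organoids in the tails")
    return _intercept_ols(sub["dx"].to_numpy(), sub["dy"].to_numpy(), "tails")


def pooled_test(cohort: PairedCohort, tails: TailAssignment) -> TestResult:
    """Paired t test of per-tumor upper- vs lower-pool mean factor deviations.

    The pool statistic is the mean δx within each tail (tails were selected
    on y); tumors missing either tail are excluded with a warning.
    """
    table = cohort.table.assign(tail=tails.labels)
    upper, lower = [], []
    excluded = []
    for tumor, sub in table.groupby("tumor_id", sort=False):
        up = sub.loc[sub["tail"] == "upper", "dx"]
        lo = sub.loc[sub["tail"] == "lower", "dx"]
        if up.empty or lo.empty:
            excluded.append(tumor)
            continue
        upper.append(up.mean())
        lower.append(lo.mean())
    if excluded:
        warnings.warn(f"tumors missing a tail excluded from pooled test: {excluded}",
                      stacklevel=2)
    if len(upper) < 2:
        raise ValueError("pooled test requires at least 2 tumors with both tails")
    upper = np.array(upper)
    lower = np.array(lower)
    diff = upper - lower
    if np.allclose(diff, diff[0]) and np.ptp(diff) == 0 and diff[0] == 0:
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(upper, lower)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return TestResult(
        test="pooled",
        beta_hat=float(diff.mean()),
        r_sq=float("nan"),
        t_stat=t_stat,
        df=len(diff) - 1,
        p_value=p,
        n_used=len(diff),
        extra={"excluded_tumors": excluded},
    )
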