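"""Landing-outcome statistics and cohort aggregation.

Impacts are classified by the body surface closest to the landing surface
(ventral, dorsal, left, right, cranial, caudal) and by outcome (success =
clung to the target; failure = bounced or fell off).  Provides the exact
Clopper-Pearson binomial CI for the success probability, simultaneous
multinomial CIs for orientation proportions against the equal-probability
(1/6) null, a chi-squared two-sample homogeneity test used to justify
pooling life stages, and grand means computed as means of individual
specimen means (each animal weighted equally regardless of trial count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import multinomial_proportions_confint

__all__ = [
    "ORIENTATIONS",
    "LandingOutcomeTable",
    "CohortSummary",
    "success_probability_ci",
    "multinomial_proportion_cis",
    "chisq_two_sample",
    "specimen_grand_mean",
]

ORIENTATIONS = ("ventral", "dorsal", "left", "right", "cranial", "caudal")
OUTCOMES = ("success", "failure")


@dataclass
class LandingOutcomeTable:
    """Counts of impacts by orientation x outcome, with per-specimen records.

    ``records`` is a DataFrame with columns specimen_id, trial_id,
    impact_orientation, outcome.
    """

    records: pd.DataFrame

    def __post_init__(self):
        required = {"specimen_id", "trial_id", "impact_orientation", "outcome"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        bad = set(self.records["impact_orientation"]) - set(ORIENTATIONS)
        if bad:
            raise ValueError(f"unknown orientations {sorted(bad)}")
        bad = set(self.records["outcome"]) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcomes {sorted(bad)}")

    @property
    def counts(self) -> pd.DataFrame:
        """Orientation x outcome count table (all six orientations present)."""
        table = pd.crosstab(self.records["impact_orientation"],
                            self.records["outcome"])
        table = table.reindex(index=list(ORIENTATIONS),
                              columns=list(OUTCOMES), fill_value=0)
        return table

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def n_specimens(self) -> int:
        return self.records["specimen_id"].nunique()

    def orientation_counts(self, outcome: str | None = None) -> np.ndarray:
        """Counts per orientation, optionally restricted to one outcome."""
        df = self.records
        if outcome is not None:
            df = df[df["outcome"] == outcome]
        counts = df["impact_orientation"].value_counts()
        return np.array([counts.get(o, 0) for o in ORIENTATIONS])

    def success_counts(self) -> tuple[int, int]:
        k = int((self.records["outcome"] == "success").sum())
        return k, self.n_trials


def success_probability_ci(k_success: int, n_total: int, conf: float = 0.95
                           ) -> tuple[float, float, float]:
    """Exact Clopper-Pearson binomial CI for a success probability.

    Bounds from beta-distribution quantiles: lower = Q_Beta(alpha/2; k,
    n-k+1), upper = Q_Beta(1-alpha/2; k+1, n-k); lower = 0 at k = 0 and
    upper = 1 at k = n.  Returns (p_hat, lower, upper).
    """
    if n_total <= 0:
        raise ValueError("need n_total > 0")
    if not 0 <= k_success <= n_total:
        raise ValueError("need 0 <= k_success <= n_total")
    alpha = 1.0 - conf
    p_hat = k_success / n_total
    lower = 0.0 if k_success == 0 else float(
        stats.beta.ppf(alpha / 2, k_success, n_total - k_success + 1))
    upper = 1.0 if k_success == n_total else float(
        stats.beta.ppf(1 - alpha / 2, k_success + 1, n_total - k_success))
    return p_hat, lower, upper


def multinomial_proportion_cis(counts, conf: float = 0.95,
                               method: str = "sison_glaz",
                               null_prob: float | None = None) -> dict:
    """Simultaneous CIs for multinomial category proportions.

    ``method``: "sison_glaz" (default) or "goodman".  When ``null_prob`` is
    given (e.g. 1/6 for six equally likely impact orientations), each
    category is classified as significantly more frequent than expected
    (its CI excludes the null from above), significantly less frequent, or
    consistent with the null.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need a 1-D array of >= 2 category counts")
    if counts.sum() == 0:
        raise ValueError("all counts are zero")
    sm_method = {"sison_glaz": "sison-glaz", "goodman": "goodman"}[method]
    try:
        ci = multinomial_proportions_confint(counts, alpha=1.0 - conf,
                                             method=sm_method)
    except Exception:
        if sm_method == "goodman":
            raise
        # Sison-Glaz is undefined for extreme tables (all mass in one cell);
        # fall back to the Goodman construction
        warnings.warn("Sison-Glaz interval undefined for this table; "
                      "falling back to Goodman")
        method = "goodman"
        ci = multinomial_proportions_confint(counts, alpha=1.0 - conf,
                                             method="goodman")
    ci = np.clip(ci, 0.0, 1.0)
    out = {
        "proportions": counts / counts.sum(),
        "lower": ci[:, 0],
        "upper": ci[:, 1],
        "method": method,
        "conf": conf,
    }
    if null_prob is not None:
        above = ci[:, 0] > null_prob
        below = ci[:, 1] < null_prob
        out["significantly_above"] = above
        out["significantly_below"] = below
    return out


def chisq_two_sample(counts_a, counts_b) -> tuple[float, int, float]:
    """Chi-squared two-sample homogeneity test on a 2 x K count table.

    Zero-margin categories are dropped with a warning; expected counts < 5
    raise a small-sample warning.  Returns (chi2, df, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the category set")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-margin categories")
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("fewer than 2 non-empty categories")
    table = np.vstack([a, b])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        warnings.warn("some expected counts are < 5; chi-squared "
                      "approximation may be poor")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def plot_orientation_proportions(counts, out_path=None, conf: float = 0.95,
                                 method: str = "sison_glaz", ax=None):
    """Bar plot of impact-orientation proportions with simultaneous CIs.

    Draws one bar per orientation with its CI error bar and a dashed line
    at the equal-probability null 1/6.  Returns the axes; saves to
    ``out_path`` when given.
    """
    import matplotlib
    if out_path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cis = multinomial_proportion_cis(counts, conf=conf, method=method)
    p = cis["proportions"]
    err = np.vstack([p - cis["lower"], cis["upper"] - p])
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(p)), p, color="0.6", edgecolor="k")
    ax.errorbar(range(len(p)), p, yerr=np.clip(err, 0, None), fmt="none",
                ecolor="k", capsize=4)
    ax.axhline(1.0 / len(p), linestyle="--", color="k", linewidth=1)
    ax.set_xticks(range(len(p)))
    ax.set_xticklabels(ORIENTATIONS[: len(p)], rotation=30)
    ax.set_ylabel("proportion of impacts")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


@dataclass(frozen=True)
class CohortSummary:
    """Grand mean over specimen means with a 95% t-interval.

    ``n_specimens`` is N (individual animals), ``n_trials`` is n (trials);
    the grand mean weights every specimen equally.
    """

    specimen_means: pd.Series
    grand_mean: float
    ci: tuple[float, float]
    n_specimens: int
    n_trials: int
    conf: float = 0.95


def specimen_grand_mean(values, specimen_ids, conf: float = 0.95
                        ) -> CohortSummary:
    """Two-stage mean: per-specimen means, then their unweighted mean.

    The CI uses the t distribution on the specimen means (undefined width
    for a single specimen, reported as NaN bounds).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "specimen": list(specimen_ids)})
    if df.empty:
        raise ValueError("no values")
    means = df.groupby("specimen")["value"].mean()
    grand = float(means.mean())
    n_spec = len(means)
    if n_spec > 1:
        sd = float(means.std(ddof=1))
        half = stats.t.ppf(0.5 + conf / 2, n_spec - 1) * sd / np.sqrt(n_spec)
        ci = (grand - half, grand + half)
    else:
        ci = (float("nan"), float("nan"))
    return CohortSummary(specimen_means=means, grand_mean=grand, ci=ci,
                         n_specimens=n_spec, n_trials=len(df), conf=conf)
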