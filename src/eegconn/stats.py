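"""Group comparison: two-sample t-tests with Benjamini–Hochberg FDR.

One test is run per (band × region or region-pair × direction) cell and
the BH step-up adjustment is applied within the declared family (by
default all cells of one estimator at one aggregation level).  The
t-test is an independent two-sample test — pooled-variance Student by
default, Welch as an option; significance is judged on the adjusted
p-value at α = 0.05.

Demographic helpers (t from summary statistics, 2×2 Pearson χ²) are
included for cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "two_sample_ttest",
    "ttest_from_summary",
    "chisq_2x2",
    "fdr_adjust",
    "compare_groups",
]


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     equal_var: bool = True) -> tuple[float, float]:
    """Independent two-sample t-test (pooled by default, Welch optional).

    Returns (t, two-sided p).  Degenerate inputs with zero pooled
    variance: equal means give (0, 1); unequal means are an error (the
    statistic is unbounded).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means: "
                         "t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t from summary statistics (Welch by default).

    Useful for checking published cohort tables that report only
    mean ± SD per group.
    """
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chisq_2x2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson χ² for a 2×2 contingency table, df = 1.

    Uncorrected by default; set ``correction=True`` for Yates.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(~np.isfinite(pvals)) or np.any(pvals < 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return adjusted


def _tidy(results: pd.DataFrame | Sequence) -> pd.DataFrame:
    """Normalize group results to a tidy frame (subject, band, cell, value)."""
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        # sequence of ConnectivityResult
        rows = []
        for res in results:
            for lab, val in zip(res.labels, res.values):
                rows.append({"subject": res.subject, "band": res.band,
                             "cell": lab, "value": float(val)})
        df = pd.DataFrame(rows)
    required = {"subject", "band", "cell", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"group results missing columns: {sorted(missing)}")
    return df


def compare_groups(results_a, results_b, alpha: float = 0.05,
                   equal_var: bool = True, group_names: tuple[str, str] = ("A", "B"),
                   ) -> pd.DataFrame:
    """Cell-wise two-sample t-tests between two groups with BH FDR.

    Parameters
    ----------
    results_a, results_b
        Tidy DataFrames with columns (subject, band, cell, value) — one
        row per subject per band per region/region-pair cell — or
        sequences of per-subject :class:`ConnectivityResult`.
    alpha : float
        Significance level applied to the adjusted p-values.
    equal_var : bool
        Pooled-variance Student t (default) or Welch.

    Returns
    -------
    DataFrame with one row per (band, cell): group means, t, p,
    p_adjusted and a significance flag, sorted by adjusted p.  The FDR
    family is exactly the set of rows of this table.
    """
    dfa, dfb = _tidy(results_a), _tidy(results_b)
    cells_a = set(map(tuple, dfa[["band", "cell"]].drop_duplicates().values))
    cells_b = set(map(tuple, dfb[["band", "cell"]].drop_duplicates().values))
    if cells_a != cells_b:
        raise ValueError(
            "family mismatch between groups: "
            f"only in {group_names[0]}: {sorted(cells_a - cells_b)}; "
            f"only in {group_names[1]}: {sorted(cells_b - cells_a)}"
        )
    for name, df in zip(group_names, (dfa, dfb)):
        if df["subject"].nunique() < 2:
            raise ValueError(
                f"group {name!r} has {df['subject'].nunique()} subject(s); "
                "group statistics need at least 2 per group"
            )
    ga = dfa.groupby(["band", "cell"])["value"]
    gb = dfb.groupby(["band", "cell"])["value"]
    rows = []
    for key in sorted(cells_a):
        va, vb = ga.get_group(key).to_numpy(), gb.get_group(key).to_numpy()
        t, p = two_sample_ttest(va, vb, equal_var=equal_var)
        rows.append({"band": key[0], "cell": key[1],
                     f"mean_{group_names[0]}": va.mean(),
                     f"mean_{group_names[1]}": vb.mean(),
                     "t": t, "p": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = fdr_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    return table.sort_values("p_adjusted", kind="mergesort").reset_index(drop=True)
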