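"""Phenotype–covariate association reporting.

Produces the per-cluster covariate summary table: continuous covariates
as mean (SD) per cluster with a Kruskal–Wallis test, categorical ones as
per-cluster counts with a Pearson chi-square test (Yates continuity
correction for 2×2 tables, matching R's `chisq.test` default).  A flat
0.05 significance threshold is used per test; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CONTINUOUS = ("age", "bmi", "pack_years")
DEFAULT_CATEGORICAL = ("sex", "smoking_status", "lungrads_group", "cancer", "obstruction")

#: Row order of the report (matches the published table layout).
COVARIATE_ORDER = (
    "age",
    "bmi",
    "sex",
    "smoking_status",
    "pack_years",
    "lungrads_group",
    "cancer",
    "obstruction",
)


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with its chi-square asymptotic p.

    All-identical values (zero tie-corrected variance) return H = 0,
    p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ids = pd.unique(groups)
    if len(ids) < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    samples = [values[groups == g] for g in ids]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 contingency table, 1 df asymptotic p.

    Yates continuity correction is applied by default — the convention of
    R's ``chisq.test``, under which the published contingency p-values
    reproduce.  All margins must be positive.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined for a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    return float(chi2), float(p)


def chi_square_rxc(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square for larger tables (no continuity correction)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def build_association_table(
    assignments: np.ndarray,
    covariates: pd.DataFrame,
    continuous_set: tuple[str, ...] = DEFAULT_CONTINUOUS,
    categorical_set: tuple[str, ...] = DEFAULT_CATEGORICAL,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster covariate summaries with test statistics and p-values.

    ``assignments`` must align row-wise with ``covariates``.  Missing
    values are handled per covariate by complete-case analysis; a
    covariate with no non-missing values is omitted with a warning.

    Returns a DataFrame with columns ``covariate``, one summary column
    per cluster (``cluster<k>_summary``), ``test``, ``statistic``,
    ``p_value`` and ``significant``.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(covariates):
        raise ValueError("assignments must cover the covariate table")
    clusters = sorted(pd.unique(assignments))
    rows = []
    for cov in COVARIATE_ORDER:
        if cov not in covariates.columns:
            continue
        col = covariates[cov]
        ok = col.notna().to_numpy()
        if not ok.any():
            import warnings

            warnings.warn(f"covariate {cov!r} entirely missing; row omitted")
            continue
        vals = col[ok]
        grp = assignments[ok]
        row: dict = {"covariate": cov}
        if cov in continuous_set:
            for k in clusters:
                sub = vals[grp == k].astype(float)
                row[f"cluster{k}_summary"] = f"{sub.mean():.2f} ({sub.std(ddof=1):.2f})"
            H, p = kruskal_wallis(vals.to_numpy(float), grp)
            row.update(test="kruskal_wallis", statistic=H, p_value=p)
        elif cov in categorical_set:
            levels = sorted(pd.unique(vals))
            table = np.array(
                [[int(((vals == lv) & (grp == k)).sum()) for lv in levels] for k in clusters]
            )
            for k, counts in zip(clusters, table):
                row[f"cluster{k}_summary"] = "/".join(str(c) for c in counts)
            if table.shape == (2, 2):
                chi2, p = chi_square_2x2(table)
            else:
                chi2, p = chi_square_rxc(table)
            row.update(test="chi_square", statistic=chi2, p_value=p)
        else:
            continue
        row["significant"] = row["p_value"] < alpha
        rows.append(row)
    return pd.DataFrame(rows)
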