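"""Cohort statistics: adjusted group contrasts, correlations, paired tests.

Age-group comparisons are ordinary least squares of the outcome on
{intercept, group, sex, site}, reporting the group coefficient, its t
statistic (df = n - rank) and a two-sided p-value. Inter-modality agreement
uses Pearson correlation; within-subject tissue and modality contrasts use
paired t-tests. Two-sided p-values throughout, no multiple-testing
correction (per-comparison alpha).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .types import TestResult

__all__ = [
    "group_compare_adjusted",
    "pearson_corr",
    "paired_ttest",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)


def _design_matrix(
    group: np.ndarray, sex: np.ndarray, site: np.ndarray
) -> pd.DataFrame:
    """Intercept + group indicator + binary covariate indicators.

    ``group`` is coded old=1 / young=0 (the reference is the first level in
    sorted order otherwise); sex and site get one indicator per non-reference
    level. Constant covariate columns (e.g. a single-site cohort) are dropped
    with a log note.
    """
    df = pd.DataFrame({"const": np.ones(len(group))})
    levels = sorted(pd.unique(group))
    if "young" in levels and "old" in levels:
        ref = "young"
    else:
        ref = levels[0]
    for lev in levels:
        if lev != ref:
            df[f"group[{lev}]"] = (group == lev).astype(float)
    for name, col in (("sex", sex), ("site", site)):
        lv = sorted(pd.unique(col))
        if len(lv) < 2:
            logger.info("covariate %r is constant; dropped from the design", name)
            continue
        for lev in lv[1:]:
            df[f"{name}[{lev}]"] = (col == lev).astype(float)
    return df


def group_compare_adjusted(
    values,
    group,
    sex,
    site,
) -> TestResult:
    """Group contrast adjusted for sex and site via OLS.

    Returns the group coefficient (second level minus reference, i.e.
    old - young), its t statistic with df = n - rank, and the two-sided p.
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    sex = np.asarray(sex)
    site = np.asarray(site)
    counts = pd.Series(group).value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need exactly 2 groups with >= 2 subjects each")
    X = _design_matrix(group, sex, site)
    X.index = pd.RangeIndex(len(y))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify which column is redundant for a useful error message
        for j, col in enumerate(X.columns):
            others = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"design matrix is rank-deficient: column {col!r}")
        raise ValueError("design matrix is rank-deficient")
    fit = sm.OLS(y, X).fit()
    term = [c for c in X.columns if c.startswith("group[")][0]
    return TestResult(
        estimate=float(fit.params[term]),
        t_statistic=float(fit.tvalues[term]),
        df=float(fit.df_resid),
        p_value=float(fit.pvalues[term]),
        test_name="group OLS adjusted for sex and site",
    )


def pearson_corr(x, y) -> TestResult:
    """Pearson correlation with t = r * sqrt((n-2) / (1-r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    n = x.size
    if abs(r) == 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return TestResult(
        estimate=float(r),
        t_statistic=float(t),
        df=float(n - 2),
        p_value=float(p),
        test_name="Pearson correlation",
    )


def paired_ttest(a, b) -> TestResult:
    """Paired t-test on differences a - b, df = n - 1, two-sided.

    Zero-variance differences are degenerate for the t distribution: an
    all-zero difference returns t = 0, p = 1; a constant nonzero difference
    returns an infinite-t sentinel with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    d = a - b
    n = d.size
    if np.std(d, ddof=0) == 0:
        mean = float(d.mean())
        if mean == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean)) * np.inf, 0.0
        return TestResult(
            estimate=mean, t_statistic=t, df=float(n - 1), p_value=p,
            test_name="paired t-test",
        )
    t, p = sps.ttest_rel(a, b)
    return TestResult(
        estimate=float(d.mean()),
        t_statistic=float(t),
        df=float(n - 1),
        p_value=float(p),
        test_name="paired t-test",
    )


def _pivot(records: pd.DataFrame) -> pd.DataFrame:
    wide = records.pivot_table(
        index=["subject_id", "group", "sex", "site"],
        columns=["modality", "compartment"],
        values="cvr",
    )
    wide.columns = [f"{m}_{c}" for m, c in wide.columns]
    return wide.reset_index()


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Cohort report: group means +/- SE, adjusted group tests, paired tests.

    ``records`` is a tidy table with columns subject_id, group, sex, site,
    modality (pc|asl|bold), compartment (wb|gm|wm), cvr and optionally
    basal_cbf (one value per subject, repeated across rows). Returns a dict
    with a per-measure group table (DataFrame), a paired-test table
    (DataFrame) and a human-readable ``text`` rendering.
    """
    required = {"subject_id", "group", "sex", "site", "modality", "compartment", "cvr"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    wide = _pivot(records)
    if "basal_cbf" in records.columns:
        cbf = records.groupby("subject_id")["basal_cbf"].first()
        wide = wide.merge(cbf, left_on="subject_id", right_index=True)
    groups = sorted(wide["group"].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly 2 groups")
    measure_cols = [
        c for c in wide.columns
        if c not in ("subject_id", "group", "sex", "site")
    ]
    rows = []
    for col in measure_cols:
        sub = wide.dropna(subset=[col])
        res = group_compare_adjusted(
            sub[col], sub["group"], sub["sex"], sub["site"]
        )
        row = {"measure": col}
        for g in groups:
            v = sub.loc[sub["group"] == g, col]
            row[f"{g}_mean"] = v.mean()
            row[f"{g}_se"] = v.std(ddof=1) / np.sqrt(len(v))
        row.update(
            estimate=res.estimate, t=res.t_statistic, df=res.df, p=res.p_value
        )
        rows.append(row)
    group_table = pd.DataFrame(rows)

    paired_rows = []

    def _add_paired(label: str, x: str, y: str) -> None:
        if x in wide.columns and y in wide.columns:
            sub = wide.dropna(subset=[x, y])
            if len(sub) >= 2:
                res = paired_ttest(sub[x], sub[y])
                paired_rows.append(
                    {"contrast": label, "mean_diff": res.estimate,
                     "t": res.t_statistic, "df": res.df, "p": res.p_value}
                )

    _add_paired("pc_wb - asl_wb", "pc_wb", "asl_wb")
    for mod in ("asl", "bold"):
        _add_paired(f"{mod}_gm - {mod}_wm", f"{mod}_gm", f"{mod}_wm")
    paired_table = pd.DataFrame(paired_rows)

    lines = ["Cohort CVR report", "=" * 60, "", "Group comparison (adjusted):"]
    for _, r in group_table.iterrows():
        lines.append(
            f"  {r['measure']:<12s} "
            + " ".join(
                f"{g}={r[f'{g}_mean']:.3g} (SE {r[f'{g}_se']:.2g})" for g in groups
            )
            + f"  t_{r['df']:.0f}={r['t']:.2f} p={r['p']:.3g}"
        )
    lines += ["", "Within-subject paired contrasts:"]
    for _, r in paired_table.iterrows():
        lines.append(
            f"  {r['contrast']:<18s} diff={r['mean_diff']:.3g} "
            f"t_{r['df']:.0f}={r['t']:.2f} p={r['p']:.3g}"
        )
    return {
        "group_table": group_table,
        "paired_table": paired_table,
        "text": "\n".join(lines),
    }
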