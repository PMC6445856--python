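"""Clinico-morphological association battery with FDR control.

Each retained clinical variable is tested against each of the four profile
features (cell-type densities): a two-sample t-test of group means for
binary variables, a Pearson correlation for continuous ones.  All executed
tests form a single family and the Benjamini–Hochberg step-up procedure
flags the discoveries at a chosen false-discovery rate.

Variable retention mirrors standard cohort practice: variables with more
than a configurable fraction of missing values, or with fewer than two
observed levels, are dropped; missing values are removed listwise per test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import CELL_TYPES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean0: float
    mean1: float


def two_sample_t_test(
    values_group0: Sequence[float],
    values_group1: Sequence[float],
    equal_var: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test of equal means (Welch by default)."""
    g0 = np.asarray(values_group0, dtype=float)
    g1 = np.asarray(values_group1, dtype=float)
    if g0.size < 2 or g1.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        raise ValueError("degenerate groups: zero variance in both")
    res = stats.ttest_ind(g0, g1, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean0=float(g0.mean()),
        mean1=float(g1.mean()),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cell_correlation_matrix(slide_profiles: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Pearson correlations of the four per-slide features."""
    if isinstance(slide_profiles, pd.DataFrame):
        arr = slide_profiles[list(CELL_TYPES)].to_numpy(dtype=float)
    else:
        arr = np.asarray(slide_profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(CELL_TYPES):
        raise ValueError(f"slide profiles must have {len(CELL_TYPES)} feature columns")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 slides")
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("a feature is constant across slides")
    corr = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(corr, index=list(CELL_TYPES), columns=list(CELL_TYPES))


def bh_adjust(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags.

    Sort the m p-values ascending, find the largest k with
    ``p_(k) <= k * alpha / m``, and flag all tests of rank <= k.  Controls
    the false discovery rate at ``alpha`` for independent or positively
    dependent tests.  Empty input yields an empty flag vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def bh_adjusted_pvalues(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up adjustment)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    _, adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return adj


# ---------------------------------------------------------------------------
# The battery
# ---------------------------------------------------------------------------


def infer_variable_types(
    clinical: pd.DataFrame, max_levels_binary: int = 2
) -> dict[str, str]:
    """Tag each clinical column as 'binary' or 'continuous'.

    Non-numeric columns and numeric columns with at most ``max_levels_binary``
    observed levels are binary; other numeric columns are continuous.
    """
    tags: dict[str, str] = {}
    for col in clinical.columns:
        series = clinical[col].dropna()
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > max_levels_binary:
            tags[col] = "continuous"
        else:
            tags[col] = "binary"
    return tags


def filter_variables(
    clinical: pd.DataFrame, max_missing: float = 0.3
) -> tuple[pd.DataFrame, list[str]]:
    """Drop variables with too many missing values or a single observed level.

    Returns the retained table and the list of dropped column names.
    """
    dropped: list[str] = []
    keep: list[str] = []
    for col in clinical.columns:
        series = clinical[col]
        if series.isna().mean() > max_missing:
            dropped.append(col)
            logger.info("dropping %r: >%d%% missing", col, int(100 * max_missing))
        elif series.dropna().nunique() < 2:
            dropped.append(col)
            logger.info("dropping %r: fewer than 2 observed levels", col)
        else:
            keep.append(col)
    return clinical[keep], dropped


def association_battery(
    slide_profiles: pd.DataFrame,
    clinical_table: pd.DataFrame,
    alpha: float = 0.05,
    max_missing: float = 0.3,
    variable_types: Mapping[str, str] | None = None,
    equal_var: bool = False,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Test every retained clinical variable against every profile feature.

    ``slide_profiles`` is a slide x cell-type density table; ``clinical_table``
    is indexed by the same slide ids.  Binary variables get a two-sample
    t-test of the group means (Welch unless ``equal_var``); continuous ones a
    Pearson correlation.  Benjamini–Hochberg flags are computed over the full
    family of executed tests at FDR ``alpha``.

    Returns a tidy table with one row per (variable, cell type): group labels
    and sizes, group means (or r), the test statistic, the raw and
    BH-adjusted p-values, and the significance flag.  Variables or contrasts
    failing their preconditions are skipped with a logged reason.
    """
    profiles = slide_profiles[list(CELL_TYPES)]
    common = profiles.index.intersection(clinical_table.index)
    if len(common) < 4:
        raise ValueError("too few slides shared between profiles and clinical table")
    profiles = profiles.loc[common]
    clinical, _ = filter_variables(clinical_table.loc[common], max_missing=max_missing)
    types = dict(variable_types or infer_variable_types(clinical))

    rows: list[dict[str, object]] = []
    for var in clinical.columns:
        kind = types.get(var, "binary")
        col = clinical[var].dropna()
        if kind == "binary":
            levels = sorted(col.unique(), key=str)
            if len(levels) != 2:
                logger.info("skipping %r: %d observed levels", var, len(levels))
                continue
            idx0 = col.index[col == levels[0]]
            idx1 = col.index[col == levels[1]]
            if len(idx0) < min_group_size or len(idx1) < min_group_size:
                logger.info("skipping %r: a group has < %d slides", var, min_group_size)
                continue
            for cell_type in CELL_TYPES:
                res = two_sample_t_test(
                    profiles.loc[idx0, cell_type],
                    profiles.loc[idx1, cell_type],
                    equal_var=equal_var,
                )
                rows.append(
                    {
                        "variable": var,
                        "cell_type": cell_type,
                        "kind": "t-test",
                        "group0": str(levels[0]),
                        "group1": str(levels[1]),
                        "n0": len(idx0),
                        "n1": len(idx1),
                        "mean0": res.mean0,
                        "mean1": res.mean1,
                        "statistic": res.t,
                        "p_value": res.p,
                    }
                )
        else:
            x = pd.to_numeric(col, errors="coerce").dropna()
            if len(x) < 3:
                logger.info("skipping %r: < 3 numeric observations", var)
                continue
            for cell_type in CELL_TYPES:
                y = profiles.loc[x.index, cell_type]
                try:
                    r, p = pearson_correlation(x.to_numpy(), y.to_numpy())
                except ValueError as exc:
                    logger.info("skipping %r x %s: %s", var, cell_type, exc)
                    continue
                rows.append(
                    {
                        "variable": var,
                        "cell_type": cell_type,
                        "kind": "pearson",
                        "group0": "",
                        "group1": "",
                        "n0": len(x),
                        "n1": 0,
                        "mean0": np.nan,
                        "mean1": np.nan,
                        "statistic": r,
                        "p_value": p,
                    }
                )

    report = pd.DataFrame(rows)
    if report.empty:
        return report
    report = report.sort_values(["variable", "cell_type"], kind="stable").reset_index(
        drop=True
    )
    report["bh_p_value"] = bh_adjusted_pvalues(report["p_value"].to_numpy())
    report["significant"] = bh_adjust(report["p_value"].to_numpy(), alpha=alpha)
    return report
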