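"""Rank and contingency tests plus Benjamini-Hochberg FDR adjustment.

These power three analyses: the two-group scanner/voltage comparison of
feature values (Wilcoxon-Mann-Whitney), the baseline clinical table
(chi-square / Fisher exact for categoricals, Mann-Whitney for continuous
variables), and the pairwise reconstruction-setting sensitivity analysis
(Wilcoxon signed-rank on paired differences). All batches of p values are
adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

__all__ = [
    "TestOutcome",
    "mann_whitney",
    "signed_rank",
    "fdr_adjust",
    "pairwise_algorithm_counts",
    "baseline_comparison",
    "univariate_scanner_voltage",
]

logger = logging.getLogger(__name__)

# Exact-distribution bounds: below these (and without ties) the exact null
# distribution is enumerated; above, a tie-corrected normal approximation
# with continuity correction is used.
MANN_WHITNEY_EXACT_N = 20
SIGNED_RANK_EXACT_N = 25


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> TestOutcome:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null distribution when the combined sample size is small and there
    are no ties; otherwise normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size < 3:
        raise ValueError("combined sample too small")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= MANN_WHITNEY_EXACT_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestOutcome(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def signed_rank(paired_diff: Sequence[float]) -> TestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classic Wilcoxon
    convention). If every difference is zero, p = 1 with a degenerate flag.
    Exact distribution for small tie-free samples, otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    d = np.asarray(paired_diff, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestOutcome(0.0, 1.0, "degenerate", degenerate=True)
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= SIGNED_RANK_EXACT_N and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return TestOutcome(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------- #
def univariate_scanner_voltage(
    table: FeatureTable,
    settings: Sequence[str] = ("FBP", "IR60"),
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of features between scanners and between voltages.

    Each feature is compared at each representative setting, once splitting
    patients by scanner model and once by tube voltage. All p values in the
    batch are FDR-adjusted together.

    Returns a frame with columns
    ``feature, comparison, statistic, p_raw, p_fdr``.
    """
    if features is None:
        features = table.feature_names
    meta = table.metadata
    rows = []
    for grouping in ("scanner", "tube_voltage"):
        levels = sorted(meta[grouping].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"{grouping} must have exactly 2 levels, got {levels}")
        for setting in settings:
            for name in features:
                mat, pids = table.feature_matrix(name, [setting])
                vals = pd.Series(mat[:, 0], index=pids)
                lab = meta.loc[pids, grouping].astype(str)
                a = vals[lab == levels[0]].to_numpy()
                b = vals[lab == levels[1]].to_numpy()
                out = mann_whitney(a, b)
                rows.append(
                    {
                        "feature": name,
                        "comparison": f"{grouping}@{setting}",
                        "statistic": out.statistic,
                        "p_raw": out.p_value,
                    }
                )
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    return df


def pairwise_algorithm_counts(
    table: FeatureTable,
    alpha: float = 0.05,
    image_type: str | None = "original",
    exclude_shape: bool = True,
    settings: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Setting x setting counts of features differing by signed-rank test.

    For every unordered setting pair, each eligible feature's paired
    differences (complete-case patients) are tested with the Wilcoxon
    signed-rank test; all p values are FDR-adjusted jointly, and the entry is
    the number of features with adjusted p below ``alpha``. The matrix is
    symmetric with a zero diagonal (the heatmap analogue).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if settings is None:
        settings = table.design.setting_labels
    settings = list(settings)
    if len(settings) < 2:
        raise ValueError("need at least two settings")
    feats = [
        f
        for f in table.features
        if (image_type is None or f.image_type == image_type)
        and not (exclude_shape and f.category == "shape")
    ]
    records = []
    for s1, s2 in combinations(settings, 2):
        for f in feats:
            mat, _ = table.feature_matrix(f.name, [s1, s2])
            out = signed_rank(mat[:, 0] - mat[:, 1])
            records.append({"pair": (s1, s2), "feature": f.name, "p_raw": out.p_value})
    df = pd.DataFrame(records)
    df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    counts = pd.DataFrame(0, index=settings, columns=settings, dtype=int)
    for (s1, s2), sub in df.groupby("pair"):
        n_sig = int((sub["p_fdr"] < alpha).sum())
        counts.loc[s1, s2] = n_sig
        counts.loc[s2, s1] = n_sig
    return counts


# ---------------------------------------------------------------------- #
def _categorical_test(table2d: np.ndarray, seed: int = 0) -> tuple[float, str]:
    """Chi-square when all expected counts >= 5, else Fisher exact.

    For tables larger than 2x2 where an exact computation is not available,
    falls back to a seeded Monte-Carlo permutation p value.
    """
    table2d = np.asarray(table2d)
    expected = stats.contingency.expected_freq(table2d)
    if np.all(expected >= 5):
        chi2, p, _, _ = stats.chi2_contingency(table2d, correction=False)
        return float(p), "chi2"
    if table2d.shape == (2, 2):
        _, p = stats.fisher_exact(table2d)
        return float(p), "fisher"
    try:
        res = stats.fisher_exact(table2d)
        return float(res.pvalue), "fisher"
    except (ValueError, TypeError, NotImplementedError):
        rng = np.random.default_rng(seed)
        rt = stats.random_table(table2d.sum(axis=1), table2d.sum(axis=0), seed=rng)
        draws = rt.rvs(9999)
        logpmf_obs = rt.logpmf(table2d)
        p = (np.sum(rt.logpmf(draws) <= logpmf_obs + 1e-12) + 1) / (9999 + 1)
        return float(p), "fisher_mc"


def baseline_comparison(
    metadata: pd.DataFrame, grouping: str, seed: int = 0
) -> pd.DataFrame:
    """Baseline-characteristics table: per-variable two-group comparison.

    Continuous variables use the Mann-Whitney test; categoricals use
    chi-square when all expected cell counts are at least 5 and Fisher's
    exact test otherwise. Missing values are dropped per variable with the
    count reported.
    """
    levels = sorted(metadata[grouping].dropna().astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    rows = []
    for col in metadata.columns:
        if col == grouping:
            continue
        sub = metadata[[grouping, col]].dropna()
        n_missing = len(metadata) - len(sub)
        g = sub[grouping].astype(str)
        if pd.api.types.is_numeric_dtype(sub[col]):
            a = sub.loc[g == levels[0], col].to_numpy(dtype=float)
            b = sub.loc[g == levels[1], col].to_numpy(dtype=float)
            out = mann_whitney(a, b)
            p, test = out.p_value, "mann-whitney"
        else:
            ct = pd.crosstab(sub[col].astype(str), g).to_numpy()
            if ct.shape[0] < 2:
                p, test = 1.0, "degenerate"
            else:
                p, test = _categorical_test(ct, seed=seed)
        rows.append(
            {"variable": col, "test": test, "p_value": p, "n_missing": n_missing}
        )
    return pd.DataFrame(rows)
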