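"""Lin's concordance correlation coefficient and its multi-setting extension.

For two measurement vectors ``x`` and ``y`` the concordance correlation
coefficient (CCC) is

    ccc = 2 S_xy / (S_x^2 + S_y^2 + (mean_x - mean_y)^2)

with moment estimators using divisor ``n``. The overall concordance
correlation coefficient (OCCC) extends this to ``J >= 2`` settings:

    occc = 2 sum_{j<k} S_jk
           / [ (J-1) sum_j S_j^2 + sum_{j<k} (mean_j - mean_k)^2 ]

which equals a weighted mean of all pairwise CCCs with weights
``S_j^2 + S_k^2 + (mean_j - mean_k)^2``. OCCC is 1 only for identical
columns, is invariant under a common positive affine transform of the whole
matrix, and drops below an agreement threshold (0.85 by convention here)
when within-subject setting differences are large relative to the
between-subject spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .feature_table import FeatureTable

__all__ = ["ccc", "occc", "occc_per_feature", "ConcordanceResult", "OCCC_THRESHOLD"]

logger = logging.getLogger(__name__)

#: Conventional agreement threshold separating reproducible features.
OCCC_THRESHOLD = 0.85


def ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient between two vectors.

    Uses divisor-``n`` moment estimators. If both vectors are constant and
    equal (all three denominator terms zero) the value is 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("ccc needs two 1-d vectors of length >= 2")
    sx = x.var()  # divisor n
    sy = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    md2 = (x.mean() - y.mean()) ** 2
    denom = sx + sy + md2
    if denom == 0.0:
        logger.warning("ccc: both vectors constant and equal; returning 1 by convention")
        return 1.0
    return float(2.0 * sxy / denom)


def occc(matrix: np.ndarray) -> float:
    """Overall concordance correlation coefficient across matrix columns.

    Parameters
    ----------
    matrix
        Subjects x settings array, no missing entries, ``n >= 2``, ``J >= 2``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("occc needs an (n>=2) x (J>=2) matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("occc input contains non-finite entries")
    J = m.shape[1]
    means = m.mean(axis=0)
    centred = m - means
    cov = centred.T @ centred / m.shape[0]  # divisor n
    variances = np.diag(cov)
    iu = np.triu_indices(J, k=1)
    sum_cov = cov[iu].sum()
    sum_md2 = ((means[:, None] - means[None, :]) ** 2)[iu].sum()
    denom = (J - 1) * variances.sum() + sum_md2
    if denom == 0.0:
        logger.warning("occc: all columns constant and equal; returning 1 by convention")
        return 1.0
    return float(2.0 * sum_cov / denom)


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-feature overall concordance over a chosen setting subset."""

    feature_name: str
    settings_used: tuple[str, ...]
    n_subjects: int
    occc: float
    pairwise_ccc: dict[frozenset, float]


def occc_per_feature(
    table: FeatureTable,
    settings: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
    pairwise: bool = False,
) -> list[ConcordanceResult]:
    """OCCC for each feature over the requested setting subset.

    Uses complete-case patients per feature. Features whose matrix cannot be
    formed are recorded with ``occc = nan`` rather than aborting the batch.
    """
    if settings is None:
        settings = table.design.setting_labels
    settings = list(settings)
    if len(settings) < 2:
        raise ValueError("need at least two settings for concordance")
    if features is None:
        features = table.feature_names
    results: list[ConcordanceResult] = []
    for name in features:
        try:
            mat, pids = table.feature_matrix(name, settings)
            value = occc(mat)
            pw: dict[frozenset, float] = {}
            if pairwise:
                for j, k in combinations(range(len(settings)), 2):
                    pw[frozenset((settings[j], settings[k]))] = ccc(mat[:, j], mat[:, k])
            results.append(
                ConcordanceResult(name, tuple(settings), len(pids), value, pw)
            )
        except (ValueError, KeyError) as exc:
            logger.warning("occc failed for feature %s: %s", name, exc)
            results.append(
                ConcordanceResult(name, tuple(settings), 0, float("nan"), {})
            )
    return results
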