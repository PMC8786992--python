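"""Feature redundancy clustering with a guaranteed intra-cluster correlation.

Features are clustered on the distance ``1 - |rho|`` (absolute Spearman rank
correlation) with complete-linkage agglomeration, cutting the tree at
``1 - threshold``. Complete linkage bounds the *maximum* pairwise distance
inside every cluster, so the construction provably enforces the stated
criterion: every feature pair within a cluster satisfies
``|rho| >= threshold``. The invariant is re-audited on every output rather
than assumed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .feature_table import FeatureTable

__all__ = ["spearman_matrix", "cluster_features", "SPEARMAN_THRESHOLD"]

logger = logging.getLogger(__name__)

#: Default minimum intra-cluster absolute Spearman correlation.
SPEARMAN_THRESHOLD = 0.75


def spearman_matrix(
    table: FeatureTable,
    setting: str | None = None,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlations between features at one setting.

    Ties receive average ranks. Constant features have undefined
    correlations and are excluded with a warning. Feature order in the
    output is lexicographic for determinism.
    """
    if setting is None:
        setting = table.design.reference_label
    if features is None:
        features = table.feature_names
    features = sorted(features)
    if len(features) < 2:
        raise ValueError("need at least two features")
    cols, names = [], []
    for name in features:
        mat, pids = table.feature_matrix(name, [setting])
        v = mat[:, 0]
        if np.ptp(v) == 0.0:
            logger.warning("feature %s constant at %s; excluded from clustering", name, setting)
            continue
        cols.append(pd.Series(v, index=pids, name=name))
        names.append(name)
    if len(names) < 2:
        raise ValueError("fewer than two non-constant features")
    wide = pd.concat(cols, axis=1).dropna(axis=0, how="any")
    if len(wide) < 3:
        raise ValueError("need at least three complete-case patients")
    stat = stats.spearmanr(wide.to_numpy()).statistic
    if np.isscalar(stat) or np.ndim(stat) == 0:  # exactly two features
        r = float(stat)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stat)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=names, columns=names)


def cluster_features(matrix: pd.DataFrame, threshold: float = SPEARMAN_THRESHOLD) -> pd.DataFrame:
    """Complete-linkage clusters with min intra-cluster ``|rho| >= threshold``.

    Parameters
    ----------
    matrix
        Symmetric Spearman correlation frame (features as index/columns).
    threshold
        Minimum absolute correlation required between every pair of features
        sharing a cluster, in (0, 1].

    Returns
    -------
    pandas.DataFrame
        Columns ``feature, cluster_id, representative``; cluster ids are
        numbered by first appearance in lexicographic feature order, and the
        representative is the member with the highest median ``|rho|`` to
        its cluster (ties broken by name).
    """
    if matrix.empty:
        raise ValueError("empty correlation matrix")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    names = sorted(matrix.index)
    m = matrix.loc[names, names].to_numpy(dtype=float)
    absrho = np.clip(np.abs(m), 0.0, 1.0)
    dist = 1.0 - absrho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    if len(names) == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        labels = hierarchy.fcluster(link, t=1.0 - threshold + 1e-12, criterion="distance")
    # renumber clusters by first appearance
    seen: dict[int, int] = {}
    ids = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        ids.append(seen[lab])
    ids = np.asarray(ids)

    # audit the invariant on the actual output
    for cid in np.unique(ids):
        members = np.flatnonzero(ids == cid)
        if members.size > 1:
            sub = absrho[np.ix_(members, members)]
            min_rho = sub[np.triu_indices(members.size, k=1)].min()
            if min_rho < threshold - 1e-9:
                raise AssertionError(
                    f"cluster {cid} violates min |rho| >= {threshold}: {min_rho}"
                )

    representative = np.zeros(len(names), dtype=bool)
    for cid in np.unique(ids):
        members = np.flatnonzero(ids == cid)
        if members.size == 1:
            representative[members[0]] = True
            continue
        med = [np.median(absrho[i, members]) for i in members]
        best = members[int(np.argmax(med))]  # argmax is first max -> name order
        representative[best] = True

    return pd.DataFrame(
        {"feature": names, "cluster_id": ids, "representative": representative}
    )
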