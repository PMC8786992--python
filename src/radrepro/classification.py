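"""Four-group reproducibility classification of features.

Each feature is cross-classified by its overall concordance (OCCC against a
threshold, 0.85 by default) and its FDR-adjusted mixed-model p value for the
setting contrast (against alpha, 0.05 by default):

* group 1 — OCCC >= threshold and p < alpha: small but systematic setting
  dependence; correctable.
* group 2 — OCCC >= threshold and p >= alpha: small, non-systematic
  variation; reproducible as-is.
* group 3 — OCCC < threshold and p < alpha: large systematic trend;
  recoverable after correction.
* group 4 — OCCC < threshold and p >= alpha: large random variation; not
  correctable.

Boundary convention mirrors the definitions literally: OCCC exactly at the
threshold takes the ">=" branch, p exactly at alpha the ">=" (non-significant)
branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import ConcordanceResult
from .design import FeatureDescriptor

__all__ = ["GroupAssignment", "classify", "classify_features", "group_counts", "scatter_export"]

logger = logging.getLogger(__name__)


def _quadrant(occc_value: float, p: float, occc_threshold: float, alpha: float) -> int:
    high_concordance = occc_value >= occc_threshold
    significant = p < alpha
    if high_concordance:
        return 1 if significant else 2
    return 3 if significant else 4


@dataclass(frozen=True)
class GroupAssignment:
    """Per-feature reproducibility group, per setting contrast and overall."""

    feature_name: str
    per_contrast_group: Mapping[str, int]
    overall_group: int
    occc: float
    min_p_fdr: float
    occc_threshold: float = 0.85
    alpha: float = 0.05


def classify(
    concordance: ConcordanceResult,
    contrast_p_fdr: Mapping[str, float],
    occc_threshold: float = 0.85,
    alpha: float = 0.05,
) -> GroupAssignment:
    """Assign a feature its group per contrast and overall.

    ``contrast_p_fdr`` maps each non-reference setting to the FDR-adjusted
    mixed-model p value of its contrast. The overall group uses the minimum
    p over available contrasts, so a feature is overall non-significant only
    if it is non-significant at every contrast. Missing p values are treated
    as absent contrasts (flagged), not as non-significance.
    """
    if not (0 < occc_threshold <= 1 and 0 < alpha <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    clean = {k: float(v) for k, v in contrast_p_fdr.items() if np.isfinite(v)}
    dropped = sorted(set(contrast_p_fdr) - set(clean))
    if dropped:
        logger.warning(
            "feature %s: missing p for contrast(s) %s; omitted",
            concordance.feature_name,
            dropped,
        )
    if not clean:
        raise ValueError(
            f"feature {concordance.feature_name}: no usable contrast p values"
        )
    per_contrast = {
        c: _quadrant(concordance.occc, p, occc_threshold, alpha)
        for c, p in clean.items()
    }
    min_p = min(clean.values())
    overall = _quadrant(concordance.occc, min_p, occc_threshold, alpha)
    return GroupAssignment(
        feature_name=concordance.feature_name,
        per_contrast_group=per_contrast,
        overall_group=overall,
        occc=concordance.occc,
        min_p_fdr=min_p,
        occc_threshold=occc_threshold,
        alpha=alpha,
    )


def classify_features(
    concordance_results: Sequence[ConcordanceResult],
    mixed_terms: pd.DataFrame,
    occc_threshold: float = 0.85,
    alpha: float = 0.05,
) -> list[GroupAssignment]:
    """Classify every feature from its concordance result and mixed-model table.

    ``mixed_terms`` is the long per-term frame from
    :func:`radrepro.mixed_model.batch_mixed_models` (``p_fdr`` column for
    ``setting[...]`` terms). Features lacking either ingredient are skipped
    with a warning.
    """
    setting_rows = mixed_terms[mixed_terms["term"].str.startswith("setting[")]
    p_by_feature: dict[str, dict[str, float]] = {}
    for _, row in setting_rows.iterrows():
        contrast = row["term"][len("setting[") : -1]
        p_by_feature.setdefault(row["feature"], {})[contrast] = row["p_fdr"]
    out = []
    for cres in concordance_results:
        pmap = p_by_feature.get(cres.feature_name)
        if pmap is None or not np.isfinite(cres.occc):
            logger.warning("feature %s skipped in classification", cres.feature_name)
            continue
        out.append(classify(cres, pmap, occc_threshold, alpha))
    return out


def group_counts(
    assignments: Sequence[GroupAssignment],
    features: Sequence[FeatureDescriptor],
    contrasts: Sequence[str] | None = None,
    exclude_shape_from_original: bool = True,
) -> pd.DataFrame:
    """Percentage of features in each group, per image type and contrast.

    Shape features are excluded from the original-image denominators (their
    values are identical across reconstructions of a shared segmentation, so
    they would trivially inflate group 2). Percentages per row sum to 100.
    """
    if not assignments:
        raise ValueError("no assignments given")
    desc = {f.name: f for f in features}
    if contrasts is None:
        contrasts = sorted({c for a in assignments for c in a.per_contrast_group})
    rows = []
    image_types = sorted({desc[a.feature_name].image_type for a in assignments if a.feature_name in desc})
    for image_type in image_types:
        pool = [
            a
            for a in assignments
            if a.feature_name in desc
            and desc[a.feature_name].image_type == image_type
            and not (
                exclude_shape_from_original
                and image_type == "original"
                and desc[a.feature_name].category == "shape"
            )
        ]
        for contrast in contrasts:
            sub = [a for a in pool if contrast in a.per_contrast_group]
            if not sub:
                continue
            counts = np.bincount(
                [a.per_contrast_group[contrast] for a in sub], minlength=5
            )[1:5]
            pct = 100.0 * counts / len(sub)
            rows.append(
                {
                    "image_type": image_type,
                    "contrast": contrast,
                    "n_features": len(sub),
                    **{f"group{g}_pct": pct[g - 1] for g in (1, 2, 3, 4)},
                }
            )
    return pd.DataFrame(rows)


def scatter_export(
    assignments: Sequence[GroupAssignment],
    contrast: str,
    features: Sequence[FeatureDescriptor] | None = None,
    mixed_terms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature (occc, p_fdr) records for one contrast (scatter analogue).

    Marker follows the published convention: triangles for first-order
    features, circles for texture features.
    """
    desc = {f.name: f for f in features} if features else {}
    p_lookup: dict[str, float] = {}
    if mixed_terms is not None:
        term = f"setting[{contrast}]"
        sub = mixed_terms[mixed_terms["term"] == term]
        p_lookup = dict(zip(sub["feature"], sub["p_fdr"]))
    rows = []
    for a in assignments:
        if contrast not in a.per_contrast_group:
            continue
        d = desc.get(a.feature_name)
        rows.append(
            {
                "feature": a.feature_name,
                "occc": a.occc,
                "p_fdr": p_lookup.get(a.feature_name, a.min_p_fdr),
                "group": a.per_contrast_group[contrast],
                "category": d.category if d else "",
                "marker": ("triangle" if d and d.category == "firstorder" else "circle"),
            }
        )
    if not rows:
        raise ValueError(f"no assignments carry contrast {contrast!r}")
    return pd.DataFrame(rows)
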