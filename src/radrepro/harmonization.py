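"""Coefficient-based harmonization of setting-dependent features.

Features with a systematic reconstruction-setting trend (groups 1 and 3 of
the four-group classification) can be corrected by subtracting, from every
observation at a non-reference setting, the fitted mixed-model coefficient
of that setting. Under the additive fixed-effect model this removes the
common trend exactly on balanced data: a refit on the corrected table yields
setting coefficients of zero, and reference-setting values are untouched
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .feature_table import FeatureTable
from .mixed_model import FeatureMixedModelResults

__all__ = ["HarmonizedTable", "harmonize", "before_after_report"]

logger = logging.getLogger(__name__)


@dataclass
class HarmonizedTable:
    """Corrected feature table plus the coefficients that were applied."""

    table: FeatureTable
    reference_setting: str
    applied_coefficients: pd.DataFrame  # columns: feature, setting, coefficient


def harmonize(
    table: FeatureTable,
    fits: Sequence[FeatureMixedModelResults],
    features: Sequence[str] | None = None,
) -> HarmonizedTable:
    """Subtract each feature's fitted setting coefficients from its values.

    Only features in ``features`` (default: all fitted features) are
    corrected; non-converged fits or fits missing a present setting term are
    skipped with a warning. Values at the reference setting and at features
    outside the selection pass through unchanged.
    """
    fit_by_name = {f.feature_name: f for f in fits}
    if features is None:
        features = list(fit_by_name)
    reference = table.design.reference_label
    non_ref = set(table.design.non_reference)

    coeff_rows = []
    corrections: dict[tuple[str, str], float] = {}
    for name in features:
        fit = fit_by_name.get(name)
        if fit is None:
            logger.warning("harmonize: no fit for feature %s; skipped", name)
            continue
        if not fit.converged:
            logger.warning("harmonize: fit for %s not converged; skipped", name)
            continue
        coefs = fit.setting_coefficients()
        present = set(table.values.loc[table.values["feature"] == name, "setting"])
        missing = sorted((present & non_ref) - set(coefs))
        if missing:
            logger.warning(
                "harmonize: %s lacks coefficients for %s; skipped", name, missing
            )
            continue
        for setting, coef in coefs.items():
            corrections[(name, setting)] = coef
            coeff_rows.append(
                {"feature": name, "setting": setting, "coefficient": coef}
            )
        coeff_rows.append({"feature": name, "setting": reference, "coefficient": 0.0})

    values = table.values.copy()
    if corrections:
        keys = list(zip(values["feature"], values["setting"]))
        shift = [corrections.get(k, 0.0) for k in keys]
        # subtracting an exact 0.0 would still be bit-exact, but avoid touching
        # untargeted rows at all
        mask = [k in corrections for k in keys]
        values.loc[mask, "value"] = values.loc[mask, "value"] - pd.Series(
            shift, index=values.index
        )[mask]
    harmonized = table.with_values(values)
    return HarmonizedTable(
        table=harmonized,
        reference_setting=reference,
        applied_coefficients=pd.DataFrame(
            coeff_rows, columns=["feature", "setting", "coefficient"]
        ),
    )


def before_after_report(
    original: FeatureTable, harmonized: HarmonizedTable, feature: str
) -> pd.DataFrame:
    """Per-setting distribution summaries before and after correction.

    Returns min, q1, median, mean, q3 and max per setting and phase — the
    tabular analogue of a before/after box plot.
    """
    if feature not in original.feature_names:
        raise ValueError(f"feature {feature!r} not in table")
    rows = []
    for phase, tab in (("before", original), ("after", harmonized.table)):
        sub = tab.values[tab.values["feature"] == feature]
        for setting, grp in sub.groupby("setting"):
            v = grp["value"].astype(float)
            rows.append(
                {
                    "phase": phase,
                    "setting": setting,
                    "min": v.min(),
                    "q1": v.quantile(0.25),
                    "median": v.median(),
                    "mean": v.mean(),
                    "q3": v.quantile(0.75),
                    "max": v.max(),
                }
            )
    return pd.DataFrame(rows)
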