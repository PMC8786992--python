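"""Study-level model: the full reproducibility analysis as Model/Results.

:class:`ReproducibilityStudy` is constructed from a :class:`FeatureTable`
(or CSVs, or a synthetic preset) and analysis thresholds; :meth:`fit` runs
the concordance analysis and per-feature mixed models, applies the FDR
correction, cross-classifies every feature into the four reproducibility
groups, and returns a :class:`ReproducibilityResults` object carrying the
tables. Harmonization, redundancy clustering, the univariate scanner/voltage
analysis and report export hang off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classification import (
    GroupAssignment,
    classify_features,
    group_counts,
    scatter_export,
)
from .concordance import OCCC_THRESHOLD, ConcordanceResult, occc_per_feature
from .design import ReconstructionDesign
from .feature_table import FeatureTable, read_feature_table, write_feature_table
from .group_tests import (
    baseline_comparison,
    pairwise_algorithm_counts,
    univariate_scanner_voltage,
)
from .harmonization import HarmonizedTable, before_after_report, harmonize
from .mixed_model import MixedModelSpec, batch_mixed_models
from .redundancy import SPEARMAN_THRESHOLD, cluster_features, spearman_matrix
from .simulate import get_preset, simulate

__all__ = ["RunConfig", "ReproducibilityStudy", "ReproducibilityResults", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    preset: str | None = "paper_shaped"
    values_path: str | None = None
    metadata_path: str | None = None
    settings: tuple[str, ...] | None = None  # None = full design
    reference: str | None = None
    restricted_settings: tuple[str, ...] = ("IR40", "IR50", "IR60", "IR80")
    restricted_reference: str = "IR40"
    occc_threshold: float = OCCC_THRESHOLD
    alpha: float = 0.05
    spearman_threshold: float = SPEARMAN_THRESHOLD
    univariate_settings: tuple[str, str] = ("FBP", "IR60")
    seed: int = 0
    outdir: str = "radrepro_out"

    def validate(self, design: ReconstructionDesign) -> None:
        for thr, lo, hi, name in (
            (self.occc_threshold, 0, 1, "occc_threshold"),
            (self.alpha, 0, 1, "alpha"),
            (self.spearman_threshold, 0, 1, "spearman_threshold"),
        ):
            if not lo < thr <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")
        if self.settings is not None:
            unknown = [s for s in self.settings if s not in design.setting_labels]
            if unknown:
                raise ValueError(f"settings {unknown} not in design")
            ref = self.reference or design.reference_label
            if ref not in self.settings:
                raise ValueError(f"reference {ref!r} not in requested subset")


class ReproducibilityStudy:
    """The reproducibility analysis model for one feature table.

    Parameters
    ----------
    table
        Validated feature table.
    occc_threshold, alpha
        Classification thresholds for concordance and FDR-adjusted
        mixed-model significance.
    settings, reference
        Optional setting subset and reference override (the design is
        restricted accordingly before analysis).
    """

    def __init__(
        self,
        table: FeatureTable,
        occc_threshold: float = OCCC_THRESHOLD,
        alpha: float = 0.05,
        settings: Sequence[str] | None = None,
        reference: str | None = None,
    ) -> None:
        if settings is not None or reference is not None:
            design = table.design.subset(
                settings or table.design.setting_labels, reference
            )
            table = FeatureTable(
                design=design,
                values=table.values[table.values["setting"].isin(design.setting_labels)]
                .reset_index(drop=True),
                metadata=table.metadata,
                features=list(table.features),
            )
        self.table = table
        self.occc_threshold = float(occc_threshold)
        self.alpha = float(alpha)

    @classmethod
    def from_csv(
        cls,
        values_path: str | Path,
        metadata_path: str | Path,
        design: ReconstructionDesign,
        **kwargs,
    ) -> "ReproducibilityStudy":
        return cls(read_feature_table(values_path, metadata_path, design), **kwargs)

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, **kwargs) -> "ReproducibilityStudy":
        table, _ = simulate(get_preset(name, seed=seed))
        return cls(table, **kwargs)

    def fit(self, spec: MixedModelSpec | None = None) -> "ReproducibilityResults":
        spec = spec or MixedModelSpec()
        conc = occc_per_feature(self.table)
        fits, terms = batch_mixed_models(self.table, spec)
        assignments = classify_features(
            conc, terms, occc_threshold=self.occc_threshold, alpha=self.alpha
        )
        return ReproducibilityResults(
            study=self,
            concordance=conc,
            mixed_fits=fits,
            mixed_terms=terms,
            assignments=assignments,
        )


@dataclass
class ReproducibilityResults:
    """Fitted study: concordance, mixed-model terms and group assignments."""

    study: ReproducibilityStudy
    concordance: list[ConcordanceResult]
    mixed_fits: list
    mixed_terms: pd.DataFrame
    assignments: list[GroupAssignment]
    _cache: dict = field(default_factory=dict, repr=False)

    # -- tabular views -------------------------------------------------- #
    def concordance_frame(self) -> pd.DataFrame:
        table = self.study.table
        rows = []
        for c in self.concordance:
            d = table.descriptor(c.feature_name)
            rows.append(
                {
                    "feature": c.feature_name,
                    "image_type": d.image_type,
                    "image_subtype": d.image_subtype,
                    "category": d.category,
                    "n_subjects": c.n_subjects,
                    "occc": c.occc,
                    "occc_lt_threshold": c.occc < self.study.occc_threshold,
                }
            )
        return pd.DataFrame(rows).sort_values("feature").reset_index(drop=True)

    def occc_medians(self) -> pd.DataFrame:
        """Median OCCC per image type and feature category."""
        df = self.concordance_frame()
        return (
            df.groupby(["image_type", "category"], as_index=False)["occc"]
            .median()
            .rename(columns={"occc": "median_occc"})
        )

    def assignments_frame(self) -> pd.DataFrame:
        contrasts = list(self.study.table.design.non_reference)
        rows = []
        for a in sorted(self.assignments, key=lambda x: x.feature_name):
            row = {
                "feature": a.feature_name,
                "occc": a.occc,
                "min_p_fdr": a.min_p_fdr,
                "overall_group": a.overall_group,
            }
            for c in contrasts:
                row[f"group[{c}]"] = a.per_contrast_group.get(c, pd.NA)
            rows.append(row)
        return pd.DataFrame(rows)

    def group_percentages(self, contrasts: Sequence[str] | None = None) -> pd.DataFrame:
        return group_counts(self.assignments, self.study.table.features, contrasts)

    def scatter_data(self, contrast: str) -> pd.DataFrame:
        return scatter_export(
            self.assignments, contrast, self.study.table.features, self.mixed_terms
        )

    # -- downstream analyses -------------------------------------------- #
    def harmonize(self, features: Sequence[str] | None = None) -> HarmonizedTable:
        """Correct the systematic setting trend for the selected features.

        Default selection: features whose overall group is 1 or 3 (the
        regimes with a correctable common trend).
        """
        if features is None:
            features = [
                a.feature_name for a in self.assignments if a.overall_group in (1, 3)
            ]
        return harmonize(self.study.table, self.mixed_fits, features)

    def cluster(
        self,
        threshold: float | None = None,
        setting: str | None = None,
        features: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Redundancy clusters of original-image features at the reference setting."""
        if features is None:
            features = [
                f.name for f in self.study.table.features if f.image_type == "original"
            ]
        mat = spearman_matrix(self.study.table, setting=setting, features=features)
        return cluster_features(
            mat, threshold if threshold is not None else SPEARMAN_THRESHOLD
        )

    def univariate(self, settings: Sequence[str] = ("FBP", "IR60")) -> pd.DataFrame:
        return univariate_scanner_voltage(self.study.table, settings=settings)

    def pairwise_counts(self, alpha: float | None = None) -> pd.DataFrame:
        return pairwise_algorithm_counts(
            self.study.table, alpha=alpha if alpha is not None else self.study.alpha
        )

    def baseline(self, grouping: str) -> pd.DataFrame:
        return baseline_comparison(self.study.table.metadata, grouping)

    # -- summary --------------------------------------------------------- #
    def summary(self) -> str:
        table = self.study.table
        cf = self.concordance_frame()
        n_low = int(cf["occc_lt_threshold"].sum())
        groups = pd.Series([a.overall_group for a in self.assignments])
        pct = groups.value_counts(normalize=True).sort_index() * 100
        lines = [
            "Radiomic feature reproducibility study",
            "=" * 46,
            f"patients:       {len(table.metadata)}",
            f"settings:       {', '.join(table.design.setting_labels)} "
            f"(reference {table.design.reference_label})",
            f"features:       {len(table.features)}",
            f"OCCC < {self.study.occc_threshold:.2f}:    {n_low}/{len(cf)} features",
            "overall groups: "
            + "  ".join(f"G{g}: {pct.get(g, 0.0):.1f}%" for g in (1, 2, 3, 4)),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle to ``config.outdir``.

    Produces the concordance table and per-category medians (main and
    restricted-subset analyses), the mixed-model term table, group
    assignments and percentages, scatter exports for the extreme contrasts,
    the pairwise signed-rank count matrix, the harmonized table with its
    coefficients and a before/after report, the redundancy cluster table,
    baseline tables by scanner and voltage, and a machine-readable manifest.

    Returns the mapping from artifact name to written path. Reruns with an
    identical config are bit-identical.
    """
    # --- input ---------------------------------------------------------
    if config.values_path and config.metadata_path:
        from .design import DEFAULT_DESIGN

        table = read_feature_table(config.values_path, config.metadata_path, DEFAULT_DESIGN)
        truth = None
    elif config.preset:
        cfg = get_preset(config.preset, seed=config.seed)
        table, truth = simulate(cfg)
    else:
        raise ValueError("config needs either a preset or values+metadata paths")
    config.validate(table.design)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    study = ReproducibilityStudy(
        table,
        occc_threshold=config.occc_threshold,
        alpha=config.alpha,
        settings=config.settings,
        reference=config.reference,
    )
    res = study.fit()

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        _write_csv(df, path)
        paths[name] = path

    emit("concordance", res.concordance_frame())

    # restricted-subset rerun (parenthetical medians)
    medians = res.occc_medians().rename(columns={"median_occc": "median_occc_main"})
    try:
        restricted = ReproducibilityStudy(
            table,
            occc_threshold=config.occc_threshold,
            alpha=config.alpha,
            settings=config.restricted_settings,
            reference=config.restricted_reference,
        ).fit()
        med_r = restricted.occc_medians().rename(
            columns={"median_occc": "median_occc_restricted"}
        )
        medians = medians.merge(med_r, on=["image_type", "category"], how="left")
        emit("group_percentages_restricted", restricted.group_percentages())
    except ValueError:
        restricted = None
    emit("occc_medians", medians)

    emit("mixed_model_terms", res.mixed_terms.sort_values(["feature", "term"]).reset_index(drop=True))
    emit("group_assignments", res.assignments_frame())
    emit("group_percentages", res.group_percentages())

    design = res.study.table.design
    extremes = [design.non_reference[0], design.non_reference[-1]]
    scatter_frames = []
    for contrast in extremes:
        sf = res.scatter_data(contrast)
        sf.insert(0, "contrast", contrast)
        scatter_frames.append(sf)
    emit("scatter", pd.concat(scatter_frames, ignore_index=True))

    counts = res.pairwise_counts()
    emit("pairwise_counts", counts.reset_index(names="setting"))

    uni_settings = [
        s for s in config.univariate_settings if s in design.setting_labels
    ] or list(design.setting_labels[:2])
    emit("univariate_scanner_voltage", res.univariate(settings=uni_settings))

    harm = res.harmonize()
    hv = harm.table.values.sort_values(["feature", "patient_id", "setting"]).reset_index(drop=True)
    emit("harmonized_values", hv)
    emit(
        "harmonization_coefficients",
        harm.applied_coefficients.sort_values(["feature", "setting"]).reset_index(drop=True),
    )
    if not harm.applied_coefficients.empty:
        example = sorted(harm.applied_coefficients["feature"].unique())[0]
        emit("harmonization_before_after", before_after_report(res.study.table, harm, example))

    try:
        emit("clusters", res.cluster(threshold=config.spearman_threshold))
    except ValueError:
        pass

    for grouping in ("scanner", "tube_voltage"):
        emit(f"baseline_{grouping}", res.baseline(grouping))

    if truth is not None:
        emit("synthetic_truth", truth.table)

    manifest = {
        "package": "radrepro",
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "occc_threshold": config.occc_threshold,
        "alpha": config.alpha,
        "spearman_threshold": config.spearman_threshold,
        "design": {
            "settings": list(design.setting_labels),
            "reference": design.reference_label,
            "blending_percent": design.blending_percent,
        },
        "n_patients": len(table.metadata),
        "n_features": len(table.features),
        "artifacts": sorted(paths),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath

    # persist the analysed input for provenance
    write_feature_table(table, outdir / "values.csv", outdir / "metadata.csv")
    paths["values"] = outdir / "values.csv"
    paths["metadata"] = outdir / "metadata.csv"
    return paths
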