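"""Synthetic feature-table generator with planted ground truth.

The generator mirrors the generative counterpart of the analysis model. For
patient *i*, setting *j* and feature *f*:

    value = intercept_f + b_{i,f} + beta_f(j) + scanner/voltage/volume terms
            + u_{i,j,f} + eps_{i,j,f}

with ``b ~ N(0, subject_sd^2)`` (between-patient spread),
``u ~ N(0, interaction_sd^2)`` an i.i.d. subject-by-setting interaction
(patient-specific, direction-free setting response), and
``eps ~ N(0, residual_sd^2)`` measurement noise. Setting effects ``beta``
are proportional to the iterative blending percent by default (linear
trend, random sign per feature), matching the commonly observed monotone
response of texture features to reconstruction strength.

The four planted reproducibility regimes are operationalised as:

* group 1 — nonzero trend, small against the between-patient spread
  (``max |beta| = 0.3 subject_sd``): high concordance, significant trend.
* group 2 — no trend, small noise: high concordance, non-significant.
* group 3 — large trend (``max |beta| = 3 subject_sd``): low concordance,
  significant trend.
* group 4 — no common trend but large subject-by-setting interaction
  (``interaction_sd = 1.5 subject_sd``): low concordance without
  systematic shift.

These constants were calibrated once so that the planted regimes are
recovered by the full pipeline at the study scale (103 patients, 6
settings) and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DEFAULT_DESIGN, FeatureDescriptor, ReconstructionDesign
from .feature_table import FeatureTable

__all__ = [
    "GroupParams",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate",
    "preset_catalog",
    "get_preset",
]

#: Frozen per-group generative constants (units of subject_sd).
GROUP_DEFAULTS = {
    1: {"beta_max": 0.3, "residual_sd": 0.1, "interaction_sd": 0.0},
    2: {"beta_max": 0.0, "residual_sd": 0.1, "interaction_sd": 0.0},
    3: {"beta_max": 3.0, "residual_sd": 0.3, "interaction_sd": 0.0},
    4: {"beta_max": 0.0, "residual_sd": 0.1, "interaction_sd": 1.5},
}

_IMAGE_TEMPLATES = (
    ("original", "", "firstorder"),
    ("original", "", "glcm"),
    ("original", "", "glrlm"),
    ("wavelet-LH", "LH", "firstorder"),
    ("wavelet-HH", "HH", "glszm"),
    ("wavelet-LL", "LL", "gldm"),
    ("log-sigma-1-0-mm", "1.0 mm", "firstorder"),
    ("log-sigma-2-5-mm", "2.5 mm", "ngtdm"),
)


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one planted reproducibility group."""

    planted_group: int
    beta_max: float
    residual_sd: float
    interaction_sd: float
    subject_sd: float = 1.0
    scanner_effect: float = 0.0
    voltage_effect: float = 0.0
    volume_slope: float = 0.0

    def validate(self) -> None:
        if self.planted_group not in (1, 2, 3, 4):
            raise ValueError("planted_group must be 1..4")
        if self.subject_sd <= 0 or self.residual_sd < 0 or self.interaction_sd < 0:
            raise ValueError("SDs must be nonnegative (subject_sd positive)")
        if self.planted_group in (2, 4) and self.beta_max != 0.0:
            raise ValueError("groups 2 and 4 are defined by a zero common trend")
        if self.planted_group == 2 and (
            self.residual_sd > 0.5 * self.subject_sd
            or self.interaction_sd > 0.5 * self.subject_sd
        ):
            raise ValueError(
                "group 2 requires small noise relative to the between-patient spread"
            )
        if self.planted_group == 4 and self.interaction_sd < self.subject_sd:
            raise ValueError("group 4 requires a large subject-by-setting interaction")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation configuration.

    Defaults emulate the clinical cohort structure: 103 patients split
    roughly 50/50 over two scanner models and two tube voltages, six
    reconstruction settings per patient, and tumour volumes log-normal and
    bounded to [5, 200] cm^3 (the study's inclusion window).
    """

    n_patients: int = 103
    design: ReconstructionDesign = DEFAULT_DESIGN
    n_features_per_group: Mapping[int, int] = field(
        default_factory=lambda: {1: 10, 2: 10, 3: 10, 4: 10}
    )
    n_shape_features: int = 0
    group_params: Mapping[int, GroupParams] | None = None
    scanner_split: float = 0.5
    voltage_split: float = 0.5
    volume_log_mean: float = 3.55  # median ~ 35 cm^3
    volume_log_sd: float = 0.75
    volume_bounds: tuple[float, float] = (5.0, 200.0)
    seed: int = 0

    def resolved_group_params(self) -> dict[int, GroupParams]:
        out = {}
        for g in (1, 2, 3, 4):
            if self.group_params and g in self.group_params:
                gp = self.group_params[g]
            else:
                gp = GroupParams(planted_group=g, **GROUP_DEFAULTS[g])
            gp.validate()
            out[g] = gp
        return out

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need at least 4 patients")
        if not 0 < self.scanner_split < 1 or not 0 < self.voltage_split < 1:
            raise ValueError("splits must lie in (0, 1)")
        lo, hi = self.volume_bounds
        if not (0 < lo < hi):
            raise ValueError("volume bounds must satisfy 0 < lo < hi")
        for g, n in self.n_features_per_group.items():
            if g not in (1, 2, 3, 4) or n < 0:
                raise ValueError("n_features_per_group keys must be 1..4, counts >= 0")
        self.resolved_group_params()


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters per simulated feature."""

    table: pd.DataFrame  # one row per feature

    def group_of(self, feature: str) -> int:
        row = self.table.loc[self.table["feature"] == feature]
        if row.empty:
            raise KeyError(feature)
        return int(row["planted_group"].iloc[0])

    @property
    def planted_groups(self) -> pd.Series:
        return self.table.set_index("feature")["planted_group"]


def _draw_volumes(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    lo, hi = cfg.volume_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(cfg.volume_log_mean, cfg.volume_log_sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate(config: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate a complete feature table plus its ground truth.

    Reproducible: the same config (including seed) yields a bit-identical
    table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = config.design
    settings = list(design.setting_labels)
    blend = np.array([design.blending_percent[s] for s in settings], dtype=float)
    ref_blend = design.blending_percent[design.reference_label]
    max_gap = np.max(np.abs(blend - ref_blend)) or 1.0
    n_pat = config.n_patients
    n_set = len(settings)

    # --- patients -----------------------------------------------------
    pids = [f"P{i + 1:03d}" for i in range(n_pat)]
    n_a = int(round(n_pat * config.scanner_split))
    scanner = np.array(["scannerA"] * n_a + ["scannerB"] * (n_pat - n_a))
    rng.shuffle(scanner)
    n_v = int(round(n_pat * config.voltage_split))
    voltage = np.array(["100kVp"] * n_v + ["120kVp"] * (n_pat - n_v))
    rng.shuffle(voltage)
    volume = _draw_volumes(rng, n_pat, config)
    metadata = pd.DataFrame(
        {
            "patient_id": pids,
            "scanner": scanner,
            "tube_voltage": voltage,
            "tumour_volume_cm3": volume,
        }
    ).set_index("patient_id")

    # --- features -----------------------------------------------------
    group_params = config.resolved_group_params()
    specs: list[tuple[FeatureDescriptor, GroupParams | None]] = []
    counter = 0
    for g in (1, 2, 3, 4):
        for _ in range(int(config.n_features_per_group.get(g, 0))):
            prefix, subtype, category = _IMAGE_TEMPLATES[counter % len(_IMAGE_TEMPLATES)]
            name = f"{prefix}_{category}_G{g}F{counter:04d}"
            image_type = (
                "original"
                if prefix == "original"
                else ("wavelet" if prefix.startswith("wavelet") else "log")
            )
            specs.append(
                (
                    FeatureDescriptor(name, image_type, subtype, category),
                    group_params[g],
                )
            )
            counter += 1
    for k in range(config.n_shape_features):
        specs.append(
            (FeatureDescriptor(f"original_shape_S{k:03d}", "original", "", "shape"), None)
        )

    scanner_ind = (scanner == "scannerB").astype(float)
    voltage_ind = (voltage == "120kVp").astype(float)

    frames = []
    truth_rows = []
    for desc, gp in specs:
        intercept = float(rng.normal(0.0, 3.0))
        if gp is None:  # shape: identical across reconstructions, no noise
            base = intercept + rng.normal(0.0, 1.0, size=n_pat)
            values = np.tile(base[:, None], (1, n_set))
            beta = np.zeros(n_set)
            truth_rows.append(
                {
                    "feature": desc.name,
                    "planted_group": 2,
                    "scanner_effect": 0.0,
                    "voltage_effect": 0.0,
                    "volume_slope": 0.0,
                    "subject_sd": 1.0,
                    "residual_sd": 0.0,
                    "interaction_sd": 0.0,
                    **{f"beta[{s}]": 0.0 for s in settings},
                }
            )
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            beta = sign * gp.beta_max * (blend - ref_blend) / max_gap
            b = rng.normal(0.0, gp.subject_sd, size=n_pat)
            u = rng.normal(0.0, gp.interaction_sd, size=(n_pat, n_set)) if gp.interaction_sd > 0 else 0.0
            eps = rng.normal(0.0, gp.residual_sd, size=(n_pat, n_set)) if gp.residual_sd > 0 else 0.0
            values = (
                intercept
                + b[:, None]
                + beta[None, :]
                + gp.scanner_effect * scanner_ind[:, None]
                + gp.voltage_effect * voltage_ind[:, None]
                + gp.volume_slope * volume[:, None]
                + u
                + eps
            )
            truth_rows.append(
                {
                    "feature": desc.name,
                    "planted_group": gp.planted_group,
                    "scanner_effect": gp.scanner_effect,
                    "voltage_effect": gp.voltage_effect,
                    "volume_slope": gp.volume_slope,
                    "subject_sd": gp.subject_sd,
                    "residual_sd": gp.residual_sd,
                    "interaction_sd": gp.interaction_sd,
                    **{f"beta[{s}]": beta[k] for k, s in enumerate(settings)},
                }
            )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pids, n_set),
                    "setting": np.tile(settings, n_pat),
                    "feature": desc.name,
                    "value": values.ravel(),
                }
            )
        )

    values_long = pd.concat(frames, ignore_index=True)
    table = FeatureTable(
        design=design,
        values=values_long,
        metadata=metadata,
        features=[d for d, _ in specs],
    )
    return table, SyntheticTruth(pd.DataFrame(truth_rows))


def preset_catalog() -> dict[str, SyntheticConfig]:
    """Named configurations, one per planted group plus the study-shaped mix.

    ``group1`` .. ``group4`` plant a single regime (40 features each);
    ``paper_shaped`` mixes the four regimes in study-like proportions
    (majority group 1, sparse group 4) with a handful of shape features.
    """
    single = {
        f"group{g}": SyntheticConfig(
            n_features_per_group={1: 0, 2: 0, 3: 0, 4: 0} | {g: 40}
        )
        for g in (1, 2, 3, 4)
    }
    mixed = SyntheticConfig(
        n_features_per_group={1: 70, 2: 15, 3: 12, 4: 3},
        n_shape_features=6,
    )
    return {**single, "paper_shaped": mixed}


def get_preset(name: str, seed: int | None = None) -> SyntheticConfig:
    """Look up a preset by name, optionally overriding the seed."""
    catalog = preset_catalog()
    if name not in catalog:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(catalog)}")
    cfg = catalog[name]
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
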