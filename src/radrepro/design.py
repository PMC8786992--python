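"""Reconstruction-setting designs and feature/patient metadata records.

A *reconstruction design* describes the set of image reconstructions available
for every patient: an ordered list of setting labels (e.g. pure filtered
backprojection plus several iterative-reconstruction blending levels), the
percentage of iterative blending behind each label, and the label used as the
reference category in regression models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "ReconstructionDesign",
    "PatientRecord",
    "FeatureDescriptor",
    "DEFAULT_DESIGN",
    "TEXTURE_CATEGORIES",
    "FEATURE_CATEGORIES",
    "parse_feature_name",
]

#: Texture-matrix feature families (everything except shape and first order).
TEXTURE_CATEGORIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

FEATURE_CATEGORIES = ("shape", "firstorder") + TEXTURE_CATEGORIES


@dataclass(frozen=True)
class ReconstructionDesign:
    """Ordered reconstruction settings with blending percents and a reference.

    Parameters
    ----------
    setting_labels
        Unique labels in acquisition-protocol order.
    reference_label
        The setting used as reference category in mixed models; must be one of
        ``setting_labels``.
    blending_percent
        Injective mapping from label to iterative blending percent (0-100);
        0 denotes pure filtered backprojection.
    """

    setting_labels: tuple[str, ...]
    reference_label: str
    blending_percent: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(self.setting_labels)
        object.__setattr__(self, "setting_labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("setting labels must be unique")
        if len(labels) < 2:
            raise ValueError("a design needs at least two settings")
        if self.reference_label not in labels:
            raise ValueError(
                f"reference setting {self.reference_label!r} is not one of {labels}"
            )
        bp = dict(self.blending_percent)
        missing = [lab for lab in labels if lab not in bp]
        if missing:
            raise ValueError(f"blending percent missing for settings {missing}")
        extra = [lab for lab in bp if lab not in labels]
        if extra:
            raise ValueError(f"blending percent given for unknown settings {extra}")
        if len(set(bp.values())) != len(bp):
            raise ValueError("blending percents must be distinct across settings")
        for lab, pct in bp.items():
            if not 0 <= pct <= 100:
                raise ValueError(f"blending percent for {lab!r} outside [0, 100]")
        object.__setattr__(self, "blending_percent", bp)

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(l for l in self.setting_labels if l != self.reference_label)

    def ordered_by_blending(self) -> tuple[str, ...]:
        """Labels sorted by blending percent (for trend plots and heatmaps)."""
        return tuple(sorted(self.setting_labels, key=self.blending_percent.__getitem__))

    def subset(self, labels, reference_label: str | None = None) -> "ReconstructionDesign":
        """Restrict the design to ``labels``, optionally changing the reference.

        Used for subgroup analyses over a contiguous range of blending levels
        (e.g. keeping only the iterative settings and re-referencing to the
        lowest retained level).
        """
        labels = tuple(labels)
        unknown = [l for l in labels if l not in self.setting_labels]
        if unknown:
            raise ValueError(f"settings {unknown} not in design")
        ref = reference_label if reference_label is not None else self.reference_label
        if ref not in labels:
            raise ValueError(
                f"reference {ref!r} not in the requested subset {labels}"
            )
        return replace(
            self,
            setting_labels=labels,
            reference_label=ref,
            blending_percent={l: self.blending_percent[l] for l in labels},
        )


#: Six-level design: pure FBP plus five iterative blending levels.
DEFAULT_DESIGN = ReconstructionDesign(
    setting_labels=("FBP", "IR20", "IR40", "IR50", "IR60", "IR80"),
    reference_label="FBP",
    blending_percent={"FBP": 0, "IR20": 20, "IR40": 40, "IR50": 50, "IR60": 60, "IR80": 80},
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's acquisition and clinical covariates."""

    patient_id: str
    scanner: str
    tube_voltage: str
    tumour_volume_cm3: float
    extra_covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scanner or not self.tube_voltage:
            raise ValueError(f"patient {self.patient_id}: scanner/voltage required")
        if not self.tumour_volume_cm3 > 0:
            raise ValueError(
                f"patient {self.patient_id}: tumour volume must be positive"
            )
        object.__setattr__(self, "extra_covariates", dict(self.extra_covariates))


@dataclass(frozen=True)
class FeatureDescriptor:
    """Feature identity: image type, filter subtype, and category.

    ``is_volume_like`` marks features that *are* the tumour volume (voxel
    volume and aliases) so downstream models can drop the clinical-volume
    covariate for them.
    """

    name: str
    image_type: str  # original | wavelet | log
    image_subtype: str = ""  # wavelet band (LH/HL/HH/LL) or LoG sigma label
    category: str = "firstorder"
    is_volume_like: bool = False

    def __post_init__(self) -> None:
        if self.image_type not in ("original", "wavelet", "log"):
            raise ValueError(f"unknown image type {self.image_type!r}")
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.category == "shape" and self.image_type != "original":
            raise ValueError(
                f"{self.name}: shape features exist only for original images"
            )

    @property
    def is_texture(self) -> bool:
        return self.category in TEXTURE_CATEGORIES


_NAME_RE = re.compile(
    r"^(?P<type>original|wavelet-(?P<band>LH|HL|HH|LL)|log-sigma-(?P<sigma>[\d-]+)-mm)"
    r"_(?P<cat>shape|firstorder|glcm|glrlm|glszm|ngtdm|gldm)_(?P<feat>.+)$"
)

#: Feature names treated as the segmented volume itself.
VOLUME_LIKE_NAMES = frozenset({"original_shape_VoxelVolume"})


def parse_feature_name(name: str, volume_like=VOLUME_LIKE_NAMES) -> FeatureDescriptor:
    """Build a :class:`FeatureDescriptor` from a conventional feature name.

    Names follow the ``<imagetype>_<category>_<feature>`` convention, e.g.
    ``original_glrlm_RunVariance``, ``wavelet-HH_firstorder_Mean`` or
    ``log-sigma-1-0-mm_glcm_Contrast``. Unparseable names fall back to an
    ``original``/``firstorder`` descriptor.
    """
    m = _NAME_RE.match(name)
    if not m:
        return FeatureDescriptor(name=name, image_type="original")
    typ = m.group("type")
    if typ == "original":
        image_type, subtype = "original", ""
    elif typ.startswith("wavelet"):
        image_type, subtype = "wavelet", m.group("band")
    else:
        image_type, subtype = "log", m.group("sigma").replace("-", ".") + " mm"
    return FeatureDescriptor(
        name=name,
        image_type=image_type,
        image_subtype=subtype,
        category=m.group("cat"),
        is_volume_like=name in volume_like,
    )
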