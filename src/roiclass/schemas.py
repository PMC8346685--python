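"""Feature schemas for atlas-based ROI tables.

A :class:`FeatureSchema` fixes the identity and column order of every ROI
feature in a cohort table: structural tables carry Desikan-Killiany cortical
thickness/surface-area measures plus FreeSurfer-aseg subcortical volumes
(152 features), diffusion tables carry JHU-atlas tract summaries of FA or RD
(41 features, three of them midline corpus-callosum segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Modality(str, Enum):
    structural = "structural"
    diffusion_FA = "diffusion_FA"
    diffusion_RD = "diffusion_RD"


class Measure(str, Enum):
    thickness = "thickness"
    surface_area = "surface_area"
    subcortical_volume = "subcortical_volume"
    FA = "FA"
    RD = "RD"


class Hemisphere(str, Enum):
    left = "left"
    right = "right"
    midline = "midline"


#: The 34 Desikan-Killiany cortical parcels (per hemisphere).
DESIKAN_KILLIANY_34: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: The 8 FreeSurfer-aseg subcortical grey-matter structures (per hemisphere).
ASEG_SUBCORTICAL_8: tuple[str, ...] = (
    "lateral_ventricle",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

#: Default bilateral JHU white-matter tracts (ENIGMA-DTI convention).
JHU_BILATERAL_19: tuple[str, ...] = (
    "ACR",
    "ALIC",
    "CGC",
    "CGH",
    "CR",
    "CST",
    "EC",
    "FXST",
    "IC",
    "IFO",
    "PCR",
    "PLIC",
    "PTR",
    "RLIC",
    "SCR",
    "SFO",
    "SLF",
    "SS",
    "UNC",
)

#: Midline corpus-callosum segments: body, genu, splenium.
JHU_MIDLINE_3: tuple[str, ...] = ("BCC", "GCC", "SCC")


class SchemaError(ValueError):
    """Raised when a schema or a table violates a schema contract."""


@dataclass(frozen=True)
class Feature:
    """One scalar ROI measurement: region, measure type, hemisphere."""

    roi_name: str
    measure: Measure
    hemisphere: Hemisphere

    @property
    def name(self) -> str:
        """Canonical column name, e.g. ``hippocampus_subcortical_volume_left``."""
        return f"{self.roi_name}_{self.measure.value}_{self.hemisphere.value}"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, validated list of ROI features for one modality."""

    modality: Modality
    atlas: str
    features: tuple[Feature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names in schema: {dupes}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def count(self, measure: Measure | None = None, hemisphere: Hemisphere | None = None) -> int:
        n = 0
        for f in self.features:
            if measure is not None and f.measure != measure:
                continue
            if hemisphere is not None and f.hemisphere != hemisphere:
                continue
            n += 1
        return n

    def subset_names(self, rois: Iterable[str]) -> list[str]:
        """Feature names whose roi_name is in ``rois`` (order preserved)."""
        wanted = set(rois)
        return [f.name for f in self.features if f.roi_name in wanted]


def build_structural_schema() -> FeatureSchema:
    """Desikan-Killiany thickness + surface area and aseg volumes, 152 features.

    Layout: 34 L + 34 R thickness, 34 L + 34 R surface area,
    8 L + 8 R subcortical volumes.
    """
    features: list[Feature] = []
    for measure, rois in (
        (Measure.thickness, DESIKAN_KILLIANY_34),
        (Measure.surface_area, DESIKAN_KILLIANY_34),
        (Measure.subcortical_volume, ASEG_SUBCORTICAL_8),
    ):
        for hemi in (Hemisphere.left, Hemisphere.right):
            features.extend(Feature(roi, measure, hemi) for roi in rois)
    return FeatureSchema(
        modality=Modality.structural,
        atlas="Desikan-Killiany+aseg",
        features=tuple(features),
    )


def build_diffusion_schema(
    measure: Measure | str = Measure.FA,
    bilateral_tracts: Sequence[str] | None = None,
) -> FeatureSchema:
    """JHU tract schema: 19 left + 19 right tracts + BCC/GCC/SCC, 41 features.

    Parameters
    ----------
    measure:
        ``FA`` or ``RD``.
    bilateral_tracts:
        Override the 19 default bilateral tract names (must contain 19
        unique names, none of them a midline segment).
    """
    measure = Measure(measure)
    if measure not in (Measure.FA, Measure.RD):
        raise SchemaError(f"diffusion measure must be FA or RD, got {measure!r}")
    tracts = tuple(bilateral_tracts) if bilateral_tracts is not None else JHU_BILATERAL_19
    if len(tracts) != 19:
        raise SchemaError(f"need exactly 19 bilateral tracts, got {len(tracts)}")
    if len(set(tracts)) != len(tracts):
        raise SchemaError("bilateral tract names must be unique")
    if set(tracts) & set(JHU_MIDLINE_3):
        raise SchemaError("midline segments cannot appear in the bilateral list")

    features: list[Feature] = []
    for hemi in (Hemisphere.left, Hemisphere.right):
        features.extend(Feature(t, measure, hemi) for t in tracts)
    features.extend(Feature(t, measure, Hemisphere.midline) for t in JHU_MIDLINE_3)
    modality = Modality.diffusion_FA if measure == Measure.FA else Modality.diffusion_RD
    return FeatureSchema(modality=modality, atlas="JHU", features=tuple(features))
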