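"""Per-cylinder morphometric measurements and per-case aggregation.

Combines the intensity-class map and the zone map into the measurement battery
reported per TMA cylinder: nuclei density and %SA, territorial and
interterritorial positive %SA, intensity-class pixel ratios, and the pixel
H-score (100 x (1*weak + 2*moderate + 3*strong fractions), range 0-300).
Cylinder rows from the same case are averaged into a case record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stains import (
    ClassFractions,
    IntensityThresholds,
    ODImage,
    PixelClass,
    RGBImage,
    StainMatrix,
    classify_pixels,
    pixel_ratios,
    rgb_to_od,
    unmix,
)
from .zoning import (
    TERRITORIAL_ZONES,
    NucleiLabels,
    TissueMask,
    Zone,
    ZoneParams,
    build_zones,
    detect_tissue,
    nuclei_density,
    segment_nuclei,
)

__all__ = [
    "CoreMetrics",
    "CaseRecord",
    "CoreAnalysis",
    "percent_sa",
    "territorial_sa",
    "interterritorial_sa",
    "hscore",
    "analyze_core",
    "core_metrics",
    "aggregate_case",
]

POSITIVE_CLASSES = (PixelClass.WEAK, PixelClass.MODERATE, PixelClass.STRONG)

#: CaseRecord covariate keys, in reporting order
COVARIATE_KEYS = (
    "age_ge_18mo",
    "stage_m",
    "hist_unfavorable",
    "mycn_amplified",
    "sca_profile",
    "del_11q",
    "high_risk",
    "high_instability",
)


@dataclass
class CoreMetrics:
    """One cylinder's measurements.

    %SA values are percentages of the cylinder tissue area in [0, 100];
    class ratios are reported as percentages of tissue pixels; the H-score
    lies in [0, 300].
    """

    core_id: str
    nuclei_density: float  # objects / mm^2
    nuclei_sa: float  # %
    inter_vn_sa: float  # %
    terr_vn_sa: float  # %
    ratio_weak: float  # % of tissue pixels
    ratio_moderate: float
    ratio_strong: float
    hscore: float

    NUMERIC_FIELDS = (
        "nuclei_density", "nuclei_sa", "inter_vn_sa", "terr_vn_sa",
        "ratio_weak", "ratio_moderate", "ratio_strong", "hscore",
    )

    def __post_init__(self) -> None:
        for name in ("nuclei_sa", "inter_vn_sa", "terr_vn_sa"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not (0.0 <= self.hscore <= 300.0):
            raise ValueError(f"hscore={self.hscore} outside [0, 300]")

    @property
    def total_positive_sa(self) -> float:
        return self.inter_vn_sa + self.terr_vn_sa

    @property
    def has_immunoreactivity(self) -> bool:
        return self.total_positive_sa > 0.0

    def as_dict(self) -> dict:
        return {"core_id": self.core_id,
                **{k: getattr(self, k) for k in self.NUMERIC_FIELDS}}


@dataclass
class CaseRecord:
    """Per-patient record: cylinder-averaged metrics, covariates, outcomes."""

    case_id: str
    metrics: CoreMetrics
    covariates: dict
    efs_time: float
    efs_event: bool
    os_time: float
    os_event: bool
    n_cylinders: int = 1

    def __post_init__(self) -> None:
        if self.efs_time < 0 or self.os_time < 0:
            raise ValueError("survival times must be >= 0")
        if self.n_cylinders < 1:
            raise ValueError("a case needs at least one cylinder")

    def as_row(self) -> dict:
        row = {"case_id": self.case_id, **self.metrics.as_dict()}
        row.pop("core_id")
        row.update({k: int(self.covariates.get(k, 0)) for k in COVARIATE_KEYS})
        row.update(
            efs_time=self.efs_time, efs_event=int(self.efs_event),
            os_time=self.os_time, os_event=int(self.os_event),
            n_cylinders=self.n_cylinders,
        )
        return row


def percent_sa(positive: np.ndarray, tissue: TissueMask) -> float:
    """Percent stained area: 100 x |positive AND tissue| / |tissue|."""
    positive = np.asarray(positive, dtype=bool)
    if positive.shape != tissue.mask.shape:
        raise ValueError("positive mask and tissue mask shapes differ")
    n_tissue = int(tissue.mask.sum())
    if n_tissue == 0:
        raise ValueError("empty tissue: %SA undefined")
    return 100.0 * int((positive & tissue.mask).sum()) / n_tissue


def _positive_mask(classes: np.ndarray) -> np.ndarray:
    classes = np.asarray(classes)
    return np.isin(classes, POSITIVE_CLASSES)


def _zone_sa(classes: np.ndarray, zones: np.ndarray, tissue: TissueMask,
             wanted: Sequence[Zone]) -> float:
    classes = np.asarray(classes)
    zones = np.asarray(zones)
    if classes.shape != zones.shape or classes.shape != tissue.mask.shape:
        raise ValueError("class map, zone map and tissue mask shapes differ")
    return percent_sa(_positive_mask(classes) & np.isin(zones, wanted), tissue)


def territorial_sa(classes: np.ndarray, zones: np.ndarray,
                   tissue: TissueMask) -> float:
    """%SA of positive pixels in the intracellular + pericellular zones."""
    return _zone_sa(classes, zones, tissue, TERRITORIAL_ZONES)


def interterritorial_sa(classes: np.ndarray, zones: np.ndarray,
                        tissue: TissueMask) -> float:
    """%SA of positive pixels in the interterritorial (intercellular) zone."""
    return _zone_sa(classes, zones, tissue, (Zone.INTERTERRITORIAL,))


def hscore(ratios: ClassFractions | Sequence[float]) -> float:
    """Pixel H-score from intensity-class fractions.

    100 x (1*weak + 2*moderate + 3*strong); fractions must sum to 1.
    """
    if isinstance(ratios, ClassFractions):
        neg, weak, mod, strong = ratios.as_tuple()
    else:
        neg, weak, mod, strong = (float(r) for r in ratios)
    total = neg + weak + mod + strong
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    return float(np.clip(100.0 * (weak + 2.0 * mod + 3.0 * strong), 0.0, 300.0))


@dataclass
class CoreAnalysis:
    """Full analysis of one cylinder: metrics plus all intermediate maps."""

    metrics: CoreMetrics
    tissue: TissueMask
    od: ODImage
    nuclei: NucleiLabels
    zones: np.ndarray
    classes: np.ndarray


def analyze_core(
    image: RGBImage,
    stains: StainMatrix | None = None,
    thresholds: IntensityThresholds = IntensityThresholds(),
    zone_params: ZoneParams = ZoneParams(),
    od_floor: float = 0.05,
    nuclei_threshold: float = 0.3,
    min_nucleus_area_um2: float = 5.0,
    max_nucleus_area_um2: float = 400.0,
    i0: float = 255.0,
) -> CoreAnalysis:
    """Run the whole per-cylinder pipeline: tissue -> unmix -> nuclei -> zones
    -> classes -> metrics. Deterministic given image and parameters."""
    stains = stains or StainMatrix.hdab()
    stage = "tissue detection"
    try:
        tissue = detect_tissue(image, od_floor=od_floor)
        stage = "stain unmixing"
        od = unmix(rgb_to_od(image.pixels, i0=i0), stains, i0=i0)
        stage = "nuclei segmentation"
        nuclei = segment_nuclei(
            od.hematoxylin, tissue,
            min_area_um2=min_nucleus_area_um2,
            max_area_um2=max_nucleus_area_um2,
            threshold=nuclei_threshold,
        )
        stage = "zoning"
        zones = build_zones(nuclei, tissue, zone_params)
        stage = "pixel classification"
        classes = classify_pixels(od.dab, tissue.mask, thresholds)
        stage = "morphometry"
        ratios = pixel_ratios(classes)
        metrics = CoreMetrics(
            core_id=image.core_id,
            nuclei_density=nuclei_density(nuclei, tissue),
            nuclei_sa=percent_sa(nuclei.labels > 0, tissue),
            inter_vn_sa=interterritorial_sa(classes, zones, tissue),
            terr_vn_sa=territorial_sa(classes, zones, tissue),
            ratio_weak=100.0 * ratios.weak,
            ratio_moderate=100.0 * ratios.moderate,
            ratio_strong=100.0 * ratios.strong,
            hscore=hscore(ratios),
        )
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    return CoreAnalysis(metrics, tissue, od, nuclei, zones, classes)


def core_metrics(image: RGBImage, **kwargs) -> CoreMetrics:
    """Convenience wrapper returning only the metrics row of analyze_core."""
    return analyze_core(image, **kwargs).metrics


def aggregate_case(
    cores: Sequence[CoreMetrics],
    case_id: str,
    covariates: Mapping | None = None,
    efs_time: float = 0.0,
    efs_event: bool = False,
    os_time: float = 0.0,
    os_event: bool = False,
) -> CaseRecord:
    """Average cylinder metrics into one case record (unweighted means)."""
    if len(cores) == 0:
        raise ValueError("cannot aggregate an empty list of cylinders")
    mean_kwargs = {
        name: float(np.mean([getattr(c, name) for c in cores]))
        for name in CoreMetrics.NUMERIC_FIELDS
    }
    metrics = CoreMetrics(core_id=case_id, **mean_kwargs)
    return CaseRecord(
        case_id=case_id,
        metrics=metrics,
        covariates=dict(covariates or {}),
        efs_time=efs_time,
        efs_event=efs_event,
        os_time=os_time,
        os_event=os_event,
        n_cylinders=len(cores),
    )
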