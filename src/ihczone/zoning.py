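"""Tissue detection, nuclei segmentation and territorial/interterritorial zoning.

The spatial vocabulary follows matrix biology: staining inside cells and in the
two thin pericellular bands (a capsular rim hugging the cell boundary and a
paracapsular layer around it, wrapping single cells or nests of grouped cells)
is *territorial*; staining in the matrix beyond those bands is
*interterritorial*. Bands are defined by Euclidean distance in physical
micrometres from the approximated cell regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import regionprops

from .stains import RGBImage, rgb_to_od

__all__ = [
    "Zone",
    "TissueMask",
    "NucleiLabels",
    "ZoneParams",
    "EmptyCoreError",
    "TERRITORIAL_ZONES",
    "detect_tissue",
    "segment_nuclei",
    "nuclei_density",
    "build_zones",
]


class EmptyCoreError(ValueError):
    """Raised when no tissue is detectable in a core image."""


class Zone(IntEnum):
    NON_TISSUE = 0
    INTRACELLULAR = 1
    CAPSULAR = 2
    PARACAPSULAR = 3
    INTERTERRITORIAL = 4


#: zones whose union constitutes the territorial compartment
TERRITORIAL_ZONES = (Zone.INTRACELLULAR, Zone.CAPSULAR, Zone.PARACAPSULAR)


@dataclass
class TissueMask:
    """Boolean tissue-vs-glass mask with its physical scale."""

    mask: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def tissue_area_mm2(self) -> float:
        """Tissue area: pixel count x (um_per_px / 1000)^2."""
        return float(self.mask.sum()) * (self.um_per_px / 1000.0) ** 2


@dataclass
class NucleiLabels:
    """Labeled nuclei (0 = background), with object count and centroids."""

    labels: np.ndarray
    n_objects: int
    centroids: np.ndarray  # (n, 2) row/col

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.max(initial=0) != self.n_objects:
            raise ValueError("labels must be contiguous 1..n_objects")


@dataclass(frozen=True)
class ZoneParams:
    """Physical widths (µm) of the pericellular bands.

    cyto_dilation_um grows each nucleus into an approximate cell region (no
    membrane stain is available, so the cytoplasm is modelled as a fixed rim);
    cells closer than nest_gap_um merge into a nest before banding.
    """

    cyto_dilation_um: float = 3.0
    capsular_width_um: float = 2.0
    paracapsular_width_um: float = 3.0
    nest_gap_um: float = 5.0

    def __post_init__(self) -> None:
        for name in ("cyto_dilation_um", "capsular_width_um",
                     "paracapsular_width_um", "nest_gap_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def detect_tissue(image: RGBImage, od_floor: float = 0.05) -> TissueMask:
    """Find the tissue disc: total OD above ``od_floor``, closed, hole-filled,
    largest connected component kept."""
    od_total = rgb_to_od(image.pixels).sum(axis=-1)
    raw = od_total > od_floor
    if not raw.any():
        raise EmptyCoreError("no pixel exceeds the OD floor: empty core")
    closed = morphology.closing(raw, morphology.disk(3))
    filled = ndi.binary_fill_holes(closed)
    labels, n = ndi.label(filled)
    if n == 0:
        raise EmptyCoreError("tissue vanished after morphological cleaning")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return TissueMask(labels == keep, um_per_px=image.um_per_px)


def segment_nuclei(
    hema: np.ndarray,
    tissue: TissueMask,
    min_area_um2: float = 5.0,
    max_area_um2: float = 400.0,
    threshold: float = 0.3,
) -> NucleiLabels:
    """Segment nuclei from the hematoxylin amount field.

    Thresholds the hematoxylin concentration inside tissue, splits touching
    blobs with a distance-transform watershed and filters objects by physical
    area bounds.
    """
    hema = np.asarray(hema, dtype=float)
    if not np.all(np.isfinite(hema)):
        raise ValueError("non-finite hematoxylin field")
    if not (0 < min_area_um2 < max_area_um2):
        raise ValueError("need 0 < min_area_um2 < max_area_um2")
    px_area = tissue.um_per_px**2
    binary = (hema >= threshold) & tissue.mask
    if not binary.any():
        return NucleiLabels(np.zeros_like(binary, dtype=np.int32), 0,
                            np.empty((0, 2)))
    distance = ndi.distance_transform_edt(binary)
    # peaks at least one typical nucleus radius apart
    min_sep = max(1, int(round(np.sqrt(min_area_um2 / np.pi) / tissue.um_per_px)))
    peaks = peak_local_max(distance, labels=binary, min_distance=min_sep,
                           exclude_border=False)
    markers = np.zeros_like(binary, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=binary)

    out = np.zeros_like(labels, dtype=np.int32)
    centroids = []
    next_label = 0
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if min_area_um2 <= area_um2 <= max_area_um2:
            next_label += 1
            out[labels == prop.label] = next_label
            centroids.append(prop.centroid)
    return NucleiLabels(out, next_label,
                        np.asarray(centroids).reshape(-1, 2))


def nuclei_density(labels: NucleiLabels, tissue: TissueMask) -> float:
    """Objects per mm² of tissue."""
    area = tissue.tissue_area_mm2
    if area <= 0:
        raise ValueError("zero tissue area: density undefined")
    return labels.n_objects / area


def build_zones(
    labels: NucleiLabels, tissue: TissueMask, params: ZoneParams = ZoneParams()
) -> np.ndarray:
    """Partition the core into the five spatial zones.

    All band boundaries are thresholds of one Euclidean distance field from
    the nuclei (in µm): cell regions at distance <= cyto_dilation_um, the
    capsular band in the next capsular_width_um shell, the paracapsular band
    in the shell after that. Using a single field makes consecutive shell
    widths exact despite rasterization. Cell regions closer than nest_gap_um
    are merged into nests by morphological closing; matrix enclosed by a nest
    is reassigned to the cell compartment. Remaining tissue is
    interterritorial. Returns an int8 map of :class:`Zone`.
    """
    px = tissue.um_per_px
    zones = np.full(tissue.mask.shape, Zone.NON_TISSUE, dtype=np.int8)
    zones[tissue.mask] = Zone.INTERTERRITORIAL
    nuclei_mask = np.asarray(labels.labels) > 0
    if not nuclei_mask.any():
        warnings.warn("no nuclei: whole tissue classified interterritorial",
                      stacklevel=2)
        return zones

    dist_nuc = ndi.distance_transform_edt(~nuclei_mask, sampling=px)
    cells = dist_nuc <= params.cyto_dilation_um
    nests = cells
    gap_px = int(round(params.nest_gap_um / 2.0 / px))
    if gap_px > 0:
        nests = morphology.closing(cells, morphology.disk(gap_px))

    shell = dist_nuc - params.cyto_dilation_um
    capsular = (~nests) & (shell > 0) & (shell <= params.capsular_width_um)
    paracapsular = (
        (~nests)
        & (shell > params.capsular_width_um)
        & (shell <= params.capsular_width_um + params.paracapsular_width_um)
    )
    t = tissue.mask
    zones[t & nests] = Zone.INTRACELLULAR
    zones[t & capsular] = Zone.CAPSULAR
    zones[t & paracapsular] = Zone.PARACAPSULAR
    return zones
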