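"""Optical-density stain separation and DAB intensity classification.

Brightfield IHC images mix a blue nuclear counterstain (hematoxylin) with the
brown DAB chromogen. In optical density (OD = -log10 of transmittance) stain
contributions add linearly (Beer-Lambert), so per-pixel stain amounts are
recovered by solving a 3x3 linear system against known unit stain vectors.
The DAB amount is then binned into the four intensity classes used in
pixel-based densitometry (negative / weak / moderate / strong).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "PixelClass",
    "RGBImage",
    "StainMatrix",
    "ODImage",
    "IntensityThresholds",
    "ClassFractions",
    "rgb_to_od",
    "od_to_rgb",
    "mix",
    "unmix",
    "classify_pixels",
    "pixel_ratios",
]

#: Standard hematoxylin / DAB unit absorption vectors in OD-RGB space
#: (Ruifrok-style published values, renormalized).
HEMATOXYLIN_VECTOR = np.array([0.650, 0.704, 0.286])
DAB_VECTOR = np.array([0.269, 0.568, 0.778])

DEFAULT_I0 = 255.0
#: guard added to intensities before the log transform, on the 0-255 scale
OD_EPSILON = 1.0


class PixelClass(IntEnum):
    """Per-pixel DAB intensity class; NON_TISSUE marks glass/background."""

    NON_TISSUE = 0
    NEGATIVE = 1
    WEAK = 2
    MODERATE = 3
    STRONG = 4


@dataclass
class RGBImage:
    """A brightfield core image with its physical pixel scale.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    um_per_px : micrometres per pixel (isotropic)
    core_id : identifier carried through to metric tables
    """

    pixels: np.ndarray
    um_per_px: float
    core_id: str = "core"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image has empty spatial dimensions")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _unit_rows(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain vector with zero norm")
    return matrix / norms


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-length stain absorption vectors (rows: hematoxylin, DAB, residual).

    The residual row completes the basis so arbitrary OD pixels have a unique
    decomposition; it is the cross product of the two stain rows with negative
    components clipped to zero and renormalized, keeping all rows non-negative.
    """

    matrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        m = self.matrix
        if m is None:
            m = self._default_hdab()
        m = _unit_rows(np.asarray(m, dtype=float))
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if np.any(m < -1e-12):
            raise ValueError("stain vectors must be non-negative")
        if np.linalg.cond(m) > self.max_condition:
            raise ValueError("stain matrix is singular or ill-conditioned")
        object.__setattr__(self, "matrix", m)

    @staticmethod
    def _default_hdab() -> np.ndarray:
        residual = np.cross(HEMATOXYLIN_VECTOR, DAB_VECTOR)
        residual = np.clip(residual, 0.0, None)
        return np.vstack([HEMATOXYLIN_VECTOR, DAB_VECTOR, residual])

    @classmethod
    def hdab(cls) -> "StainMatrix":
        """The default hematoxylin + DAB basis."""
        return cls()

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class ODImage:
    """Per-pixel stain amounts from unmixing an OD image.

    ``concentrations`` has shape (H, W, 3) with the stain axis ordered as the
    StainMatrix rows (hematoxylin, DAB, residual); values are clipped to >= 0.
    """

    concentrations: np.ndarray
    stains: StainMatrix
    i0: float = DEFAULT_I0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.concentrations)):
            raise ValueError("non-finite stain concentrations")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.concentrations[..., 0]

    @property
    def dab(self) -> np.ndarray:
        return self.concentrations[..., 1]


@dataclass(frozen=True)
class IntensityThresholds:
    """DAB-amount cutpoints separating negative/weak/moderate/strong pixels.

    Half-open intervals, the boundary value belongs to the higher class:
    [0, t_pos) negative, [t_pos, t_weak_mod) weak, [t_weak_mod, t_mod_strong)
    moderate, [t_mod_strong, inf) strong. Defaults are calibrated so that the
    synthetic generator's weak/moderate/strong deposits are recovered from
    noise-free renders.
    """

    t_pos: float = 0.15
    t_weak_mod: float = 0.45
    t_mod_strong: float = 0.85

    def __post_init__(self) -> None:
        if not (0 < self.t_pos < self.t_weak_mod < self.t_mod_strong):
            raise ValueError(
                "thresholds must satisfy 0 < t_pos < t_weak_mod < t_mod_strong"
            )


@dataclass(frozen=True)
class ClassFractions:
    """Fractions of tissue pixels in each intensity class (sum to 1)."""

    negative: float
    weak: float
    moderate: float
    strong: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.negative, self.weak, self.moderate, self.strong)


def rgb_to_od(
    pixels: np.ndarray, i0: float = DEFAULT_I0, epsilon: float = OD_EPSILON
) -> np.ndarray:
    """Beer-Lambert transform of RGB intensities to per-channel optical density.

    OD = -log10((v + epsilon) / i0); the small guard avoids infinities at v=0.
    """
    if not i0 > 0:
        raise ValueError("i0 must be positive")
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[-1] != 3:
        raise ValueError("expected a 3-channel image")
    return -np.log10((pixels + epsilon) / i0)


def od_to_rgb(od: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Inverse Beer-Lambert: transmitted intensity i0 * 10**(-OD), as float."""
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def mix(concentrations: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Forward model: stain amounts -> per-channel OD (OD = C @ M)."""
    return np.asarray(concentrations, dtype=float) @ stains.matrix


def unmix(od: np.ndarray, stains: StainMatrix, i0: float = DEFAULT_I0) -> ODImage:
    """Solve OD = C @ M for per-pixel stain amounts; negatives clipped to 0."""
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError("expected per-channel OD with 3 channels")
    conc = od @ stains.inverse
    return ODImage(np.clip(conc, 0.0, None), stains=stains, i0=i0)


def classify_pixels(
    dab: np.ndarray, tissue: np.ndarray, thresholds: IntensityThresholds
) -> np.ndarray:
    """Bin the DAB amount of every tissue pixel into the four intensity classes.

    Returns an int8 map of :class:`PixelClass`; non-tissue pixels get
    ``NON_TISSUE``. Boundary values promote to the higher class.
    """
    dab = np.asarray(dab, dtype=float)
    tissue = np.asarray(tissue, dtype=bool)
    if dab.shape != tissue.shape:
        raise ValueError(
            f"dab field shape {dab.shape} does not match tissue mask {tissue.shape}"
        )
    classes = np.full(dab.shape, PixelClass.NON_TISSUE, dtype=np.int8)
    classes[tissue] = PixelClass.NEGATIVE
    classes[tissue & (dab >= thresholds.t_pos)] = PixelClass.WEAK
    classes[tissue & (dab >= thresholds.t_weak_mod)] = PixelClass.MODERATE
    classes[tissue & (dab >= thresholds.t_mod_strong)] = PixelClass.STRONG
    return classes


def pixel_ratios(classes: np.ndarray) -> ClassFractions:
    """Fractions of NEGATIVE/WEAK/MODERATE/STRONG among tissue pixels."""
    classes = np.asarray(classes)
    tissue = classes != PixelClass.NON_TISSUE
    total = int(tissue.sum())
    if total == 0:
        raise ValueError("no tissue pixels: cannot compute class ratios")
    counts = [int((classes == c).sum()) for c in
              (PixelClass.NEGATIVE, PixelClass.WEAK, PixelClass.MODERATE, PixelClass.STRONG)]
    return ClassFractions(*(c / total for c in counts))
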