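"""Construction of the four attenuation-map (mu-map) variants.

A PET/CT scanner converts CT Hounsfield units to 511 keV linear attenuation
coefficients (LAC, cm^-1) with a two-segment ("bilinear") map; a
segmentation-based PET/MR mu-map instead assigns one fixed LAC per tissue
class (air/lung/fat/soft) and sees no bone and no intra-lung density
variation.  The experiment interpolates between the two by editing the
CT-derived map step by step:

  CTAC                 continuous CT-derived LACs (reference)
  CTAC_MRLUNG          lung voxels overwritten with the fixed lung-class LAC
  CTAC_MRLUNG_NOBONE   additionally, LAC > 0.10 cm^-1 set to the soft LAC
  MRAC                 pure 4-class map from the tissue labels

plus a voxelwise difference histogram used as a consistency check between
the edited CT map and the class map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import phantom as ph
from .errors import GeometryError, InputError, SeedError

VARIANTS = ("CTAC", "CTAC_MRLUNG", "CTAC_MRLUNG_NOBONE", "MRAC")


@dataclass(frozen=True)
class BilinearTransformParams:
    """Two-segment HU -> LAC map, anchored at mu(-1000 HU) = 0.

    Below the break the slope is the 511 keV water-scaling value
    9.6e-5 cm^-1/HU; above it the slope is kVp-dependent (default: 120 kVp).
    ``intercept_above`` defaults to the value that makes the map continuous
    at the break; passing it explicitly overrides that.
    """

    break_hu: float = 47.0
    slope_below: float = 9.6e-5
    slope_above: float = 5.1e-5
    intercept_above: float | None = None

    def __post_init__(self):
        if self.slope_below < 0 or self.slope_above < 0:
            raise InputError("bilinear slopes must be non-negative")
        if self.intercept_above is None:
            cont = (self.slope_below * (self.break_hu + 1000.0)
                    - self.slope_above * self.break_hu)
            object.__setattr__(self, "intercept_above", cont)

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        below = self.slope_below * (hu + 1000.0)
        above = self.slope_above * hu + self.intercept_above
        return np.clip(np.where(hu <= self.break_hu, below, above), 0.0, None)


@dataclass(frozen=True)
class TissueClassLACs:
    """Fixed per-class 511 keV LACs of the segmentation method, cm^-1."""

    air: float = 0.0
    lung: float = 0.0224
    fat: float = 0.0854
    soft: float = 0.1

    def __post_init__(self):
        if not (self.air < self.lung < self.fat < self.soft):
            raise InputError("class LACs must satisfy air < lung < fat < soft")


@dataclass
class MuMap:
    """Voxel grid of 511 keV linear attenuation coefficients, cm^-1."""

    lac_volume: np.ndarray
    spacing_mm: float
    variant: str

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InputError(f"unknown mu-map variant {self.variant!r}")

    def copy_as(self, variant: str) -> "MuMap":
        return MuMap(self.lac_volume.copy(), self.spacing_mm, variant)


@dataclass
class LungMask:
    mask: np.ndarray
    seed_points: Sequence[tuple[int, ...]] = field(default_factory=list)
    hu_threshold: float = -300.0


def hu_to_lac(hu_volume: np.ndarray,
              params: BilinearTransformParams | None = None,
              spacing_mm: float = 2.6) -> MuMap:
    """CT-derived continuous mu-map (variant CTAC)."""
    hu_volume = np.asarray(hu_volume, dtype=float)
    if not np.all(np.isfinite(hu_volume)):
        raise InputError("HU volume contains non-finite values")
    params = params or BilinearTransformParams()
    return MuMap(params(hu_volume), spacing_mm, "CTAC")


def build_segmentation_mumap(label_volume: np.ndarray,
                             lacs: TissueClassLACs | None = None,
                             spacing_mm: float = 2.6) -> MuMap:
    """4-class mu-map (variant MRAC): bone is deliberately mapped to the
    soft-tissue class — segmentation-based attenuation correction does not
    see bone."""
    lacs = lacs or TissueClassLACs()
    table = {ph.AIR: lacs.air, ph.LUNG_LEFT: lacs.lung,
             ph.LUNG_RIGHT: lacs.lung, ph.FAT: lacs.fat,
             ph.SOFT: lacs.soft, ph.BONE: lacs.soft}
    labels = np.asarray(label_volume)
    unknown = set(np.unique(labels)) - set(table)
    if unknown:
        raise InputError(f"unknown tissue labels {sorted(unknown)}")
    lut = np.zeros(max(table) + 1)
    for code, lac in table.items():
        lut[code] = lac
    return MuMap(lut[labels.astype(np.intp)], spacing_mm, "MRAC")


def grow_lung_mask(hu_volume: np.ndarray,
                   seeds: Sequence[tuple[int, ...]],
                   hu_threshold: float = -300.0) -> LungMask:
    """Region growing: voxels face-connected to a seed through HU < threshold."""
    hu_volume = np.asarray(hu_volume)
    below = hu_volume < hu_threshold
    for s in seeds:
        if not below[tuple(s)]:
            raise SeedError(f"seed {tuple(s)} has HU >= {hu_threshold}")
    structure = ndimage.generate_binary_structure(hu_volume.ndim, 1)
    comp, _ = ndimage.label(below, structure=structure)
    keep = {comp[tuple(s)] for s in seeds}
    mask = np.isin(comp, sorted(keep))
    return LungMask(mask=mask, seed_points=[tuple(s) for s in seeds],
                    hu_threshold=hu_threshold)


def replace_lung_lac(mumap_ctac: MuMap, mask: LungMask,
                     lacs: TissueClassLACs | None = None) -> MuMap:
    """Overwrite lung voxels with the fixed lung-class LAC (CTAC_MRLUNG)."""
    lacs = lacs or TissueClassLACs()
    if mask.mask.shape != mumap_ctac.lac_volume.shape:
        raise GeometryError("lung mask and mu-map grids differ")
    out = mumap_ctac.copy_as("CTAC_MRLUNG")
    out.lac_volume[mask.mask] = lacs.lung
    return out


def strip_bone(mumap: MuMap, lacs: TissueClassLACs | None = None,
               threshold: float = 0.10) -> MuMap:
    """Set voxels with LAC strictly above ``threshold`` to the soft-tissue
    class LAC (CTAC_MRLUNG_NOBONE).  The strict inequality means a voxel at
    exactly the threshold is left untouched."""
    lacs = lacs or TissueClassLACs()
    if threshold <= 0:
        raise InputError("bone threshold must be > 0")
    out = mumap.copy_as("CTAC_MRLUNG_NOBONE")
    out.lac_volume[out.lac_volume > threshold] = lacs.soft
    return out


@dataclass
class DifferenceHistogram:
    """Voxelwise (a - b) histogram inside the body, plus the fraction of body
    voxels whose |a - b| is within ``tol`` of the soft-tissue LAC."""

    counts: np.ndarray
    bin_edges: np.ndarray
    fraction_within: float
    tol: float


def mumap_difference_histogram(a: MuMap, b: MuMap, body_mask: np.ndarray,
                               tol: float = 0.10, n_bins: int = 81,
                               lacs: TissueClassLACs | None = None
                               ) -> DifferenceHistogram:
    lacs = lacs or TissueClassLACs()
    if a.lac_volume.shape != b.lac_volume.shape \
            or body_mask.shape != a.lac_volume.shape:
        raise GeometryError("mu-map / body-mask grids differ")
    diff = (a.lac_volume - b.lac_volume)[body_mask]
    lim = max(float(np.abs(diff).max()), 1e-6)
    counts, edges = np.histogram(diff, bins=n_bins, range=(-lim, lim))
    frac = float(np.mean(np.abs(diff) <= tol * lacs.soft))
    return DifferenceHistogram(counts=counts, bin_edges=edges,
                               fraction_within=frac, tol=tol)


def build_all_mumaps(phantom: ph.DigitalPhantom,
                     params: BilinearTransformParams | None = None,
                     lacs: TissueClassLACs | None = None,
                     hu_threshold: float = -300.0,
                     ) -> tuple[dict[str, MuMap], LungMask]:
    """Build the four variants for one phantom.

    The lung mask is region-grown from the centroid of each true lung (the
    phantom stands in for the operator's seed click), not copied from the
    label volume.
    """
    params = params or BilinearTransformParams()
    lacs = lacs or TissueClassLACs()
    seeds = []
    for code in (ph.LUNG_LEFT, ph.LUNG_RIGHT):
        pts = np.argwhere(phantom.label_volume == code)
        seeds.append(tuple(np.round(pts.mean(axis=0)).astype(int)))
    mask = grow_lung_mask(phantom.hu_volume, seeds, hu_threshold)

    ctac = hu_to_lac(phantom.hu_volume, params, phantom.spacing_mm)
    mrlung = replace_lung_lac(ctac, mask, lacs)
    nobone = strip_bone(mrlung, lacs)
    mrac = build_segmentation_mumap(phantom.label_volume, lacs,
                                    phantom.spacing_mm)
    return ({"CTAC": ctac, "CTAC_MRLUNG": mrlung,
             "CTAC_MRLUNG_NOBONE": nobone, "MRAC": mrac}, mask)
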