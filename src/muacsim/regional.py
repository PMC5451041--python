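"""ROI scheme, regional SUV statistics and the emphysema screen.

Twelve 1 cm ROIs per subject: for each lung, anterior/middle/posterior at a
hilum level and again at a basal level (a single-slice phantom uses the same
slice for both levels).  Regional summaries pool left/right and hilum/basal
per depth position, report SUVmean and the per-ROI relative difference of
each reconstruction arm against the CT-corrected reference, and compare
regions with one-way ANOVA plus Bonferroni-adjusted pairwise t-tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .attenuation import LungMask
from .errors import GeometryError, InputError

POSITIONS = ("anterior", "middle", "posterior")
SIDES = ("left", "right")
LEVELS = ("hilum", "basal")
ROI_DEPTH_FRACTIONS = {"anterior": 0.2, "middle": 0.5, "posterior": 0.8}


@dataclass(frozen=True)
class ROISpec:
    side: str
    level: str
    position: str
    slice_index: int
    center_vox: tuple[float, float]  # (row, col), voxel units
    diameter_mm: float = 10.0


@dataclass
class ROIMeasurement:
    roi: ROISpec
    suv_mean: dict[str, float]
    hu_mean: float


def roi_voxels(roi: ROISpec, shape: tuple[int, int],
               spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of voxels whose centres fall inside the ROI disc."""
    radius_vox = roi.diameter_mm / 2.0 / spacing_mm
    r0, c0 = roi.center_vox
    rr = np.arange(int(np.floor(r0 - radius_vox)), int(np.ceil(r0 + radius_vox)) + 1)
    cc = np.arange(int(np.floor(c0 - radius_vox)), int(np.ceil(c0 + radius_vox)) + 1)
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise GeometryError("ROI extends beyond the image bounds")
    R, C = np.meshgrid(rr, cc, indexing="ij")
    inside = (R - r0) ** 2 + (C - c0) ** 2 <= radius_vox ** 2
    return R[inside], C[inside]


def roi_mean(volume: np.ndarray, roi: ROISpec, spacing_mm: float) -> float:
    """Mean over the ROI disc on the given slice of a (slices, r, c) volume."""
    vol = np.asarray(volume)
    if vol.ndim == 2:
        vol = vol[None]
    sl = vol[roi.slice_index]
    rr, cc = roi_voxels(roi, sl.shape, spacing_mm)
    return float(sl[rr, cc].mean())


def _fit_center(mask2d: np.ndarray, row: int, col0: float,
                radius_vox: float) -> float | None:
    """Shift the ROI centre column until the whole disc fits in the mask."""
    n = mask2d.shape[1]
    for off in sorted(range(-int(2 * radius_vox) - 3, int(2 * radius_vox) + 4),
                      key=abs):
        col = col0 + off
        if not (radius_vox <= col <= n - 1 - radius_vox):
            continue
        rr = np.arange(int(np.floor(row - radius_vox)),
                       int(np.ceil(row + radius_vox)) + 1)
        cc = np.arange(int(np.floor(col - radius_vox)),
                       int(np.ceil(col + radius_vox)) + 1)
        if rr.min() < 0 or rr.max() >= mask2d.shape[0]:
            continue
        R, C = np.meshgrid(rr, cc, indexing="ij")
        inside = (R - row) ** 2 + (C - col) ** 2 <= radius_vox ** 2
        if mask2d[R[inside], C[inside]].all():
            return float(col)
    return None


def place_rois(lung_mask: LungMask, spacing_mm: float,
               diameter_mm: float = 10.0) -> list[ROISpec]:
    """Twelve ROIs: 2 sides x 2 levels x 3 depth positions.

    Depth positions sit at 20 / 50 / 80 % of each lung's anterior-posterior
    extent; the centre column starts at the lung's mid-column at that depth
    and is nudged laterally until the full disc lies inside the mask.
    """
    mask = np.asarray(lung_mask.mask)
    if mask.ndim == 2:
        mask = mask[None]
    n_slices = mask.shape[0]
    levels = {"hilum": n_slices // 3, "basal": (2 * n_slices) // 3}
    radius_vox = diameter_mm / 2.0 / spacing_mm

    mid_col = mask.shape[2] / 2.0
    rois: list[ROISpec] = []
    for side in SIDES:
        for level, sl in levels.items():
            m2d = mask[sl]
            cols_any = np.where(m2d.any(axis=0))[0]
            side_cols = cols_any[cols_any < mid_col] if side == "left" \
                else cols_any[cols_any >= mid_col]
            if side_cols.size == 0:
                raise GeometryError(f"no {side} lung found in the mask")
            side_mask = np.zeros_like(m2d)
            side_mask[:, side_cols] = m2d[:, side_cols]
            rows = np.where(side_mask.any(axis=1))[0]
            rmin, rmax = rows.min(), rows.max()
            for position in POSITIONS:
                f = ROI_DEPTH_FRACTIONS[position]
                row = int(round(rmin + f * (rmax - rmin)))
                cols = np.where(side_mask[row])[0]
                if cols.size == 0:
                    raise GeometryError(
                        f"{side}/{position} depth row holds no lung voxels")
                col = _fit_center(side_mask, row, float(cols.mean()), radius_vox)
                if col is None:
                    raise GeometryError(
                        f"lung too small for a {diameter_mm} mm ROI "
                        f"({side}/{level}/{position})")
                rois.append(ROISpec(side=side, level=level, position=position,
                                    slice_index=sl,
                                    center_vox=(float(row), col),
                                    diameter_mm=diameter_mm))
    assert len(rois) == 12
    return rois


def relative_difference(suv_x: float, suv_ref: float) -> float:
    """(x - ref) / ref * 100, in percent."""
    if suv_ref <= 0:
        raise InputError("reference SUV must be positive")
    return (suv_x - suv_ref) / suv_ref * 100.0


@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]


def compare_groups(values_by_group: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise two-sample t-tests.

    Degenerate inputs are resolved by the limit of the test: identical
    groups give p = 1; zero within-group variance with unequal means gives
    p = 0.
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InputError("need >= 2 groups with >= 2 values each")

    grand = np.concatenate(groups)
    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means_equal = np.allclose([g.mean() for g in groups], grand.mean())
    if within_var == 0.0:
        f, p = (0.0, 1.0) if means_equal else (np.inf, 0.0)
    else:
        f, p = stats.f_oneway(*groups)
        if np.isnan(f):  # all data identical
            f, p = 0.0, 1.0

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for (na, ga), (nb, gb) in itertools.combinations(zip(names, groups), 2):
        if np.allclose(ga.var() + gb.var(), 0.0):
            praw = 1.0 if np.isclose(ga.mean(), gb.mean()) else 0.0
        else:
            praw = stats.ttest_ind(ga, gb).pvalue
        pairwise[(na, nb)] = min(1.0, float(praw) * n_pairs)
    return GroupComparison(anova_f=float(f), anova_p=float(p),
                           pairwise_p=pairwise)


@dataclass
class RegionalReport:
    """Pooled per-position statistics of one or many subjects."""

    variants: tuple[str, ...]
    reference: str
    # position -> variant -> array of ROI SUVmeans
    suv_by_region: dict[str, dict[str, np.ndarray]]
    # position -> variant -> array of per-ROI relative differences vs reference
    reldiff_by_region: dict[str, dict[str, np.ndarray]]
    hu_by_region: dict[str, np.ndarray]

    def suv_mean_sd(self, position: str, variant: str) -> tuple[float, float]:
        v = self.suv_by_region[position][variant]
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    def reldiff_mean_sd(self, position: str, variant: str) -> tuple[float, float]:
        v = self.reldiff_by_region[position][variant]
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    def ap_suv_gradient(self, variant: str) -> float:
        """Posterior-minus-anterior mean SUV — the dependent-density gradient."""
        return (self.suv_by_region["posterior"][variant].mean()
                - self.suv_by_region["anterior"][variant].mean())

    def anterior_posterior_pvalue(self, variant: str) -> float:
        cmp = compare_groups({
            "anterior": self.suv_by_region["anterior"][variant],
            "posterior": self.suv_by_region["posterior"][variant]})
        return cmp.pairwise_p[("anterior", "posterior")]


def regional_summary(measurements: list[ROIMeasurement],
                     reference: str = "CTAC") -> RegionalReport:
    """Pool ROI measurements (across sides, levels and subjects) by depth
    position and attach per-ROI relative differences against the reference
    arm.  Relative differences are computed per ROI, then averaged — not as
    differences of regional means."""
    if not measurements:
        raise InputError("no ROI measurements supplied")
    if len(measurements) % 12 != 0:
        raise InputError("expected complete 12-ROI sets")
    variants = tuple(measurements[0].suv_mean)
    if reference not in variants:
        raise InputError(f"reference arm {reference!r} missing")

    suv = {p: {v: [] for v in variants} for p in POSITIONS}
    rel = {p: {v: [] for v in variants} for p in POSITIONS}
    hu = {p: [] for p in POSITIONS}
    for m in measurements:
        p = m.roi.position
        hu[p].append(m.hu_mean)
        for v in variants:
            suv[p][v].append(m.suv_mean[v])
            rel[p][v].append(relative_difference(m.suv_mean[v],
                                                 m.suv_mean[reference]))
    return RegionalReport(
        variants=variants, reference=reference,
        suv_by_region={p: {v: np.array(suv[p][v]) for v in variants}
                       for p in POSITIONS},
        reldiff_by_region={p: {v: np.array(rel[p][v]) for v in variants}
                           for p in POSITIONS},
        hu_by_region={p: np.array(hu[p]) for p in POSITIONS})


@dataclass
class MLDSegment:
    lung: str
    segment: str
    mld_hu: float
    emphysema_flag: bool


@dataclass
class MLDReport:
    segments: list[MLDSegment] = field(default_factory=list)
    cutoff_hu: float = -950.0

    @property
    def n_flagged(self) -> int:
        return sum(s.emphysema_flag for s in self.segments)


def mld_screen(hu_volume: np.ndarray, lung_mask: LungMask,
               cutoff_hu: float = -950.0, axis: int | None = None) -> MLDReport:
    """Mean lung density per lung third; a segment is flagged iff its MLD is
    strictly below the cutoff.

    Each lung is split into three equal-extent segments along the
    cranio-caudal axis when several slices are available; single-slice
    volumes fall back to the in-plane anterior-posterior axis as a
    surrogate.
    """
    hu = np.asarray(hu_volume)
    mask = np.asarray(lung_mask.mask)
    if hu.ndim == 2:
        hu, mask = hu[None], mask[None]
    if hu.shape != mask.shape:
        raise GeometryError("HU volume and lung mask grids differ")
    if axis is None:
        axis = 0 if hu.shape[0] >= 3 else 1

    mid_col = hu.shape[2] / 2.0
    cols = np.arange(hu.shape[2])
    report = MLDReport(cutoff_hu=cutoff_hu)
    for lung, sel in (("left", cols < mid_col), ("right", cols >= mid_col)):
        lmask = mask.copy()
        lmask[:, :, ~sel] = False
        if not lmask.any():
            raise GeometryError(f"no {lung} lung voxels in the mask")
        pos = np.where(lmask.any(axis=tuple(i for i in range(3) if i != axis)))[0]
        lo, hi = pos.min(), pos.max() + 1
        bounds = np.linspace(lo, hi, 4).round().astype(int)
        for name, (a, b) in zip(("upper", "middle", "lower"),
                                zip(bounds[:-1], bounds[1:])):
            seg = lmask.copy()
            keep = np.zeros(hu.shape[axis], dtype=bool)
            keep[a:b] = True
            seg = seg & np.expand_dims(
                keep, tuple(i for i in range(3) if i != axis))
            if not seg.any():
                raise GeometryError(f"empty MLD segment {lung}/{name}")
            mld = float(hu[seg].mean())
            report.segments.append(MLDSegment(
                lung=lung, segment=name, mld_hu=mld,
                emphysema_flag=mld < cutoff_hu))
    return report
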