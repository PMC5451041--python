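"""Digital thorax phantom with a gravity-like lung-density gradient.

The phantom is an axial thorax section on an isotropic voxel grid: an
elliptical body with a subcutaneous fat layer, two elliptical lungs, a
posterior-medial spine and optional rib arcs.  Lung Hounsfield units rise
from anterior to posterior, emulating the dependent-density gradient seen in
supine end-expiratory CT; the three depth bands (anterior / middle /
posterior) hit configurable mean HU targets exactly at zero noise.

Co-registered HU, activity-concentration and tissue-label volumes are
produced from one configuration, so the attenuation ground truth and the
emission ground truth are consistent by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError

# tissue label codes
AIR = 0
LUNG_LEFT = 1
LUNG_RIGHT = 2
FAT = 3
SOFT = 4
BONE = 5

LABEL_NAMES = {
    AIR: "air",
    LUNG_LEFT: "lung_left",
    LUNG_RIGHT: "lung_right",
    FAT: "fat",
    SOFT: "soft",
    BONE: "bone",
}

HU_MIN, HU_MAX = -1000.0, 3071.0


@dataclass(frozen=True)
class BoneGeometry:
    """Spine cylinder plus rib arc, all sizes in mm.

    The spine sits posterior-medial, adjacent to the posterior lung bands;
    ribs are small circles placed on an ellipse just inside the fat layer,
    over the lateral-posterior arc only (the anterior chest wall carries
    little bone in the imaged section).
    """

    enabled: bool = True
    spine_radius_mm: float = 20.0
    spine_center_ap_mm: float = 78.0  # posterior offset from grid centre
    rib_radius_mm: float = 5.0
    n_ribs_per_side: int = 4
    rib_arc_deg: tuple[float, float] = (95.0, 185.0)  # from anterior midline


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to generate one phantom, reproducibly.

    HU band targets default to the regional lung means of supine
    end-expiratory chest CT (anterior -779, middle -746, posterior -685 HU);
    the activity map is uniform within each tissue class, expressed as the
    standardized-uptake value the class should read, so that a perfectly
    corrected reconstruction recovers a flat lung at ``lung_suv``.
    """

    grid_size: int = 256
    n_slices: int = 1
    voxel_spacing_mm: float = 2.6

    # lung HU depth-band targets (anterior -> posterior)
    lung_hu_anterior: float = -779.0
    lung_hu_middle: float = -746.0
    lung_hu_posterior: float = -685.0
    gradient_model: str = "linear"  # "linear" or "uniform" (middle HU only)
    hu_noise_sd: float = 20.0

    soft_tissue_hu: float = 40.0
    fat_hu: float = -90.0
    bone_hu: float = 700.0

    # geometry, all mm, semi-axes
    body_halfwidth_mm: float = 160.0
    body_halfdepth_mm: float = 115.0
    fat_thickness_mm: float = 12.0
    lung_halfwidth_mm: float = 48.0
    lung_halfdepth_mm: float = 75.0
    lung_center_lateral_mm: float = 55.0
    lung_center_ap_mm: float = -8.0  # slightly anterior of grid centre
    bone_geometry: BoneGeometry = field(default_factory=BoneGeometry)

    # activity (target SUV per tissue class) and scaling
    lung_activity: float = 0.4
    soft_activity: float = 1.0
    fat_activity: float = 0.3
    bone_activity: float = 0.5
    # optional residual anterior->posterior true-uptake gradient inside the
    # lung: +g means the posterior lung edge is (1+g) times the anterior edge
    activity_gradient: float = 0.0

    subject_weight_g: float = 70_000.0
    injected_dose_bq: float = 3.5e8

    rng_seed: int = 0

    def validate(self) -> None:
        if self.grid_size < 64:
            raise ConfigurationError("grid_size must be >= 64")
        if self.voxel_spacing_mm <= 0:
            raise ConfigurationError("voxel_spacing_mm must be > 0")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if self.gradient_model not in ("linear", "uniform"):
            raise ConfigurationError(
                f"unknown gradient_model {self.gradient_model!r}")
        hus = (self.lung_hu_anterior, self.lung_hu_middle,
               self.lung_hu_posterior, self.soft_tissue_hu, self.fat_hu,
               self.bone_hu)
        for hu in hus:
            if not (HU_MIN <= hu <= HU_MAX):
                raise ConfigurationError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
        if (self.gradient_model == "linear"
                and not (self.lung_hu_anterior <= self.lung_hu_posterior)):
            raise ConfigurationError(
                "dependent lung density requires anterior HU <= posterior HU")
        if self.hu_noise_sd < 0:
            raise ConfigurationError("hu_noise_sd must be >= 0")
        if self.subject_weight_g <= 0 or self.injected_dose_bq <= 0:
            raise ConfigurationError("weight and dose must be positive")
        fov = self.grid_size * self.voxel_spacing_mm
        if 2 * self.body_halfwidth_mm >= fov or 2 * self.body_halfdepth_mm >= fov:
            raise ConfigurationError("body does not fit in the field of view")

    @property
    def dose_per_weight(self) -> float:
        """Injected dose per body mass, Bq/g — the SUV normalisation."""
        return self.injected_dose_bq / self.subject_weight_g

    def scaled(self, factor: float) -> "PhantomConfig":
        """Uniformly scale the in-plane anatomy (desk-scale phantoms)."""
        bg = self.bone_geometry
        return dataclasses.replace(
            self,
            body_halfwidth_mm=self.body_halfwidth_mm * factor,
            body_halfdepth_mm=self.body_halfdepth_mm * factor,
            fat_thickness_mm=self.fat_thickness_mm * factor,
            lung_halfwidth_mm=self.lung_halfwidth_mm * factor,
            lung_halfdepth_mm=self.lung_halfdepth_mm * factor,
            lung_center_lateral_mm=self.lung_center_lateral_mm * factor,
            lung_center_ap_mm=self.lung_center_ap_mm * factor,
            bone_geometry=dataclasses.replace(
                bg,
                spine_radius_mm=bg.spine_radius_mm * factor,
                spine_center_ap_mm=bg.spine_center_ap_mm * factor,
                rib_radius_mm=bg.rib_radius_mm * factor,
            ),
        )


def class_matched_config(**overrides) -> PhantomConfig:
    """Config whose continuous CT attenuation equals the 4-class values.

    Lung/fat/soft HU are set so the bilinear transform (below-break slope
    9.6e-5 cm^-1/HU anchored at -1000 HU) maps them exactly onto the
    segmentation-class attenuation coefficients, the lung gradient is turned
    off and bone is disabled: all four mu-map variants then coincide.  Used
    as the null-experiment control.
    """
    slope = 9.6e-5
    defaults = dict(
        lung_hu_anterior=0.0224 / slope - 1000.0,
        lung_hu_middle=0.0224 / slope - 1000.0,
        lung_hu_posterior=0.0224 / slope - 1000.0,
        gradient_model="uniform",
        fat_hu=0.0854 / slope - 1000.0,
        soft_tissue_hu=0.1 / slope - 1000.0,
        hu_noise_sd=0.0,
        bone_geometry=BoneGeometry(enabled=False),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@dataclass
class DigitalPhantom:
    """Co-registered HU, activity and label volumes plus their provenance.

    Volumes are shaped ``(n_slices, rows, cols)``; row index increases
    anterior -> posterior, column index runs across the patient (lower
    column = "left" by package convention).
    """

    hu_volume: np.ndarray        # HU
    activity_volume: np.ndarray  # Bq/mL
    label_volume: np.ndarray     # tissue codes
    config: PhantomConfig

    @property
    def spacing_mm(self) -> float:
        return self.config.voxel_spacing_mm

    @property
    def lung_mask(self) -> np.ndarray:
        return (self.label_volume == LUNG_LEFT) | (self.label_volume == LUNG_RIGHT)

    @property
    def body_mask(self) -> np.ndarray:
        return self.label_volume != AIR


def _grid_mm(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(row_mm, col_mm) coordinate grids, centred so that a column flip is an
    exact mirror (the centre sits at (N-1)/2 voxels)."""
    n = config.grid_size
    idx = (np.arange(n) - (n - 1) / 2.0) * config.voxel_spacing_mm
    return np.meshgrid(idx, idx, indexing="ij")


def _in_ellipse(r, c, center_r, center_c, a_r, a_c):
    return ((r - center_r) / a_r) ** 2 + ((c - center_c) / a_c) ** 2 <= 1.0


def _lung_depth_profile(config: PhantomConfig):
    """Continuous piecewise-linear HU(f), f in [0, 1] anterior->posterior.

    Three equal-depth bands; slopes are solved so each band's *mean* equals
    its target exactly (the targets need not be collinear), with the free
    parameter fixed by s2 = (s1 + s3) / 2, which also keeps the profile
    continuous at the band boundaries.
    """
    t1, t2, t3 = (config.lung_hu_anterior, config.lung_hu_middle,
                  config.lung_hu_posterior)
    s2 = 1.5 * (t3 - t1)
    s1 = 6.0 * (t2 - t1) - s2
    s3 = 6.0 * (t3 - t2) - s2

    def profile(f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        out = np.empty_like(f)
        b1 = f < 1.0 / 3.0
        b3 = f >= 2.0 / 3.0
        b2 = ~(b1 | b3)
        out[b1] = t1 + s1 * (f[b1] - 1.0 / 6.0)
        out[b2] = t2 + s2 * (f[b2] - 0.5)
        out[b3] = t3 + s3 * (f[b3] - 5.0 / 6.0)
        return out

    return profile


def generate_thorax_phantom(config: PhantomConfig) -> DigitalPhantom:
    """Generate one phantom; bit-identical for a fixed config and seed."""
    config.validate()
    n = config.grid_size
    r_mm, c_mm = _grid_mm(config)

    body = _in_ellipse(r_mm, c_mm, 0.0, 0.0,
                       config.body_halfdepth_mm, config.body_halfwidth_mm)
    inner = _in_ellipse(r_mm, c_mm, 0.0, 0.0,
                        config.body_halfdepth_mm - config.fat_thickness_mm,
                        config.body_halfwidth_mm - config.fat_thickness_mm)
    lung_l = _in_ellipse(r_mm, c_mm, config.lung_center_ap_mm,
                         -config.lung_center_lateral_mm,
                         config.lung_halfdepth_mm, config.lung_halfwidth_mm)
    lung_r = _in_ellipse(r_mm, c_mm, config.lung_center_ap_mm,
                         config.lung_center_lateral_mm,
                         config.lung_halfdepth_mm, config.lung_halfwidth_mm)

    bone = np.zeros_like(body)
    bg = config.bone_geometry
    if bg.enabled:
        bone |= ((r_mm - bg.spine_center_ap_mm) ** 2 + c_mm ** 2
                 <= bg.spine_radius_mm ** 2)
        # ribs on an ellipse 8 mm inside the fat layer, lateral-posterior arc
        rib_a_c = config.body_halfwidth_mm - config.fat_thickness_mm - 8.0
        rib_a_r = config.body_halfdepth_mm - config.fat_thickness_mm - 8.0
        lo, hi = np.deg2rad(bg.rib_arc_deg)
        for phi in np.linspace(lo, hi, bg.n_ribs_per_side):
            rr = -rib_a_r * np.cos(phi)
            for sign in (-1.0, 1.0):
                cc = sign * rib_a_c * np.sin(phi)
                bone |= ((r_mm - rr) ** 2 + (c_mm - cc) ** 2
                         <= bg.rib_radius_mm ** 2)
        if np.any(bone & ~body):
            raise GeometryError("bone compartment exceeds the body contour")
        if np.any(bone & (lung_l | lung_r)):
            raise GeometryError("bone compartment intersects a lung")

    label2d = np.full((n, n), AIR, dtype=np.int8)
    label2d[body] = FAT
    label2d[inner] = SOFT
    label2d[lung_l] = LUNG_LEFT
    label2d[lung_r] = LUNG_RIGHT
    label2d[bone] = BONE
    if not np.all((lung_l | lung_r) <= inner):
        raise GeometryError("lungs exceed the inner body contour")

    # lung HU as a function of depth fraction within each lung's AP extent
    hu2d = np.full((n, n), HU_MIN)
    hu2d[label2d == FAT] = config.fat_hu
    hu2d[label2d == SOFT] = config.soft_tissue_hu
    hu2d[label2d == BONE] = config.bone_hu
    profile = _lung_depth_profile(config)
    for code, mask in ((LUNG_LEFT, label2d == LUNG_LEFT),
                       (LUNG_RIGHT, label2d == LUNG_RIGHT)):
        rows = np.where(mask.any(axis=1))[0]
        rmin, rmax = rows.min(), rows.max()
        rr, cc = np.where(mask)
        f = (rr - rmin) / max(rmax - rmin, 1)
        if config.gradient_model == "uniform":
            hu2d[rr, cc] = config.lung_hu_middle
        else:
            vals = profile(f)
            # the ellipse narrows with depth, so discrete band means drift a
            # little off target; re-centre each band exactly on its mean
            targets = (config.lung_hu_anterior, config.lung_hu_middle,
                       config.lung_hu_posterior)
            for band, target in enumerate(targets):
                sel = (f >= band / 3.0) & (f < (band + 1) / 3.0) \
                    if band < 2 else (f >= 2.0 / 3.0)
                if sel.any():
                    vals[sel] += target - vals[sel].mean()
            hu2d[rr, cc] = vals

    suv2d = np.zeros((n, n))
    suv2d[label2d == FAT] = config.fat_activity
    suv2d[label2d == SOFT] = config.soft_activity
    suv2d[label2d == BONE] = config.bone_activity
    lungs = (label2d == LUNG_LEFT) | (label2d == LUNG_RIGHT)
    if config.activity_gradient == 0.0:
        suv2d[lungs] = config.lung_activity
    else:
        rows = np.where(lungs.any(axis=1))[0]
        rr, cc = np.where(lungs)
        f = (rr - rows.min()) / max(rows.max() - rows.min(), 1)
        g = config.activity_gradient
        suv2d[rr, cc] = config.lung_activity * (1.0 + g * (f - 0.5))

    rng = np.random.default_rng(config.rng_seed)
    hu = np.repeat(hu2d[None], config.n_slices, axis=0).astype(float)
    noise = rng.normal(0.0, config.hu_noise_sd, size=hu.shape)
    body3 = np.repeat((label2d != AIR)[None], config.n_slices, axis=0)
    if config.hu_noise_sd > 0:
        hu[body3] += noise[body3]
        np.clip(hu, HU_MIN, HU_MAX, out=hu)

    label = np.repeat(label2d[None], config.n_slices, axis=0)
    activity = np.repeat(suv2d[None], config.n_slices, axis=0) \
        * config.dose_per_weight  # Bq/mL, 1 g/mL tissue density
    return DigitalPhantom(hu_volume=hu, activity_volume=activity,
                          label_volume=label, config=config)


def lung_band_masks(phantom: DigitalPhantom) -> dict[str, np.ndarray]:
    """Anterior/middle/posterior equal-depth thirds of the combined lungs,
    computed per lung from its own anterior-posterior extent."""
    bands = {k: np.zeros_like(phantom.lung_mask) for k in
             ("anterior", "middle", "posterior")}
    for code in (LUNG_LEFT, LUNG_RIGHT):
        mask = phantom.label_volume == code
        rows = np.where(mask.any(axis=(0, 2)))[0]
        rmin, rmax = rows.min(), rows.max()
        f = np.zeros(phantom.label_volume.shape[1])
        f[rmin:rmax + 1] = (np.arange(rmin, rmax + 1) - rmin) / max(rmax - rmin, 1)
        fvol = np.broadcast_to(f[None, :, None], mask.shape)
        bands["anterior"] |= mask & (fvol < 1 / 3)
        bands["middle"] |= mask & (fvol >= 1 / 3) & (fvol < 2 / 3)
        bands["posterior"] |= mask & (fvol >= 2 / 3)
    return bands


def mirror_symmetry_check(phantom: DigitalPhantom, tol_hu: float = 0.5) -> bool:
    """True iff the HU volume is invariant under a left-right column flip."""
    return mirror_asymmetry(phantom) <= tol_hu


def mirror_asymmetry(phantom: DigitalPhantom) -> float:
    """Max |HU - HU mirrored| over the volume."""
    return float(np.abs(phantom.hu_volume
                        - phantom.hu_volume[:, :, ::-1]).max())


def save_phantom(phantom: DigitalPhantom, out_dir: str | Path) -> None:
    """Write hu/activity/label volumes as NIfTI-1 plus a JSON truth sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = phantom.spacing_mm
    affine = np.diag([s, s, s, 1.0])
    for name, vol in (("hu", phantom.hu_volume),
                      ("activity", phantom.activity_volume),
                      ("labels", phantom.label_volume)):
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32).T, affine)
        nib.save(img, out / f"{name}.nii.gz")
    cfg = dataclasses.asdict(phantom.config)
    (out / "truth.json").write_text(json.dumps(cfg, indent=2))


def load_hu_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI HU volume; returns (volume (slices, rows, cols), spacing)."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float).T
    spacing = float(img.header.get_zooms()[0])
    if vol.ndim == 2:
        vol = vol[None]
    return vol, spacing
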