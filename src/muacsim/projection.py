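"""2-D parallel-beam projection model and scatter-free emission simulation.

The system model is an explicit sparse matrix per projection angle, built by
sampling each line of response (LOR) at sub-voxel steps with bilinear
interpolation.  Forward projection and backprojection are therefore exact
matrix transposes of each other — the adjoint identity holds to floating
point — which is what makes the EM updates and the attenuation physics
testable against closed forms.

Line integrals carry units of (image value) * mm; attenuation factors use
LACs in cm^-1, so the exponent divides the path integral by 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .attenuation import MuMap
from .errors import ConfigurationError, GeometryError, InputError


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam geometry over [0, pi).

    Defaults pair a 256-voxel image at 2.6 mm with 168 angles (divisible by
    the 21 OSEM subsets) and detector bins as wide as a voxel.
    """

    n_angles: int = 168
    n_bins: int = 256
    bin_width_mm: float = 2.6
    image_size: int = 256
    spacing_mm: float = 2.6
    step_frac: float = 0.5  # ray sampling step, fraction of a voxel

    def validate(self) -> None:
        if self.n_angles < 1 or self.n_bins < 1 or self.image_size < 1:
            raise ConfigurationError("geometry sizes must be positive")
        if self.bin_width_mm <= 0 or self.spacing_mm <= 0 or self.step_frac <= 0:
            raise ConfigurationError("geometry spacings must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def n_pixels(self) -> int:
        return self.image_size * self.image_size


@dataclass
class Sinogram:
    """Projection data shaped (n_angles, n_bins)."""

    values: np.ndarray
    geometry: ProjectionGeometry


@dataclass
class AttenuationFactors:
    """Per-LOR photon survival probabilities exp(-integral mu dl), in (0, 1]."""

    values: np.ndarray
    geometry: ProjectionGeometry


class Projector:
    """Matched ray-driven projector / backprojector for one geometry."""

    def __init__(self, geometry: ProjectionGeometry):
        geometry.validate()
        self.geometry = geometry
        self._mats = [self._angle_matrix(theta) for theta in geometry.angles]

    def _angle_matrix(self, theta: float) -> sparse.csr_matrix:
        g = self.geometry
        n = g.image_size
        s = (np.arange(g.n_bins) - (g.n_bins - 1) / 2.0) * g.bin_width_mm
        half = n * g.spacing_mm * np.sqrt(2.0) / 2.0
        h = g.step_frac * g.spacing_mm
        n_t = int(np.ceil(2.0 * half / h)) + 1
        t = (np.arange(n_t) - (n_t - 1) / 2.0) * h
        cos, sin = np.cos(theta), np.sin(theta)
        # sample points in mm, centred on the image centre
        u = s[:, None] * cos - t[None, :] * sin  # column axis
        v = s[:, None] * sin + t[None, :] * cos  # row axis
        c = u / g.spacing_mm + (n - 1) / 2.0
        r = v / g.spacing_mm + (n - 1) / 2.0
        r0 = np.floor(r).astype(np.int64)
        c0 = np.floor(c).astype(np.int64)
        fr, fc = r - r0, c - c0
        bins = np.broadcast_to(np.arange(g.n_bins)[:, None], r.shape)

        rows_l, cols_l, data_l = [], [], []
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)),
                          (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)),
                          (1, 1, fr * fc)):
            ri, ci = r0 + dr, c0 + dc
            ok = (ri >= 0) & (ri < n) & (ci >= 0) & (ci < n) & (w > 0)
            rows_l.append(bins[ok])
            cols_l.append(ri[ok] * n + ci[ok])
            data_l.append(w[ok] * h)
        mat = sparse.coo_matrix(
            (np.concatenate(data_l),
             (np.concatenate(rows_l), np.concatenate(cols_l))),
            shape=(g.n_bins, g.n_pixels))
        return mat.tocsr()

    def forward(self, image: np.ndarray,
                angle_idx: np.ndarray | None = None) -> np.ndarray:
        """Line integrals; returns (len(angle_idx), n_bins)."""
        g = self.geometry
        if image.shape != (g.image_size, g.image_size):
            raise GeometryError("image does not match projection geometry")
        idx = range(g.n_angles) if angle_idx is None else angle_idx
        x = image.ravel()
        return np.stack([self._mats[a] @ x for a in idx])

    def back(self, part: np.ndarray,
             angle_idx: np.ndarray | None = None) -> np.ndarray:
        """Adjoint of :meth:`forward`; returns an image."""
        g = self.geometry
        idx = list(range(g.n_angles)) if angle_idx is None else list(angle_idx)
        out = np.zeros(g.n_pixels)
        for row, a in zip(part, idx):
            out += self._mats[a].T @ row
        return out.reshape(g.image_size, g.image_size)


_PROJECTOR_CACHE: dict[ProjectionGeometry, Projector] = {}


def get_projector(geometry: ProjectionGeometry) -> Projector:
    """Projectors are expensive to build; cache one per geometry."""
    if geometry not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[geometry] = Projector(geometry)
    return _PROJECTOR_CACHE[geometry]


def forward_project(image: np.ndarray,
                    geometry: ProjectionGeometry) -> Sinogram:
    return Sinogram(get_projector(geometry).forward(image), geometry)


def attenuation_factors(mumap: MuMap,
                        geometry: ProjectionGeometry) -> AttenuationFactors:
    """Survival probability per LOR from a mu-map (LAC in cm^-1)."""
    mu = np.squeeze(mumap.lac_volume)
    if mu.ndim != 2:
        raise GeometryError("attenuation_factors expects a single-slice mu-map")
    if np.any(mu < 0):
        raise InputError("mu-map contains negative LACs")
    if not np.isclose(mumap.spacing_mm, geometry.spacing_mm):
        raise GeometryError("mu-map spacing does not match the geometry")
    path_cm = get_projector(geometry).forward(mu) / 10.0
    return AttenuationFactors(np.exp(-path_cm), geometry)


@dataclass
class EmissionData:
    """Simulated coincidence data for one slice plus its count calibration.

    ``count_scale`` converts line integrals (Bq/mL * mm) to expected counts;
    reconstruction divides by it to get back to concentration units.
    """

    counts: Sinogram
    count_scale: float
    af_true: AttenuationFactors


def simulate_emission(activity_image: np.ndarray, mumap_true: MuMap,
                      geometry: ProjectionGeometry, total_counts: float,
                      rng_seed: int | None = 0,
                      noise: bool = True) -> EmissionData:
    """Poisson emission data attenuated by the TRUE mu-map.

    The expected total over all LORs equals ``total_counts``; with
    ``noise=False`` the noise-free expectation is returned instead of a
    Poisson draw.
    """
    if total_counts <= 0:
        raise ConfigurationError("total_counts must be > 0")
    activity_image = np.squeeze(np.asarray(activity_image, dtype=float))
    if not np.any(activity_image > 0):
        raise ConfigurationError("activity volume is identically zero")
    proj = get_projector(geometry)
    expected = proj.forward(activity_image)
    af = attenuation_factors(mumap_true, geometry)
    expected = expected * af.values
    scale = total_counts / expected.sum()
    mean = scale * expected
    if noise:
        rng = np.random.default_rng(rng_seed)
        values = rng.poisson(mean).astype(float)
    else:
        values = mean
    return EmissionData(counts=Sinogram(values, geometry),
                        count_scale=scale, af_true=af)


def make_disc(image_size: int, spacing_mm: float, radius_mm: float,
              value: float = 1.0, center_mm: tuple[float, float] = (0.0, 0.0),
              supersample: int = 4) -> np.ndarray:
    """Anti-aliased disc image (edge voxels get partial-area weights)."""
    n = image_size * supersample
    idx = (np.arange(n) - (n - 1) / 2.0) * spacing_mm / supersample
    r, c = np.meshgrid(idx, idx, indexing="ij")
    fine = ((r - center_mm[0]) ** 2 + (c - center_mm[1]) ** 2
            <= radius_mm ** 2).astype(float)
    coarse = fine.reshape(image_size, supersample,
                          image_size, supersample).mean(axis=(1, 3))
    return value * coarse
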