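"""End-to-end four-arm attenuation-correction experiment.

For each synthetic subject: generate a phantom, build the four mu-map
variants, simulate emission data attenuated by the TRUE (CT-derived)
mu-map, reconstruct the same data four times — once per attenuation-
correction arm — scale to SUV, place the 12-ROI scheme once on the grown
lung mask and apply it to every arm, and pool regional statistics across
subjects.

Subjects are i.i.d. phantom draws (fresh HU noise plus a small geometric
jitter of the anatomy).  Their spread emulates scan-to-scan variability
only; it is NOT comparable to inter-patient spread in a clinical cohort,
and the reports label it accordingly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attenuation as att
from . import phantom as ph
from . import projection as prj
from . import recon as rc
from . import regional as reg
from .errors import ConfigurationError

ARMS = att.VARIANTS  # ("CTAC", "CTAC_MRLUNG", "CTAC_MRLUNG_NOBONE", "MRAC")


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: ph.PhantomConfig = field(default_factory=ph.PhantomConfig)
    bilinear: att.BilinearTransformParams = field(
        default_factory=att.BilinearTransformParams)
    lacs: att.TissueClassLACs = field(default_factory=att.TissueClassLACs)
    recon: rc.ReconConfig = field(default_factory=rc.ReconConfig)
    n_angles: int = 168
    n_subjects: int = 5
    total_counts: float = 1.0e7  # expected counts per slice
    poisson_noise: bool = True
    geometry_jitter: float = 0.02  # SD of the per-subject anatomy scale
    seed: int = 0

    def validate(self) -> None:
        self.phantom.validate()
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.total_counts <= 0:
            raise ConfigurationError("total_counts must be > 0")
        if self.n_angles % self.recon.subsets != 0:
            raise ConfigurationError("subsets must divide n_angles")

    def geometry(self) -> prj.ProjectionGeometry:
        p = self.phantom
        return prj.ProjectionGeometry(
            n_angles=self.n_angles, n_bins=p.grid_size,
            bin_width_mm=p.voxel_spacing_mm, image_size=p.grid_size,
            spacing_mm=p.voxel_spacing_mm)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: int
    seed: int
    measurements: list[reg.ROIMeasurement]
    regional: reg.RegionalReport
    mld: reg.MLDReport
    qc_fraction_within: float
    hu_band_means: dict[str, float]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    config_hash: str
    subject_seeds: list[int]
    subjects: list[SubjectResult]
    pooled: reg.RegionalReport

    @property
    def arms(self) -> tuple[str, ...]:
        return self.pooled.variants


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_subject(config: ExperimentConfig, subject_id: int,
                seed: int) -> SubjectResult:
    rng = np.random.default_rng(seed)
    jitter = 1.0 + config.geometry_jitter * rng.standard_normal() \
        if config.geometry_jitter > 0 else 1.0
    pconf = dataclasses.replace(config.phantom.scaled(jitter),
                                rng_seed=int(rng.integers(2 ** 31)))
    phantom = ph.generate_thorax_phantom(pconf)

    mumaps, lung_mask = att.build_all_mumaps(phantom, config.bilinear,
                                             config.lacs)
    qc = att.mumap_difference_histogram(
        mumaps["CTAC_MRLUNG_NOBONE"], mumaps["MRAC"], phantom.body_mask,
        lacs=config.lacs)

    geometry = config.geometry()
    rois = reg.place_rois(lung_mask, phantom.spacing_mm)

    n_slices = phantom.hu_volume.shape[0]
    suv_per_arm = {arm: [] for arm in ARMS}
    for sl in range(n_slices):
        em = prj.simulate_emission(
            phantom.activity_volume[sl], _slice_map(mumaps["CTAC"], sl),
            geometry, config.total_counts,
            rng_seed=int(rng.integers(2 ** 31)), noise=config.poisson_noise)
        for arm in ARMS:
            af = prj.attenuation_factors(_slice_map(mumaps[arm], sl), geometry)
            img = rc.osem_reconstruct(em.counts, af, config.recon)
            suv = rc.suv_scale(img, pconf.injected_dose_bq,
                               pconf.subject_weight_g, em.count_scale,
                               pconf.voxel_spacing_mm)
            suv_per_arm[arm].append(suv.values)
    suv_vols = {arm: np.stack(v) for arm, v in suv_per_arm.items()}

    measurements = []
    for roi in rois:
        measurements.append(reg.ROIMeasurement(
            roi=roi,
            suv_mean={arm: reg.roi_mean(suv_vols[arm], roi,
                                        phantom.spacing_mm) for arm in ARMS},
            hu_mean=reg.roi_mean(phantom.hu_volume, roi, phantom.spacing_mm)))

    bands = ph.lung_band_masks(phantom)
    hu_band_means = {k: float(phantom.hu_volume[m].mean())
                     for k, m in bands.items()}
    return SubjectResult(
        subject_id=subject_id, seed=seed, measurements=measurements,
        regional=reg.regional_summary(measurements),
        mld=reg.mld_screen(phantom.hu_volume, lung_mask),
        qc_fraction_within=qc.fraction_within,
        hu_band_means=hu_band_means)


def _slice_map(mumap: att.MuMap, sl: int) -> att.MuMap:
    return att.MuMap(mumap.lac_volume[sl], mumap.spacing_mm, mumap.variant)


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentReport:
    """Run the full cohort; fully deterministic given the config seed."""
    config = config or ExperimentConfig()
    config.validate()
    seeds = _subject_seeds(config.seed, config.n_subjects)
    subjects = [run_subject(config, i, s) for i, s in enumerate(seeds)]
    pooled = reg.regional_summary(
        [m for s in subjects for m in s.measurements])
    return ExperimentReport(config=config, config_hash=config.config_hash(),
                            subject_seeds=seeds, subjects=subjects,
                            pooled=pooled)


# ---------------------------------------------------------------- tables ---

def report_to_tables(report: ExperimentReport,
                     out_dir: str | Path | None = None
                     ) -> dict[str, pd.DataFrame]:
    """Flatten the pooled report into three tables: regional lung HU,
    regional SUVmean per arm, and relative differences per arm vs CTAC.
    Spread columns are across pooled ROIs of synthetic subjects, not across
    patients."""
    if not report.subjects:
        raise ConfigurationError("report contains no subjects")
    pooled = report.pooled

    hu_rows = [{"region": p,
                "hu_mean": float(pooled.hu_by_region[p].mean()),
                "hu_sd": float(pooled.hu_by_region[p].std(ddof=1)),
                "n_rois": int(pooled.hu_by_region[p].size)}
               for p in reg.POSITIONS]
    table_hu = pd.DataFrame(hu_rows)

    suv_rows = []
    for arm in pooled.variants:
        row = {"arm": arm}
        for p in reg.POSITIONS:
            m, sd = pooled.suv_mean_sd(p, arm)
            row[f"suv_{p}"], row[f"sd_{p}"] = m, sd
        row["p_anterior_posterior"] = pooled.anterior_posterior_pvalue(arm)
        suv_rows.append(row)
    table_suv = pd.DataFrame(suv_rows)

    rel_rows = []
    for arm in pooled.variants:
        if arm == pooled.reference:
            continue
        row = {"arm": arm, "reference": pooled.reference}
        for p in reg.POSITIONS:
            m, sd = pooled.reldiff_mean_sd(p, arm)
            row[f"reldiff_{p}_pct"], row[f"sd_{p}"] = m, sd
        rel_rows.append(row)
    table_rel = pd.DataFrame(rel_rows)

    tables = {"table_hu": table_hu, "table_suv": table_suv,
              "table_reldiff": table_rel}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        meta = {"config_hash": report.config_hash,
                "subject_seeds": report.subject_seeds,
                "n_subjects": len(report.subjects),
                "qc_fraction_within":
                    [s.qc_fraction_within for s in report.subjects],
                "mld_flagged": [s.mld.n_flagged for s in report.subjects]}
        (out / "report.json").write_text(json.dumps(meta, indent=2))
    return tables
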