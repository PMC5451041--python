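#!/usr/bin/env python
"""Run the default five-subject cohort and write the pooled tables.

This is the headline analysis: per subject, four attenuation-correction
arms are reconstructed from one emission data set and twelve 1 cm lung
ROIs are read on every arm.  The pooled tables give regional lung HU,
regional SUVmean per arm, and the per-ROI relative differences of each
segmentation-style arm against the CT-corrected reference — the
anterior-overestimation / posterior-underestimation pattern and the extra
posterior drop after bone stripping.
"""

from pathlib import Path

import muacsim as m

OUT = Path("results/cohort")


def main() -> None:
    config = m.ExperimentConfig(seed=1)
    report = m.run_experiment(config)
    tables = m.report_to_tables(report, OUT)

    print(f"config hash {report.config_hash}; "
          f"subject seeds {report.subject_seeds}\n")
    print("regional lung HU (pooled ROIs):")
    print(tables["table_hu"].round(1).to_string(index=False))
    print("\nregional SUVmean per arm:")
    print(tables["table_suv"].round(4).to_string(index=False))
    print("\nrelative differences vs CTAC (%):")
    print(tables["table_reldiff"].round(2).to_string(index=False))
    print("\nemphysema screen: "
          f"{sum(s.mld.n_flagged for s in report.subjects)} of "
          f"{6 * len(report.subjects)} lung segments below -950 HU")
    print("mu-map QC fraction within 10% of soft LAC per subject: "
          + ", ".join(f"{s.qc_fraction_within:.3f}" for s in report.subjects))


if __name__ == "__main__":
    main()
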