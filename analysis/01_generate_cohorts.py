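#!/usr/bin/env python
"""Generate the synthetic study cohorts and characterize them.

Builds the Gaussian-marginal and skewed-marginal null pools used throughout
the analyses and summarizes the properties that matter downstream: pooled
voxel skewness, neighbouring-voxel correlation (smoothness), per-subject
global variation, and the age/gender covariate distributions.

Writes results/cohort_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from solocase.synthdata import CohortSpec, ellipsoid_mask, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def summarize(name: str, spec: CohortSpec) -> dict:
    images, cov = generate_cohort(spec)
    support = ellipsoid_mask(spec.grid_shape).include
    pooled = np.concatenate([im.values[support] for im in images])
    pair = support[:-1] & support[1:]
    lag1 = np.mean(
        [np.corrcoef(im.values[:-1][pair], im.values[1:][pair])[0, 1] for im in images]
    )
    globals_ = [im.values[support].mean() for im in images]
    return {
        "cohort": name,
        "n_subjects": spec.n_subjects,
        "smoothing_fwhm_mm": spec.smoothing_fwhm,
        "marginal": spec.marginal,
        "skew_param": spec.skew,
        "pooled_skewness": stats.skew(pooled),
        "lag1_voxel_corr": lag1,
        "global_cv": np.std(globals_) / np.mean(globals_),
        "age_mean": cov["age"].mean(),
        "age_sd": cov["age"].std(ddof=1),
        "prop_gender_1": cov["gender"].mean(),
    }


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for fwhm in (4.0, 8.0, 12.0):
        rows.append(summarize(
            f"gaussian-{fwhm:g}mm", CohortSpec(smoothing_fwhm=fwhm, seed=0)
        ))
    rows.append(summarize(
        "skewed-8mm", CohortSpec(marginal="skewed", skew=0.5, seed=0)
    ))
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "cohort_summary.csv", index=False)
    print(table.round(3).to_string(index=False))
    print(
        "\nSmoothing raises the lag-1 voxel correlation "
        f"({table['lag1_voxel_corr'].iloc[0]:.2f} at 4 mm to "
        f"{table['lag1_voxel_corr'].iloc[2]:.2f} at 12 mm); the skewed regime "
        f"has pooled skewness {table['pooled_skewness'].iloc[-1]:.2f} versus "
        f"{table['pooled_skewness'].iloc[1]:.2f} for the Gaussian regime."
    )


if __name__ == "__main__":
    main()
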