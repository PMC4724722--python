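#!/usr/bin/env python
"""Permutation-engine false-positive-rate experiment.

Runs scaled-down single-case permutation comparisons on Gaussian null cohorts
across three smoothing levels (modulated) plus the 8 mm unmodulated condition,
then reports the per-condition family-wise error rates with their Monte Carlo
bands, the logistic regressions of the error flag on smoothing/modulation/
direction with Hosmer-Lemeshow fit tests, and the localization of false
positives over the synthetic region partition.

Writes results/permutation/{table1,table2,logistic}.csv and results.json.
"""

import time
from pathlib import Path

from solocase.fprharness import ExperimentConfig, run_fpr_experiment
from solocase.io import write_report
from solocase.synthdata import CohortSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "permutation"

#: scaled-down problem size: 40 comparisons per condition, 60-subject pool,
#: 40 controls per comparison (41 relabelings)
CONFIG = ExperimentConfig(
    m_comparisons=40,
    pool_size=60,
    control_group_size=40,
    alpha=0.05,
    conditions=((4.0, "modulated"), (8.0, "modulated"),
                (12.0, "modulated"), (8.0, "unmodulated")),
    engine="permutation",
    cohort_spec=CohortSpec(grid_shape=(18, 18, 18)),
    n_regions=8,
    seed=1,
)


def main() -> None:
    t0 = time.time()
    result = run_fpr_experiment(CONFIG)
    write_report(result, OUT)

    print(f"ran {CONFIG.m_comparisons} comparisons x {len(CONFIG.conditions)} "
          f"conditions in {time.time() - t0:.0f}s\n")
    t = result.condition_table
    for _, r in t.iterrows():
        print(f"  {r['condition_tag']:>11s} {r['smoothing_fwhm']:>4g} mm "
              f"{r['direction']:<8s} FWER {r['fwer_pct']:5.1f}% "
              f"(band {r['ci_lo_pct']:.1f}-{r['ci_hi_pct']:.1f}%)")
    inside = ((t["fwer_pct"] >= t["ci_lo_pct"]) & (t["fwer_pct"] <= t["ci_hi_pct"])).sum()
    print(f"\n{inside}/{len(t)} condition-direction cells inside their 95% band.")

    for name, fit in (("smoothing+direction", result.logistic_smoothing),
                      ("modulation+direction", result.logistic_modulation)):
        if fit is None:
            print(f"logistic model ({name}): not fit (degenerate outcomes)")
            continue
        ps = ", ".join(f"{k} p={v:.3f}" for k, v in fit.wald_p.items())
        print(f"logistic model ({name}): {ps}; Hosmer-Lemeshow p={fit.hl_p:.3f}")

    print(f"\nfalse-positive peaks by region written to table2.csv; "
          f"Spearman volume-vs-count rho={result.spearman_rho:.2f} "
          f"p={result.spearman_p:.2f}"
          + (" (degenerate: constant counts)" if result.spearman_degenerate else ""))


if __name__ == "__main__":
    main()
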