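#!/usr/bin/env python
"""Parametric versus non-parametric inference on the same skewed null data.

Runs paired experiments (identical pools, cases and control draws) with the
random-field-theory engine and the permutation engine on skewed-marginal null
cohorts, plus the parametric engine on Gaussian nulls as a control condition.
The skewed case is where the single-case t-test's normality assumption fails:
the parametric increase-direction FWER inflates far above the 95% Monte Carlo
band while the exact permutation test stays inside it.

Writes results/parametric/inflation.csv.
"""

import time
from pathlib import Path

import pandas as pd

from solocase.fprharness import ExperimentConfig, run_fpr_experiment
from solocase.synthdata import CohortSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "parametric"

COMMON = dict(
    m_comparisons=50,
    pool_size=70,
    control_group_size=50,
    alpha=0.05,
    conditions=((8.0, "modulated"),),
    cohort_spec=CohortSpec(),
    seed=1,
)


def run(engine: str, marginal: str) -> list[dict]:
    spec = CohortSpec() if marginal == "gaussian" else CohortSpec(marginal="skewed", skew=0.5)
    cfg = ExperimentConfig(engine=engine, **{**COMMON, "cohort_spec": spec})
    res = run_fpr_experiment(cfg)
    rows = []
    for _, r in res.condition_table.iterrows():
        rows.append({
            "engine": engine,
            "marginal": marginal,
            "direction": r["direction"],
            "fwer_pct": r["fwer_pct"],
            "fwe_count": int(r["fwe_count"]),
            "m": int(r["m"]),
            "band_lo_pct": r["ci_lo_pct"],
            "band_hi_pct": r["ci_hi_pct"],
        })
    return rows


def main() -> None:
    t0 = time.time()
    rows = []
    rows += run("parametric", "gaussian")
    rows += run("parametric", "skewed")
    rows += run("permutation", "skewed")
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "inflation.csv", index=False)

    print(table.to_string(index=False))
    sk = table[(table["marginal"] == "skewed") & (table["direction"] == "increase")]
    par = sk[sk["engine"] == "parametric"]["fwer_pct"].iloc[0]
    perm = sk[sk["engine"] == "permutation"]["fwer_pct"].iloc[0]
    print(f"\nSkewed nulls, increases: parametric FWER {par:.0f}% vs "
          f"permutation {perm:.0f}% (band upper limit "
          f"{sk['band_hi_pct'].iloc[0]:.1f}%) — the parametric single-case test "
          f"inflates under non-normality; the permutation test does not. "
          f"({time.time() - t0:.0f}s)")


if __name__ == "__main__":
    main()
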