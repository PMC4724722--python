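"""False-positive-rate experiment: repeated null single-case comparisons.

Runs M one-vs-N single-case comparisons per condition (smoothing level x
modulation tag) on a null cohort, counts family-wise errors per direction,
attaches the Monte Carlo confidence band around the nominal level, fits
logistic regressions of the error flag on smoothing/modulation/direction with
Hosmer-Lemeshow goodness-of-fit tests, and localizes false-positive peaks over
a synthetic region partition with a Spearman volume-vs-count correlation.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .npperm import single_case_permutation_test
from .records import ComparisonRecord
from .rftpar import parametric_compare
from .synthdata import (
    BrainMask,
    CohortSpec,
    RegionPartition,
    ellipsoid_mask,
    generate_cohort,
    make_partition,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "LogisticFit",
    "SeparationError",
    "spec_for_condition",
    "run_fpr_experiment",
    "monte_carlo_ci",
    "fit_fwe_logistic",
    "hosmer_lemeshow",
    "localize_false_positives",
    "volume_count_correlation",
]

#: marginal intensity amplitude by condition tag — the "modulation" factor is a
#: generator parameterization, not a deformation-based operation
TAG_AMPLITUDE = {"modulated": 0.20, "unmodulated": 0.15}

DEFAULT_CONDITIONS = (
    (4.0, "modulated"),
    (8.0, "modulated"),
    (12.0, "modulated"),
    (8.0, "unmodulated"),
)

_ENGINES = {
    "permutation": single_case_permutation_test,
    "parametric": parametric_compare,
}


logger = logging.getLogger("solocase.fprharness")


class SeparationError(RuntimeError):
    """Logistic regression failed due to (quasi-)complete separation."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one false-positive-rate experiment."""

    m_comparisons: int = 100
    pool_size: int = 120
    control_group_size: int = 100
    alpha: float = 0.05
    conditions: tuple = DEFAULT_CONDITIONS
    engine: str = "permutation"
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    n_regions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_comparisons < 1:
            raise ValueError(f"m_comparisons must be >= 1, got {self.m_comparisons}")
        if self.control_group_size >= self.pool_size:
            raise ValueError(
                f"control_group_size ({self.control_group_size}) must be below "
                f"pool_size ({self.pool_size})"
            )
        if self.m_comparisons > self.pool_size:
            raise ValueError("m_comparisons cannot exceed pool_size (distinct cases)")
        if self.engine not in _ENGINES:
            raise ValueError(f"engine must be one of {sorted(_ENGINES)}, got {self.engine!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass
class LogisticFit:
    """Logistic regression of the FWE flag on experimental factors."""

    params: pd.Series
    wald_p: dict                 # factor -> joint Wald p-value
    hl_statistic: float
    hl_p: float
    factors: tuple
    n_obs: int
    llf: float


@dataclass
class ExperimentResult:
    """Aggregate of one experiment; a pure function of its config."""

    config: ExperimentConfig
    condition_table: pd.DataFrame
    records: list
    logistic_smoothing: LogisticFit | None
    logistic_modulation: LogisticFit | None
    localization: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    spearman_degenerate: bool
    partition: RegionPartition
    failures: list


def spec_for_condition(
    base: CohortSpec, smoothing_fwhm: float, condition_tag: str, seed: int
) -> CohortSpec:
    """Cohort spec for one experimental condition.

    The condition tag selects the generator parameterization (marginal
    amplitude); the smoothing level sets the field FWHM.
    """
    return base.replace(
        smoothing_fwhm=float(smoothing_fwhm),
        condition_tag=condition_tag,
        amplitude=TAG_AMPLITUDE[condition_tag],
        seed=seed,
    )


def monte_carlo_ci(p0: float, m: int) -> tuple[float, float]:
    """95% normal-approximation band (in %) for an empirical rate at m trials.

    ``100 (p0 +/- 1.96 sqrt(p0 (1 - p0) / m))``, floored at 0. For the nominal
    5% level and 100 comparisons this is (0.7%, 9.3%).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    half = 1.96 * np.sqrt(p0 * (1.0 - p0) / m)
    return (max(0.0, 100.0 * (p0 - half)), 100.0 * (p0 + half))


def run_fpr_experiment(config: ExperimentConfig, on_result=None) -> ExperimentResult:
    """Run the full false-positive-rate experiment.

    Per condition: generate a null pool once, then for each comparison take a
    distinct case and draw the control group without replacement from the
    remaining pool (controls are shared across comparisons, as in a fixed
    volunteer pool). Runs the configured engine, counts per-direction
    family-wise errors, and attaches confidence bands, logistic regressions and
    peak localization. Engine failures are recorded per comparison; the run
    aborts only if more than 10% of comparisons fail.

    ``on_result``, if given, is called with each comparison's
    :class:`~solocase.records.SingleCaseResult` (for auditing p-maps etc.);
    it does not affect the aggregate.
    """
    engine = _ENGINES[config.engine]
    master = np.random.SeedSequence(config.seed)
    cond_streams = master.spawn(len(config.conditions))

    records: list[ComparisonRecord] = []
    failures: list[tuple[str, str]] = []
    rows = []
    total = 0
    for (fwhm, tag), stream in zip(config.conditions, cond_streams):
        pool_seed_ss, sample_ss = stream.spawn(2)
        pool_seed = int(pool_seed_ss.generate_state(1)[0] % (2**31))
        spec = spec_for_condition(
            config.cohort_spec.replace(n_subjects=config.pool_size),
            fwhm, tag, pool_seed,
        )
        pool, _ = generate_cohort(spec)
        rng = np.random.Generator(np.random.Philox(sample_ss))
        case_ids = rng.permutation(config.pool_size)[: config.m_comparisons]
        cond_records: list[ComparisonRecord] = []
        for i, case_idx in enumerate(case_ids):
            total += 1
            cid = f"{config.engine}-{tag}-{fwhm:g}mm-{i:03d}"
            others = np.delete(np.arange(config.pool_size), case_idx)
            ctrl_idx = rng.choice(others, size=config.control_group_size, replace=False)
            t_start = time.perf_counter()
            try:
                result = engine(
                    pool[case_idx],
                    [pool[j] for j in ctrl_idx],
                    alpha=config.alpha,
                    smoothing_fwhm=fwhm,
                    condition_tag=tag,
                    comparison_id=cid,
                )
            except Exception as exc:  # recorded, not fatal (unless >10% fail)
                failures.append((cid, repr(exc)))
                continue
            logger.debug(
                "%s: max_t=%.3f min_p=%.4f flags=%s %.2fs",
                cid,
                float(result.tmap.t_values.max()),
                float(min(result.p_increase.min(), result.p_decrease.min())),
                {r.direction: r.fwe_flag for r in result.records},
                time.perf_counter() - t_start,
            )
            if on_result is not None:
                on_result(result)
            cond_records.extend(result.records)
        records.extend(cond_records)
        m_ok = len(cond_records) // 2
        for direction in ("increase", "decrease"):
            sub = [r for r in cond_records if r.direction == direction]
            count = sum(r.fwe_flag for r in sub)
            n_peaks = sum(len(r.peaks) for r in sub)
            lo, hi = monte_carlo_ci(config.alpha, max(m_ok, 1)) if 0 < config.alpha < 1 else (0.0, 100.0)
            rows.append(
                {
                    "smoothing_fwhm": fwhm,
                    "condition_tag": tag,
                    "direction": direction,
                    "m": m_ok,
                    "fwe_count": count,
                    "n_peaks": n_peaks,
                    "fwer_pct": 100.0 * count / m_ok if m_ok else np.nan,
                    "ci_lo_pct": lo,
                    "ci_hi_pct": hi,
                }
            )
    if total and len(failures) > 0.1 * total:
        raise RuntimeError(
            f"{len(failures)}/{total} comparisons failed; first: {failures[0]}"
        )
    condition_table = pd.DataFrame(rows)

    logistic_smoothing = _try_fit(records, ("smoothing", "direction"), tag="modulated")
    logistic_modulation = _try_fit_modulation(records, config)

    support = ellipsoid_mask(config.cohort_spec.grid_shape)
    partition = make_partition(support, config.cohort_spec.voxel_size, config.n_regions)
    localization = localize_false_positives(records, partition)
    rho, p, degenerate = volume_count_correlation(localization)

    return ExperimentResult(
        config=config,
        condition_table=condition_table,
        records=records,
        logistic_smoothing=logistic_smoothing,
        logistic_modulation=logistic_modulation,
        localization=localization,
        spearman_rho=rho,
        spearman_p=p,
        spearman_degenerate=degenerate,
        partition=partition,
        failures=failures,
    )


def _try_fit(records, factors, tag=None):
    sub = [r for r in records if tag is None or r.condition_tag == tag]
    smoothings = {r.smoothing_fwhm for r in sub}
    if "smoothing" in factors and len(smoothings) < 2:
        return None
    try:
        return fit_fwe_logistic(sub, factors)
    except (SeparationError, ValueError):
        return None


def _try_fit_modulation(records, config):
    # modulation model uses the smoothing level shared by both tags
    by_tag = {}
    for r in records:
        by_tag.setdefault(r.condition_tag, set()).add(r.smoothing_fwhm)
    shared = set.intersection(*by_tag.values()) if len(by_tag) == 2 else set()
    if not shared:
        return None
    sub = [r for r in records if r.smoothing_fwhm in shared]
    try:
        return fit_fwe_logistic(sub, ("modulation", "direction"))
    except (SeparationError, ValueError):
        return None


def _design_from_records(records, factors):
    df = pd.DataFrame(
        {
            "fwe": [int(r.fwe_flag) for r in records],
            "smoothing": [r.smoothing_fwhm for r in records],
            "direction": [1 if r.direction == "increase" else 0 for r in records],
            "modulation": [1 if r.condition_tag == "modulated" else 0 for r in records],
        }
    )
    cols = {}
    groups = {}
    for factor in factors:
        if factor == "smoothing":
            levels = sorted(df["smoothing"].unique())
            if len(levels) < 2:
                raise ValueError("smoothing factor needs >= 2 levels")
            names = []
            for lev in levels[1:]:  # smallest level is the reference
                name = f"smoothing_{lev:g}"
                cols[name] = (df["smoothing"] == lev).astype(float)
                names.append(name)
            groups[factor] = names
        elif factor in ("direction", "modulation"):
            if df[factor].nunique() < 2:
                raise ValueError(f"{factor} factor needs >= 2 levels")
            cols[factor] = df[factor].astype(float)
            groups[factor] = [factor]
        else:
            raise ValueError(f"unknown factor {factor!r}")
    X = pd.DataFrame(cols)
    X.insert(0, "intercept", 1.0)
    return df["fwe"].to_numpy(), X, groups


def _check_separation(y, X, groups):
    """Name a factor whose levels perfectly predict the outcome, if any."""
    for factor, names in groups.items():
        for name in names:
            col = X[name].to_numpy()
            for level in np.unique(col):
                yy = y[col == level]
                if len(yy) and len(np.unique(yy)) == 1 and len(np.unique(y)) > 1:
                    other = y[col != level]
                    if len(other) and np.all(~np.isin(yy[0], other)):
                        return factor
    return None


def fit_fwe_logistic(records, factors) -> LogisticFit:
    """Maximum-likelihood logistic regression of the FWE flag on factors.

    ``factors`` is a subset of {"smoothing", "direction", "modulation"}.
    Smoothing enters as a categorical factor with the smallest level as
    reference; its Wald p is the joint test that all its dummies are zero.
    Complete separation raises :class:`SeparationError` naming the factor;
    all-identical outcomes raise ``ValueError``.
    """
    if not records:
        raise ValueError("no records to fit")
    y, X, groups = _design_from_records(records, factors)
    if len(np.unique(y)) < 2:
        raise ValueError("outcomes are all identical; logistic model is undefined")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
    except Exception as exc:
        factor = _check_separation(y, X, groups)
        if factor is not None:
            raise SeparationError(f"complete separation on factor {factor!r}") from exc
        raise
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 15):
        factor = _check_separation(y, X, groups)
        raise SeparationError(
            f"logistic fit did not converge (separation on factor "
            f"{factor if factor else 'unknown'})"
        )
    cov = res.cov_params()
    wald_p = {}
    for factor, names in groups.items():
        b = res.params[names].to_numpy()
        V = cov.loc[names, names].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        wald_p[factor] = float(stats.chi2.sf(stat, len(names)))
    fitted = res.predict(X)
    hl_stat, hl_p = hosmer_lemeshow(y, fitted)
    return LogisticFit(
        params=res.params,
        wald_p=wald_p,
        hl_statistic=hl_stat,
        hl_p=hl_p,
        factors=tuple(factors),
        n_obs=len(y),
        llf=float(res.llf),
    )


def hosmer_lemeshow(outcomes, fitted_probs, g: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square over g groups of fitted risk.

    Observations are binned by quantiles of the fitted probability ("deciles
    of risk" for g = 10); the statistic sums ``(O - E)^2 / (E (1 - E/n))`` over
    groups and is referred to chi-square with (groups - 2) degrees of freedom.
    Groups with duplicated quantile edges are merged (with a warning).
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(fitted_probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("outcomes and fitted_probs must have the same length")
    if g < 2:
        raise ValueError(f"g must be >= 2, got {g}")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)))
    if len(edges) - 1 < g:
        warnings.warn(
            f"fewer distinct fitted values than groups; merged to {max(len(edges) - 1, 1)} groups",
            UserWarning,
            stacklevel=2,
        )
    if len(edges) == 1:  # all fitted probabilities identical: a single group
        n_g = len(y)
        o, e = y.sum(), p.sum()
        denom = e * (1.0 - e / n_g)
        statistic = 0.0 if denom <= 0 else float((o - e) ** 2 / denom)
        return statistic, float(stats.chi2.sf(statistic, 1))
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    statistic = 0.0
    n_groups = 0
    for k in range(len(edges) - 1):
        sel = idx == k
        n_g = int(sel.sum())
        if n_g == 0:
            continue
        n_groups += 1
        o = y[sel].sum()
        e = p[sel].sum()
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            if not np.isclose(o, e):
                statistic = np.inf
            continue
        statistic += (o - e) ** 2 / denom
    df = max(n_groups - 2, 1)
    return float(statistic), float(stats.chi2.sf(statistic, df))


def localize_false_positives(records, partition: RegionPartition) -> pd.DataFrame:
    """Tally false-positive peaks per region of the partition.

    Returns one row per region (plus an ``unassigned`` row when peaks fall
    outside the partition): raw peak count, percentage of all peaks, region
    volume in mm^3, and volume percentage.
    """
    counts = dict.fromkeys(partition.region_names, 0)
    unassigned = 0
    for rec in records:
        for pk in rec.peaks:
            label = int(partition.labels[pk.voxel])
            if label == 0:
                unassigned += 1
            else:
                counts[partition.region_names[label - 1]] += 1
    total = sum(counts.values()) + unassigned
    vol_total = float(partition.region_volumes_mm3.sum())
    rows = [
        {
            "region": name,
            "volume_mm3": float(vol),
            "volume_pct": 100.0 * float(vol) / vol_total,
            "count": counts[name],
            "count_pct": 100.0 * counts[name] / total if total else 0.0,
        }
        for name, vol in zip(partition.region_names, partition.region_volumes_mm3)
    ]
    if unassigned:
        rows.append(
            {
                "region": "unassigned",
                "volume_mm3": np.nan,
                "volume_pct": np.nan,
                "count": unassigned,
                "count_pct": 100.0 * unassigned / total,
            }
        )
    return pd.DataFrame(rows)


def volume_count_correlation(table: pd.DataFrame) -> tuple[float, float, bool]:
    """Spearman correlation between region volume and false-positive count.

    Ignores the ``unassigned`` row. Returns ``(rho, p, degenerate)``; constant
    counts (or volumes) make the rank correlation undefined, reported as
    rho = 0, p = 1 with the degeneracy flag set.
    """
    sub = table[table["region"] != "unassigned"]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 regions, got {len(sub)}")
    counts = sub["count"].to_numpy(dtype=float)
    vols = sub["volume_mm3"].to_numpy(dtype=float)
    if np.all(counts == counts[0]) or np.all(vols == vols[0]):
        return 0.0, 1.0, True
    rho, p = stats.spearmanr(vols, counts)
    return float(rho), float(p), False
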