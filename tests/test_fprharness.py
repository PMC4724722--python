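"""Experiment harness: CIs, logistic fits, Hosmer-Lemeshow, localization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solocase.fprharness import (
    ExperimentConfig,
    SeparationError,
    fit_fwe_logistic,
    hosmer_lemeshow,
    localize_false_positives,
    monte_carlo_ci,
    run_fpr_experiment,
    volume_count_correlation,
)
from solocase.records import ComparisonRecord, Peak
from solocase.synthdata import CohortSpec, ellipsoid_mask, make_partition


def record(direction="increase", flag=False, smoothing=8.0, tag="modulated",
           peaks=(), cid="c0"):
    peaks = list(peaks)
    if flag and not peaks:
        peaks = [peak((0, 0, 0))]  # flags require at least one peak
    return ComparisonRecord(
        comparison_id=cid, engine="permutation", smoothing_fwhm=smoothing,
        condition_tag=tag, direction=direction, fwe_flag=flag, peaks=peaks,
    )


def peak(voxel, t=5.0):
    return Peak(voxel=voxel, world_mm=(0.0, 0.0, 0.0), t=t, p_fwe=0.01)


class TestMonteCarloCI:
    def test_nominal_five_percent_band(self):
        lo, hi = monte_carlo_ci(0.05, 100)
        assert round(lo, 1) == 0.7
        assert round(hi, 1) == 9.3

    def test_even_rate_band(self):
        lo, hi = monte_carlo_ci(0.5, 100)
        assert lo == pytest.approx(40.2, abs=0.05)
        assert hi == pytest.approx(59.8, abs=0.05)

    def test_band_collapses_at_large_m(self):
        lo, hi = monte_carlo_ci(0.05, 10**12)
        assert lo == pytest.approx(5.0, abs=1e-3)
        assert hi == pytest.approx(5.0, abs=1e-3)

    def test_floor_at_zero(self):
        lo, _ = monte_carlo_ci(0.01, 10)
        assert lo == 0.0

    @pytest.mark.parametrize("p0, m", [(0.0, 100), (1.0, 100), (0.05, 0)])
    def test_invalid_inputs_rejected(self, p0, m):
        with pytest.raises(ValueError):
            monte_carlo_ci(p0, m)


def irls_logistic(X, y, n_iter=60):
    """Independent iteratively-reweighted least-squares reference fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        z = eta + (y - mu) / W
        beta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
    return beta


class TestFitFweLogistic:
    @staticmethod
    def _mixed_records(rng=None, n_per_cell=30, rates=None):
        rng = rng or np.random.default_rng(0)
        rates = rates or {}
        recs = []
        for smoothing in (4.0, 8.0, 12.0):
            for direction in ("increase", "decrease"):
                rate = rates.get((smoothing, direction), 0.2)
                for i in range(n_per_cell):
                    recs.append(record(direction=direction, smoothing=smoothing,
                                       flag=bool(rng.random() < rate), cid=f"c{i}"))
        return recs

    def test_coefficients_match_irls_reference(self):
        recs = self._mixed_records(rates={(4.0, "increase"): 0.5, (12.0, "decrease"): 0.1})
        fit = fit_fwe_logistic(recs, ("smoothing", "direction"))
        y = np.array([int(r.fwe_flag) for r in recs], dtype=float)
        X = np.column_stack([
            np.ones(len(recs)),
            [r.smoothing_fwhm == 8.0 for r in recs],
            [r.smoothing_fwhm == 12.0 for r in recs],
            [r.direction == "increase" for r in recs],
        ]).astype(float)
        expected = irls_logistic(X, y)
        np.testing.assert_allclose(fit.params.to_numpy(), expected, atol=1e-6)

    def test_duplicating_records_preserves_coefficients(self):
        recs = self._mixed_records()
        fit1 = fit_fwe_logistic(recs, ("smoothing", "direction"))
        fit2 = fit_fwe_logistic(recs + recs, ("smoothing", "direction"))
        np.testing.assert_allclose(
            fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-6
        )

    def test_all_identical_outcomes_rejected(self):
        recs = [record(flag=False, smoothing=s) for s in (4.0, 8.0)] * 10
        with pytest.raises(ValueError, match="identical"):
            fit_fwe_logistic(recs, ("smoothing",))

    def test_complete_separation_names_factor(self):
        recs = []
        for i in range(20):
            recs.append(record(direction="increase", flag=True, cid=f"a{i}",
                               peaks=[peak((0, 0, 0))]))
            recs.append(record(direction="decrease", flag=False, cid=f"b{i}"))
        with pytest.raises(SeparationError, match="direction"):
            fit_fwe_logistic(recs, ("direction",))

    def test_null_wald_p_calibration(self):
        """With outcomes independent of factors, Wald p is uniform: the 0.05
        rejection rate stays near nominal over replicates."""
        rng = np.random.default_rng(11)
        rejections = {"smoothing": 0, "direction": 0}
        n_rep = 120
        for _ in range(n_rep):
            recs = self._mixed_records(rng=rng)
            try:
                fit = fit_fwe_logistic(recs, ("smoothing", "direction"))
            except (SeparationError, ValueError):
                continue
            for factor in rejections:
                rejections[factor] += fit.wald_p[factor] < 0.05
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)  # ~= 0.11
        for factor, k in rejections.items():
            assert k / n_rep <= bound, factor


class TestHosmerLemeshow:
    def test_matches_hand_computed_example(self):
        # 20 observations, 4 groups of 5 by fitted risk; plain chi-square arithmetic
        y = np.array([0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1, 1, 0, 1])
        p = np.repeat([0.1, 0.3, 0.6, 0.8], 5)
        stat, pval = hosmer_lemeshow(y, p, g=4)
        expected = 0.0
        for k in range(4):
            o = y[5 * k: 5 * k + 5].sum()
            e = 5 * [0.1, 0.3, 0.6, 0.8][k]
            expected += (o - e) ** 2 / (e * (1 - e / 5))
        assert stat == pytest.approx(expected, abs=1e-10)
        assert pval == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_perfectly_calibrated_single_group(self):
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 1])
        p = np.full(10, y.mean())
        with pytest.warns(UserWarning, match="merged"):
            stat, _ = hosmer_lemeshow(y, p, g=4)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_well_specified_model_rarely_rejects(self):
        """HL p stays non-significant for >= 90% of well-specified fits."""
        rng = np.random.default_rng(3)
        nonsig = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.normal(size=300)
            eta = -1.0 + 0.8 * x
            y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(300), x])
            beta = irls_logistic(X, y)
            fitted = 1 / (1 + np.exp(-(X @ beta)))
            _, pval = hosmer_lemeshow(y, fitted, g=10)
            nonsig += pval >= 0.05
        assert nonsig >= 90

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            hosmer_lemeshow([0, 1], [0.5], g=2)


class TestLocalization:
    @pytest.fixture
    def partition(self):
        mask = ellipsoid_mask((12, 12, 12))
        return make_partition(mask, (3.0, 3.0, 3.0), 4)

    def test_all_peaks_in_one_region(self, partition):
        vox = tuple(np.argwhere(partition.labels == 2)[0])
        recs = [record(flag=True, peaks=[peak(vox)], cid=f"c{i}") for i in range(3)]
        table = localize_false_positives(recs, partition)
        row = table.set_index("region")
        assert row.loc["region_02", "count"] == 3
        assert row.loc["region_02", "count_pct"] == pytest.approx(100.0)
        assert (row.drop("region_02")["count"] == 0).all()

    def test_counts_conserve_total_peaks(self, partition):
        rng = np.random.default_rng(8)
        in_mask = np.argwhere(partition.labels > 0)
        recs = []
        for i in range(10):
            pts = in_mask[rng.integers(0, len(in_mask), size=rng.integers(0, 4))]
            pks = [peak(tuple(v)) for v in pts]
            recs.append(record(flag=bool(pks), peaks=pks, cid=f"c{i}"))
        table = localize_false_positives(recs, partition)
        assert table["count"].sum() == sum(len(r.peaks) for r in recs)

    def test_known_coordinates_match_hand_tally(self, partition):
        vox_by_region = {
            k: tuple(np.argwhere(partition.labels == k)[0]) for k in (1, 2, 4)
        }
        recs = [
            record(flag=True, cid="c0",
                   peaks=[peak(vox_by_region[1]), peak(vox_by_region[2])]),
            record(flag=True, cid="c1",
                   peaks=[peak(vox_by_region[2]), peak(vox_by_region[4])]),
        ]
        table = localize_false_positives(recs, partition).set_index("region")
        assert table["count"].to_dict() == {
            "region_01": 1, "region_02": 2, "region_03": 0, "region_04": 1,
        }

    def test_outside_peak_counted_unassigned(self, partition):
        outside = tuple(np.argwhere(partition.labels == 0)[0])
        recs = [record(flag=True, peaks=[peak(outside)])]
        table = localize_false_positives(recs, partition).set_index("region")
        assert table.loc["unassigned", "count"] == 1


class TestVolumeCountCorrelation:
    @staticmethod
    def _table(volumes, counts):
        return pd.DataFrame(
            {
                "region": [f"r{i}" for i in range(len(volumes))],
                "volume_mm3": volumes,
                "volume_pct": 100 * np.asarray(volumes) / np.sum(volumes),
                "count": counts,
                "count_pct": 100 * np.asarray(counts) / max(np.sum(counts), 1),
            }
        )

    def test_monotone_counts_give_rho_one(self):
        rho, p, degenerate = volume_count_correlation(
            self._table([10, 20, 30, 40], [1, 2, 5, 9])
        )
        assert rho == pytest.approx(1.0)
        assert not degenerate

    def test_constant_counts_degenerate(self):
        rho, p, degenerate = volume_count_correlation(
            self._table([10, 20, 30], [2, 2, 2])
        )
        assert (rho, p, degenerate) == (0.0, 1.0, True)

    def test_eight_regions_match_rank_then_pearson(self):
        rng = np.random.default_rng(4)
        volumes = rng.uniform(50, 500, size=8)
        counts = rng.integers(0, 12, size=8).astype(float)
        rho, p, _ = volume_count_correlation(self._table(volumes, counts))
        rv = stats.rankdata(volumes)
        rc = stats.rankdata(counts)
        expected_rho = np.corrcoef(rv, rc)[0, 1]
        tstat = expected_rho * np.sqrt(6 / (1 - expected_rho**2))
        expected_p = 2 * stats.t.sf(abs(tstat), 6)
        assert rho == pytest.approx(expected_rho, abs=1e-12)
        assert p == pytest.approx(expected_p, abs=1e-10)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="3"):
            volume_count_correlation(self._table([10, 20], [1, 2]))


class TestRunExperiment:
    TINY = dict(
        m_comparisons=4, pool_size=14, control_group_size=10,
        conditions=((8.0, "modulated"), (8.0, "unmodulated")),
        cohort_spec=CohortSpec(grid_shape=(10, 10, 10)), n_regions=4, seed=9,
    )

    def test_fixed_seed_reproducible(self):
        res1 = run_fpr_experiment(ExperimentConfig(**self.TINY))
        res2 = run_fpr_experiment(ExperimentConfig(**self.TINY))
        assert res1.condition_table.equals(res2.condition_table)
        assert res1.spearman_rho == res2.spearman_rho
        assert len(res1.records) == len(res2.records)
        for a, b in zip(res1.records, res2.records):
            assert (a.comparison_id, a.fwe_flag, len(a.peaks)) == (
                b.comparison_id, b.fwe_flag, len(b.peaks)
            )

    def test_alpha_one_gives_total_fwer(self):
        cfg = ExperimentConfig(**{**self.TINY, "alpha": 1.0})
        res = run_fpr_experiment(cfg)
        assert (res.condition_table["fwer_pct"] == 100.0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="control_group_size"):
            ExperimentConfig(**{**self.TINY, "control_group_size": 14})
        with pytest.raises(ValueError, match="engine"):
            ExperimentConfig(**{**self.TINY, "engine": "bayesian"})
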