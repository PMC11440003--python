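import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import abcrasch as abc
from abcrasch.fit_stats import (
    flag_misfit,
    infit_outfit,
    point_measure_corr,
    separation_reliability,
    standardized_residuals,
)
from abcrasch.rasch import RaschFit
from conftest import make_rm, simulate_rasch


def fixed_fit(beta, delta, person_ids, item_ids):
    return RaschFit(
        beta=pd.Series(beta, index=person_ids),
        delta=pd.Series(delta, index=item_ids),
        se_beta=pd.Series(0.1, index=person_ids),
        se_delta=pd.Series(0.1, index=item_ids),
        converged=True,
        n_iter=1,
        loglik=np.nan,
    )


class TestStandardizedResiduals:
    @pytest.mark.parametrize(
        "x,p,expected", [(1.0, 0.5, 1.0), (0.0, 0.5, -1.0), (1.0, 0.9, 1 / 3)]
    )
    def test_closed_form(self, x, p, expected):
        rm = make_rm([[x, 1 - x], [1 - x, x]])
        fit = fixed_fit([0.0, 0.0], [-logit(p), logit(p)], rm.X.index, rm.X.columns)
        z = standardized_residuals(fit, rm)
        assert z.iloc[0, 0] == pytest.approx(expected)

    def test_missing_stays_missing(self):
        rm = make_rm([[1, None], [0, 1]])
        fit = fixed_fit([0.0, 0.0], [0.0, 0.0], rm.X.index, rm.X.columns)
        z = standardized_residuals(fit, rm)
        assert np.isnan(z.iloc[0, 1]) and not np.isnan(z.iloc[0, 0])


class TestInfitOutfit:
    def test_model_true_mnsq_near_one(self):
        screened, _ = simulate_rasch(2000, np.linspace(-2, 2, 20), seed=77)
        fit = abc.estimate_jml(screened)
        rep = infit_outfit(fit, screened)
        assert 0.95 <= rep.per_item["infit_mnsq"].mean() <= 1.05
        assert 0.95 <= rep.per_person["infit_mnsq"].mean() <= 1.05

    def test_guttman_person_overfits(self):
        # deterministic response pattern given the difficulties: infit < 1
        screened, _ = simulate_rasch(200, np.linspace(-1.5, 1.5, 12), seed=9)
        fit = abc.estimate_jml(screened)
        X = screened.X.copy()
        pid = X.index[0]
        X.loc[pid] = (fit.delta.to_numpy() < float(fit.beta[pid])).astype(float)
        rm = abc.ResponseMatrix(X=X, covariates=screened.covariates)
        rep = infit_outfit(fit, rm)
        row = rep.per_person.set_index("id").loc[pid]
        assert row["infit_mnsq"] < 1.0

    def test_zstd_clamped_for_reporting(self):
        # an item anti-ordered against the measures is impossibly misfitting
        screened, _ = simulate_rasch(2000, np.linspace(-1, 1, 10), seed=21)
        fit = abc.estimate_jml(screened)
        X = screened.X.copy()
        X.iloc[:, 0] = (fit.beta.to_numpy() < np.median(fit.beta)).astype(float)
        rep = infit_outfit(fit, abc.ResponseMatrix(X=X))
        assert rep.per_item["infit_zstd"].iloc[0] == pytest.approx(9.9)
        assert rep.per_item["infit_zstd"].abs().max() <= 9.9

    def test_outfit_pool_partitions_both_ways(self):
        screened, _ = simulate_rasch(300, np.linspace(-1, 1, 8), seed=4)
        fit = abc.estimate_jml(screened)
        rep = infit_outfit(fit, screened)
        items = (rep.per_item["outfit_mnsq"] * rep.per_item["count"]).sum()
        persons = (rep.per_person["outfit_mnsq"] * rep.per_person["count"]).sum()
        assert items == pytest.approx(persons, rel=1e-10)

    def test_type_one_rate_loose(self):
        flagged, total = 0, 0
        for seed in range(10):
            screened, _ = simulate_rasch(500, np.linspace(-2, 2, 20), seed=100 + seed)
            fit = abc.estimate_jml(screened)
            rep = infit_outfit(fit, screened)
            flagged += int((rep.per_item["infit_zstd"].abs() > 2).sum())
            total += len(rep.per_item)
        assert flagged / total <= 0.15


class TestFlagMisfit:
    def test_inside_windows_unflagged(self):
        tbl = pd.DataFrame({"id": [1], "infit_mnsq": [1.0], "infit_zstd": [0.0]})
        flags = flag_misfit(tbl)
        assert not flags[["mnsq_violation", "zstd_violation", "any", "both"]].any().any()

    def test_widening_windows_monotone(self):
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame(
            {
                "id": np.arange(50),
                "infit_mnsq": rng.uniform(0.5, 1.6, 50),
                "infit_zstd": rng.uniform(-5, 5, 50),
            }
        )
        narrow = flag_misfit(tbl, (0.8, 1.2), (-1.5, 1.5))
        wide = flag_misfit(tbl, (0.7, 1.4), (-2.5, 2.5))
        assert (wide["any"] <= narrow["any"]).all()


class TestSeparationReliability:
    def test_unit_separation(self):
        # measures [-1, 1]: observed var 2, error var 1 -> G = 1, R = 0.5
        out = separation_reliability([-1.0, 1.0], [1.0, 1.0])
        assert out["separation"] == pytest.approx(1.0)
        assert out["reliability"] == pytest.approx(0.5)

    def test_no_true_variance(self):
        out = separation_reliability([0.3, 0.3, 0.3], [0.5, 0.5, 0.5])
        assert out == {"separation": 0.0, "reliability": 0.0}

    def test_identity_holds(self, calibrated_medium):
        _, _, fit = calibrated_medium
        out = separation_reliability(fit.beta, fit.se_beta)
        G = out["separation"]
        assert out["reliability"] == pytest.approx(G**2 / (1 + G**2), abs=1e-9)


class TestPointMeasureCorr:
    def test_ordered_item_near_plus_one(self, calibrated_medium):
        screened, _, fit = calibrated_medium
        X = screened.X.copy()
        X.iloc[:, 0] = (fit.beta.to_numpy() > np.median(fit.beta)).astype(float)
        corr = point_measure_corr(abc.ResponseMatrix(X=X), fit)
        assert corr.iloc[0] > 0.7

    def test_random_item_near_zero(self):
        screened, _ = simulate_rasch(2000, np.linspace(-1, 1, 10), seed=13)
        fit = abc.estimate_jml(screened)
        X = screened.X.copy()
        X.iloc[:, 0] = np.random.default_rng(99).integers(0, 2, len(X)).astype(float)
        corr = point_measure_corr(abc.ResponseMatrix(X=X), fit)
        assert abs(corr.iloc[0]) < 0.1

    def test_anti_ordered_negative(self, calibrated_medium):
        screened, _, fit = calibrated_medium
        X = screened.X.copy()
        X.iloc[:, 0] = (fit.beta.to_numpy() < np.median(fit.beta)).astype(float)
        corr = point_measure_corr(abc.ResponseMatrix(X=X), fit)
        assert corr.iloc[0] < 0

    def test_constant_column_missing(self, calibrated_medium):
        screened, _, fit = calibrated_medium
        X = screened.X.copy()
        X.iloc[:, 0] = 1.0
        corr = point_measure_corr(abc.ResponseMatrix(X=X), fit)
        assert np.isnan(corr.iloc[0])
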