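import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit

import abcrasch as abc
from abcrasch.dif import (
    DIFModel,
    DIFPath,
    build_design,
    dif_table,
    fit_dif_path,
    item_response_logodds,
    select_bic,
)


def covariates(rows):
    return pd.DataFrame(
        rows, columns=["gender", "age_group", "symptom_level"],
        index=[f"p{k}" for k in range(len(rows))],
    )


def sim_dif(seed, n=800, ni=15, gamma=None, shift=None):
    cfg = abc.SimConfig(
        n_persons=n,
        item_difficulties=np.linspace(-2, 2, ni),
        item_discriminations=np.ones(ni),
        group_proportions={"gender": {"male": 0.5, "female": 0.5}},
        gamma=gamma if gamma is not None else np.zeros((ni, 7)),
        theta_shift_by_group=shift,
        seed=seed,
    )
    data, _ = abc.simulate(cfg)
    screened, _, _ = abc.screen_extremes(data)
    return screened


class TestBuildDesign:
    def test_dummy_coding(self):
        d = build_design(covariates([["male", "infant", "non_autism"]]))
        row = d.matrix.iloc[0]
        assert row["gender"] == 1 and row["infant"] == 1 and row["non_autism"] == 1
        assert row.sum() == 3

    def test_reference_person_all_zero(self):
        d = build_design(covariates([["female", "high", "severe"]]))
        assert (d.matrix.iloc[0] == 0).all()

    def test_shape_and_columns(self):
        d = build_design(
            covariates(
                [
                    ["male", "infant", "non_autism"],
                    ["female", "primary", "severe"],
                    ["female", "high", "mild_moderate"],
                ]
            )
        )
        assert d.matrix.shape == (3, 7)
        assert d.columns == [
            "gender", "infant", "kindergarten", "primary", "junior_high",
            "non_autism", "mild_moderate",
        ]

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="toddler"):
            build_design(covariates([["male", "toddler", "severe"]]))


def toy_model(alpha, diff, gamma_rows):
    ni = len(alpha)
    cols = ["gender", "infant", "kindergarten", "primary", "junior_high",
            "non_autism", "mild_moderate"]
    return DIFModel(
        alpha=pd.Series(alpha, index=[f"i{k}" for k in range(ni)]),
        diff=pd.Series(diff, index=[f"i{k}" for k in range(ni)]),
        gamma=pd.DataFrame(gamma_rows, index=[f"i{k}" for k in range(ni)], columns=cols),
        lambda_=1.0, loglik=0.0, bic=0.0, df=0, converged=True,
    )


class TestLogOdds:
    def test_no_dif_reduction(self):
        m = toy_model([1.3], [0.4], [np.zeros(7)])
        x = np.zeros(7)
        assert item_response_logodds(0.9, 0, x, m) == pytest.approx(1.3 * (0.9 - 0.4))

    def test_gender_shift_matches_worked_reading(self):
        # gamma_gender = -0.087: a boy's effective difficulty is diff - 0.087
        g = np.zeros(7); g[0] = -0.087
        m = toy_model([1.0], [0.5], [g])
        boy = np.zeros(7); boy[0] = 1.0
        lo_boy = item_response_logodds(0.0, 0, boy, m)
        lo_girl = item_response_logodds(0.0, 0, np.zeros(7), m)
        assert lo_boy - lo_girl == pytest.approx(0.087)
        assert lo_boy == pytest.approx(-(0.5 - 0.087))

    def test_midpoint_probability(self):
        g = np.zeros(7); g[1] = 0.3
        m = toy_model([0.8], [0.2], [g])
        x = np.zeros(7); x[1] = 1.0
        theta_eff = 0.2 + 0.3
        assert expit(item_response_logodds(theta_eff, 0, x, m)) == pytest.approx(0.5)


class TestSelectBIC:
    def path_with_bics(self, bics, lambdas=None):
        lambdas = lambdas or list(np.linspace(2, 1, len(bics)))
        models = [
            toy_model([1.0], [0.0], [np.zeros(7)]) for _ in bics
        ]
        for m, b, lam in zip(models, bics, lambdas):
            m.bic, m.lambda_ = b, lam
        return DIFPath(models=models)

    def test_argmin(self):
        path = self.path_with_bics([100.0, 90.0, 95.0])
        assert select_bic(path) is path.models[1]

    def test_tie_prefers_larger_lambda(self):
        path = self.path_with_bics([90.0, 90.0], lambdas=[1.0, 0.5])
        sel = select_bic(path)
        assert sel.lambda_ == 1.0

    def test_single_model(self):
        path = self.path_with_bics([42.0])
        assert select_bic(path) is path.models[0]

    def test_nonconverged_skipped(self):
        path = self.path_with_bics([80.0, 90.0])
        path.models[0].converged = False
        assert select_bic(path) is path.models[1]


@pytest.fixture(scope="module")
def planted_path():
    g = np.zeros((15, 7)); g[4, 0] = 1.0
    screened = sim_dif(seed=3, gamma=g)
    design = build_design(screened.covariates)
    path = fit_dif_path(screened, design, n_lambda=8, quadrature_nodes=15)
    return screened, design, path


class TestFitPath:
    def test_lambda_max_all_zero(self, planted_path):
        _, _, path = planted_path
        first = path.models[0]
        assert (first.nonzero_gamma().to_numpy() == 0).all()
        # strictly inside the path the planted coefficient activates
        assert any(
            (m.nonzero_gamma().to_numpy() != 0).any() for m in path.models[1:]
        )

    def test_nonzero_count_monotone_in_lambda(self, planted_path):
        _, _, path = planted_path
        counts = [int((m.nonzero_gamma().to_numpy() != 0).sum()) for m in path.models]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_planted_effect_selected_with_sign(self, planted_path):
        _, design, path = planted_path
        sel = path.selected
        assert sel.nonzero_gamma().loc["item_5", "gender"] > 0

    def test_alpha_positive(self, planted_path):
        _, _, path = planted_path
        for m in path.models:
            assert (m.alpha > 0).all()

    def test_dif_table_layout_and_zero_printing(self, planted_path):
        _, design, path = planted_path
        tbl = dif_table(path.selected, design)
        assert list(tbl.columns) == design.columns
        assert (tbl.abs() >= 1e-4).to_numpy().sum() == (tbl.to_numpy() != 0).sum()

    def test_misaligned_design_rejected(self, planted_path):
        screened, design, _ = planted_path
        shuffled = design.matrix.iloc[::-1]
        bad = abc.DIFDesign(matrix=shuffled, coding_map=design.coding_map)
        with pytest.raises(ValueError, match="aligned"):
            fit_dif_path(screened, bad, n_lambda=2, quadrature_nodes=7)


class TestNoDIFReduction:
    def test_reference_only_sample_matches_plain_irt(self):
        # all persons in reference groups -> design is all zeros -> the fit
        # must equal a plain marginal 2PL; cross-check the marginal
        # log-likelihood with an independent direct quadrature evaluation
        cfg = abc.SimConfig(
            n_persons=300,
            item_difficulties=np.linspace(-1, 1, 8),
            item_discriminations=np.ones(8),
            group_proportions={
                "gender": {"male": 0.0, "female": 1.0},
                "age_group": {"infant": 0.0, "kindergarten": 0.0, "primary": 0.0,
                              "junior_high": 0.0, "high": 1.0},
                "symptom_level": {"non_autism": 0.0, "mild_moderate": 0.0, "severe": 1.0},
            },
            seed=8,
        )
        data, _ = abc.simulate(cfg)
        screened, _, _ = abc.screen_extremes(data)
        design = build_design(screened.covariates)
        assert (design.matrix.to_numpy() == 0).all()
        path = fit_dif_path(screened, design, n_lambda=3, quadrature_nodes=21)
        sel = path.models[-1]
        assert (sel.nonzero_gamma().to_numpy() == 0).all()

        # independent oracle for the marginal log-likelihood at the estimate
        nodes, w = hermegauss(21)
        w = w / w.sum()
        X = screened.values()
        P = expit(
            sel.alpha.to_numpy()[None, None, :]
            * (nodes[None, :, None] - sel.diff.to_numpy()[None, None, :])
        )
        lik = (
            np.where(X[:, None, :] == 1, P, 1 - P).prod(axis=2) * w[None, :]
        ).sum(axis=1)
        oracle_ll = float(np.log(lik).sum())
        assert sel.loglik == pytest.approx(oracle_ll, abs=1e-4)


class TestDiffRecovery:
    def test_rmse_within_tolerance(self):
        screened = sim_dif(seed=55, n=1000, ni=15)
        design = build_design(screened.covariates)
        path = fit_dif_path(screened, design, n_lambda=4, quadrature_nodes=15)
        sel = path.models[0]  # no-DIF end of the path
        true = np.linspace(-2, 2, 15)
        idx = [int(c.split("_")[1]) - 1 for c in screened.X.columns]
        rmse = float(np.sqrt(np.mean((sel.diff.to_numpy() - true[idx]) ** 2)))
        assert rmse <= 0.15
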