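"""Lasso-penalized uniform DIF detection for dichotomous IRT models.

Uniform differential item functioning (DIF) means an item is systematically
easier or harder for a demographic group at equal latent-trait level.  Each
item i gets a coefficient vector gamma_i over dummy-coded person covariates
x_p, entering the two-parameter logistic log-odds as a difficulty shift:

    logit P(x_pi = 1 | theta_p) = alpha_i * (theta_p - (diff_i + x_p @ gamma_i))

A negative gamma_ik makes the item easier for group k (e.g. a gender
coefficient of -0.087 lowers the effective difficulty for boys).  The latent trait is standard normal and the likelihood is marginal,
integrated by Gauss-Hermite quadrature.  An L1 penalty lambda * sum|gamma|
shrinks DIF coefficients exactly to zero, so DIF detection becomes model
selection: a path of decreasing lambda is fitted with warm starts, from
lambda_max (the smallest penalty at which every gamma is zero, obtained from
the score equations of the no-DIF fit) down to lambda_max/1000, and the model
minimizing BIC = -2 loglik + log(n_persons) * df is selected, df counting the
surviving parameters.

The optimizer splits gamma = gamma+ - gamma- with both halves bound at zero,
which turns the penalty into a smooth linear term and lets L-BFGS-B deliver
exact zeros on active bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp

from .data_io import AGE_LEVELS, GENDER_LEVELS, SYMPTOM_LEVELS, ResponseMatrix

__all__ = [
    "DIFDesign",
    "DIFModel",
    "DIFPath",
    "DEFAULT_REFERENCES",
    "build_design",
    "item_response_logodds",
    "fit_dif_path",
    "select_bic",
    "dif_table",
]

#: reference (dummy = all-zero) level per factor: the study convention sets
#: female, high-school and severe-ASD rows to zero.
DEFAULT_REFERENCES = {
    "gender": "female",
    "age_group": "high",
    "symptom_level": "severe",
}

ZERO_THRESHOLD = 1e-4
N_LAMBDA = 50
QUADRATURE_NODES = 21
LAMBDA_MIN_RATIO = 1e-3

_FACTOR_LEVELS = {
    "gender": GENDER_LEVELS,
    "age_group": AGE_LEVELS,
    "symptom_level": SYMPTOM_LEVELS,
}


@dataclass(frozen=True)
class DIFDesign:
    """Dummy-coded persons × groups matrix with named reference levels."""

    matrix: pd.DataFrame  # persons × q, cells in {0, 1}
    coding_map: dict  # factor -> reference level

    @property
    def q(self) -> int:
        return self.matrix.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class DIFModel:
    """One fitted point on the penalty path."""

    alpha: pd.Series  # per-item discrimination, > 0
    diff: pd.Series  # per-item difficulty (reference groups)
    gamma: pd.DataFrame  # items × covariate columns
    lambda_: float
    loglik: float
    bic: float
    df: int
    converged: bool
    theta_scale: dict = field(default_factory=lambda: {"mean": 0.0, "sd": 1.0})

    def nonzero_gamma(self, threshold: float = ZERO_THRESHOLD) -> pd.DataFrame:
        g = self.gamma.copy()
        g[g.abs() < threshold] = 0.0
        return g


@dataclass
class DIFPath:
    """Ordered models over decreasing lambda plus the BIC-selected index."""

    models: list
    selected_index: int = -1

    @property
    def selected(self) -> DIFModel:
        return self.models[self.selected_index]

    def export(self, path) -> pd.DataFrame:
        rows = [
            (
                m.lambda_,
                m.loglik,
                m.df,
                m.bic,
                int((m.nonzero_gamma().to_numpy() != 0).sum()),
                m.converged,
            )
            for m in self.models
        ]
        tbl = pd.DataFrame(
            rows, columns=["lambda", "loglik", "df", "bic", "n_nonzero_gamma", "converged"]
        )
        tbl.to_csv(path, index=False)
        return tbl


def build_design(
    covariates: pd.DataFrame, coding_map: dict | None = None
) -> DIFDesign:
    """Dummy-code gender/age_group/symptom_level with the stated references.

    With the default references the columns are gender (male), four age
    groups (infant..junior_high) and two symptom levels (non_autism,
    mild_moderate); a female/high-school/severe person is an all-zero row.
    """
    coding = dict(DEFAULT_REFERENCES)
    if coding_map:
        coding.update(coding_map)
    cols = {}
    for factor, levels in _FACTOR_LEVELS.items():
        ref = coding[factor]
        if ref not in levels:
            raise ValueError(f"unknown reference level {ref!r} for {factor}")
        observed = set(covariates[factor].astype(str))
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(
                f"unknown {factor} level(s) {sorted(unknown)}; allowed: {list(levels)}"
            )
        for lev in levels:
            if lev == ref:
                continue
            name = lev if factor != "gender" else "gender"
            cols[name] = (covariates[factor].astype(str) == lev).astype(float)
    matrix = pd.DataFrame(cols, index=covariates.index)
    return DIFDesign(matrix=matrix, coding_map=coding)


def item_response_logodds(theta, item: int, person_covariates, model: DIFModel):
    """Log-odds alpha_i * (theta - (diff_i + x @ gamma_i)) for one item."""
    x = np.asarray(person_covariates, dtype=float)
    eff = float(model.diff.iloc[item]) + float(x @ model.gamma.iloc[item].to_numpy())
    return float(model.alpha.iloc[item]) * (np.asarray(theta, dtype=float) - eff)


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for a standard-normal latent trait."""
    nodes, weights = hermegauss(n)
    return nodes, weights / weights.sum()


class _MarginalLikelihood:
    """Penalized marginal likelihood with analytic gradient.

    Parameter vector layout: [log_alpha (ni, absent when Rasch-constrained),
    diff (ni), gamma_pos (ni*q), gamma_neg (ni*q)].
    """

    def __init__(self, data: ResponseMatrix, design: DIFDesign, n_nodes: int,
                 rasch_constrained: bool):
        values = data.values()
        self.M = ~np.isnan(values)
        self.U = np.where(self.M, np.nan_to_num(values), 0.0)  # observed 1s
        self.V = np.where(self.M, 1.0 - np.nan_to_num(values), 0.0)  # observed 0s
        self.n, self.ni = values.shape
        Xd = design.matrix.to_numpy(dtype=float)
        self.q = Xd.shape[1]
        # compress persons into distinct covariate patterns
        pats, self.pat_idx = np.unique(Xd, axis=0, return_inverse=True)
        self.patterns = pats
        self.nodes, self.weights = _gh_nodes(n_nodes)
        self.logw = np.log(self.weights)
        self.Xd = Xd
        self.rasch = rasch_constrained

    def n_smooth(self) -> int:
        return (0 if self.rasch else self.ni) + self.ni

    def unpack(self, params):
        ni, q = self.ni, self.q
        if self.rasch:
            log_alpha = np.zeros(ni)
            rest = params
        else:
            log_alpha, rest = params[:ni], params[ni:]
        diff = rest[:ni]
        gpos = rest[ni : ni + ni * q].reshape(ni, q)
        gneg = rest[ni + ni * q :].reshape(ni, q)
        return log_alpha, diff, gpos, gneg

    def _eta(self, alpha, diff, gamma):
        eff = diff[None, :] + self.patterns @ gamma.T  # (npat, ni)
        return alpha[None, None, :] * (
            self.nodes[None, :, None] - eff[:, None, :]
        )  # (npat, nq, ni)

    def loglik_and_grad(self, params):
        log_alpha, diff, gpos, gneg = self.unpack(params)
        alpha = np.exp(log_alpha)
        gamma = gpos - gneg
        eta = self._eta(alpha, diff, gamma)
        A = log_expit(eta)  # log P
        B = log_expit(-eta)  # log (1-P)
        Ap, Bp = A[self.pat_idx], B[self.pat_idx]  # (n, nq, ni)
        ll_pq = np.einsum("pi,pqi->pq", self.U, Ap) + np.einsum(
            "pi,pqi->pq", self.V, Bp
        )
        ll_pq += self.logw[None, :]
        lse = logsumexp(ll_pq, axis=1)
        loglik = float(lse.sum())

        wt = np.exp(ll_pq - lse[:, None])  # posterior node weights (n, nq)
        P = expit(eta)
        Pp = P[self.pat_idx]
        E = np.einsum("pq,pqi->pi", wt, Pp)  # posterior mean P per cell
        S = np.where(self.M, self.U - E, 0.0)  # residual, observed cells
        g_diff = -alpha * S.sum(axis=0)
        g_gamma = -alpha[:, None] * (S.T @ self.Xd)  # (ni, q)
        if self.rasch:
            g_la = None
        else:
            etap = eta[self.pat_idx]
            Eeta = np.einsum("pq,pqi->pi", wt, etap)
            EPeta = np.einsum("pq,pqi->pi", wt, Pp * etap)
            g_la = (self.U * Eeta - np.where(self.M, EPeta, 0.0)).sum(axis=0)
            # U already zero on missing; EPeta must be masked explicitly
        grad = np.concatenate(
            ([] if self.rasch else [g_la])
            + [g_diff, g_gamma.ravel(), -g_gamma.ravel()]
        )
        return loglik, grad

    def objective(self, params, lam):
        _, _, gpos, gneg = self.unpack(params)
        loglik, grad = self.loglik_and_grad(params)
        pen = lam * float(gpos.sum() + gneg.sum())
        gpen = np.zeros_like(params)
        gpen[self.n_smooth() :] = lam
        return -loglik + pen, -grad + gpen


def _fit_at_lambda(ml, lam, start, bounds, maxiter):
    res = minimize(
        ml.objective,
        start,
        args=(lam,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 4 * maxiter},
    )
    return res


def fit_dif_path(
    data: ResponseMatrix,
    design: DIFDesign,
    n_lambda: int = N_LAMBDA,
    quadrature_nodes: int = QUADRATURE_NODES,
    rasch_constrained: bool = False,
    zero_threshold: float = ZERO_THRESHOLD,
    lambda_min_ratio: float = LAMBDA_MIN_RATIO,
    maxiter: int = 400,
) -> DIFPath:
    """Fit the penalized model over a decreasing log-spaced lambda path.

    The path starts at lambda_max — computed from the gradient of the
    unpenalized likelihood with respect to gamma at the no-DIF fit, so the
    first model has gamma identically zero — and ends at
    lambda_max * lambda_min_ratio, warm-starting each fit from the previous
    solution.  Non-converging path points are flagged and skipped for
    selection; an all-flagged path raises.
    """
    if not design.matrix.index.equals(data.X.index):
        raise ValueError("design rows are not aligned to the response matrix persons")
    ml = _MarginalLikelihood(data, design, quadrature_nodes, rasch_constrained)
    ni, q = ml.ni, ml.q
    n_smooth = ml.n_smooth()
    n_params = n_smooth + 2 * ni * q
    bounds = [(None, None)] * n_smooth + [(0.0, None)] * (2 * ni * q)

    # stage 1: no-DIF fit (gamma frozen at zero via equal bounds)
    start = np.zeros(n_params)
    p0 = data.values()
    col_mean = np.nanmean(p0, axis=0)
    diff0 = -np.log(col_mean / (1.0 - col_mean))
    start[(0 if rasch_constrained else ni) : n_smooth] = np.clip(diff0, -4, 4)
    frozen = [(None, None)] * n_smooth + [(0.0, 0.0)] * (2 * ni * q)
    res0 = minimize(
        ml.objective, start, args=(0.0,), jac=True, method="L-BFGS-B",
        bounds=frozen, options={"maxiter": maxiter, "maxfun": 4 * maxiter},
    )
    base = res0.x
    _, grad0 = ml.loglik_and_grad(base)
    g_gamma = grad0[n_smooth : n_smooth + ni * q]
    lambda_max = float(np.abs(g_gamma).max())
    if lambda_max <= 0.0:  # no covariate contrast at all (all-zero design)
        lambda_max = 1e-8
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambda)

    item_ids = list(data.X.columns)
    cols = design.columns
    models: list[DIFModel] = []
    current = base.copy()
    n_persons = ml.n
    for lam in lambdas:
        res = _fit_at_lambda(ml, lam, current, bounds, maxiter)
        current = res.x
        log_alpha, diff, gpos, gneg = ml.unpack(current)
        gamma = gpos - gneg
        loglik, _ = ml.loglik_and_grad(current)
        values = np.concatenate([np.exp(log_alpha), diff, np.where(
            np.abs(gamma) >= zero_threshold, gamma, 0.0).ravel()])
        df = int((np.abs(values) > zero_threshold).sum())
        bic = -2.0 * loglik + np.log(n_persons) * df
        models.append(
            DIFModel(
                alpha=pd.Series(np.exp(log_alpha), index=item_ids),
                diff=pd.Series(diff.copy(), index=item_ids),
                gamma=pd.DataFrame(gamma.copy(), index=item_ids, columns=cols),
                lambda_=float(lam),
                loglik=loglik,
                bic=float(bic),
                df=df,
                converged=bool(res.success),
            )
        )
    if not any(m.converged for m in models):
        raise RuntimeError("no lambda on the DIF path converged")
    path = DIFPath(models=models)
    select_bic(path)
    return path


def select_bic(path: DIFPath) -> DIFModel:
    """Model minimizing BIC among converged fits; ties go to larger lambda."""
    if not path.models:
        raise ValueError("empty DIF path")
    best, best_bic = None, np.inf
    for idx, m in enumerate(path.models):
        if not m.converged:
            continue
        if m.bic < best_bic:  # strict: first (largest-lambda) winner kept on ties
            best, best_bic = idx, m.bic
    if best is None:
        best = 0
    path.selected_index = best
    return path.models[best]


def dif_table(
    model: DIFModel, design: DIFDesign, zero_threshold: float = ZERO_THRESHOLD
) -> pd.DataFrame:
    """Items × covariate-columns coefficient table; sub-threshold values print 0."""
    tbl = model.nonzero_gamma(zero_threshold)
    return tbl.reindex(columns=design.columns)
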