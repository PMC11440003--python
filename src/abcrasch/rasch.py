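"""Dichotomous Rasch calibration by joint maximum likelihood (JML).

The Rasch model gives person p a probability

    P(x_pi = 1) = exp(beta_p - delta_i) / (1 + exp(beta_p - delta_i))

of endorsing item i, where beta_p is the person's trait level (ability) and
delta_i the item's difficulty, both in logits.  The raw score is sufficient
for each parameter, so estimation alternates Newton solves of the per-person
and per-item score equations, re-centering the difficulties to mean zero each
cycle (the gauge convention: translation of all parameters leaves every
probability unchanged).

JML is the estimation style of WINSTEPS-like software.  It is consistent only
as both margins grow and carries a known bias of order (L-1)/L at small item
counts L; an optional multiplicative correction is provided, default off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import DataError, ResponseMatrix

__all__ = ["RaschFit", "item_prob", "estimate_jml", "standard_errors", "export_fit"]


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class RaschFit:
    """Person abilities and item difficulties, in logits, with their errors.

    ``beta``/``delta`` are indexed by person/item id.  Standard errors are
    filled by :func:`standard_errors` and are NaN until then.
    """

    beta: pd.Series
    delta: pd.Series
    se_beta: pd.Series
    se_delta: pd.Series
    converged: bool
    n_iter: int
    loglik: float

    @property
    def person_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.delta.index)

    def prob_matrix(self) -> pd.DataFrame:
        """Model probabilities P_pi for every person × item pair."""
        eta = self.beta.to_numpy()[:, None] - self.delta.to_numpy()[None, :]
        return pd.DataFrame(expit(eta), index=self.beta.index, columns=self.delta.index)


def item_prob(beta, delta):
    """Endorsement probability exp(b-d)/(1+exp(b-d)); stable for |b-d| ≤ ~700."""
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(delta).all()):
        raise ValueError("item_prob requires finite beta and delta")
    out = expit(beta - delta)
    return out if out.ndim else float(out)


def _loglik(values: np.ndarray, obs: np.ndarray, beta: np.ndarray, delta: np.ndarray) -> float:
    eta = beta[:, None] - delta[None, :]
    # log(1+e^eta) computed stably
    log1p = np.logaddexp(0.0, eta)
    ll = np.where(obs, values * eta - log1p, 0.0)
    return float(ll.sum())


def _newton_margin(
    targets: np.ndarray,
    eta_fixed: np.ndarray,
    obs: np.ndarray,
    start: np.ndarray,
    sign: float,
    max_steps: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve the score equations for one margin, all entities at once.

    For persons, eta = x + eta_fixed with eta_fixed = -delta per column and
    sign = +1; for items, eta = eta_fixed - x with sign = -1.  Newton steps
    are damped to ±1 logit to keep the solve monotone-safe.
    """
    x = start.copy()
    for _ in range(max_steps):
        eta = sign * x[:, None] + eta_fixed
        P = expit(eta)
        P = np.where(obs, P, 0.0)
        W = P * (1.0 - P)
        f = targets - P.sum(axis=1)
        h = W.sum(axis=1)
        step = sign * f / np.maximum(h, 1e-12)
        step = np.clip(step, -1.0, 1.0)
        x = x + step
        if np.max(np.abs(step)) < tol:
            break
    return x


def estimate_jml(
    data: ResponseMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
    bias_correction: bool = False,
) -> RaschFit:
    """Joint maximum-likelihood Rasch fit of a screened response matrix.

    Alternates Newton solves of person abilities (difficulties fixed) and item
    difficulties (abilities fixed), re-centering difficulties — and shifting
    abilities by the same amount, so the likelihood is untouched — every
    cycle.  Stops when the largest absolute parameter change over a full cycle
    drops below ``tol``.  ``bias_correction`` applies the (L-1)/L shrinkage to
    the centered difficulties of the returned fit.

    The input must already have passed extreme-score screening; perfect or
    zero margins make the corresponding parameter infinite.
    """
    values = data.values()
    obs = ~np.isnan(values)
    X = np.where(obs, values, 0.0)
    n, L = X.shape
    r = X.sum(axis=1)  # person raw scores
    k = obs.sum(axis=1)  # items administered per person
    s = X.sum(axis=0)  # item scores
    m = obs.sum(axis=0)
    if ((r == 0) | (r == k)).any() or ((s == 0) | (s == m)).any():
        raise DataError("estimate_jml requires screened data with no extreme margins")

    beta = np.log((r + 0.5) / (k - r + 0.5))
    p_fail = (m - s) / m
    delta = np.log(p_fail / (1.0 - p_fail))
    delta -= delta.mean()

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta_old, delta_old = beta.copy(), delta.copy()
        beta = _newton_margin(r, -delta[None, :] * np.ones((n, 1)), obs, beta, +1.0)
        delta = _newton_margin(s, (beta[:, None] * np.ones((1, L))).T, obs.T, delta, -1.0)
        shift = delta.mean()
        delta -= shift
        beta -= shift
        change = max(np.max(np.abs(beta - beta_old)), np.max(np.abs(delta - delta_old)))
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"JML did not converge in {max_iter} cycles (last change {change:.2e})",
            ConvergenceWarning,
        )

    if bias_correction:
        delta = delta * (L - 1) / L

    ll = _loglik(X, obs, beta, delta)
    person_ids = data.X.index
    item_ids = data.X.columns
    nan_p = pd.Series(np.nan, index=person_ids)
    nan_i = pd.Series(np.nan, index=item_ids)
    fit = RaschFit(
        beta=pd.Series(beta, index=person_ids),
        delta=pd.Series(delta, index=item_ids),
        se_beta=nan_p,
        se_delta=nan_i,
        converged=converged,
        n_iter=it,
        loglik=ll,
    )
    return standard_errors(fit, data)


def standard_errors(fit: RaschFit, data: ResponseMatrix) -> RaschFit:
    """Fill asymptotic standard errors from the binomial information.

    se(delta_i) = 1/sqrt(sum_p P_pi(1-P_pi)) over observed cells, and
    analogously over items for each person.
    """
    values = data.values()
    obs = ~np.isnan(values)
    P = expit(fit.beta.to_numpy()[:, None] - fit.delta.to_numpy()[None, :])
    W = np.where(obs, P * (1.0 - P), 0.0)
    info_p = W.sum(axis=1)
    info_i = W.sum(axis=0)
    with np.errstate(divide="ignore"):
        se_b = np.where(info_p > 0, 1.0 / np.sqrt(info_p), np.nan)
        se_d = np.where(info_i > 0, 1.0 / np.sqrt(info_i), np.nan)
    fit.se_beta = pd.Series(se_b, index=fit.beta.index)
    fit.se_delta = pd.Series(se_d, index=fit.delta.index)
    return fit


def export_fit(fit: RaschFit, data: ResponseMatrix, path) -> pd.DataFrame:
    """Write the measure table (entity_type, id, measure, se, raw_score, count)."""
    values = data.values()
    obs = ~np.isnan(values)
    X = np.where(obs, values, 0.0)
    rows = []
    for pid, b, se, score, cnt in zip(
        fit.beta.index, fit.beta, fit.se_beta, X.sum(axis=1), obs.sum(axis=1)
    ):
        rows.append(("person", pid, b, se, int(score), int(cnt)))
    for iid, d, se, score, cnt in zip(
        fit.delta.index, fit.delta, fit.se_delta, X.sum(axis=0), obs.sum(axis=0)
    ):
        rows.append(("item", iid, d, se, int(score), int(cnt)))
    table = pd.DataFrame(
        rows, columns=["entity_type", "id", "measure", "se", "raw_score", "count"]
    )
    table.to_csv(path, index=False)
    return table
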