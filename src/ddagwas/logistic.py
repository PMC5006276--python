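"""Penalized multivariate logistic regression and marginal pairwise tests.

The collective logistic baseline maximizes

    L = Σ_k ln Pr(y^k | a^k) - (λ/2) Σ_{i<j} γ_ij²

jointly over the intercept α, marginal effects β_i, and interaction
effects γ_ij (ridge on γ only, mirroring the genotype-distribution
method's unpenalized fields).  The marginal pairwise test fits, for each
SNP pair separately, a logistic model with two marginal terms plus the
product term and reports the likelihood-ratio p-value of the product
term (1 d.f. binary, 4 d.f. genotypic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .cohort import EncodedMatrix
from .fit import _mnlogit_newton, _values
from .models import collapse, indicator_matrix, n_levels, pair_indices
from .risk import RiskModel

log = logging.getLogger(__name__)


@dataclass
class PairwiseTestResult:
    """Marginal epistasis test for one SNP pair."""

    pair: tuple[int, int]
    interaction_estimate: float
    statistic: float
    p_value: float
    marginal_estimates: np.ndarray
    flagged: bool = False


def _design(values: np.ndarray, model: str
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """[1 | singles | pair products] design plus penalty/γ masks."""
    n, m = values.shape
    L = n_levels(model)
    iu, ju = pair_indices(m)
    if L == 1:
        V = values.astype(float)
        X = np.concatenate([np.ones((n, 1)), V, V[:, iu] * V[:, ju]],
                           axis=1)
        n_beta = m
    else:
        Z = indicator_matrix(values, model).reshape(n, m, 2)
        pairs = (Z[:, iu, :, None] * Z[:, ju, None, :]).reshape(n, -1)
        X = np.concatenate([np.ones((n, 1)), Z.reshape(n, 2 * m), pairs],
                           axis=1)
        n_beta = 2 * m
    d = X.shape[1]
    pen = np.zeros(d)
    pen[1 + n_beta:] = 1.0  # ridge on interaction coefficients only
    return X, pen, np.arange(1 + n_beta, d)


def fit_logistic(enc, labels, penalizer: float = 0.0) -> RiskModel:
    """Joint penalized logistic fit with all pairwise interactions."""
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    labels = np.asarray(labels)
    m = values.shape[1]
    L = n_levels(model)
    rows = np.concatenate([values, labels[:, None]], axis=1)
    uniq, w = collapse(rows)
    uv, uy = uniq[:, :-1], uniq[:, -1]
    X, pen, _ = _design(uv, model)
    Y = np.zeros((len(uniq), 2))
    Y[np.arange(len(uniq)), uy] = w
    # per-individual penalty convention: total ridge strength scales with n
    W, ll, conv, it = _mnlogit_newton(X, Y, penalizer * len(labels),
                                      pen[None, :],
                                      np.zeros((1, X.shape[1])))
    coef = W[0]
    iu, ju = pair_indices(m)
    if L == 1:
        beta = coef[1: 1 + m]
        gamma = np.zeros((m, m))
        gamma[iu, ju] = coef[1 + m:]
        gamma += gamma.T
    else:
        beta = coef[1: 1 + 2 * m].reshape(m, 2)
        gamma = np.zeros((m, m, 2, 2))
        blocks = coef[1 + 2 * m:].reshape(-1, 2, 2)
        gamma[iu, ju] = blocks
        gamma[ju, iu] = np.swapaxes(blocks, 1, 2)
    if not conv and penalizer == 0.0:
        log.warning("logistic fit flagged: possible separation at "
                    "penalizer 0")
    prev = float(np.clip(labels.mean(), 1e-9, 1 - 1e-9))
    return RiskModel(alpha=float(coef[0]), beta=beta, gamma=gamma,
                     prevalence=prev, source="logistic", model=model,
                     converged=conv)


def _pair_design(values: np.ndarray, i: int, j: int, model: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair design [1 | marg_i | marg_j | product] and product cols."""
    n = values.shape[0]
    L = n_levels(model)
    if L == 1:
        vi = values[:, i].astype(float)
        vj = values[:, j].astype(float)
        X = np.column_stack([np.ones(n), vi, vj, vi * vj])
        return X, np.array([3])
    Zi = np.column_stack([values[:, i] == 1, values[:, i] == 2]) * 1.0
    Zj = np.column_stack([values[:, j] == 1, values[:, j] == 2]) * 1.0
    prod = (Zi[:, :, None] * Zj[:, None, :]).reshape(n, 4)
    X = np.concatenate([np.ones((n, 1)), Zi, Zj, prod], axis=1)
    return X, np.arange(5, 9)


def pairwise_epistasis(enc, labels) -> list[PairwiseTestResult]:
    """Marginal per-pair interaction LR tests over all m(m-1)/2 pairs."""
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    labels = np.asarray(labels, dtype=float)
    m = values.shape[1]
    if m < 2:
        raise ValueError("pairwise tests need m >= 2")
    results = []
    iu, ju = pair_indices(m)
    for i, j in zip(iu, ju):
        i, j = int(i), int(j)
        X, prod_cols = _pair_design(values, i, j, model)
        degenerate = (np.ptp(values[:, i]) == 0 or np.ptp(values[:, j]) == 0)
        if degenerate:
            results.append(PairwiseTestResult(
                (i, j), 0.0, 0.0, 1.0, np.zeros(X.shape[1] - 1
                                                - len(prod_cols)),
                flagged=True))
            continue
        try:
            full = sm.GLM(labels, X,
                          family=sm.families.Binomial()).fit()
            red = sm.GLM(labels, np.delete(X, prod_cols, axis=1),
                         family=sm.families.Binomial()).fit()
            stat = max(0.0, float(red.deviance - full.deviance))
            df = len(prod_cols)
            p = float(chi2.sf(stat, df=df))
            est = (float(full.params[prod_cols[0]]) if df == 1
                   else float(np.max(np.abs(full.params[prod_cols]))))
            marg = np.asarray(full.params[1: prod_cols[0]])
            results.append(PairwiseTestResult(
                (i, j), est, stat, max(p, np.finfo(float).tiny), marg))
        except Exception as exc:  # separation / perfect fit edge cases
            log.warning("pairwise test (%d, %d) failed: %s", i, j, exc)
            results.append(PairwiseTestResult(
                (i, j), 0.0, 0.0, 1.0, np.zeros(2), flagged=True))
    return results


def pairwise_theta(enc, labels) -> RiskModel:
    """Risk parameters assembled from marginal tests only.

    β_i from each SNP's single-locus log odds ratio (0.5 pseudo-counts on
    boundary cells), γ_ij from the per-pair product-term estimates; the
    comparison baseline for collective-inference accuracy studies.
    """
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    labels = np.asarray(labels)
    from .fit import fit_independent
    from .risk import to_risk_model
    ind = fit_independent(EncodedMatrix(values, model), labels)
    rm = to_risk_model(ind, calibration=(values, labels))
    m = values.shape[1]
    L = n_levels(model)
    gamma = np.zeros((m, m)) if L == 1 else np.zeros((m, m, 2, 2))
    for res in pairwise_epistasis(enc, labels):
        i, j = res.pair
        if L == 1:
            gamma[i, j] = gamma[j, i] = res.interaction_estimate
        else:
            # genotypic per-pair tests carry a 2x2 block of products
            X, prod_cols = _pair_design(values, i, j, model)
            try:
                full = sm.GLM(labels.astype(float), X,
                              family=sm.families.Binomial()).fit()
                block = np.asarray(full.params[prod_cols]).reshape(2, 2)
            except Exception:
                block = np.zeros((2, 2))
            gamma[i, j] = block
            gamma[j, i] = block.T
    return RiskModel(alpha=rm.alpha, beta=rm.beta, gamma=gamma,
                     prevalence=rm.prevalence, source="pairwise",
                     model=model)
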