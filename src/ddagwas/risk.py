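"""Disease-risk models, AUC scoring, and cross-validated penalizer choice.

Bayes' theorem converts a pair of fitted genotype distributions into a
posterior disease probability

    Pr(y=1 | a) = 1 / (1 + exp(-α - Σ β_i a_i - Σ_{i<j} γ_ij a_i a_j))

with β = h⁽¹⁾ - h⁽⁰⁾ and γ = J⁽¹⁾ - J⁽⁰⁾; α carries the prevalence and
the log-partition difference.  Prediction quality is scored by the
Mann-Whitney AUC with Hanley-McNeil confidence intervals, and the
penalizer (λ for EE/PL, ε for MF) is selected by stratified K-fold
cross-validation, optionally with independent-SNP p-value filtering
computed on each training fold only (the unbiased protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import chi2, norm, rankdata

from .cohort import EncodedMatrix
from .fit import FitResult, _values, fit
from .models import indicator_matrix, n_levels, pair_indices

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 2, 13))
DEFAULT_EPSILON_GRID = tuple(np.linspace(0.0, 1.0, 11))


@dataclass
class RiskModel:
    """Logistic-form disease-risk parameters θ = (α, β, γ)."""

    alpha: float
    beta: np.ndarray
    gamma: np.ndarray
    prevalence: float
    source: str = "DDA"
    model: str = "dominant"
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    def with_prevalence(self, p1: float) -> "RiskModel":
        """Re-specify prevalence; shifts α by the log-odds difference."""
        shift = logit(p1) - logit(self.prevalence)
        return RiskModel(self.alpha + shift, self.beta.copy(),
                         self.gamma.copy(), p1, self.source, self.model,
                         self.converged)

    def linear_predictor(self, enc) -> np.ndarray:
        """α-free part of the risk score for each genotype row."""
        values = _values(enc)
        L = n_levels(self.model)
        if L == 1:
            V = values.astype(float)
            return V @ self.beta \
                + 0.5 * np.einsum("ki,ij,kj->k", V, self.gamma, V)
        n, m = values.shape
        Z = indicator_matrix(values, self.model).reshape(n, m, 2)
        s = np.einsum("kig,ig->k", Z, self.beta)
        s += 0.5 * np.einsum("kig,ijgf,kjf->k", Z, self.gamma, Z,
                             optimize=True)
        return s

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta.tolist(),
                "gamma": self.gamma.tolist(),
                "prevalence": self.prevalence, "source": self.source,
                "model": self.model}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(d["alpha"], np.asarray(d["beta"]),
                   np.asarray(d["gamma"]), d["prevalence"],
                   d.get("source", "DDA"), d.get("model", "dominant"))


@dataclass
class CVResult:
    """Cross-validation profile over a penalizer grid."""

    grid: np.ndarray
    auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    best_penalizer: float
    score_label: str = "AUC"
    mean_snp_count: float | None = None
    fold_assignments: np.ndarray | None = None

    @property
    def best_auc(self) -> float:
        idx = int(np.flatnonzero(self.grid == self.best_penalizer)[0])
        return float(self.auc[idx])


def _calibrate_alpha(scores: np.ndarray, labels: np.ndarray,
                     maxiter: int = 100) -> float:
    """One-parameter MLE of the intercept given a fixed linear predictor."""
    labels = np.asarray(labels, dtype=float)
    alpha = float(logit(np.clip(labels.mean(), 1e-9, 1 - 1e-9))
                  - scores.mean())
    for _ in range(maxiter):
        p = expit(alpha + scores)
        g = float(np.sum(labels - p))
        h = float(np.sum(p * (1 - p)))
        if h <= 0:
            break
        step = g / h
        alpha += step
        if abs(step) < 1e-12:
            break
    return alpha


def to_risk_model(fitres: FitResult, prevalence: float | None = None,
                  calibration: tuple | None = None) -> RiskModel:
    """Bayes conversion of a per-group fit into disease-risk parameters.

    β and γ are the element-wise case-minus-control differences.  α uses
    ln(p1/p0) + lnZ0 - lnZ1 when both log-partitions are exact or stored;
    if ``calibration=(enc, labels)`` is supplied (recommended for PL/MF),
    α is instead fit by a one-parameter MLE on that data and then shifted
    to the requested prevalence.
    """
    psi0, psi1 = fitres.psi0, fitres.psi1
    if psi0.model != psi1.model or psi0.m != psi1.m:
        raise ValueError("case and control fits must share model and m")
    beta = psi1.h - psi0.h
    gamma = psi1.J - psi0.J
    model = RiskModel(alpha=0.0, beta=beta, gamma=gamma,
                      prevalence=0.5, source="DDA", model=psi0.model)
    if calibration is not None:
        enc, labels = calibration
        s = model.linear_predictor(enc)
        alpha = _calibrate_alpha(s, labels)
        sample_prev = float(np.mean(labels))
        if prevalence is None:
            prevalence = sample_prev
        alpha += logit(prevalence) - logit(np.clip(sample_prev, 1e-9,
                                                   1 - 1e-9))
    else:
        if psi0.log_partition is None or psi1.log_partition is None:
            raise ValueError("log-partition values missing; pass "
                             "calibration data instead")
        if prevalence is None:
            prevalence = 0.5
        alpha = (logit(prevalence)
                 + psi0.log_partition - psi1.log_partition)
    model.alpha = float(alpha)
    model.prevalence = prevalence
    return model


def predict_risk(model: RiskModel, enc) -> np.ndarray:
    """Posterior disease probability per genotype row; in (0, 1)."""
    return expit(model.alpha + model.linear_predictor(enc))


def auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC (midrank ties) with 95 % Hanley-McNeil CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    a = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n0 - 1) * (q2 - a * a)) / (n0 * n1)
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return float(a), (float(a - half), float(a + half))


def independent_snp_pvalues(enc, labels) -> np.ndarray:
    """Per-SNP no-interaction likelihood-ratio (G-test) p-values.

    Binary: 2x2 carrier table, χ²(1); genotypic: 2x3 table, χ²(2).
    Analytic — no numerical optimization.
    """
    values = _values(enc)
    labels = np.asarray(labels)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    L = n_levels(model)
    n_lev = L + 1
    m = values.shape[1]
    g = np.zeros(m)
    for y, rows in ((0, values[labels == 0]), (1, values[labels == 1])):
        ny = rows.shape[0]
        for i in range(m):
            obs = np.bincount(rows[:, i], minlength=n_lev).astype(float)
            tot = np.bincount(values[:, i], minlength=n_lev).astype(float)
            exp = tot * ny / len(values)
            nz = obs > 0
            g[i] += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz]
                                                        / exp[nz])))
    return chi2.sf(g, df=L)


def stratified_folds(labels, folds: int, seed: int) -> np.ndarray:
    """Fold assignment array preserving case/control proportions."""
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assign = np.empty(len(labels), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has fewer samples ({len(idx)}) than folds")
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def _fit_and_score(train_v, train_y, test_v, model, method, penalizer,
                   map_fn=map):
    if method == "logistic":
        from .logistic import fit_logistic
        rm = fit_logistic(EncodedMatrix(train_v, model), train_y, penalizer)
    else:
        fr = fit(EncodedMatrix(train_v, model), train_y, method, penalizer,
                 map_fn=map_fn)
        rm = to_risk_model(fr, calibration=(train_v, train_y))
    return predict_risk(rm, test_v)


def cross_validate(enc, labels, method: str = "EE",
                   grid=None, p_c: float | None = None, folds: int = 5,
                   seed: int = 0, phenotype_preselected: bool = False,
                   map_fn=map) -> CVResult:
    """Stratified K-fold AUC profile over a penalizer grid.

    For each grid value, models are trained per fold and the test-fold
    scores pooled into a single ROC before computing AUC.  With ``p_c``
    set, independent-SNP p-values are computed on each training fold
    alone and SNPs with p >= p_c dropped before fitting (so the reported
    score is an unbiased AUC).  If SNP selection used phenotype data on
    the full sample, pass ``phenotype_preselected=True`` and the score is
    labelled pAUC.  Ties in the argmax break toward the larger penalizer.
    """
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    labels = np.asarray(labels)
    if grid is None:
        grid = DEFAULT_EPSILON_GRID if method == "MF" else \
            DEFAULT_LAMBDA_GRID
    grid = np.asarray(list(grid), dtype=float)
    assign = stratified_folds(labels, folds, seed)

    aucs = np.empty(len(grid))
    lo = np.empty(len(grid))
    hi = np.empty(len(grid))
    snp_counts = []
    for gi, pen in enumerate(grid):
        pooled_scores = np.empty(len(labels))
        for k in range(folds):
            test = assign == k
            train = ~test
            tv, ty = values[train], labels[train]
            sv = values[test]
            if p_c is not None:
                pvals = independent_snp_pvalues(
                    EncodedMatrix(tv, model), ty)
                keep = pvals < p_c
                if not keep.any():
                    keep = pvals == pvals.min()
                snp_counts.append(int(keep.sum()))
                tv, sv = tv[:, keep], sv[:, keep]
            pooled_scores[test] = _fit_and_score(tv, ty, sv, model,
                                                 method, pen, map_fn)
        aucs[gi], (lo[gi], hi[gi]) = auc(pooled_scores, labels)
    best = np.flatnonzero(aucs == aucs.max())
    best_pen = float(grid[best[np.argmax(grid[best])]])
    return CVResult(grid=grid, auc=aucs, ci_low=lo, ci_high=hi,
                    best_penalizer=best_pen,
                    score_label="pAUC" if phenotype_preselected else "AUC",
                    mean_snp_count=(float(np.mean(snp_counts))
                                    if snp_counts else None),
                    fold_assignments=assign)


def mse_vs_truth(model: RiskModel, true_theta: RiskModel) -> float:
    """Mean squared error over all distinct β and γ entries."""
    if model.m != true_theta.m:
        raise ValueError("risk models differ in m")
    iu, ju = pair_indices(model.m)
    db = (model.beta - true_theta.beta).ravel()
    dg = (model.gamma - true_theta.gamma)[iu, ju].ravel()
    err = np.concatenate([db, dg])
    return float(np.mean(err ** 2))
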