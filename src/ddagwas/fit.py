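"""Penalized maximum-likelihood fitting of per-group genotype distributions.

Three routes maximize the penalized log-likelihood per individual

    L_y / n_y = (1/n_y) Σ_k ln Pr(a^k | y) - (λ/2) Σ_{i<j} J_ij²

(penalty on couplings only, fields unpenalized; the total penalty scales
with the group size, so λ's shrinkage strength is sample-size free):

* EE — exact enumeration of the state space; Newton iterations on the
  concave objective, with the gradient of the log-partition equal to the
  model moments.  Exact, but limited to small SNP counts.
* PL — pseudo-likelihood: each site's conditional distribution given the
  rest is a penalized (multinomial) logistic problem; couplings are
  symmetrized by averaging.  Scales to large panels and parallelizes.
* MF — naive mean field: couplings from the inverse of the connected
  covariance matrix, shrunk off-diagonal by ε ∈ [0, 1] (ε = 0 is the
  independent-SNP limit); log-partition approximated by the mean-field
  free energy.

The no-interaction (independent-SNP) model is solved analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, ncx2

from .cohort import EncodedMatrix
from .models import (FIT_MAX_BINARY, FIT_MAX_GENOTYPIC, ModelParams,
                     collapse, energies, feature_matrix, n_levels, n_params,
                     pack_params, pair_indices, penalty_mask, state_table,
                     suff_stats, unpack_params)

log = logging.getLogger(__name__)

GROUPS = ("control", "case", "pooled")

# above this Phi size (states x params), EE falls back to a
# gradient-only quasi-Newton path with chunked moment accumulation
_EE_DENSE_LIMIT = 40_000_000


@dataclass
class FitResult:
    """Per-group fitted parameters and their penalized objective values."""

    psi0: ModelParams
    psi1: ModelParams
    psi_pooled: ModelParams
    loglik0: float
    loglik1: float
    loglik_pooled: float
    method: str
    penalizer: float
    converged: bool = True
    iterations: int = 0

    @property
    def m(self) -> int:
        return self.psi0.m

    @property
    def model(self) -> str:
        return self.psi0.model


def _values(enc) -> np.ndarray:
    return enc.values if isinstance(enc, EncodedMatrix) else np.asarray(enc)


def _group_rows(values: np.ndarray, labels: np.ndarray, group: str
                ) -> np.ndarray:
    labels = np.asarray(labels)
    if group == "case":
        return values[labels == 1]
    if group == "control":
        return values[labels == 0]
    if group == "pooled":
        return values
    raise ValueError(f"unknown group {group!r}")


def _pair_sq_sum(J: np.ndarray, model: str) -> float:
    iu, ju = pair_indices(J.shape[0])
    return float(np.sum(np.asarray(J)[iu, ju] ** 2))


def penalized_loglik(psi: ModelParams, rows, lam: float) -> float:
    """Total penalized log-likelihood of one group's data under psi.

    Uses the exact log-partition by enumeration when feasible, else the
    stored approximation on ``psi.log_partition``.
    """
    rows = _values(rows)
    if rows.shape[1] != psi.m:
        raise ValueError(
            f"data has {rows.shape[1]} SNPs but psi has m={psi.m}")
    cap = FIT_MAX_BINARY if psi.n_levels == 1 else FIT_MAX_GENOTYPIC
    if psi.m <= cap:
        states = state_table(psi.m, psi.model)
        lnZ = float(logsumexp(energies(states, psi)))
    elif psi.log_partition is not None:
        lnZ = psi.log_partition
    else:
        raise ValueError("m too large for enumeration and no stored "
                         "log-partition on psi")
    uniq, w = collapse(rows)
    e = float(w @ energies(uniq, psi))
    n = rows.shape[0]
    return e - n * lnZ - n * 0.5 * lam * _pair_sq_sum(psi.J, psi.model)


# --- fixed-coordinate bookkeeping ---------------------------------------

def _fixed_to_theta(fixed: dict | None, m: int, model: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Translate a fixed-parameter spec to flat theta indices/values.

    fixed = {"h": [(i, level, value), ...],
             "J": [(i, j, level_i, level_j, value), ...]}
    """
    from .models import J_index, h_index
    idx, vals = [], []
    if fixed:
        for i, g, v in fixed.get("h", []):
            idx.append(h_index(i, m, model, g))
            vals.append(v)
        for i, j, gi, gj, v in fixed.get("J", []):
            idx.append(J_index(i, j, m, model, gi, gj))
            vals.append(v)
    return np.asarray(idx, dtype=int), np.asarray(vals, dtype=float)


def fix_h(i: int, value, model: str) -> dict:
    """Fixed-spec pinning all field levels of site i to ``value``."""
    value = np.atleast_1d(np.asarray(value, dtype=float))
    L = n_levels(model)
    return {"h": [(i, g, float(value[g - 1] if L > 1 else value[0]))
                  for g in range(1, L + 1)]}


def fix_J(i: int, j: int, value, model: str) -> dict:
    """Fixed-spec pinning the full coupling block of pair (i, j)."""
    L = n_levels(model)
    if L == 1:
        return {"J": [(i, j, 1, 1, float(np.asarray(value).reshape(())))]}
    block = np.asarray(value, dtype=float).reshape(2, 2)
    return {"J": [(i, j, gi, gj, float(block[gi - 1, gj - 1]))
                  for gi in (1, 2) for gj in (1, 2)]}


# --- exact enumeration --------------------------------------------------

_EE_CACHE: dict[tuple[int, str], tuple[np.ndarray, np.ndarray | None]] = {}


def _ee_tables(m: int, model: str):
    key = (m, model)
    if key not in _EE_CACHE:
        states = state_table(m, model)
        p = n_params(m, model)
        Phi = (feature_matrix(states, model)
               if states.shape[0] * p <= _EE_DENSE_LIMIT else None)
        if len(_EE_CACHE) > 8:
            _EE_CACHE.clear()
        _EE_CACHE[key] = (states, Phi)
    return _EE_CACHE[key]


def _ee_solve(phibar: np.ndarray, n: float, lam: float, m: int, model: str,
              fixed: dict | None = None, warm: np.ndarray | None = None,
              gtol: float = 1e-8, maxiter: int = 500):
    """Maximize the EE penalized objective given empirical moments.

    Returns (theta, lnZ, loglik_total, converged, iterations).  The
    objective depends on the data only through the mean sufficient
    statistics, so the cost is independent of sample size.
    """
    states, Phi = _ee_tables(m, model)
    p = n_params(m, model)
    mask = penalty_mask(m, model)
    lam = lam * n  # per-individual penalty convention
    fidx, fval = _fixed_to_theta(fixed, m, model)
    free = np.setdiff1d(np.arange(p), fidx)

    theta = np.zeros(p) if warm is None else warm.copy()
    theta[fidx] = fval

    def eval_all(th):
        if Phi is not None:
            eta = Phi @ th
            emax = eta.max()
            w = np.exp(eta - emax)
            Z = w.sum()
            prob = w / Z
            lnZ = np.log(Z) + emax
            mu = prob @ Phi
        else:  # moment accumulation without an explicit feature matrix
            h, J = unpack_params(th, m, model)
            psi = ModelParams(model=model, h=h, J=J)
            e = energies(states, psi)
            emax = e.max()
            w = np.exp(e - emax)
            Z = w.sum()
            prob = w / Z
            lnZ = np.log(Z) + emax
            from .models import indicator_matrix
            Zi = indicator_matrix(states, model)
            singles = prob @ Zi
            pair_full = (Zi * prob[:, None]).T @ Zi
            iu, ju = pair_indices(m)
            L = n_levels(model)
            if L == 1:
                mu = np.concatenate([singles, pair_full[iu, ju]])
            else:
                blocks = pair_full.reshape(m, 2, m, 2).transpose(0, 2, 1, 3)
                mu = np.concatenate([singles,
                                     blocks[iu, ju].reshape(-1)])
        ll = n * (phibar @ th - lnZ) - 0.5 * lam * np.sum(mask * th ** 2)
        grad = n * (phibar - mu) - lam * mask * th
        return ll, grad, prob, lnZ

    if Phi is None:  # quasi-Newton, gradient only
        def negf(x):
            th = theta.copy()
            th[free] = x
            ll, grad, _, _ = eval_all(th)
            return -ll, -grad[free]

        res = optimize.minimize(negf, theta[free], jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": maxiter,
                                         "gtol": gtol * n})
        theta[free] = res.x
        ll, grad, _, lnZ = eval_all(theta)
        conv = bool(np.max(np.abs(grad[free]), initial=0.0) / n < 100 * gtol
                    or res.success)
        return theta, lnZ, ll, conv, int(res.nit)

    ll, grad, prob, lnZ = eval_all(theta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        gfree = grad[free]
        if gfree.size == 0 or np.max(np.abs(gfree)) / n < gtol:
            converged = True
            break
        PW = Phi * prob[:, None]
        mu = prob @ Phi
        cov = PW.T @ Phi - np.outer(mu, mu)
        H = n * cov + lam * np.diag(mask)
        Hf = H[np.ix_(free, free)]
        Hf[np.diag_indices_from(Hf)] += 1e-10 * n
        try:
            step = np.linalg.solve(Hf, gfree)
        except np.linalg.LinAlgError:
            step = gfree / (np.diag(Hf) + 1e-8)
        t = 1.0
        for _ in range(40):
            cand = theta.copy()
            cand[free] += t * step
            ll_new, grad_new, prob_new, lnZ_new = eval_all(cand)
            if ll_new >= ll + 1e-4 * t * (gfree @ step):
                theta, ll, grad, prob, lnZ = cand, ll_new, grad_new, \
                    prob_new, lnZ_new
                break
            t *= 0.5
        else:
            break  # no ascent step found; flag non-convergence
    else:
        it = maxiter
    if not converged:
        gfree = grad[free]
        converged = bool(gfree.size == 0
                         or np.max(np.abs(gfree)) / n < gtol * 100)
        if not converged:
            log.warning("EE Newton did not reach tolerance in %d iterations",
                        it)
    return theta, lnZ, ll, converged, it


def fit_ee(enc, labels, penalizer: float = 0.0, group: str = "pooled",
           fixed: dict | None = None, warm: ModelParams | None = None
           ) -> ModelParams:
    """Exact-enumeration fit of one group's genotype distribution."""
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else \
        ("dominant" if values.max(initial=0) <= 1 else "genotypic")
    rows = _group_rows(values, labels, group)
    m = rows.shape[1]
    cap = FIT_MAX_BINARY if n_levels(model) == 1 else FIT_MAX_GENOTYPIC
    if m > cap:
        raise ValueError(f"EE limited to m<={cap} for {model!r} encodings")
    phibar = suff_stats(rows, model)
    theta, lnZ, _, conv, _ = _ee_solve(
        phibar, rows.shape[0], penalizer, m, model, fixed=fixed,
        warm=None if warm is None else warm.theta())
    h, J = unpack_params(theta, m, model)
    return ModelParams(model=model, h=h, J=J, group=group,
                       log_partition=lnZ)


class EEEngine:
    """Cached sufficient statistics for repeated EE fits on one panel.

    Likelihood-ratio scans and permutation nulls re-fit the same data
    hundreds of times with different labels or pinned parameters; the
    EE objective depends on the data only through per-group mean
    sufficient statistics, which this engine computes once per label
    assignment from a collapsed row table.  Restricted refits warm-start
    from the unrestricted optimum and reuse its Hessian factor as a
    preconditioner.
    """

    def __init__(self, values: np.ndarray, model: str):
        values = np.asarray(values)
        self.model = model
        self.m = values.shape[1]
        states, Phi = _ee_tables(self.m, model)
        if Phi is None:
            raise ValueError("panel too large for the dense EE engine")
        self.Phi = Phi
        self.mask = penalty_mask(self.m, model)
        uniq, inv = np.unique(values, axis=0, return_inverse=True)
        self.Phi_data = feature_matrix(uniq, model)
        self.inv = inv
        self.n_unique = len(uniq)

    def group_stats(self, labels, group: str) -> tuple[np.ndarray, float]:
        """(mean sufficient statistics, group size) for one group."""
        labels = np.asarray(labels)
        if group == "pooled":
            sel = self.inv
        elif group == "case":
            sel = self.inv[labels == 1]
        elif group == "control":
            sel = self.inv[labels == 0]
        else:
            raise ValueError(f"unknown group {group!r}")
        counts = np.bincount(sel, minlength=self.n_unique).astype(float)
        n = counts.sum()
        return (counts @ self.Phi_data) / n, n

    def _eval(self, theta, phibar, n, lam):
        lam = lam * n  # per-individual penalty convention
        eta = self.Phi @ theta
        emax = eta.max()
        w = np.exp(eta - emax)
        Z = w.sum()
        prob = w / Z
        lnZ = np.log(Z) + emax
        ll = n * (phibar @ theta - lnZ) \
            - 0.5 * lam * np.sum(self.mask * theta ** 2)
        mu = prob @ self.Phi
        grad = n * (phibar - mu) - lam * self.mask * theta
        return ll, grad, prob, mu, lnZ

    def hessian(self, theta, n, lam) -> np.ndarray:
        lam = lam * n  # per-individual penalty convention
        eta = self.Phi @ theta
        prob = np.exp(eta - eta.max())
        prob /= prob.sum()
        PW = self.Phi * prob[:, None]
        mu = prob @ self.Phi
        H = n * (PW.T @ self.Phi - np.outer(mu, mu))
        H += lam * np.diag(self.mask)
        return H

    def solve(self, phibar, n, lam, fixed: dict | None = None,
              warm: np.ndarray | None = None,
              precond: np.ndarray | None = None,
              gtol: float = 1e-8, maxiter: int = 200):
        """Maximize the penalized objective; returns (theta, lnZ, ll, ok).

        With ``precond`` (a Hessian from a nearby solution), iterations
        use the fixed factor instead of rebuilding the Hessian; the loop
        falls back to exact Newton if progress stalls.
        """
        p = self.Phi.shape[1]
        fidx, fval = _fixed_to_theta(fixed, self.m, self.model)
        free = np.setdiff1d(np.arange(p), fidx)
        theta = np.zeros(p) if warm is None else warm.copy()
        theta[fidx] = fval

        pre_cho = None
        if precond is not None:
            from scipy.linalg import cho_factor, cho_solve
            try:
                pre_cho = cho_factor(precond[np.ix_(free, free)])
            except np.linalg.LinAlgError:
                pre_cho = None

        ll, grad, prob, mu, lnZ = self._eval(theta, phibar, n, lam)
        converged = False
        use_precond = pre_cho is not None
        for it in range(1, maxiter + 1):
            g = grad[free]
            if g.size == 0 or np.max(np.abs(g)) / n < gtol:
                converged = True
                break
            if use_precond and it <= 15:
                from scipy.linalg import cho_solve
                step = cho_solve(pre_cho, g)
            else:
                use_precond = False
                H = self.hessian(theta, n, lam)
                Hf = H[np.ix_(free, free)]
                Hf[np.diag_indices_from(Hf)] += 1e-10 * n
                step = np.linalg.solve(Hf, g)
            t = 1.0
            ok = False
            for _ in range(40):
                cand = theta.copy()
                cand[free] += t * step
                out = self._eval(cand, phibar, n, lam)
                if out[0] >= ll + 1e-4 * t * (g @ step):
                    theta, (ll, grad, prob, mu, lnZ) = cand, out
                    ok = True
                    break
                t *= 0.5
            if not ok:
                if use_precond:
                    use_precond = False  # retry with the exact Hessian
                    continue
                break
        return theta, lnZ, ll, converged


# --- analytic independent-SNP solution ----------------------------------

def carrier_frequency(maf) -> np.ndarray:
    """Dominant-model carrier frequency under Hardy-Weinberg proportions.

    f = 2φ(1-φ) + φ² = φ(2-φ) for minor-allele frequency φ.
    """
    maf = np.asarray(maf, dtype=float)
    return maf * (2.0 - maf)


def _boundary_adjusted_freqs(rows: np.ndarray, model: str) -> np.ndarray:
    """Level frequencies with a 0.5 pseudo-count applied only on boundaries."""
    n, m = rows.shape
    L = n_levels(model)
    if L == 1:
        k = rows.sum(axis=0).astype(float)
        bad = (k == 0) | (k == n)
        if bad.any():
            log.info("added 0.5 pseudo-count to %d boundary frequencies",
                     int(bad.sum()))
            k = np.where(bad, k + 0.5, k)
            return k / np.where(bad, n + 1.0, float(n))
        return k / n
    counts = np.stack([(rows == g).sum(axis=0) for g in (0, 1, 2)],
                      axis=1).astype(float)  # (m, 3)
    bad = (counts == 0).any(axis=1)
    if bad.any():
        log.info("added 0.5 pseudo-count to %d boundary genotype cells",
                 int(bad.sum()))
        counts[bad] += 0.5
    return counts / counts.sum(axis=1, keepdims=True)


def _independent_params(rows: np.ndarray, model: str, group: str
                        ) -> tuple[ModelParams, float]:
    """Closed-form no-interaction fit; returns (psi, loglik_total)."""
    n, m = rows.shape
    L = n_levels(model)
    f = _boundary_adjusted_freqs(rows, model)
    if L == 1:
        h = np.log(f / (1.0 - f))
        J = np.zeros((m, m))
        lnZ = float(np.sum(np.log1p(np.exp(h))))
    else:
        h = np.log(f[:, 1:] / f[:, :1])
        J = np.zeros((m, m, 2, 2))
        lnZ = float(np.sum(np.log(1.0 + np.exp(h).sum(axis=1))))
    psi = ModelParams(model=model, h=h, J=J, group=group,
                      log_partition=lnZ)
    ll = penalized_loglik(psi, rows, 0.0)
    return psi, ll


def fit_independent(enc, labels) -> FitResult:
    """Analytic independent-SNP solution for all three groups.

    Binary: h_i = ln(f_i / (1 - f_i)); genotypic: h_i(g) =
    ln(f_i(g) / f_i(0)).  Couplings are identically zero and no numerical
    optimization is performed.  Boundary frequencies get a logged 0.5
    pseudo-count so fields stay finite.
    """
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    out = {}
    for group in GROUPS:
        rows = _group_rows(values, labels, group)
        if rows.shape[0] == 0:
            raise ValueError(f"group {group!r} is empty")
        out[group] = _independent_params(rows, model, group)
    return FitResult(psi0=out["control"][0], psi1=out["case"][0],
                     psi_pooled=out["pooled"][0],
                     loglik0=out["control"][1], loglik1=out["case"][1],
                     loglik_pooled=out["pooled"][1],
                     method="independent", penalizer=np.inf)


def power_independent(f0: float, f1: float, n: int,
                      alpha_level: float = 0.05) -> float:
    """Power of the single-SNP likelihood-ratio test (binary encoding).

    Uses the noncentral chi-square(1) approximation with noncentrality
    equal to the expected LR statistic at the true carrier frequencies
    f0 (control) and f1 (case), equal group sizes n/2 each.
    """
    if not (0 < f0 < 1 and 0 < f1 < 1):
        raise ValueError("frequencies must lie strictly in (0, 1)")
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must lie in (0, 1)")
    ny = n / 2.0
    fbar = (f0 + f1) / 2.0

    def kl(f):
        return f * np.log(f / fbar) + (1 - f) * np.log((1 - f) / (1 - fbar))

    nc = 2.0 * ny * (kl(f0) + kl(f1))
    crit = chi2.ppf(1.0 - alpha_level, df=1)
    return float(ncx2.sf(crit, df=1, nc=nc))


# --- pseudo-likelihood --------------------------------------------------

def _mnlogit_newton(X: np.ndarray, Y: np.ndarray, lam: float,
                    pen_mask: np.ndarray, W0: np.ndarray,
                    fixed_mask: np.ndarray | None = None,
                    gtol: float = 1e-8, maxiter: int = 200):
    """Penalized multinomial logistic Newton solver (reference class 0).

    X: (r, d) design over unique rows; Y: (r, C) response-class weights
    (column 0 = reference); W0: (C-1, d) start; pen_mask: (C-1, d) of
    0/1 penalty indicators; fixed_mask marks coordinates held at W0.
    Returns (W, loglik_penalized, converged, iters).
    """
    r, d = X.shape
    C = Y.shape[1]
    L = C - 1
    N = Y.sum(axis=1)
    ntot = float(N.sum())
    W = W0.copy()
    flat_pen = pen_mask.ravel()
    free = np.flatnonzero(~fixed_mask.ravel()) if fixed_mask is not None \
        else np.arange(L * d)

    def eval_all(Wc):
        eta = X @ Wc.T  # (r, L)
        full = np.concatenate([np.zeros((r, 1)), eta], axis=1)
        lse = logsumexp(full, axis=1)
        logp = full - lse[:, None]
        ll = float(np.sum(Y * logp)) \
            - 0.5 * lam * float(np.sum(pen_mask * Wc ** 2))
        P = np.exp(logp)  # (r, C)
        G = (Y[:, 1:] - N[:, None] * P[:, 1:]).T @ X - lam * pen_mask * Wc
        return ll, G, P

    ll, G, P = eval_all(W)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        g = G.ravel()[free]
        if g.size == 0 or np.max(np.abs(g)) / max(ntot, 1.0) < gtol:
            converged = True
            break
        Pp = P[:, 1:]
        A = N[:, None, None] * (np.einsum("rg,gf->rgf", Pp, np.eye(L))
                                - np.einsum("rg,rf->rgf", Pp, Pp))
        H = np.einsum("rgf,rd,re->gdfe", A, X, X,
                      optimize=True).reshape(L * d, L * d)
        H += lam * np.diag(flat_pen)
        Hf = H[np.ix_(free, free)]
        Hf[np.diag_indices_from(Hf)] += 1e-10 * max(ntot, 1.0)
        try:
            step = np.linalg.solve(Hf, g)
        except np.linalg.LinAlgError:
            step = g / (np.diag(Hf) + 1e-8)
        t = 1.0
        for _ in range(40):
            Wc = W.copy()
            flat = Wc.ravel()
            flat[free] += t * step
            Wc = flat.reshape(L, d)
            ll_new, G_new, P_new = eval_all(Wc)
            if ll_new >= ll + 1e-4 * t * (g @ step):
                W, ll, G, P = Wc, ll_new, G_new, P_new
                break
            t *= 0.5
        else:
            break
    return W, ll, converged, it


def _site_design(uniq: np.ndarray, w: np.ndarray, site: int, model: str
                 ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Design matrix and class weights for one site's conditional problem."""
    L = n_levels(model)
    others = [j for j in range(uniq.shape[1]) if j != site]
    r = uniq.shape[0]
    if L == 1:
        X = np.concatenate([np.ones((r, 1)),
                            uniq[:, others].astype(float)], axis=1)
        Y = np.zeros((r, 2))
        a = uniq[:, site]
        Y[np.arange(r), a] = w
    else:
        Z = np.zeros((r, len(others), 2))
        Z[:, :, 0] = uniq[:, others] == 1
        Z[:, :, 1] = uniq[:, others] == 2
        X = np.concatenate([np.ones((r, 1)), Z.reshape(r, -1)], axis=1)
        Y = np.zeros((r, 3))
        a = uniq[:, site]
        Y[np.arange(r), a] = w
    return X, Y, others


def _pl_site_solution(uniq, w, site, model, lam, fixed, warm_h, warm_J):
    """Solve one site's conditional problem; returns (h_site, J_row)."""
    m = uniq.shape[1]
    L = n_levels(model)
    X, Y, others = _site_design(uniq, w, site, model)
    d = X.shape[1]
    pen = np.ones((L, d))
    pen[:, 0] = 0.0
    W0 = np.zeros((L, d))
    if warm_h is not None:
        W0[:, 0] = np.atleast_1d(warm_h)
        for c, j in enumerate(others):
            if L == 1:
                W0[0, 1 + c] = warm_J[j]
            else:
                W0[:, 1 + 2 * c: 3 + 2 * c] = warm_J[j]  # (g_site, g_j)

    fixed_mask = np.zeros((L, d), dtype=bool)
    if fixed:
        for i, g, v in fixed.get("h", []):
            if i == site:
                W0[g - 1, 0] = v
                fixed_mask[g - 1, 0] = True
        for i, j, gi, gj, v in fixed.get("J", []):
            for a, b, ga, gb in ((i, j, gi, gj), (j, i, gj, gi)):
                if a == site:
                    c = others.index(b)
                    col = 1 + c if L == 1 else 1 + 2 * c + (gb - 1)
                    W0[ga - 1, col] = v
                    fixed_mask[ga - 1, col] = True

    W, ll, conv, it = _mnlogit_newton(X, Y, lam, pen, W0,
                                      fixed_mask=fixed_mask)
    if L == 1:
        h_site = float(W[0, 0])
        J_row = np.zeros(m)
        J_row[others] = W[0, 1:]
    else:
        h_site = W[:, 0].copy()
        J_row = np.zeros((m, 2, 2))
        for c, j in enumerate(others):
            J_row[j] = W[:, 1 + 2 * c: 3 + 2 * c]  # (g_site, g_j)
    return h_site, J_row, ll, conv, it


def _pl_objective(uniq, w, psi: ModelParams, lam: float) -> float:
    """Penalized pseudo-log-likelihood Σ_i Σ_k ln Pr(a_i | a_-i) - pen."""
    m = psi.m
    L = psi.n_levels
    n = float(np.sum(w))
    total = 0.0
    for site in range(m):
        X, Y, others = _site_design(uniq, w, site, psi.model)
        if L == 1:
            Wc = np.empty((1, X.shape[1]))
            Wc[0, 0] = psi.h[site]
            Wc[0, 1:] = psi.J[site, others]
        else:
            Wc = np.empty((2, X.shape[1]))
            Wc[:, 0] = psi.h[site]
            for c, j in enumerate(others):
                Wc[:, 1 + 2 * c: 3 + 2 * c] = psi.J[site, j]
        eta = X @ Wc.T
        full = np.concatenate([np.zeros((len(X), 1)), eta], axis=1)
        logp = full - logsumexp(full, axis=1)[:, None]
        total += float(np.sum(Y * logp))
    return total - n * 0.5 * lam * _pair_sq_sum(psi.J, psi.model)


def fit_pl(enc, labels, penalizer: float = 0.01, group: str = "pooled",
           fixed: dict | None = None, warm: ModelParams | None = None,
           map_fn=map) -> ModelParams:
    """Pseudo-likelihood fit of one group (per-site conditional problems).

    Sites are dispatched through ``map_fn`` (a parallel map may be
    supplied; results are independent of execution order), then couplings
    are symmetrized by averaging J_ij and J_ji.
    """
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    rows = _group_rows(values, labels, group)
    n, m = rows.shape
    if m < 2:
        raise ValueError("pseudo-likelihood needs m >= 2")
    uniq, w = collapse(rows)
    L = n_levels(model)
    lam_total = penalizer * n  # per-individual penalty convention

    def solve_site(site):
        wh = None if warm is None else warm.h[site]
        wJ = None if warm is None else warm.J[site]
        return _pl_site_solution(uniq, w, site, model, lam_total, fixed,
                                 wh, wJ)

    results = list(map_fn(solve_site, range(m)))
    if L == 1:
        h = np.array([r[0] for r in results])
        J = np.stack([r[1] for r in results])  # rows: site-major
        J = 0.5 * (J + J.T)
        np.fill_diagonal(J, 0.0)
    else:
        h = np.stack([r[0] for r in results])
        Jrows = np.stack([r[1] for r in results])  # (m, m, g_i, g_j)
        J = 0.5 * (Jrows + np.transpose(Jrows, (1, 0, 3, 2)))
        for i in range(m):
            J[i, i] = 0.0
    if penalizer == 0.0:
        conv = all(r[3] for r in results)
        if not conv:
            log.warning("PL at penalizer=0 may suffer separation; "
                        "some site problems did not converge")
    psi = ModelParams(model=model, h=h, J=J, group=group)
    psi.log_partition = mean_field_log_partition(psi)
    return psi


# --- mean field ---------------------------------------------------------

def fit_mf(enc, labels, epsilon: float = 1.0, group: str = "pooled"
           ) -> ModelParams:
    """Naive mean-field fit from the shrunk connected covariance matrix.

    C_ij = f_ij - f_i f_j with off-diagonal entries multiplied by
    ε ∈ [0, 1]; J = -C(ε)⁻¹ off the diagonal; fields from the local
    consistency h_i = logit(f_i) - Σ_j J_ij f_j (block analog for the
    genotypic model).  ε = 0 reproduces the analytic independent fit.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    rows = _group_rows(values, np.asarray(labels), group)
    n, m = rows.shape
    L = n_levels(model)
    f = _boundary_adjusted_freqs(rows, model)

    if L == 1:
        f2 = (rows.astype(float).T @ rows.astype(float)) / n
        C = f2 - np.outer(f, f)
        np.fill_diagonal(C, f * (1.0 - f))
        off = ~np.eye(m, dtype=bool)
        Ce = C.copy()
        Ce[off] *= epsilon
        Cinv = _safe_inv(Ce)
        J = -Cinv
        np.fill_diagonal(J, 0.0)
        h = np.log(f / (1 - f)) - J @ f
    else:
        fl = f[:, 1:]  # (m, 2) level-1/2 frequencies
        Z = np.zeros((n, m, 2))
        Z[:, :, 0] = rows == 1
        Z[:, :, 1] = rows == 2
        Zf = Z.reshape(n, 2 * m)
        fp = (Zf.T @ Zf) / n
        fv = fl.reshape(2 * m)
        C = fp - np.outer(fv, fv)
        for i in range(m):  # exact within-SNP blocks from cell frequencies
            block = np.diag(fl[i]) - np.outer(fl[i], fl[i])
            C[2 * i: 2 * i + 2, 2 * i: 2 * i + 2] = block
        Ce = C * epsilon
        for i in range(m):
            Ce[2 * i: 2 * i + 2, 2 * i: 2 * i + 2] = \
                C[2 * i: 2 * i + 2, 2 * i: 2 * i + 2]
        Cinv = _safe_inv(Ce)
        J = np.zeros((m, m, 2, 2))
        for i in range(m):
            for j in range(m):
                if i != j:
                    J[i, j] = -Cinv[2 * i: 2 * i + 2, 2 * j: 2 * j + 2]
        h = np.log(fl / f[:, :1]) \
            - np.einsum("ijgf,jf->ig", J, fl)
    psi = ModelParams(model=model, h=h, J=J, group=group)
    psi.log_partition = mean_field_log_partition(psi, start=f)
    return psi


def _safe_inv(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(C)
    except np.linalg.LinAlgError:
        log.warning("covariance matrix singular; adding 1e-8 diagonal "
                    "jitter")
        C = C + 1e-8 * np.eye(len(C))
        return np.linalg.inv(C)


def mean_field_log_partition(psi: ModelParams,
                             start: np.ndarray | None = None,
                             tol: float = 1e-12, maxiter: int = 500
                             ) -> float:
    """Mean-field (variational) estimate of ln Z.

    Solves the self-consistency equations for the site marginals by
    damped fixed-point iteration and evaluates the corresponding free
    energy lower bound.
    """
    m, L = psi.m, psi.n_levels
    if L == 1:
        q = expit(psi.h) if start is None else np.clip(start, 1e-9, 1 - 1e-9)
        for _ in range(maxiter):
            q_new = expit(psi.h + psi.J @ q)
            if np.max(np.abs(q_new - q)) < tol:
                q = q_new
                break
            q = 0.5 * q + 0.5 * q_new
        ent = -(q * np.log(q + 1e-300)
                + (1 - q) * np.log(1 - q + 1e-300)).sum()
        energy = psi.h @ q + 0.5 * q @ psi.J @ q
        return float(ent + energy)
    if start is None:
        eh = np.exp(psi.h)
        q = eh / (1.0 + eh.sum(axis=1, keepdims=True))
    else:
        q = np.clip(start[:, 1:], 1e-9, 1.0)
        q /= np.maximum(q.sum(axis=1, keepdims=True) + 1e-9, 1.0)
    for _ in range(maxiter):
        field = psi.h + np.einsum("ijgf,jf->ig", psi.J, q)
        e = np.exp(field - field.max(axis=1, keepdims=True))
        q_new = e / (np.exp(-field.max(axis=1, keepdims=True)) +
                     e.sum(axis=1, keepdims=True))
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = 0.5 * q + 0.5 * q_new
    q0 = np.clip(1.0 - q.sum(axis=1), 1e-300, 1.0)
    ent = -(q * np.log(q + 1e-300)).sum() - (q0 * np.log(q0)).sum()
    energy = float(np.sum(psi.h * q)
                   + 0.5 * np.einsum("ig,ijgf,jf->", q, psi.J, q))
    return float(ent + energy)


# --- unified fitting front end ------------------------------------------

def _fit_group(values: np.ndarray, model: str, labels, group: str,
               method: str, penalizer: float, fixed: dict | None = None,
               warm: ModelParams | None = None, map_fn=map
               ) -> tuple[ModelParams, float]:
    """Fit one group with any method; returns (psi, penalized objective)."""
    enc = EncodedMatrix(values, model)
    rows = _group_rows(values, np.asarray(labels), group)
    uniq, w = collapse(rows)
    if method == "EE":
        psi = fit_ee(enc, labels, penalizer, group, fixed=fixed, warm=warm)
        ll = penalized_loglik(psi, rows, penalizer)
    elif method == "PL":
        psi = fit_pl(enc, labels, penalizer, group, fixed=fixed, warm=warm,
                     map_fn=map_fn)
        ll = _pl_objective(uniq, w, psi, penalizer)
    elif method == "MF":
        psi = fit_mf(enc, labels, penalizer, group)
        if fixed:
            _apply_fixed(psi, fixed)
            psi.log_partition = mean_field_log_partition(psi)
        e = float(w @ energies(uniq, psi))
        ll = e - rows.shape[0] * psi.log_partition
    elif method == "independent":
        psi, ll = _independent_params(rows, model, group)
    else:
        raise ValueError(f"unknown method {method!r}")
    return psi, ll


def _apply_fixed(psi: ModelParams, fixed: dict) -> None:
    # closed-form methods: pin the restricted entries in place
    for i, g, v in fixed.get("h", []):
        if psi.n_levels == 1:
            psi.h[i] = v
        else:
            psi.h[i, g - 1] = v
    for i, j, gi, gj, v in fixed.get("J", []):
        if psi.n_levels == 1:
            psi.J[i, j] = psi.J[j, i] = v
        else:
            psi.J[i, j, gi - 1, gj - 1] = v
            psi.J[j, i, gj - 1, gi - 1] = v


def fit(enc, labels, method: str = "EE", penalizer: float = 0.0,
        map_fn=map) -> FitResult:
    """Fit case, control, and pooled genotype distributions.

    ``method`` is one of EE, PL, MF, independent; ``penalizer`` is λ for
    EE/PL and ε for MF (ignored for the independent solution).
    """
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    if method == "independent":
        return fit_independent(EncodedMatrix(values, model), labels)
    out, lls = {}, {}
    warm = None
    for group in ("pooled", "control", "case"):
        psi, ll = _fit_group(values, model, labels, group, method,
                             penalizer, warm=warm, map_fn=map_fn)
        out[group], lls[group] = psi, ll
        if group == "pooled":
            warm = psi  # warm-start group fits from the pooled solution
    return FitResult(psi0=out["control"], psi1=out["case"],
                     psi_pooled=out["pooled"],
                     loglik0=lls["control"], loglik1=lls["case"],
                     loglik_pooled=lls["pooled"],
                     method=method, penalizer=penalizer)
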