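"""Likelihood-ratio statistics with χ² asymptotics and permutation nulls.

The overall statistic is q = 2[(L₁ + L₀) - L_pooled].  Per-site and
per-pair statistics come from restricted models in which the tested
parameter is pinned, in both groups, to its pooled-fit value at the same
penalizer, and all remaining parameters are re-optimized.  Single-SNP
p-values use the asymptotic χ² distribution (upper bounds in the
penalized setting); interaction p-values use empirical null
distributions built by phenotype-label permutation at the same
penalizer, with the add-one estimator p = (1 + #{q_null ≥ q_obs})/(1+N).

For the exact-enumeration method, restricted refits run through a
cached-sufficient-statistics engine (the objective never touches the
raw data again), which is what makes the permutation resampling loop
affordable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .cohort import EncodedMatrix
from .fit import (EEEngine, FitResult, _fit_group, _values, fit, fix_h,
                  fix_J)
from .models import n_levels, pair_indices

log = logging.getLogger(__name__)


@dataclass
class LRTResult:
    """Collected likelihood-ratio statistics for one panel."""

    q_overall: float
    q_single: np.ndarray
    p_single: np.ndarray
    df_single: int
    q_pair: dict
    p_pair: dict
    null_cdfs: dict
    n_permutations: int
    penalizer: float
    method: str


def lr_overall(fitres: FitResult) -> float:
    """q = 2[(L1 + L0) - L_pooled], clipped at zero."""
    if fitres.psi_pooled is None:
        raise ValueError("fit result lacks a pooled fit")
    q = 2.0 * ((fitres.loglik1 + fitres.loglik0) - fitres.loglik_pooled)
    return float(max(q, 0.0))


class _EEContext:
    """Per-dataset cache for repeated restricted EE refits."""

    def __init__(self, engine: EEEngine, labels, fitres: FitResult):
        self.engine = engine
        self.lam = fitres.penalizer
        self.stats = {g: engine.group_stats(labels, g)
                      for g in ("control", "case")}
        self.theta = {"control": fitres.psi0.theta(),
                      "case": fitres.psi1.theta()}
        self.precond = {g: engine.hessian(self.theta[g],
                                          self.stats[g][1], self.lam)
                        for g in ("control", "case")}
        self.full_ll = fitres.loglik0 + fitres.loglik1

    def restricted_loglik(self, fixed: dict) -> float:
        total = 0.0
        for g in ("control", "case"):
            phibar, n = self.stats[g]
            _, _, ll, _ = self.engine.solve(
                phibar, n, self.lam, fixed=fixed, warm=self.theta[g],
                precond=self.precond[g])
            total += ll
        return total


def _maybe_engine(values, model, method) -> EEEngine | None:
    if method != "EE":
        return None
    try:
        return EEEngine(values, model)
    except ValueError:
        return None


def _restricted_generic(values, model, labels, fitres, fixed, map_fn
                        ) -> float:
    total = 0.0
    for group, warm in (("control", fitres.psi0), ("case", fitres.psi1)):
        _, ll = _fit_group(values, model, labels, group, fitres.method,
                           fitres.penalizer, fixed=fixed, warm=warm,
                           map_fn=map_fn)
        total += ll
    return total


def lr_single(enc, labels, fitres: FitResult, site: int, map_fn=map,
              context: _EEContext | None = None) -> tuple[float, float]:
    """Single-site statistic q_i and its asymptotic χ² p-value.

    The restricted model pins h_i (all levels) in both groups to the
    pooled value; d.f. = 1 (binary) or 2 (genotypic).  In the penalized
    setting the p-value is an upper bound (the penalizer pushes null
    statistics toward zero).
    """
    values = _values(enc)
    model = fitres.model
    L = n_levels(model)
    fixed = fix_h(site, fitres.psi_pooled.h[site], model)
    if context is None:
        engine = _maybe_engine(values, model, fitres.method)
        if engine is not None:
            context = _EEContext(engine, labels, fitres)
    if context is not None:
        restr = context.restricted_loglik(fixed)
        full = context.full_ll
    else:
        restr = _restricted_generic(values, model, labels, fitres, fixed,
                                    map_fn)
        full = fitres.loglik0 + fitres.loglik1
    q = max(0.0, 2.0 * (full - restr))
    return float(q), float(chi2.sf(q, df=L))


def lr_pair(enc, labels, fitres: FitResult, pair: tuple[int, int],
            map_fn=map, context: _EEContext | None = None) -> float:
    """Interaction statistic q_ij (restricted model pins J_ij to pooled).

    For the closed-form MF method the pooled value is plugged into the
    full solution without re-optimization; validity rests on the
    permutation null in either case.
    """
    i, j = pair
    values = _values(enc)
    model = fitres.model
    fixed = fix_J(i, j, fitres.psi_pooled.J[i, j], model)
    if context is None:
        engine = _maybe_engine(values, model, fitres.method)
        if engine is not None:
            context = _EEContext(engine, labels, fitres)
    if context is not None:
        restr = context.restricted_loglik(fixed)
        full = context.full_ll
    else:
        restr = _restricted_generic(values, model, labels, fitres, fixed,
                                    map_fn)
        full = fitres.loglik0 + fitres.loglik1
    return float(max(0.0, 2.0 * (full - restr)))


def all_pair_statistics(enc, labels, fitres: FitResult, map_fn=map) -> dict:
    """q_ij for every pair, reusing the full fit and cached statistics."""
    values = _values(enc)
    m = fitres.m
    engine = _maybe_engine(values, fitres.model, fitres.method)
    context = (None if engine is None
               else _EEContext(engine, labels, fitres))
    iu, ju = pair_indices(m)
    return {(int(i), int(j)): lr_pair(enc, labels, fitres,
                                      (int(i), int(j)), map_fn, context)
            for i, j in zip(iu, ju)}


def all_single_statistics(enc, labels, fitres: FitResult, map_fn=map
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(q_i, p_i) for every site, reusing cached statistics."""
    values = _values(enc)
    engine = _maybe_engine(values, fitres.model, fitres.method)
    context = (None if engine is None
               else _EEContext(engine, labels, fitres))
    m = fitres.m
    q = np.empty(m)
    p = np.empty(m)
    for site in range(m):
        q[site], p[site] = lr_single(enc, labels, fitres, site, map_fn,
                                     context)
    return q, p


def permutation_null(enc, labels, method: str = "EE",
                     penalizer: float = 0.0, n_perm: int = 199,
                     seed: int = 0, pairs: list | None = None, map_fn=map
                     ) -> dict:
    """Empirical per-pair null distributions of q_ij by label reshuffling.

    Each permutation reshuffles phenotype labels (preserving group
    sizes), refits both groups at the same penalizer, and records q_ij
    for the requested pairs.  One child random stream per permutation
    index, so enlarging n_perm leaves earlier draws unchanged and
    execution order is immaterial.  Failed permutations are logged and
    skipped.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    labels = np.asarray(labels)
    m = values.shape[1]
    if pairs is None:
        iu, ju = pair_indices(m)
        pairs = [(int(i), int(j)) for i, j in zip(iu, ju)]

    # the pooled fit does not depend on labels: compute once
    psi_pool, ll_pool = _fit_group(values, model, labels, "pooled", method,
                                   penalizer, map_fn=map_fn)
    engine = _maybe_engine(values, model, method)
    streams = np.random.SeedSequence(seed).spawn(n_perm)

    def one_perm_engine(k):
        rng = np.random.default_rng(streams[k])
        perm = rng.permutation(labels)
        theta_pool = psi_pool.theta()
        stats, theta, precond, full_ll = {}, {}, {}, 0.0
        for g in ("control", "case"):
            phibar, n = engine.group_stats(perm, g)
            th, _, ll, _ = engine.solve(phibar, n, penalizer,
                                        warm=theta_pool)
            stats[g] = (phibar, n)
            theta[g] = th
            precond[g] = engine.hessian(th, n, penalizer)
            full_ll += ll
        out = {}
        for (i, j) in pairs:
            fixed = fix_J(i, j, psi_pool.J[i, j], model)
            restr = 0.0
            for g in ("control", "case"):
                phibar, n = stats[g]
                _, _, ll, _ = engine.solve(phibar, n, penalizer,
                                           fixed=fixed, warm=theta[g],
                                           precond=precond[g])
                restr += ll
            out[(i, j)] = max(0.0, 2.0 * (full_ll - restr))
        return out

    def one_perm_generic(k):
        rng = np.random.default_rng(streams[k])
        perm = rng.permutation(labels)
        psi0, ll0 = _fit_group(values, model, perm, "control", method,
                               penalizer, warm=psi_pool, map_fn=map_fn)
        psi1, ll1 = _fit_group(values, model, perm, "case", method,
                               penalizer, warm=psi_pool, map_fn=map_fn)
        fr = FitResult(psi0=psi0, psi1=psi1, psi_pooled=psi_pool,
                       loglik0=ll0, loglik1=ll1, loglik_pooled=ll_pool,
                       method=method, penalizer=penalizer)
        return {p: lr_pair(EncodedMatrix(values, model), perm, fr, p,
                           map_fn) for p in pairs}

    one_perm = one_perm_engine if engine is not None else one_perm_generic
    draws = {p: [] for p in pairs}
    n_failed = 0
    for k in range(n_perm):
        try:
            stats_k = one_perm(k)
        except Exception as exc:
            n_failed += 1
            log.warning("permutation %d failed (%s); skipped", k, exc)
            continue
        for p, q in stats_k.items():
            draws[p].append(q)
    if n_failed:
        log.warning("%d/%d permutations failed", n_failed, n_perm)
    return {p: np.sort(np.asarray(v)) for p, v in draws.items()}


def empirical_pvalue(q_obs: float, null_draws: np.ndarray) -> float:
    """Add-one permutation p-value; never 0 and never above 1."""
    null_draws = np.asarray(null_draws)
    return float((1 + int(np.sum(null_draws >= q_obs)))
                 / (1 + len(null_draws)))


def interaction_scan(enc, labels, method: str = "EE",
                     penalizer: float = 0.0, n_perm: int = 199,
                     seed: int = 0, map_fn=map) -> LRTResult:
    """Full single-SNP + interaction significance scan of one panel."""
    values = _values(enc)
    model = enc.model if isinstance(enc, EncodedMatrix) else "dominant"
    fitres = fit(EncodedMatrix(values, model), labels, method, penalizer,
                 map_fn=map_fn)
    q_single, p_single = all_single_statistics(enc, labels, fitres, map_fn)
    q_pair = all_pair_statistics(enc, labels, fitres, map_fn)
    nulls = permutation_null(enc, labels, method, penalizer, n_perm, seed,
                             pairs=list(q_pair), map_fn=map_fn)
    p_pair = {p: empirical_pvalue(q_pair[p], nulls[p]) for p in q_pair}
    return LRTResult(q_overall=lr_overall(fitres), q_single=q_single,
                     p_single=p_single, df_single=n_levels(model),
                     q_pair=q_pair, p_pair=p_pair, null_cdfs=nulls,
                     n_permutations=n_perm, penalizer=penalizer,
                     method=method)


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs for a quantile-quantile plot."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    p_sorted = np.sort(p)  # ascending p = descending significance rank
    expected = -np.log10(np.arange(1, n + 1) / (n + 1.0))
    observed = -np.log10(p_sorted)
    return expected, observed
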