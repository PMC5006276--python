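"""Case-control genotype simulation by exhaustive enumeration.

Case and control genotype distributions are exponential-family models
whose fields and couplings are drawn from normal distributions with
group-specific means; the full state space (2^m binary / 3^m genotypic)
is enumerated, weights normalized exactly, and samples drawn by a single
multinomial draw per group (no MCMC).

By default the per-entry Gaussian noise realization is *shared* between
case and control groups with only the means differing, so the true
disease-risk parameters are exactly the mean differences and all
non-designated pairs are exactly null.  Independent per-group draws are
available via ``shared_noise=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import EncodedMatrix
from .models import (ENUM_MAX_BINARY, ENUM_MAX_GENOTYPIC, ModelParams,
                     energies, n_levels, pair_indices, state_table)


@dataclass
class SimulationSpec:
    """Study conditions for one simulated case-control panel.

    hbar_y / jbar_y are (control, case) pairs of means; each entry may be
    a scalar or a per-site (m,) / per-pair (m, m) array, which is how
    designs with designated causal sites or pairs are expressed.
    ``overrides`` pins individual parameter entries to exact values after
    noise, as ``{"h": [(y, i, value), ...], "J": [(y, i, j, value), ...]}``.
    """

    m: int
    n0: int
    n1: int
    hbar_y: tuple = (-1.0, -1.0)
    jbar_y: tuple = (0.0, 0.0)
    sigma_h: float = 0.0
    sigma_j: float = 0.0
    model: str = "dominant"
    shared_noise: bool = True
    overrides: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.sigma_h < 0 or self.sigma_j < 0:
            raise ValueError("sigma_h and sigma_j must be >= 0")
        cap = ENUM_MAX_BINARY if n_levels(self.model) == 1 \
            else ENUM_MAX_GENOTYPIC
        if self.m > cap:
            raise ValueError(
                f"exhaustive enumeration limited to m<={cap} for "
                f"{self.model!r}")


@dataclass
class GenotypeDistributionTable:
    """Fully enumerated genotype distribution of one group."""

    states: np.ndarray
    probabilities: np.ndarray
    log_partition: float


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    # disjoint child streams: parameter draws never perturb genotype draws
    children = np.random.SeedSequence(seed).spawn(2)
    return (np.random.default_rng(children[0]),
            np.random.default_rng(children[1]))


def _broadcast_h(value, m: int, L: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    shape = (m,) if L == 1 else (m, 2)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if L == 2 and arr.shape == (m,):
        return np.repeat(arr[:, None], 2, axis=1)
    if arr.shape != shape:
        raise ValueError(f"per-site means must broadcast to {shape}")
    return arr.copy()


def _broadcast_j(value, m: int, L: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    shape = (m, m) if L == 1 else (m, m, 2, 2)
    if arr.ndim == 0:
        out = np.full(shape, float(arr))
    elif L == 2 and arr.shape == (m, m):
        out = np.repeat(arr[:, :, None, None], 4, axis=-1).reshape(m, m, 2, 2)
    elif arr.shape == shape:
        out = arr.copy()
    else:
        raise ValueError(f"per-pair means must broadcast to {shape}")
    iu, ju = pair_indices(m)
    sym = np.zeros(shape)
    sym[iu, ju] = out[iu, ju]
    if L == 1:
        sym += sym.T
    else:
        sym[ju, iu] = np.swapaxes(out[iu, ju], -1, -2)
    return sym


def sample_parameters(spec: SimulationSpec
                      ) -> tuple[ModelParams, ModelParams]:
    """Draw (psi0, psi1) according to the spec; reproducible under seed."""
    rng, _ = _streams(spec.seed)
    m, L = spec.m, n_levels(spec.model)
    iu, ju = pair_indices(m)
    noise_shape_h = (m,) if L == 1 else (m, 2)
    noise_shape_j = (len(iu),) if L == 1 else (len(iu), 2, 2)

    eps_h = {0: rng.normal(0.0, spec.sigma_h, noise_shape_h)}
    eps_j = {0: rng.normal(0.0, spec.sigma_j, noise_shape_j)}
    if spec.shared_noise:
        eps_h[1], eps_j[1] = eps_h[0], eps_j[0]
    else:
        eps_h[1] = rng.normal(0.0, spec.sigma_h, noise_shape_h)
        eps_j[1] = rng.normal(0.0, spec.sigma_j, noise_shape_j)

    out = []
    for y in (0, 1):
        h = _broadcast_h(spec.hbar_y[y], m, L) + eps_h[y]
        Jbar = _broadcast_j(spec.jbar_y[y], m, L)
        J = np.zeros_like(Jbar)
        J[iu, ju] = Jbar[iu, ju] + eps_j[y]
        if L == 1:
            J += J.T
        else:
            J[ju, iu] = np.swapaxes(J[iu, ju], -1, -2)
        out.append(ModelParams(model=spec.model, h=h, J=J,
                               group="control" if y == 0 else "case"))

    if spec.overrides:
        for y, i, value in spec.overrides.get("h", []):
            if not (y in (0, 1) and 0 <= i < m):
                raise ValueError(f"h override index out of range: {(y, i)}")
            out[y].h[i] = value
        for y, i, j, value in spec.overrides.get("J", []):
            if not (y in (0, 1) and 0 <= i < m and 0 <= j < m and i != j):
                raise ValueError(
                    f"J override index out of range: {(y, i, j)}")
            out[y].J[i, j] = value
            out[y].J[j, i] = (value if L == 1
                              else np.swapaxes(np.asarray(value), -1, -2))
    return out[0], out[1]


def enumerate_distribution(psi: ModelParams) -> GenotypeDistributionTable:
    """Exact probabilities of every genotype configuration under psi."""
    states = state_table(psi.m, psi.model)
    e = energies(states, psi)
    emax = e.max()
    w = np.exp(e - emax)
    Z = w.sum()
    return GenotypeDistributionTable(states, w / Z,
                                     float(np.log(Z) + emax))


def sample_genotypes(psi0: ModelParams, psi1: ModelParams, n0: int, n1: int,
                     seed: int = 0) -> tuple[EncodedMatrix, np.ndarray]:
    """Draw n0 control and n1 case genotype rows i.i.d. from each group."""
    if psi0.model != psi1.model or psi0.m != psi1.m:
        raise ValueError("psi0 and psi1 must share model and m")
    _, rng = _streams(seed)
    rows = []
    for psi, ny in ((psi0, n0), (psi1, n1)):
        table = enumerate_distribution(psi)
        counts = rng.multinomial(ny, table.probabilities)
        rows.append(np.repeat(table.states, counts, axis=0))
    values = np.vstack(rows)
    labels = np.concatenate([np.zeros(n0, dtype=np.int8),
                             np.ones(n1, dtype=np.int8)])
    # shuffle so row order carries no phenotype information
    order = rng.permutation(len(labels))
    enc = EncodedMatrix(values[order], psi0.model)
    return enc, labels[order]


def simulate(spec: SimulationSpec
             ) -> tuple[EncodedMatrix, np.ndarray, ModelParams, ModelParams]:
    """Convenience wrapper: parameters + genotype sample from one spec."""
    psi0, psi1 = sample_parameters(spec)
    enc, labels = sample_genotypes(psi0, psi1, spec.n0, spec.n1,
                                   seed=spec.seed)
    return enc, labels, psi0, psi1


# --- canonical simulation study designs ---------------------------------

def design_strong_effects(n: int, m: int = 10, seed: int = 0
                          ) -> SimulationSpec:
    """All sites carry appreciable marginal and interaction effects.

    Means (control, case) = (-1, -0.3) for fields and (0, 0.1) for
    couplings, with per-entry SD 0.2; dominant model.
    """
    return SimulationSpec(m=m, n0=n // 2, n1=n - n // 2,
                          hbar_y=(-1.0, -0.3), jbar_y=(0.0, 0.1),
                          sigma_h=0.2, sigma_j=0.2, seed=seed)


def design_sparse_effects(n: int, m: int = 20, n_causal: int = 4,
                          delta_h: float = 0.7, delta_j: float = 0.5,
                          seed: int = 0) -> SimulationSpec:
    """Only the first ``n_causal`` sites (and their pairs) are associated."""
    h1 = np.full(m, -1.0)
    h1[:n_causal] += delta_h
    j1 = np.zeros((m, m))
    j1[:n_causal, :n_causal] = delta_j
    return SimulationSpec(m=m, n0=n // 2, n1=n - n // 2,
                          hbar_y=(-1.0, h1), jbar_y=(0.0, j1),
                          sigma_h=0.2, sigma_j=0.2, seed=seed)


def design_single_causal_pair(n: int, m: int = 10, seed: int = 0
                              ) -> SimulationSpec:
    """Identical group means except one pair with stronger case coupling.

    Fields mean -1 in both groups (SD 0.1); couplings mean 0.01 in both
    groups (SD 0.05) except the (0, 1) pair, whose case mean is 0.11.
    """
    j1 = np.full((m, m), 0.01)
    j1[0, 1] = j1[1, 0] = 0.11
    return SimulationSpec(m=m, n0=n // 2, n1=n - n // 2,
                          hbar_y=(-1.0, -1.0), jbar_y=(0.01, j1),
                          sigma_h=0.1, sigma_j=0.05, seed=seed)
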