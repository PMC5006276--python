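"""Exponential-family genotype distribution parameters and sufficient statistics.

The per-group genotype distribution is

    Pr(a | y) ∝ exp( Σ_i h_i a_i + Σ_{i<j} J_ij a_i a_j )

for binary encodings (dominant/recessive), and its reference-category
generalization for the three-level genotypic encoding, where each SNP i
carries level indicators z_i(g) = 1[a_i = g] for g ∈ {1, 2} (level 0 has
zero energy) with fields h_i(g) and per-pair 2x2 coupling blocks
J_ij(g, g').  Everything downstream (enumeration, exact fitting,
pseudo-likelihood conditionals, sufficient statistics) works off the flat
parameter vector theta = [h..., J_upper...] defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BINARY_MODELS = ("dominant", "recessive")
MODELS = ("dominant", "recessive", "genotypic")

#: sentinel for a missing genotype in raw (un-encoded) matrices
MISSING = -1

# state-table caps: memory for the full enumeration (int8 states + float64
# probabilities) at 8 GiB working memory
ENUM_MAX_BINARY = 22
ENUM_MAX_GENOTYPIC = 13
FIT_MAX_BINARY = 20
FIT_MAX_GENOTYPIC = 12


def n_levels(model: str) -> int:
    """Number of non-reference encoded levels (1 binary, 2 genotypic)."""
    if model in BINARY_MODELS:
        return 1
    if model == "genotypic":
        return 2
    raise ValueError(f"unknown encoding model: {model!r}")


def n_params(m: int, model: str) -> int:
    L = n_levels(model)
    return m * L + (m * (m - 1) // 2) * L * L


def pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i<j) pair index arrays in canonical order."""
    return np.triu_indices(m, 1)


def _pair_pos(i: int, j: int, m: int) -> int:
    # position of (i, j), i<j, in np.triu_indices order
    if not (0 <= i < j < m):
        raise IndexError(f"pair ({i}, {j}) out of range for m={m}")
    return i * m - i * (i + 1) // 2 + (j - i - 1)


def h_index(i: int, m: int, model: str, level: int = 1) -> int:
    """Flat theta index of h_i (of h_i(level) for the genotypic model)."""
    L = n_levels(model)
    if not 1 <= level <= L:
        raise IndexError(f"level {level} invalid for model {model!r}")
    return i * L + (level - 1)


def J_index(i: int, j: int, m: int, model: str,
            level_i: int = 1, level_j: int = 1) -> int:
    """Flat theta index of J_ij (of the (level_i, level_j) block entry)."""
    L = n_levels(model)
    if i > j:
        i, j, level_i, level_j = j, i, level_j, level_i
    pos = _pair_pos(i, j, m)
    return m * L + pos * L * L + (level_i - 1) * L + (level_j - 1)


def J_indices_for_pair(i: int, j: int, m: int, model: str) -> list[int]:
    """All flat theta indices belonging to the coupling of pair (i, j)."""
    L = n_levels(model)
    return [J_index(i, j, m, model, gi, gj)
            for gi in range(1, L + 1) for gj in range(1, L + 1)]


@dataclass
class ModelParams:
    """Fields h and couplings J of one group's genotype distribution.

    h has shape (m,) for binary encodings and (m, 2) for the genotypic
    model; J has shape (m, m) (symmetric, zero diagonal) or (m, m, 2, 2)
    with J[i, j] == J[j, i].T and zero diagonal blocks.
    """

    model: str
    h: np.ndarray
    J: np.ndarray
    group: str = "pooled"
    log_partition: float | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.model not in MODELS:
            raise ValueError(f"unknown encoding model: {self.model!r}")
        L = n_levels(self.model)
        m = self.m
        want_h = (m,) if L == 1 else (m, 2)
        want_J = (m, m) if L == 1 else (m, m, 2, 2)
        if self.h.shape != want_h:
            raise ValueError(f"h shape {self.h.shape} != {want_h}")
        if self.J.shape != want_J:
            raise ValueError(f"J shape {self.J.shape} != {want_J}")

    @property
    def m(self) -> int:
        return self.h.shape[0]

    @property
    def n_levels(self) -> int:
        return n_levels(self.model)

    def copy(self) -> "ModelParams":
        return replace(self, h=self.h.copy(), J=self.J.copy())

    @classmethod
    def zeros(cls, m: int, model: str, group: str = "pooled") -> "ModelParams":
        L = n_levels(model)
        h = np.zeros(m) if L == 1 else np.zeros((m, 2))
        J = np.zeros((m, m)) if L == 1 else np.zeros((m, m, 2, 2))
        return cls(model=model, h=h, J=J, group=group)

    def theta(self) -> np.ndarray:
        return pack_params(self.h, self.J, self.model)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "group": self.group,
            "h": self.h.tolist(),
            "J": self.J.tolist(),
            "log_partition": self.log_partition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(model=d["model"], h=np.asarray(d["h"]),
                   J=np.asarray(d["J"]), group=d.get("group", "pooled"),
                   log_partition=d.get("log_partition"))


def pack_params(h: np.ndarray, J: np.ndarray, model: str) -> np.ndarray:
    m = h.shape[0]
    iu, ju = pair_indices(m)
    if n_levels(model) == 1:
        return np.concatenate([h, J[iu, ju]])
    return np.concatenate([h.ravel(), J[iu, ju].reshape(-1)])


def unpack_params(theta: np.ndarray, m: int, model: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    L = n_levels(model)
    iu, ju = pair_indices(m)
    if L == 1:
        h = theta[:m].copy()
        J = np.zeros((m, m))
        J[iu, ju] = theta[m:]
        J += J.T
        return h, J
    h = theta[: 2 * m].reshape(m, 2).copy()
    J = np.zeros((m, m, 2, 2))
    blocks = theta[2 * m:].reshape(-1, 2, 2)
    J[iu, ju] = blocks
    J[ju, iu] = np.swapaxes(blocks, 1, 2)
    return h, J


def penalty_mask(m: int, model: str) -> np.ndarray:
    """1 on coupling coordinates, 0 on field coordinates (h unpenalized)."""
    L = n_levels(model)
    mask = np.ones(n_params(m, model))
    mask[: m * L] = 0.0
    return mask


def state_table(m: int, model: str) -> np.ndarray:
    """All (L+1)^m genotype configurations, shape (n_states, m), int8."""
    L = n_levels(model)
    base = L + 1
    cap = ENUM_MAX_BINARY if L == 1 else ENUM_MAX_GENOTYPIC
    if m > cap:
        raise ValueError(
            f"exhaustive enumeration limited to m<={cap} for {model!r} "
            f"encodings (requested m={m})")
    grids = np.meshgrid(*([np.arange(base, dtype=np.int8)] * m),
                        indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def indicator_matrix(values: np.ndarray, model: str) -> np.ndarray:
    """Level indicators, shape (n, m*L); identity for binary encodings."""
    values = np.asarray(values)
    if n_levels(model) == 1:
        return values.astype(float)
    n, m = values.shape
    Z = np.zeros((n, m, 2))
    Z[:, :, 0] = values == 1
    Z[:, :, 1] = values == 2
    return Z.reshape(n, 2 * m)


def feature_matrix(values: np.ndarray, model: str) -> np.ndarray:
    """Sufficient-statistic features [singles..., pair products...].

    Row k is the feature vector T(a^k) such that
    log Pr(a^k) = T(a^k) . theta - log Z.
    """
    values = np.asarray(values)
    n, m = values.shape
    L = n_levels(model)
    iu, ju = pair_indices(m)
    if L == 1:
        V = values.astype(float)
        return np.concatenate([V, V[:, iu] * V[:, ju]], axis=1)
    Z = indicator_matrix(values, model).reshape(n, m, 2)
    pairs = Z[:, iu, :, None] * Z[:, ju, None, :]  # (n, npairs, 2, 2)
    return np.concatenate([Z.reshape(n, 2 * m),
                           pairs.reshape(n, -1)], axis=1)


def energies(values: np.ndarray, params: ModelParams) -> np.ndarray:
    """Unnormalized log-weights of the given configurations."""
    values = np.asarray(values)
    if params.n_levels == 1:
        V = values.astype(float)
        return V @ params.h + 0.5 * np.einsum("ki,ij,kj->k", V, params.J, V)
    n, m = values.shape
    Z = indicator_matrix(values, params.model).reshape(n, m, 2)
    e = np.einsum("kig,ig->k", Z, params.h)
    e += 0.5 * np.einsum("kig,ijgf,kjf->k", Z, params.J, Z, optimize=True)
    return e


def collapse(values: np.ndarray, weights: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Unique rows with multiplicities; the workhorse for small-m speed."""
    values = np.asarray(values)
    if weights is None:
        uniq, counts = np.unique(values, axis=0, return_counts=True)
        return uniq, counts.astype(float)
    uniq, inv = np.unique(values, axis=0, return_inverse=True)
    return uniq, np.bincount(inv, weights=weights,
                             minlength=len(uniq)).astype(float)


def suff_stats(values: np.ndarray, model: str,
               weights: np.ndarray | None = None) -> np.ndarray:
    """Mean feature vector of a sample (empirical moments in theta layout)."""
    uniq, w = collapse(values, weights)
    Phi = feature_matrix(uniq, model)
    return (w / w.sum()) @ Phi
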