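"""Case-control cohort container, quality control, encoding, and moments.

Genotypes are stored as minor-allele counts in {0, 1, 2} with -1 marking a
missing call.  QC applies the standard per-SNP filters (minor allele
frequency, exact Hardy-Weinberg test on controls, per-SNP missingness) and
re-identifies the minor allele from pooled frequencies.  Encoding maps the
counts onto the dominant ({0,1}: non-carrier/carrier), recessive, or
genotypic ({0,1,2}) scale with deterministic modal imputation of missing
calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import plink
from .models import BINARY_MODELS, MISSING, n_levels

log = logging.getLogger(__name__)


class DegenerateCohortError(ValueError):
    """A cohort with an empty case or control group."""


class EmptyPanelError(ValueError):
    """All SNPs removed by quality control."""


@dataclass
class CohortData:
    """Raw genotypes plus phenotypes and SNP metadata.

    genotypes: (n, m) int8 minor-allele counts, -1 = missing
    phenotypes: (n,) int8 in {0, 1}, 1 = case
    snp_meta: DataFrame with columns snp, chrom, pos, a1, a2
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if len(self.phenotypes) != self.genotypes.shape[0]:
            raise ValueError("phenotype length mismatch")
        if not np.isin(self.phenotypes, [0, 1]).all():
            raise ValueError("phenotypes must be coded 0 (control)/1 (case)")
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("genotype entries must be in {0,1,2,-1}")
        if self.snp_meta["snp"].duplicated().any():
            dup = self.snp_meta["snp"][self.snp_meta["snp"].duplicated()]
            raise ValueError(f"duplicate SNP identifiers: {list(dup[:5])}")
        if not self.sample_ids:
            self.sample_ids = [f"S{k + 1}" for k in range(self.n)]
        if self.n0 == 0 or self.n1 == 0:
            raise DegenerateCohortError(
                f"need both groups non-empty (n0={self.n0}, n1={self.n1})")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n1(self) -> int:
        return int(self.phenotypes.sum())

    @property
    def n0(self) -> int:
        return self.n - self.n1

    def subset_snps(self, keep: np.ndarray) -> "CohortData":
        return CohortData(self.genotypes[:, keep],
                          self.phenotypes,
                          self.snp_meta.iloc[np.flatnonzero(keep)
                                             if keep.dtype == bool else keep]
                          .reset_index(drop=True),
                          list(self.sample_ids))


@dataclass
class EncodedMatrix:
    """Encoded, imputation-complete genotype matrix for one model."""

    values: np.ndarray
    model: str
    minor_allele_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        top = 1 if self.model in BINARY_MODELS else 2
        if self.values.size and not (
                (self.values >= 0) & (self.values <= top)).all():
            raise ValueError(f"encoded values outside [0, {top}]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class EmpiricalMoments:
    """Per-SNP frequencies and per-pair co-occurrence frequencies."""

    f_single: np.ndarray
    f_pair: np.ndarray
    group: str
    model: str


def load_genotypes(path: str, format: str = "ped") -> CohortData:
    """Read a PLINK fileset (prefix without extension) into a cohort."""
    if format == "ped":
        geno, pheno, meta, ids, _ = plink.read_ped(path)
    elif format == "bed":
        geno, pheno, meta, ids, _ = plink.read_bed(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected ped or bed)")
    return CohortData(geno, pheno, meta, ids)


def hwe_exact_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP's genotype counts.

    Sums the probabilities of all heterozygote counts (given the observed
    minor-allele count) whose conditional probability does not exceed the
    observed configuration's.
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # orient to the rarer allele
        n_minor = 2 * n - n_minor
    parity = n_minor % 2
    hets = np.arange(parity, n_minor + 1, 2)
    hom_r = (n_minor - hets) // 2
    hom_c = n - hets - hom_r
    logp = (gammaln(n + 1) - gammaln(hets + 1) - gammaln(hom_r + 1)
            - gammaln(hom_c + 1) + hets * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # inconsistent counts (parity); treat as extreme
        return 0.0
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_filter(data: CohortData, maf_min: float = 0.01,
              hwe_p_min: float = 1e-6, miss_max: float = 0.05
              ) -> tuple[CohortData, pd.DataFrame]:
    """Apply per-SNP QC and re-orient counts to the pooled minor allele.

    Removes SNPs with pooled MAF <= maf_min, exact HWE p-value (controls
    only) <= hwe_p_min, or missing-call fraction >= miss_max.  Returns the
    filtered cohort and a per-criterion report.
    """
    for name, v in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                    ("miss_max", miss_max)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    G = data.genotypes
    n, m = G.shape
    obs = G != MISSING
    miss_frac = 1.0 - obs.mean(axis=0)
    counts = np.where(obs, G, 0).astype(float)

    # pooled allele-1 frequency over non-missing calls
    n_obs = obs.sum(axis=0)
    freq = np.divide(counts.sum(axis=0), 2 * n_obs,
                     out=np.full(m, np.nan), where=n_obs > 0)
    maf = np.minimum(freq, 1.0 - freq)

    ctrl = data.phenotypes == 0
    hwe_p = np.ones(m)
    for i in range(m):
        col = G[ctrl, i]
        col = col[col != MISSING]
        hwe_p[i] = hwe_exact_pvalue(int((col == 2).sum()),
                                    int((col == 1).sum()),
                                    int((col == 0).sum()))

    fail_maf = ~(maf > maf_min)
    fail_hwe = ~(hwe_p > hwe_p_min)
    fail_miss = ~(miss_frac < miss_max)
    keep = ~(fail_maf | fail_hwe | fail_miss)
    report = pd.DataFrame({
        "snp": data.snp_meta["snp"],
        "maf": maf, "hwe_p": hwe_p, "miss_frac": miss_frac,
        "fail_maf": fail_maf, "fail_hwe": fail_hwe, "fail_miss": fail_miss,
        "kept": keep,
    })
    log.info("QC: removed %d/%d SNPs (maf %d, hwe %d, missingness %d)",
             (~keep).sum(), m, fail_maf.sum(), fail_hwe.sum(),
             fail_miss.sum())
    if not keep.any():
        raise EmptyPanelError("quality control removed every SNP")

    out = data.subset_snps(keep)
    # re-identify the minor allele from the pooled sample; flip counts where
    # allele 1 is the major allele
    flip = freq[keep] > 0.5
    if flip.any():
        Gf = out.genotypes.copy()
        cols = np.flatnonzero(flip)
        block = Gf[:, cols]
        obs_block = block != MISSING
        block = np.where(obs_block, 2 - block, MISSING).astype(np.int8)
        Gf[:, cols] = block
        meta = out.snp_meta.copy()
        a1 = meta["a1"].to_numpy().copy()
        a2 = meta["a2"].to_numpy().copy()
        a1[cols], a2[cols] = a2[cols], a1[cols].copy()
        meta["a1"], meta["a2"] = a1, a2
        out = CohortData(Gf, out.phenotypes, meta, out.sample_ids)
    return out, report


def encode(data: CohortData, model: str) -> EncodedMatrix:
    """Encode counts for one inheritance model; impute missing calls.

    dominant: carrier indicator (count >= 1); recessive: minor-homozygote
    indicator (count == 2); genotypic: identity.  Missing entries are set
    to the per-SNP modal genotype of the pooled sample before encoding.
    """
    if model not in ("dominant", "recessive", "genotypic"):
        raise ValueError(f"unknown encoding model: {model!r}")
    G = data.genotypes.copy()
    n_imputed = 0
    for i in range(G.shape[1]):
        col = G[:, i]
        miss = col == MISSING
        if miss.any():
            observed = col[~miss]
            if observed.size == 0:
                mode = 0
            else:
                mode = np.bincount(observed, minlength=3).argmax()
            col[miss] = mode
            n_imputed += int(miss.sum())
    if n_imputed:
        log.info("imputed %d missing genotype calls to modal values",
                 n_imputed)
    if model == "dominant":
        V = (G >= 1).astype(np.int8)
    elif model == "recessive":
        V = (G == 2).astype(np.int8)
    else:
        V = G
    return EncodedMatrix(V, model)


def empirical_moments(enc: EncodedMatrix, labels: np.ndarray,
                      group: str = "pooled") -> EmpiricalMoments:
    """Single and pairwise frequency estimates over one group.

    Binary: f_single[i] = mean a_i; f_pair[i, j] = mean a_i a_j (diagonal
    equals f_single).  Genotypic: per-level frequencies f_single[i, g-1]
    and level-pair co-occurrences f_pair[i, j, g-1, g'-1].
    """
    labels = np.asarray(labels)
    if group == "case":
        rows = enc.values[labels == 1]
    elif group == "control":
        rows = enc.values[labels == 0]
    elif group == "pooled":
        rows = enc.values
    else:
        raise ValueError(f"unknown group {group!r}")
    if rows.shape[0] == 0:
        raise DegenerateCohortError(f"group {group!r} is empty")
    m = rows.shape[1]
    if n_levels(enc.model) == 1:
        V = rows.astype(float)
        f1 = V.mean(axis=0)
        fp = (V.T @ V) / len(V)
        np.fill_diagonal(fp, f1)
        return EmpiricalMoments(f1, fp, group, enc.model)
    Z = np.zeros((len(rows), m, 2))
    Z[:, :, 0] = rows == 1
    Z[:, :, 1] = rows == 2
    f1 = Z.mean(axis=0)
    fp = np.einsum("kig,kjf->ijgf", Z, Z) / len(rows)
    for i in range(m):
        fp[i, i] = np.diag(f1[i])
    return EmpiricalMoments(f1, fp, group, enc.model)
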