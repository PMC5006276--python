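"""Pathway-based SNP sets, collective-inference scoring, and chromatin
state enrichment.

SNPs are assigned to genes when they fall within a window (default
50 kb) of the gene's coding region; a pathway's SNP set is the union
over its member genes, and sets below a minimum size (default 20) are
dropped.  Each set is scored by the cross-validated prediction AUC of
collective inference on the restricted panel; AUC values are calibrated
against phenotype-permutation p-values through a linear regression of
-log10 p on AUC.  Chromatin-state enrichment compares the summed
active-state fraction of LD-proxy groups against a genome-wide
background frequency with a binomial test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, linregress

from .cohort import CohortData, EncodedMatrix, encode
from .risk import DEFAULT_EPSILON_GRID, auc, cross_validate, \
    stratified_folds

log = logging.getLogger(__name__)


@dataclass
class SnpSetCatalog:
    """Named, phenotype-independent SNP groups (e.g., pathways)."""

    sets: dict[str, list[str]]
    provenance: str = ""
    window_bp: int = 50_000

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SetScore:
    """Collective and independent-SNP scores of one SNP set."""

    set_name: str
    auc: float
    ci: tuple[float, float]
    independent_auc: float
    independent_ci: tuple[float, float]
    snp_count: int
    best_penalizer: float | None = None
    p_estimate: float | None = None
    passes_bonferroni: bool | None = None
    flagged: bool = False


@dataclass
class StateAnnotation:
    """Active-chromatin-state intervals for one reference epigenome.

    intervals: chrom -> (starts, ends) sorted arrays, 0-based half-open;
    background_freq: genome-wide active fraction for this epigenome.
    """

    epigenome_id: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]]
    background_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.background_freq < 1.0:
            raise ValueError("background_freq must lie in (0, 1)")

    def is_active(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position in any active interval."""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        k = np.searchsorted(starts, pos - 1, side="right") - 1
        return bool(k >= 0 and pos - 1 < ends[k])

    @classmethod
    def from_table(cls, table: pd.DataFrame, epigenome_id: str,
                   active_states: set[str],
                   background_freq: float | None = None
                   ) -> "StateAnnotation":
        """Build from a (chrom, start, end, state, epigenome) table."""
        sub = table[(table["epigenome"] == epigenome_id)]
        act = sub[sub["state"].isin(active_states)]
        intervals = {}
        for chrom, grp in act.groupby("chrom"):
            order = np.argsort(grp["start"].to_numpy())
            intervals[str(chrom)] = (
                grp["start"].to_numpy()[order].astype(np.int64),
                grp["end"].to_numpy()[order].astype(np.int64))
        if background_freq is None:
            total = float((sub["end"] - sub["start"]).sum())
            active = float((act["end"] - act["start"]).sum())
            background_freq = active / total if total else 0.5
        return cls(epigenome_id, intervals, background_freq)


def build_snp_sets(snp_meta: pd.DataFrame, gene_regions: pd.DataFrame,
                   pathways: dict[str, list[str]],
                   window_bp: int = 50_000, min_snps: int = 20
                   ) -> SnpSetCatalog:
    """Assign SNPs to genes within a window and union them per pathway.

    gene_regions: BED-like table with columns chrom, start, end, gene
    (0-based half-open); snp_meta positions are 1-based.  A SNP belongs
    to a gene iff start - window <= pos0 < end + window on the same
    chromosome.  Sets smaller than ``min_snps`` are dropped (counted in
    the log).
    """
    gene_to_snps: dict[str, set[str]] = {}
    by_chrom = {str(c): g for c, g in snp_meta.groupby("chrom")}
    for _, row in gene_regions.iterrows():
        chrom = str(row["chrom"])
        snps = by_chrom.get(chrom)
        if snps is None:
            members = set()
        else:
            pos0 = snps["pos"].to_numpy() - 1  # 1-based -> 0-based
            lo = row["start"] - window_bp
            hi = row["end"] + window_bp
            members = set(snps["snp"].to_numpy()[(pos0 >= lo)
                                                 & (pos0 < hi)])
        gene_to_snps.setdefault(str(row["gene"]), set()).update(members)

    sets, dropped = {}, 0
    for name, genes in pathways.items():
        union: set[str] = set()
        for g in genes:
            union |= gene_to_snps.get(g, set())
        if len(union) >= min_snps:
            sets[name] = sorted(union)
        else:
            dropped += 1
    if dropped:
        log.info("dropped %d sets below min_snps=%d", dropped, min_snps)
    if not sets:
        raise ValueError("no SNP set survived the size filter")
    return SnpSetCatalog(sets=sets, window_bp=window_bp)


def score_snp_set(snp_ids: list[str], data: CohortData,
                  method: str = "MF", model: str = "dominant",
                  grid=None, folds: int = 5, seed: int = 0,
                  p_c_for_large: float | None = 1e-5,
                  large_threshold: int = 6000, set_name: str = "",
                  map_fn=map) -> SetScore:
    """Cross-validated collective vs independent AUC of one SNP set.

    SNPs absent from the panel are ignored; sets losing every member are
    returned flagged with p = 1.  Large sets (above ``large_threshold``)
    get within-training-fold independent-SNP p-value filtering at
    ``p_c_for_large``.  The same seed gives identical fold assignments
    for every set, keeping scores comparable across sets.
    """
    present = data.snp_meta["snp"].isin(snp_ids).to_numpy()
    if not present.any():
        return SetScore(set_name, 0.5, (0.0, 1.0), 0.5, (0.0, 1.0), 0,
                        p_estimate=1.0, flagged=True)
    sub = data.subset_snps(present)
    enc = encode(sub, model)
    p_c = p_c_for_large if enc.m > large_threshold else None
    if grid is None:
        grid = DEFAULT_EPSILON_GRID if method == "MF" else None
    cv = cross_validate(enc, sub.phenotypes, method=method, grid=grid,
                        p_c=p_c, folds=folds, seed=seed, map_fn=map_fn)
    cv_ind = cross_validate(enc, sub.phenotypes, method="independent",
                            grid=[0.0], p_c=p_c, folds=folds, seed=seed,
                            map_fn=map_fn)
    best = int(np.flatnonzero(cv.grid == cv.best_penalizer)[0])
    return SetScore(set_name=set_name, auc=float(cv.auc[best]),
                    ci=(float(cv.ci_low[best]), float(cv.ci_high[best])),
                    independent_auc=float(cv_ind.auc[0]),
                    independent_ci=(float(cv_ind.ci_low[0]),
                                    float(cv_ind.ci_high[0])),
                    snp_count=enc.m, best_penalizer=cv.best_penalizer)


def _null_auc_pvalue(enc: EncodedMatrix, labels: np.ndarray,
                     observed_auc: float, method: str, folds: int,
                     n_perm: int, seed: int, map_fn=map) -> float:
    """Permutation p-value of a set's CV AUC (labels reshuffled)."""
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    count = 0
    for k in range(n_perm):
        rng = np.random.default_rng(streams[k])
        perm = rng.permutation(labels)
        cv = cross_validate(enc, perm, method=method,
                            grid=[0.0] if method == "independent"
                            else None, folds=folds, seed=seed,
                            map_fn=map_fn)
        if cv.auc.max() >= observed_auc:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class AucCalibration:
    """Linear map from AUC to -log10 p with a Bonferroni threshold."""

    slope: float
    intercept: float
    r_squared: float
    auc_threshold: float
    n_sets: int
    calibration_points: list = field(default_factory=list)

    def p_value(self, auc_value: float) -> float:
        neglog = self.slope * auc_value + self.intercept
        return float(10.0 ** (-max(neglog, 0.0)))


def calibrate_auc_to_p(scores: list[SetScore], data: CohortData,
                       n_perm: int = 99, seed: int = 0,
                       model: str = "dominant", method: str = "independent",
                       folds: int = 5, auc_cut: float = 0.52,
                       catalog: SnpSetCatalog | None = None,
                       map_fn=map) -> AucCalibration:
    """Fit the AUC → -log10 p regression from permutation calibration.

    Calibration sets default to the 10 sets with AUC nearest 0.5 plus 5
    evenly spaced up to the maximum; each contributes a permutation
    p-value with its CV AUC as the statistic.  The linear fit is
    restricted to AUC > ``auc_cut`` with a non-negative slope enforced,
    and the Bonferroni threshold is the AUC whose mapped p equals
    0.05 / (number of scored sets).
    """
    if len(scores) < 5:
        raise ValueError("need at least 5 scored sets to calibrate")
    ranked = sorted(scores, key=lambda s: abs(s.auc - 0.5))
    chosen = ranked[:10]
    rest = sorted(ranked[10:], key=lambda s: s.auc)
    if rest:
        picks = np.unique(np.linspace(0, len(rest) - 1,
                                      min(5, len(rest))).astype(int))
        chosen += [rest[k] for k in picks]

    points = []
    for sc in chosen:
        if catalog is not None and sc.set_name in catalog.sets:
            ids = catalog.sets[sc.set_name]
        else:
            ids = None
        if ids is None:
            continue
        present = data.snp_meta["snp"].isin(ids).to_numpy()
        sub = data.subset_snps(present)
        enc = encode(sub, model)
        p = _null_auc_pvalue(enc, sub.phenotypes, sc.auc, method, folds,
                             n_perm, seed, map_fn)
        points.append((sc.auc, -math.log10(p)))
    if len(points) < 2:
        raise ValueError("too few calibration points")

    pts = np.asarray(points)
    fit_pts = pts[pts[:, 0] > auc_cut]
    if fit_pts.shape[0] < 2:
        raise ValueError(f"fewer than 2 calibration points with "
                         f"AUC > {auc_cut}")
    res = linregress(fit_pts[:, 0], fit_pts[:, 1])
    slope = max(float(res.slope), 0.0)
    intercept = (float(res.intercept) if slope > 0.0
                 else float(np.mean(fit_pts[:, 1])))
    n_sets = len(scores)
    target = -math.log10(0.05 / n_sets)
    thr = (target - intercept) / slope if slope > 0 else float("inf")
    return AucCalibration(slope=slope, intercept=intercept,
                          r_squared=float(res.rvalue ** 2),
                          auc_threshold=float(thr), n_sets=n_sets,
                          calibration_points=points)


def annotate_scores(scores: list[SetScore], calib: AucCalibration) -> None:
    """Attach calibrated p-estimates and Bonferroni flags in place."""
    for sc in scores:
        sc.p_estimate = calib.p_value(sc.auc)
        sc.passes_bonferroni = sc.auc > calib.auc_threshold


def _active_fractions(proxies: pd.DataFrame, ann: StateAnnotation
                      ) -> pd.Series:
    """Per-SNP fraction of LD proxies lying in active states (vectorized)."""
    pos = proxies["proxy_pos"].to_numpy(dtype=np.int64)
    chroms = proxies["proxy_chrom"].astype(str).to_numpy()
    act = np.zeros(len(proxies), dtype=bool)
    for chrom in np.unique(chroms):
        iv = ann.intervals.get(str(chrom))
        if iv is None:
            continue
        sel = chroms == chrom
        starts, ends = iv
        k = np.searchsorted(starts, pos[sel] - 1, side="right") - 1
        kk = np.clip(k, 0, len(ends) - 1)
        act[sel] = (k >= 0) & (pos[sel] - 1 < ends[kk])
    return pd.Series(act).groupby(proxies["snp"].to_numpy()).mean()


def _active_fraction(proxies: pd.DataFrame, snp: str,
                     ann: StateAnnotation) -> float:
    """Fraction of one SNP's LD proxies lying in active states."""
    grp = proxies[proxies["snp"] == snp]
    if grp.empty:
        raise ValueError(f"SNP {snp} has no LD proxies (should include "
                         "itself)")
    return float(_active_fractions(grp, ann).iloc[0])


def state_enrichment(snp_list: list[str], ld_proxies: pd.DataFrame,
                     annotation: StateAnnotation) -> float:
    """Binomial over-representation p of active states among SNPs.

    Per-SNP active fractions over LD proxies are summed into an
    effective observed count (rounded half-up; the fractional value is
    used only to form the count) and tested upper-tail against the
    background frequency.
    """
    if not snp_list:
        raise ValueError("empty SNP list")
    fractions = _active_fractions(ld_proxies, annotation)
    missing = [s for s in snp_list if s not in fractions.index]
    if missing:
        raise ValueError(f"SNPs without LD proxies (should include "
                         f"themselves): {missing[:5]}")
    k_eff = float(fractions.loc[list(snp_list)].sum())
    n = len(snp_list)
    k = int(math.floor(k_eff + 0.5))
    return float(binom.sf(k - 1, n, annotation.background_freq))


def pair_state_enrichment(snp_pairs: list[tuple[str, str]],
                          ld_proxies: pd.DataFrame,
                          annotation_a: StateAnnotation,
                          annotation_b: StateAnnotation) -> float:
    """Binomial enrichment of active-active pairs across two epigenomes.

    For each SNP pair, the product of the two proxy groups' active
    fractions (group 1 in epigenome a, group 2 in epigenome b) is the
    per-pair success fraction; the summed effective count is tested
    against the product of the background frequencies.
    """
    if not snp_pairs:
        raise ValueError("empty SNP-pair list")
    k_eff = 0.0
    for s1, s2 in snp_pairs:
        k_eff += (_active_fraction(ld_proxies, s1, annotation_a)
                  * _active_fraction(ld_proxies, s2, annotation_b))
    n = len(snp_pairs)
    k = int(math.floor(k_eff + 0.5))
    bg = annotation_a.background_freq * annotation_b.background_freq
    return float(binom.sf(k - 1, n, bg))


def ld_r2_from_haplotypes(haps: np.ndarray) -> np.ndarray:
    """Pairwise r² from a phased 0/1 haplotype matrix (synthetic tests)."""
    H = np.asarray(haps, dtype=float)
    f = H.mean(axis=0)
    C = (H.T @ H) / len(H) - np.outer(f, f)
    denom = np.sqrt(np.outer(f * (1 - f), f * (1 - f)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, (C / denom) ** 2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2
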