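"""Reading and writing PLINK genotype files (.ped/.map and .bed/.bim/.fam).

Text .ped/.map files are whitespace-delimited with allele pairs and "0" as
the missing-allele code.  Binary .bed files carry the magic bytes
0x6c 0x1b followed by 0x01 (SNP-major mode) and two bits per genotype:
00 homozygous A1, 10 heterozygous, 11 homozygous A2, 01 missing.
Genotypes are returned as counts of allele 1 (0/1/2, missing = -1);
minor-allele orientation is resolved later during QC from pooled
frequencies.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .models import MISSING

log = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])

#: 2-bit code -> allele-1 count (01 is the missing code)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkParseError(ValueError):
    """Malformed PLINK input; message names the offending file and line."""


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (3, 4):
                raise PlinkParseError(
                    f"{path}: line {lineno}: expected 3 or 4 fields, "
                    f"got {len(tok)}")
            # 3-column .map files omit genetic distance
            chrom, snp = tok[0], tok[1]
            pos = int(tok[-1])
            rows.append((chrom, snp, pos))
    df = pd.DataFrame(rows, columns=["chrom", "snp", "pos"])
    df["a1"] = "0"
    df["a2"] = "0"
    return df


def read_ped(prefix: str | Path) -> tuple[np.ndarray, np.ndarray,
                                          pd.DataFrame, list[str], int]:
    """Load a .ped/.map pair.

    Returns (genotypes, phenotypes, snp_meta, sample_ids, n_dropped) where
    genotypes count copies of allele 1 (the first allele seen per SNP),
    phenotype codes 1/2 are mapped to 0/1, and samples with any other
    phenotype code are dropped (their count returned).
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    meta = _read_map(map_path)
    m = len(meta)

    geno_rows, phenos, sample_ids = [], [], []
    n_dropped = 0
    allele1 = ["0"] * m
    allele2 = ["0"] * m
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} "
                    f"fields for {m} SNPs, got {len(tok)}")
            pheno_code = tok[5]
            if pheno_code not in ("1", "2"):
                n_dropped += 1
                continue
            row = np.empty(m, dtype=np.int8)
            for i in range(m):
                b1, b2 = tok[6 + 2 * i], tok[7 + 2 * i]
                if b1 == "0" or b2 == "0":
                    row[i] = MISSING
                    continue
                for b in (b1, b2):
                    if allele1[i] == "0":
                        allele1[i] = b
                    elif b != allele1[i] and allele2[i] == "0":
                        allele2[i] = b
                    elif b not in (allele1[i], allele2[i]):
                        raise PlinkParseError(
                            f"{ped_path}: line {lineno}: SNP {i + 1} has "
                            f"more than two alleles")
                row[i] = (b1 == allele1[i]) + (b2 == allele1[i])
            geno_rows.append(row)
            phenos.append(int(pheno_code) - 1)
            sample_ids.append(f"{tok[0]}_{tok[1]}")
    if n_dropped:
        log.info("dropped %d samples with phenotype codes outside {1,2}",
                 n_dropped)
    meta["a1"] = allele1
    meta["a2"] = allele2
    genotypes = (np.vstack(geno_rows) if geno_rows
                 else np.empty((0, m), dtype=np.int8))
    return genotypes, np.asarray(phenos, dtype=np.int8), meta, sample_ids, \
        n_dropped


def read_bed(prefix: str | Path) -> tuple[np.ndarray, np.ndarray,
                                          pd.DataFrame, list[str], int]:
    """Load a .bed/.bim/.fam trio (SNP-major .bed only)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    meta = bim[["chrom", "snp", "pos", "a1", "a2"]].copy()
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    m, n = len(meta), len(fam)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkParseError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != 0x01:
        raise PlinkParseError(f"{prefix}.bed: not in SNP-major mode")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != m * bytes_per_snp:
        raise PlinkParseError(
            f"{prefix}.bed: expected {m * bytes_per_snp} data bytes, "
            f"got {len(body)}")
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    blocks = body.reshape(m, bytes_per_snp)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    genotypes = _BED_DECODE[codes[:, :n]].T.copy()  # (n, m)

    keep = fam["pheno"].astype(str).isin(["1", "2"]).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d samples with phenotype codes outside {1,2}",
                 n_dropped)
    phenos = fam.loc[keep, "pheno"].astype(int).to_numpy() - 1
    sample_ids = (fam.loc[keep, "fid"].astype(str) + "_"
                  + fam.loc[keep, "iid"].astype(str)).tolist()
    return genotypes[keep], phenos.astype(np.int8), meta, sample_ids, \
        n_dropped


def write_ped(prefix: str | Path, genotypes: np.ndarray,
              phenotypes: np.ndarray, snp_meta: pd.DataFrame,
              sample_ids: list[str] | None = None) -> None:
    """Write a .ped/.map pair; genotypes are allele-1 counts (-1 missing)."""
    prefix = Path(prefix)
    n, m = genotypes.shape
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in snp_meta.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\n")
    a1 = snp_meta["a1"].tolist()
    a2 = snp_meta["a2"].tolist()
    pair = {2: lambda i: (a1[i], a1[i]),
            1: lambda i: (a1[i], a2[i]),
            0: lambda i: (a2[i], a2[i]),
            MISSING: lambda i: ("0", "0")}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for k in range(n):
            sid = sample_ids[k] if sample_ids else f"F{k + 1}_I{k + 1}"
            fid, _, iid = sid.partition("_")
            fields = [fid, iid or sid, "0", "0", "0",
                      str(int(phenotypes[k]) + 1)]
            for i in range(m):
                fields.extend(pair[int(genotypes[k, i])](i))
            fh.write(" ".join(fields) + "\n")


def write_bed(prefix: str | Path, genotypes: np.ndarray,
              phenotypes: np.ndarray, snp_meta: pd.DataFrame,
              sample_ids: list[str] | None = None) -> None:
    """Write a SNP-major .bed/.bim/.fam trio."""
    prefix = Path(prefix)
    n, m = genotypes.shape
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, r in snp_meta.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\t"
                     f"{r['a1']}\t{r['a2']}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for k in range(n):
            sid = sample_ids[k] if sample_ids else f"F{k + 1}_I{k + 1}"
            fid, _, iid = sid.partition("_")
            fh.write(f"{fid} {iid or sid} 0 0 0 {int(phenotypes[k]) + 1}\n")
    encode = np.zeros(4, dtype=np.uint8)
    encode[2], encode[1], encode[0] = 0b00, 0b10, 0b11
    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC + b"\x01")
    for i in range(m):
        col = genotypes[:, i]
        codes = np.where(col == MISSING, 0b01, encode[np.clip(col, 0, 2)])
        padded = np.zeros(bytes_per_snp * 4, dtype=np.uint8)
        padded[:n] = codes
        packed = (padded[0::4] | (padded[1::4] << 2)
                  | (padded[2::4] << 4) | (padded[3::4] << 6))
        out.extend(packed.tobytes())
    prefix.with_suffix(".bed").write_bytes(bytes(out))
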