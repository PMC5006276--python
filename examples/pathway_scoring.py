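"""Score phenotype-independent SNP sets by cross-validated AUC.

Builds a small synthetic cohort in which one block of SNPs carries a
case-control frequency shift, assigns SNPs to genes and genes to
pathways, and ranks the pathway SNP sets by their prediction AUC.
"""

import numpy as np
import pandas as pd

from ddagwas import CohortData, build_snp_sets, score_snp_set

rng = np.random.default_rng(8)
n, m = 1_000, 30
pheno = np.tile([0, 1], n // 2).astype(np.int8)
geno = np.empty((n, m), dtype=np.int8)
for i in range(m):
    f1 = 0.42 if i < 10 else 0.30  # SNPs 0-9 associated
    geno[:, i] = rng.binomial(2, np.where(pheno == 1, f1, 0.30))
meta = pd.DataFrame({"chrom": "1",
                     "snp": [f"rs{i}" for i in range(m)],
                     "pos": np.arange(m) * 100_000 + 50_000,
                     "a1": "A", "a2": "G"})
data = CohortData(geno, pheno, meta)

genes = pd.DataFrame({
    "chrom": "1",
    "start": [0, 1_000_000, 2_000_000],
    "end": [950_000, 1_950_000, 2_950_000],
    "gene": ["GENE_A", "GENE_B", "GENE_C"]})
pathways = {"assoc_pathway": ["GENE_A"],
            "null_pathway": ["GENE_B", "GENE_C"]}

catalog = build_snp_sets(data.snp_meta, genes, pathways,
                         window_bp=50_000, min_snps=5)
print("set              m    AUC    [95% CI]   independent AUC")
for name, ids in catalog.sets.items():
    sc = score_snp_set(ids, data, method="MF", grid=[0.0, 0.5, 1.0],
                       folds=5, seed=1, set_name=name)
    print(f"{name:15s} {sc.snp_count:3d}  {sc.auc:.3f}  "
          f"[{sc.ci[0]:.3f}, {sc.ci[1]:.3f}]  {sc.independent_auc:.3f}")
# The associated pathway should score clearly above 0.5 while the null
# pathway's confidence interval straddles 0.5; both sets share fold
# assignments (same seed) so the scores are directly comparable.
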