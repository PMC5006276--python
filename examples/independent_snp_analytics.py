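"""Analytic no-interaction inference for a single SNP.

Builds a case-control panel whose dominant-model carrier frequencies
follow Hardy-Weinberg proportions at minor-allele frequencies 0.1
(controls) and 0.25 (cases), solves the independent-SNP model in closed
form, and computes the test power at those frequencies.
"""

import numpy as np

from ddagwas import (EncodedMatrix, carrier_frequency, fit_independent,
                     power_independent, to_risk_model)

phi = {"control": 0.10, "case": 0.25}
n_side = 10_000

cols, labels = [], []
for y, (group, p) in enumerate(phi.items()):
    f = float(carrier_frequency(p))
    k = round(f * n_side)
    cols.append(np.repeat([1, 0], [k, n_side - k]).astype(np.int8))
    labels.append(np.full(n_side, y, dtype=np.int8))
enc = EncodedMatrix(np.concatenate(cols)[:, None], "dominant")
labels = np.concatenate(labels)

fit = fit_independent(enc, labels)
rm = to_risk_model(fit, prevalence=0.5)
f0, f1 = carrier_frequency(phi["control"]), carrier_frequency(phi["case"])

print(f"carrier frequencies  f = ({f0:.4f}, {f1:.4f})")
print(f"fields               h = ({fit.psi0.h[0]:.4f}, "
      f"{fit.psi1.h[0]:.4f})")
print(f"risk effect          beta = {rm.beta[0]:.4f}")
print(f"power at n=1000      {power_independent(f0, f1, 1000):.4f}")
# h is the log-odds of carrying the minor allele within each group; their
# difference beta is the log odds ratio of disease per carrier genotype,
# and the power is for the 1-d.f. likelihood-ratio test at level 0.05.
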