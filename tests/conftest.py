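import numpy as np
import pandas as pd
import pytest

from ddagwas import EncodedMatrix, design_strong_effects, simulate


def make_meta(m, chrom="1"):
    return pd.DataFrame({
        "chrom": [chrom] * m,
        "snp": [f"snp{i + 1}" for i in range(m)],
        "pos": np.arange(1, m + 1) * 1000,
        "a1": ["A"] * m,
        "a2": ["G"] * m,
    })


@pytest.fixture
def tiny_ped(tmp_path):
    """4 samples x 2 SNPs; phenotypes (1, 1, 2, 2); one missing call."""
    (tmp_path / "tiny.map").write_text(
        "1 snp1 0 1000\n1 snp2 0 2000\n")
    (tmp_path / "tiny.ped").write_text(
        "F1 I1 0 0 1 1 A G A A\n"
        "F2 I2 0 0 1 1 A A A G\n"
        "F3 I3 0 0 1 2 G G A G\n"
        "F4 I4 0 0 1 2 A G 0 0\n")
    return tmp_path / "tiny"


@pytest.fixture
def saturated_pair():
    """2-SNP pooled table with counts (40, 20, 20, 20) over states."""
    vals = np.repeat(np.array([[0, 0], [1, 0], [0, 1], [1, 1]],
                              dtype=np.int8), [40, 20, 20, 20], axis=0)
    labels = np.zeros(100, dtype=np.int8)
    labels[::2] = 1
    return EncodedMatrix(vals, "dominant"), labels


@pytest.fixture
def carrier_table():
    """Binary single-SNP panel: 40/100 case carriers vs 30/100 controls."""
    vals = np.concatenate([np.repeat([1, 0], [40, 60]),
                           np.repeat([1, 0], [30, 70])]).astype(np.int8)
    labels = np.concatenate([np.ones(100), np.zeros(100)]).astype(np.int8)
    return EncodedMatrix(vals[:, None], "dominant"), labels


@pytest.fixture(scope="session")
def sim_panel_m6():
    """Interacting 6-SNP dominant panel at n=1e4 (session-cached)."""
    spec = design_strong_effects(n=10_000, m=6, seed=42)
    enc, labels, psi0, psi1 = simulate(spec)
    return enc, labels, psi0, psi1
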