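import numpy as np
import pandas as pd
import pytest

from dcmscan.genio import HaplotypePanel


def build_panel(
    H,
    pops=None,
    positions=None,
    chrom="1",
    phased=True,
    ref="A",
    alt="G",
):
    """Construct a HaplotypePanel from a (2*n_samples x n_snps) allele array."""
    H = np.asarray(H, dtype=np.int8)
    n_samples = H.shape[0] // 2
    n_snps = H.shape[1]
    if pops is None:
        pops = ["pop"] * n_samples
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "id": [f"snp{i}" for i in range(n_snps)],
            "ref": ref,
            "alt": alt,
        }
    )
    samples = [f"s{i}" for i in range(n_samples)]
    return HaplotypePanel(variants=variants, samples=samples, pops=list(pops), H=H,
                          phased=phased)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_pop_panel(rng):
    """40 samples in two populations with different allele frequencies."""
    n_snps = 120
    f0 = rng.uniform(0.1, 0.9, n_snps)
    f1 = np.clip(f0 + rng.normal(0, 0.25, n_snps), 0.02, 0.98)
    H0 = (rng.random((40, n_snps)) < f0).astype(np.int8)
    H1 = (rng.random((40, n_snps)) < f1).astype(np.int8)
    return build_panel(np.vstack([H0, H1]), pops=["A"] * 20 + ["B"] * 20)
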