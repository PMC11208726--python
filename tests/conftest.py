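import numpy as np
import pytest

from haploae import (
    BlockConfig,
    BlockSimConfig,
    GenotypeMatrix,
    PanelSimConfig,
    VariantRecord,
    simulate_panel,
)


def make_matrix(dosages, chrom="22", spacing=1000, sample_prefix="S"):
    """GenotypeMatrix from a plain array, with evenly spaced positions."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n, m = dosages.shape
    variants = [
        VariantRecord(id=f"snp{j}", chrom=chrom, pos_bp=1 + j * spacing,
                      ref_allele="A", alt_allele="G")
        for j in range(m)
    ]
    return GenotypeMatrix(dosages, variants, [f"{sample_prefix}{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic 6-block panel, 300 samples: fast but LD-realistic."""
    cfg = PanelSimConfig(
        n_samples=300,
        blocks=tuple(
            BlockSimConfig(n_snps=6, n_founders=k, mutation_rate=0.01)
            for k in (2, 3, 2, 4, 3, 2)
        ),
        seed=7,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def tight_config():
    return BlockConfig()
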