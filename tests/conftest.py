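import numpy as np
import pandas as pd
import pytest

from geneqx.models import FrequencyPanel, GeneModel, VariantWeight
from geneqx.synth import FrequencyModel, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_model(weights, gene_id="G1", tissue="SYNTH", r2=0.5, prefix="v"):
    """Small gene model with given weights."""
    variants = [
        VariantWeight(
            variant_id=f"{prefix}{i}",
            chrom="1",
            pos=100 + i,
            ref_allele="A",
            effect_allele="G",
            weight=float(w),
        )
        for i, w in enumerate(weights)
    ]
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id, tissue=tissue, training_r2=r2, variants=variants
    )


def make_panel(freqs, ids=None, pops=None, ref_freq=None):
    """FrequencyPanel from an (n_variants, n_pops) array."""
    freqs = np.asarray(freqs, dtype=float)
    ids = ids or [f"v{i}" for i in range(freqs.shape[0])]
    pops = pops or [f"POP{j+1}" for j in range(freqs.shape[1])]
    df = pd.DataFrame(freqs, index=pd.Index(ids, name="variant_id"), columns=pops)
    ref = pd.Series(ref_freq, index=df.index) if ref_freq is not None else None
    return FrequencyPanel(df, ref)


@pytest.fixture(scope="session")
def null_dataset():
    """Shared neutral synthetic study: 60 genes, no injected selection."""
    return generate_dataset(n_genes=60, n_neutral=8000, seed=42)
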