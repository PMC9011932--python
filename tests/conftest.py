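import numpy as np
import pytest

from dualgcn.bio_graph import assemble_bio_graph
from dualgcn.drug_graph import pad_drug_graph
from dualgcn.model import DualGCN, ModelConfig
from dualgcn.preprocess import ZScoreNormalizer
from dualgcn.synthetic import SyntheticConfig, generate_dataset


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    """Random binary symmetric zero-diagonal adjacency."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small end-to-end dataset shared by model-level tests."""
    ds = generate_dataset(SyntheticConfig(n_drugs=6, n_samples=12, n_genes=20,
                                          noise_sd=0.2, seed=11))
    expr_z = ZScoreNormalizer().fit(ds.expr).transform(ds.expr)
    cnv_z = ZScoreNormalizer().fit(ds.cnv).transform(ds.cnv)
    bios = {s: assemble_bio_graph(expr_z[s].to_dict(), cnv_z[s].to_dict(),
                                  ds.network, (1, 1), sample_id=s)
            for s in ds.expr.columns}
    drugs = {d.drug_id: pad_drug_graph(d) for d in ds.drugs}
    return ds, drugs, bios


def tiny_config(**kw) -> ModelConfig:
    base = dict(drug_gcn_widths=[16, 16], bio_gcn_widths=[16, 16],
                gene_encoder_dims=(8, 8), head_widths=[32, 1],
                max_epochs=3, patience=3, batch_size=8, seed=3)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_dataset):
    ds, drugs, bios = tiny_dataset
    model = DualGCN(tiny_config(), ds.network)
    model.fit(drugs, bios, ds.responses)
    return model
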