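import networkx as nx
import numpy as np
import pytest

from dualgcn.synthetic import (ATOM_RANGE, DEFAULT_PLANT_WEIGHTS,
                               SyntheticConfig, aromatic_fraction,
                               gen_molecules, gen_ppi_and_omics,
                               generate_dataset, module_genes, plant_response,
                               write_fixtures)


class TestGenMolecules:
    def test_invariants_and_connectivity(self):
        for g in gen_molecules(20, seed=0):
            g.validate()  # one-hot blocks, symmetry, binary adjacency
            G = nx.from_numpy_array(g.A_raw)
            assert nx.is_connected(G)

    def test_atom_counts_within_reported_range(self):
        for g in gen_molecules(40, seed=1):
            assert ATOM_RANGE[0] <= g.n_atoms <= ATOM_RANGE[1]

    def test_same_seed_identical(self):
        a = gen_molecules(10, seed=5)
        b = gen_molecules(10, seed=5)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.X_raw, gb.X_raw)
            assert np.array_equal(ga.A_raw, gb.A_raw)


class TestGenPpiAndOmics:
    def test_network_invariants_and_omics_shapes(self):
        cfg = SyntheticConfig(n_genes=40, n_samples=10, seed=2)
        net, expr, cnv = gen_ppi_and_omics(cfg)
        net.validate()
        assert expr.shape == cnv.shape == (40, 10)
        assert (expr.values >= 0).all() and (cnv.values >= 0).all()

    def test_zero_density_gives_edgeless_network(self):
        cfg = SyntheticConfig(n_genes=30, edge_density=0.0, seed=3)
        net, _, _ = gen_ppi_and_omics(cfg)
        assert net.n_edges == 0

    def test_edge_count_near_binomial_expectation(self):
        cfg = SyntheticConfig(n_genes=60, edge_density=0.2, seed=4)
        net, _, _ = gen_ppi_and_omics(cfg)
        n_pairs = 60 * 59 / 2
        mean = 0.2 * n_pairs
        sd = np.sqrt(n_pairs * 0.2 * 0.8)
        assert abs(net.n_edges - mean) < 3 * sd

    def test_preferential_attachment_model(self):
        cfg = SyntheticConfig(n_genes=30, edge_model="preferential_attachment",
                              attachment=2, seed=5)
        net, _, _ = gen_ppi_and_omics(cfg)
        assert net.n_edges == (30 - 2) * 2  # BA graph edge count

    def test_module_genes_are_correlated(self):
        cfg = SyntheticConfig(n_genes=50, n_samples=40, seed=6)
        _, expr, _ = gen_ppi_and_omics(cfg)
        module = module_genes(list(expr.index))
        m = expr.loc[module].T.corr().values
        off_diag = m[~np.eye(len(module), dtype=bool)]
        assert off_diag.mean() > 0.3  # shared latent factor


class TestPlantResponse:
    def test_zero_noise_deterministic(self):
        cfg = SyntheticConfig(noise_sd=0.0, seed=7)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert [r.ln_ic50 for r in a.responses] == [r.ln_ic50 for r in b.responses]

    def test_drug_only_weights_make_per_drug_variance_zero(self):
        cfg = SyntheticConfig(noise_sd=0.0, seed=8,
                              weights={"beta": 0.0, "gamma": 0.0, "delta": 0.0})
        ds = generate_dataset(cfg)
        for d in ds.drugs:
            vals = [r.ln_ic50 for r in ds.responses if r.drug_id == d.drug_id]
            assert np.var(vals) == pytest.approx(0.0, abs=1e-24)

    def test_variance_decomposition(self):
        noise_sd = 0.5
        noiseless = generate_dataset(SyntheticConfig(
            n_drugs=30, n_samples=60, noise_sd=0.0, seed=9))
        noisy = generate_dataset(SyntheticConfig(
            n_drugs=30, n_samples=60, noise_sd=noise_sd, seed=9))
        signal = np.var([r.ln_ic50 for r in noiseless.responses])
        total = np.var([r.ln_ic50 for r in noisy.responses])
        expected = signal + noise_sd ** 2
        assert total == pytest.approx(expected, rel=0.15)

    def test_aromatic_fraction_drives_drug_effect(self):
        ds = generate_dataset(SyntheticConfig(noise_sd=0.0, seed=10,
                                              weights={"beta": 0, "gamma": 0,
                                                       "delta": 0}))
        alpha = DEFAULT_PLANT_WEIGHTS["alpha"]
        for d in ds.drugs[:5]:
            r = next(r for r in ds.responses if r.drug_id == d.drug_id)
            assert r.ln_ic50 == pytest.approx(alpha * aromatic_fraction(d))

    def test_noise_requires_rng(self):
        ds = generate_dataset(SyntheticConfig(noise_sd=0.0, seed=1))
        with pytest.raises(ValueError, match="rng"):
            plant_response(ds.drugs[0], ds.expr.iloc[:, 0], ds.cnv.iloc[:, 0],
                           module_genes(ds.network.genes), noise_sd=0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_genes=3)
    with pytest.raises(ValueError):
        SyntheticConfig(n_drugs=1)
    with pytest.raises(ValueError):
        SyntheticConfig(noise_sd=-1)


def test_fixture_files_roundtrip(tmp_path):
    from dualgcn.bio_graph import build_ppi_adjacency, read_gene_list, read_ppi_tsv
    from dualgcn.drug_graph import read_graph_text
    from dualgcn.preprocess import (read_gene_intervals, read_omics_tsv,
                                    read_response_tsv, read_segments_tsv)

    ds = generate_dataset(SyntheticConfig(n_drugs=4, n_samples=6, n_genes=12,
                                          seed=12))
    write_fixtures(ds, tmp_path)
    genes = read_gene_list(tmp_path / "genes.txt")
    assert genes == ds.network.genes
    net = build_ppi_adjacency(read_ppi_tsv(tmp_path / "ppi.tsv"), genes,
                              min_score=0)
    assert np.array_equal(net.A_b, ds.network.A_b)
    expr = read_omics_tsv(tmp_path / "expr.tsv")
    np.testing.assert_allclose(expr.values, ds.expr.values, atol=1e-9)
    responses = read_response_tsv(tmp_path / "responses.tsv")
    assert len(responses) == len(ds.responses)
    for d in ds.drugs:
        g = read_graph_text(tmp_path / "drugs" / f"{d.drug_id}.txt")
        assert np.array_equal(g.X_raw, d.X_raw)
        assert np.array_equal(g.A_raw, d.A_raw)
    assert len(read_segments_tsv(tmp_path / "segments.tsv")) > 0
    assert len(read_gene_intervals(tmp_path / "gene_intervals.tsv")) == 12
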