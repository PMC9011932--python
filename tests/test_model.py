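import numpy as np
import pytest

from conftest import tiny_config
from dualgcn.bio_graph import BioGraph
from dualgcn.drug_graph import featurize_smiles, pad_drug_graph
from dualgcn.gcn_core import normalize_adjacency
from dualgcn.model import (DualGCN, FingerprintError, ModelConfig, forward,
                           predict_batch, train)
from dualgcn.synthetic import BUNDLED_SMILES
from rdkit import Chem


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(head_widths=[32, 2])  # non-scalar output
    with pytest.raises(ValueError):
        ModelConfig(max_epochs=5, patience=10)
    cfg = ModelConfig()
    assert ModelConfig.from_dict(cfg.to_dict()) == cfg


def test_same_seed_same_model_and_history(tiny_dataset):
    ds, drugs, bios = tiny_dataset
    m1 = DualGCN(tiny_config(), ds.network).fit(drugs, bios, ds.responses)
    m2 = DualGCN(tiny_config(), ds.network).fit(drugs, bios, ds.responses)
    assert m1.history == m2.history
    pair = (ds.responses[0].drug_id, ds.responses[0].sample_id)
    assert predict_batch([pair], m1, drugs, bios) == \
        predict_batch([pair], m2, drugs, bios)


def test_repeated_inference_bit_identical(trained_tiny_model, tiny_dataset):
    ds, drugs, bios = tiny_dataset
    pairs = [(r.drug_id, r.sample_id) for r in ds.responses[:5]]
    p1 = predict_batch(pairs, trained_tiny_model, drugs, bios)
    p2 = predict_batch(pairs, trained_tiny_model, drugs, bios)
    assert p1 == p2


def test_batch_equals_one_at_a_time(trained_tiny_model, tiny_dataset):
    ds, drugs, bios = tiny_dataset
    pairs = [(r.drug_id, r.sample_id) for r in ds.responses[:8]]
    batched = predict_batch(pairs, trained_tiny_model, drugs, bios)
    single = [predict_batch([p], trained_tiny_model, drugs, bios)[0]
              for p in pairs]
    np.testing.assert_allclose(batched, single, atol=1e-5)


def test_duplicate_and_empty_pair_lists(trained_tiny_model, tiny_dataset):
    ds, drugs, bios = tiny_dataset
    pair = (ds.responses[0].drug_id, ds.responses[0].sample_id)
    out = predict_batch([pair, pair], trained_tiny_model, drugs, bios)
    assert out[0] == out[1]
    assert predict_batch([], trained_tiny_model, drugs, bios) == []
    with pytest.raises(KeyError, match="nope"):
        predict_batch([("nope", pair[1])], trained_tiny_model, drugs, bios)


def test_atom_permutation_invariant_prediction(trained_tiny_model, tiny_dataset):
    ds, drugs, bios = tiny_dataset
    mol = Chem.MolFromSmiles(BUNDLED_SMILES["sorafenib"])
    perm = list(np.random.default_rng(1).permutation(mol.GetNumAtoms()))
    from dualgcn.drug_graph import featurize_molecule
    g0 = pad_drug_graph(featurize_molecule(mol, "m0"))
    g1 = pad_drug_graph(featurize_molecule(
        Chem.RenumberAtoms(mol, [int(i) for i in perm]), "m1"))
    bio = next(iter(bios.values()))
    y0 = trained_tiny_model.forward_pair(g0, bio)
    y1 = trained_tiny_model.forward_pair(g1, bio)
    assert y0 == pytest.approx(y1, abs=1e-5)


def test_padding_invariance_of_drug_embedding(trained_tiny_model):
    g = featurize_smiles(BUNDLED_SMILES["imatinib"], "ima")
    padded = pad_drug_graph(g, 100)
    m = trained_tiny_model
    e_native = m.drug_embedding(g.X_raw, normalize_adjacency(g.A_raw).A_hat,
                                np.ones(g.n_atoms))
    e_padded = m.drug_embedding(padded.X, normalize_adjacency(padded.A).A_hat,
                                padded.node_mask)
    np.testing.assert_allclose(e_native, e_padded, atol=1e-5)


def test_checkpoint_roundtrip_bit_exact(trained_tiny_model, tiny_dataset, tmp_path):
    ds, drugs, bios = tiny_dataset
    path = tmp_path / "model.ckpt"
    trained_tiny_model.save(path)
    loaded = DualGCN.load(path)
    pairs = [(r.drug_id, r.sample_id) for r in ds.responses[:10]]
    assert predict_batch(pairs, trained_tiny_model, drugs, bios) == \
        predict_batch(pairs, loaded, drugs, bios)
    assert loaded.fingerprint == trained_tiny_model.fingerprint


@pytest.mark.parametrize("mask,channel", [((1, 0), 1), ((0, 1), 0)])
def test_ablation_masks_ignore_other_channel(tiny_dataset, mask, channel):
    ds, drugs, bios = tiny_dataset
    cfg = tiny_config(feature_mask=mask, max_epochs=2, patience=2)
    model = DualGCN(cfg, ds.network).fit(drugs, bios, ds.responses)
    rng = np.random.default_rng(0)
    pairs = [(r.drug_id, r.sample_id) for r in ds.responses[:6]]
    base = predict_batch(pairs, model, drugs, bios)
    # perturb the masked-off channel arbitrarily
    perturbed = {
        s: BioGraph(sample_id=s,
                    X_raw=b.X_raw + rng.normal(size=b.X_raw.shape)
                    * np.eye(2)[channel][None, :],
                    feature_mask=b.feature_mask)
        for s, b in bios.items()}
    after = predict_batch(pairs, model, drugs, perturbed)
    assert max(abs(a - b) for a, b in zip(base, after)) == 0.0


def test_gene_count_mismatch_raises(trained_tiny_model, tiny_dataset):
    ds, drugs, bios = tiny_dataset
    bad = BioGraph(sample_id="x", X_raw=np.zeros((5, 2)))
    with pytest.raises(FingerprintError):
        trained_tiny_model.forward_pair(next(iter(drugs.values())), bad)
    from dualgcn.bio_graph import PPINetwork
    other = PPINetwork(genes=["a", "b"], A_b=np.zeros((2, 2), dtype=np.int8))
    with pytest.raises(FingerprintError):
        forward(next(iter(drugs.values())), bad, other, trained_tiny_model)


def test_constant_target_learned(tiny_dataset):
    ds, drugs, bios = tiny_dataset
    from dualgcn.preprocess import ResponseRecord
    const = [ResponseRecord(r.drug_id, r.sample_id, 2.5) for r in ds.responses]
    cfg = tiny_config(max_epochs=20, patience=20)
    model = train([(drugs[r.drug_id], bios[r.sample_id], r) for r in const],
                  ds.network, cfg)
    preds = predict_batch([(r.drug_id, r.sample_id) for r in const[:10]],
                          model, drugs, bios)
    assert np.sqrt(np.mean((np.array(preds) - 2.5) ** 2)) < 0.2


def test_training_preconditions(tiny_dataset):
    ds, drugs, bios = tiny_dataset
    with pytest.raises(ValueError, match="empty"):
        train([], ds.network, tiny_config())
    cfg = tiny_config(batch_size=64)
    with pytest.raises(ValueError, match="batch_size"):
        train([(drugs[r.drug_id], bios[r.sample_id], r)
               for r in ds.responses[:10]], ds.network, cfg)
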