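"""Encoders: permutation invariance, determinism, batching, gradient flow."""

import numpy as np
import pytest
from rdkit import Chem

import evimol.autodiff as ad
from evimol import loss as loss_mod
from evimol.encoder import (
    EncoderConfig,
    FingerprintEncoder,
    GraphAttentionEncoder,
    batch_graphs,
    encode,
    encode_batch,
    make_encoder,
)
from evimol.mol_io import ClassCounts, LabeledMolecule, featurize
from evimol.models import EvidentialClassifier

CFG = EncoderConfig(latent_dim=3, hidden_dim=12, n_message_steps=2,
                    n_readout_steps=2, dropout=0.1)

SMILES_POOL = [
    "CCO", "CCN", "c1ccccc1", "CC(=O)O", "C1CCCCC1", "CCOC(=O)C",
    "c1ccncc1", "CC(C)CO", "OCCO", "CNC(=O)C", "C1COCCN1", "CC(F)(F)F",
    "c1ccc(Cl)cc1", "CCSCC", "CC=CC", "C#N", "CC(C)(C)C", "OC1CCCC1",
    "CCn1cccc1", "N#Cc1ccccc1",
]


@pytest.fixture(scope="module")
def enc():
    return GraphAttentionEncoder(CFG, seed=0)


class TestGraphEncoder:
    def test_output_dimension(self, enc):
        z = encode(featurize("CCO"), enc)
        assert z.z.shape == (3,)

    def test_permutation_invariance_over_pool(self, enc, rng):
        for smiles in SMILES_POOL:
            mol = Chem.MolFromSmiles(smiles)
            z_ref = encode(featurize(smiles), enc).z
            perm = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
            shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm),
                                        canonical=False)
            z_perm = encode(featurize(shuffled), enc).z
            np.testing.assert_allclose(z_perm, z_ref, atol=1e-5)

    def test_eval_mode_deterministic(self, enc):
        g = featurize("CC(=O)Nc1ccc(O)cc1")
        z1 = encode(g, enc).z
        z2 = encode(g, enc).z
        np.testing.assert_array_equal(z1, z2)

    def test_batch_matches_singles(self, enc):
        graphs = [featurize(s) for s in SMILES_POOL[:6]]
        batched = encode_batch(graphs, enc)
        for g, zb in zip(graphs, batched):
            np.testing.assert_allclose(zb.z, encode(g, enc).z, atol=1e-5)

    def test_empty_batch(self, enc):
        assert encode_batch([], enc) == []

    def test_single_atom_molecule(self, enc):
        z = encode(featurize("C"), enc)
        assert np.all(np.isfinite(z.z))


class TestFingerprintEncoder:
    def test_prepare_shape_and_determinism(self):
        cfg = EncoderConfig(encoder_kind="fingerprint_mlp", latent_dim=2,
                            hidden_dim=8, fingerprint_bits=512)
        enc = FingerprintEncoder(cfg, seed=0)
        mols = [LabeledMolecule(s, None, str(i))
                for i, s in enumerate(SMILES_POOL[:4])]
        X1, X2 = enc.prepare(mols), enc.prepare(mols)
        assert X1.shape == (4, 512)
        np.testing.assert_array_equal(X1, X2)

    def test_forward_latent_dim(self):
        cfg = EncoderConfig(encoder_kind="fingerprint_mlp", latent_dim=5,
                            hidden_dim=8, fingerprint_bits=256)
        enc = FingerprintEncoder(cfg, seed=1)
        mols = [LabeledMolecule("CCO", None, "0")]
        assert enc.forward(enc.prepare(mols)).shape == (1, 5)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"latent_dim": 1}, {"hidden_dim": 0}, {"dropout": 1.0},
        {"encoder_kind": "transformer"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EncoderConfig(**{**{"latent_dim": 3}, **kwargs})


class TestGradientFlow:
    def test_loss_gradient_matches_finite_differences(self):
        """Central-difference check through encoder + flows on a 2-mol batch."""
        cfg = EncoderConfig(latent_dim=2, hidden_dim=6, n_message_steps=1,
                            n_readout_steps=1, dropout=0.0)
        model = EvidentialClassifier(cfg, n_density=2, batch_norm=False, seed=2)
        model.class_counts = ClassCounts(5, 5)
        mols = [LabeledMolecule("CCO", 0, "a"), LabeledMolecule("CCN", 1, "b")]
        X = model.prepare(mols)
        labels = np.array([0, 1])

        def loss_value():
            a0, a1 = model.forward_alphas(X, training=False)
            return loss_mod.batch_loss(a0, a1, labels)

        out = loss_value()
        out.backward()
        params = model.parameters()
        g = np.random.default_rng(0)
        checked = 0
        for p in params:
            if p.grad is None:
                continue
            flat = p.data.reshape(-1)
            for k in g.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[k]
                flat[k] = orig + eps
                up = loss_value().item()
                flat[k] = orig - eps
                down = loss_value().item()
                flat[k] = orig
                fd = (up - down) / (2 * eps)
                an = p.grad.reshape(-1)[k]
                assert an == pytest.approx(fd, rel=1e-3, abs=1e-8)
                checked += 1
        assert checked >= 20


def test_make_encoder_dispatch():
    assert isinstance(make_encoder(CFG), GraphAttentionEncoder)
    fp_cfg = EncoderConfig(encoder_kind="fingerprint_mlp", latent_dim=2)
    assert isinstance(make_encoder(fp_cfg), FingerprintEncoder)


def test_batch_graphs_offsets():
    graphs = [featurize("CC"), featurize("CCC")]
    b = batch_graphs(graphs)
    assert b.atom_features.shape[0] == 5
    assert b.mol_index.tolist() == [0, 0, 1, 1, 1]
    assert b.src.max() >= 2  # second molecule's edges are offset
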