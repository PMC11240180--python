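"""Training pipeline: determinism, CV contracts, ensembling, grid search."""

import numpy as np
import pytest

from evimol.encoder import EncoderConfig
from evimol.metrics import brier
from evimol.mol_io import LabeledDataset
from evimol.models import load_model, save_model
from evimol.train import (
    TrainConfig,
    ensemble_predict,
    grid_search,
    kfold_cv,
    train_model,
)

FAST_ENCODER = EncoderConfig(encoder_kind="fingerprint_mlp", latent_dim=2,
                             hidden_dim=16, fingerprint_bits=512, dropout=0.1)


def fast_cfg(**kw):
    base = dict(epochs=8, batch_size=32, learning_rate=5e-3, k_folds=3,
                seed=0, patience=8, encoder=FAST_ENCODER, n_density=3)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def splits(small_synthetic):
    train, test = small_synthetic
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(train))
    n_val = len(train) // 5
    return (train.subset(idx[n_val:], "tr"), train.subset(idx[:n_val], "va"),
            test)


class TestTrainModel:
    def test_loss_improves_and_is_finite(self, splits):
        tr, va, _ = splits
        tm = train_model(tr, va, fast_cfg(), head="postnet")
        losses = [r["train_loss"] for r in tm.train_log]
        assert np.all(np.isfinite(losses))
        assert min(r["val_loss"] for r in tm.train_log) <= tm.train_log[0]["val_loss"]

    def test_seeded_determinism_of_loss_curves(self, splits):
        tr, va, _ = splits
        cfg = fast_cfg(epochs=4)
        log1 = train_model(tr, va, cfg, head="postnet").train_log
        log2 = train_model(tr, va, cfg, head="postnet").train_log
        assert [r["train_loss"] for r in log1] == [r["train_loss"] for r in log2]
        assert [r["val_loss"] for r in log1] == [r["val_loss"] for r in log2]

    def test_single_class_training_fatal(self, splits):
        tr, va, _ = splits
        only_neg = LabeledDataset([m for m in tr if m.label == 0], "neg")
        with pytest.raises(ValueError):
            train_model(only_neg, va, fast_cfg())

    def test_softmax_baseline_trains(self, splits):
        tr, va, _ = splits
        tm = train_model(tr, va, fast_cfg(epochs=4), head="softmax")
        assert np.isfinite(tm.train_log[-1]["val_loss"])

    def test_roundtrip_serialization(self, splits, tmp_path):
        tr, va, te = splits
        tm = train_model(tr, va, fast_cfg(epochs=3), head="postnet")
        save_model(tm.model, tmp_path / "m")
        clone = load_model(tmp_path / "m")
        mols = list(te)[:10]
        orig = tm.model.predict(mols)
        back = clone.predict(mols)
        for a, b in zip(orig, back):
            assert a.p_mean == pytest.approx(b.p_mean, rel=1e-12)
            assert a.evidence == pytest.approx(b.evidence, rel=1e-12)


class TestKFoldCV:
    def test_fold_contracts(self, small_synthetic):
        train, _ = small_synthetic
        cfg = fast_cfg(epochs=2, k_folds=4)
        models, oof = kfold_cv(train, cfg, head="postnet")
        assert len(models) == 4
        # every sample predicted exactly once out-of-fold
        assert len(oof) == len(train)
        assert all(r is not None for r in oof)
        ids = [r.mol_id for r in oof]
        assert ids == [m.mol_id for m in train]

    def test_stratification_balance(self, small_synthetic):
        train, _ = small_synthetic
        labels = np.array([m.label for m in train])
        global_frac = labels.mean()
        cfg = fast_cfg(epochs=1, k_folds=4)
        models, _ = kfold_cv(train, cfg, head="postnet")
        for tm in models:
            counts = tm.model.class_counts
            frac = counts.n_positive / counts.total
            # per-fold positive fraction close to the global fraction
            assert abs(frac - global_frac) <= 1.5 / cfg.k_folds

    def test_infeasible_stratification_fatal(self, splits):
        tr, _, _ = splits
        few = LabeledDataset(
            [m for m in tr if m.label == 1][:2]
            + [m for m in tr if m.label == 0][:20], "skew")
        with pytest.raises(ValueError):
            kfold_cv(few, fast_cfg(k_folds=5))


class TestEnsemble:
    def test_single_model_identity(self, splits):
        tr, va, te = splits
        tm = train_model(tr, va, fast_cfg(epochs=3), head="postnet")
        mols = list(te)[:8]
        single = tm.predict(mols)
        ens = ensemble_predict([tm], mols)
        for a, b in zip(single, ens):
            assert a.p_mean == pytest.approx(b.p_mean, rel=1e-12)

    def test_two_member_mean(self, splits):
        tr, va, te = splits
        m1 = train_model(tr, va, fast_cfg(epochs=3, seed=0), head="postnet")
        m2 = train_model(tr, va, fast_cfg(epochs=3, seed=1), head="postnet")
        mols = list(te)[:8]
        p1 = [r.p_mean for r in m1.predict(mols)]
        p2 = [r.p_mean for r in m2.predict(mols)]
        pe = [r.p_mean for r in ensemble_predict([m1, m2], mols)]
        np.testing.assert_allclose(pe, (np.array(p1) + np.array(p2)) / 2,
                                   atol=1e-12)

    def test_ensemble_brier_not_worse_than_member_mean(self, splits):
        """Jensen's inequality: Brier of the mean <= mean of the Briers."""
        tr, va, te = splits
        members = [train_model(tr, va, fast_cfg(epochs=3, seed=s), head="postnet")
                   for s in range(3)]
        mols = [m for m in te if m.label is not None]
        labels = np.array([m.label for m in mols])
        member_briers = [brier([r.p_mean for r in tm.predict(mols)], labels)
                         for tm in members]
        ens = ensemble_predict(members, mols)
        assert brier([r.p_mean for r in ens], labels) <= np.mean(member_briers) + 1e-12

    def test_config_mismatch_fatal(self, splits):
        tr, va, _ = splits
        m1 = train_model(tr, va, fast_cfg(epochs=1), head="postnet")
        other_enc = EncoderConfig(encoder_kind="fingerprint_mlp", latent_dim=3,
                                  hidden_dim=16, fingerprint_bits=512)
        m2 = train_model(tr, va, fast_cfg(epochs=1, encoder=other_enc),
                         head="postnet")
        with pytest.raises(ValueError):
            ensemble_predict([m1, m2], list(tr)[:2])

    def test_empty_ensemble_fatal(self):
        with pytest.raises(ValueError):
            ensemble_predict([], [])


class TestGridSearch:
    def test_single_cell_returned(self, small_synthetic):
        train, _ = small_synthetic
        cfg = fast_cfg(epochs=1, k_folds=3)
        best, table = grid_search(train, cfg, grid=[(2, 2)])
        assert best == (2, 2)
        assert len(table) == 1

    def test_one_row_per_cell_and_determinism(self, small_synthetic):
        train, _ = small_synthetic
        cfg = fast_cfg(epochs=1, k_folds=3)
        grid = [(2, 2), (3, 2)]
        best1, table1 = grid_search(train, cfg, grid=grid)
        best2, table2 = grid_search(train, cfg, grid=grid)
        assert len(table1) == 2
        assert best1 == best2
        assert table1 == table2

    def test_empty_grid_fatal(self, small_synthetic):
        train, _ = small_synthetic
        with pytest.raises(ValueError):
            grid_search(train, fast_cfg(), grid=[])
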