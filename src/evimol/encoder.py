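"""Latent encoders: attention message passing over molecular graphs, and an
ECFP-fingerprint feed-forward alternative.

Both encoders map molecules to a point ``z`` in a low-dimensional latent
space (``latent_dim``, typically 2-10); the evidential head downstream is
agnostic to which encoder produced ``z``.  The graph encoder uses gated
attention over neighbor messages and an attention-weighted readout; it is a
generic message-passing network, not a re-implementation of any particular
published architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from . import autodiff as ad
from .mol_io import (
    LabeledMolecule,
    MolecularGraph,
    N_ATOM_FEATURES,
    featurize,
)


@dataclass(frozen=True)
class EncoderConfig:
    latent_dim: int = 4
    hidden_dim: int = 64
    n_message_steps: int = 2
    n_readout_steps: int = 2
    dropout: float = 0.1
    encoder_kind: str = "graph_attention"  # or "fingerprint_mlp"
    fingerprint_bits: int = 2048

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        for attr in ("hidden_dim", "n_message_steps", "n_readout_steps"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.encoder_kind not in ("graph_attention", "fingerprint_mlp"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")


@dataclass(frozen=True)
class LatentPoint:
    """The encoder output z for one molecule."""

    z: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent point has non-finite entries")


@dataclass
class BatchedGraphs:
    """Concatenation of several molecular graphs with membership indices."""

    atom_features: np.ndarray   # (total_atoms, F)
    src: np.ndarray             # (total_edges,)
    dst: np.ndarray             # (total_edges,)
    mol_index: np.ndarray       # (total_atoms,) molecule id per atom
    n_mols: int


def batch_graphs(graphs: Sequence[MolecularGraph]) -> BatchedGraphs:
    feats, srcs, dsts, midx = [], [], [], []
    offset = 0
    for k, g in enumerate(graphs):
        feats.append(g.atom_features)
        srcs.append(g.bond_index[0] + offset)
        dsts.append(g.bond_index[1] + offset)
        midx.append(np.full(g.n_atoms, k, dtype=np.int64))
        offset += g.n_atoms
    return BatchedGraphs(
        atom_features=np.concatenate(feats, axis=0),
        src=np.concatenate(srcs).astype(np.int64),
        dst=np.concatenate(dsts).astype(np.int64),
        mol_index=np.concatenate(midx),
        n_mols=len(graphs),
    )


def _linear_init(rng, n_in, n_out):
    return ad.parameter(rng.standard_normal((n_in, n_out)) / np.sqrt(n_in))


class GraphAttentionEncoder:
    """Gated-attention message passing + attention-weighted readout."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h, d = config.hidden_dim, config.latent_dim
        F = N_ATOM_FEATURES
        p = {}
        p["W_in"] = _linear_init(rng, F, h)
        p["b_in"] = ad.parameter(np.zeros(h))
        for t in range(config.n_message_steps):
            p[f"Wa_{t}"] = _linear_init(rng, h, h)
            p[f"Wb_{t}"] = _linear_init(rng, h, h)
            p[f"va_{t}"] = _linear_init(rng, h, 1)
            p[f"Wm_{t}"] = _linear_init(rng, h, h)
            p[f"Wu_{t}"] = _linear_init(rng, h, h)
            p[f"Wz_{t}"] = _linear_init(rng, h, h)
            p[f"bu_{t}"] = ad.parameter(np.zeros(h))
            p[f"Wh_{t}"] = _linear_init(rng, h, h)
            p[f"Wc_{t}"] = _linear_init(rng, h, h)
            p[f"bc_{t}"] = ad.parameter(np.zeros(h))
        p["Wr"] = _linear_init(rng, h, h)
        p["br"] = ad.parameter(np.zeros(h))
        p["vr"] = _linear_init(rng, h, 1)
        for t in range(config.n_readout_steps):
            p[f"Wg_{t}"] = _linear_init(rng, h, h)
            p[f"Wp_{t}"] = _linear_init(rng, h, h)
            p[f"bg_{t}"] = ad.parameter(np.zeros(h))
        p["W_out"] = _linear_init(rng, h, d)
        p["b_out"] = ad.parameter(np.zeros(d))
        self.params = p

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def prepare(self, molecules: Sequence[LabeledMolecule]) -> BatchedGraphs:
        return batch_graphs([featurize(m) for m in molecules])

    # item-level API lets the training loop featurize once and re-collate
    def prepare_items(self, molecules: Sequence[LabeledMolecule]) -> list[MolecularGraph]:
        return [featurize(m) for m in molecules]

    def collate(self, items: Sequence[MolecularGraph]) -> BatchedGraphs:
        return batch_graphs(list(items))

    def forward(self, batch: BatchedGraphs, training: bool = False,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        if batch.n_mols == 0:
            return ad.constant(np.zeros((0, self.config.latent_dim)))
        p = self.params
        cfg = self.config
        h = ad.tanh(ad.matmul(ad.constant(batch.atom_features), p["W_in"]) + p["b_in"])
        n_atoms = batch.atom_features.shape[0]
        for t in range(cfg.n_message_steps):
            if len(batch.src):
                hs = ad.gather(h, batch.src)
                hd = ad.gather(h, batch.dst)
                score = ad.matmul(
                    ad.tanh(ad.matmul(hs, p[f"Wa_{t}"]) + ad.matmul(hd, p[f"Wb_{t}"])),
                    p[f"va_{t}"],
                )
                att = ad.segment_softmax(score, batch.dst, n_atoms)
                msg = ad.segment_sum(att * ad.matmul(hs, p[f"Wm_{t}"]),
                                     batch.dst, n_atoms)
            else:  # single-atom molecules only: no messages
                msg = ad.constant(np.zeros((n_atoms, cfg.hidden_dim)))
            u = ad.sigmoid(ad.matmul(h, p[f"Wu_{t}"]) + ad.matmul(msg, p[f"Wz_{t}"])
                           + p[f"bu_{t}"])
            cand = ad.tanh(ad.matmul(h, p[f"Wh_{t}"]) + ad.matmul(msg, p[f"Wc_{t}"])
                           + p[f"bc_{t}"])
            h = u * h + (1.0 - u) * cand
            if training and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                h = h * ad.constant(mask)
        score = ad.matmul(ad.tanh(ad.matmul(h, p["Wr"]) + p["br"]), p["vr"])
        att = ad.segment_softmax(score, batch.mol_index, batch.n_mols)
        g = ad.segment_sum(att * h, batch.mol_index, batch.n_mols)
        state = g
        for t in range(cfg.n_readout_steps):
            state = ad.tanh(ad.matmul(state, p[f"Wg_{t}"]) + ad.matmul(g, p[f"Wp_{t}"])
                            + p[f"bg_{t}"])
        return ad.matmul(state, p["W_out"]) + p["b_out"]


class FingerprintEncoder:
    """Morgan fingerprint (radius 2) -> one-hidden-layer MLP -> z."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        nbits, h, d = config.fingerprint_bits, config.hidden_dim, config.latent_dim
        self.params = {
            "W1": _linear_init(rng, nbits, h),
            "b1": ad.parameter(np.zeros(h)),
            "W2": _linear_init(rng, h, d),
            "b2": ad.parameter(np.zeros(d)),
        }
        self._fpgen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=nbits)

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def prepare(self, molecules: Sequence[LabeledMolecule]) -> np.ndarray:
        rows = []
        for m in molecules:
            rdmol = Chem.MolFromSmiles(m.smiles)
            fp = self._fpgen.GetFingerprintAsNumPy(rdmol)
            rows.append(fp.astype(np.float64))
        return (np.stack(rows) if rows
                else np.zeros((0, self.config.fingerprint_bits)))

    def prepare_items(self, molecules: Sequence[LabeledMolecule]) -> np.ndarray:
        return self.prepare(molecules)

    def collate(self, items: np.ndarray) -> np.ndarray:
        return np.asarray(items)

    def forward(self, fps: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        p = self.params
        h = ad.tanh(ad.matmul(ad.constant(fps), p["W1"]) + p["b1"])
        if training and self.config.dropout > 0:
            mask = (rng.random(h.shape) >= self.config.dropout) / (1 - self.config.dropout)
            h = h * ad.constant(mask)
        return ad.matmul(h, p["W2"]) + p["b2"]


def make_encoder(config: EncoderConfig, seed: int = 0):
    if config.encoder_kind == "graph_attention":
        return GraphAttentionEncoder(config, seed)
    return FingerprintEncoder(config, seed)


def encode(graph: MolecularGraph, encoder: GraphAttentionEncoder) -> LatentPoint:
    """Encode one molecular graph to its latent point (evaluation mode)."""
    if graph.n_atoms == 0:
        raise ValueError("cannot encode an empty graph")
    batch = batch_graphs([graph])
    z = encoder.forward(batch, training=False)
    return LatentPoint(z.data[0])


def encode_batch(graphs: Sequence[MolecularGraph],
                 encoder: GraphAttentionEncoder) -> list[LatentPoint]:
    if not graphs:
        return []
    z = encoder.forward(batch_graphs(graphs), training=False)
    return [LatentPoint(row) for row in z.data]
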