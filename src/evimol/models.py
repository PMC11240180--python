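"""Full classifiers: encoder + evidential flow head, and the Softmax baseline.

``EvidentialClassifier`` composes a latent encoder with two per-class radial
flows; its forward pass yields per-sample Dirichlet parameters.  The
``SoftmaxClassifier`` shares the encoder and replaces the head with a linear
map to two logits — the traditional architecture used as a baseline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .encoder import EncoderConfig, make_encoder
from .flow import FlowDensityModel, LatentNormalizer, init_flow
from .mol_io import ClassCounts, LabeledMolecule
from .posterior import alphas_from_log_densities, binary_entropy


@dataclass(frozen=True)
class PredictionRecord:
    mol_id: str
    smiles: str
    alpha0: float
    alpha1: float
    p_mean: float
    evidence: float
    entropy: float


class EvidentialClassifier:
    """Encoder -> (optional batch-norm) -> per-class flow densities -> alpha."""

    def __init__(self, encoder_config: EncoderConfig, n_density: int = 6,
                 batch_norm: bool = True, seed: int = 0):
        self.encoder_config = encoder_config
        self.n_density = n_density
        self.batch_norm = batch_norm
        self.seed = seed
        self.encoder = make_encoder(encoder_config, seed=seed)
        d = encoder_config.latent_dim
        self.flows: list[FlowDensityModel] = [
            init_flow(0, d, n_density, seed=seed * 2 + 1),
            init_flow(1, d, n_density, seed=seed * 2 + 2),
        ]
        self.normalizer = LatentNormalizer(d) if batch_norm else None
        self.class_counts: ClassCounts | None = None

    def parameters(self) -> list[ad.Tensor]:
        params = self.encoder.parameters()
        for f in self.flows:
            params += f.parameters()
        return params

    def prepare(self, molecules: Sequence[LabeledMolecule]):
        return self.encoder.prepare(molecules)

    def latent(self, inputs, training: bool = False,
               rng: np.random.Generator | None = None) -> ad.Tensor:
        z = self.encoder.forward(inputs, training=training, rng=rng)
        if self.normalizer is not None:
            z = self.normalizer.forward(z, training=training)
        return z

    def forward_alphas(self, inputs, training: bool = False,
                       rng: np.random.Generator | None = None):
        if self.class_counts is None:
            raise RuntimeError("class_counts unset; call fit or assign before predicting")
        z = self.latent(inputs, training=training, rng=rng)
        log_p0 = self.flows[0].log_density(z)
        log_p1 = self.flows[1].log_density(z)
        return alphas_from_log_densities(log_p0, log_p1, self.class_counts)

    def predict(self, molecules: Sequence[LabeledMolecule]) -> list[PredictionRecord]:
        if not molecules:
            return []
        inputs = self.prepare(molecules)
        a0, a1 = self.forward_alphas(inputs, training=False)
        a0, a1 = a0.data[:, 0], a1.data[:, 0]
        s = a0 + a1
        p = a1 / s
        ent = np.atleast_1d(binary_entropy(p))
        return [
            PredictionRecord(m.mol_id, m.smiles, float(a0[i]), float(a1[i]),
                             float(p[i]), float(s[i]), float(ent[i]))
            for i, m in enumerate(molecules)
        ]


class SoftmaxClassifier:
    """Encoder -> linear logits -> softmax; the traditional baseline."""

    def __init__(self, encoder_config: EncoderConfig, seed: int = 0):
        self.encoder_config = encoder_config
        self.seed = seed
        self.encoder = make_encoder(encoder_config, seed=seed)
        rng = np.random.default_rng(seed + 7919)
        d = encoder_config.latent_dim
        self.W = ad.parameter(rng.standard_normal((d, 2)) / np.sqrt(d))
        self.b = ad.parameter(np.zeros(2))
        self.class_counts: ClassCounts | None = None  # parity with evidential API

    def parameters(self) -> list[ad.Tensor]:
        return self.encoder.parameters() + [self.W, self.b]

    def prepare(self, molecules: Sequence[LabeledMolecule]):
        return self.encoder.prepare(molecules)

    def forward_logits(self, inputs, training: bool = False,
                       rng: np.random.Generator | None = None) -> ad.Tensor:
        z = self.encoder.forward(inputs, training=training, rng=rng)
        return ad.matmul(z, self.W) + self.b

    def predict(self, molecules: Sequence[LabeledMolecule]) -> list[PredictionRecord]:
        if not molecules:
            return []
        logits = self.forward_logits(self.prepare(molecules), training=False).data
        shift = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shift)
        p = e[:, 1] / e.sum(axis=1)
        ent = np.atleast_1d(binary_entropy(p))
        return [
            PredictionRecord(m.mol_id, m.smiles, float("nan"), float("nan"),
                             float(p[i]), float("nan"), float(ent[i]))
            for i, m in enumerate(molecules)
        ]


# ------------------------------------------------------------- serialization
def save_model(model, path: str | Path) -> None:
    """Serialize a trained classifier to a directory (JSON text files)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kind = "evidential" if isinstance(model, EvidentialClassifier) else "softmax"
    meta = {
        "kind": kind,
        "encoder_config": asdict(model.encoder_config),
        "seed": model.seed,
        "class_counts": (None if model.class_counts is None
                         else [model.class_counts.n_negative,
                               model.class_counts.n_positive]),
    }
    state = {}
    if kind == "evidential":
        meta["n_density"] = model.n_density
        meta["batch_norm"] = model.batch_norm
        if model.normalizer is not None:
            state["running_mean"] = model.normalizer.running_mean.tolist()
            state["running_var"] = model.normalizer.running_var.tolist()
    state["params"] = [p.data.tolist() for p in model.parameters()]
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    (path / "state.json").write_text(json.dumps(state))


def load_model(path: str | Path):
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    state = json.loads((path / "state.json").read_text())
    enc_cfg = EncoderConfig(**meta["encoder_config"])
    if meta["kind"] == "evidential":
        model = EvidentialClassifier(enc_cfg, n_density=meta["n_density"],
                                     batch_norm=meta["batch_norm"],
                                     seed=meta["seed"])
        if model.normalizer is not None:
            model.normalizer.running_mean = np.array(state["running_mean"])
            model.normalizer.running_var = np.array(state["running_var"])
    else:
        model = SoftmaxClassifier(enc_cfg, seed=meta["seed"])
    if meta["class_counts"] is not None:
        model.class_counts = ClassCounts(*meta["class_counts"])
    for p, saved in zip(model.parameters(), state["params"], strict=True):
        p.data = np.asarray(saved, dtype=np.float64).reshape(p.data.shape)
    return model
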