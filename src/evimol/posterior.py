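"""Dirichlet evidence head: from per-class latent densities to predictions.

The head replaces a Softmax output layer.  For a latent point z with
per-class densities P_c(z) and training-set class counts N_c, the Dirichlet
concentration parameters are

    alpha_c = 1 + N_c * P_c(z),        c in {0, 1},

so alpha_c acts as a pseudo-count of evidence for class c.  The predictive
probability is the Dirichlet mean p = alpha_1 / (alpha_0 + alpha_1), and the
total evidence alpha_0 + alpha_1 is an epistemic-uncertainty score: far from
the training data both densities underflow and alpha -> (1, 1), giving
p = 0.5 with minimal evidence 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .mol_io import ClassCounts

#: clamp on log P_c(z) before exponentiation; the lower bound maps density
#: underflow to alpha ~ 1 (finite gradients), the upper bound prevents overflow
LOG_DENSITY_MIN = -40.0
LOG_DENSITY_MAX = 30.0


@dataclass(frozen=True)
class DirichletParams:
    alpha0: float
    alpha1: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha0) and np.isfinite(self.alpha1)):
            raise ValueError("alpha parameters must be finite")
        if self.alpha0 < 1.0 or self.alpha1 < 1.0:
            raise ValueError("alpha parameters must be >= 1")


@dataclass(frozen=True)
class PredictiveDistribution:
    p_mean: float
    evidence: float
    entropy: float


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Entropy (nats) of a Bernoulli(p), with 0 log 0 := 0."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -pm * np.log(pm) - (1 - pm) * np.log1p(-pm)
    return float(out) if out.ndim == 0 else out


def alphas_from_log_densities(log_p0: ad.Tensor, log_p1: ad.Tensor,
                              counts: ClassCounts) -> tuple[ad.Tensor, ad.Tensor]:
    """Batch Tensor version of the evidence map (autodiff-capable)."""
    if counts.n_negative < 0 or counts.n_positive < 0:
        raise ValueError("class counts must be non-negative")
    a0 = 1.0 + counts.n_negative * ad.exp(
        ad.clip(log_p0, LOG_DENSITY_MIN, LOG_DENSITY_MAX))
    a1 = 1.0 + counts.n_positive * ad.exp(
        ad.clip(log_p1, LOG_DENSITY_MIN, LOG_DENSITY_MAX))
    return a0, a1


def compute_alphas(log_p0: float, log_p1: float,
                   counts: ClassCounts) -> DirichletParams:
    """Evidence for one sample from its two log-densities and class counts.

    ``-inf`` log-densities (underflow) map to alpha exactly 1.
    """
    def one(log_p: float, n_c: int) -> float:
        if np.isneginf(log_p):
            return 1.0  # underflow: no evidence beyond the prior pseudo-count
        clamped = float(np.clip(log_p, LOG_DENSITY_MIN, LOG_DENSITY_MAX))
        return 1.0 + n_c * float(np.exp(clamped))

    if counts.n_negative < 0 or counts.n_positive < 0:
        raise ValueError("class counts must be non-negative")
    return DirichletParams(one(log_p0, counts.n_negative),
                           one(log_p1, counts.n_positive))


def predictive(alphas: DirichletParams) -> PredictiveDistribution:
    """Dirichlet mean, total evidence, and predictive binary entropy."""
    s = alphas.alpha0 + alphas.alpha1
    p = alphas.alpha1 / s
    return PredictiveDistribution(p_mean=p, evidence=s, entropy=binary_entropy(p))


def softmax_head(logits: tuple[float, float]) -> PredictiveDistribution:
    """Baseline Softmax output; evidence is reported as NaN (not applicable)."""
    l0, l1 = logits
    if not (np.isfinite(l0) and np.isfinite(l1)):
        raise ValueError("logits must be finite")
    m = max(l0, l1)
    e0, e1 = np.exp(l0 - m), np.exp(l1 - m)
    p = e1 / (e0 + e1)
    return PredictiveDistribution(p_mean=float(p), evidence=float("nan"),
                                  entropy=binary_entropy(float(p)))
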