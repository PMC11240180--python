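"""Training objectives for the evidential head and the Softmax baseline.

The evidential objective averages, over the batch, the uncertain
cross-entropy (UCE) minus a weighted Dirichlet entropy regularizer:

    L = (1/N) sum_i [ psi(a0_i + a1_i) - psi(a_{c*_i}) - w * H(Dir(a_i)) ],

where psi is the digamma function and c* the true label.  The UCE term is
the expectation of the cross-entropy under the predicted Dirichlet; the
entropy term smooths the Dirichlet toward the uniform prior.  With w = 1 the
objective is the unweighted form; the default w = 1e-5 keeps the regularizer
from dominating on small batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .posterior import DirichletParams


@dataclass(frozen=True)
class LossConfig:
    entropy_weight: float = 1e-5
    reduction: str = "mean"

    def __post_init__(self):
        if self.entropy_weight < 0:
            raise ValueError("entropy_weight must be >= 0")
        if self.reduction != "mean":
            raise ValueError("only mean reduction is supported")


def uce_terms(a0: ad.Tensor, a1: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Per-sample UCE: psi(a0+a1) - psi(a_label).  Tensor shapes (n, 1)."""
    labels = np.asarray(labels).reshape(-1, 1)
    a_true = ad.constant(1.0 - labels) * a0 + ad.constant(labels.astype(float)) * a1
    return ad.digamma(a0 + a1) - ad.digamma(a_true)


def dirichlet_entropies(a0: ad.Tensor, a1: ad.Tensor) -> ad.Tensor:
    """Differential entropy of Dir(a0, a1) (= Beta(a1, a0)), closed form."""
    s = a0 + a1
    log_beta = ad.gammaln(a0) + ad.gammaln(a1) - ad.gammaln(s)
    return (log_beta
            - (a0 - 1.0) * ad.digamma(a0)
            - (a1 - 1.0) * ad.digamma(a1)
            + (s - 2.0) * ad.digamma(s))


def batch_loss(a0: ad.Tensor, a1: ad.Tensor, labels: np.ndarray,
               cfg: LossConfig = LossConfig()) -> ad.Tensor:
    """Mean UCE minus weighted Dirichlet entropy over a batch (autodiff)."""
    if len(labels) == 0:
        raise ValueError("empty batch")
    terms = uce_terms(a0, a1, labels) - cfg.entropy_weight * dirichlet_entropies(a0, a1)
    return ad.tmean(terms)


def _pair(alphas: DirichletParams) -> tuple[ad.Tensor, ad.Tensor]:
    return (ad.constant(np.array([[alphas.alpha0]])),
            ad.constant(np.array([[alphas.alpha1]])))


def uce_term(alphas: DirichletParams, label: int) -> float:
    """UCE for one sample; always >= 0 since psi is increasing."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    a0, a1 = _pair(alphas)
    return float(uce_terms(a0, a1, np.array([label])).data[0, 0])


def dirichlet_entropy(alphas: DirichletParams) -> float:
    """Entropy of the predicted Dirichlet; 0 at alpha = (1, 1) (uniform)."""
    a0, a1 = _pair(alphas)
    return float(dirichlet_entropies(a0, a1).data[0, 0])


def total_loss(alphas: Sequence[DirichletParams], labels: Sequence[int],
               cfg: LossConfig = LossConfig()) -> float:
    """Batch-mean evidential loss from per-sample Dirichlet parameters."""
    if len(alphas) != len(labels):
        raise ValueError("alphas and labels must have equal length")
    if len(alphas) == 0:
        raise ValueError("empty batch")
    for lab in labels:
        if lab not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {lab!r}")
    a0 = ad.constant(np.array([[a.alpha0] for a in alphas]))
    a1 = ad.constant(np.array([[a.alpha1] for a in alphas]))
    return float(batch_loss(a0, a1, np.asarray(labels), cfg).data)


def cross_entropy(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Standard softmax cross-entropy for the baseline head (autodiff).

    ``logits`` has shape (n, 2); computed via log-sum-exp for stability.
    """
    labels = np.asarray(labels).reshape(-1)
    shift = ad.constant(logits.data.max(axis=1, keepdims=True))
    ls = logits - shift
    lse = ad.log(ad.tsum(ad.exp(ls), axis=1, keepdims=True))
    log_probs = ls - lse
    picked = ad.gather(log_probs, (np.arange(len(labels)), labels))
    return -ad.tmean(picked)
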