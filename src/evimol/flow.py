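"""Per-class normalizing-flow densities in the latent space.

Each class density P_c(z) is a stack of radial transforms applied to z,
with a standard-normal base distribution: by the change-of-variables
formula,

    log P_c(z) = log N(f_K(...f_1(z)); 0, I) + sum_k log|det J_{f_k}|.

A radial layer expands or contracts density around a reference point z0:

    f(z) = z + beta * h(alpha, r) * (z - z0),   h = 1/(alpha + r),

with r = ||z - z0||.  The constraint beta >= -alpha (enforced by
reparameterizing beta = -alpha + softplus(b)) keeps the transform bijective,
and the log-Jacobian has the closed form

    log|det J| = (d - 1) log(1 + beta h) + log(1 + beta h - beta r h^2).

Density evaluation therefore needs only forward passes; inversion exists but
is never required at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

_EPS_R = 1e-12  # inside sqrt: keeps the radius differentiable at z == z0


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


@dataclass
class RadialLayer:
    """Parameters of one radial transform (all trainable Tensors)."""

    z0: ad.Tensor      # (d,) reference point
    a_raw: ad.Tensor   # scalar; alpha = softplus(a_raw) > 0
    b_raw: ad.Tensor   # scalar; beta = -alpha + softplus(b_raw) >= -alpha

    def parameters(self) -> list[ad.Tensor]:
        return [self.z0, self.a_raw, self.b_raw]


def _layer_terms(layer: RadialLayer, z: ad.Tensor):
    alpha = ad.softplus(layer.a_raw)
    beta = ad.softplus(layer.b_raw) - alpha
    diff = z - layer.z0.reshape(1, -1)
    r = ad.sqrt(ad.tsum(diff * diff, axis=1, keepdims=True) + _EPS_R)
    h = 1.0 / (alpha + r)
    return alpha, beta, diff, r, h


def transform_layer(layer: RadialLayer, z: ad.Tensor | np.ndarray):
    """Apply one radial layer to a batch of latent points.

    Returns ``(z_out, log_det)`` where ``log_det`` has shape (n, 1) and is
    the log absolute Jacobian determinant at each input point.
    """
    if not isinstance(z, ad.Tensor):
        z = ad.constant(np.atleast_2d(z))
    d = z.shape[1]
    alpha, beta, diff, r, h = _layer_terms(layer, z)
    bh = beta * h
    z_out = z + bh * diff
    log_det = (d - 1) * ad.log(1.0 + bh) + ad.log(1.0 + bh - beta * r * h * h)
    return z_out, log_det


def invert_layer(layer: RadialLayer, z_out: np.ndarray,
                 tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Numerically invert a radial layer (bisection on the radius).

    The map acts radially: r_out = r (1 + beta/(alpha + r)) is strictly
    increasing in r, so the inverse radius is found by bisection and the
    direction is preserved.
    """
    alpha = float(np.logaddexp(0.0, layer.a_raw.data))
    beta = float(np.logaddexp(0.0, layer.b_raw.data)) - alpha
    z0 = layer.z0.data
    out = np.empty_like(z_out)
    for i, zo in enumerate(np.atleast_2d(z_out)):
        dvec = zo - z0
        r_out = np.linalg.norm(dvec)
        if r_out < 1e-15:
            out[i] = z0
            continue
        lo, hi = 0.0, max(r_out * 2, r_out + abs(beta) + 1.0)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            val = mid * (1 + beta / (alpha + mid))
            if val < r_out:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        r_in = 0.5 * (lo + hi)
        out[i] = z0 + dvec / r_out * r_in
    return out


class FlowDensityModel:
    """A per-class density: radial transform stack over a standard normal."""

    def __init__(self, class_id: int, latent_dim: int, n_density: int,
                 seed: int = 0, init_scale: float = 0.01):
        if class_id not in (0, 1):
            raise ValueError("class_id must be 0 or 1")
        if latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if n_density < 1:
            raise ValueError("n_density must be >= 1")
        self.class_id = class_id
        self.latent_dim = latent_dim
        self.n_density = n_density
        rng = np.random.default_rng(seed)
        self.layers: list[RadialLayer] = []
        for _ in range(n_density):
            a_raw = _softplus_inv(1.0) + init_scale * rng.standard_normal()
            alpha = float(np.logaddexp(0.0, a_raw))
            # beta starts near 0 so the initial density is close to the base
            b_raw = _softplus_inv(alpha) + init_scale * rng.standard_normal()
            self.layers.append(RadialLayer(
                z0=ad.parameter(rng.standard_normal(latent_dim) * 0.5),
                a_raw=ad.parameter(np.array(a_raw)),
                b_raw=ad.parameter(np.array(b_raw)),
            ))

    def parameters(self) -> list[ad.Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def log_density(self, z: ad.Tensor | np.ndarray) -> ad.Tensor:
        """log P_c(z) for a batch of latent points; shape (n, 1)."""
        if not isinstance(z, ad.Tensor):
            z = ad.constant(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent dim mismatch: flow has {self.latent_dim}, z has {z.shape[1]}")
        total_log_det = ad.constant(np.zeros((z.shape[0], 1)))
        for layer in self.layers:
            z, log_det = transform_layer(layer, z)
            total_log_det = total_log_det + log_det
        d = self.latent_dim
        base = (-0.5 * d * np.log(2 * np.pi)
                - 0.5 * ad.tsum(z * z, axis=1, keepdims=True))
        return base + total_log_det


def init_flow(class_id: int, latent_dim: int, n_density: int,
              seed: int = 0, init_scale: float = 0.01) -> FlowDensityModel:
    """Build a per-class flow with reproducible, near-identity initialization."""
    return FlowDensityModel(class_id, latent_dim, n_density, seed, init_scale)


def log_density(flow: FlowDensityModel, z) -> np.ndarray:
    """Evaluate log P_c(z); accepts a single point or a batch, returns floats."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    out = flow.log_density(z).data[:, 0]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite log-density encountered")
    return out


class LatentNormalizer:
    """Batch normalization of z before density evaluation (no affine part).

    Joint training of encoder and flow densities lets the scale of z drift;
    normalizing z with batch statistics (running statistics in evaluation
    mode) anchors the latent distribution near the flow's base density.
    """

    def __init__(self, latent_dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.latent_dim = latent_dim
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(latent_dim)
        self.running_var = np.ones(latent_dim)

    def forward(self, z: ad.Tensor, training: bool = False) -> ad.Tensor:
        if training:
            mu = ad.tmean(z, axis=0, keepdims=True)
            var = ad.tmean((z - mu) * (z - mu), axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
            return (z - mu) / ad.sqrt(var + self.eps)
        mu = ad.constant(self.running_mean.reshape(1, -1))
        sd = ad.constant(np.sqrt(self.running_var + self.eps).reshape(1, -1))
        return (z - mu) / sd
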