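"""Variational objective: Gaussian KL, reconstruction likelihood, the
reparameterized beta-ELBO, and the 10-sample Monte-Carlo ELBO estimator.

The per-image objective is

    ELBO_beta(x) = (1 - beta) * E_q[log p(x|z)] - beta * KL(q(z|x) || N(0, I))

with beta in [0, 1].  At beta = 0.5 this is half the standard ELBO, so the
weighting trades the two terms against each other while keeping the total
magnitude roughly constant across beta.  The reconstruction likelihood is
approximated by negative pixel-wise mean squared error; the KL of the
diagonal-Gaussian posterior against the standard-normal prior is closed
form, per dimension:

    KL_d = 1/2 * (mu_d^2 + sigma_d^2 - 1 - 2 ln sigma_d)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import GaussianLatent, VAEModel

#: number of posterior draws used by the reported ELBO estimator
N_ESTIMATOR_SAMPLES = 10


@dataclass
class ElboParts:
    """Per-image decomposition of the objective for one model."""

    recon: np.ndarray  # E_q[log p(x|z)] estimate, shape (n,)
    kl: np.ndarray  # KL(q||p) summed over dimensions, shape (n,)
    kl_per_dim: np.ndarray  # shape (n, latent)
    beta: float
    value: np.ndarray  # (1-beta)*recon - beta*kl, shape (n,)

    @property
    def unweighted(self) -> np.ndarray:
        """The beta-free bound recon - kl used for model selection."""
        return self.recon - self.kl


def gaussian_kl(latent: GaussianLatent) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form KL of N(mu, diag(sigma^2)) against N(0, I).

    Returns (per-dimension matrix of shape (n, d), per-image sums of
    shape (n,)).  Raises on non-positive sigma.
    """
    mu = np.asarray(latent.mu, dtype=np.float64)
    sigma = np.asarray(latent.sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    per_dim = 0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))
    # clamp tiny negative rounding noise; KL is analytically >= 0
    per_dim = np.maximum(per_dim, 0.0)
    return per_dim, per_dim.sum(axis=1)


def reconstruction_term(
    x: np.ndarray, xhat: np.ndarray, reduction: str = "sum"
) -> np.ndarray:
    """Negative pixel-wise squared error per image (larger = better).

    ``reduction="sum"`` (the default, recorded in checkpoints) keeps the raw
    per-image sum of squares; ``"mean"`` divides by the pixel count.
    """
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    axes = tuple(range(1, x.ndim))
    sq = ((x - xhat) ** 2).sum(axis=axes)
    if reduction == "mean":
        sq = sq / np.prod(x.shape[1:])
    elif reduction != "sum":
        raise ValueError("reduction must be 'mean' or 'sum'")
    return -sq


def elbo_beta(
    x: np.ndarray,
    model: VAEModel,
    beta: float,
    x_ref: np.ndarray | None = None,
    label: np.ndarray | None = None,
    n_samples: int = 1,
    seed: int | None = None,
    reduction: str = "sum",
) -> ElboParts:
    """Reparameterized beta-ELBO with the reconstruction term averaged over
    ``n_samples`` posterior draws."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 1 + model.spec.dimensionality:
        x = x[None]
    lat = model.encode(x, x_ref, label)
    kl_per_dim, kl = gaussian_kl(lat)
    rng = np.random.default_rng(seed)
    recon = np.zeros(x.shape[0], dtype=np.float64)
    for _ in range(n_samples):
        # common random numbers: one draw shared across the batch, so a
        # cell's estimate does not depend on which other cells are present
        eps = rng.standard_normal((1, lat.mu.shape[1])).astype(np.float32)
        z = lat.mu + lat.sigma * eps
        xhat = model.decode(z, x_ref, label)
        recon += reconstruction_term(x, xhat, reduction)
    recon /= n_samples
    value = (1.0 - beta) * recon - beta * kl
    return ElboParts(recon=recon, kl=kl, kl_per_dim=kl_per_dim, beta=beta, value=value)


def estimate_elbo(
    x: np.ndarray,
    model: VAEModel,
    x_ref: np.ndarray | None = None,
    label: np.ndarray | None = None,
    seed: int = 0,
    reduction: str = "sum",
) -> np.ndarray:
    """Unweighted per-image ELBO (recon - KL), reconstruction averaged over
    ten posterior samples.  Deterministic given ``seed``."""
    parts = elbo_beta(
        x, model, beta=0.5, x_ref=x_ref, label=label,
        n_samples=N_ESTIMATOR_SAMPLES, seed=seed, reduction=reduction,
    )
    return parts.unweighted


def elbo_gradients(
    x: np.ndarray,
    xhat: np.ndarray,
    mu: np.ndarray,
    logvar: np.ndarray,
    beta: float,
    reduction: str = "sum",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the mean negative beta-ELBO over a batch.

    Returns (d/dxhat, d/dmu, d/dlogvar) for the loss
    L = -mean_i[(1-beta)*recon_i - beta*KL_i], matching the caches of
    :meth:`VAEModel.backward_train`.
    """
    n = x.shape[0]
    npix = np.prod(x.shape[1:]) if reduction == "mean" else 1.0
    dxhat = (1.0 - beta) * 2.0 * (xhat - x) / (npix * n)
    dmu = beta * mu / n
    dlogvar = beta * 0.5 * (np.exp(logvar) - 1.0) / n
    return (
        dxhat.astype(np.float32),
        dmu.astype(np.float32),
        dlogvar.astype(np.float32),
    )
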