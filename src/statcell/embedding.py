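"""Latent-space analytics: embeddings, dimension importance, latent walks,
feature correlation, PC regression and population-shift projection.

Embeddings are posterior means (no sampling), so every analysis here is a
deterministic function of a trained checkpoint and its inputs.  Dimension
importance is measured two ways: by mean absolute deviation from zero of
the embedding coordinates, and by the per-dimension KL divergence against
the prior — a dimension whose population-mean KL exceeds a threshold
(0.6 by default) is "active", i.e. carries information past the prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .architecture import VAEModel
from .objective import gaussian_kl

_BATCH = 64  # encode in chunks to bound memory


@dataclass
class EmbeddingTable:
    """Posterior-mean matrix (cells x latent dims) plus per-cell metadata."""

    values: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding values")
        if self.metadata is not None and len(self.metadata) != len(self.values):
            raise ValueError("metadata row count must match embedding rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


def _batched_encode(model: VAEModel, x, x_ref, label):
    mus, sigmas = [], []
    for start in range(0, len(x), _BATCH):
        sl = slice(start, start + _BATCH)
        lat = model.encode(
            x[sl],
            None if x_ref is None else x_ref[sl],
            None if label is None else label[sl],
        )
        mus.append(lat.mu)
        sigmas.append(lat.sigma)
    return np.concatenate(mus), np.concatenate(sigmas)


def embed_population(
    model: VAEModel,
    x: np.ndarray,
    x_ref: np.ndarray | None = None,
    label: np.ndarray | None = None,
    metadata: pd.DataFrame | None = None,
) -> EmbeddingTable:
    """Posterior means for every cell; no new training, no sampling."""
    if model.spec.conditional and (x_ref is None or label is None):
        raise TypeError("conditional model requires x_ref and label")
    mu, _ = _batched_encode(model, np.asarray(x, dtype=np.float32), x_ref, label)
    return EmbeddingTable(values=mu, metadata=metadata)


def rank_dimensions_by_mad(table: EmbeddingTable) -> tuple[np.ndarray, np.ndarray]:
    """Dimensions ordered by descending mean |mu_d|; ties broken by index.

    Returns (order, mad) with ``mad[order[0]]`` the largest.
    """
    if table.n_cells < 1:
        raise ValueError("empty embedding table")
    mad = np.abs(table.values).mean(axis=0)
    order = np.argsort(-mad, kind="stable")
    return order, mad


def dimension_kld(
    model: VAEModel,
    x: np.ndarray,
    x_ref: np.ndarray | None = None,
    label: np.ndarray | None = None,
    threshold: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Population-mean per-dimension KL and the active set above threshold."""
    mu, sigma = _batched_encode(model, np.asarray(x, dtype=np.float32), x_ref, label)
    from .architecture import GaussianLatent

    per_dim, _ = gaussian_kl(GaussianLatent(mu=mu, sigma=sigma))
    mean_kld = per_dim.mean(axis=0)
    active = np.flatnonzero(mean_kld > threshold)
    return mean_kld, active


def latent_walk(
    model: VAEModel,
    table: EmbeddingTable,
    dim: int,
    n_steps: int = 9,
    span: float = 2.0,
    x_ref: np.ndarray | None = None,
    label: np.ndarray | None = None,
) -> np.ndarray:
    """Decode a sweep of one latent dimension across +-span population SDs.

    Step k sets dimension ``dim`` to (-span + 2*span*k/(n_steps-1)) * SD_d
    with every other dimension at 0; SD_d is the standard deviation of the
    embedding coordinates in ``table`` (conventionally the test split).
    """
    if not 0 <= dim < model.spec.latent_dim:
        raise IndexError(f"dimension {dim} outside [0, {model.spec.latent_dim})")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    sd = float(table.values[:, dim].std())
    coords = np.linspace(-span, span, n_steps) * sd
    z = np.zeros((n_steps, model.spec.latent_dim), dtype=np.float32)
    z[:, dim] = coords
    if x_ref is not None and x_ref.ndim == model.spec.dimensionality + 1:
        x_ref = np.repeat(x_ref[None], n_steps, axis=0)
    if label is not None and label.ndim == 2 and label.shape[0] == 1:
        label = np.repeat(label, n_steps, axis=0)
    return model.decode(z, x_ref, label)


def correlate_features(
    table: EmbeddingTable,
    features: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Rank (or linear) correlation of each latent dimension with each
    feature; constant columns yield missing values, not zeros."""
    if len(features) != table.n_cells:
        raise ValueError("feature rows must match embedding rows")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    dims = table.values
    out = np.full((table.n_dims, features.shape[1]), np.nan)
    fvals = features.to_numpy(dtype=np.float64)
    for j in range(features.shape[1]):
        col = fvals[:, j]
        if np.ptp(col) == 0:
            continue
        for d in range(table.n_dims):
            zcol = dims[:, d]
            if np.ptp(zcol) == 0:
                continue
            if method == "spearman":
                r = stats.spearmanr(zcol, col).statistic
            else:
                r = stats.pearsonr(zcol, col).statistic
            out[d, j] = r
    return pd.DataFrame(
        out, index=[f"z{d}" for d in range(table.n_dims)], columns=features.columns
    )


@dataclass
class PCRegressionResult:
    r2_per_pc: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_pcs, n_features)
    n_active_dims: int


def feature_pc_regression(
    table: EmbeddingTable,
    features: pd.DataFrame | np.ndarray,
    active_set: np.ndarray,
    n_pcs: int = 5,
    train_frac: float = 0.9,
    seed: int = 0,
) -> PCRegressionResult:
    """Linear decodability of the feature space's top PCs from the active
    latent dimensions.

    Features are z-scored, projected onto their top ``n_pcs`` principal
    components; each PC is fit by ordinary least squares from the active
    embedding dims on a ``train_frac`` split and scored by out-of-sample R^2.
    """
    f = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=np.float64,
    )
    if len(f) != table.n_cells:
        raise ValueError("feature rows must match embedding rows")
    if len(f) < 10:
        raise ValueError("need at least 10 rows")
    sd = f.std(axis=0)
    sd[sd == 0] = 1.0
    fz = (f - f.mean(axis=0)) / sd
    n_pcs = min(n_pcs, fz.shape[1])
    pca = PCA(n_components=n_pcs, random_state=0)
    pcs = pca.fit_transform(fz)
    active_set = np.asarray(active_set, dtype=int)
    if len(active_set) < 1:
        import warnings

        warnings.warn("no active latent dimensions; reporting R^2 = 0")
        return PCRegressionResult(
            r2_per_pc=np.zeros(n_pcs),
            explained_variance_ratio=pca.explained_variance_ratio_,
            loadings=pca.components_,
            n_active_dims=0,
        )
    z = table.values[:, active_set]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(f))
    n_train = int(round(train_frac * len(f)))
    tr, te = order[:n_train], order[n_train:]
    r2 = np.zeros(n_pcs)
    for k in range(n_pcs):
        reg = LinearRegression().fit(z[tr], pcs[tr, k])
        pred = reg.predict(z[te])
        ss_res = float(((pcs[te, k] - pred) ** 2).sum())
        ss_tot = float(((pcs[te, k] - pcs[te, k].mean()) ** 2).sum())
        r2[k] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PCRegressionResult(
        r2_per_pc=r2,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_,
        n_active_dims=len(active_set),
    )


@dataclass
class PopulationShift:
    shift: np.ndarray  # centroid(treated) - centroid(control)
    direction: np.ndarray  # unit vector along the shift (zeros if no shift)
    control_projection: np.ndarray  # scalar coordinates, control centroid at 0
    treated_projection: np.ndarray

    def cells_at_quantiles(self, quantiles, population: str = "treated"):
        """Indices of cells nearest the given projection quantiles."""
        proj = (
            self.treated_projection if population == "treated" else self.control_projection
        )
        qs = np.quantile(proj, quantiles)
        return np.array([int(np.argmin(np.abs(proj - q))) for q in qs])


def population_shift(
    treated: EmbeddingTable, control: EmbeddingTable
) -> PopulationShift:
    """Centroid displacement of a perturbed population and per-cell
    projections onto the displacement direction."""
    if treated.n_cells == 0 or control.n_cells == 0:
        raise ValueError("empty population")
    if treated.n_dims != control.n_dims:
        raise ValueError("latent spaces differ in dimension")
    c0 = control.values.mean(axis=0)
    c1 = treated.values.mean(axis=0)
    shift = c1 - c0
    norm = np.linalg.norm(shift)
    direction = shift / norm if norm > 0 else np.zeros_like(shift)
    return PopulationShift(
        shift=shift,
        direction=direction,
        control_projection=(control.values - c0) @ direction,
        treated_projection=(treated.values - c0) @ direction,
    )
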