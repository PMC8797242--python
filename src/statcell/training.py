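"""Dataset splitting, the optimization loop, model selection and the
beta-sweep harness.

Training maximizes the reparameterized objective
``(1-beta)*recon - beta*KL`` by Adam (batch size 32, learning rate 2e-4,
moment coefficients (0.9, 0.999) by default); model selection uses the
*unweighted* validation bound ``recon - KL`` so checkpoints are comparable
across beta.  Splits are stratified by structure label when labels are
present, so every label occurs in every split even for small populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import VAEModel, one_hot
from .nn.layers import Adam, collect_state, restore_state
from .objective import elbo_beta, elbo_gradients, gaussian_kl


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 2e-4
    epochs: int = 300
    adam_betas: tuple = (0.9, 0.999)
    beta: float = 0.5
    split_fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    recon_reduction: str = "sum"
    patience: int | None = None  # optional early stopping; off by default

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


@dataclass
class TrainData:
    """Arrays for one sub-model: inputs, optional conditioning, labels."""

    x: np.ndarray  # (n, C, *spatial)
    x_ref: np.ndarray | None = None  # (n, 2, *spatial) for the target model
    labels: np.ndarray | None = None  # (n,) integer label indices
    n_classes: int | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.n_classes is None:
                self.n_classes = int(self.labels.max()) + 1

    def __len__(self):
        return len(self.x)

    def onehot(self, idx) -> np.ndarray | None:
        if self.labels is None:
            return None
        return one_hot(self.labels[idx], self.n_classes)

    def ref(self, idx) -> np.ndarray | None:
        return None if self.x_ref is None else self.x_ref[idx]

    @classmethod
    def from_phantoms(cls, dataset, target: str = "reference") -> "TrainData":
        """Build arrays from a :class:`~statcell.phantom.PhantomDataset`.

        ``target="reference"`` yields the 2-channel dye stack for M_R;
        ``target="structure"`` yields the structure channel as input with
        the dye stack as conditioning and the mix-local label index.
        """
        arr = dataset.arrays()
        if target == "reference":
            return cls(x=arr[:, :2])
        if target == "structure":
            return cls(
                x=arr[:, 2:3],
                x_ref=arr[:, :2],
                labels=dataset.metadata["label_index"].to_numpy(),
                n_classes=len(dataset.kinds),
            )
        raise ValueError("target must be 'reference' or 'structure'")


def split_dataset(
    n_or_labels, fractions=(0.8, 0.1, 0.1), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/validation/test index split.

    Pass the dataset size for a plain shuffle split, or an array of labels
    for a stratified split (each label distributed across all three parts).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if np.isscalar(n_or_labels):
        n = int(n_or_labels)
        labels = np.zeros(n, dtype=int)
    else:
        labels = np.asarray(n_or_labels)
        n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(seed)
    parts: list[list] = [[], [], []]
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        m = len(idx)
        n_train = int(round(fractions[0] * m))
        n_val = int(round(fractions[1] * m))
        n_train = min(n_train, m - 2) if m >= 3 else n_train
        n_val = max(1, n_val) if m - n_train >= 2 else n_val
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def evaluate(
    model: VAEModel, data: TrainData, idx: np.ndarray, cfg: TrainConfig, seed: int = 0
):
    """Mean ELBO parts over a subset, deterministic given seed."""
    parts = elbo_beta(
        data.x[idx], model, beta=cfg.beta,
        x_ref=data.ref(idx), label=data.onehot(idx),
        n_samples=1, seed=seed, reduction=cfg.recon_reduction,
    )
    return {
        "recon": float(parts.recon.mean()),
        "kl": float(parts.kl.mean()),
        "combined": float(parts.value.mean()),
        "elbo": float(parts.unweighted.mean()),
    }


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: dict
    best_epoch: int
    splits: tuple  # (train_idx, val_idx, test_idx)
    config: TrainConfig


def train(model: VAEModel, data: TrainData, cfg: TrainConfig) -> TrainResult:
    """Fixed-epoch optimization with best-validation-ELBO selection."""
    tr, va, te = split_dataset(
        data.labels if data.labels is not None else len(data),
        cfg.split_fractions,
        cfg.seed,
    )
    opt = Adam(model.params(), lr=cfg.learning_rate, betas=cfg.adam_betas)
    rng = np.random.default_rng(cfg.seed + 17)
    sample_rng = np.random.default_rng(cfg.seed + 29)
    rows = []
    best_state, best_elbo, best_epoch = collect_state(model), -np.inf, -1
    since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr)
        ep_recon, ep_kl, nb = 0.0, 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = data.x[idx]
            refb, lblb = data.ref(idx), data.onehot(idx)
            opt.zero_grad()
            lat, z, xhat = model.forward_train(xb, refb, lblb, sample_rng=sample_rng)
            if not np.all(np.isfinite(xhat)):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {nb} "
                    f"(cells {idx.tolist()})"
                )
            logvar = 2.0 * np.log(lat.sigma)
            dxhat, dmu, dlogvar = elbo_gradients(
                xb, xhat, lat.mu, logvar, cfg.beta, cfg.recon_reduction
            )
            model.backward_train(dxhat, dmu, dlogvar)
            opt.step()
            _, kl = gaussian_kl(lat)
            npix = np.prod(xb.shape[1:]) if cfg.recon_reduction == "mean" else 1.0
            sq = ((xb.astype(np.float64) - xhat) ** 2).sum(
                axis=tuple(range(1, xb.ndim))
            ) / npix
            ep_recon += float(-sq.mean())
            ep_kl += float(kl.mean())
            nb += 1
        # fixed evaluation seed: epochs are compared on the same draws
        val = evaluate(model, data, va, cfg, seed=cfg.seed + 1000)
        rows.append(
            {
                "epoch": epoch,
                "train_recon": ep_recon / max(nb, 1),
                "train_kl": ep_kl / max(nb, 1),
                "val_recon": val["recon"],
                "val_kl": val["kl"],
                "val_elbo": val["elbo"],
            }
        )
        if val["elbo"] > best_elbo:
            best_elbo, best_epoch = val["elbo"], epoch
            best_state = collect_state(model)
            since_best = 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best > cfg.patience:
                break
    restore_state(model, best_state)
    return TrainResult(
        history=pd.DataFrame(rows),
        best_state=best_state,
        best_epoch=best_epoch,
        splits=(tr, va, te),
        config=cfg,
    )


def beta_sweep(
    data: TrainData,
    betas,
    base_cfg: TrainConfig,
    model_factory,
    kld_threshold: float = 0.6,
) -> pd.DataFrame:
    """Train one model per beta; report test-set rate/distortion and the
    active-dimension count.

    ``model_factory(beta_index)`` must return a freshly initialized model;
    the split is identical across betas (it depends only on the config
    seed), so rows are comparable.
    """
    betas = list(betas)
    if len(betas) < 2:
        raise ValueError("need at least 2 beta values")
    from .embedding import dimension_kld  # local import, avoids a cycle

    rows = []
    for i, beta in enumerate(betas):
        cfg = TrainConfig(
            batch_size=base_cfg.batch_size,
            learning_rate=base_cfg.learning_rate,
            epochs=base_cfg.epochs,
            adam_betas=base_cfg.adam_betas,
            beta=float(beta),
            split_fractions=base_cfg.split_fractions,
            seed=base_cfg.seed,
            recon_reduction=base_cfg.recon_reduction,
            patience=base_cfg.patience,
        )
        model = model_factory(i)
        result = train(model, data, cfg)
        te = result.splits[2]
        parts = elbo_beta(
            data.x[te], model, beta=float(beta),
            x_ref=data.ref(te), label=data.onehot(te),
            n_samples=1, seed=cfg.seed + 7, reduction=cfg.recon_reduction,
        )
        mean_kld, active = dimension_kld(
            model, data.x[te], x_ref=data.ref(te), label=data.onehot(te),
            threshold=kld_threshold,
        )
        rows.append(
            {
                "beta": float(beta),
                "rate": float(parts.kl.mean()),
                "distortion": float(-parts.recon.mean()),
                "test_elbo": float(parts.unweighted.mean()),
                "active_dims": int(len(active)),
                "best_epoch": result.best_epoch,
            }
        )
    return pd.DataFrame(rows)
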