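"""Model / Results interface around the SparNet network.

`SparNetClassifier` is constructed from window-level region tensors and
labels; `fit()` runs mini-batch RMSprop training with early stopping on a
held-out validation split and returns a `SparNetResults` carrying the
learned weights, the loss history and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ArchitectureSpec, RMSprop, SparNet, cross_entropy

__all__ = ["TrainConfig", "SparNetClassifier", "SparNetResults"]


@dataclass
class TrainConfig:
    """Training hyperparameters: mini-batches of 8, at most 50 epochs,
    RMSprop, early stop after 10 epochs without validation improvement."""

    batch_size: int = 8
    max_epochs: int = 50
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


class SparNetClassifier:
    """SparNet fitted to window-level features.

    Parameters
    ----------
    regions : list of ndarray
        Five tensors, each (n_windows, C_region, L), in canonical region
        order (C, F, O, P, T).
    labels : ndarray of int
        Window labels; 1 = depressed (positive class), 0 = control.
    groups : ndarray, optional
        Per-window subject identifiers, used to stratify the validation
        split so every subject contributes proportionally.
    arch : ArchitectureSpec, optional
        Network hyperparameters; inferred from the data shapes by default.
    """

    def __init__(self, regions, labels, groups=None, arch: ArchitectureSpec | None = None):
        self.regions = [np.asarray(r, dtype=float) for r in regions]
        self.labels = np.asarray(labels, dtype=int)
        n = len(self.labels)
        for r in self.regions:
            if r.shape[0] != n:
                raise ValueError("all region tensors must share the window axis")
        classes = np.unique(self.labels)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.groups = (
            np.asarray(groups) if groups is not None else np.zeros(n, dtype=int)
        )
        if arch is None:
            arch = ArchitectureSpec(
                region_channels=tuple(r.shape[1] for r in self.regions),
                feature_length=self.regions[0].shape[2],
            )
        self.arch = arch
        # per-(channel, feature) standardisation from the training windows;
        # raw FFT amplitudes are strictly positive and channel-dependent in
        # scale, which starves ReLU paths of sign diversity at init
        self._norm = []
        for r in self.regions:
            mu = r.mean(axis=0)
            sd = r.std(axis=0)
            self._norm.append((mu, np.where(sd > 1e-12, sd, 1.0)))

    def _standardize(self, regions):
        return [
            (np.asarray(r, dtype=float) - mu) / sd
            for r, (mu, sd) in zip(regions, self._norm)
        ]

    # -- data splitting -----------------------------------------------------

    def _validation_split(self, rng: np.random.Generator, fraction: float):
        """Hold out ~fraction of windows, stratified by (subject, class)."""
        n = len(self.labels)
        val_mask = np.zeros(n, dtype=bool)
        if fraction <= 0:
            return ~val_mask, val_mask
        for g in np.unique(self.groups):
            for c in np.unique(self.labels):
                idx = np.nonzero((self.groups == g) & (self.labels == c))[0]
                if idx.size == 0:
                    continue
                k = max(int(round(idx.size * fraction)), 1)
                val_mask[rng.choice(idx, size=k, replace=False)] = True
        if val_mask.all():
            raise ValueError("validation split consumed all training windows")
        return ~val_mask, val_mask

    def _take(self, mask):
        return [r[mask] for r in self._std_regions], self.labels[mask]

    # -- fitting ------------------------------------------------------------

    def fit(self, cfg: TrainConfig | None = None) -> "SparNetResults":
        cfg = cfg or TrainConfig()
        cfg.validate()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 901]))
        net = SparNet(self.arch, seed=cfg.seed)
        opt = RMSprop(lr=cfg.learning_rate)
        self._std_regions = self._standardize(self.regions)

        train_mask, val_mask = self._validation_split(rng, cfg.validation_fraction)
        Xtr, ytr = self._take(train_mask)
        Xva, yva = self._take(val_mask)
        ytr_oh = _one_hot(ytr, self.arch.n_classes)
        yva_oh = _one_hot(yva, self.arch.n_classes)
        monitor_val = len(yva) > 0

        history = {"train_loss": [], "val_loss": []}
        best_loss = np.inf
        best_params = net.get_params()
        since_best = 0
        n_tr = len(ytr)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            for start in range(0, n_tr, cfg.batch_size):
                take = order[start : start + cfg.batch_size]
                batch = [r[take] for r in Xtr]
                loss, grads = net.loss_and_grads(batch, ytr_oh[take])
                opt.step(net, grads)
                epoch_loss += loss * len(take)
            train_loss = epoch_loss / n_tr
            if monitor_val:
                val_loss = cross_entropy(net.forward(Xva), yva_oh, reduction="mean")
            else:
                val_loss = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_params = net.get_params()
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
        net.set_params(best_params)
        return SparNetResults(
            model=self, network=net, config=cfg, history=history,
            best_val_loss=float(best_loss), n_epochs_run=len(history["train_loss"]),
        )


@dataclass
class SparNetResults:
    """Fitted-model container: weights, training history, predictions, summary."""

    model: SparNetClassifier
    network: SparNet
    config: TrainConfig
    history: dict
    best_val_loss: float
    n_epochs_run: int
    extras: dict = field(default_factory=dict)

    def predict_proba(self, regions) -> np.ndarray:
        """Class probabilities for new window tensors; column 1 is P(depressed)."""
        return self.network.predict_proba(self.model._standardize(regions))

    def predict(self, regions, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(regions)[:, 1] >= threshold).astype(int)

    def score(self, regions, labels) -> float:
        """Plain window-level accuracy."""
        return float(np.mean(self.predict(regions) == np.asarray(labels, dtype=int)))

    @property
    def param_count(self) -> int:
        return self.network.count_params()

    def summary(self) -> str:
        total, per_layer = self.network.count_params(breakdown=True)
        arch = self.network.arch
        lines = [
            "SparNet classifier results",
            "=" * 42,
            f"regions (channels):      {arch.region_channels}",
            f"feature length:          {arch.feature_length}",
            f"SE attention:            {'on' if arch.use_senet else 'off'}",
            f"trainable parameters:    {total}",
            f"epochs run:              {self.n_epochs_run} (max {self.config.max_epochs})",
            f"best validation loss:    {self.best_val_loss:.4f}",
            f"final training loss:     {self.history['train_loss'][-1]:.4f}",
            "-" * 42,
            "parameters per layer:",
        ]
        lines += [f"  {name:<16} {n:>6}" for name, n in per_layer.items()]
        return "\n".join(lines)
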