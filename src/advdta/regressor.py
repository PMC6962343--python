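"""Supervised affinity regression on frozen adversarial features.

The leaked drug and protein feature vectors are concatenated (drug block
first) and treated as a one-channel 1-D signal. Three convolution layers —
16, 32 and 48 output channels, kernel size 4, stride 1, no padding, each
followed by a ReLU — feed a flatten and a single affine output unit with an
identity activation, yielding one continuous affinity per pair. Training
minimises the mean squared error with Adam (initial learning rate 1e-4); the
upstream feature extractors stay frozen throughout.

Inputs are z-scored with statistics of the training features and the output
bias starts at the training-target mean; both are standard conditioning
choices that leave the model class unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import Adam, Conv1D, Dense, Flatten, ReLU, Sequential


@dataclass(frozen=True)
class FeaturePair:
    """Concatenated per-modality feature vectors; drug block first."""

    drug_features: np.ndarray
    protein_features: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.drug_features, self.protein_features])


@dataclass(frozen=True)
class RegressorConfig:
    conv_channels: tuple[int, int, int] = (16, 32, 48)
    kernel_size: int = 4
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three convolution layers")


def combine_features(drug_f: np.ndarray, protein_f: np.ndarray) -> FeaturePair:
    """Concatenate the two leaked feature vectors, drug block first."""
    drug_f = np.asarray(drug_f, dtype=np.float64)
    protein_f = np.asarray(protein_f, dtype=np.float64)
    if drug_f.size == 0 or protein_f.size == 0:
        raise ValueError("feature vectors must be non-empty")
    return FeaturePair(drug_features=drug_f, protein_features=protein_f)


class AffinityRegressor:
    """conv(16,k4)-ReLU-conv(32,k4)-ReLU-conv(48,k4)-ReLU-flatten-affine(1)."""

    def __init__(self, input_dim: int, cfg: RegressorConfig = RegressorConfig()) -> None:
        min_len = 3 * (cfg.kernel_size - 1) + 1
        if input_dim < min_len:
            raise ValueError(f"combined feature length {input_dim} shorter than "
                             f"the receptive field {min_len}")
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3 = cfg.conv_channels
        k = cfg.kernel_size
        flat = c3 * (input_dim - 3 * (k - 1))
        self.net = Sequential(
            Conv1D(1, c1, k, rng), ReLU(),
            Conv1D(c1, c2, k, rng), ReLU(),
            Conv1D(c2, c3, k, rng), ReLU(),
            Flatten(),
            Dense(flat, 1, rng),
        )
        # feature standardisation, fitted on the training set
        self._mu = np.zeros(input_dim, dtype=nnet.DTYPE)
        self._sd = np.ones(input_dim, dtype=nnet.DTYPE)
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------
    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nnet.DTYPE)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected feature length {self.input_dim}, got {X.shape[1]}")
        return ((X - self._mu) / self._sd)[:, None, :]  # (n, 1, L)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predicted affinities, one scalar per row of X."""
        return self.net.forward(self._prep(X)).ravel().astype(np.float64)

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "AffinityRegressor":
        X = np.asarray(X, dtype=nnet.DTYPE)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature/target length mismatch")
        self._mu = X.mean(axis=0).astype(nnet.DTYPE)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0).astype(nnet.DTYPE)
        out_layer = self.net.layers[-1]
        out_layer.params["b"][...] = y.mean()
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.net.parameter_layers(), lr=cfg.lr)
        n = X.shape[0]
        bs = min(cfg.batch_size, n)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                self.net.zero_grad()
                pred = self.net.forward(self._prep(X[idx])).ravel()
                loss, dpred = nnet.mse_grad(pred, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError("training loss became non-finite (divergence)")
                self.net.backward(dpred.reshape(-1, 1).astype(nnet.DTYPE))
                opt.step()
                epoch_losses.append(loss)
            self.loss_history.append(float(np.mean(epoch_losses)))
        return self

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {"mu": self._mu, "sd": self._sd}
        for i, st in enumerate(self.net.state_dict()):
            for k, v in st.items():
                arrays[f"net_{i}_{k}"] = v
        meta = {"input_dim": self.input_dim,
                "conv_channels": list(self.cfg.conv_channels),
                "kernel_size": self.cfg.kernel_size,
                "lr": self.cfg.lr, "epochs": self.cfg.epochs,
                "batch_size": self.cfg.batch_size, "seed": self.cfg.seed,
                "loss_history": self.loss_history}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AffinityRegressor":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
            cfg = RegressorConfig(conv_channels=tuple(meta["conv_channels"]),
                                  kernel_size=meta["kernel_size"], lr=meta["lr"],
                                  epochs=meta["epochs"], batch_size=meta["batch_size"],
                                  seed=meta["seed"])
            model = cls(meta["input_dim"], cfg)
            model._mu = npz["mu"]
            model._sd = npz["sd"]
            state = []
            for i, layer in enumerate(model.net.layers):
                state.append({k: npz[f"net_{i}_{k}"] for k in layer.params})
            model.net.load_state_dict(state)
            model.loss_history = list(meta["loss_history"])
            return model


def regression_forward(model: AffinityRegressor, pair: FeaturePair) -> float:
    """Scalar prediction for one drug-protein feature pair."""
    return float(model.forward(pair.combined[None])[0])


def mse_loss(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Training objective: (1/n) sum (p_k - y_k)^2."""
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(truths, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.mean((p - y) ** 2))


def train_regressor(pairs: list[FeaturePair], affinities: np.ndarray,
                    cfg: RegressorConfig = RegressorConfig()) -> AffinityRegressor:
    """Fit a regressor on (FeaturePair, affinity) training examples."""
    if not pairs:
        raise ValueError("no training pairs")
    X = np.stack([p.combined for p in pairs])
    model = AffinityRegressor(X.shape[1], cfg)
    return model.fit(X, np.asarray(affinities, dtype=np.float64))


def predict_affinity(model: AffinityRegressor, pairs: list[FeaturePair],
                     truths: np.ndarray | None = None):
    """Batch predictions in input order; with truths, returns a
    :class:`~advdta.metrics.PredictionSet` ready for the metric battery."""
    X = np.stack([p.combined for p in pairs])
    preds = model.forward(X)
    if truths is None:
        return preds
    from .metrics import PredictionSet
    return PredictionSet(predictions=preds, truths=np.asarray(truths, dtype=np.float64))
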