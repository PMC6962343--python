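"""Per-modality adversarial feature learning.

One GAN is trained per input modality (protein sequences, SMILES strings) on
an unlabeled sequence pool. The generator is a four-layer fully connected
network mapping a noise vector to per-position softmax distributions over the
vocabulary; real sequences enter as one-hot matrices, so fake and real samples
share one continuous representation (a fully connected generator cannot emit
discrete strings). The discriminator is a three-layer fully connected network
decomposed as

    D(s) = sigmoid(phi_l . F(s; phi_f))

where ``F`` (the first two affine layers with leaky-ReLU activations) is the
feature extractor whose output — the last hidden layer of D — is leaked to
the downstream affinity regressor after adversarial training.

Training plays the standard minimax game: the discriminator maximises
``log D(x) + log(1 - D(G(z)))`` while the generator maximises ``log D(G(z))``
(the non-saturating form, which avoids the vanishing gradient of the
saturating loss). At the optimum for a fixed generator the discriminator
converges to the closed form ``D*(x) = P_data(x) / (P_data(x) + P_G(x))``,
which serves as the training oracle on toy discrete problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet
from .encoding import Vocabulary
from .nnet import Adam, Dense, LeakyReLU, PositionSoftmax, ReLU, Sequential


class GanDivergenceError(RuntimeError):
    """Raised when an adversarial loss becomes non-finite."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Four affine layers: noise -> h1 -> h2 -> h3 -> max_len * n_symbols,
    followed by a per-position softmax over the vocabulary."""

    noise_dim: int = 128
    hidden_dims: tuple[int, int, int] = (256, 256, 256)
    output_shape: tuple[int, int] = (100, 22)  # (max_len, n_symbols)

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != 3:
            raise ValueError("generator needs exactly 3 hidden widths (4 affine layers)")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Three affine layers: flat input -> hidden -> feature_dim -> 1."""

    input_shape: tuple[int, int] = (100, 22)
    hidden_dim: int = 512
    feature_dim: int = 256


class Generator:
    def __init__(self, cfg: GeneratorConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L, S = cfg.output_shape
        h1, h2, h3 = cfg.hidden_dims
        self.net = Sequential(
            Dense(cfg.noise_dim, h1, rng), ReLU(),
            Dense(h1, h2, rng), ReLU(),
            Dense(h2, h3, rng), ReLU(),
            Dense(h3, L * S, rng),
            PositionSoftmax(L, S),
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n fake samples, shape ``(n, max_len, n_symbols)``, each row a
        probability vector over the vocabulary."""
        z = rng.standard_normal((n, self.cfg.noise_dim)).astype(nnet.DTYPE)
        L, S = self.cfg.output_shape
        return self.net.forward(z).reshape(n, L, S)


class Discriminator:
    """D(s) = sigmoid(phi_l . F(s; phi_f)); the head carries no bias so the
    decomposition is an exact dot product with the leaked feature vector."""

    def __init__(self, cfg: DiscriminatorConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L, S = cfg.input_shape
        self.body = Sequential(          # F(.; phi_f): affine layers 1-2
            Dense(L * S, cfg.hidden_dim, rng), LeakyReLU(0.2),
            Dense(cfg.hidden_dim, cfg.feature_dim, rng), LeakyReLU(0.2),
        )
        self.head = Dense(cfg.feature_dim, 1, rng, bias=False)  # phi_l

    def _flat(self, samples: np.ndarray) -> np.ndarray:
        x = np.asarray(samples, dtype=nnet.DTYPE)
        L, S = self.cfg.input_shape
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != (L, S):
            raise ValueError(f"sample shape {x.shape[-2:]} does not match "
                             f"discriminator input {(L, S)}")
        return x.reshape(x.shape[0], L * S)

    def features(self, samples: np.ndarray) -> np.ndarray:
        return self.body.forward(self._flat(samples))

    def logits(self, samples: np.ndarray) -> np.ndarray:
        return self.head.forward(self.features(samples)).ravel()

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dlogits.reshape(-1, 1)))

    def zero_grad(self) -> None:
        self.body.zero_grad()
        self.head.zero_grad()

    def parameter_layers(self) -> list:
        return self.body.parameter_layers() + [self.head]

    def state_dict(self) -> dict:
        return {"body": self.body.state_dict(), "head": self.head.params["W"].copy()}


@dataclass
class AdversarialState:
    """Generator + discriminator with the running loss history."""

    generator: Generator
    discriminator: Discriminator
    step: int = 0
    history: list[tuple[int, float, float]] = field(default_factory=list)  # (step, d_loss, g_loss)


def generate_fake(gen: Generator, n: int, seed: int) -> np.ndarray:
    """n fake samples from a fresh seeded noise stream (reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return gen.sample(n, np.random.default_rng(seed))


def discriminate(disc: Discriminator, sample: np.ndarray) -> float | np.ndarray:
    """Probability the sample is real, strictly inside (0, 1)."""
    single = np.asarray(sample).ndim == 2
    p = nnet.sigmoid(disc.logits(sample))
    p = np.clip(p, np.finfo(np.float64).tiny, 1.0 - np.finfo(np.float64).epsneg)
    return float(p[0]) if single else p


def extract_features(disc: Discriminator, sample: np.ndarray) -> np.ndarray:
    """The leaked feature vector(s) f = F(s; phi_f)."""
    single = np.asarray(sample).ndim == 2
    f = disc.features(sample)
    return f[0] if single else f


def optimal_discriminator(p_data: np.ndarray, p_g: np.ndarray) -> np.ndarray:
    """Closed-form optimum D*(x) = P_data(x) / (P_data(x) + P_G(x)) over a
    shared finite support; outcomes with zero total mass yield NaN."""
    p_data = np.asarray(p_data, dtype=np.float64)
    p_g = np.asarray(p_g, dtype=np.float64)
    if p_data.shape != p_g.shape:
        raise ValueError("distributions must share one support")
    total = p_data + p_g
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, p_data / np.where(total > 0, total, 1.0), np.nan)


def _check_finite(value: float, what: str) -> None:
    if not np.isfinite(value):
        raise GanDivergenceError(f"{what} became non-finite (divergence)")


def adversarial_train(state: AdversarialState, real_onehots: np.ndarray,
                      epochs: int = 200, batch_size: int = 64,
                      lr: float = 1e-4, seed: int = 0) -> AdversarialState:
    """Alternate one discriminator-ascent and one generator-ascent step per
    minibatch of the real pool. Fully deterministic under a fixed seed."""
    real = np.asarray(real_onehots, dtype=nnet.DTYPE)
    n = real.shape[0]
    if n < batch_size:
        batch_size = n
    rng = np.random.default_rng(seed)
    gen, disc = state.generator, state.discriminator
    d_opt = Adam(disc.parameter_layers(), lr=lr)
    g_opt = Adam(gen.net.parameter_layers(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n - batch_size + 1, batch_size):
            batch = real[order[start:start + batch_size]]
            # --- discriminator step: maximise log D(x) + log(1 - D(G(z)))
            fake = gen.sample(batch_size, rng)
            disc.zero_grad()
            lz_real = disc.logits(batch)
            loss_r, dlz = nnet.bce_with_logits(lz_real, np.ones(batch_size))
            disc.backward(dlz)
            lz_fake = disc.logits(fake)  # fake detached: grads stop at D input
            loss_f, dlz = nnet.bce_with_logits(lz_fake, np.zeros(batch_size))
            disc.backward(dlz)
            d_loss = loss_r + loss_f
            _check_finite(d_loss, "discriminator loss")
            d_opt.step()
            # --- generator step: maximise log D(G(z)) (non-saturating)
            gen.net.zero_grad()
            disc.zero_grad()
            fake = gen.sample(batch_size, rng)
            lz = disc.logits(fake)
            g_loss, dlz = nnet.bce_with_logits(lz, np.ones(batch_size))
            _check_finite(g_loss, "generator loss")
            dflat = disc.backward(dlz)  # route grads through frozen-D to G
            L, S = gen.cfg.output_shape
            gen.net.backward(dflat.reshape(batch_size, L * S))
            g_opt.step()
            state.step += 1
            state.history.append((state.step, d_loss, g_loss))
    return state


def train_discriminator(disc: Discriminator, real_sampler, fake_sampler,
                        steps: int, batch_size: int = 128,
                        lr: float = 1e-4, seed: int = 0) -> list[float]:
    """Train only the discriminator against fixed samplers (callables
    ``(n, rng) -> (n, L, S)`` array). Used to compare a trained D with the
    closed-form optimum on toy problems with a frozen generator."""
    rng = np.random.default_rng(seed)
    opt = Adam(disc.parameter_layers(), lr=lr)
    losses = []
    for _ in range(steps):
        disc.zero_grad()
        lz = disc.logits(real_sampler(batch_size, rng))
        loss_r, dlz = nnet.bce_with_logits(lz, np.ones(batch_size))
        disc.backward(dlz)
        lz = disc.logits(fake_sampler(batch_size, rng))
        loss_f, dlz = nnet.bce_with_logits(lz, np.zeros(batch_size))
        disc.backward(dlz)
        _check_finite(loss_r + loss_f, "discriminator loss")
        opt.step()
        losses.append(loss_r + loss_f)
    return losses


# ---------------------------------------------------------------------------
# checkpointing

def save_extractor(path: str | Path, state: AdversarialState, vocab: Vocabulary,
                   max_len: int) -> None:
    """Persist the trained extractor (phi_f, phi_l), the generator weights,
    the vocabulary and the architecture config in one npz archive."""
    disc, gen = state.discriminator, state.generator
    arrays: dict[str, np.ndarray] = {"head_W": disc.head.params["W"]}
    for i, st in enumerate(disc.body.state_dict()):
        for k, v in st.items():
            arrays[f"body_{i}_{k}"] = v
    for i, st in enumerate(gen.net.state_dict()):
        for k, v in st.items():
            arrays[f"gen_{i}_{k}"] = v
    meta = {
        "modality": vocab.modality,
        "tokens": vocab.token_to_index,
        "max_len": max_len,
        "gen_cfg": {"noise_dim": gen.cfg.noise_dim,
                    "hidden_dims": list(gen.cfg.hidden_dims),
                    "output_shape": list(gen.cfg.output_shape)},
        "disc_cfg": {"input_shape": list(disc.cfg.input_shape),
                     "hidden_dim": disc.cfg.hidden_dim,
                     "feature_dim": disc.cfg.feature_dim},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_extractor(path: str | Path) -> tuple[AdversarialState, Vocabulary, int]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        gen = Generator(GeneratorConfig(
            noise_dim=meta["gen_cfg"]["noise_dim"],
            hidden_dims=tuple(meta["gen_cfg"]["hidden_dims"]),
            output_shape=tuple(meta["gen_cfg"]["output_shape"])))
        disc = Discriminator(DiscriminatorConfig(
            input_shape=tuple(meta["disc_cfg"]["input_shape"]),
            hidden_dim=meta["disc_cfg"]["hidden_dim"],
            feature_dim=meta["disc_cfg"]["feature_dim"]))
        disc.head.params["W"][...] = npz["head_W"]
        body_state = []
        for i, layer in enumerate(disc.body.layers):
            body_state.append({k: npz[f"body_{i}_{k}"] for k in layer.params})
        disc.body.load_state_dict(body_state)
        gen_state = []
        for i, layer in enumerate(gen.net.layers):
            gen_state.append({k: npz[f"gen_{i}_{k}"] for k in layer.params})
        gen.net.load_state_dict(gen_state)
        vocab = Vocabulary(modality=meta["modality"], token_to_index=meta["tokens"])
        return AdversarialState(generator=gen, discriminator=disc), vocab, int(meta["max_len"])


def extractor_weight_hash(disc: Discriminator) -> str:
    """Stable hash of the extractor parameters, to verify freezing."""
    import hashlib
    h = hashlib.sha256()
    for st in disc.body.state_dict():
        for k in sorted(st):
            h.update(st[k].tobytes())
    h.update(disc.head.params["W"].tobytes())
    return h.hexdigest()
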