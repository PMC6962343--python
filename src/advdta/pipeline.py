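"""Two-round training pipeline.

Round one trains one GAN per modality on an unlabeled sequence pool (the
labeled sequences are folded into the pool — the semi-supervised reuse that
motivates the whole design). Round two freezes the discriminator feature
extractors, projects every labeled drug-protein pair into the concatenated
feature space, and trains the convolutional affinity regressor on the
training fold of a pair-level 80/20 split. Evaluation scores the held-out
fold with the full metric battery (CI, MSE, rm2, AUPR).

A single global seed fans out deterministically to per-phase seeds
(seed, seed+1, ...), so an identical config + seed reproduces the entire run
report bit-for-bit apart from wall-clock fields.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datasets import (AffinityDataset, LabeledPair, SplitSpec, flatten_pairs,
                       load_affinity_dataset, train_test_split,
                       write_split_manifest)
from .encoding import Vocabulary, build_vocabulary, encode_sequence, one_hot_batch
from .gan import (AdversarialState, Discriminator, DiscriminatorConfig,
                  Generator, GeneratorConfig, adversarial_train,
                  extractor_weight_hash, load_extractor, save_extractor)
from .metrics import PredictionSet, metric_report
from .regressor import AffinityRegressor, RegressorConfig
from . import nnet


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs. Defaults are sized for desk-scale synthetic
    universes; the per-module classes keep their own larger defaults."""

    # encoding
    protein_max_len: int = 100
    smiles_max_len: int = 40
    # round one: adversarial pretraining (per modality)
    gan_noise_dim: int = 64
    gan_hidden_dims: tuple[int, int, int] = (128, 128, 128)
    disc_hidden_dim: int = 256
    feature_dim: int = 64
    gan_epochs: int = 40
    gan_batch_size: int = 64
    gan_lr: float = 1e-4
    # round two: frozen-feature regression
    reg_conv_channels: tuple[int, int, int] = (16, 32, 48)
    reg_kernel_size: int = 4
    reg_epochs: int = 30
    reg_batch_size: int = 128
    reg_lr: float = 1e-4
    # split & evaluation
    train_fraction: float = 0.8
    validation_fraction: float = 0.0
    binarization_threshold: float | None = 7.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gan_hidden_dims", "reg_conv_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a flat mapping")
        return cls.from_dict(data)


@dataclass
class ModalityExtractor:
    """A trained per-modality feature extractor plus its encoding contract."""

    state: AdversarialState
    vocab: Vocabulary
    max_len: int

    def encode(self, sequences: list[str]) -> np.ndarray:
        encs = [encode_sequence(s, self.vocab, self.max_len) for s in sequences]
        return one_hot_batch(encs, self.vocab)

    def features(self, sequences: list[str], batch: int = 256) -> np.ndarray:
        chunks = []
        for start in range(0, len(sequences), batch):
            x = self.encode(sequences[start:start + batch])
            chunks.append(self.state.discriminator.features(x))
        return np.concatenate(chunks).astype(np.float64)

    def weight_hash(self) -> str:
        return extractor_weight_hash(self.state.discriminator)


def _strip(seq_pool: list[str]) -> list[str]:
    return [s for s in seq_pool if s]


def pretrain_modality(sequences: list[str], modality: str, cfg: PipelineConfig,
                      seed: int) -> ModalityExtractor:
    """Round one for one modality: build the vocabulary from the pool, train
    the GAN, return the extractor with its loss history."""
    sequences = _strip(sequences)
    if not sequences:
        raise ValueError(f"no sequences available to pretrain the {modality} GAN")
    vocab = build_vocabulary(sequences, modality)
    max_len = cfg.protein_max_len if modality == "protein" else cfg.smiles_max_len
    shape = (max_len, vocab.n_symbols)
    gen = Generator(GeneratorConfig(noise_dim=cfg.gan_noise_dim,
                                    hidden_dims=cfg.gan_hidden_dims,
                                    output_shape=shape), seed=seed)
    disc = Discriminator(DiscriminatorConfig(input_shape=shape,
                                             hidden_dim=cfg.disc_hidden_dim,
                                             feature_dim=cfg.feature_dim), seed=seed + 1)
    state = AdversarialState(generator=gen, discriminator=disc)
    encs = [encode_sequence(s, vocab, max_len) for s in sequences]
    real = one_hot_batch(encs, vocab)
    adversarial_train(state, real, epochs=cfg.gan_epochs,
                      batch_size=cfg.gan_batch_size, lr=cfg.gan_lr, seed=seed + 2)
    return ModalityExtractor(state=state, vocab=vocab, max_len=max_len)


def run_pretrain(dataset: AffinityDataset, unlabeled_proteins: list[str],
                 unlabeled_drugs: list[str], cfg: PipelineConfig
                 ) -> dict[str, ModalityExtractor]:
    """Pretrain both modality GANs on labeled + unlabeled sequence pools.
    If an unlabeled pool is empty, that GAN still trains on the labeled
    sequences alone."""
    protein_pool = list(dataset.protein_seqs) + list(unlabeled_proteins or [])
    drug_pool = list(dataset.drug_smiles) + list(unlabeled_drugs or [])
    return {
        "protein": pretrain_modality(protein_pool, "protein", cfg, seed=cfg.seed + 1),
        "smiles": pretrain_modality(drug_pool, "smiles", cfg, seed=cfg.seed + 2),
    }


def pair_feature_matrix(dataset: AffinityDataset, pairs: list[LabeledPair],
                        extractors: dict[str, ModalityExtractor]) -> np.ndarray:
    """Concatenated (drug-first) leaked features for each labeled pair.
    Features are computed once per unique drug/protein and gathered."""
    drug_f = extractors["smiles"].features(dataset.drug_smiles)
    protein_f = extractors["protein"].features(dataset.protein_seqs)
    di = np.array([p.drug_index for p in pairs])
    pj = np.array([p.protein_index for p in pairs])
    return np.hstack([drug_f[di], protein_f[pj]])


def run_train(dataset: AffinityDataset, train_pairs: list[LabeledPair],
              extractors: dict[str, ModalityExtractor], cfg: PipelineConfig
              ) -> tuple[AffinityRegressor, dict[str, dict[str, str]]]:
    """Round two: train the regressor on frozen features. Returns the model
    and the pre/post extractor weight hashes (must match — frozen)."""
    hashes = {m: {"before": e.weight_hash()} for m, e in extractors.items()}
    X = pair_feature_matrix(dataset, train_pairs, extractors)
    y = np.array([p.affinity for p in train_pairs])
    reg_cfg = RegressorConfig(conv_channels=cfg.reg_conv_channels,
                              kernel_size=cfg.reg_kernel_size, lr=cfg.reg_lr,
                              epochs=cfg.reg_epochs, batch_size=cfg.reg_batch_size,
                              seed=cfg.seed + 3)
    model = AffinityRegressor(X.shape[1], reg_cfg).fit(X, y)
    for m, e in extractors.items():
        hashes[m]["after"] = e.weight_hash()
        if hashes[m]["after"] != hashes[m]["before"]:
            raise RuntimeError(f"{m} extractor weights changed during regression")
    return model, hashes


def run_evaluate(dataset: AffinityDataset, test_pairs: list[LabeledPair],
                 extractors: dict[str, ModalityExtractor],
                 model: AffinityRegressor, cfg: PipelineConfig) -> dict:
    """Score the held-out fold with the full metric battery."""
    if not test_pairs:
        raise ValueError("test split is empty")
    X = pair_feature_matrix(dataset, test_pairs, extractors)
    y = np.array([p.affinity for p in test_pairs])
    ps = PredictionSet(predictions=model.forward(X), truths=y)
    return metric_report(ps, threshold=cfg.binarization_threshold)


def run_pipeline(dataset: AffinityDataset, unlabeled_proteins: list[str],
                 unlabeled_drugs: list[str], cfg: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Full two-round run; returns (and optionally writes) the run report."""
    # JSON-canonical snapshot (tuples as lists) so a reloaded report compares equal
    report: dict = {"config": json.loads(json.dumps(asdict(cfg))), "phases": {}}
    t0 = time.perf_counter()
    extractors = run_pretrain(dataset, unlabeled_proteins, unlabeled_drugs, cfg)
    report["phases"]["pretrain"] = {
        "wall_clock_s": time.perf_counter() - t0,
        "final_losses": {m: {"d_loss": e.state.history[-1][1],
                             "g_loss": e.state.history[-1][2]}
                         for m, e in extractors.items()},
    }
    pairs = flatten_pairs(dataset)
    train_pairs, test_pairs = train_test_split(pairs, SplitSpec(cfg.train_fraction,
                                                                seed=cfg.seed))
    t1 = time.perf_counter()
    model, hashes = run_train(dataset, train_pairs, extractors, cfg)
    report["phases"]["train"] = {"wall_clock_s": time.perf_counter() - t1,
                                 "final_train_mse": model.loss_history[-1],
                                 "extractor_hashes": hashes}
    t2 = time.perf_counter()
    report["metrics"] = run_evaluate(dataset, test_pairs, extractors, model, cfg)
    report["phases"]["evaluate"] = {"wall_clock_s": time.perf_counter() - t2}
    report["n_train"] = len(train_pairs)
    report["n_test"] = len(test_pairs)
    if out_dir is not None:
        _write_artifacts(out_dir, dataset, cfg, extractors, model, report,
                         train_pairs, test_pairs)
    return report


def _write_artifacts(out_dir, dataset, cfg, extractors, model, report,
                     train_pairs, test_pairs) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for modality, ext in extractors.items():
        ckpt = out / f"extractor_{modality}.npz"
        save_extractor(ckpt, ext.state, ext.vocab, ext.max_len)
        losses = out / f"gan_losses_{modality}.csv"
        with open(losses, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "d_loss", "g_loss"])
            for step, d, g in ext.state.history:
                w.writerow([step, repr(d), repr(g)])
        artifacts[f"extractor_{modality}"] = str(ckpt)
        artifacts[f"gan_losses_{modality}"] = str(losses)
    reg_ckpt = out / "regressor.npz"
    model.save(reg_ckpt)
    artifacts["regressor"] = str(reg_ckpt)
    manifest = out / "split_manifest.tsv"
    write_split_manifest(dataset, train_pairs, test_pairs, manifest)
    artifacts["split_manifest"] = str(manifest)
    preds = out / "predictions.tsv"
    X = pair_feature_matrix(dataset, test_pairs, extractors)
    yhat = model.forward(X)
    with open(preds, "w") as fh:
        fh.write("drug_id\tprotein_id\ty_true\ty_pred\n")
        for p, v in zip(test_pairs, yhat):
            fh.write(f"{dataset.drug_ids[p.drug_index]}\t"
                     f"{dataset.protein_ids[p.protein_index]}\t"
                     f"{p.affinity!r}\t{v!r}\n")
    artifacts["predictions"] = str(preds)
    report["artifacts"] = artifacts
    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")


def report_comparable(report: dict) -> dict:
    """A copy of a run report with wall-clock fields removed, for
    determinism comparisons."""
    def scrub(obj):
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in obj.items()
                    if not k.startswith("wall_clock")}
        if isinstance(obj, list):
            return [scrub(v) for v in obj]
        return obj
    return scrub(report)
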