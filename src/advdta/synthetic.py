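"""Desk-scale synthetic drug/protein universes with a known latent affinity.

Sequences are random strings over the modality alphabets — proteins over the
20 canonical amino acids, "SMILES-like" drugs over a small chemistry-flavoured
character set (no chemical validity claimed; the downstream model treats
SMILES as raw text). A ground-truth model assigns every (drug, protein) pair
a latent affinity that is linear in motif/token counts:

    affinity(d, p) = intercept + sum_m w_m * count(motif m in p)
                               + sum_t w_t * count(token t in d)

plus Gaussian noise, clipped to a plausible affinity range. Protein motifs may
additionally be planted into the sequences so they occur more often than by
chance. Separate unlabeled pools are drawn from the same generative process,
mirroring the premise that freely available unlabeled sequences share the data
distribution of the labeled set. The noiseless latent value is exposed so
tests can score the Bayes-optimal predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datasets import AffinityDataset, load_affinity_dataset, write_dataset
from .encoding import PROTEIN_ALPHABET

SMILES_ALPHABET = "CON=()12"


@dataclass(frozen=True)
class GroundTruthModel:
    """Latent affinity: linear in substring counts, plus an intercept."""

    protein_motifs: dict[str, float]
    drug_tokens: dict[str, float]
    intercept: float = 7.0

    def __post_init__(self) -> None:
        if not any(w != 0 for w in {**self.protein_motifs, **self.drug_tokens}.values()):
            raise ValueError("ground truth needs at least one nonzero weight")


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 200
    n_proteins: int = 50
    protein_len_range: tuple[int, int] = (50, 80)
    smiles_len_range: tuple[int, int] = (15, 35)
    n_unlabeled_proteins: int = 300
    n_unlabeled_drugs: int = 300
    #: standard deviation of the measurement noise; None means 10% of the
    #: empirical standard deviation of the latent affinities
    noise_sd: float | None = None
    affinity_range: tuple[float, float] = (0.0, 16.0)
    motif_plant_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_proteins) < 1:
            raise ValueError("need at least one drug and one protein")
        for lo, hi in (self.protein_len_range, self.smiles_len_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must be non-empty")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: default planted signal: protein composition + one 3-mer motif, drug tokens
DEFAULT_GROUND_TRUTH = GroundTruthModel(
    protein_motifs={"K": 0.30, "E": -0.25, "W": 0.40, "CDE": 0.90},
    drug_tokens={"N": 0.35, "=": -0.30, "1": 0.25},
    intercept=7.0,
)


@dataclass
class SyntheticUniverse:
    dataset: AffinityDataset
    ground_truth: GroundTruthModel
    unlabeled_proteins: list[str]
    unlabeled_drugs: list[str]
    config: SyntheticConfig


def oracle_affinity(model: GroundTruthModel, smiles: str, protein: str) -> float:
    """Noiseless latent affinity of one pair (the Bayes-optimal prediction)."""
    value = model.intercept
    for motif, w in model.protein_motifs.items():
        value += w * protein.count(motif)
    for token, w in model.drug_tokens.items():
        value += w * smiles.count(token)
    return float(value)


def _random_sequence(rng: np.random.Generator, alphabet: str,
                     len_range: tuple[int, int]) -> str:
    length = int(rng.integers(len_range[0], len_range[1] + 1))
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _plant_motif(rng: np.random.Generator, seq: str, motifs: list[str],
                 prob: float) -> str:
    eligible = [m for m in motifs if len(m) > 1 and len(m) <= len(seq)]
    if eligible and rng.random() < prob:
        m = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(0, len(seq) - len(m) + 1))
        seq = seq[:pos] + m + seq[pos + len(m):]
    return seq


def simulate_universe(cfg: SyntheticConfig = SyntheticConfig(),
                      ground_truth: GroundTruthModel = DEFAULT_GROUND_TRUTH
                      ) -> SyntheticUniverse:
    """Draw a full labeled + unlabeled universe, reproducibly from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    motifs = list(ground_truth.protein_motifs)

    def protein(r):
        return _plant_motif(r, _random_sequence(r, PROTEIN_ALPHABET, cfg.protein_len_range),
                            motifs, cfg.motif_plant_prob)

    proteins = [protein(rng) for _ in range(cfg.n_proteins)]
    drugs = [_random_sequence(rng, SMILES_ALPHABET, cfg.smiles_len_range)
             for _ in range(cfg.n_drugs)]
    latent = np.array([[oracle_affinity(ground_truth, d, p) for p in proteins]
                       for d in drugs])
    noise_sd = cfg.noise_sd
    if noise_sd is None:
        noise_sd = 0.1 * float(latent.std())
    affinity = latent + rng.normal(0.0, noise_sd, latent.shape) if noise_sd > 0 else latent.copy()
    affinity = np.clip(affinity, *cfg.affinity_range)
    dataset = AffinityDataset(
        drug_ids=[f"D{i:04d}" for i in range(cfg.n_drugs)],
        drug_smiles=drugs,
        protein_ids=[f"P{j:04d}" for j in range(cfg.n_proteins)],
        protein_seqs=proteins,
        affinity=affinity,
        affinity_unit="arbitrary",
    )
    unlabeled_proteins = [protein(rng) for _ in range(cfg.n_unlabeled_proteins)]
    unlabeled_drugs = [_random_sequence(rng, SMILES_ALPHABET, cfg.smiles_len_range)
                       for _ in range(cfg.n_unlabeled_drugs)]
    return SyntheticUniverse(dataset=dataset, ground_truth=ground_truth,
                             unlabeled_proteins=unlabeled_proteins,
                             unlabeled_drugs=unlabeled_drugs, config=cfg)


def write_fixture(universe: SyntheticUniverse, out_dir: str | Path) -> dict[str, Path]:
    """Write the universe in the dataset I/O formats plus unlabeled pools and
    a manifest JSON recording the config and ground-truth weights."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_dataset(universe.dataset, out, prefix="labeled")
    unl_fasta = out / "unlabeled_proteins.fasta"
    with open(unl_fasta, "w") as fh:
        for j, seq in enumerate(universe.unlabeled_proteins):
            fh.write(f">U{j:05d}\n{seq}\n")
    unl_smiles = out / "unlabeled_drugs.tsv"
    with open(unl_smiles, "w") as fh:
        for i, smi in enumerate(universe.unlabeled_drugs):
            fh.write(f"UD{i:05d}\t{smi}\n")
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({
        "config": asdict(universe.config),
        "ground_truth": {"protein_motifs": universe.ground_truth.protein_motifs,
                         "drug_tokens": universe.ground_truth.drug_tokens,
                         "intercept": universe.ground_truth.intercept},
    }, indent=2) + "\n")
    paths.update({"unlabeled_proteins": unl_fasta, "unlabeled_drugs": unl_smiles,
                  "manifest": manifest})
    return paths


def load_fixture(out_dir: str | Path) -> SyntheticUniverse:
    """Inverse of :func:`write_fixture`."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfg_d = manifest["config"]
    for key in ("protein_len_range", "smiles_len_range", "affinity_range"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = SyntheticConfig(**cfg_d)
    gt = GroundTruthModel(protein_motifs=manifest["ground_truth"]["protein_motifs"],
                          drug_tokens=manifest["ground_truth"]["drug_tokens"],
                          intercept=manifest["ground_truth"]["intercept"])
    dataset = load_affinity_dataset(out / "labeled_proteins.fasta",
                                    out / "labeled_drugs.tsv",
                                    out / "labeled_affinity.tsv", unit="arbitrary")
    from Bio import SeqIO
    unl_proteins = [str(r.seq) for r in SeqIO.parse(str(out / "unlabeled_proteins.fasta"), "fasta")]
    unl_drugs = []
    with open(out / "unlabeled_drugs.tsv") as fh:
        for line in fh:
            if line.strip():
                unl_drugs.append(line.rstrip("\n").split("\t")[1])
    return SyntheticUniverse(dataset=dataset, ground_truth=gt,
                             unlabeled_proteins=unl_proteins,
                             unlabeled_drugs=unl_drugs, config=cfg)
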