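"""Benchmark-style dataset I/O: proteins (FASTA), drugs (TSV of SMILES), and a
drug x protein affinity matrix (TSV) with explicit missing-value handling.

The layout mirrors the public kinase binding benchmarks: a Davis-style dataset
is a dense matrix of dissociation constants Kd in nM (converted to pKd at load
time), while a KIBA-style dataset is the same matrix shape with missing cells
("NA"/"nan"/empty) where no integrated bioactivity score was measured. One
code path serves both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING_MARKERS = {"", "NA", "na", "nan", "NaN", "NAN"}

AffinityUnit = str  # one of {"Kd_nM", "pKd", "kiba_score", "arbitrary"}
_UNITS = ("Kd_nM", "pKd", "kiba_score", "arbitrary")


@dataclass
class AffinityDataset:
    """Paired drug/protein registries plus an affinity matrix.

    ``affinity[i, j]`` is the measured affinity of drug i against protein j;
    missing entries are NaN. After loading with ``unit="Kd_nM"`` the matrix
    holds pKd values and ``affinity_unit`` is ``"pKd"``.
    """

    drug_ids: list[str]
    drug_smiles: list[str]
    protein_ids: list[str]
    protein_seqs: list[str]
    affinity: np.ndarray
    affinity_unit: AffinityUnit = "arbitrary"

    def __post_init__(self) -> None:
        if self.affinity_unit not in _UNITS:
            raise ValueError(f"unknown affinity unit {self.affinity_unit!r}")
        self.affinity = np.asarray(self.affinity, dtype=np.float64)
        nd, np_ = self.affinity.shape
        if nd != len(self.drug_ids) or len(self.drug_ids) != len(self.drug_smiles):
            raise ValueError(
                f"drug axis mismatch: {len(self.drug_ids)} ids, "
                f"{len(self.drug_smiles)} SMILES, {nd} matrix rows")
        if np_ != len(self.protein_ids) or len(self.protein_ids) != len(self.protein_seqs):
            raise ValueError(
                f"protein axis mismatch: {len(self.protein_ids)} ids, "
                f"{len(self.protein_seqs)} sequences, {np_} matrix columns")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug ids not unique")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("protein ids not unique")
        observed = self.affinity[~np.isnan(self.affinity)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed affinities must be finite")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.affinity)))


@dataclass(frozen=True)
class LabeledPair:
    drug_index: int
    protein_index: int
    affinity: float


@dataclass(frozen=True)
class SplitSpec:
    """Pair-level train/test split: fraction of pairs in the training fold."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def kd_to_pkd(kd_nM: float) -> float:
    """Convert a dissociation constant in nM to pKd = -log10(Kd in M)."""
    if not kd_nM > 0:
        raise ValueError(f"Kd must be positive, got {kd_nM}")
    return -math.log10(kd_nM / 1e9)


def _read_smiles_tsv(path: str | Path) -> tuple[list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "smiles"],
                     dtype=str, comment="#")
    if df["smiles"].isna().any():
        raise ValueError(f"{path}: rows must have two tab-separated columns")
    return df["id"].tolist(), df["smiles"].tolist()


def _read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    protein_ids = [str(c) for c in df.columns]
    drug_ids = [str(i) for i in df.index]
    mat = np.full((len(drug_ids), len(protein_ids)), np.nan)
    for i in range(len(drug_ids)):
        for j in range(len(protein_ids)):
            cell = df.iat[i, j]
            text = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if text in MISSING_MARKERS:
                continue
            try:
                mat[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable numeric cell {text!r} at row "
                    f"{drug_ids[i]!r}, column {protein_ids[j]!r}") from None
    return drug_ids, protein_ids, mat


def load_affinity_dataset(proteins_path: str | Path, smiles_path: str | Path,
                          matrix_path: str | Path,
                          unit: AffinityUnit = "arbitrary") -> AffinityDataset:
    """Load an affinity dataset from its three on-disk files.

    Davis-style Kd values (``unit="Kd_nM"``) are transformed to pKd here, so
    downstream code always works on the log scale; KIBA scores and already
    transformed data pass through unchanged.
    """
    records = list(SeqIO.parse(str(proteins_path), "fasta"))
    protein_ids = [r.id for r in records]
    protein_seqs = [str(r.seq) for r in records]
    drug_ids, drug_smiles = _read_smiles_tsv(smiles_path)
    mat_drugs, mat_proteins, mat = _read_matrix_tsv(matrix_path)
    if mat_drugs != drug_ids:
        raise ValueError(
            f"drug axis mismatch: matrix rows {len(mat_drugs)} vs SMILES registry {len(drug_ids)}")
    if mat_proteins != protein_ids:
        raise ValueError(
            f"protein axis mismatch: matrix columns {len(mat_proteins)} vs FASTA registry {len(protein_ids)}")
    if unit == "Kd_nM":
        observed = ~np.isnan(mat)
        if np.any(mat[observed] <= 0):
            raise ValueError("Kd values must be positive for pKd transform")
        mat = np.where(observed, -np.log10(np.where(observed, mat, 1.0) / 1e9), np.nan)
        unit = "pKd"
    return AffinityDataset(drug_ids=drug_ids, drug_smiles=drug_smiles,
                           protein_ids=protein_ids, protein_seqs=protein_seqs,
                           affinity=mat, affinity_unit=unit)


def write_dataset(ds: AffinityDataset, out_dir: str | Path,
                  prefix: str = "dataset") -> dict[str, Path]:
    """Write the three dataset files; floats use repr precision so that
    ``load_affinity_dataset`` round-trips bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / f"{prefix}_proteins.fasta"
    smiles = out / f"{prefix}_drugs.tsv"
    matrix = out / f"{prefix}_affinity.tsv"
    SeqIO.write([SeqRecord(Seq(s), id=i, description="")
                 for i, s in zip(ds.protein_ids, ds.protein_seqs)], str(fasta), "fasta")
    with open(smiles, "w") as fh:
        for i, s in zip(ds.drug_ids, ds.drug_smiles):
            fh.write(f"{i}\t{s}\n")
    with open(matrix, "w") as fh:
        fh.write("drug_id\t" + "\t".join(ds.protein_ids) + "\n")
        for i, did in enumerate(ds.drug_ids):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in ds.affinity[i]]
            fh.write(did + "\t" + "\t".join(cells) + "\n")
    return {"proteins": fasta, "smiles": smiles, "matrix": matrix}


def flatten_pairs(ds: AffinityDataset) -> list[LabeledPair]:
    """One labeled pair per observed matrix cell, in row-major (drug-major)
    order; missing cells are skipped."""
    pairs: list[LabeledPair] = []
    for i in range(ds.n_drugs):
        row = ds.affinity[i]
        for j in range(ds.n_proteins):
            if not np.isnan(row[j]):
                pairs.append(LabeledPair(i, j, float(row[j])))
    return pairs


def train_test_split(pairs: list[LabeledPair],
                     spec: SplitSpec = SplitSpec()) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Seeded pair-level shuffle split; train size uses round-half-up so the
    same fraction gives the same sizes on every platform."""
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    n_train = int(math.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [pairs[k] for k in perm[:n_train]]
    test = [pairs[k] for k in perm[n_train:]]
    return train, test


def write_split_manifest(ds: AffinityDataset, train: list[LabeledPair],
                         test: list[LabeledPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\taffinity\tfold\n")
        for fold, pairs in (("train", train), ("test", test)):
            for p in pairs:
                fh.write(f"{ds.drug_ids[p.drug_index]}\t{ds.protein_ids[p.protein_index]}"
                         f"\t{p.affinity!r}\t{fold}\n")
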