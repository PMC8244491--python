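"""Small-molecule I/O, fingerprints, Tanimoto similarity and ligand-profile
comparison.

Fingerprints approximate the 881-bit PubChem/CACTVS scheme with RDKit
Morgan (radius 2) fingerprints folded to 881 bits; the scheme name and bit
length are recorded on every fingerprint so downstream reports can state
what was actually computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

FP_NBITS = 881
FP_SCHEME = f"rdkit-morgan-r2-{FP_NBITS}bit"


class LigandError(ValueError):
    pass


@dataclass
class Ligand:
    """A small molecule with optional 3D conformer."""

    id: str
    smiles: str
    mol: Chem.Mol = field(repr=False, default=None)
    source_id: str | None = None

    @classmethod
    def from_smiles(cls, id: str, smiles: str, source_id: str | None = None) -> "Ligand":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LigandError(f"{id}: unparseable SMILES {smiles!r}")
        return cls(id=id, smiles=Chem.MolToSmiles(mol), mol=mol, source_id=source_id)

    @classmethod
    def from_mol(cls, id: str, mol: Chem.Mol, source_id: str | None = None) -> "Ligand":
        return cls(
            id=id, smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)), mol=mol,
            source_id=source_id,
        )

    @property
    def has_conformer(self) -> bool:
        return self.mol is not None and self.mol.GetNumConformers() > 0

    def coordinates(self) -> np.ndarray:
        """Heavy-atom coordinates (N, 3) in Angstroms."""
        if not self.has_conformer:
            raise LigandError(f"{self.id}: no 3D conformer")
        conf = self.mol.GetConformer()
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return np.array([list(conf.GetAtomPosition(i)) for i in idx], dtype=float)


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    n_bits: int
    ligand_id: str
    scheme: str = FP_SCHEME

    def __len__(self) -> int:
        return self.n_bits


@dataclass
class ReadResult:
    ligands: list[Ligand]
    n_skipped: int = 0


def read_ligands(path: str | Path, format: str | None = None) -> ReadResult:
    """Read ligands from a SMILES (``id`` after whitespace) or SDF file.

    Invalid entries are skipped with a warning and counted; zero valid
    entries is an error. Order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    ligands: list[Ligand] = []
    n_skipped = 0
    if format == "smiles":
        with open(path) as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                lig_id = parts[1].strip() if len(parts) > 1 else f"lig{line_no}"
                try:
                    ligands.append(Ligand.from_smiles(lig_id, smiles))
                except LigandError:
                    logger.warning("%s:%d: skipping unparseable SMILES", path, line_no)
                    n_skipped += 1
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: skipping unparseable SDF record %d", path, i)
                n_skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"lig{i + 1}"
            ligands.append(Ligand.from_mol(name or f"lig{i + 1}", mol))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not ligands:
        raise LigandError(f"{path}: no valid ligand entries")
    return ReadResult(ligands=ligands, n_skipped=n_skipped)


_FP_GEN = GetMorganGenerator(radius=2, fpSize=FP_NBITS)


def fingerprint(ligand: Ligand) -> Fingerprint:
    """Deterministic folded fingerprint of the ligand's molecular graph."""
    mol = Chem.MolFromSmiles(ligand.smiles)
    if mol is None:
        raise LigandError(f"{ligand.id}: cannot sanitise {ligand.smiles!r}")
    bv = _FP_GEN.GetFingerprint(mol)
    return Fingerprint(
        bits=frozenset(bv.GetOnBits()), n_bits=FP_NBITS, ligand_id=ligand.id
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; 0.0 when both fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass
class ProfileComparison:
    matrix: pd.DataFrame  # rows: template ligands, columns: target ligands
    aggregate: pd.Series  # per template ligand
    aggregate_name: str


def similarity_matrix(
    rows: Sequence[Ligand], cols: Sequence[Ligand]
) -> pd.DataFrame:
    fps_r = [fingerprint(l) for l in rows]
    fps_c = [fingerprint(l) for l in cols]
    data = [[tanimoto(fr, fc) for fc in fps_c] for fr in fps_r]
    return pd.DataFrame(
        data, index=[l.id for l in rows], columns=[l.id for l in cols]
    )


def profile_compare(
    target_ligands: Sequence[Ligand],
    template_ligands: Sequence[Ligand],
    aggregate: str = "median",
) -> ProfileComparison:
    """Cross Tanimoto matrix (template rows x target columns) plus a
    per-template-ligand aggregate (median by default) used for ranking."""
    if not target_ligands or not template_ligands:
        raise LigandError("both ligand lists must be non-empty")
    matrix = similarity_matrix(template_ligands, target_ligands)
    if aggregate == "median":
        agg = matrix.median(axis=1)
    elif aggregate == "mean":
        agg = matrix.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    agg = agg.sort_values(ascending=False, kind="stable")
    return ProfileComparison(matrix=matrix, aggregate=agg, aggregate_name=aggregate)


def embed_3d(ligand: Ligand, seed: int = 0xF00D) -> Ligand:
    """Attach a 3D conformer (ETKDG distance geometry, deterministic seed)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(ligand.smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise LigandError(f"{ligand.id}: 3D embedding failed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return Ligand.from_mol(ligand.id, mol, source_id=ligand.source_id)
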