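"""Embedded reference tables and synthetic-data generators.

Every bundled table is checksummed against ``data/manifest.tsv`` at load
time. The generators are pure functions of their spec (including the
seed), so fixtures are reproducible byte-for-byte with no network access.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .hydro import HydroScale, load_eisenberg_scale
from .ligands import Ligand, LigandError
from .pocket import PocketDefinition, SubstitutionMatrix
from .sequences import ReceptorSequence, TMAnnotation

TABLE_FILES = {
    "eisenberg": "eisenberg.tsv",
    "orthosteric24": "orthosteric24.txt",
    "or_important11": "or_important11.txt",
    "known_or1a2_ligands": "known_or1a2_ligands.tsv",
}


class FixtureError(ValueError):
    pass


def _data_text(filename: str) -> str:
    return resources.files("gpcrscreen.data").joinpath(filename).read_text()


def _manifest() -> dict[str, str]:
    out = {}
    for line in _data_text("manifest.tsv").splitlines():
        if not line or line.startswith("#"):
            continue
        name, sha = line.split("\t")
        out[name] = sha
    return out


def _verify_checksum(name: str, filename: str) -> None:
    expected = _manifest().get(name)
    if expected is None:
        raise FixtureError(f"table {name!r} missing from manifest")
    actual = hashlib.sha256(_data_text(filename).encode()).hexdigest()
    if actual != expected:
        raise FixtureError(
            f"checksum mismatch for table {name!r}: {actual} != {expected}"
        )


def validation_data_dir() -> Path:
    return Path(str(resources.files("gpcrscreen.data").joinpath("validation")))


def load_table(name: str):
    """Load a validated bundled table by name.

    Known names: ``eisenberg`` (hydrophobicity scale), ``orthosteric24``
    and ``or_important11`` (BW position lists), ``known_or1a2_ligands``
    (13-entry ligand manifest), ``gpcrtm`` (substitution matrix; requires a
    user-supplied matrix file, see ``data/validation/README.txt``).
    """
    if name == "gpcrtm":
        path = validation_data_dir() / "gpcrtm.txt"
        if not path.exists():
            raise FileNotFoundError(
                "the GPCRtm matrix is not redistributed with this package; "
                f"place an NCBI-format copy at {path}"
            )
        return SubstitutionMatrix.from_file(path, name="GPCRtm")
    if name not in TABLE_FILES:
        raise FixtureError(f"unknown table {name!r}")
    _verify_checksum(name, TABLE_FILES[name])
    if name == "eisenberg":
        return load_eisenberg_scale()
    if name in ("orthosteric24", "or_important11"):
        labels = tuple(
            l.strip()
            for l in _data_text(TABLE_FILES[name]).splitlines()
            if l.strip() and not l.startswith("#")
        )
        expected = 24 if name == "orthosteric24" else 11
        if len(labels) != expected:
            raise FixtureError(f"{name}: expected {expected} entries, got {len(labels)}")
        return PocketDefinition(name=name, bw_positions=labels)
    # known_or1a2_ligands
    rows = []
    for line in _data_text(TABLE_FILES[name]).splitlines():
        if not line or line.startswith("#") or line.startswith("id\t"):
            continue
        lig_id, smiles = line.split("\t")
        rows.append((lig_id, smiles))
    if len(rows) != 13:
        raise FixtureError(f"known_or1a2_ligands: expected 13 entries, got {len(rows)}")
    return [Ligand.from_smiles(i, s) for i, s in rows]


# ---------------------------------------------------------------------------
# Synthetic receptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticReceptorSpec:
    n_helices: int = 7
    helix_length_range: tuple[int, int] = (20, 30)
    target_hydro: tuple[float, ...] | float = 0.8
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_length_range[0] < 11:
            raise FixtureError("helix lengths must be >= 11 (profile window)")


LOOP = "GNSTDSG"  # hydrophilic linker between helices


@dataclass
class SyntheticReceptor:
    sequence: ReceptorSequence
    tms: tuple[TMAnnotation, ...]
    anchors: dict[str, int]


def _build_helix(
    rng: np.random.Generator, length: int, target: float, scale: HydroScale
) -> str:
    values = scale.values
    lo, hi = min(values.values()), max(values.values())
    if not (lo <= target <= hi):
        raise FixtureError(f"infeasible hydrophobicity target {target}")
    letters = sorted(values)
    helix = list(rng.choice(letters, size=length))
    # greedy repair toward the target mean
    for _ in range(20 * length):
        mean = sum(values[r] for r in helix) / length
        if abs(mean - target) <= 0.05:
            break
        pos = int(rng.integers(length))
        need = target * length - sum(values[r] for i, r in enumerate(helix) if i != pos)
        best = min(letters, key=lambda r: abs(values[r] - need))
        helix[pos] = best
    else:
        raise FixtureError("could not reach hydrophobicity target")
    return "".join(helix)


def make_receptor(
    spec: SyntheticReceptorSpec, rec_id: str = "synthetic"
) -> SyntheticReceptor:
    """Deterministic synthetic 7-TM receptor with controlled per-helix mean
    hydrophobicity (realised within +/-0.1 of the target)."""
    rng = np.random.default_rng(spec.seed)
    scale = load_eisenberg_scale()
    targets = (
        spec.target_hydro
        if isinstance(spec.target_hydro, tuple)
        else (spec.target_hydro,) * spec.n_helices
    )
    if len(targets) != spec.n_helices:
        raise FixtureError("one hydrophobicity target per helix required")
    parts = [LOOP]
    tms: list[TMAnnotation] = []
    anchors: dict[str, int] = {}
    pos = len(LOOP)
    for h in range(spec.n_helices):
        length = int(rng.integers(*spec.helix_length_range, endpoint=True))
        helix = _build_helix(rng, length, targets[h], scale)
        start = pos + 1
        end = pos + length
        tms.append(TMAnnotation(f"TM{h + 1}", start, end))
        anchors[f"TM{h + 1}"] = (start + end) // 2
        parts.append(helix)
        parts.append(LOOP)
        pos = end + len(LOOP)
    seq = ReceptorSequence(
        id=rec_id, residues="".join(parts), source=f"synthetic seed={spec.seed}"
    )
    receptor = SyntheticReceptor(sequence=seq, tms=tuple(tms), anchors=anchors)
    if spec.mutation_rate > 0:
        receptor = mutate_receptor(receptor, spec.mutation_rate, spec.seed + 1)
    return receptor


def mutate_receptor(
    base: SyntheticReceptor, rate: float, seed: int
) -> SyntheticReceptor:
    """Point-mutate helix residues at the given per-residue rate."""
    rng = np.random.default_rng(seed)
    residues = list(base.sequence.residues)
    letters = sorted("ACDEFGHIKLMNPQRSTVWY")
    for tm in base.tms:
        for idx in range(tm.start - 1, tm.end):
            if rng.random() < rate:
                choices = [l for l in letters if l != residues[idx]]
                residues[idx] = str(rng.choice(choices))
    seq = ReceptorSequence(
        id=base.sequence.id + "_mut",
        residues="".join(residues),
        source=base.sequence.source + f" mutated rate={rate} seed={seed}",
    )
    return SyntheticReceptor(sequence=seq, tms=base.tms, anchors=dict(base.anchors))


# ---------------------------------------------------------------------------
# Synthetic ligand libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLigandSpec:
    scaffold: str = "CC(C)CCCCCC(=O)O"  # iso-branched fatty acid
    n_actives: int = 10
    n_decoys: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 2:
            raise FixtureError("need at least 2 actives (consensus requires >= 2)")


# prefixes appended before the scaffold SMILES; each yields a valid molecule
# sharing the full scaffold substructure
_DECORATIONS = (
    "", "C", "CC", "CCC", "OC", "OCC", "CC(C)", "C(C)C", "ClC", "BrC",
    "CCCC", "OC(C)", "ClCC", "CC(C)C", "OCCC", "C(C)(C)C",
)

_DECOY_SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1", "c1ccsc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "c1ccc(O)cc1", "c1ccc(N)cc1",
    "c1ccc(C(=O)O)cc1", "c1ccc(S(N)(=O)=O)cc1", "C1CC1", "c1cnc2[nH]ccc2c1",
    "OC1OC(CO)C(O)C(O)C1O", "NC(=O)c1ccccc1", "O=C1CCCCC1", "N1CCOCC1",
    "c1ccc(OC)cc1", "CC(=O)Nc1ccccc1", "O=S(=O)(O)c1ccccc1",
    "c1cc2cccnc2cn1", "OCC(O)CO", "N#Cc1ccccc1",
)


def _embed_with_retries(lig_id: str, smiles: str, seed: int, retries: int = 5) -> Ligand:
    last: Exception | None = None
    for attempt in range(retries):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise FixtureError(f"{lig_id}: generated invalid SMILES {smiles!r}")
        molh = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + 7919 * attempt
        if AllChem.EmbedMolecule(molh, params) == 0:
            AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
            return Ligand.from_mol(lig_id, molh)
        last = LigandError(f"{lig_id}: embedding failed (attempt {attempt + 1})")
    raise FixtureError(str(last))


def make_library(
    spec: SyntheticLigandSpec,
) -> tuple[list[Ligand], list[Ligand]]:
    """Actives sharing the spec scaffold plus unrelated decoys, all with 3D
    conformers; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_actives > len(_DECORATIONS):
        raise FixtureError(f"at most {len(_DECORATIONS)} actives supported")
    deco_order = rng.permutation(len(_DECORATIONS))
    actives = []
    for i in range(spec.n_actives):
        smiles = _DECORATIONS[deco_order[i]] + spec.scaffold
        actives.append(
            _embed_with_retries(
                f"active_{i + 1:02d}", smiles, seed=int(spec.seed * 100 + i)
            )
        )
    decoys = []
    for i in range(spec.n_decoys):
        scaffold = _DECOY_SCAFFOLDS[i % len(_DECOY_SCAFFOLDS)]
        deco = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        smiles = deco + scaffold if deco else scaffold
        if Chem.MolFromSmiles(smiles) is None:  # decoration chemically invalid here
            smiles = scaffold
        decoys.append(
            _embed_with_retries(
                f"decoy_{i + 1:02d}", smiles, seed=int(spec.seed * 100 + 1000 + i)
            )
        )
    return actives, decoys


def write_sdf(ligands: Sequence[Ligand], path: str | Path) -> None:
    """Write ligands (with conformers) to an SDF V2000 file."""
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(True)
    for lig in ligands:
        mol = Chem.Mol(lig.mol)
        mol.SetProp("_Name", lig.id)
        writer.write(mol)
    writer.close()
    Path(path).write_text(buf.getvalue())
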