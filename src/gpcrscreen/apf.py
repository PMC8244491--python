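"""Atomic-property-field (APF) pharmacophore engine.

Each heavy atom carries a seven-channel property vector (hydrogen-bond
donor, hydrogen-bond acceptor, sp2 hybridisation, lipophilicity, size,
electropositivity/negativity, charge). Aligned ligands are accumulated
into a seven-channel 3D Gaussian grid; a pose is scored by the
pseudo-energy

    E = - sum_j sum_i  phi_i^j * P_i(r_j)

(trilinear interpolation of the grid P at each atom position r_j), and the
APF score is S = -E, so better poses score higher. A consensus
pharmacophore keeps only channels exhibited by a given fraction (default
75%) of the contributing ligands. Superposition is rigid-body: random
restarts over SO(3) followed by pattern-search refinement of the six pose
parameters.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen
from scipy.spatial.transform import Rotation

from .ligands import Ligand, LigandError

logger = logging.getLogger(__name__)

CHANNELS = (
    "donor",
    "acceptor",
    "sp2",
    "lipophilicity",
    "size",
    "electronegativity",
    "charge",
)
N_CHANNELS = 7

# Pauling electronegativities; the channel stores the deviation from carbon.
_PAULING_EN = {
    1: 2.20, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16, 35: 2.96, 53: 2.66,
}

_PT = Chem.GetPeriodicTable()


class APFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Property assignment
# ---------------------------------------------------------------------------

def assign_properties(ligand: Ligand) -> tuple[np.ndarray, np.ndarray]:
    """Per-heavy-atom coordinates (N, 3) and 7-channel property vectors (N, 7).

    Donor: N/O/S bearing at least one hydrogen. Acceptor: neutral or anionic
    N/O. sp2: hybridisation flag. Lipophilicity: Crippen atomic logP
    contribution (hydrogens folded into their heavy atom). Size: van der
    Waals radius cubed, normalised to carbon. Electronegativity: Pauling
    value minus carbon's. Charge: Gasteiger partial charge including
    attached hydrogens.
    """
    if not ligand.has_conformer:
        raise APFError(f"{ligand.id}: conformer required for property assignment")
    mol = Chem.Mol(ligand.mol)
    try:
        Chem.SanitizeMol(mol)
        AllChem.ComputeGasteigerCharges(mol)
        crippen = Crippen.rdMolDescriptors._CalcCrippenContribs(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise APFError(f"{ligand.id}: sanitisation failed: {exc}") from exc

    conf = mol.GetConformer()
    r_c = _PT.GetRvdw(6)
    coords: list[list[float]] = []
    props: list[list[float]] = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z <= 1:
            continue
        idx = atom.GetIdx()
        h_idxs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        n_h = atom.GetTotalNumHs(includeNeighbors=True)

        donor = 1.0 if (z in (7, 8, 16) and n_h > 0) else 0.0
        acceptor = 1.0 if (z in (7, 8) and atom.GetFormalCharge() <= 0) else 0.0
        sp2 = 1.0 if atom.GetHybridization() == Chem.HybridizationType.SP2 else 0.0
        logp = crippen[idx][0] + sum(crippen[h][0] for h in h_idxs)
        size = (_PT.GetRvdw(z) / r_c) ** 3
        en = _PAULING_EN.get(z, 2.55) - 2.55
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        for h in h_idxs:
            q += float(mol.GetAtomWithIdx(h).GetDoubleProp("_GasteigerCharge"))
        if not math.isfinite(q):
            q = 0.0

        coords.append(list(conf.GetAtomPosition(idx)))
        props.append([donor, acceptor, sp2, logp, size, en, q])
    return np.asarray(coords, dtype=float), np.asarray(props, dtype=float)


# ---------------------------------------------------------------------------
# Property fields
# ---------------------------------------------------------------------------

@dataclass
class PropertyField:
    """Seven co-registered scalar grids on a regular axis-aligned lattice."""

    origin: np.ndarray  # (3,) corner of node (0,0,0), Angstroms
    spacing: float
    grids: np.ndarray  # (7, nx, ny, nz)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grids.shape[0] != N_CHANNELS:
            raise APFError("field must have exactly 7 channels")
        if not np.all(np.isfinite(self.grids)):
            raise APFError("non-finite field values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grids.shape[1:]

    def same_geometry(self, other: "PropertyField") -> bool:
        return (
            self.grids.shape == other.grids.shape
            and np.allclose(self.origin, other.origin)
            and math.isclose(self.spacing, other.spacing)
        )

    def sample(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear interpolation at ``coords`` (N, 3).

        Returns (values (N, 7), inside-mask (N,)); values are 0 for atoms
        outside the grid.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        rel = (coords - self.origin) / self.spacing
        upper = np.array(self.shape, dtype=float) - 1.0
        inside = np.all((rel >= 0.0) & (rel <= upper), axis=1)
        values = np.zeros((coords.shape[0], N_CHANNELS))
        if not np.any(inside):
            return values, inside
        r = rel[inside]
        i0 = np.minimum(np.floor(r).astype(int), np.array(self.shape) - 2)
        i0 = np.maximum(i0, 0)
        f = r - i0
        acc = np.zeros((r.shape[0], N_CHANNELS))
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1.0 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1.0 - f[:, 2]
                    w = wx * wy * wz
                    corner = self.grids[
                        :, i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                    ]  # (7, n)
                    acc += (corner * w).T
        values[inside] = acc
        return values, inside

    def mass_center(self) -> np.ndarray:
        """Centroid of the field's absolute density, for pose initialisation."""
        weight = np.abs(self.grids).sum(axis=0)
        total = weight.sum()
        if total <= 0:
            return self.origin + 0.5 * self.spacing * (np.array(self.shape) - 1)
        idx = np.indices(self.shape, dtype=float)
        com = np.array([(idx[d] * weight).sum() / total for d in range(3)])
        return self.origin + com * self.spacing


def grid_geometry(
    atom_sets: Sequence[np.ndarray], spacing: float, padding: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Common axis-aligned grid covering all atoms plus ``padding``."""
    allc = np.vstack(atom_sets)
    lo = allc.min(axis=0) - padding
    hi = allc.max(axis=0) + padding
    shape = tuple(int(math.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return lo, shape


def build_field(
    atom_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    kernel_sigma: float = 1.0,
    spacing: float = 0.5,
    padding: float = 3.0,
    geometry: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> PropertyField:
    """Accumulate Gaussian-smeared atomic properties onto a grid.

    ``atom_sets`` holds one (coords, props) pair per aligned ligand; the
    field is the per-ligand mean of the individual contributions, i.e.
    P_i(r) = (1/n) sum_atoms phi_i * exp(-|r - r_atom|^2 / (2 sigma^2)),
    with each atom's kernel truncated to a per-axis 3.5-sigma box window.
    """
    if not atom_sets:
        raise APFError("no ligands given")
    if kernel_sigma <= 0 or spacing <= 0:
        raise APFError("kernel_sigma and spacing must be positive")
    if geometry is None:
        origin, shape = grid_geometry([c for c, _ in atom_sets], spacing, padding)
    else:
        origin, shape = geometry
        origin = np.asarray(origin, dtype=float)
    grids = np.zeros((N_CHANNELS,) + tuple(shape))
    cutoff = 3.5 * kernel_sigma
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    for coords, props in atom_sets:
        for pos, phi in zip(coords, props):
            sl = []
            local_axes = []
            for d in range(3):
                lo = int(math.ceil((pos[d] - cutoff - origin[d]) / spacing))
                hi = int(math.floor((pos[d] + cutoff - origin[d]) / spacing))
                lo, hi = max(lo, 0), min(hi, shape[d] - 1)
                if lo > hi:
                    sl = None
                    break
                sl.append(slice(lo, hi + 1))
                local_axes.append(axes[d][lo : hi + 1] - pos[d])
            if sl is None:
                continue
            dx2 = local_axes[0][:, None, None] ** 2
            dy2 = local_axes[1][None, :, None] ** 2
            dz2 = local_axes[2][None, None, :] ** 2
            g = np.exp(-(dx2 + dy2 + dz2) / (2.0 * kernel_sigma**2))
            grids[(slice(None),) + tuple(sl)] += phi[:, None, None, None] * g
    grids /= len(atom_sets)
    return PropertyField(origin=origin, spacing=spacing, grids=grids, sigma=kernel_sigma)


def fields_for_ligands(
    ligands: Sequence[Ligand],
    kernel_sigma: float = 1.0,
    spacing: float = 0.5,
    padding: float = 3.0,
) -> list[PropertyField]:
    """One single-ligand field per ligand, all on a shared grid geometry."""
    atom_sets = [assign_properties(l) for l in ligands]
    geom = grid_geometry([c for c, _ in atom_sets], spacing, padding)
    return [
        build_field([s], kernel_sigma, spacing, padding, geometry=geom)
        for s in atom_sets
    ]


# ---------------------------------------------------------------------------
# Consensus pharmacophore
# ---------------------------------------------------------------------------

def channel_included(n_present: int, n_ligands: int, fraction: float) -> bool:
    """The inclusion rule: present in at least ceil(fraction * n) ligands."""
    return n_present >= math.ceil(fraction * n_ligands)


@dataclass
class Pharmacophore:
    field: PropertyField
    included: tuple[bool, ...]  # per channel
    n_ligands: int
    fraction: float

    @property
    def included_channels(self) -> tuple[str, ...]:
        return tuple(c for c, inc in zip(CHANNELS, self.included) if inc)


def consensus(
    fields: Sequence[PropertyField],
    fraction: float = 0.75,
    presence_cutoff_rel: float = 0.05,
) -> Pharmacophore:
    """Mean field over ligands, keeping only channels exhibited by at least
    ``fraction`` of them.

    A ligand "exhibits" a channel when the absolute maximum of its
    single-ligand field on that channel exceeds ``presence_cutoff_rel``
    times the channel's absolute maximum across all ligands.
    """
    if len(fields) < 2:
        raise APFError("consensus needs at least 2 ligand fields")
    first = fields[0]
    for f in fields[1:]:
        if not f.same_geometry(first):
            raise APFError("field geometry mismatch")
    n = len(fields)
    maxima = np.array(
        [[np.abs(f.grids[i]).max() for i in range(N_CHANNELS)] for f in fields]
    )  # (n_ligands, 7)
    global_max = maxima.max(axis=0)
    cutoff = presence_cutoff_rel * global_max
    present_counts = (maxima > np.maximum(cutoff, 1e-12)).sum(axis=0)
    included = tuple(
        channel_included(int(present_counts[i]), n, fraction)
        for i in range(N_CHANNELS)
    )
    mean_grids = np.mean([f.grids for f in fields], axis=0)
    for i, inc in enumerate(included):
        if not inc:
            mean_grids[i] = 0.0
    cons = PropertyField(
        origin=first.origin.copy(),
        spacing=first.spacing,
        grids=mean_grids,
        sigma=first.sigma,
    )
    return Pharmacophore(field=cons, included=included, n_ligands=n, fraction=fraction)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APFScore:
    energy: float
    score: float
    per_channel: tuple[float, ...]
    n_atoms_outside: int


def apf_energy(
    coords: np.ndarray,
    props: np.ndarray,
    field: PropertyField | Pharmacophore,
) -> APFScore:
    """Pseudo-energy E = -sum_j sum_i phi_i^j P_i(r_j) of a pose."""
    if isinstance(field, Pharmacophore):
        field = field.field
    coords = np.atleast_2d(coords)
    values, inside = field.sample(coords)
    if not np.any(inside):
        raise APFError("no atoms inside the grid")
    per_channel = -np.sum(values * props, axis=0)
    energy = float(per_channel.sum())
    return APFScore(
        energy=energy,
        score=-energy,
        per_channel=tuple(float(x) for x in per_channel),
        n_atoms_outside=int(np.sum(~inside)),
    )


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> rotation @ x + translation (Angstroms)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise APFError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _pose_coords(
    coords: np.ndarray, centroid: np.ndarray, params: np.ndarray
) -> np.ndarray:
    rot = Rotation.from_rotvec(params[3:6]).as_matrix()
    return (coords - centroid) @ rot.T + centroid + params[0:3]


def _pose_transform(centroid: np.ndarray, params: np.ndarray) -> RigidTransform:
    rot = Rotation.from_rotvec(params[3:6]).as_matrix()
    trans = centroid + params[0:3] - rot @ centroid
    return RigidTransform(rotation=rot, translation=trans)


def _refine(
    coords: np.ndarray,
    props: np.ndarray,
    centroid: np.ndarray,
    field: PropertyField,
    params: np.ndarray,
    step_t: float = 1.0,
    step_r: float = 0.35,
    min_step_t: float = 0.04,
    max_evals: int = 400,
) -> tuple[np.ndarray, float]:
    """Pattern search over the six pose parameters; returns (params, score)."""

    def score_of(p: np.ndarray) -> float:
        pose = _pose_coords(coords, centroid, p)
        values, inside = field.sample(pose)
        if not np.any(inside):
            return -np.inf
        return float(np.sum(values * props))

    best = params.copy()
    best_score = score_of(best)
    steps = np.array([step_t] * 3 + [step_r] * 3)
    n_evals = 1
    while steps[0] >= min_step_t and n_evals < max_evals:
        improved = False
        for k in range(6):
            for sign in (1.0, -1.0):
                trial = best.copy()
                trial[k] += sign * steps[k]
                s = score_of(trial)
                n_evals += 1
                if s > best_score:
                    best, best_score = trial, s
                    improved = True
                    break
        if not improved:
            steps *= 0.5
    return best, best_score


def superpose(
    ligand: Ligand | tuple[np.ndarray, np.ndarray],
    pharmacophore: Pharmacophore | PropertyField,
    n_restarts: int = 32,
    seed: int = 0,
) -> tuple[RigidTransform, APFScore]:
    """Best rigid pose of the ligand in the pharmacophore field.

    The input pose is always evaluated (and refined when restarts > 0), so
    ``n_restarts=0`` returns the input pose score unchanged. Restarts draw
    uniform random rotations about the ligand centroid and translate the
    centroid to the field's density centre with Gaussian jitter.
    """
    field = (
        pharmacophore.field
        if isinstance(pharmacophore, Pharmacophore)
        else pharmacophore
    )
    if isinstance(ligand, Ligand):
        coords, props = assign_properties(ligand)
    else:
        coords, props = ligand
    centroid = coords.mean(axis=0)
    if n_restarts == 0:
        return RigidTransform.identity(), apf_energy(coords, props, field)

    rng = np.random.default_rng(seed)
    target = field.mass_center()
    candidates: list[np.ndarray] = [np.zeros(6)]
    # a centroid-aligned, unrotated start
    base = np.zeros(6)
    base[0:3] = target - centroid
    candidates.append(base)
    for _ in range(n_restarts):
        rot = Rotation.random(random_state=rng).as_rotvec()
        jitter = rng.normal(scale=0.75, size=3)
        p = np.concatenate([target - centroid + jitter, rot])
        candidates.append(p)

    best_params: np.ndarray | None = None
    best_score = -np.inf
    for p in candidates:
        refined, s = _refine(coords, props, centroid, field, p)
        if s > best_score:
            best_params, best_score = refined, s
    assert best_params is not None
    transform = _pose_transform(centroid, best_params)
    final = apf_energy(transform.apply(coords), props, field)
    return transform, final


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _ligand_seed(seed: int, ligand_id: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(ligand_id.encode())) % 2**31


def screen(
    library: Sequence[Ligand],
    pharmacophore: Pharmacophore | PropertyField,
    threshold: float | None = None,
    seed: int = 0,
    n_restarts: int = 8,
) -> pd.DataFrame:
    """Score every library ligand against the pharmacophore.

    Returns a table (ligand_id, score, energy, n_atoms_outside_grid[, is_hit])
    sorted by descending score, ties broken by ligand id. Ligands without
    conformers are skipped with a warning. Per-ligand randomness depends only
    on ``seed`` and the ligand id, not on library order.
    """
    if not library:
        raise APFError("empty library")
    rows = []
    for lig in library:
        if not lig.has_conformer:
            logger.warning("%s: no conformer, skipped", lig.id)
            continue
        _, score = superpose(
            lig, pharmacophore, n_restarts=n_restarts,
            seed=_ligand_seed(seed, lig.id),
        )
        rows.append(
            {
                "ligand_id": lig.id,
                "score": score.score,
                "energy": score.energy,
                "n_atoms_outside_grid": score.n_atoms_outside,
            }
        )
    df = pd.DataFrame(
        rows, columns=["ligand_id", "score", "energy", "n_atoms_outside_grid"]
    )
    df = df.sort_values(
        ["score", "ligand_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if threshold is not None:
        df["is_hit"] = df["score"] >= threshold
    return df
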