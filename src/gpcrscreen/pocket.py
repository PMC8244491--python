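"""Orthosteric-pocket extraction and substitution-matrix pocket comparison.

Pockets are defined as ordered lists of Ballesteros-Weinstein positions;
two receptors are compared by summing substitution-matrix values over the
positions resolvable in both, and by the percentage of positions whose
residue pair satisfies a similarity predicate (positive matrix score by
default, exact identity as an alternative).

The GPCRtm matrix (Rios et al. 2015) is the intended matrix for
GPCR-vs-GPCR comparisons; it is not redistributed here and must be
supplied as an NCBI-format matrix file (see ``data/validation/README.txt``).
Any Biopython-bundled matrix (e.g. BLOSUM62) can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

from Bio.Align import substitution_matrices

from .sequences import BWMap, ReceptorSequence, parse_bw_label

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PocketDefinition:
    """Named, ordered set of BW positions."""

    name: str
    bw_positions: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for label in self.bw_positions:
            parse_bw_label(label)  # validates form
            if label in seen:
                raise ValueError(f"{self.name}: duplicate position {label}")
            seen.add(label)

    def __len__(self) -> int:
        return len(self.bw_positions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PocketDefinition":
        """Read a pocket definition TSV: first column name (row 1) or
        one BW label per line; lines starting with '#' ignored."""
        labels: list[str] = []
        name = Path(path).stem
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("name\t"):
                name = line.split("\t")[1]
                continue
            labels.append(line.split("\t")[0])
        return cls(name=name, bw_positions=tuple(labels))


class SubstitutionMatrix:
    """Symmetric 20x20 residue-pair score table."""

    def __init__(self, scores: Mapping[tuple[str, str], float], name: str):
        self.name = name
        self._scores = dict(scores)
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if (a, b) not in self._scores:
                    raise ValueError(f"{name}: missing pair ({a}, {b})")
                if self._scores[(a, b)] != self._scores[(b, a)]:
                    raise ValueError(f"{name}: asymmetric at ({a}, {b})")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self._scores[pair]

    @classmethod
    def from_biopython(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        arr = substitution_matrices.load(name)
        scores = {
            (a, b): float(arr[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        return cls(scores, name)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "SubstitutionMatrix":
        """Read an NCBI-format matrix file (rows/columns of residue letters)."""
        arr = substitution_matrices.read(str(path))
        scores = {
            (a, b): float(arr[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        return cls(scores, name or Path(path).stem)


@dataclass(frozen=True)
class PocketExtraction:
    """Residues recovered at each resolvable pocket position."""

    receptor_id: str
    residues: Mapping[str, str]  # BW label -> one-letter residue
    missing: tuple[str, ...]  # positions not resolvable in this receptor


def extract_pocket(
    seq: ReceptorSequence, bw: BWMap, pocket: PocketDefinition
) -> PocketExtraction:
    """Map each pocket position to its residue; unresolvable positions are
    reported under ``missing``, never silently dropped."""
    residues: dict[str, str] = {}
    missing: list[str] = []
    for label in pocket.bw_positions:
        idx = bw.index(label)
        if idx is None or not (1 <= idx <= len(seq)):
            missing.append(label)
        else:
            residues[label] = seq.residues[idx - 1]
    return PocketExtraction(
        receptor_id=seq.id, residues=residues, missing=tuple(missing)
    )


Predicate = Callable[[str, str, SubstitutionMatrix], bool]


def positive_score_predicate(a: str, b: str, matrix: SubstitutionMatrix) -> bool:
    return matrix[a, b] > 0


def identity_predicate(a: str, b: str, matrix: SubstitutionMatrix) -> bool:
    return a == b


PREDICATES: dict[str, Predicate] = {
    "positive": positive_score_predicate,
    "identity": identity_predicate,
}


@dataclass(frozen=True)
class PocketComparison:
    positions_used: tuple[str, ...]
    score: float
    missing: tuple[str, ...]
    similar_pct: float


def pocket_score(
    res_a: Mapping[str, str],
    res_b: Mapping[str, str],
    matrix: SubstitutionMatrix,
    predicate: str | Predicate = "positive",
) -> PocketComparison:
    """Sum matrix values over positions resolvable in both receptors."""
    pred = PREDICATES[predicate] if isinstance(predicate, str) else predicate
    shared = [p for p in res_a if p in res_b]
    if not shared:
        raise ValueError("no shared pocket positions")
    missing = tuple(sorted((set(res_a) | set(res_b)) - set(shared)))
    score = sum(matrix[res_a[p], res_b[p]] for p in shared)
    n_similar = sum(1 for p in shared if pred(res_a[p], res_b[p], matrix))
    return PocketComparison(
        positions_used=tuple(shared),
        score=score,
        missing=missing,
        similar_pct=100.0 * n_similar / len(shared),
    )


def hotspot_overlap(
    res_a: Mapping[str, str],
    res_b: Mapping[str, str],
    hotspots: PocketDefinition,
    matrix: SubstitutionMatrix,
    predicate: str | Predicate = "positive",
) -> int:
    """Percent (nearest integer) of hot-spot positions with similar residues."""
    pred = PREDICATES[predicate] if isinstance(predicate, str) else predicate
    usable = [p for p in hotspots.bw_positions if p in res_a and p in res_b]
    if not usable:
        raise ValueError("no hot-spot position resolvable in both receptors")
    n_similar = sum(1 for p in usable if pred(res_a[p], res_b[p], matrix))
    return round(100.0 * n_similar / len(usable))
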