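"""Receptor sequence handling: FASTA I/O, transmembrane-helix annotation,
Ballesteros-Weinstein (BW) generic numbering, global pairwise identity and
coverage, and centre-tethered helix alignment.

BW labels have the form ``"h.pp"``: helix ``h`` (1-7), position ``pp``,
anchored so that a user-designated reference residue of each helix is
``h.50`` and labels increase by one per residue along the helix.

Alignment convention (documented, since upstream methods rarely state one):
global Needleman-Wunsch with BLOSUM62, gap open 10 and gap extend 0.5 in
matrix units; identity is the percentage of identical pairs among aligned
columns *excluding* terminal-gap runs; coverage is the percentage of target
residues aligned opposite a non-gap template residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

HELIX_IDS = tuple(f"TM{i}" for i in range(1, 8))


class SequenceError(ValueError):
    """Raised for malformed sequence input or annotation."""


@dataclass(frozen=True)
class ReceptorSequence:
    """A receptor amino-acid sequence (one-letter, canonical alphabet)."""

    id: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in CANONICAL_AA:
                raise SequenceError(
                    f"{self.id}: non-canonical residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TMAnnotation:
    """One transmembrane helix span, 1-based inclusive coordinates."""

    helix_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.helix_id not in HELIX_IDS:
            raise SequenceError(f"bad helix id {self.helix_id!r} (expected TM1..TM7)")
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"{self.helix_id}: bad span [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def number(self) -> int:
        return int(self.helix_id[2])


def validate_annotations(seq: ReceptorSequence, tms: Sequence[TMAnnotation]) -> None:
    """Check helices fit the sequence, are ordered TM1->TM7 and disjoint."""
    ordered = sorted(tms, key=lambda t: t.number)
    prev_end = 0
    prev_num = 0
    for tm in ordered:
        if tm.number <= prev_num:
            raise SequenceError(f"duplicate helix {tm.helix_id}")
        if tm.start <= prev_end:
            raise SequenceError(f"{tm.helix_id} overlaps the preceding helix")
        if tm.end > len(seq):
            raise SequenceError(
                f"{tm.helix_id} end {tm.end} beyond sequence length {len(seq)}"
            )
        prev_end = tm.end
        prev_num = tm.number


_BW_RE = re.compile(r"^([1-7])\.(\d{1,3})$")


@dataclass
class BWMap:
    """Bidirectional residue-index <-> BW-label map over annotated helices.

    ``index_to_label`` maps 1-based residue index to a label like ``"3.50"``.
    """

    index_to_label: dict[int, str] = field(default_factory=dict)
    label_to_index: dict[str, int] = field(default_factory=dict)

    def label(self, index: int) -> str | None:
        return self.index_to_label.get(index)

    def index(self, label: str) -> int | None:
        return self.label_to_index.get(label)


def parse_bw_label(label: str) -> tuple[int, int]:
    m = _BW_RE.match(label)
    if not m:
        raise SequenceError(f"malformed BW label {label!r}")
    return int(m.group(1)), int(m.group(2))


def assign_bw_numbers(
    seq: ReceptorSequence,
    tms: Sequence[TMAnnotation],
    anchors: Mapping[str, int],
) -> BWMap:
    """Assign BW numbers given per-helix x.50 anchor residue indices.

    ``anchors`` maps helix id (``"TM3"``) to the 1-based sequence index of
    the residue that receives label ``h.50``.
    """
    validate_annotations(seq, tms)
    bw = BWMap()
    for tm in tms:
        try:
            anchor = anchors[tm.helix_id]
        except KeyError:
            raise SequenceError(f"missing anchor for {tm.helix_id}") from None
        if not (tm.start <= anchor <= tm.end):
            raise SequenceError(
                f"{tm.helix_id}: anchor {anchor} outside span "
                f"[{tm.start}, {tm.end}]"
            )
        for idx in range(tm.start, tm.end + 1):
            label = f"{tm.number}.{50 + idx - anchor}"
            bw.index_to_label[idx] = label
            bw.label_to_index[label] = idx
    return bw


# ---------------------------------------------------------------------------
# FASTA / annotation I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReceptorSequence]:
    """Read a FASTA file into validated :class:`ReceptorSequence` records.

    The first whitespace-delimited header token is the record id. An empty
    file yields an empty list. Non-canonical residues raise
    :class:`SequenceError` naming the character and position.
    """
    path = Path(path)
    records: list[ReceptorSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise SequenceError(f"{path}:{line_no}: record {header!r} has no residues")
        records.append(ReceptorSequence(id=header, residues=seq, source=str(path)))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise SequenceError(f"{path}:{line_no}: empty FASTA header")
            else:
                if header is None:
                    raise SequenceError(
                        f"{path}:{line_no}: sequence data before any header"
                    )
                chunks.append(line)
        flush(line_no if "line_no" in locals() else 0)
    return records


def read_tm_annotations(
    path: str | Path,
) -> tuple[list[TMAnnotation], dict[str, int]]:
    """Read a TM annotation TSV (columns: helix, start, end, anchor).

    Returns the helix spans and the per-helix BW anchor indices. Lines
    starting with ``#`` and a header row are ignored.
    """
    tms: list[TMAnnotation] = []
    anchors: dict[str, int] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() == "helix":
                continue
            if len(parts) != 4:
                raise SequenceError(f"{path}:{line_no}: expected 4 columns")
            helix, start, end, anchor = parts
            tms.append(TMAnnotation(helix, int(start), int(end)))
            anchors[helix] = int(anchor)
    tms.sort(key=lambda t: t.number)
    return tms, anchors


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    identity_pct: float
    coverage_pct: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _trim_terminal_gaps(a: str, b: str) -> tuple[int, int]:
    """Return [lo, hi) column range excluding terminal-gap runs of either row."""
    n = len(a)
    lo = 0
    while lo < n and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    # widen back: only *runs touching the ends* are terminal; the loops above
    # stop at the first column where both rows have residues, which is exactly
    # the convention we document.
    return lo, hi


def align_global(a: ReceptorSequence, b: ReceptorSequence) -> PairwiseAlignment:
    """Global alignment of ``a`` vs ``b`` under the documented convention."""
    aligner = _make_aligner()
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    lo, hi = _trim_terminal_gaps(ga, gb)
    cols = hi - lo
    if cols <= 0:
        raise SequenceError(f"degenerate alignment between {a.id} and {b.id}")
    matches = sum(1 for x, y in zip(ga[lo:hi], gb[lo:hi]) if x == y and x != "-")
    identity = round(100.0 * matches / cols, 1)
    covered = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    coverage = round(100.0 * covered / len(a), 1)
    return PairwiseAlignment(ga, gb, identity, coverage)


def global_identity(a: ReceptorSequence, b: ReceptorSequence) -> float:
    """Percent identity (1 d.p.) among aligned non-terminal-gap columns."""
    return align_global(a, b).identity_pct


def query_coverage(target: ReceptorSequence, template: ReceptorSequence) -> float:
    """Percent of target residues aligned opposite a template residue."""
    return align_global(target, template).coverage_pct


# ---------------------------------------------------------------------------
# Centre-tethered helix alignment
# ---------------------------------------------------------------------------

def center_index(length: int) -> int:
    """1-based centre index, floor((L+1)/2) convention."""
    return (length + 1) // 2


def center_tether_align(tm_a: str, tm_b: str) -> list[tuple[int, int]]:
    """Pair helix positions by tethering centre residues together.

    Returns 1-based (index_in_a, index_in_b) pairs; unmatched overhangs are
    dropped. Centres are at floor((L+1)/2). Output is strictly increasing in
    both coordinates, and swapping the inputs transposes the pairs.
    """
    if not tm_a or not tm_b:
        raise SequenceError("empty helix in centre-tether alignment")
    ca, cb = center_index(len(tm_a)), center_index(len(tm_b))
    left = min(ca, cb) - 1
    right = min(len(tm_a) - ca, len(tm_b) - cb)
    return [(ca + k, cb + k) for k in range(-left, right + 1)]


def helix_residues(seq: ReceptorSequence, tm: TMAnnotation) -> str:
    return seq.residues[tm.start - 1 : tm.end]


def tm_by_id(tms: Iterable[TMAnnotation], helix_id: str) -> TMAnnotation:
    for tm in tms:
        if tm.helix_id == helix_id:
            return tm
    raise SequenceError(f"missing annotation for {helix_id}")
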