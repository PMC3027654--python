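"""Alignments, simple indel coding, and the combined character matrix.

Per-marker reference alignments are *inputs* (curated by hand in
practice, or emitted as the true alignment by the simulator); this
module never computes multiple sequence alignment. It turns alignments
into the unit of parsimony analysis: nucleotide columns concatenated
across markers, followed by binary indel characters, with ``?`` filled in
for taxa that lack a marker.

Simple indel coding converts each distinct maximal gap run of length
>= ``min_len`` into one binary presence/absence character: a sequence is
scored 1 when its own gap run spans exactly the character's columns, and
missing when a longer run of that sequence strictly contains them
(the longer deletion makes the shorter event unobservable); any other
configuration scores 0. Terminal (leading/trailing) gap runs are treated
as absence of data, not as deletion events: partial sequences truncate,
they do not delete.

Coordinates are 0-based half-open throughout and refer to the input
alignment; a gap run shared by every sequence still codes one
(parsimony-uninformative) character, matching the coding scheme's
definition. Use :meth:`Alignment.drop_all_gap_columns` first if
artefactual all-gap columns should be cleaned away.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ValidationError
from .markers import GAP, IUPAC_CODES, MISSING, Marker

__all__ = [
    "Alignment",
    "IndelState",
    "IndelCharacter",
    "Partition",
    "CombinedMatrix",
    "read_alignment",
    "write_alignment",
    "simple_indel_code",
    "combine_partitions",
]

_ALLOWED = IUPAC_CODES | {GAP, MISSING}


@dataclass
class Alignment:
    """An aligned block of sequences for one marker (equal-length rows)."""

    ids: list[str]
    rows: list[str]
    marker: Marker

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate seq_ids in alignment: {dup}")
        if not self.rows:
            raise EmptyInputError("alignment has no rows")
        width = len(self.rows[0])
        self.rows = [r.upper().replace("U", "T") for r in self.rows]
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValidationError(
                    f"record {sid!r} has length {len(row)}, expected {width}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise ValidationError(f"record {sid!r}: non-IUPAC characters {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [
            j for j in range(self.width) if any(r[j] != GAP for r in self.rows)
        ]
        if len(keep) == self.width:
            return self
        rows = ["".join(r[j] for j in keep) for r in self.rows]
        return Alignment(ids=list(self.ids), rows=rows, marker=self.marker)


def read_alignment(path: str | Path, marker: Marker) -> Alignment:
    """Read an aligned FASTA file; rows must have equal lengths."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    ids = [rec.description.split("|")[0].strip() or rec.id for rec in records]
    rows = [str(rec.seq) for rec in records]
    width = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != width:
            raise ValidationError(
                f"{path}: record {sid!r} has length {len(row)}, expected {width}"
            )
    return Alignment(ids=ids, rows=rows, marker=marker)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Simple indel coding


class IndelState(enum.IntEnum):
    ABSENT = 0
    PRESENT = 1
    MISSING = 2


@dataclass(frozen=True)
class IndelCharacter:
    """A binary gap character spanning columns [start, end)."""

    start: int
    end: int
    states: Mapping[str, IndelState]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("indel character span must be non-empty")


def _gap_runs(row: str) -> list[tuple[int, int, bool]]:
    """Maximal gap runs of ``row`` as (start, end, is_terminal)."""
    runs = []
    width = len(row)
    j = 0
    while j < width:
        if row[j] == GAP:
            k = j
            while k < width and row[k] == GAP:
                k += 1
            runs.append((j, k, j == 0 or k == width))
            j = k
        else:
            j += 1
    return runs


def score_indel_span(row: str, start: int, end: int) -> IndelState:
    """Score one sequence for the gap character [start, end)."""
    for s, e, terminal in _gap_runs(row):
        if terminal:
            if s <= start and end <= e:
                return IndelState.MISSING
            continue
        if s == start and e == end:
            return IndelState.PRESENT
        if s <= start and end <= e and (s, e) != (start, end):
            return IndelState.MISSING
    return IndelState.ABSENT


def simple_indel_code(aln: Alignment, min_len: int = 3) -> list[IndelCharacter]:
    """Code internal gap runs of length >= ``min_len`` as binary characters.

    Returns one character per distinct (start, end) run observed in at
    least one sequence, in left-to-right order; coordinates refer to the
    input alignment. A run shared by every sequence still codes one
    (parsimony-uninformative) character. ``min_len`` defaults to 3 so
    that single-base slippage around homopolymer runs is not scored as
    an evolutionary event.
    """
    if min_len < 1:
        raise ValidationError(f"min_len must be >= 1, got {min_len}")
    spans: list[tuple[int, int]] = []
    seen = set()
    for row in aln.rows:
        for s, e, terminal in _gap_runs(row):
            if terminal or e - s < min_len:
                continue
            if (s, e) not in seen:
                seen.add((s, e))
                spans.append((s, e))
    spans.sort()
    out = []
    for s, e in spans:
        states = {
            sid: score_indel_span(row, s, e) for sid, row in zip(aln.ids, aln.rows)
        }
        out.append(IndelCharacter(start=s, end=e, states=states))
    return out


# ---------------------------------------------------------------------------
# Combined matrix


class CharacterKind(str, enum.Enum):
    NUCLEOTIDE = "nucleotide"
    INDEL = "indel-binary"


@dataclass(frozen=True)
class Partition:
    """A contiguous column range of the combined matrix."""

    marker: Marker
    kind: CharacterKind
    start: int
    end: int
    #: for indel partitions: the (start, end) span of each character in
    #: the coordinates of its marker's nucleotide partition
    indel_spans: tuple[tuple[int, int], ...] = ()

    @property
    def width(self) -> int:
        return self.end - self.start


_INDEL_CHAR = {IndelState.ABSENT: "0", IndelState.PRESENT: "1", IndelState.MISSING: "?"}


@dataclass
class CombinedMatrix:
    """Taxa x characters, nucleotide columns then indel columns per marker."""

    taxa: list[str]
    cells: np.ndarray  # (n_taxa, width) of single characters, dtype '<U1'
    partitions: list[Partition]

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.taxa), self.width):
            raise ValidationError(
                f"cells shape {self.cells.shape} does not match taxa/partitions"
            )

    @property
    def width(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row_string(self, taxon: str) -> str:
        return "".join(self.cells[self.taxa.index(taxon)])

    def nucleotide_columns(self) -> np.ndarray:
        mask = np.zeros(self.width, dtype=bool)
        for p in self.partitions:
            if p.kind is CharacterKind.NUCLEOTIDE:
                mask[p.start : p.end] = True
        return mask

    def partition_for(self, marker: Marker, kind: CharacterKind) -> Partition | None:
        for p in self.partitions:
            if p.marker is marker and p.kind is kind:
                return p
        return None

    def with_row(self, taxon: str, row: str) -> "CombinedMatrix":
        """Return a copy with one extra taxon row appended."""
        if taxon in self.taxa:
            raise ValidationError(f"taxon {taxon!r} already present")
        if len(row) != self.width:
            raise ValidationError(
                f"row length {len(row)} != matrix width {self.width}"
            )
        cells = np.vstack([self.cells, np.array(list(row), dtype="<U1")])
        return CombinedMatrix(
            taxa=self.taxa + [taxon], cells=cells, partitions=list(self.partitions)
        )

    # -- serialisation -------------------------------------------------
    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP: name, two spaces, row ('?' missing)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.width}\n")
            for taxon, row in zip(self.taxa, self.cells):
                fh.write(f"{taxon.replace(' ', '_')}  {''.join(row)}\n")

    def partition_map(self) -> list[dict]:
        return [
            {
                "marker": p.marker.value,
                "kind": p.kind.value,
                "start": p.start,
                "end": p.end,
                "indel_spans": [list(s) for s in p.indel_spans],
            }
            for p in self.partitions
        ]

    def write_partition_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.partition_map(), indent=2))


def combine_partitions(
    alignments: Sequence[Alignment],
    indel_sets: Sequence[Sequence[IndelCharacter]] | None = None,
    all_taxa: Iterable[str] | None = None,
) -> CombinedMatrix:
    """Concatenate marker partitions into one matrix.

    Partition order follows the declared alignment order: each marker's
    nucleotide block, then its indel block. Taxa absent from a marker are
    filled with ``?`` across both blocks of that marker. ``all_taxa``
    fixes the row order; by default it is the union of alignment taxa in
    first-seen order.
    """
    if indel_sets is None:
        indel_sets = [[] for _ in alignments]
    if len(indel_sets) != len(alignments):
        raise ValidationError("one indel set required per alignment")
    if all_taxa is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for sid in aln.ids:
                seen.setdefault(sid)
        taxa = list(seen)
    else:
        taxa = list(all_taxa)
        for aln in alignments:
            extra = set(aln.ids) - set(taxa)
            if extra:
                raise ValidationError(f"alignment taxa not in all_taxa: {sorted(extra)}")

    parts: list[Partition] = []
    blocks: list[np.ndarray] = []
    offset = 0
    for aln, indels in zip(alignments, indel_sets):
        idx = {sid: i for i, sid in enumerate(aln.ids)}
        nuc = np.full((len(taxa), aln.width), MISSING, dtype="<U1")
        for t, taxon in enumerate(taxa):
            if taxon in idx:
                nuc[t] = list(aln.rows[idx[taxon]])
        blocks.append(nuc)
        parts.append(
            Partition(aln.marker, CharacterKind.NUCLEOTIDE, offset, offset + aln.width)
        )
        offset += aln.width
        if indels:
            ind = np.full((len(taxa), len(indels)), MISSING, dtype="<U1")
            for j, ch in enumerate(indels):
                for t, taxon in enumerate(taxa):
                    if taxon in ch.states:
                        ind[t, j] = _INDEL_CHAR[ch.states[taxon]]
            blocks.append(ind)
            parts.append(
                Partition(
                    aln.marker,
                    CharacterKind.INDEL,
                    offset,
                    offset + len(indels),
                    indel_spans=tuple((c.start, c.end) for c in indels),
                )
            )
            offset += len(indels)
    cells = np.hstack(blocks) if blocks else np.empty((len(taxa), 0), dtype="<U1")
    return CombinedMatrix(taxa=taxa, cells=cells, partitions=parts)
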