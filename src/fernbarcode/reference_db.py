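"""Reference database of trusted barcode sequences.

A regional barcoding database holds, per marker, one or more reference
sequences for every taxon of the target species pool. Allopolyploids and
apomictic aggregates that share a chloroplast genome with their maternal
donor cannot be separated by any cpDNA marker; such species are collapsed
into a single *species complex* label ("<donor> s.l.") before any
discrimination or identification analysis.

FASTA header grammar for reference files::

    >seq_id|Taxon binomial[|accession[|origin]]

``origin`` is a one-letter code: ``O`` (sequenced by the database authors
in a previous study), ``G`` (public-archive accession), ``N`` (newly
sequenced). A sidecar TSV with the same columns is also accepted via
:func:`read_complexes_tsv` for complex definitions.
"""

from __future__ import annotations

import enum
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ParseError, ValidationError
from .markers import GAP, IUPAC_CODES, MISSING, Marker

__all__ = [
    "Origin",
    "MarkerSequence",
    "SpeciesComplex",
    "ReferenceDatabase",
    "MarkerComposition",
    "CompositionReport",
    "load_reference_fasta",
    "write_reference_fasta",
    "read_complexes_tsv",
    "write_complexes_tsv",
    "apply_complex_merges",
    "validate_database",
]

_ALLOWED = IUPAC_CODES | {GAP, MISSING}


class Origin(str, enum.Enum):
    """Provenance of a reference sequence."""

    OWN = "O"
    GENBANK = "G"
    NEW = "N"


@dataclass(frozen=True)
class MarkerSequence:
    """One reference (or query) sequence for one marker.

    ``residues`` is the IUPAC DNA string, upper-cased, with ``U`` mapped
    to ``T``; it may contain ``-`` (aligned form) and ``?`` (missing).
    """

    seq_id: str
    taxon: str
    marker: Marker
    residues: str
    origin: Origin = Origin.OWN
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValidationError("seq_id must be non-empty")
        if len(self.taxon.split()) < 2:
            raise ValidationError(
                f"taxon {self.taxon!r} of {self.seq_id!r} is not a binomial"
            )
        residues = self.residues.upper().replace("U", "T")
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise ValidationError(f"record {self.seq_id!r} has an empty sequence")
        for pos, ch in enumerate(residues):
            if ch not in _ALLOWED:
                raise ValidationError(
                    f"record {self.seq_id!r}: non-IUPAC character {ch!r} "
                    f"at position {pos}"
                )

    @property
    def genus(self) -> str:
        return self.taxon.split()[0]

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "").replace(MISSING, "")


@dataclass(frozen=True)
class SpeciesComplex:
    """A set of species sharing an identical chloroplast genome.

    The label names the complex after its diploid cpDNA donor when the
    donor is in the database ("<donor> s.l."); when the donor could not
    be included the label is chosen from a representative member.
    """

    label: str
    members: frozenset[str]
    donor: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValidationError(
                f"complex {self.label!r} needs >= 2 members, got {len(self.members)}"
            )
        if self.donor is not None and self.donor not in self.members:
            raise ValidationError(
                f"complex {self.label!r}: donor {self.donor!r} not among members"
            )
        genera = {m.split()[0] for m in self.members}
        if len(genera) != 1:
            raise ValidationError(
                f"complex {self.label!r} spans genera {sorted(genera)}"
            )

    @classmethod
    def from_donor(cls, donor: str, members: Iterable[str]) -> "SpeciesComplex":
        return cls(label=f"{donor} s.l.", members=frozenset(members) | {donor}, donor=donor)

    @property
    def genus(self) -> str:
        return next(iter(self.members)).split()[0]


@dataclass
class ReferenceDatabase:
    """Sequences plus complex-collapsed taxon labelling."""

    sequences: list[MarkerSequence]
    complexes: list[SpeciesComplex] = field(default_factory=list)

    def __post_init__(self) -> None:
        # one individual may contribute one sequence per marker under a
        # shared seq_id (markers join on it in the combined matrix)
        ids = Counter((s.seq_id, s.marker) for s in self.sequences)
        dups = sorted(f"{i}/{m.value}" for (i, m), n in ids.items() if n > 1)
        if dups:
            raise ValidationError(f"duplicate seq_id/marker pairs: {dups}")
        taxon_of: dict[str, str] = {}
        for s in self.sequences:
            if taxon_of.setdefault(s.seq_id, s.taxon) != s.taxon:
                raise ValidationError(
                    f"seq_id {s.seq_id!r} maps to several taxa "
                    f"({taxon_of[s.seq_id]!r}, {s.taxon!r})"
                )
        _check_disjoint(self.complexes)

    # -- labelling -----------------------------------------------------
    @property
    def taxon_label(self) -> dict[str, str]:
        """Map raw taxon -> effective label after complex collapsing."""
        out: dict[str, str] = {}
        member_of = {m: c.label for c in self.complexes for m in c.members}
        for s in self.sequences:
            out[s.taxon] = member_of.get(s.taxon, s.taxon)
        return out

    @property
    def effective_taxon(self) -> dict[str, str]:
        """Map seq_id -> effective taxon label."""
        tl = self.taxon_label
        return {s.seq_id: tl[s.taxon] for s in self.sequences}

    def by_marker(self, marker: Marker) -> list[MarkerSequence]:
        return [s for s in self.sequences if s.marker is marker]

    def effective_taxa(self, marker: Marker | None = None) -> set[str]:
        tl = self.taxon_label
        seqs = self.sequences if marker is None else self.by_marker(marker)
        return {tl[s.taxon] for s in seqs}

    def sequences_of_label(self, label: str, marker: Marker | None = None) -> list[MarkerSequence]:
        eff = self.effective_taxon
        seqs = self.sequences if marker is None else self.by_marker(marker)
        return [s for s in seqs if eff[s.seq_id] == label]

    def genus_of_label(self, label: str) -> str:
        return label.split()[0]


# ---------------------------------------------------------------------------
# FASTA I/O


def _parse_header(header: str, path: str) -> tuple[str, str, str | None, Origin]:
    parts = [p.strip() for p in header.split("|")]
    if len(parts) < 2 or not parts[0] or not parts[1]:
        raise ParseError(
            f"{path}: malformed header {header!r} "
            "(expected 'seq_id|taxon[|accession[|origin]]')"
        )
    seq_id, taxon = parts[0], parts[1]
    accession = parts[2] if len(parts) > 2 and parts[2] else None
    origin = Origin.OWN
    if len(parts) > 3 and parts[3]:
        try:
            origin = Origin(parts[3])
        except ValueError as exc:
            raise ParseError(
                f"{path}: record {seq_id!r}: unknown origin code {parts[3]!r}"
            ) from exc
    return seq_id, taxon, accession, origin


def load_reference_fasta(path: str | Path, marker: Marker) -> list[MarkerSequence]:
    """Load one marker's reference sequences from FASTA.

    Raises :class:`ParseError` for malformed headers,
    :class:`EmptyInputError` for an empty file and
    :class:`ValidationError` for non-IUPAC residues.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        seq_id, taxon, accession, origin = _parse_header(rec.description, str(path))
        out.append(
            MarkerSequence(
                seq_id=seq_id,
                taxon=taxon,
                marker=marker,
                residues=str(rec.seq),
                origin=origin,
                accession=accession,
            )
        )
    return out


def write_reference_fasta(seqs: Sequence[MarkerSequence], path: str | Path) -> None:
    """Write sequences using the documented header grammar (round-trips)."""
    records = []
    for s in seqs:
        header = f"{s.seq_id}|{s.taxon}"
        if s.accession or s.origin is not Origin.OWN:
            header += f"|{s.accession or ''}|{s.origin.value}"
        records.append(SeqRecord(Seq(s.residues), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Complex tables


def read_complexes_tsv(path: str | Path) -> list[SpeciesComplex]:
    """Read a complex table: TSV columns ``label<TAB>member<TAB>is_donor``."""
    groups: dict[str, list[tuple[str, bool]]] = defaultdict(list)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            label, member, donor_flag = (f.strip() for f in fields)
            if donor_flag not in {"0", "1"}:
                raise ParseError(f"{path}:{lineno}: donor flag must be 0 or 1")
            groups[label].append((member, donor_flag == "1"))
    out = []
    for label, rows in groups.items():
        donors = [m for m, is_d in rows if is_d]
        if len(donors) > 1:
            raise ParseError(f"complex {label!r} lists several donors: {donors}")
        out.append(
            SpeciesComplex(
                label=label,
                members=frozenset(m for m, _ in rows),
                donor=donors[0] if donors else None,
            )
        )
    return out


def write_complexes_tsv(complexes: Sequence[SpeciesComplex], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in complexes:
            for m in sorted(c.members):
                fh.write(f"{c.label}\t{m}\t{int(m == c.donor)}\n")


def _check_disjoint(complexes: Sequence[SpeciesComplex]) -> None:
    seen: dict[str, str] = {}
    for c in complexes:
        for m in c.members:
            if m in seen and seen[m] != c.label:
                raise ValidationError(
                    f"species {m!r} appears in complexes {seen[m]!r} and {c.label!r}"
                )
            seen[m] = c.label


def apply_complex_merges(
    db: ReferenceDatabase, table: Sequence[SpeciesComplex]
) -> ReferenceDatabase:
    """Return a database whose effective taxa collapse complex members.

    Idempotent: merging an already merged database with the same table
    changes nothing. Complexes must be pairwise disjoint and confined to
    a single genus each (enforced by :class:`SpeciesComplex`).
    """
    _check_disjoint(table)
    return ReferenceDatabase(sequences=list(db.sequences), complexes=list(table))


# ---------------------------------------------------------------------------
# Composition report


@dataclass
class MarkerComposition:
    marker: Marker
    n_sequences: int
    n_effective_taxa: int
    multi_sequence_taxa: dict[str, int]
    missing_taxa: list[str]


@dataclass
class CompositionReport:
    per_marker: dict[Marker, MarkerComposition]
    n_effective_taxa_total: int

    def to_dict(self) -> dict:
        return {
            "n_effective_taxa_total": self.n_effective_taxa_total,
            "markers": {
                mc.marker.value: {
                    "n_sequences": mc.n_sequences,
                    "n_effective_taxa": mc.n_effective_taxa,
                    "multi_sequence_taxa": dict(sorted(mc.multi_sequence_taxa.items())),
                    "missing_taxa": mc.missing_taxa,
                }
                for mc in self.per_marker.values()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate_database(db: ReferenceDatabase) -> CompositionReport:
    """Report, per marker, counts and per-taxon coverage (report-only)."""
    eff = db.effective_taxon
    all_labels = set(eff.values())
    per_marker: dict[Marker, MarkerComposition] = {}
    markers = sorted({s.marker for s in db.sequences}, key=lambda m: m.value)
    for marker in markers:
        seqs = db.by_marker(marker)
        counts = Counter(eff[s.seq_id] for s in seqs)
        per_marker[marker] = MarkerComposition(
            marker=marker,
            n_sequences=len(seqs),
            n_effective_taxa=len(counts),
            multi_sequence_taxa={t: n for t, n in counts.items() if n >= 2},
            missing_taxa=sorted(all_labels - set(counts)),
        )
    return CompositionReport(per_marker=per_marker, n_effective_taxa_total=len(all_labels))
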