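"""Query identification: similarity ranking, tree placement, PgiC rules.

Two complementary decision methods mirror standard barcoding practice:

*Similarity* — the query is globally aligned (terminal gaps free) to
every reference of a marker and hits are ranked by maximal percent
identity (MPI) over the aligned overlap. Genus assignment requires that
every hit above the MPI threshold (default 95%) involves a single genus
for each available marker; species assignment requires the top-MPI
stratum (all hits tied at the maximum) to map to exactly one effective
taxon with MPI above the threshold.

*Tree* — the query is inserted into the combined reference matrix (one
query at a time) and a bootstrap parsimony analysis is run; the query is
assigned to the finest group (species, then genus) with which it forms a
monophyletic clade at bootstrap support above 70%; support in (50, 70]
is reported as insufficient, with the candidate noted.

Either method can only reach the *complex* rank for plastid-identical
species groups; nuclear PgiC band lengths resolve those where the
members' fragment lengths differ (a double band marks the allotetraploid
hybrid derivative).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .alignment import CharacterKind, CombinedMatrix, score_indel_span, IndelState
from .errors import ValidationError
from .markers import GAP, MISSING, Marker, reverse_complement
from .parsimony import ParsimonyMatrix, SearchConfig, bootstrap_consensus
from .reference_db import ReferenceDatabase

__all__ = [
    "QuerySample",
    "SimilarityHit",
    "Rank",
    "Method",
    "IdResult",
    "IdentificationConfig",
    "rank_by_identity",
    "similarity_identify",
    "tree_identify",
    "resolve_complex",
    "identify_sample",
    "SampleIdentification",
]


class Rank(enum.IntEnum):
    """Assignment ranks, ordered coarse to fine."""

    NONE = 0
    GENUS = 1
    COMPLEX = 2
    SPECIES = 3


class Method(str, enum.Enum):
    SIMILARITY = "similarity"
    TREE = "tree"
    PGIC = "pgic"
    COMBINED = "combined"


@dataclass
class QuerySample:
    """An unknown specimen: per-marker unaligned residues, optional PgiC."""

    sample_id: str
    sequences: dict[Marker, str]
    pgic_fragment_lengths: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequences = {
            m: s.upper().replace("U", "T") for m, s in self.sequences.items() if s
        }
        if not self.sequences:
            raise ValidationError(f"query {self.sample_id!r} has no marker sequence")


@dataclass(frozen=True)
class SimilarityHit:
    seq_id: str
    taxon: str  # effective label
    genus: str
    mpi: float  # percent identity over the aligned overlap
    overlap: int  # compared sites


@dataclass
class IdResult:
    sample_id: str
    method: Method
    rank: Rank
    label: str | None
    evidence: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.label is None) != (self.rank is Rank.NONE):
            raise ValidationError("label must be set iff a rank was assigned")


@dataclass(frozen=True)
class IdentificationConfig:
    """Decision thresholds and alignment scoring for identification."""

    mpi_threshold: float = 95.0
    support_threshold: float = 70.0
    insufficient_support: float = 50.0  # (insufficient, threshold] reported
    identity_floor: float = 60.0  # below: query unalignable, no tree method
    mpi_tie_tolerance: float = 0.0  # MPI gap treated as a tie in the top stratum
    min_overlap: int = 100  # hits overlapping fewer sites are discarded
    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -4.0
    extend_gap_score: float = -1.0
    search: SearchConfig = field(
        default_factory=lambda: SearchConfig(n_bootstrap=20, n_addition_cycles=2)
    )


def _aligner(cfg: IdentificationConfig) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = cfg.match_score
    al.mismatch_score = cfg.mismatch_score
    al.open_gap_score = cfg.open_gap_score
    al.extend_gap_score = cfg.extend_gap_score
    al.end_insertion_score = 0.0  # terminal gaps are free on both sequences
    al.end_deletion_score = 0.0
    return al


def _overlap_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and length of the terminal-gap-free overlap."""
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    res_a = arr_a != b"-"
    res_b = arr_b != b"-"
    ia = np.flatnonzero(res_a)
    ib = np.flatnonzero(res_b)
    if ia.size == 0 or ib.size == 0:
        return 0.0, 0
    lo = max(ia[0], ib[0])
    hi = min(ia[-1], ib[-1]) + 1
    if hi <= lo:
        return 0.0, 0
    win_a, win_b = arr_a[lo:hi], arr_b[lo:hi]
    ident = int(((win_a == win_b) & (win_a != b"-")).sum())
    return 100.0 * ident / (hi - lo), hi - lo


def _align_pair(aligner: Align.PairwiseAligner, query: str, ref: str):
    aln = aligner.align(ref, query)[0]
    return str(aln[0]), str(aln[1])


def orient_query(
    query: str, refs: Sequence[str], cfg: IdentificationConfig
) -> tuple[str, bool]:
    """Return the query in the better-scoring strand orientation.

    Alignment *scores* (not percent identities) decide the strand: a
    wrong-strand query slides past the reference on free terminal gaps
    and can fake a perfect identity over a negligible overlap, but its
    score stays near zero.
    """
    al = _aligner(cfg)
    rc = reverse_complement(query)
    # a handful of probes spread over the references is ample: the
    # wrong strand scores near zero against everything
    probes = refs[:: max(1, len(refs) // 5)]
    fwd = max(al.score(r, query) for r in probes)
    rev = max(al.score(r, rc) for r in probes)
    return (rc, True) if rev > fwd else (query, False)


def rank_by_identity(
    q: QuerySample,
    db: ReferenceDatabase,
    marker: Marker,
    cfg: IdentificationConfig | None = None,
    oriented_seq: str | None = None,
) -> list[SimilarityHit]:
    """MPI-ranked hits of one query marker against all its references.

    Both query orientations are tried and the better one used (pass
    ``oriented_seq`` to reuse an already-determined orientation). Hits
    are sorted by MPI descending, ties by overlap descending then label.
    """
    cfg = cfg or IdentificationConfig()
    if marker not in q.sequences:
        raise ValidationError(f"query {q.sample_id!r} lacks marker {marker.value}")
    refs = db.by_marker(marker)
    if not refs:
        return []
    eff = db.effective_taxon
    if oriented_seq is None:
        seq, _ = orient_query(q.sequences[marker], [r.ungapped for r in refs], cfg)
    else:
        seq = oriented_seq
    al = _aligner(cfg)
    hits = []
    for r in refs:
        mpi, overlap = _overlap_identity(*_align_pair(al, seq, r.ungapped))
        if overlap < cfg.min_overlap:
            continue  # too little shared sequence for a meaningful identity
        label = eff[r.seq_id]
        hits.append(
            SimilarityHit(
                seq_id=r.seq_id,
                taxon=label,
                genus=label.split()[0],
                mpi=mpi,
                overlap=overlap,
            )
        )
    hits.sort(key=lambda h: (-h.mpi, -h.overlap, h.taxon, h.seq_id))
    return hits


def _is_complex_label(db: ReferenceDatabase, label: str) -> bool:
    return any(c.label == label for c in db.complexes)


def similarity_identify(
    sample_id: str,
    hits_by_marker: Mapping[Marker, Sequence[SimilarityHit]],
    db: ReferenceDatabase,
    cfg: IdentificationConfig | None = None,
) -> IdResult:
    """Apply the MPI decision rules to per-marker hit lists."""
    cfg = cfg or IdentificationConfig()
    usable = {m: list(h) for m, h in hits_by_marker.items() if h}
    if not usable:
        raise ValidationError("no non-empty hit list")
    notes: list[str] = []
    evidence = {m.value: {"max_mpi": h[0].mpi, "top_taxon": h[0].taxon} for m, h in usable.items()}

    # genus rule: per marker, every hit above threshold names one genus
    genera_per_marker: dict[Marker, set[str]] = {}
    for m, hits in usable.items():
        above = {h.genus for h in hits if h.mpi > cfg.mpi_threshold}
        if above:
            genera_per_marker[m] = above
    genus: str | None = None
    if genera_per_marker:
        union = set.union(*genera_per_marker.values())
        if any(len(g) > 1 for g in genera_per_marker.values()) or len(union) > 1:
            notes.append(f"conflicting genera above threshold: {sorted(union)}")
            return IdResult(sample_id, Method.SIMILARITY, Rank.NONE, None, evidence, notes)
        genus = next(iter(union))
    else:
        notes.append("no hit above the MPI threshold")
        return IdResult(sample_id, Method.SIMILARITY, Rank.NONE, None, evidence, notes)

    # species rule: top stratum of each marker maps to one taxon, MPI > threshold
    votes: set[str] = set()
    for m, hits in usable.items():
        top = hits[0].mpi
        if top <= cfg.mpi_threshold:
            continue
        stratum = {h.taxon for h in hits if h.mpi >= top - cfg.mpi_tie_tolerance}
        if len(stratum) == 1:
            votes.add(next(iter(stratum)))
        else:
            notes.append(
                f"{m.value}: top MPI stratum ambiguous ({sorted(stratum)})"
            )
    if len(votes) == 1:
        label = next(iter(votes))
        rank = Rank.COMPLEX if _is_complex_label(db, label) else Rank.SPECIES
        return IdResult(sample_id, Method.SIMILARITY, rank, label, evidence, notes)
    if len(votes) > 1:
        notes.append(f"markers disagree at species rank: {sorted(votes)}")
    return IdResult(sample_id, Method.SIMILARITY, Rank.GENUS, genus, evidence, notes)


# ---------------------------------------------------------------------------
# Tree method


def insert_query_row(
    q: QuerySample,
    base: CombinedMatrix,
    db: ReferenceDatabase,
    cfg: IdentificationConfig | None = None,
    hits_by_marker: Mapping[Marker, Sequence[SimilarityHit]] | None = None,
    oriented: Mapping[Marker, str] | None = None,
) -> tuple[str, dict[Marker, float]]:
    """Map the query onto the combined matrix columns.

    For each marker the query is pairwise-aligned to its top-MPI
    reference; residues are written into that reference's columns
    (query-specific insertions are discarded — they would require
    realigning the references), terminal truncation becomes ``?`` and
    internal deletions become ``-``. Indel characters are then scored
    from the reconstructed gapped row. Returns the row and the top MPI
    per marker used for anchoring.
    """
    cfg = cfg or IdentificationConfig()
    al = _aligner(cfg)
    row = np.full(base.width, MISSING, dtype="<U1")
    anchor_mpi: dict[Marker, float] = {}
    for marker in {p.marker for p in base.partitions}:
        nuc = base.partition_for(marker, CharacterKind.NUCLEOTIDE)
        if nuc is None or marker not in q.sequences:
            continue
        if hits_by_marker is not None and marker in hits_by_marker:
            hits = list(hits_by_marker[marker])
        else:
            hits = rank_by_identity(q, db, marker, cfg)
        if not hits:
            continue
        anchor_mpi[marker] = hits[0].mpi
        if hits[0].mpi < cfg.identity_floor:
            continue
        ref_seq = next(s for s in db.by_marker(marker) if s.seq_id == hits[0].seq_id)
        try:
            ref_row = base.row_string(ref_seq.seq_id)[nuc.start : nuc.end]
        except ValueError:
            continue
        if oriented is not None and marker in oriented:
            seq = oriented[marker]
        else:
            seq, _ = orient_query(
                q.sequences[marker], [r.ungapped for r in db.by_marker(marker)], cfg
            )
        a_ref, a_q = _align_pair(al, seq, ref_seq.ungapped)
        # ungapped reference position -> combined-matrix column
        pos_to_col = [
            nuc.start + j for j, ch in enumerate(ref_row) if ch not in (GAP, MISSING)
        ]
        marker_row = np.full(nuc.width, GAP, dtype="<U1")
        rpos = 0
        placed_cols: list[int] = []
        for ca, cq in zip(a_ref, a_q):
            if ca != "-":
                if cq != "-" and rpos < len(pos_to_col):
                    col = pos_to_col[rpos] - nuc.start
                    marker_row[col] = cq
                    placed_cols.append(col)
                rpos += 1
        if placed_cols:
            lo, hi = min(placed_cols), max(placed_cols)
            marker_row[:lo] = MISSING
            marker_row[hi + 1 :] = MISSING
        else:
            marker_row[:] = MISSING
        row[nuc.start : nuc.end] = marker_row
        ind = base.partition_for(marker, CharacterKind.INDEL)
        if ind is not None:
            gapped = "".join(marker_row).replace(MISSING, GAP)
            for j, (s, e) in enumerate(ind.indel_spans):
                state = score_indel_span(gapped, s, e)
                if placed_cols and (e <= min(placed_cols) or s > max(placed_cols)):
                    state = IndelState.MISSING  # span outside query coverage
                row[ind.start + j] = {
                    IndelState.ABSENT: "0",
                    IndelState.PRESENT: "1",
                    IndelState.MISSING: MISSING,
                }[state]
    return "".join(row), anchor_mpi


def tree_identify(
    q: QuerySample,
    base: CombinedMatrix,
    db: ReferenceDatabase,
    cfg: IdentificationConfig | None = None,
    hits_by_marker: Mapping[Marker, Sequence[SimilarityHit]] | None = None,
    oriented: Mapping[Marker, str] | None = None,
) -> IdResult:
    """Per-query bootstrap parsimony placement (one query at a time).

    Species (or complex) assignment: the query plus every sequence of
    exactly one effective taxon forms a clade at support above the
    threshold. Genus assignment: the query plus all sequences of one
    genus does. Support in (50, 70] yields a genus assignment with an
    "insufficient support" note naming the candidate.
    """
    cfg = cfg or IdentificationConfig()
    row, anchor_mpi = insert_query_row(q, base, db, cfg, hits_by_marker, oriented)
    evidence: dict = {"anchor_mpi": {m.value: v for m, v in anchor_mpi.items()}}
    if not anchor_mpi or max(anchor_mpi.values()) < cfg.identity_floor:
        return IdResult(
            q.sample_id,
            Method.TREE,
            Rank.NONE,
            None,
            evidence,
            [
                f"query could not be aligned to any reference "
                f"(best identity below {cfg.identity_floor}%)"
            ],
        )
    qid = f"QUERY::{q.sample_id}"
    matrix = base.with_row(qid, row)
    pm = ParsimonyMatrix.from_combined(matrix)
    st = bootstrap_consensus(pm, cfg.search)

    eff = db.effective_taxon
    in_matrix = set(base.taxa)
    label_seqs: dict[str, list[str]] = {}
    for sid, label in eff.items():
        if sid in in_matrix:
            label_seqs.setdefault(label, []).append(sid)
    genus_seqs: dict[str, list[str]] = {}
    for label, sids in label_seqs.items():
        genus_seqs.setdefault(label.split()[0], []).extend(sids)

    def best_group(groups: dict[str, list[str]]) -> tuple[str | None, float]:
        scored = [
            (st.frequency({qid, *sids}), name) for name, sids in groups.items()
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        return (scored[0][1], scored[0][0]) if scored else (None, 0.0)

    sp_label, sp_support = best_group(label_seqs)
    gen_label, gen_support = best_group(genus_seqs)
    evidence["species_support"] = {"label": sp_label, "support": sp_support}
    evidence["genus_support"] = {"label": gen_label, "support": gen_support}

    notes: list[str] = []
    if sp_label is not None and sp_support > cfg.support_threshold:
        rank = Rank.COMPLEX if _is_complex_label(db, sp_label) else Rank.SPECIES
        return IdResult(q.sample_id, Method.TREE, rank, sp_label, evidence, notes)
    if sp_label is not None and sp_support > cfg.insufficient_support:
        notes.append(
            f"insufficient support ({sp_support:.1f}) for candidate {sp_label!r}"
        )
    if gen_label is not None and gen_support > cfg.support_threshold:
        return IdResult(q.sample_id, Method.TREE, Rank.GENUS, gen_label, evidence, notes)
    if gen_label is not None and gen_support > cfg.insufficient_support:
        notes.append(
            f"insufficient support ({gen_support:.1f}) for genus {gen_label!r}"
        )
    notes.append("no group with sufficient bootstrap support")
    return IdResult(q.sample_id, Method.TREE, Rank.NONE, None, evidence, notes)


# ---------------------------------------------------------------------------
# PgiC band rules


def resolve_complex(
    sample_id: str,
    label: str,
    lengths: Sequence[int] | None,
    rules: Mapping[str, Mapping[str, frozenset[int] | set[int]]],
) -> IdResult:
    """Resolve a plastid-identical complex by PgiC fragment lengths.

    ``rules[label]`` maps each member species to its expected set of
    band lengths (two bands for a hybrid-derived allotetraploid). The
    observed set must match exactly one member's expectation; species
    with indistinguishable expectations stay unresolved.
    """
    if label not in rules:
        raise ValidationError(f"no PgiC band rules for complex {label!r}")
    band_table = {sp: frozenset(ls) for sp, ls in rules[label].items()}
    evidence = {"observed_lengths": sorted(lengths or [])}
    if not lengths:
        return IdResult(
            sample_id, Method.PGIC, Rank.COMPLEX, label, evidence,
            ["no PgiC fragment lengths observed; complex unresolved"],
        )
    observed = frozenset(lengths)
    matches = sorted(sp for sp, exp in band_table.items() if exp == observed)
    if len(matches) == 1:
        return IdResult(sample_id, Method.PGIC, Rank.SPECIES, matches[0], evidence, [])
    if len(matches) > 1:
        note = f"band pattern shared by {matches}; complex unresolved"
    else:
        note = f"band pattern {sorted(observed)} matches no member; complex unresolved"
    return IdResult(sample_id, Method.PGIC, Rank.COMPLEX, label, evidence, [note])


# ---------------------------------------------------------------------------
# Combined verdict


@dataclass
class SampleIdentification:
    """Per-method results and the combined verdict for one query."""

    sample_id: str
    similarity: IdResult
    tree: IdResult
    pgic: IdResult | None
    combined: IdResult


def _demote(db: ReferenceDatabase, result: IdResult, rank: Rank) -> str | None:
    if result.rank is Rank.NONE or result.label is None:
        return None
    if rank is Rank.GENUS:
        return result.label.split()[0]
    return result.label


def identify_sample(
    q: QuerySample,
    db: ReferenceDatabase,
    base: CombinedMatrix,
    cfg: IdentificationConfig | None = None,
    pgic_rules: Mapping[str, Mapping[str, set[int]]] | None = None,
) -> SampleIdentification:
    """Run both methods (plus PgiC when applicable) and combine.

    The combined verdict is the finest rank on which the non-abstaining
    methods agree; a species-rank disagreement demotes to the agreeing
    rank with a conflict note. A complex verdict is afterwards refined
    by the PgiC band rules when fragment lengths are available.
    """
    cfg = cfg or IdentificationConfig()
    oriented: dict[Marker, str] = {}
    hits: dict[Marker, list[SimilarityHit]] = {}
    for m in q.sequences:
        if m is Marker.PGIC:
            continue
        refs = db.by_marker(m)
        if refs:
            oriented[m], _ = orient_query(
                q.sequences[m], [r.ungapped for r in refs], cfg
            )
        hits[m] = rank_by_identity(q, db, m, cfg, oriented_seq=oriented.get(m))
    sim = similarity_identify(q.sample_id, hits, db, cfg)
    tre = tree_identify(q, base, db, cfg, hits_by_marker=hits, oriented=oriented)

    voters = [r for r in (sim, tre) if r.rank is not Rank.NONE]
    notes: list[str] = []
    if not voters:
        combined = IdResult(q.sample_id, Method.COMBINED, Rank.NONE, None, {}, ["all methods abstained"])
    else:
        rank = min(r.rank for r in voters)
        if rank >= Rank.COMPLEX:
            labels = {r.label for r in voters}
            if len(labels) > 1:
                notes.append(f"species-rank conflict: {sorted(labels)}")
                rank = Rank.GENUS
        if rank is Rank.GENUS:
            genera = {r.label.split()[0] for r in voters}
            if len(genera) == 1:
                combined = IdResult(
                    q.sample_id, Method.COMBINED, Rank.GENUS, genera.pop(), {}, notes
                )
            else:
                notes.append(f"genus conflict: {sorted(genera)}")
                combined = IdResult(q.sample_id, Method.COMBINED, Rank.NONE, None, {}, notes)
        else:
            label = next(iter({r.label for r in voters}))
            combined = IdResult(q.sample_id, Method.COMBINED, rank, label, {}, notes)

    pg: IdResult | None = None
    if (
        combined.rank is Rank.COMPLEX
        and pgic_rules is not None
        and combined.label in pgic_rules
    ):
        complex_label = combined.label
        pg = resolve_complex(q.sample_id, complex_label, q.pgic_fragment_lengths, pgic_rules)
        if pg.rank is Rank.SPECIES:
            combined = IdResult(
                q.sample_id,
                Method.COMBINED,
                Rank.SPECIES,
                pg.label,
                dict(combined.evidence),
                combined.notes + [f"complex {complex_label!r} resolved by PgiC"],
            )
    return SampleIdentification(
        sample_id=q.sample_id, similarity=sim, tree=tre, pgic=pg, combined=combined
    )
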