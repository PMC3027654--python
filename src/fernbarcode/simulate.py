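"""Synthetic reference databases and query sets.

The generator reproduces the statistical structure the analysis relies
on, so every stage of the pipeline can be exercised without sequence
downloads:

* a genus/species hierarchy in which interspecific divergence clearly
  exceeds intraspecific divergence (nearest-neighbour distance around
  0.03 substitutions/site on the combined data, with one shallow genus
  around 0.007 mimicking the hardest congeners);
* a conservative coding marker (rbcL-like, ~1300 bp) and a faster
  noncoding marker (trnL-F-like, ~900 bp) that also accumulates
  deletions and carries a homopolymer C-run of jittering length;
* species complexes whose members carry byte-identical plastid
  sequences (allopolyploids copying their cpDNA donor), resolvable only
  by nuclear PgiC band lengths;
* deeply divergent taxa represented by the coding marker only (their
  noncoding sequences cannot be aligned with the rest); and
* queries with partial contiguous coverage (~85%), occasional missing
  markers and occasional reverse-complemented submissions.

Sequences evolve site-independently under a Jukes–Cantor process
(per-branch Poisson substitution counts, uniform base exchange) —
uncorrected distances and equal-weights parsimony require nothing
richer. Deletions are placed only between a protected 50 bp margin and
never overlap, so the true alignment is emitted directly and multiple
sequence alignment is never needed. Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
import numpy as np

from .alignment import Alignment
from .errors import ValidationError
from .identify import QuerySample
from .markers import GAP, Marker, reverse_complement
from .reference_db import (
    MarkerSequence,
    Origin,
    ReferenceDatabase,
    SpeciesComplex,
    write_complexes_tsv,
    write_reference_fasta,
)

__all__ = [
    "SimParams",
    "nw_europe_ferns",
    "TruthRow",
    "TruthTable",
    "SimulatedReference",
    "simulate_reference",
    "simulate_queries",
    "study_scale_composition",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Simulation settings; defaults follow :func:`nw_europe_ferns`.

    Divergences are expected substitutions/site on the length-weighted
    combined data; the per-marker rates are scaled so the combined
    expectation matches while trnL-F evolves ``marker_rate_ratio`` times
    faster than rbcL.
    """

    n_genera: int = 5
    species_per_genus: int = 3
    seqs_per_species: int = 2
    intra_divergence: float = 0.002
    inter_divergence: float = 0.035
    shallow_inter_divergence: float = 0.007
    genus_divergence: float = 0.09
    marker_rate_ratio: float = 2.0
    rbcl_length: int = 1300
    trnlf_length: int = 900
    indel_rate: float = 0.02  # deletion events per substitution event (trnL-F)
    indel_mean_length: float = 4.0
    homopolymer: tuple[str, int] = ("C", 9)
    complexes: tuple[tuple[int, int], ...] = ((0, 2),)  # (genus index, members)
    shallow_genera: tuple[int, ...] = (0,)
    missing_marker_taxa: int = 1  # divergent monotypic genera, rbcL only
    query_coverage_mean: float = 0.85
    query_coverage_sd: float = 0.05
    #: probability a query lacks trnL-F (amplification failures hit the
    #: noncoding marker; the coding backbone locus amplifies reliably)
    p_missing_marker: float = 0.05
    p_reverse_complement: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0.0
            < self.intra_divergence
            < self.shallow_inter_divergence
            < self.inter_divergence
            < self.genus_divergence
        ):
            raise ValidationError(
                "need 0 < intra < shallow_inter < inter < genus divergence"
            )
        if self.marker_rate_ratio < 1.0:
            raise ValidationError("marker_rate_ratio must be >= 1")
        if not 0.0 < self.query_coverage_mean <= 1.0:
            raise ValidationError("query coverage mean must be in (0, 1]")
        for g, k in self.complexes:
            if not 0 <= g < self.n_genera or k < 2 or k > self.species_per_genus:
                raise ValidationError(f"invalid complex spec ({g}, {k})")

    # -- derived -------------------------------------------------------
    @property
    def marker_lengths(self) -> dict[Marker, int]:
        return {Marker.RBCL: self.rbcl_length, Marker.TRNLF: self.trnlf_length}

    @property
    def marker_rates(self) -> dict[Marker, float]:
        total = self.rbcl_length + self.trnlf_length
        w_r = self.rbcl_length / total
        w_t = self.trnlf_length / total
        base = 1.0 / (w_r + self.marker_rate_ratio * w_t)
        return {Marker.RBCL: base, Marker.TRNLF: self.marker_rate_ratio * base}


def nw_europe_ferns(seed: int = 0, **overrides) -> SimParams:
    """The default desk-scale preset emulating the NW-European fern pool."""
    return replace(SimParams(seed=seed), **overrides)


@dataclass(frozen=True)
class TruthRow:
    genus: str
    species: str
    effective_label: str
    node: str  # generating species node


@dataclass
class TruthTable:
    rows: dict[str, TruthRow] = field(default_factory=dict)

    def __getitem__(self, key: str) -> TruthRow:
        return self.rows[key]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tgenus\tspecies\teffective_label\tnode\n")
            for sid, r in sorted(self.rows.items()):
                fh.write(f"{sid}\t{r.genus}\t{r.species}\t{r.effective_label}\t{r.node}\n")


@dataclass
class _Species:
    name: str
    genus: str
    code: str
    effective_label: str
    is_complex_member: bool
    divergent: bool
    # aligned-space ancestor row per marker (deletions applied, no homopolymer)
    ancestor: dict[Marker, np.ndarray] = field(default_factory=dict)
    plastid_source: str | None = None  # donor species name for complex members


@dataclass
class SimulatedReference:
    """Everything :func:`simulate_reference` produces."""

    params: SimParams
    db: ReferenceDatabase
    alignments: dict[Marker, Alignment]
    truth: TruthTable
    tree_newick: str
    pgic_rules: dict[str, dict[str, frozenset[int]]]
    species: list[_Species]

    def species_by_name(self, name: str) -> _Species:
        return next(s for s in self.species if s.name == name)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for marker, aln in self.alignments.items():
            tag = marker.value.replace("-", "").lower()
            seqs = [s for s in self.db.sequences if s.marker is marker]
            write_reference_fasta(seqs, outdir / f"{tag}_aligned.fasta")
            unaligned = [replace_residues(s) for s in seqs]
            write_reference_fasta(unaligned, outdir / f"{tag}.fasta")
        write_complexes_tsv(self.db.complexes, outdir / "complexes.tsv")
        self.truth.write_tsv(outdir / "truth.tsv")
        (outdir / "tree.nwk").write_text(self.tree_newick + "\n")
        (outdir / "params.json").write_text(json.dumps(asdict(self.params), indent=2))


def replace_residues(s: MarkerSequence) -> MarkerSequence:
    """Copy of a reference sequence with alignment gaps stripped."""
    return MarkerSequence(
        seq_id=s.seq_id,
        taxon=s.taxon,
        marker=s.marker,
        residues=s.ungapped,
        origin=s.origin,
        accession=s.accession,
    )


# ---------------------------------------------------------------------------
# Tree scaffold


@dataclass
class _Node:
    nid: str
    depth: float
    children: list["_Node"] = field(default_factory=list)
    species: _Species | None = None  # set on species-ancestor nodes


def _random_joins(items: list[_Node], depths: list[float], rng) -> _Node:
    """Random sequential coalescent: join random pairs at sorted depths."""
    nodes = list(items)
    for d in sorted(depths):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = _Node(nid=f"anc_{left.nid}_{right.nid}", depth=d, children=[left, right])
        nodes.append(parent)
    assert len(nodes) == 1
    return nodes[0]


def _newick(node: _Node, parent_depth: float | None = None) -> str:
    blen = "" if parent_depth is None else f":{parent_depth - node.depth:.6f}"
    if not node.children:
        return f"{node.nid}{blen}"
    inner = ",".join(_newick(c, node.depth) for c in node.children)
    return f"({inner}){blen}"


# ---------------------------------------------------------------------------
# Sequence evolution


def _mutate(seq: np.ndarray, n_sub: int, rng) -> np.ndarray:
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.integers(0, len(out), size=n_sub)
    for site in sites:
        current = out[site]
        choices = _BASES[_BASES != current]
        out[site] = rng.choice(choices)
    return out


def _evolve(
    node: _Node,
    seq: np.ndarray,
    rate: float,
    rng,
    out: dict[str, np.ndarray],
) -> None:
    out[node.nid] = seq
    for child in node.children:
        blen = node.depth - child.depth
        n_sub = rng.poisson(rate * blen * len(seq))
        child_seq = _mutate(seq, int(n_sub), rng)
        _evolve(child, child_seq, rate, rng, out)


def _assign_deletions(
    root: _Node, rate_t: float, L: int, p: SimParams, rng
) -> dict[str, list[tuple[int, int]]]:
    """Per-node inherited deletion intervals (trnL-F only), non-overlapping."""
    margin = 50
    taken: list[tuple[int, int]] = []
    per_node: dict[str, list[tuple[int, int]]] = {}

    def place(n_events: int) -> list[tuple[int, int]]:
        got = []
        for _ in range(n_events):
            for _try in range(30):
                length = int(rng.geometric(1.0 / p.indel_mean_length))
                start = int(rng.integers(margin, L - margin - length))
                iv = (start, start + length)
                ok = all(iv[1] <= s or e <= iv[0] for (s, e) in taken)
                if ok:
                    taken.append(iv)
                    got.append(iv)
                    break
        return got

    def walk(node: _Node, inherited: list[tuple[int, int]]) -> None:
        per_node[node.nid] = inherited
        for child in node.children:
            blen = node.depth - child.depth
            n_events = int(rng.poisson(p.indel_rate * rate_t * blen * L))
            walk(child, inherited + place(n_events))

    walk(root, [])
    return per_node


# ---------------------------------------------------------------------------
# Reference simulation


def _species_names(p: SimParams) -> tuple[list[_Species], dict[int, list[_Species]]]:
    species: list[_Species] = []
    by_genus: dict[int, list[_Species]] = {}
    complex_of = {g: k for g, k in p.complexes}
    for g in range(p.n_genera):
        genus = f"Simgenus{g + 1}"
        members = []
        k_complex = complex_of.get(g, 0)
        for s in range(p.species_per_genus):
            name = f"{genus} species{s + 1}"
            sp = _Species(
                name=name,
                genus=genus,
                code=f"G{g + 1}S{s + 1}",
                effective_label=name,
                is_complex_member=s < k_complex,
                divergent=False,
            )
            members.append(sp)
        if k_complex:
            donor = members[0]
            label = f"{donor.name} s.l."
            for sp in members[:k_complex]:
                sp.effective_label = label
                if sp is not donor:
                    sp.plastid_source = donor.name
        species.extend(members)
        by_genus[g] = members
    for d in range(p.missing_marker_taxa):
        genus = f"Simgenus{p.n_genera + d + 1}"
        name = f"{genus} species1"
        sp = _Species(
            name=name,
            genus=genus,
            code=f"G{p.n_genera + d + 1}S1",
            effective_label=name,
            is_complex_member=False,
            divergent=True,
        )
        species.append(sp)
        by_genus[p.n_genera + d] = [sp]
    return species, by_genus


def simulate_reference(p: SimParams | None = None) -> SimulatedReference:
    """Generate the reference database, true alignments and truth table."""
    p = p or SimParams()
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    species, by_genus = _species_names(p)

    # ---- tree scaffold (depths in combined substitutions/site) -------
    genus_roots: list[_Node] = []
    for g, members in sorted(by_genus.items()):
        tips = []
        for sp in members:
            node = _Node(nid=sp.code, depth=p.intra_divergence / 2.0, species=sp)
            tips.append(node)
        if len(tips) == 1:
            genus_roots.append(tips[0])
            continue
        inter = (
            p.shallow_inter_divergence
            if g in p.shallow_genera
            else p.inter_divergence
        )
        depths = [
            0.5 * inter * (1.0 + 0.1 * rng.random()) for _ in range(len(tips) - 1)
        ]
        genus_roots.append(_random_joins(tips, depths, rng))
    depths = [
        0.5 * p.genus_divergence * (1.0 + rng.random())
        for _ in range(len(genus_roots) - 1)
    ]
    root = _random_joins(genus_roots, depths, rng)

    # ---- evolve both markers -----------------------------------------
    rates = p.marker_rates
    lengths = p.marker_lengths
    node_seqs: dict[Marker, dict[str, np.ndarray]] = {}
    for marker in (Marker.RBCL, Marker.TRNLF):
        root_seq = rng.choice(_BASES, size=lengths[marker])
        store: dict[str, np.ndarray] = {}
        _evolve(root, root_seq, rates[marker], rng, store)
        node_seqs[marker] = store
    del_per_node = _assign_deletions(
        root, rates[Marker.TRNLF], lengths[Marker.TRNLF], p, rng
    )

    # ---- species ancestors (aligned space, deletions applied) --------
    def collect(node: _Node) -> None:
        if node.species is not None:
            sp = node.species
            for marker in (Marker.RBCL, Marker.TRNLF):
                row = node_seqs[marker][node.nid].copy()
                if marker is Marker.TRNLF:
                    for s, e in del_per_node[node.nid]:
                        row[s:e] = GAP
                sp.ancestor[marker] = row
        for child in node.children:
            collect(child)

    collect(root)
    # complex members carry the donor's plastid verbatim
    for sp in species:
        if sp.plastid_source:
            donor = next(s for s in species if s.name == sp.plastid_source)
            sp.ancestor = {m: a.copy() for m, a in donor.ancestor.items()}

    # ---- individuals --------------------------------------------------
    hp_base, hp_len = p.homopolymer
    hp_pos = lengths[Marker.TRNLF] // 2

    def tip_row(sp: _Species, marker: Marker, rng) -> str:
        anc = sp.ancestor[marker]
        residues = anc != GAP
        n_sub = int(
            rng.poisson(rates[marker] * (p.intra_divergence / 2.0) * residues.sum())
        )
        row = anc.copy()
        idx = np.flatnonzero(residues)
        for site in rng.integers(0, len(idx), size=n_sub):
            j = idx[site]
            row[j] = rng.choice(_BASES[_BASES != row[j]])
        if marker is Marker.TRNLF:
            run = hp_len + int(rng.integers(-1, 2))
            block = np.array(list(hp_base * run + GAP * (hp_len + 1 - run)))
            row = np.concatenate([row[:hp_pos], block, row[hp_pos:]])
        return "".join(row)

    sequences: list[MarkerSequence] = []
    aln_rows: dict[Marker, tuple[list[str], list[str]]] = {
        Marker.RBCL: ([], []),
        Marker.TRNLF: ([], []),
    }
    truth = TruthTable()
    origin_choices = [Origin.OWN, Origin.GENBANK, Origin.NEW]
    acc_counter = 0
    tip_cache: dict[str, dict[Marker, list[str]]] = {}
    for sp in species:
        if sp.plastid_source:
            # identical chloroplast genome: copy the donor's individuals
            rows_by_marker = {
                m: list(rows) for m, rows in tip_cache[sp.plastid_source].items()
            }
        else:
            rows_by_marker = {
                m: [tip_row(sp, m, rng) for _ in range(p.seqs_per_species)]
                for m in (Marker.RBCL, Marker.TRNLF)
            }
        tip_cache[sp.name] = rows_by_marker
        for k in range(p.seqs_per_species):
            sid = f"{sp.code}{chr(ord('a') + k)}"
            origin = origin_choices[int(rng.choice(3, p=[0.5, 0.3, 0.2]))]
            acc = None
            if origin is Origin.GENBANK:
                acc_counter += 1
                acc = f"SYN{acc_counter:05d}"
            for marker in (Marker.RBCL, Marker.TRNLF):
                if marker is Marker.TRNLF and sp.divergent:
                    continue
                sequences.append(
                    MarkerSequence(
                        seq_id=sid,
                        taxon=sp.name,
                        marker=marker,
                        residues=rows_by_marker[marker][k],
                        origin=origin,
                        accession=acc,
                    )
                )
                ids, rows = aln_rows[marker]
                ids.append(sid)
                rows.append(rows_by_marker[marker][k])
            truth.rows[sid] = TruthRow(
                genus=sp.genus,
                species=sp.name,
                effective_label=sp.effective_label,
                node=sp.code,
            )

    complexes = []
    for g, k in p.complexes:
        members = [sp for sp in by_genus[g][:k]]
        complexes.append(
            SpeciesComplex.from_donor(members[0].name, [m.name for m in members])
        )
    db = ReferenceDatabase(sequences=sequences, complexes=complexes)
    alignments = {
        m: Alignment(ids=ids, rows=rows, marker=m)
        for m, (ids, rows) in aln_rows.items()
    }
    # PgiC band rules: donor diploid single band; other members are
    # hybrid-derived allotetraploids showing the donor band plus their own
    pgic_rules: dict[str, dict[str, frozenset[int]]] = {}
    for c in complexes:
        members = sorted(c.members)
        donor = c.donor or members[0]
        table = {donor: frozenset({420})}
        for i, m in enumerate(m for m in members if m != donor):
            table[m] = frozenset({420, 450 + 30 * i})
        pgic_rules[c.label] = table

    return SimulatedReference(
        params=p,
        db=db,
        alignments=alignments,
        truth=truth,
        tree_newick=_newick(root) + ";",
        pgic_rules=pgic_rules,
        species=species,
    )


# ---------------------------------------------------------------------------
# Query simulation


def simulate_queries(
    sim: SimulatedReference,
    n_queries: int,
    seed: int | None = None,
) -> tuple[list[QuerySample], dict[str, TruthRow]]:
    """Draw queries from random species with partial coverage.

    Each query evolves a fresh individual from its species' ancestral
    sequence, is truncated to a contiguous window whose fractional
    coverage follows ``Normal(query_coverage_mean, sd)`` clipped to
    (0.3, 1], loses its trnL-F sequence with probability
    ``p_missing_marker`` (the failure mode seen in practice; the coding
    marker amplifies reliably) and is reverse-complemented with
    probability ``p_reverse_complement``. Complex-member queries carry
    the PgiC band lengths from the simulated band table.
    """
    if n_queries < 1:
        raise ValidationError("n_queries must be >= 1")
    p = sim.params
    rng = np.random.default_rng(
        np.random.SeedSequence(p.seed if seed is None else seed).spawn(1)[0]
    )
    rates = p.marker_rates
    hp_base, hp_len = p.homopolymer
    hp_pos = p.marker_lengths[Marker.TRNLF] // 2
    queries: list[QuerySample] = []
    truth: dict[str, TruthRow] = {}
    for i in range(n_queries):
        sp = sim.species[int(rng.integers(0, len(sim.species)))]
        qid = f"Q{i + 1:03d}"
        seqs: dict[Marker, str] = {}
        for marker in (Marker.RBCL, Marker.TRNLF):
            anc = sp.ancestor[marker]
            residues = anc != GAP
            n_sub = int(
                rng.poisson(
                    rates[marker] * (p.intra_divergence / 2.0) * residues.sum()
                )
            )
            row = anc.copy()
            idx = np.flatnonzero(residues)
            for site in rng.integers(0, len(idx), size=n_sub):
                j = idx[site]
                row[j] = rng.choice(_BASES[_BASES != row[j]])
            if marker is Marker.TRNLF:
                run = hp_len + int(rng.integers(-1, 2))
                block = np.array(list(hp_base * run))
                row = np.concatenate([row[:hp_pos], block, row[hp_pos:]])
            seq = "".join(row[row != GAP])
            frac = float(
                np.clip(
                    rng.normal(p.query_coverage_mean, p.query_coverage_sd), 0.3, 1.0
                )
            )
            win = max(1, int(round(frac * len(seq))))
            start = int(rng.integers(0, len(seq) - win + 1))
            seq = seq[start : start + win]
            if rng.random() < p.p_reverse_complement:
                seq = reverse_complement(seq)
            seqs[marker] = seq
        if rng.random() < p.p_missing_marker:
            del seqs[Marker.TRNLF]
        lengths = None
        if sp.is_complex_member:
            label = sp.effective_label
            lengths = sorted(sim.pgic_rules[label][sp.name])
        queries.append(
            QuerySample(sample_id=qid, sequences=seqs, pgic_fragment_lengths=lengths)
        )
        truth[qid] = TruthRow(
            genus=sp.genus,
            species=sp.name,
            effective_label=sp.effective_label,
            node=sp.code,
        )
    return queries, truth


# ---------------------------------------------------------------------------
# Study-scale composition stand-in


def study_scale_composition(seed: int = 0) -> ReferenceDatabase:
    """A synthetic database shaped like the study's reference composition.

    Purely a composition stand-in (random short sequences): 52 taxa in
    23 genera; 77 rbcL sequences; 74 trnL-F sequences over 47 of the
    taxa (5 taxa carry rbcL only). Used to exercise loading, validation
    and the composition report at the study's scale.
    """
    rng = np.random.default_rng(seed)
    n_taxa, n_genera = 52, 23
    genus_of_taxon = sorted(rng.integers(0, n_genera, size=n_taxa - n_genera).tolist())
    genera_assignment = list(range(n_genera)) + genus_of_taxon
    taxa = [
        f"Standingenus{g + 1} species{sum(1 for x in genera_assignment[:i] if x == g) + 1}"
        for i, g in enumerate(genera_assignment)
    ]
    rbcl_counts = np.ones(n_taxa, dtype=int)
    extra = rng.choice(n_taxa, size=77 - n_taxa, replace=False)
    rbcl_counts[extra] += 1
    trnlf_idx = np.sort(rng.choice(n_taxa, size=47, replace=False))
    trnlf_counts = np.ones(n_taxa, dtype=int)
    trnlf_counts[[i for i in range(n_taxa) if i not in set(trnlf_idx.tolist())]] = 0
    extra_t = rng.choice(trnlf_idx, size=74 - 47, replace=True)
    for i in extra_t:
        trnlf_counts[i] += 1
    sequences = []
    for i, taxon in enumerate(taxa):
        for marker, counts in ((Marker.RBCL, rbcl_counts), (Marker.TRNLF, trnlf_counts)):
            for k in range(int(counts[i])):
                tag = "r" if marker is Marker.RBCL else "t"
                sequences.append(
                    MarkerSequence(
                        seq_id=f"ST{i + 1:03d}{tag}{k + 1}",
                        taxon=taxon,
                        marker=marker,
                        residues="".join(rng.choice(_BASES, size=60)),
                        origin=Origin.GENBANK,
                        accession=f"STAND{i:03d}{tag}{k}",
                    )
                )
    return ReferenceDatabase(sequences=sequences)
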