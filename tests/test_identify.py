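"""Similarity ranking, decision rules, tree placement, PgiC resolution."""

from __future__ import annotations

import numpy as np
import pytest

from fernbarcode.alignment import Alignment
from fernbarcode.errors import ValidationError
from fernbarcode.identify import (
    IdentificationConfig,
    Method,
    QuerySample,
    Rank,
    SimilarityHit,
    identify_sample,
    rank_by_identity,
    resolve_complex,
    similarity_identify,
    tree_identify,
)
from fernbarcode.markers import Marker, reverse_complement
from fernbarcode.parsimony import SearchConfig
from fernbarcode.pipeline import build_combined_matrix
from fernbarcode.reference_db import MarkerSequence, ReferenceDatabase, SpeciesComplex

FAST = IdentificationConfig(search=SearchConfig(n_bootstrap=20, n_addition_cycles=2, seed=17))


def _ref_of(sim, label, marker=Marker.RBCL):
    return sim.db.sequences_of_label(label, marker)[0]


# ---------------------------------------------------------------------------
# MPI ranking


def test_identical_query_hits_mpi_100(small_sim):
    ref = small_sim.db.by_marker(Marker.RBCL)[0]
    q = QuerySample("q", {Marker.RBCL: ref.ungapped})
    hits = rank_by_identity(q, small_sim.db, Marker.RBCL, FAST)
    assert hits[0].mpi == 100.0
    assert hits[0].seq_id == ref.seq_id


def test_exact_substring_scores_100_over_its_overlap():
    rng = np.random.default_rng(1)
    full = "".join(rng.choice(list("ACGT"), size=1200))
    db = ReferenceDatabase(
        sequences=[MarkerSequence("R1", "Genus one", Marker.RBCL, full)]
    )
    q = QuerySample("q", {Marker.RBCL: full[450:750]})
    (hit,) = rank_by_identity(q, db, Marker.RBCL, FAST)
    assert hit.mpi == 100.0
    assert hit.overlap == 300


def test_five_mismatches_in_500_scores_99():
    rng = np.random.default_rng(2)
    ref = "".join(rng.choice(list("ACGT"), size=500))
    mutated = list(ref)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for pos in (10, 100, 250, 333, 480):
        mutated[pos] = flip[mutated[pos]]
    db = ReferenceDatabase(
        sequences=[MarkerSequence("R1", "Genus one", Marker.RBCL, ref)]
    )
    q = QuerySample("q", {Marker.RBCL: "".join(mutated)})
    (hit,) = rank_by_identity(q, db, Marker.RBCL, FAST)
    assert hit.mpi == pytest.approx(99.0)
    assert hit.overlap == 500


def test_reverse_complemented_query_gives_same_hits(small_sim):
    ref = small_sim.db.by_marker(Marker.RBCL)[0]
    fwd = QuerySample("q", {Marker.RBCL: ref.ungapped})
    rev = QuerySample("q", {Marker.RBCL: reverse_complement(ref.ungapped)})
    h_fwd = rank_by_identity(fwd, small_sim.db, Marker.RBCL, FAST)
    h_rev = rank_by_identity(rev, small_sim.db, Marker.RBCL, FAST)
    assert [(h.seq_id, round(h.mpi, 6)) for h in h_fwd] == [
        (h.seq_id, round(h.mpi, 6)) for h in h_rev
    ]


def test_hits_independent_of_reference_order(small_sim):
    ref = small_sim.db.by_marker(Marker.RBCL)[0]
    q = QuerySample("q", {Marker.RBCL: ref.ungapped[:500]})
    shuffled = ReferenceDatabase(
        sequences=list(reversed(small_sim.db.sequences)),
        complexes=list(small_sim.db.complexes),
    )
    a = rank_by_identity(q, small_sim.db, Marker.RBCL, FAST)
    b = rank_by_identity(q, shuffled, Marker.RBCL, FAST)
    assert [h.seq_id for h in a] == [h.seq_id for h in b]


def test_query_without_marker_raises(small_sim):
    q = QuerySample("q", {Marker.RBCL: "ACGT" * 50})
    with pytest.raises(ValidationError, match="lacks marker"):
        rank_by_identity(q, small_sim.db, Marker.TRNLF, FAST)


# ---------------------------------------------------------------------------
# Similarity decision rules


def _hit(taxon, mpi, overlap=500, seq_id=None):
    return SimilarityHit(
        seq_id=seq_id or taxon.replace(" ", "_"),
        taxon=taxon,
        genus=taxon.split()[0],
        mpi=mpi,
        overlap=overlap,
    )


@pytest.fixture
def plain_db():
    return ReferenceDatabase(
        sequences=[
            MarkerSequence("A1", "Athyrium filix-femina", Marker.RBCL, "ACGT"),
            MarkerSequence("D1", "Dryopteris carthusiana", Marker.RBCL, "ACGA"),
            MarkerSequence("D2", "Dryopteris cristata", Marker.RBCL, "ACGC"),
        ],
        complexes=[
            SpeciesComplex(
                label="Dryopteris carthusiana s.l.",
                members={"Dryopteris carthusiana", "Dryopteris cristata"},
            )
        ],
    )


def test_unique_top_hit_above_threshold_gives_species(plain_db):
    hits = {
        Marker.RBCL: [
            _hit("Athyrium filix-femina", 99.3),
            _hit("Athyrium distentifolium", 97.0),
        ]
    }
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.SPECIES
    assert res.label == "Athyrium filix-femina"


def test_tied_top_stratum_demotes_to_genus(plain_db):
    hits = {
        Marker.RBCL: [
            _hit("Athyrium filix-femina", 99.0),
            _hit("Athyrium distentifolium", 99.0),
        ]
    }
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.GENUS
    assert res.label == "Athyrium"


def test_top_hit_on_complex_label_gives_complex_rank(plain_db):
    hits = {Marker.RBCL: [_hit("Dryopteris carthusiana s.l.", 99.0)]}
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.COMPLEX
    assert res.label == "Dryopteris carthusiana s.l."


def test_conflicting_genera_above_threshold_gives_none(plain_db):
    hits = {
        Marker.RBCL: [_hit("Athyrium filix-femina", 99.0)],
        Marker.TRNLF: [_hit("Dryopteris carthusiana s.l.", 98.0)],
    }
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.NONE
    assert any("conflicting genera" in n for n in res.notes)


def test_no_hit_above_threshold_gives_none(plain_db):
    hits = {Marker.RBCL: [_hit("Athyrium filix-femina", 91.0)]}
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.NONE


def test_one_marker_resolves_species_other_only_genus(plain_db):
    # the coding marker is ambiguous within the genus, the faster marker
    # resolves: species is assigned (the study's typical outcome)
    hits = {
        Marker.RBCL: [
            _hit("Athyrium filix-femina", 99.6),
            _hit("Athyrium distentifolium", 99.6),
        ],
        Marker.TRNLF: [
            _hit("Athyrium filix-femina", 99.3),
            _hit("Athyrium distentifolium", 97.1),
        ],
    }
    res = similarity_identify("s", hits, plain_db)
    assert res.rank is Rank.SPECIES
    assert res.label == "Athyrium filix-femina"


# ---------------------------------------------------------------------------
# Tree identification


def test_tree_identifies_species_from_simulated_query(small_sim, small_matrix):
    sp = next(s for s in small_sim.species if not s.is_complex_member)
    ref = small_sim.db.sequences_of_label(sp.effective_label, Marker.RBCL)[0]
    trn = small_sim.db.sequences_of_label(sp.effective_label, Marker.TRNLF)[0]
    q = QuerySample("q", {Marker.RBCL: ref.ungapped, Marker.TRNLF: trn.ungapped})
    res = tree_identify(q, small_matrix, small_sim.db, FAST)
    assert res.rank is Rank.SPECIES
    assert res.label == sp.effective_label
    assert res.evidence["species_support"]["support"] > 70.0


def test_tree_gives_complex_rank_for_plastid_identical_query(small_sim, small_matrix):
    member = next(s for s in small_sim.species if s.is_complex_member)
    ref = small_sim.db.sequences_of_label(member.effective_label, Marker.RBCL)[0]
    trn = small_sim.db.sequences_of_label(member.effective_label, Marker.TRNLF)[0]
    q = QuerySample("q", {Marker.RBCL: ref.ungapped, Marker.TRNLF: trn.ungapped})
    res = tree_identify(q, small_matrix, small_sim.db, FAST)
    assert res.rank is Rank.COMPLEX
    assert res.label == member.effective_label


def test_tree_abstains_when_query_unalignable(small_sim, small_matrix):
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=400))
    q = QuerySample("q", {Marker.RBCL: junk})
    res = tree_identify(q, small_matrix, small_sim.db, FAST)
    assert res.rank in (Rank.NONE, Rank.GENUS)  # random DNA may be ~50% similar
    if res.rank is Rank.NONE:
        assert res.notes


# ---------------------------------------------------------------------------
# PgiC band rules


POLYSTICHUM_RULES = {
    "Polystichum setiferum s.l.": {
        "Polystichum setiferum": {420},
        "Polystichum lonchitis": {465},
        "Polystichum aculeatum": {420, 465},  # allotetraploid double band
    }
}


def test_double_band_resolves_allotetraploid():
    res = resolve_complex("s", "Polystichum setiferum s.l.", [420, 465], POLYSTICHUM_RULES)
    assert res.rank is Rank.SPECIES
    assert res.label == "Polystichum aculeatum"


def test_single_band_resolves_diploid_parent():
    res = resolve_complex("s", "Polystichum setiferum s.l.", [420], POLYSTICHUM_RULES)
    assert res.label == "Polystichum setiferum"


def test_indistinguishable_band_table_stays_unresolved():
    rules = {
        "Dryopteris carthusiana s.l.": {
            "Dryopteris carthusiana": {500},
            "Dryopteris cristata": {500},
            "Dryopteris dilatata": {500},
        }
    }
    res = resolve_complex("s", "Dryopteris carthusiana s.l.", [500], rules)
    assert res.rank is Rank.COMPLEX
    assert any("unresolved" in n for n in res.notes)


def test_missing_lengths_stay_unresolved():
    res = resolve_complex("s", "Polystichum setiferum s.l.", None, POLYSTICHUM_RULES)
    assert res.rank is Rank.COMPLEX
    assert any("no PgiC" in n for n in res.notes)


def test_unknown_complex_label_raises():
    with pytest.raises(ValidationError, match="band rules"):
        resolve_complex("s", "Unknown s.l.", [420], POLYSTICHUM_RULES)


# ---------------------------------------------------------------------------
# Combined verdicts


def test_identical_query_identified_by_both_methods(small_sim, small_matrix):
    """A query byte-identical to a reference lands on its effective taxon."""
    sp = next(s for s in small_sim.species if not s.is_complex_member)
    ref = small_sim.db.sequences_of_label(sp.effective_label, Marker.RBCL)[0]
    trn = small_sim.db.sequences_of_label(sp.effective_label, Marker.TRNLF)[0]
    q = QuerySample("q", {Marker.RBCL: ref.ungapped, Marker.TRNLF: trn.ungapped})
    res = identify_sample(q, small_sim.db, small_matrix, FAST)
    assert res.similarity.rank is Rank.SPECIES
    assert res.tree.rank is Rank.SPECIES
    assert res.combined.rank is Rank.SPECIES
    assert res.combined.label == sp.effective_label


def test_complex_query_combines_to_complex_then_pgic_resolves(small_sim, small_matrix):
    member = next(s for s in small_sim.species if s.plastid_source)
    ref = small_sim.db.sequences_of_label(member.effective_label, Marker.RBCL)[0]
    trn = small_sim.db.sequences_of_label(member.effective_label, Marker.TRNLF)[0]
    bands = sorted(small_sim.pgic_rules[member.effective_label][member.name])
    q = QuerySample(
        "q",
        {Marker.RBCL: ref.ungapped, Marker.TRNLF: trn.ungapped},
        pgic_fragment_lengths=bands,
    )
    no_pgic = identify_sample(q, small_sim.db, small_matrix, FAST)
    assert no_pgic.combined.rank is Rank.COMPLEX
    with_pgic = identify_sample(
        q, small_sim.db, small_matrix, FAST, pgic_rules=small_sim.pgic_rules
    )
    assert with_pgic.combined.rank is Rank.SPECIES
    assert with_pgic.combined.label == member.name
    assert with_pgic.pgic is not None and with_pgic.pgic.method is Method.PGIC
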