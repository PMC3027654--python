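"""P-distances and barcoding-gap statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fernbarcode.alignment import Alignment, combine_partitions
from fernbarcode.distances import (
    discrimination_report,
    distance_matrix,
    divergence_summary,
    p_distance,
)
from fernbarcode.errors import ValidationError
from fernbarcode.markers import Marker
from fernbarcode.pipeline import gap_analysis


def test_p_distance_hand_cases():
    assert p_distance("ACGT", "ACGA") == (0.25, 4)
    assert p_distance("ACGT", "ACGT") == (0.0, 4)
    # pairwise deletion: the gapped site is excluded for this pair only
    assert p_distance("AC-T", "ACGT") == (0.0, 3)


def test_p_distance_excludes_missing_and_ambiguity():
    # N and ? are not comparable sites
    assert p_distance("ACNT", "ACG?") == (0.0, 2)


def test_p_distance_no_comparable_sites_flagged():
    d, n = p_distance("----", "ACGT")
    assert d is None and n == 0


def test_p_distance_length_mismatch():
    with pytest.raises(ValidationError):
        p_distance("ACG", "ACGT")


dna = st.text(alphabet="ACGT-?N", min_size=1, max_size=60)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.data())
def test_p_distance_symmetric_and_bounded(data):
    a = data.draw(dna)
    b = data.draw(st.text(alphabet="ACGT-?N", min_size=len(a), max_size=len(a)))
    dab, nab = p_distance(a, b)
    dba, nba = p_distance(b, a)
    assert (dab, nab) == (dba, nba)
    if dab is not None:
        assert 0.0 <= dab <= 1.0


def _matrix(rows: dict[str, str], marker=Marker.RBCL):
    aln = Alignment(ids=list(rows), rows=list(rows.values()), marker=marker)
    return combine_partitions([aln])


def test_distance_matrix_matches_hand_pairs():
    rows = {"a": "ACGTACGT", "b": "ACGAACGT", "c": "AC-TACGA"}
    dm = distance_matrix(_matrix(rows))
    assert dm.pair("a", "b") == pytest.approx(1 / 8)
    assert dm.pair("a", "c") == pytest.approx(1 / 7)
    assert dm.pair("b", "c") == pytest.approx(2 / 7)
    assert dm.pair("a", "a") == 0.0


def test_distance_matrix_symmetry_on_random_input():
    rng = np.random.default_rng(5)
    rows = {
        f"t{i}": "".join(rng.choice(list("ACGT-?"), size=100, p=[0.23] * 4 + [0.04, 0.04]))
        for i in range(10)
    }
    dm = distance_matrix(_matrix(rows))
    assert np.allclose(dm.d, dm.d.T, equal_nan=True)
    assert np.array_equal(dm.comparable_sites, dm.comparable_sites.T)


def test_indel_partition_excluded_from_distances():
    aln = Alignment(ids=["a", "b"], rows=["AC---T", "ACGGGT"], marker=Marker.TRNLF)
    from fernbarcode.alignment import simple_indel_code

    m = combine_partitions([aln], [simple_indel_code(aln, min_len=3)])
    dm = distance_matrix(m)
    # only the 3 shared nucleotide sites count; the indel column does not
    assert dm.comparable_sites[0, 1] == 3
    assert dm.pair("a", "b") == 0.0


def test_divergence_summary_four_sequence_toy():
    rows = {
        "x1": "AAAAAAAAAAAAAAAAAAAA",
        "x2": "AAAAAAAAAAAAAAAAAAAC",  # intra X: 0.05
        "y1": "AAAAAAAAAATTTTTTTTTT",
        "y2": "AAAAAAAAAATTTTTTTTTG",  # inter >= 9/20
    }
    labels = {"x1": "Genus x", "x2": "Genus x", "y1": "Genus y", "y2": "Genus y"}
    recs = divergence_summary(distance_matrix(_matrix(rows)), labels)
    by = {r.taxon: r for r in recs}
    assert by["Genus x"].max_intra == pytest.approx(0.05)
    assert by["Genus x"].min_inter == pytest.approx(0.5)
    assert by["Genus x"].discriminated and by["Genus y"].discriminated
    assert by["Genus x"].ratio >= 5
    assert by["Genus x"].nearest_neighbours == ["Genus y"]


def test_single_sequence_taxon_has_no_intra_but_inter():
    rows = {"x1": "AAAA", "y1": "AATT", "y2": "AATT"}
    labels = {"x1": "Genus x", "y1": "Genus y", "y2": "Genus y"}
    recs = divergence_summary(distance_matrix(_matrix(rows)), labels)
    by = {r.taxon: r for r in recs}
    assert by["Genus x"].max_intra is None
    assert by["Genus x"].min_inter == pytest.approx(0.5)
    assert by["Genus x"].discriminated is None


def test_collapsed_complex_members_contribute_no_inter_distance():
    rows = {"c1": "AAAA", "c2": "AAAA", "o1": "TTTT"}
    labels = {"c1": "Genus c s.l.", "c2": "Genus c s.l.", "o1": "Genus o"}
    recs = divergence_summary(distance_matrix(_matrix(rows)), labels)
    by = {r.taxon: r for r in recs}
    assert by["Genus c s.l."].max_intra == 0.0
    assert by["Genus c s.l."].min_inter == pytest.approx(1.0)
    assert by["Genus c s.l."].ratio == math.inf


def test_mean_min_inter_brute_force_small_instance():
    """Mean nearest-neighbour distance equals an exhaustive hand computation."""
    rng = np.random.default_rng(11)
    rows = {f"t{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(5)}
    labels = {k: f"Taxon {k}" for k in rows}
    dm = distance_matrix(_matrix(rows))
    recs = divergence_summary(dm, labels)
    # brute force: per sequence, min distance over all other sequences
    seqs = list(rows)
    expect = []
    for i, a in enumerate(seqs):
        vals = []
        for j, b in enumerate(seqs):
            if i == j:
                continue
            mism = sum(x != y for x, y in zip(rows[a], rows[b]))
            vals.append(mism / 40)
        expect.append(min(vals))
    got = [r.min_inter for r in sorted(recs, key=lambda r: r.taxon)]
    expect_sorted = [e for _, e in sorted(zip([f"Taxon {s}" for s in seqs], expect))]
    assert got == pytest.approx(expect_sorted)
    rep = discrimination_report(recs)
    assert rep.mean_min_inter == pytest.approx(float(np.mean(expect)))


def test_report_overall_mean_and_monotypic_genus():
    rows = {"a1": "AAAAAAAAAA" * 5, "b1": "AAAAAAAAAT" * 5, "c1": "TTTTTTTTTT" * 5}
    labels = {"a1": "Alpha one", "b1": "Alpha two", "c1": "Beta one"}
    recs = divergence_summary(distance_matrix(_matrix(rows)), labels)
    rep = discrimination_report(recs, {"Alpha one": "Alpha", "Alpha two": "Alpha", "Beta one": "Beta"})
    assert rep.per_genus_mean_min_inter["Alpha"] == pytest.approx(0.1)
    assert rep.per_genus_mean_min_inter["Beta"] is None  # monotypic genus
    assert rep.n_multi_sequence == 0


def test_simulated_regime_recovers_full_discrimination(sim, sim_matrix):
    """Intra << inter divergence yields a clean barcoding gap for all taxa."""
    records, report = gap_analysis(sim.db, sim_matrix)
    multi = [r for r in records if r.discriminated is not None]
    assert multi, "expected multi-sequence taxa"
    assert all(r.discriminated for r in multi)
    assert report.discrimination_fraction == 1.0
    # nearest-neighbour regime around 0.03 on the combined data
    assert 0.02 < report.mean_min_inter < 0.045


def test_collapsing_never_decreases_other_taxas_min_inter(sim, sim_matrix):
    from fernbarcode.distances import distance_matrix as dmf

    dm = dmf(sim_matrix)
    eff = sim.db.effective_taxon
    raw = {s.seq_id: s.taxon for s in sim.db.sequences}
    before = {r.taxon: r.min_inter for r in divergence_summary(dm, raw)}
    after = {r.taxon: r.min_inter for r in divergence_summary(dm, eff)}
    collapsed = {m for c in sim.db.complexes for m in c.members}
    for taxon, mi in after.items():
        if taxon in before and taxon not in collapsed:
            assert mi >= before[taxon] - 1e-12
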