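"""Fitch scoring, exhaustive/heuristic search, bootstrap, monophyly."""

from __future__ import annotations

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from fernbarcode.errors import ValidationError
from fernbarcode.parsimony import (
    ParsimonyMatrix,
    SearchConfig,
    bootstrap_consensus,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    n_unrooted_topologies,
)
from fernbarcode.trees import (
    NOT_A_CLADE,
    SupportTree,
    Tree,
    group_support,
    majority_consensus,
)


def _random_matrix(rng, n_taxa, n_chars, missing=0.1):
    alphabet = list("ACGT")
    rows = {}
    for i in range(n_taxa):
        chars = rng.choice(alphabet, size=n_chars).tolist()
        for j in range(n_chars):
            if rng.random() < missing:
                chars[j] = "?" if rng.random() < 0.5 else "-"
        rows[f"t{i}"] = "".join(chars)
    return ParsimonyMatrix.from_strings(rows)


# ---------------------------------------------------------------------------
# Fitch


def test_fitch_hand_cases():
    t = Tree.from_newick("((A,B),(C,D));")
    assert fitch_length(t, ParsimonyMatrix.from_strings({"A": "A", "B": "A", "C": "G", "D": "G"})) == 1
    assert fitch_length(t, ParsimonyMatrix.from_strings({"A": "A", "B": "G", "C": "A", "D": "G"})) == 2
    assert fitch_length(t, ParsimonyMatrix.from_strings({"A": "?", "B": "?", "C": "?", "D": "?"})) == 0


def test_fitch_ambiguity_codes_are_state_sets():
    t = Tree.from_newick("((A,B),(C,D));")
    # R = {A,G} intersects both sides: no forced change
    m = ParsimonyMatrix.from_strings({"A": "A", "B": "R", "C": "G", "D": "G"})
    assert fitch_length(t, m) == 1


def test_fitch_invariant_under_rerooting_and_rotation():
    m = ParsimonyMatrix.from_strings(
        {"A": "ACGTT", "B": "ACGTA", "C": "TCGAA", "D": "TCTAA", "E": "TCTAG"}
    )
    newicks = [
        "((A,B),(C,(D,E)));",
        "(((A,B),C),(D,E));",
        "((E,D),(C,(B,A)));",
        "(C,(A,B),(D,E));",
    ]
    scores = {fitch_length(Tree.from_newick(nw), m) for nw in newicks}
    assert len(scores) == 1


def test_fitch_taxon_mismatch_lists_difference():
    t = Tree.from_newick("((A,B),(C,D));")
    m = ParsimonyMatrix.from_strings({"A": "A", "B": "A", "C": "G", "E": "G"})
    with pytest.raises(ValidationError, match=r"\['D', 'E'\]"):
        fitch_length(t, m)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_fitch_matches_phangorn(tmp_path):
    """Independent oracle: R/phangorn's parsimony() on the same tree."""
    rng = np.random.default_rng(42)
    taxa = [f"t{i}" for i in range(6)]
    rows = {t: "".join(rng.choice(list("ACGT"), size=40)) for t in taxa}
    newick = "((t0,t1),(t2,t3),(t4,t5));"
    ours = fitch_length(Tree.from_newick(newick), ParsimonyMatrix.from_strings(rows))
    fasta = "".join(f">{t}\n{s}\n" for t, s in rows.items())
    (tmp_path / "m.fasta").write_text(fasta)
    (tmp_path / "t.nwk").write_text(newick + "\n")
    script = textwrap.dedent(
        """
        suppressMessages(library(phangorn))
        d <- read.phyDat(commandArgs(TRUE)[1], format="fasta")
        t <- read.tree(commandArgs(TRUE)[2])
        cat(parsimony(t, d, method="fitch"))
        """
    )
    (tmp_path / "s.R").write_text(script)
    out = subprocess.run(
        ["Rscript", str(tmp_path / "s.R"), str(tmp_path / "m.fasta"), str(tmp_path / "t.nwk")],
        capture_output=True,
        text=True,
        check=True,
    )
    assert int(out.stdout.strip()) == ours


# ---------------------------------------------------------------------------
# Exhaustive search


def test_exhaustive_topology_counts():
    rng = np.random.default_rng(0)
    assert exhaustive_search(_random_matrix(rng, 4, 12)).n_topologies == 3
    assert exhaustive_search(_random_matrix(rng, 6, 12)).n_topologies == 105
    assert n_unrooted_topologies(9) == 135135


def test_exhaustive_refuses_large_inputs():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError, match="refused"):
        exhaustive_search(_random_matrix(rng, 10, 10))


def test_homoplasy_free_characters_recover_generating_topology():
    """Characters simulated without homoplasy pin down the true tree."""
    true = Tree.from_newick("((A,B),((C,D),(E,F)));")
    # one binary character per internal edge, repeated thrice
    clades = [{"A", "B"}, {"C", "D"}, {"E", "F"}, {"C", "D", "E", "F"}]
    taxa = list("ABCDEF")
    cols = []
    for clade in clades * 3:
        cols.append(["T" if t in clade else "A" for t in taxa])
    rows = {t: "".join(c[i] for c in cols) for i, t in enumerate(taxa)}
    res = exhaustive_search(ParsimonyMatrix.from_strings(rows))
    assert res.score == 12  # one change per character
    assert len(res.trees) == 1
    assert res.trees[0].topology_key() == true.topology_key()


# ---------------------------------------------------------------------------
# Heuristic search


def test_heuristic_matches_exhaustive_on_small_matrices():
    rng = np.random.default_rng(123)
    for trial in range(8):
        n = int(rng.integers(5, 10))
        m = _random_matrix(rng, n, int(rng.integers(20, 61)))
        ex = exhaustive_search(m)
        he = heuristic_search(m, SearchConfig(n_addition_cycles=10, seed=trial))
        assert he.score == ex.score


def test_heuristic_deterministic_given_seed():
    rng = np.random.default_rng(9)
    m = _random_matrix(rng, 8, 30)
    cfg = SearchConfig(n_addition_cycles=5, seed=77)
    r1 = heuristic_search(m, cfg)
    r2 = heuristic_search(m, cfg)
    assert r1.score == r2.score
    assert [t.topology_key() for t in r1.trees] == [t.topology_key() for t in r2.trees]


def test_constant_matrix_scores_zero():
    m = ParsimonyMatrix.from_strings({f"t{i}": "AAAA" for i in range(6)})
    res = heuristic_search(m, SearchConfig(n_addition_cycles=2, seed=0))
    assert res.score == 0


def test_nni_swap_supported_tbr_rejected():
    rng = np.random.default_rng(4)
    m = _random_matrix(rng, 6, 30)
    ex = exhaustive_search(m)
    he = heuristic_search(m, SearchConfig(n_addition_cycles=10, swap="nni", seed=1))
    assert he.score == ex.score
    with pytest.raises(ValidationError, match="unsupported"):
        SearchConfig(swap="tbr")


def test_search_config_validation():
    with pytest.raises(ValidationError):
        SearchConfig(n_addition_cycles=0)
    with pytest.raises(ValidationError):
        SearchConfig(consensus_threshold=0.4)


# ---------------------------------------------------------------------------
# Bootstrap + consensus


def test_bootstrap_perfect_split_near_full_support():
    rows = {
        "A": "A" * 30 + "C" * 30,
        "B": "A" * 30 + "C" * 30,
        "C": "T" * 30 + "C" * 30,
        "D": "T" * 30 + "G" * 30,
        "E": "T" * 30 + "G" * 30,
    }
    m = ParsimonyMatrix.from_strings(rows)
    st = bootstrap_consensus(m, SearchConfig(n_bootstrap=200, n_addition_cycles=3, seed=6))
    assert st.frequency({"A", "B"}) >= 98.0
    assert st.frequency({"D", "E"}) >= 98.0
    for pct in st.split_frequencies.values():
        assert 0.0 <= pct <= 100.0
    for mask, pct in st.support.items():
        assert pct > 50.0  # consensus keeps only majority splits


def test_bootstrap_no_informative_characters_gives_star():
    m = ParsimonyMatrix.from_strings({f"t{i}": "ACGT" for i in range(5)})
    st = bootstrap_consensus(m, SearchConfig(n_bootstrap=20, n_addition_cycles=1, seed=0))
    assert st.splits() == frozenset()
    assert st.support == {}


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(2)
    m = _random_matrix(rng, 6, 40)
    cfg = SearchConfig(n_bootstrap=30, n_addition_cycles=2, seed=5)
    a = bootstrap_consensus(m, cfg)
    b = bootstrap_consensus(m, cfg)
    assert a.split_frequencies == b.split_frequencies


def test_true_bipartitions_strongly_supported_without_homoplasy(sim_matrix):
    """Clean signal: generating-tree splits exceed the 70% support rule."""
    rows = {
        "A": "AATTTTAAAAAAAAAAAACC",
        "B": "AATTTTAAAAAAAAAACCCC",
        "C": "AAAAAATTTTAAAACCAACC",
        "D": "AAAAAATTTTAACCAAAACC",
        "E": "AAAAAAAAAATTTTAAAAGG",
        "F": "AAAAAAAAAATTTTAAAAGG",
    }
    # splits: {A,B} x4, {C,D} x4, {E,F} x4 + autapomorphies
    m = ParsimonyMatrix.from_strings({k: v * 5 for k, v in rows.items()})
    st = bootstrap_consensus(m, SearchConfig(n_bootstrap=100, n_addition_cycles=3, seed=3))
    for clade in ({"A", "B"}, {"C", "D"}, {"E", "F"}):
        assert st.frequency(clade) > 70.0


# ---------------------------------------------------------------------------
# Trees, consensus building, monophyly


def test_group_support_lookup_and_not_a_clade():
    st = SupportTree.from_newick("((A,B)87,(C,D)92,E);")
    assert group_support(st, {"A", "B"}) == 87.0
    assert group_support(st, {"C", "D"}) == 92.0
    assert group_support(st, {"A", "C"}) is NOT_A_CLADE
    assert group_support(st, {"A"}) == 100.0
    with pytest.raises(ValidationError):
        group_support(st, {"A", "B", "C", "D", "E"})
    with pytest.raises(ValidationError):
        group_support(st, {"Z"})


def test_newick_round_trip_preserves_topology_and_support():
    st = SupportTree.from_newick("(('Genus one sp','Genus two sp')88,(C,D)71,E);")
    again = SupportTree.from_newick(st.to_newick())
    assert again.topology_key() == st.topology_key()
    assert again.support == st.support


def test_majority_consensus_from_frequencies():
    leaves = ["A", "B", "C", "D", "E"]
    mask = lambda *names: sum(1 << leaves.index(n) for n in names)
    freqs = {
        mask("B", "C"): 90.0,
        mask("D", "E"): 60.0,
        mask("C", "D"): 40.0,  # below threshold, excluded
    }
    st = majority_consensus(freqs, leaves, threshold=0.5)
    assert group_support(st, {"B", "C"}) == 90.0
    assert group_support(st, {"D", "E"}) == 60.0
    assert group_support(st, {"C", "D"}) is NOT_A_CLADE
    # below-threshold splits remain queryable as frequencies
    assert st.frequency({"C", "D"}) == 40.0


def test_incompatible_splits_cannot_both_reach_majority():
    leaves = ["A", "B", "C", "D"]
    mask = lambda *names: sum(1 << leaves.index(n) for n in names)
    # A|B and B|C conflict; frequencies must sum <= 100 over replicates,
    # so both >50 cannot occur; the consensus builder assumes that.
    freqs = {mask("A", "B"): 49.0, mask("B", "C"): 49.0}
    st = majority_consensus(freqs, leaves)
    assert st.splits() == frozenset()
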