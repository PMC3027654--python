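"""Shared fixtures: toy databases and a session-scoped simulation."""

from __future__ import annotations

import pytest

from fernbarcode.alignment import Alignment
from fernbarcode.markers import Marker
from fernbarcode.pipeline import build_combined_matrix
from fernbarcode.reference_db import MarkerSequence, ReferenceDatabase, SpeciesComplex
from fernbarcode.simulate import nw_europe_ferns, simulate_reference


@pytest.fixture(scope="session")
def sim():
    """The default-preset reference simulation (fixed seed)."""
    return simulate_reference(nw_europe_ferns(seed=7))


@pytest.fixture(scope="session")
def sim_matrix(sim):
    return build_combined_matrix(sim.alignments)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced, faster simulation for identification unit tests."""
    p = nw_europe_ferns(
        seed=3,
        n_genera=3,
        species_per_genus=2,
        rbcl_length=600,
        trnlf_length=400,
        missing_marker_taxa=0,
        complexes=((0, 2),),
    )
    return simulate_reference(p)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    return build_combined_matrix(small_sim.alignments)


@pytest.fixture
def toy_db():
    """Three taxa, two markers, hand-written sequences."""
    seqs = [
        MarkerSequence("R1", "Dryopteris carthusiana", Marker.RBCL, "ACGTACGTAC"),
        MarkerSequence("R2", "Dryopteris cristata", Marker.RBCL, "ACGTACGTAC"),
        MarkerSequence("R3", "Athyrium filix-femina", Marker.RBCL, "TTGTACGACC"),
        MarkerSequence("T1", "Dryopteris carthusiana", Marker.TRNLF, "GGGTTTAA"),
    ]
    return ReferenceDatabase(sequences=seqs)


@pytest.fixture
def toy_alignment():
    return Alignment(
        ids=["S1", "S2", "S3"],
        rows=["ACGGAT", "AC--AT", "A----T"],
        marker=Marker.TRNLF,
    )
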