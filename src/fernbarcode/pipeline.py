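"""Convenience orchestration: alignments -> matrix -> gap analysis.

Thin glue over the per-stage modules so examples, tests and scripts can
run the standard two-marker workflow in a couple of calls.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .alignment import Alignment, CombinedMatrix, combine_partitions, simple_indel_code
from .distances import (
    DiscriminationReport,
    DivergenceRecord,
    discrimination_report,
    distance_matrix,
    divergence_summary,
)
from .markers import Marker
from .reference_db import ReferenceDatabase

__all__ = ["build_combined_matrix", "gap_analysis"]


def build_combined_matrix(
    alignments: Mapping[Marker, Alignment],
    indel_min_len: int = 3,
    code_indels: bool = True,
    all_taxa: Sequence[str] | None = None,
) -> CombinedMatrix:
    """Concatenate marker alignments plus their simple-indel characters.

    Markers are ordered rbcL first (the backbone locus), then trnL-F;
    indel characters are coded for every marker by default.
    """
    order = [m for m in (Marker.RBCL, Marker.TRNLF, Marker.PGIC) if m in alignments]
    alns = [alignments[m] for m in order]
    indels = [simple_indel_code(a, indel_min_len) if code_indels else [] for a in alns]
    return combine_partitions(alns, indels, all_taxa=all_taxa)


def gap_analysis(
    db: ReferenceDatabase, matrix: CombinedMatrix
) -> tuple[list[DivergenceRecord], DiscriminationReport]:
    """Barcoding-gap statistics of the (complex-collapsed) database."""
    dm = distance_matrix(matrix)
    eff = db.effective_taxon
    records = divergence_summary(dm, {sid: eff[sid] for sid in dm.ids})
    genus_of = {r.taxon: db.genus_of_label(r.taxon) for r in records}
    return records, discrimination_report(records, genus_of)
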