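"""Uncorrected P-distances and barcoding-gap statistics.

A species is considered *discriminated* by the barcode when the minimal
interspecific (nearest-neighbour) P-distance involving it exceeds its
maximal intraspecific P-distance. Distances are computed on the combined
nucleotide data of both markers with pairwise deletion: any site where
either sequence shows a gap, missing data or an ambiguity code is
excluded from the comparison for that pair only. This is the only
deletion scheme compatible with partial, per-marker query coverage.

Species complexes must be collapsed *before* this analysis: distances
between members of one complex are intra-label comparisons and never
count as interspecific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import CombinedMatrix
from .errors import ValidationError

__all__ = [
    "p_distance",
    "DistanceMatrix",
    "distance_matrix",
    "DivergenceRecord",
    "divergence_summary",
    "DiscriminationReport",
    "discrimination_report",
]

_CODE = np.full(128, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i


def _encode(row: str) -> np.ndarray:
    """A/C/G/T -> 0..3; gaps, missing and ambiguity codes -> -1."""
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def p_distance(a: str, b: str) -> tuple[float | None, int]:
    """Uncorrected P-distance between two aligned rows.

    Returns ``(distance, comparable_sites)``; the distance is ``None``
    when no site is comparable.
    """
    if len(a) != len(b):
        raise ValidationError(f"rows differ in length ({len(a)} vs {len(b)})")
    ca, cb = _encode(a), _encode(b)
    ok = (ca >= 0) & (cb >= 0)
    n = int(ok.sum())
    if n == 0:
        return None, 0
    mism = int((ca[ok] != cb[ok]).sum())
    return mism / n, n


@dataclass
class DistanceMatrix:
    """Pairwise P-distances; undefined pairs are NaN."""

    ids: list[str]
    d: np.ndarray  # (n, n) float, NaN where undefined
    comparable_sites: np.ndarray  # (n, n) int

    def pair(self, i: str, j: str) -> float:
        return float(self.d[self.ids.index(i), self.ids.index(j)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def distance_matrix(m: CombinedMatrix) -> DistanceMatrix:
    """All pairwise P-distances over the nucleotide partitions of ``m``."""
    if m.n_taxa < 2:
        raise ValidationError("need >= 2 taxa for a distance matrix")
    mask = m.nucleotide_columns()
    rows = ["".join(r[mask]) for r in m.cells]
    codes = np.stack([_encode(r) for r in rows])
    valid = codes >= 0
    n = len(rows)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ok = valid[i] & valid[i + 1 :]
        cnt = ok.sum(axis=1)
        mism = ((codes[i] != codes[i + 1 :]) & ok).sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = np.where(cnt > 0, mism / np.maximum(cnt, 1), np.nan)
        d[i, i + 1 :] = d[i + 1 :, i] = dij
        sites[i, i + 1 :] = sites[i + 1 :, i] = cnt
        sites[i, i] = int(valid[i].sum())
    return DistanceMatrix(ids=list(m.taxa), d=d, comparable_sites=sites)


@dataclass
class DivergenceRecord:
    """Per-taxon barcoding-gap record (one row of the divergence table)."""

    taxon: str
    n: int
    max_intra: float | None  # None when n < 2 (or no defined intra pair)
    min_inter: float | None  # None when no defined inter pair
    nearest_neighbours: list[str] = field(default_factory=list)
    min_inter_within_genus: float | None = None

    @property
    def ratio(self) -> float | None:
        if self.max_intra is None or self.min_inter is None:
            return None
        if self.max_intra == 0.0:
            return math.inf
        return self.min_inter / self.max_intra

    @property
    def discriminated(self) -> bool | None:
        if self.max_intra is None or self.min_inter is None:
            return None
        return self.min_inter > self.max_intra


def divergence_summary(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> list[DivergenceRecord]:
    """Per effective taxon: max intra-, min inter-label distance and NN.

    ``labels`` maps seq_id -> effective taxon label (complexes already
    collapsed). Nearest-neighbour ties are all reported, sorted.
    """
    lab = [labels[i] for i in dm.ids]
    taxa = sorted(set(lab))
    if len(taxa) < 2:
        raise ValidationError("need >= 2 effective taxa")
    idx_of = {t: [i for i, l in enumerate(lab) if l == t] for t in taxa}
    genus = {t: t.split()[0] for t in taxa}
    out = []
    for t in taxa:
        rows = idx_of[t]
        intra = [
            dm.d[i, j]
            for a, i in enumerate(rows)
            for j in rows[a + 1 :]
            if not np.isnan(dm.d[i, j])
        ]
        max_intra = max(intra) if intra else None
        min_inter: float | None = None
        nn: set[str] = set()
        min_genus: float | None = None
        for u in taxa:
            if u == t:
                continue
            vals = [
                dm.d[i, j]
                for i in rows
                for j in idx_of[u]
                if not np.isnan(dm.d[i, j])
            ]
            if not vals:
                continue
            v = min(vals)
            if min_inter is None or v < min_inter - 1e-12:
                min_inter, nn = v, {u}
            elif abs(v - min_inter) <= 1e-12:
                nn.add(u)
            if genus[u] == genus[t] and (min_genus is None or v < min_genus):
                min_genus = v
        out.append(
            DivergenceRecord(
                taxon=t,
                n=len(rows),
                max_intra=max_intra,
                min_inter=min_inter,
                nearest_neighbours=sorted(nn),
                min_inter_within_genus=min_genus,
            )
        )
    return out


@dataclass
class DiscriminationReport:
    """Aggregate barcoding-gap summary over all divergence records."""

    mean_min_inter: float
    per_genus_mean_min_inter: dict[str, float | None]
    n_multi_sequence: int
    n_discriminated: int
    points: list[tuple[float | None, float | None, str]]

    @property
    def discrimination_fraction(self) -> float | None:
        if self.n_multi_sequence == 0:
            return None
        return self.n_discriminated / self.n_multi_sequence

    def to_frame(self, records: Sequence[DivergenceRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [r.taxon for r in records],
                "N": [r.n for r in records],
                "max_intra": [r.max_intra for r in records],
                "min_inter": [r.min_inter for r in records],
                "ratio": [r.ratio for r in records],
                "nearest_neighbour": ["; ".join(r.nearest_neighbours) for r in records],
                "discriminated": [r.discriminated for r in records],
            }
        )


def discrimination_report(
    records: Sequence[DivergenceRecord],
    genus_of: Mapping[str, str] | None = None,
) -> DiscriminationReport:
    """Overall and per-genus nearest-neighbour means plus the gap verdict.

    The per-genus mean uses each taxon's minimal distance to a congener,
    so monotypic genera report ``None``.
    """
    if not records:
        raise ValidationError("no divergence records")
    if genus_of is None:
        genus_of = {r.taxon: r.taxon.split()[0] for r in records}
    inter = [r.min_inter for r in records if r.min_inter is not None]
    mean_min_inter = float(np.mean(inter)) if inter else float("nan")
    per_genus: dict[str, float | None] = {}
    for g in sorted(set(genus_of.values())):
        vals = [
            r.min_inter_within_genus
            for r in records
            if genus_of[r.taxon] == g and r.min_inter_within_genus is not None
        ]
        per_genus[g] = float(np.mean(vals)) if vals else None
    multi = [r for r in records if r.discriminated is not None]
    return DiscriminationReport(
        mean_min_inter=mean_min_inter,
        per_genus_mean_min_inter=per_genus,
        n_multi_sequence=len(multi),
        n_discriminated=sum(bool(r.discriminated) for r in multi),
        points=[(r.max_intra, r.min_inter, r.taxon) for r in records],
    )
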