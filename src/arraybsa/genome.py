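"""Genomic context of markers: genetic-window queries on gene annotation.

Physical windows are derived from genetic distance under the working
assumption that a normal chromosome spans 100 cM, so a window of c cM on
a chromosome of L bp covers ``round(c / 100 * L)`` bp.  Genes whose
nearest boundary falls within that window of a marker locus are reported
with signed distances (positive = downstream in increasing-coordinate
orientation; overlap = 0).  Coordinates are 1-based inclusive, the GFF3
convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DomainError


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a chromosome."""

    chromosome: str
    start: int
    end: int
    strand: str | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomainError(
                f"invalid interval {self.chromosome}:{self.start}..{self.end}"
            )


def cm_to_bp(cm: float, chromosome_length_bp: int) -> int:
    """Convert a genetic distance to base pairs (100 cM per chromosome)."""
    if cm < 0:
        raise DomainError("genetic distance must be nonnegative")
    if chromosome_length_bp <= 0:
        raise DomainError("chromosome length must be positive")
    if cm > 100:
        warnings.warn(
            f"{cm} cM exceeds the 100 cM chromosome assumption; "
            "window larger than the chromosome"
        )
    return int(math.floor(cm / 100.0 * chromosome_length_bp + 0.5))


def signed_distance(marker: GenomicInterval, gene: GenomicInterval) -> int:
    """Boundary-to-boundary gap, signed; 0 when the intervals overlap."""
    if gene.start > marker.end:
        return gene.start - marker.end
    if gene.end < marker.start:
        return gene.end - marker.start
    return 0


def genes_within_window(
    marker: GenomicInterval,
    genes: Sequence[GenomicInterval],
    window_bp: int,
) -> list[tuple[GenomicInterval, int]]:
    """Genes whose nearest boundary lies within window_bp of the marker.

    Results are sorted by absolute distance, ties by gene id.  Genes on
    other chromosomes are ignored; if none share the marker's chromosome
    an empty list is returned with a warning.
    """
    if window_bp < 0:
        raise DomainError("window must be nonnegative")
    same_chrom = [g for g in genes if g.chromosome == marker.chromosome]
    if genes and not same_chrom:
        warnings.warn(
            f"no annotated genes on chromosome {marker.chromosome!r}"
        )
    hits = []
    for g in same_chrom:
        d = signed_distance(marker, g)
        if abs(d) <= window_bp:
            hits.append((g, d))
    hits.sort(key=lambda gd: (abs(gd[1]), gd[0].id or ""))
    return hits


def read_gff3_genes(
    path: str | Path, feature_types: Sequence[str] = ("gene",)
) -> list[GenomicInterval]:
    """Read gene records from a GFF3 file into genomic intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GenomicInterval] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            gid = feat.attributes.get("ID", [feat.id])[0]
            name = feat.attributes.get("Name", [gid])[0]
            out.append(
                GenomicInterval(
                    chromosome=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else None,
                    id=name,
                )
            )
    return out


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome, length_bp) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chromosome", "length"])
    return {str(r.chromosome): int(r.length) for r in df.itertuples()}


def annotate_marker(
    marker: GenomicInterval,
    genes: Sequence[GenomicInterval],
    chromosome_length_bp: int,
    cm_window: float = 5.0,
) -> pd.DataFrame:
    """Genes within a genetic window of a marker, as a tidy table."""
    window = cm_to_bp(cm_window, chromosome_length_bp)
    hits = genes_within_window(marker, genes, window)
    return pd.DataFrame(
        [
            {
                "gene_id": g.id,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand or ".",
                "distance_bp": d,
                "relation": "overlap" if d == 0 else (
                    "downstream" if d > 0 else "upstream"
                ),
            }
            for g, d in hits
        ]
    )
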