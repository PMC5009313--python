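"""Flowering-response phenotyping and DNA-bulk assembly.

Day-neutrality strength is scored on a 1-4 scale in midsummer:

==== ============================================== ======
score description                                    class
==== ============================================== ======
1    flower formation on runners                     DN1 (strong day-neutral)
2    two or more recently emerged inflorescences     DN2 (intermediate)
3    fewer than two recently emerged inflorescences  DN3 (weak)
4    no flowers or fruits                            SD  (short-day)
==== ============================================== ======

Bulks here are metadata: membership lists that the simulator uses to
compute mean allele dosage per bulk.  Actual DNA pooling is a wet-lab
step outside this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError

FLOWERING_CLASSES = ("DN1", "DN2", "DN3", "SD")

_SCORE_TO_CLASS = {1: "DN1", 2: "DN2", 3: "DN3", 4: "SD"}

#: Minimum plants per class recommended for bulked segregant analysis.
RECOMMENDED_BULK_SIZE = 10


@dataclass
class PhenotypeRecord:
    """One scored F1 plant; ``dosage`` is filled by the simulator."""

    plant_id: str
    cross_id: str
    flowering_score: int
    dosage: float | None = None

    @property
    def flowering_class(self) -> str:
        return score_to_class(self.flowering_score)


@dataclass
class Bulk:
    """A DNA bulk: all members share one flowering class."""

    bulk_id: str
    members: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def score_to_class(score: int) -> str:
    """Map a 1-4 flowering score to its day-neutrality class."""
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise DomainError(f"flowering score must be an integer, got {score!r}")
    if score not in _SCORE_TO_CLASS:
        raise DomainError(f"flowering score {score} outside 1-4")
    return _SCORE_TO_CLASS[score]


def assemble_bulks(
    records: Sequence[PhenotypeRecord],
    min_recommended: int = RECOMMENDED_BULK_SIZE,
) -> tuple[dict[str, Bulk], pd.DataFrame]:
    """Partition classified plants into the four predefined bulks.

    Returns one :class:`Bulk` per non-empty class plus a per-cross x
    per-class count table (with a Total row).  Bulks smaller than
    ``min_recommended`` carry a warning; every record lands in exactly one
    bulk, so bulk sizes sum to the number of records.
    """
    if not records:
        warnings.warn("no phenotype records; returning empty bulk set")
        return {}, pd.DataFrame(columns=list(FLOWERING_CLASSES))
    bulks: dict[str, Bulk] = {}
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        cls = rec.flowering_class
        bulks.setdefault(cls, Bulk(bulk_id=cls)).members.append(rec.plant_id)
        counts.setdefault(rec.cross_id, dict.fromkeys(FLOWERING_CLASSES, 0))
        counts[rec.cross_id][cls] += 1
    for cls, bulk in bulks.items():
        if bulk.size < min_recommended:
            msg = (
                f"bulk {cls} has only {bulk.size} plant(s); "
                f"at least {min_recommended} are recommended for BSA"
            )
            bulk.warnings.append(msg)
            warnings.warn(msg)
    empty = [c for c in FLOWERING_CLASSES if c not in bulks]
    if empty:
        warnings.warn(f"no plants in class(es): {', '.join(empty)}")
    table = pd.DataFrame(counts).T.reindex(columns=list(FLOWERING_CLASSES))
    table.loc["Total"] = table.sum()
    table.index.name = "cross_id"
    return bulks, table


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype CSV/TSV with plant_id, cross_id, flowering_score."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"plant_id", "cross_id", "flowering_score"}
    if not required.issubset(df.columns):
        raise DomainError(
            f"phenotype table {path} must have columns {sorted(required)}"
        )
    return [
        PhenotypeRecord(
            plant_id=str(r.plant_id),
            cross_id=str(r.cross_id),
            flowering_score=int(r.flowering_score),
        )
        for r in df.itertuples()
    ]


def bulk_summary_frame(bulks: dict[str, Bulk]) -> pd.DataFrame:
    rows = [
        {
            "bulk_id": b.bulk_id,
            "size": b.size,
            "warnings": "; ".join(b.warnings),
        }
        for b in bulks.values()
    ]
    return pd.DataFrame(rows)
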