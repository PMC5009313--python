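"""Data model and file I/O for quantified array scans.

The measurement unit throughout the package is the signal-to-noise ratio
(SNR) of one printed array feature in one hybridization.  This module
defines the containers that carry those values together with their
replicate structure, and the readers/writers for the plain-text formats
the pipeline consumes:

* a *feature annotation* table describing the printed layout (feature id,
  category, grid position),
* per-hybridization *scan tables* (GenePix-results-like tab-delimited
  exports with signal mean, background mean, background SD and a manual
  quality flag),
* a *sample sheet* mapping hybridizations to targets (bulks, tester pool,
  driver pool) and replicate indices,
* the *fingerprint* matrix (one normalized value per feature per bulk)
  that all downstream statistics run on.

Feature order is always the printed layout order, so repeated runs produce
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    AnnotationMismatchError,
    DuplicateReplicateError,
    FormatError,
)

FEATURE_CATEGORIES = (
    "subtracted",
    "positive_control",
    "negative_control",
    "printing_control",
    "spike_in",
)

#: Canonical hybridization targets.  Arbitrary custom targets are allowed;
#: these are the ones the bulked-segregant design uses.
KNOWN_TARGETS = ("DN1", "DN2", "DN3", "SD", "tester_pool", "driver_pool")

#: Default header-based column map for scan tables (GenePix-results-like
#: dialect; the quantification software's exact export schema is
#: configurable because vendors differ).
DEFAULT_SCAN_COLUMNS: Mapping[str, str] = {
    "feature_id": "ID",
    "signal_mean": "F Mean",
    "background_mean": "B Mean",
    "background_sd": "B SD",
    "flag": "Flags",
}

#: Tokens accepted for each manual-flag state (case-insensitive).
DEFAULT_FLAG_VOCABULARY: Mapping[str, str] = {
    "good": "good",
    "0": "good",
    "": "good",
    "ok": "good",
    "bad": "bad",
    "-100": "bad",
    "empty": "empty",
    "-75": "empty",
    "absent": "empty",
}


@dataclass(frozen=True)
class FeatureAnnotation:
    """One printed array feature: identity, category and grid position."""

    feature_id: str
    category: str
    grid_position: tuple[int, int, int] = (0, 0, 0)
    sequence_accession: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise FormatError(
                f"unknown feature category {self.category!r} for "
                f"{self.feature_id!r}; expected one of {FEATURE_CATEGORIES}"
            )


@dataclass(frozen=True)
class SpotMeasurement:
    """Quantified fluorescence of one spot in one hybridization."""

    feature_id: str
    signal_mean: float
    background_mean: float
    background_sd: float
    manual_flag: str = "good"

    def __post_init__(self) -> None:
        if self.signal_mean < 0 or self.background_mean < 0:
            raise FormatError(
                f"negative fluorescence for {self.feature_id!r}"
            )
        if self.background_sd < 0:
            raise FormatError(
                f"negative background SD for {self.feature_id!r}"
            )
        if self.manual_flag not in ("good", "bad", "empty"):
            raise FormatError(
                f"flag must be good/bad/empty, got {self.manual_flag!r}"
            )


@dataclass
class Hybridization:
    """One slide hybridization: a target, replicate indices and its spots.

    The study design is 2 biological x 6 technical replicates per bulk,
    i.e. 12 data points per feature, but any positive replicate counts are
    accepted.
    """

    hybridization_id: str
    target: str
    biological_replicate: int
    technical_replicate: int
    spots: list[SpotMeasurement] = field(default_factory=list)
    scan_file: str | None = None

    @property
    def replicate_key(self) -> tuple[str, int, int]:
        return (self.target, self.biological_replicate, self.technical_replicate)


@dataclass
class FeatureSignalMatrix:
    """SNR values for every (feature, hybridization) cell.

    Attributes
    ----------
    values : pandas.DataFrame
        SNR, rows = feature ids in layout order, columns = hybridization ids.
    mask : pandas.DataFrame of bool
        True marks a cell excluded from all statistics.
    flags : pandas.DataFrame of str
        Manual flag per cell (``good``/``bad``/``empty``).
    annotation : pandas.DataFrame
        Indexed by feature id; at least a ``category`` column.
    design : pandas.DataFrame
        Indexed by hybridization id; ``target``, ``biological_replicate``,
        ``technical_replicate`` columns.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    flags: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not (
            self.values.shape == self.mask.shape == self.flags.shape
        ):
            raise AlignmentError("values/mask/flags shapes differ")
        if list(self.values.index) != list(self.annotation.index):
            raise AlignmentError("feature order differs from annotation")
        if list(self.values.columns) != list(self.design.index):
            raise AlignmentError("hybridization order differs from design")

    def copy(self) -> "FeatureSignalMatrix":
        return FeatureSignalMatrix(
            self.values.copy(),
            self.mask.copy(),
            self.flags.copy(),
            self.annotation.copy(),
            self.design.copy(),
        )

    def features_of_category(self, category: str) -> list[str]:
        return list(self.annotation.index[self.annotation["category"] == category])

    def columns_for(self, target: str) -> list[str]:
        return list(self.design.index[self.design["target"] == target])


@dataclass
class FeatureFingerprint:
    """One normalized SNR per retained feature for one bulk.

    ``values`` is indexed by feature id; missing features (masked in every
    replicate) carry NaN.  ``provenance`` records how many technical and
    biological replicates were combined.
    """

    bulk_id: str
    values: pd.Series
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_annotation(path: str | Path) -> list[FeatureAnnotation]:
    """Read a feature-annotation TSV (feature_id, category[, block,row,column])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "category"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation file {path} must have columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        grid = (
            int(row.get("block", 0) or 0),
            int(row.get("row", 0) or 0),
            int(row.get("column", 0) or 0),
        )
        out.append(
            FeatureAnnotation(
                feature_id=row["feature_id"],
                category=row["category"],
                grid_position=grid,
                sequence_accession=row.get("sequence_accession") or None,
            )
        )
    ids = [a.feature_id for a in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate feature ids in annotation file {path}")
    return out


def write_feature_annotation(layout: Sequence[FeatureAnnotation], path: str | Path) -> None:
    rows = [
        {
            "feature_id": a.feature_id,
            "category": a.category,
            "block": a.grid_position[0],
            "row": a.grid_position[1],
            "column": a.grid_position[2],
        }
        for a in layout
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotation_frame(layout: Sequence[FeatureAnnotation]) -> pd.DataFrame:
    """Layout as a DataFrame indexed by feature id, in printed order."""
    df = pd.DataFrame(
        {
            "category": [a.category for a in layout],
            "block": [a.grid_position[0] for a in layout],
            "row": [a.grid_position[1] for a in layout],
            "column": [a.grid_position[2] for a in layout],
        },
        index=pd.Index([a.feature_id for a in layout], name="feature_id"),
    )
    return df


def _normalize_flag(token: object, vocabulary: Mapping[str, str]) -> str:
    key = str(token).strip().lower()
    if key in ("nan", "none"):
        key = ""
    if key not in vocabulary:
        raise FormatError(f"unrecognized manual flag token {token!r}")
    return vocabulary[key]


def read_scan_table(
    path: str | Path,
    layout: Sequence[FeatureAnnotation],
    *,
    hybridization_id: str | None = None,
    target: str = "custom",
    biological_replicate: int = 1,
    technical_replicate: int = 1,
    column_map: Mapping[str, str] = DEFAULT_SCAN_COLUMNS,
    flag_vocabulary: Mapping[str, str] = DEFAULT_FLAG_VOCABULARY,
) -> Hybridization:
    """Parse one quantified scan export into a :class:`Hybridization`.

    The file must be tab-delimited with a header naming at least the five
    mapped columns.  Feature ids not present in ``layout`` are rejected;
    features missing from the file raise as well, so one hybridization
    always carries exactly one spot per printed feature.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise FormatError(f"scan table {path} missing column(s) {missing}")
    layout_ids = [a.feature_id for a in layout]
    known = set(layout_ids)
    spots: dict[str, SpotMeasurement] = {}
    for _, row in df.iterrows():
        fid = str(row[column_map["feature_id"]])
        if fid not in known:
            raise AnnotationMismatchError(
                f"feature {fid!r} in {path} absent from array layout"
            )
        spots[fid] = SpotMeasurement(
            feature_id=fid,
            signal_mean=float(row[column_map["signal_mean"]]),
            background_mean=float(row[column_map["background_mean"]]),
            background_sd=float(row[column_map["background_sd"]]),
            manual_flag=_normalize_flag(row[column_map["flag"]], flag_vocabulary),
        )
    absent = [fid for fid in layout_ids if fid not in spots]
    if absent:
        raise AnnotationMismatchError(
            f"scan table {path} lacks printed feature(s) {absent[:5]}"
        )
    return Hybridization(
        hybridization_id=hybridization_id or path.stem,
        target=target,
        biological_replicate=biological_replicate,
        technical_replicate=technical_replicate,
        spots=[spots[fid] for fid in layout_ids],
        scan_file=str(path),
    )


def write_scan_table(
    hyb: Hybridization,
    path: str | Path,
    column_map: Mapping[str, str] = DEFAULT_SCAN_COLUMNS,
) -> None:
    flag_token = {"good": "0", "bad": "-100", "empty": "-75"}
    rows = [
        {
            column_map["feature_id"]: s.feature_id,
            column_map["signal_mean"]: f"{s.signal_mean:.6g}",
            column_map["background_mean"]: f"{s.background_mean:.6g}",
            column_map["background_sd"]: f"{s.background_sd:.6g}",
            column_map["flag"]: flag_token[s.manual_flag],
        }
        for s in hyb.spots
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


SAMPLE_SHEET_COLUMNS = (
    "hybridization_id",
    "target",
    "biological_replicate",
    "technical_replicate",
    "scan_file",
)


def read_sample_sheet(path: str | Path) -> list[Hybridization]:
    """Read the hybridization design (CSV or TSV, sniffed).

    Returns descriptors only; scan files are checked for existence lazily
    when the tables are actually read.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"sample sheet {path} is empty")
        return []
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing column(s) {missing}")
    out: list[Hybridization] = []
    seen: set[tuple[str, int, int]] = set()
    for _, row in df.iterrows():
        h = Hybridization(
            hybridization_id=row["hybridization_id"],
            target=row["target"],
            biological_replicate=int(row["biological_replicate"]),
            technical_replicate=int(row["technical_replicate"]),
            scan_file=row["scan_file"],
        )
        if h.replicate_key in seen:
            raise DuplicateReplicateError(
                f"duplicate replicate key {h.replicate_key} in {path}"
            )
        seen.add(h.replicate_key)
        out.append(h)
    if not out:
        warnings.warn(f"sample sheet {path} contains no hybridizations")
    return out


def write_sample_sheet(hybs: Sequence[Hybridization], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "hybridization_id": h.hybridization_id,
                "target": h.target,
                "biological_replicate": h.biological_replicate,
                "technical_replicate": h.technical_replicate,
                "scan_file": h.scan_file or "",
            }
            for h in hybs
        ]
    ).to_csv(path, sep="\t", index=False)


def write_fingerprint_table(
    fingerprints: Sequence[FeatureFingerprint], path: str | Path
) -> None:
    """Write fingerprints as a TSV matrix (rows = features, cols = bulks).

    All fingerprints must share one feature set; values round-trip through
    :func:`read_fingerprint_table` at 12 significant digits.
    """
    if not fingerprints:
        raise AlignmentError("no fingerprints to write")
    index = fingerprints[0].values.index
    for fp in fingerprints[1:]:
        if not fp.values.index.equals(index):
            raise AlignmentError(
                f"bulk {fp.bulk_id!r} has a different feature set"
            )
    df = pd.DataFrame(
        {fp.bulk_id: fp.values for fp in fingerprints}, index=index
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_fingerprint_table(path: str | Path) -> list[FeatureFingerprint]:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return [FeatureFingerprint(bulk_id=c, values=df[c]) for c in df.columns]


def fingerprint_frame(fingerprints: Sequence[FeatureFingerprint]) -> pd.DataFrame:
    """Fingerprints as one DataFrame (features x bulks)."""
    return pd.DataFrame({fp.bulk_id: fp.values for fp in fingerprints})
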