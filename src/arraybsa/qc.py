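"""Quality control, spike-in normalization and fingerprint construction.

The processing order mirrors standard subtracted-array practice:

1. compute the signal-to-noise ratio (SNR) of every spot,
2. mask manually flagged cells and negative controls,
3. keep only features whose SNR exceeds a detection threshold (default 7)
   in strictly more than half of the technical replicates of at least one
   (bulk, biological-replicate) group,
4. rescale every hybridization so its spike-in control matches the grand
   mean across hybridizations (removes slide-to-slide systematic scale),
5. average technical replicates within each biological replicate, then
   average biological replicates with equal weight, giving one fingerprint
   value per feature per bulk.

A separate helper quantifies subtraction efficiency from a driver-pool
hybridization: the percentage of printed subtracted features that do *not*
hybridize with the driver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBackgroundError,
    DegenerateDataError,
    InsufficientDataError,
    NormalizationError,
)
from .io import (
    FeatureAnnotation,
    FeatureFingerprint,
    FeatureSignalMatrix,
    Hybridization,
    SpotMeasurement,
    annotation_frame,
)


@dataclass
class QCConfig:
    """Detection-filter settings.

    ``snr_threshold`` is strict (SNR must be > threshold), and
    ``min_pass_fraction`` is the strict "more than half of the technical
    replicates" rule: with six technical replicates, 4 passes suffice and
    3 do not.
    """

    snr_threshold: float = 7.0
    min_pass_fraction: float = 0.5
    detection_threshold_driver: float | None = None

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")
        if not 0 < self.min_pass_fraction < 1:
            raise ValueError("min_pass_fraction must lie in (0, 1)")

    @property
    def driver_threshold(self) -> float:
        if self.detection_threshold_driver is None:
            return self.snr_threshold
        return self.detection_threshold_driver


def compute_snr(spot: SpotMeasurement) -> float:
    """(signal mean - background mean) / background SD.

    The conventional scanner definition; may be negative for
    sub-background spots.
    """
    if spot.background_sd == 0:
        raise DegenerateBackgroundError(
            f"background SD is zero for {spot.feature_id!r}"
        )
    return (spot.signal_mean - spot.background_mean) / spot.background_sd


def build_signal_matrix(
    hybridizations: Sequence[Hybridization],
    layout: Sequence[FeatureAnnotation],
) -> FeatureSignalMatrix:
    """Assemble SNR values from loaded hybridizations into a matrix."""
    ann = annotation_frame(layout)
    hyb_ids = [h.hybridization_id for h in hybridizations]
    values = np.empty((len(ann), len(hyb_ids)))
    flags = np.empty((len(ann), len(hyb_ids)), dtype=object)
    feat_pos = {fid: i for i, fid in enumerate(ann.index)}
    for j, h in enumerate(hybridizations):
        for spot in h.spots:
            i = feat_pos[spot.feature_id]
            values[i, j] = compute_snr(spot)
            flags[i, j] = spot.manual_flag
    design = pd.DataFrame(
        {
            "target": [h.target for h in hybridizations],
            "biological_replicate": [h.biological_replicate for h in hybridizations],
            "technical_replicate": [h.technical_replicate for h in hybridizations],
        },
        index=pd.Index(hyb_ids, name="hybridization_id"),
    )
    return FeatureSignalMatrix(
        values=pd.DataFrame(values, index=ann.index, columns=hyb_ids),
        mask=pd.DataFrame(False, index=ann.index, columns=hyb_ids),
        flags=pd.DataFrame(flags, index=ann.index, columns=hyb_ids),
        annotation=ann,
        design=design,
    )


def matrix_from_values(
    values: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
) -> FeatureSignalMatrix:
    """Wrap a plain SNR table (e.g. simulated) into a signal matrix."""
    return FeatureSignalMatrix(
        values=values,
        mask=pd.DataFrame(False, index=values.index, columns=values.columns),
        flags=pd.DataFrame("good", index=values.index, columns=values.columns),
        annotation=annotation,
        design=design,
    )


def apply_qc_flags(matrix: FeatureSignalMatrix) -> FeatureSignalMatrix:
    """Mask bad/empty cells and mask negative controls everywhere.

    Positive and printing controls stay unmasked (they are excluded from
    marker statistics by category, not by mask).
    """
    out = matrix.copy()
    out.mask |= out.flags.isin(["bad", "empty"])
    neg = out.annotation["category"] == "negative_control"
    out.mask.loc[neg, :] = True
    return out


def snr_detection_filter(
    matrix: FeatureSignalMatrix,
    config: QCConfig | None = None,
    targets: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split subtracted features into (retained, dropped) by detection.

    A feature is retained when, in at least one (target, biological
    replicate) group, strictly more than ``min_pass_fraction`` of its
    unmasked technical replicates have SNR strictly above the threshold.
    The any-group aggregation is deliberate: a feature detected in one
    bulk but absent in another is exactly a candidate marker.
    """
    config = config or QCConfig()
    subtracted = matrix.features_of_category("subtracted")
    design = matrix.design
    if targets is not None:
        design = design[design["target"].isin(list(targets))]
    groups = design.groupby(["target", "biological_replicate"], sort=True)
    passed = pd.Series(False, index=subtracted)
    any_unmasked = pd.Series(False, index=subtracted)
    for _, cols in groups.groups.items():
        vals = matrix.values.loc[subtracted, cols]
        unmasked = ~matrix.mask.loc[subtracted, cols]
        n_unmasked = unmasked.sum(axis=1)
        n_pass = ((vals > config.snr_threshold) & unmasked).sum(axis=1)
        any_unmasked |= n_unmasked > 0
        passed |= n_pass > config.min_pass_fraction * n_unmasked
    # a feature never pass in a group with zero unmasked replicates
    never_measured = [f for f in subtracted if not any_unmasked[f]]
    if never_measured:
        warnings.warn(
            f"{len(never_measured)} feature(s) have no unmasked replicate "
            "anywhere and were dropped"
        )
    retained = [f for f in subtracted if passed[f]]
    dropped = [f for f in subtracted if not passed[f]]
    return retained, dropped


def spike_in_normalize(matrix: FeatureSignalMatrix) -> FeatureSignalMatrix:
    """Rescale each hybridization by its spike-in control.

    Every hybridization's SNRs are multiplied by
    ``reference / mean(spike-in SNR in that hybridization)`` where the
    reference is the grand mean of the per-hybridization spike-in means.
    Afterwards every hybridization carries the same spike-in level, so the
    operation is idempotent.
    """
    spike = matrix.features_of_category("spike_in")
    if not spike:
        raise NormalizationError("layout has no spike-in feature")
    per_hyb = []
    for hyb in matrix.values.columns:
        vals = matrix.values.loc[spike, hyb]
        ok = ~matrix.mask.loc[spike, hyb]
        if not ok.any():
            raise NormalizationError(
                f"spike-in masked in hybridization {hyb!r}"
            )
        m = float(vals[ok].mean())
        if m <= 0:
            raise NormalizationError(
                f"non-positive spike-in SNR in hybridization {hyb!r}"
            )
        per_hyb.append(m)
    per_hyb_arr = np.asarray(per_hyb)
    reference = per_hyb_arr.mean()
    out = matrix.copy()
    out.values = out.values * (reference / per_hyb_arr)
    return out


def build_fingerprint(
    matrix: FeatureSignalMatrix,
    bulk_id: str,
    features: Sequence[str] | None = None,
) -> FeatureFingerprint:
    """Average technical then biological replicates of one bulk.

    Per feature: the mean over unmasked technical replicates within each
    biological replicate, then the equal-weight mean over biological
    replicates.  Features masked in every replicate get NaN.
    """
    cols = matrix.columns_for(bulk_id)
    if not cols:
        raise InsufficientDataError(f"no hybridizations for bulk {bulk_id!r}")
    if features is None:
        features = list(matrix.values.index)
    design = matrix.design.loc[cols]
    bio_means = []
    for _, bio_cols in design.groupby("biological_replicate").groups.items():
        vals = matrix.values.loc[features, bio_cols].where(
            ~matrix.mask.loc[features, bio_cols]
        )
        bio_means.append(vals.mean(axis=1, skipna=True))
    stacked = pd.concat(bio_means, axis=1)
    fp = stacked.mean(axis=1, skipna=True)
    return FeatureFingerprint(
        bulk_id=bulk_id,
        values=fp,
        provenance={
            "n_biological_replicates": int(design["biological_replicate"].nunique()),
            "n_technical_replicates": int(
                design.groupby("biological_replicate").size().max()
            ),
            "n_missing_features": int(fp.isna().sum()),
        },
    )


@dataclass
class SubtractionEfficiency:
    """Outcome of the tester/driver validation of a subtracted array."""

    n_detected: int
    n_total: int
    efficiency_percent: float
    efficiency_percent_rounded: int
    detected_ids: list[str] = field(default_factory=list)


def subtraction_efficiency(
    driver_fingerprint: FeatureFingerprint | pd.Series,
    layout: Sequence[FeatureAnnotation] | None = None,
    threshold: float = 7.0,
) -> SubtractionEfficiency:
    """Fraction of printed subtracted features invisible to the driver pool.

    A feature "hybridizes with the driver" when its driver fingerprint
    exceeds the detection threshold; those features represent incompletely
    subtracted fragments and are listed for removal.  Efficiency is
    ``100 * (n_total - n_detected) / n_total``, reported exactly and
    rounded half-up to an integer percent.
    """
    values = (
        driver_fingerprint.values
        if isinstance(driver_fingerprint, FeatureFingerprint)
        else driver_fingerprint
    )
    if layout is not None:
        ids = [a.feature_id for a in layout if a.category == "subtracted"]
        values = values.loc[ids]
    n_total = int(values.size)
    if n_total == 0:
        raise DegenerateDataError("no subtracted features in layout")
    detected = values[values > threshold]
    n_detected = int(detected.size)
    pct = 100.0 * (n_total - n_detected) / n_total
    return SubtractionEfficiency(
        n_detected=n_detected,
        n_total=n_total,
        efficiency_percent=pct,
        efficiency_percent_rounded=int(math.floor(pct + 0.5)),
        detected_ids=sorted(detected.index),
    )


def qc_report(
    matrix: FeatureSignalMatrix,
    retained: Sequence[str],
    dropped: Sequence[str],
) -> pd.DataFrame:
    """Per-feature QC outcome table (feature, category, status, reason)."""
    rows = []
    retained_set = set(retained)
    for fid in matrix.values.index:
        cat = matrix.annotation.loc[fid, "category"]
        if cat != "subtracted":
            status, reason = "control", cat
        elif fid in retained_set:
            status, reason = "retained", "detected"
        else:
            status, reason = "dropped", "below detection threshold"
        rows.append(
            {"feature_id": fid, "category": cat, "status": status, "reason": reason}
        )
    return pd.DataFrame(rows)
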