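"""Bundled reference data from a strawberry day-neutrality BSA experiment.

A subtracted diversity array with 290 printed strawberry-enriched
features was hybridized with four DNA bulks (DN1, DN2, DN3, SD) built
from F1 progeny of day-neutral x short-day crosses.  These tables carry
the published summary of that experiment — progeny counts per cross and
flowering class, driver-pool validation, the stepwise-DFA feature
selections, the Fisher's-ratio top-10 rankings, and per-feature group
statistics with t-tests — and serve as worked-example fixtures: the raw
hybridization values are not redistributed here, but the group means and
SDs are sufficient to reconstruct the t statistics exactly via the
exact-moment sampler in :mod:`arraybsa.simulate`.
"""

from __future__ import annotations

import pandas as pd

#: Progeny counts per cross and flowering class (DN x SD and two DN x DN
#: crosses; 49 plants total, bulk sizes 2/19/18/10).
CROSS_COUNTS: dict[str, dict[str, int]] = {
    "01-061-311 x Juliette": {"DN1": 0, "DN2": 6, "DN3": 6, "SD": 10},
    "01-061-311 x 05-069-63": {"DN1": 1, "DN2": 8, "DN3": 7, "SD": 0},
    "01-069-311 x 05-069-194": {"DN1": 1, "DN2": 5, "DN3": 5, "SD": 0},
}

#: Driver-pool validation: printed subtracted features and the three that
#: still hybridized with the driver (non-angiosperm) pool.
N_PRINTED_SUBTRACTED = 290
DRIVER_DETECTED = ("FaP1G12", "FaP4D5", "FaP4C2")

#: Stepwise-DFA feature selections per bulk comparison.
DFA_SELECTED: dict[str, tuple[str, ...]] = {
    "DN1-SD": ("FaP2E11", "FaP3F4", "FaP2D6", "FaP2B4", "FaP2D12", "FaP2G4"),
    "DN2-SD": ("FaP2E2", "FaP3H2", "FaP3E5", "FaP1E10", "FaP3E7", "FaP2E9"),
    "DN3-SD": ("FaP1A1", "FaP2A2", "FaP3D4", "FaP3B3", "FaP3B10", "FaP2E9"),
}

#: Published training/test percent-correct for the reciprocal
#: biological-replicate validation.
CLASSIFICATION_ACCURACY: dict[str, dict[str, float]] = {
    "DN1-SD": {"training": 100.0, "test": 83.3},
    "DN2-SD": {"training": 100.0, "test": 66.7},
    "DN3-SD": {"training": 100.0, "test": 83.3},
}

#: Fisher's-ratio top-10 rankings (rank order preserved).
FISHER_TOP10: dict[str, tuple[str, ...]] = {
    "DN1-SD": (
        "FaP1G3", "FaP2G5", "FaP2E11", "FaP1B10", "FaP3F7",
        "FaP1B9", "FaP2E4", "FaP1G1", "FaP1C4", "FaP1H8",
    ),
    "DN2-SD": (
        "FaP1A1", "FaP4A8", "FaP2D3", "FaP4D1", "FaP2F11",
        "FaP2G5", "FaP1G7", "FaP3B1", "FaP2C11", "FaP3F7",
    ),
    "DN3-SD": (
        "FaP1A1", "FaP2G12", "FaP3F7", "FaP2G11", "FaP3A5",
        "FaP4B1", "FaP2D3", "FaP1C8", "FaP2F5", "FaP3G6",
    ),
}

#: Group statistics and t-tests for the DFA-selected features.
#: Means/SDs are normalized SNR over 12 values per bulk (2 biological x 6
#: technical replicates).  ``df`` is as printed: 22 for pooled-variance
#: rows, one decimal for Welch rows.  ``significance``: '**' p<0.01,
#: '*' p<0.05, 'ns' otherwise.
GROUP_TTEST_ROWS: tuple[dict, ...] = (
    {"comparison": "DN1-SD", "feature_id": "FaP2E11", "mean_dn": 743.53, "sd_dn": 252.08, "mean_sd": 259.98, "sd_sd": 148.78, "t": 5.723, "df": 22.0, "variant": "pooled", "significance": "**"},
    {"comparison": "DN1-SD", "feature_id": "FaP3F4", "mean_dn": 133.90, "sd_dn": 71.34, "mean_sd": 210.06, "sd_sd": 191.96, "t": 1.288, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN1-SD", "feature_id": "FaP2D6", "mean_dn": 188.96, "sd_dn": 119.83, "mean_sd": 337.52, "sd_sd": 250.68, "t": 1.852, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN1-SD", "feature_id": "FaP2B4", "mean_dn": 74.95, "sd_dn": 53.71, "mean_sd": 117.72, "sd_sd": 89.99, "t": 1.414, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN1-SD", "feature_id": "FaP2D12", "mean_dn": 223.23, "sd_dn": 146.47, "mean_sd": 433.96, "sd_sd": 143.61, "t": -3.559, "df": 22.0, "variant": "pooled", "significance": "**"},
    {"comparison": "DN1-SD", "feature_id": "FaP2G4", "mean_dn": 161.45, "sd_dn": 69.35, "mean_sd": 105.77, "sd_sd": 65.22, "t": -2.026, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN2-SD", "feature_id": "FaP2E2", "mean_dn": 85.71, "sd_dn": 48.94, "mean_sd": 232.53, "sd_sd": 172.45, "t": -2.837, "df": 12.8, "variant": "welch", "significance": "*"},
    {"comparison": "DN2-SD", "feature_id": "FaP3H2", "mean_dn": 545.45, "sd_dn": 243.59, "mean_sd": 368.65, "sd_sd": 322.27, "t": -1.516, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN2-SD", "feature_id": "FaP3E5", "mean_dn": 104.54, "sd_dn": 41.97, "mean_sd": 131.37, "sd_sd": 108.95, "t": 0.796, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN2-SD", "feature_id": "FaP1E10", "mean_dn": 200.32, "sd_dn": 118.04, "mean_sd": 179.75, "sd_sd": 116.79, "t": -0.429, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN2-SD", "feature_id": "FaP3E7", "mean_dn": 202.05, "sd_dn": 85.17, "mean_sd": 296.19, "sd_sd": 232.35, "t": 1.318, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN2-SD", "feature_id": "FaP2E9", "mean_dn": 40.82, "sd_dn": 25.66, "mean_sd": 67.17, "sd_sd": 30.59, "t": 2.287, "df": 22.0, "variant": "pooled", "significance": "*"},
    {"comparison": "DN3-SD", "feature_id": "FaP1A1", "mean_dn": 0.27, "sd_dn": 0.35, "mean_sd": 713.71, "sd_sd": 499.52, "t": -4.948, "df": 11.0, "variant": "welch", "significance": "**"},
    {"comparison": "DN3-SD", "feature_id": "FaP2A2", "mean_dn": 253.29, "sd_dn": 117.27, "mean_sd": 354.78, "sd_sd": 287.26, "t": 1.133, "df": 14.6, "variant": "welch", "significance": "ns"},
    {"comparison": "DN3-SD", "feature_id": "FaP3D4", "mean_dn": 133.98, "sd_dn": 82.77, "mean_sd": 137.14, "sd_sd": 70.63, "t": 0.101, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN3-SD", "feature_id": "FaP3B3", "mean_dn": 227.30, "sd_dn": 136.36, "mean_sd": 300.66, "sd_sd": 237.70, "t": -0.927, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN3-SD", "feature_id": "FaP3B10", "mean_dn": 38.87, "sd_dn": 18.90, "mean_sd": 49.46, "sd_sd": 23.85, "t": 1.206, "df": 22.0, "variant": "pooled", "significance": "ns"},
    {"comparison": "DN3-SD", "feature_id": "FaP2E9", "mean_dn": 46.73, "sd_dn": 19.48, "mean_sd": 67.17, "sd_sd": 30.59, "t": 1.953, "df": 22.0, "variant": "pooled", "significance": "ns"},
)

#: Replicate design of the reference experiment.
N_BIOLOGICAL_REPLICATES = 2
N_TECHNICAL_REPLICATES = 6

#: Features significant at p < 0.05 (the t-test circle of the reference
#: three-way Venn analysis).
T_SIGNIFICANT = ("FaP1A1", "FaP2E11", "FaP2D12", "FaP2E2", "FaP2E9")


def group_ttest_frame() -> pd.DataFrame:
    """The per-feature group statistics / t-test table as a DataFrame."""
    return pd.DataFrame(list(GROUP_TTEST_ROWS))


def cross_count_records():
    """Expand the per-cross counts into individual phenotype records."""
    from .phenotype import PhenotypeRecord

    class_to_score = {"DN1": 1, "DN2": 2, "DN3": 3, "SD": 4}
    records = []
    k = 0
    for cross, counts in CROSS_COUNTS.items():
        for cls, n in counts.items():
            for _ in range(n):
                k += 1
                records.append(
                    PhenotypeRecord(
                        plant_id=f"plant{k:03d}",
                        cross_id=cross,
                        flowering_score=class_to_score[cls],
                    )
                )
    return records
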