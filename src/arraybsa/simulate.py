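"""Synthetic data with the statistical structure the pipeline assumes.

Three generators are provided:

* **exact-moment fixtures** — n values with a prescribed sample mean and
  SD (affine transform of a seeded normal draw), used to reconstruct the
  reference study's t statistics from its printed group statistics;
* an **allele-dosage F1 population** — in an octoploid, each offspring
  receives two gametes of ``ploidy/2`` chromosomes, each carrying the
  trait allele with probability ``parent_dosage/ploidy``; offspring
  dosage (0..8) maps to the 1-4 flowering score through configurable
  thresholds.  The dosage model quantifies the hypothesis that flowering
  strength tracks the copy number of a marker-linked allele; its
  thresholds are parameters, not biological claims;
* a **bulk-hybridization signal model** — the SNR of feature f in a
  hybridization of bulk b is

      SNR(f, h) = mu_f * (1 + beta * D_b * [f is the planted marker])
                  * exp(eps_fh) * g_h

  with per-feature baselines mu_f (log-normal), mean bulk allele dosage
  D_b, multiplicative log-normal cell noise eps (sd sigma, default 0.35)
  and a per-slide scale distortion g_h that spike-in normalization must
  undo.  With sigma = 0 and beta chosen so that
  (1 + beta*D_DN1) / (1 + beta*D_SD) = 3, the planted feature's
  normalized DN1/SD fingerprint ratio is exactly 3, matching the
  reference marker's reported threefold signal difference.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from . import datasets
from .io import (
    FeatureAnnotation,
    FeatureSignalMatrix,
    Hybridization,
    SpotMeasurement,
    annotation_frame,
    write_feature_annotation,
    write_sample_sheet,
    write_scan_table,
)
from .phenotype import PhenotypeRecord, assemble_bulks
from .qc import matrix_from_values

BULKS = ("DN1", "DN2", "DN3", "SD")


# ---------------------------------------------------------------------------
# exact-moment fixtures
# ---------------------------------------------------------------------------

def exact_moment_sample(
    n: int,
    target_mean: float,
    target_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n values whose sample mean and SD (ddof=1) equal the targets.

    A seeded standard-normal draw is centered, scaled to unit sample SD
    and affinely transformed; the moments are exact to floating point,
    so any statistic that depends on the data only through (mean, SD, n)
    — pooled and Welch t, Fisher's ratio — is reproduced exactly.
    """
    if target_sd < 0:
        raise DomainError("target SD must be nonnegative")
    if n < 1 or (n < 2 and target_sd > 0):
        raise InsufficientDataError(
            "need n >= 2 for a sample with positive SD"
        )
    if target_sd == 0:
        return np.full(n, float(target_mean))
    if rng is None:
        rng = np.random.default_rng(seed)
    base = rng.standard_normal(n)
    while base.std(ddof=1) == 0:  # pragma: no cover - essentially impossible
        base = rng.standard_normal(n)
    z = (base - base.mean()) / base.std(ddof=1)
    return target_mean + target_sd * z


def reference_moment_fixtures(seed: int = 0) -> pd.DataFrame:
    """Replicate-level fixtures for every reference group-statistics row.

    For each published (comparison, feature) row, 12 DN and 12 SD values
    are built by :func:`exact_moment_sample` from the printed means and
    SDs.  Running the univariate statistics on these fixtures reproduces
    the printed t and df columns.
    """
    n = datasets.N_BIOLOGICAL_REPLICATES * datasets.N_TECHNICAL_REPLICATES
    rng = np.random.default_rng(seed)
    rows = []
    for row in datasets.GROUP_TTEST_ROWS:
        rows.append(
            {
                **row,
                "values_dn": exact_moment_sample(
                    n, row["mean_dn"], row["sd_dn"], rng=rng
                ),
                "values_sd": exact_moment_sample(
                    n, row["mean_sd"], row["sd_sd"], rng=rng
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele-dosage population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosageModel:
    """Gamete sampling and dosage-to-score thresholds for a polyploid.

    ``score_thresholds`` maps minimum offspring dosage to flowering score,
    checked in descending dosage order; the defaults partition 0..8 as
    >=6 -> 1 (strong DN), 4-5 -> 2, 2-3 -> 3, <=1 -> 4 (short-day).
    """

    ploidy: int = 8
    score_thresholds: tuple[tuple[int, int], ...] = ((6, 1), (4, 2), (2, 3), (0, 4))

    def __post_init__(self) -> None:
        if self.ploidy < 2 or self.ploidy % 2:
            raise DomainError("ploidy must be a positive even integer")
        scores = {s for _, s in self.score_thresholds}
        if scores != {1, 2, 3, 4}:
            raise DomainError("thresholds must cover scores 1-4")

    def score_from_dosage(self, dosage: int) -> int:
        for min_dosage, score in sorted(self.score_thresholds, reverse=True):
            if dosage >= min_dosage:
                return score
        return self.score_thresholds[-1][1]


def simulate_f1_population(
    n_plants: int,
    parent1_dosage: float,
    parent2_dosage: float,
    model: DosageModel | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cross_id: str = "cross1",
) -> list[PhenotypeRecord]:
    """F1 progeny under binomial gamete sampling of the trait allele.

    Each gamete carries ``Binomial(ploidy/2, parent_dosage/ploidy)``
    copies; offspring dosage is the sum of the two gametes.
    """
    model = model or DosageModel()
    for d in (parent1_dosage, parent2_dosage):
        if not 0 <= d <= model.ploidy:
            raise DomainError(
                f"parent dosage {d} outside [0, {model.ploidy}]"
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    half = model.ploidy // 2
    g1 = rng.binomial(half, parent1_dosage / model.ploidy, size=n_plants)
    g2 = rng.binomial(half, parent2_dosage / model.ploidy, size=n_plants)
    dosage = g1 + g2
    return [
        PhenotypeRecord(
            plant_id=f"{cross_id}-{i + 1:03d}",
            cross_id=cross_id,
            flowering_score=model.score_from_dosage(int(d)),
            dosage=float(d),
        )
        for i, d in enumerate(dosage)
    ]


def offspring_dosage_pmf(
    parent1_dosage: float, parent2_dosage: float, model: DosageModel | None = None
) -> np.ndarray:
    """Analytic offspring-dosage distribution (binomial convolution)."""
    from scipy import stats as sps

    model = model or DosageModel()
    half = model.ploidy // 2
    k = np.arange(half + 1)
    p1 = sps.binom.pmf(k, half, parent1_dosage / model.ploidy)
    p2 = sps.binom.pmf(k, half, parent2_dosage / model.ploidy)
    return np.convolve(p1, p2)


# ---------------------------------------------------------------------------
# bulk-hybridization signal model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalModel:
    """Parameters of the array-signal generator.

    ``noise_sd`` is the log-scale SD of the multiplicative cell noise
    (default 0.35, giving a coefficient of variation comparable to the
    reference group statistics).  ``slide_scale_sd`` is the log-scale SD
    of the per-hybridization distortion that spike-in normalization is
    meant to remove.  ``marker_effect`` is beta in the dosage-response
    term ``1 + beta * D_b``; see :func:`beta_for_ratio`.
    """

    n_features: int = 287
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    marker_effect: float = 0.4
    noise_sd: float = 0.35
    planted_index: int = 0
    n_bio: int = 2
    n_tech: int = 6
    slide_scale_sd: float = 0.2
    spike_in_snr: float = 50.0
    positive_control_snr: float = 100.0
    printing_control_snr: float = 30.0
    n_positive_controls: int = 6
    n_negative_controls: int = 9
    n_printing_controls: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.slide_scale_sd < 0:
            raise DomainError("noise SDs must be nonnegative")
        if not 0 <= self.planted_index < self.n_features:
            raise DomainError("planted index outside the feature range")


def beta_for_ratio(ratio: float, d_high: float, d_low: float) -> float:
    """Marker effect giving an expected high/low fingerprint ratio.

    Solves ``(1 + beta*d_high) / (1 + beta*d_low) = ratio``; requires
    ``d_high > ratio * d_low`` so the effect is positive and finite.
    """
    if ratio <= 1:
        raise DomainError("ratio must exceed 1")
    denom = d_high - ratio * d_low
    if denom <= 0:
        raise DomainError(
            f"dosages ({d_high}, {d_low}) cannot produce a {ratio}x ratio"
        )
    return (ratio - 1.0) / denom


def make_layout(model: SignalModel) -> list[FeatureAnnotation]:
    """Printed layout: subtracted features plus the control categories."""
    layout = [
        FeatureAnnotation(f"FS{i + 1:03d}", "subtracted", (1, 1 + i // 24, 1 + i % 24))
        for i in range(model.n_features)
    ]
    block = 2
    for i in range(model.n_positive_controls):
        layout.append(FeatureAnnotation(f"POS{i + 1}", "positive_control", (block, 1, i + 1)))
    for i in range(model.n_negative_controls):
        layout.append(FeatureAnnotation(f"NEG{i + 1}", "negative_control", (block, 2, i + 1)))
    for i in range(model.n_printing_controls):
        layout.append(FeatureAnnotation(f"PRT{i + 1}", "printing_control", (block, 3, i + 1)))
    layout.append(FeatureAnnotation("SPIKE1", "spike_in", (block, 4, 1)))
    return layout


@dataclass
class GroundTruth:
    """What the simulator planted, for end-to-end validation."""

    planted_feature: str
    marker_effect: float
    bulk_dosages: dict[str, float]
    expected_ratio_dn1_sd: float
    baseline: dict[str, float] = field(default_factory=dict)


def simulate_bulk_hybridization(
    bulk_dosages: Mapping[str, float],
    model: SignalModel | None = None,
    seed: int | None = None,
) -> tuple[FeatureSignalMatrix, GroundTruth]:
    """Simulate SNR matrices for all bulk hybridizations.

    One column per (bulk, biological replicate, technical replicate);
    each column carries an independent per-slide scale distortion, and
    every cell independent log-normal noise.  The planted feature's
    expected signal scales with the bulk's mean allele dosage.
    """
    model = model or SignalModel()
    rng = np.random.default_rng(seed)
    layout = make_layout(model)
    ann = annotation_frame(layout)
    subtracted = [a.feature_id for a in layout if a.category == "subtracted"]
    planted = subtracted[model.planted_index]
    mu = np.exp(
        rng.normal(model.baseline_log_mean, model.baseline_log_sd, model.n_features)
    )

    hyb_ids, targets, bios, techs = [], [], [], []
    for b in bulk_dosages:
        for i in range(1, model.n_bio + 1):
            for j in range(1, model.n_tech + 1):
                hyb_ids.append(f"{b}_b{i}_t{j}")
                targets.append(b)
                bios.append(i)
                techs.append(j)
    n_hyb = len(hyb_ids)
    values = pd.DataFrame(
        0.0, index=ann.index, columns=hyb_ids
    )

    def noise(size):
        if model.noise_sd == 0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, model.noise_sd, size))

    g = (
        np.exp(rng.normal(0.0, model.slide_scale_sd, n_hyb))
        if model.slide_scale_sd > 0
        else np.ones(n_hyb)
    )
    for h, hyb in enumerate(hyb_ids):
        d_b = float(bulk_dosages[targets[h]])
        dose_term = np.ones(model.n_features)
        dose_term[model.planted_index] = 1.0 + model.marker_effect * d_b
        values.loc[subtracted, hyb] = mu * dose_term * noise(model.n_features) * g[h]
        values.loc["SPIKE1", hyb] = model.spike_in_snr * float(noise(1)[0]) * g[h]
        for a in layout:
            if a.category == "positive_control":
                values.loc[a.feature_id, hyb] = (
                    model.positive_control_snr * float(noise(1)[0]) * g[h]
                )
            elif a.category == "printing_control":
                values.loc[a.feature_id, hyb] = (
                    model.printing_control_snr * float(noise(1)[0]) * g[h]
                )
            elif a.category == "negative_control":
                values.loc[a.feature_id, hyb] = float(
                    np.abs(rng.normal(0.0, 1.0))
                )
    design = pd.DataFrame(
        {
            "target": targets,
            "biological_replicate": bios,
            "technical_replicate": techs,
        },
        index=pd.Index(hyb_ids, name="hybridization_id"),
    )
    matrix = matrix_from_values(values, ann, design)
    d = dict(bulk_dosages)
    expected = None
    if "DN1" in d and "SD" in d:
        expected = (1 + model.marker_effect * d["DN1"]) / (
            1 + model.marker_effect * d["SD"]
        )
    truth = GroundTruth(
        planted_feature=planted,
        marker_effect=model.marker_effect,
        bulk_dosages=d,
        expected_ratio_dn1_sd=expected if expected is not None else float("nan"),
        baseline={fid: float(m) for fid, m in zip(subtracted, mu)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# full study emulation
# ---------------------------------------------------------------------------

#: Bulk sizes of the reference study (DN1, DN2, DN3, SD).
STUDY_BULK_SIZES = {"DN1": 2, "DN2": 19, "DN3": 18, "SD": 10}

#: Crosses used to raise the emulated F1 population: one day-neutral x
#: short-day cross and two day-neutral x day-neutral crosses, 200 plants
#: each (600 screened).  Parent trait-allele dosages of 3 (day-neutral)
#: and 0 (short-day) make the segregation match the reference pattern:
#: most F1 plants short-day, and strong day-neutrals appearing only as
#: rare transgressive segregants of the DN x DN crosses.
STUDY_CROSSES = (
    ("dnxsd", 3.0, 0.0, 200),
    ("dnxdn1", 3.0, 3.0, 200),
    ("dnxdn2", 3.0, 3.0, 200),
)


@dataclass
class StudySimulation:
    population: list[PhenotypeRecord]
    bulks: dict
    bulk_dosages: dict[str, float]
    model: SignalModel
    matrix: FeatureSignalMatrix
    truth: GroundTruth


def simulate_study(
    seed: int,
    model: SignalModel | None = None,
    dosage_model: DosageModel | None = None,
    target_ratio: float = 3.0,
    bulk_sizes: Mapping[str, int] = STUDY_BULK_SIZES,
) -> StudySimulation:
    """End-to-end emulation of the bulked-segregant array experiment.

    Simulates an F1 population from the study's cross structure, samples
    bulk members to the study's bulk sizes, computes each bulk's mean
    allele dosage, sets the marker effect so the expected DN1/SD
    fingerprint ratio of the planted feature equals ``target_ratio``
    (default 3), and generates the hybridization signal matrix.
    """
    rng = np.random.default_rng(seed)
    dosage_model = dosage_model or DosageModel()
    population: list[PhenotypeRecord] = []
    for cross_id, d1, d2, n in STUDY_CROSSES:
        population.extend(
            simulate_f1_population(
                n, d1, d2, model=dosage_model, rng=rng, cross_id=cross_id
            )
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        all_bulks, _ = assemble_bulks(population)
    by_id = {p.plant_id: p for p in population}
    members: dict[str, list[str]] = {}
    for cls, size in bulk_sizes.items():
        pool = sorted(all_bulks[cls].members) if cls in all_bulks else []
        if not pool:
            raise InsufficientDataError(
                f"simulated population produced no {cls} plants"
            )
        take = min(size, len(pool))
        members[cls] = list(rng.choice(pool, size=take, replace=False))
    dosages = {
        cls: float(np.mean([by_id[p].dosage for p in ms]))
        for cls, ms in members.items()
    }
    beta = beta_for_ratio(target_ratio, dosages["DN1"], dosages["SD"])
    model = replace(model or SignalModel(), marker_effect=beta)
    matrix, truth = simulate_bulk_hybridization(
        dosages, model, seed=int(rng.integers(2**31 - 1))
    )
    return StudySimulation(
        population=population,
        bulks={cls: ms for cls, ms in members.items()},
        bulk_dosages=dosages,
        model=model,
        matrix=matrix,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# scan-table export (for the CLI and file-based pipeline runs)
# ---------------------------------------------------------------------------

def matrix_to_hybridizations(
    matrix: FeatureSignalMatrix,
    background_mean: float = 100.0,
    background_sd: float = 10.0,
) -> list[Hybridization]:
    """Convert an SNR matrix back into spot-level scan measurements.

    SNR is inverted through the scanner definition with a flat synthetic
    background: signal = background + SNR * background_sd (floored at 0).
    """
    out = []
    for hyb_id, row in matrix.design.iterrows():
        spots = []
        for fid in matrix.values.index:
            snr = float(matrix.values.loc[fid, hyb_id])
            spots.append(
                SpotMeasurement(
                    feature_id=fid,
                    signal_mean=max(background_mean + snr * background_sd, 0.0),
                    background_mean=background_mean,
                    background_sd=background_sd,
                    manual_flag=str(matrix.flags.loc[fid, hyb_id]),
                )
            )
        out.append(
            Hybridization(
                hybridization_id=str(hyb_id),
                target=str(row["target"]),
                biological_replicate=int(row["biological_replicate"]),
                technical_replicate=int(row["technical_replicate"]),
                spots=spots,
            )
        )
    return out


def write_simulated_run(sim: StudySimulation, outdir: str | Path) -> Path:
    """Write scan tables, sample sheet, layout and ground truth to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_layout(sim.model)
    write_feature_annotation(layout, outdir / "layout.tsv")
    hybs = matrix_to_hybridizations(sim.matrix)
    scans = outdir / "scans"
    scans.mkdir(exist_ok=True)
    for h in hybs:
        fname = scans / f"{h.hybridization_id}.tsv"
        write_scan_table(h, fname)
        h.scan_file = str(fname.relative_to(outdir))
    write_sample_sheet(hybs, outdir / "sample_sheet.tsv")
    truth = {
        "planted_feature": sim.truth.planted_feature,
        "marker_effect": sim.truth.marker_effect,
        "bulk_dosages": sim.truth.bulk_dosages,
        "expected_ratio_dn1_sd": sim.truth.expected_ratio_dn1_sd,
        "bulk_members": sim.bulks,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
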