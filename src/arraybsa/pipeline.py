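"""End-to-end orchestration: QC -> normalize -> stats -> DFA -> markers.

One :class:`RunConfig` carries every threshold of the analysis; a run
echoes the resolved configuration next to its outputs so results are
auditable, and repeated runs with the same configuration and seed write
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dfa import DFAConfig, DFAResult, reciprocal_cross_validate
from .errors import ArrayBSAError
from .io import (
    FeatureFingerprint,
    FeatureSignalMatrix,
    read_feature_annotation,
    read_sample_sheet,
    read_scan_table,
    write_fingerprint_table,
)
from .markers import MarkerReport, select_markers
from .qc import (
    QCConfig,
    apply_qc_flags,
    build_fingerprint,
    build_signal_matrix,
    qc_report,
    snr_detection_filter,
    spike_in_normalize,
)
from .stats import two_bulk_stats

log = logging.getLogger("arraybsa")

DEFAULT_COMPARISONS = (("DN1", "SD"), ("DN2", "SD"), ("DN3", "SD"))


@dataclass
class RunConfig:
    """All tunable thresholds of one pipeline run."""

    snr_threshold: float = 7.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    fisher_k: int = 10
    t_alpha: float = 0.05
    levene_alpha: float = 0.05
    cm_window: float = 5.0
    select_on: str = "all"
    comparisons: tuple = DEFAULT_COMPARISONS
    seed: int | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        return cls(**d)


@dataclass
class PipelineResult:
    matrix: FeatureSignalMatrix
    retained: list[str]
    dropped: list[str]
    fingerprints: list[FeatureFingerprint]
    stats_tables: dict[str, pd.DataFrame]
    dfa_results: dict[str, DFAResult]
    report: MarkerReport
    config: RunConfig


def analyze_matrix(matrix: FeatureSignalMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run the full statistical pipeline on a loaded signal matrix."""
    config = config or RunConfig()
    qc_cfg = QCConfig(snr_threshold=config.snr_threshold)
    present = set(matrix.design["target"])
    comparisons = [c for c in config.comparisons if set(c) <= present]
    if not comparisons:
        raise ArrayBSAError(
            f"no configured comparison is available among targets {sorted(present)}"
        )
    bulk_targets = sorted({t for c in comparisons for t in c})

    log.info("QC: masking flagged cells and negative controls")
    masked = apply_qc_flags(matrix)
    retained, dropped = snr_detection_filter(masked, qc_cfg, targets=bulk_targets)
    log.info("QC: %d features retained, %d dropped", len(retained), len(dropped))
    if not retained:
        raise ArrayBSAError("detection filter retained no features")

    log.info("normalizing by spike-in control")
    norm = spike_in_normalize(masked)

    fingerprints = [
        build_fingerprint(norm, b, features=retained) for b in bulk_targets
    ]

    stats_tables = {}
    dfa_results = {}
    for dn, sd in comparisons:
        comp = f"{dn}-{sd}"
        log.info("comparison %s: univariate statistics", comp)
        stats_tables[comp] = two_bulk_stats(
            norm, dn, sd, features=retained, alpha_levene=config.levene_alpha
        )
        log.info("comparison %s: stepwise discriminant analysis", comp)
        dfa_results[comp] = reciprocal_cross_validate(
            norm,
            (dn, sd),
            DFAConfig(
                p_enter=config.p_enter,
                p_remove=config.p_remove,
                select_on=config.select_on,  # type: ignore[arg-type]
            ),
            features=retained,
        )

    report = select_markers(
        dfa_results, stats_tables, fisher_k=config.fisher_k, t_alpha=config.t_alpha
    )
    log.info("putative markers: %s", ", ".join(report.marker_ids) or "(none)")
    return PipelineResult(
        matrix=norm,
        retained=retained,
        dropped=dropped,
        fingerprints=fingerprints,
        stats_tables=stats_tables,
        dfa_results=dfa_results,
        report=report,
        config=config,
    )


def load_input_dir(input_dir: str | Path) -> FeatureSignalMatrix:
    """Load layout + sample sheet + scan tables from a run directory."""
    input_dir = Path(input_dir)
    layout = read_feature_annotation(input_dir / "layout.tsv")
    descriptors = read_sample_sheet(input_dir / "sample_sheet.tsv")
    hybs = []
    for d in descriptors:
        hybs.append(
            read_scan_table(
                input_dir / d.scan_file,
                layout,
                hybridization_id=d.hybridization_id,
                target=d.target,
                biological_replicate=d.biological_replicate,
                technical_replicate=d.technical_replicate,
            )
        )
    return build_signal_matrix(hybs, layout)


def _dfa_report_dict(dfa_results: dict[str, DFAResult]) -> dict:
    return {
        comp: {
            "selected": res.selected,
            "lambda_trace": res.lambda_trace,
            "trace": [
                {
                    "step": r.step,
                    "action": r.action,
                    "feature": r.feature,
                    "wilks_lambda": r.wilks_lambda,
                    "F": None if r.F != r.F or r.F == float("inf") else r.F,
                    "p": r.p,
                }
                for r in res.trace
            ],
            "training_accuracy_percent": res.training_accuracy_percent,
            "test_accuracy_percent": res.test_accuracy_percent,
            "coefficients": res.coefficients,
            "directions": {
                k: {
                    "selected": v["selected"],
                    "training_accuracy_percent": v["training_accuracy_percent"],
                    "test_accuracy_percent": v["test_accuracy_percent"],
                }
                for k, v in res.directions.items()
            },
        }
        for comp, res in dfa_results.items()
    }


def write_artifacts(result: PipelineResult, outdir: str | Path) -> Path:
    """Write every pipeline artifact into ``outdir`` deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "config.yaml")
    qc_report(result.matrix, result.retained, result.dropped).to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False
    )
    write_fingerprint_table(result.fingerprints, outdir / "fingerprints.tsv")
    for comp, tbl in result.stats_tables.items():
        tbl.to_csv(
            outdir / f"stats_{comp}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
    (outdir / "dfa_report.json").write_text(
        json.dumps(_dfa_report_dict(result.dfa_results), indent=2, sort_keys=True)
    )
    venn = {
        "regions": result.report.venn.to_dict(),
        "counts": result.report.venn.counts,
        "params": result.report.params,
    }
    (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
    result.report.markers_frame().to_csv(
        outdir / "markers.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return outdir


def run_pipeline(
    config: RunConfig,
    input_dir: str | Path | None = None,
    matrix: FeatureSignalMatrix | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Load inputs, run the analysis and optionally write artifacts.

    Exactly one of ``input_dir`` / ``matrix`` must be given.  Any stage
    failure propagates as an :class:`~arraybsa.errors.ArrayBSAError`
    naming the stage in its message.
    """
    if (input_dir is None) == (matrix is None):
        raise ValueError("provide exactly one of input_dir or matrix")
    if matrix is None:
        log.info("loading inputs from %s", input_dir)
        matrix = load_input_dir(input_dir)
    result = analyze_matrix(matrix, config)
    if outdir is not None:
        write_artifacts(result, outdir)
        log.info("artifacts written to %s", outdir)
    return result
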