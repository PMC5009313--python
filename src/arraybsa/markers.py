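"""Three-criterion marker selection and the three-way Venn partition.

A feature becomes a putative marker when it satisfies all three of:

* selected by stepwise discriminant analysis in at least one bulk
  comparison (set A),
* ranked in the top k (default 10) by Fisher's ratio in at least one
  comparison (set B),
* significant in the independent-samples t-test in at least one
  comparison (set C, default alpha 0.05).

Counting uses unique features (set semantics): a feature selected in two
comparisons is still one member.  The default t-test circle uses
alpha = 0.05; 0.01 is available via configuration — with the reference
study's printed statistics only the 0.05 threshold makes the published
region contents internally consistent, and both thresholds are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dfa import DFAResult
from .stats import TTestResult

REGION_KEYS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class VennPartition:
    """Disjoint regions of three feature sets A (DFA), B (Fisher top-k),
    C (t-test significant)."""

    A: set
    B: set
    C: set
    regions: dict[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regions:
            A, B, C = self.A, self.B, self.C
            self.regions = {
                "A": A - B - C,
                "B": B - A - C,
                "C": C - A - B,
                "AB": (A & B) - C,
                "AC": (A & C) - B,
                "BC": (B & C) - A,
                "ABC": A & B & C,
            }

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def triple_intersection(self) -> set:
        return set(self.regions["ABC"])

    def to_dict(self) -> dict:
        return {k: sorted(v) for k, v in self.regions.items()}


def venn3_partition(A: Iterable, B: Iterable, C: Iterable) -> VennPartition:
    """Partition three finite sets into the seven exclusive Venn regions."""
    return VennPartition(A=set(A), B=set(B), C=set(C))


def fisher_top_k(
    ratios: Mapping[str, Mapping[str, float]] | Mapping[str, pd.Series],
    k: int = 10,
) -> tuple[dict[str, list[str]], set]:
    """Top-k features by Fisher's ratio per comparison, plus their union.

    Ties at the cut rank break by lexicographic feature id, so the result
    is deterministic.  Comparisons with fewer than k features keep all of
    them with a warning.
    """
    per_comparison: dict[str, list[str]] = {}
    union: set = set()
    for comparison, r in ratios.items():
        s = pd.Series(dict(r), dtype=float)
        if s.size < k:
            warnings.warn(
                f"comparison {comparison!r} has only {s.size} features "
                f"(< k={k}); keeping all"
            )
        ranked = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
        top = [fid for fid, _ in ranked[:k]]
        per_comparison[comparison] = top
        union.update(top)
    return per_comparison, union


def significant_by_ttest(
    results: Iterable[TTestResult] | pd.DataFrame,
    alpha: float = 0.05,
) -> set:
    """Features with p < alpha in any comparison (strict inequality)."""
    if isinstance(results, pd.DataFrame):
        return set(results.loc[results["p"] < alpha, "feature_id"])
    return {r.feature_id for r in results if r.p < alpha}


@dataclass
class MarkerEvidence:
    """Per-marker record of which criteria and comparisons supported it."""

    feature_id: str
    comparisons_dfa: list[str]
    comparisons_fisher: list[str]
    comparisons_significant: list[str]
    direction: str  # "DN" or "SD"
    best_comparison: str
    t: float
    p: float
    fisher_ratio: float


@dataclass
class MarkerReport:
    """Full outcome of the three-criterion selection."""

    venn: VennPartition
    markers: list[MarkerEvidence]
    per_comparison_fisher_top: dict[str, list[str]]
    dfa_selected: dict[str, list[str]]
    params: dict = field(default_factory=dict)

    @property
    def marker_ids(self) -> list[str]:
        return sorted(m.feature_id for m in self.markers)

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": m.feature_id,
                    "direction": m.direction,
                    "best_comparison": m.best_comparison,
                    "t": m.t,
                    "p": m.p,
                    "fisher_ratio": m.fisher_ratio,
                    "dfa_comparisons": ";".join(m.comparisons_dfa),
                    "fisher_comparisons": ";".join(m.comparisons_fisher),
                    "significant_comparisons": ";".join(m.comparisons_significant),
                }
                for m in self.markers
            ]
        )


def select_markers(
    dfa_results: Mapping[str, DFAResult] | Mapping[str, Sequence[str]],
    stats_tables: Mapping[str, pd.DataFrame],
    fisher_k: int = 10,
    t_alpha: float = 0.05,
) -> MarkerReport:
    """Combine DFA, Fisher-ratio and t-test criteria into a marker report.

    ``dfa_results`` maps comparison id to a :class:`~arraybsa.dfa.DFAResult`
    (or a plain feature list); ``stats_tables`` maps comparison id to the
    per-feature table from :func:`arraybsa.stats.two_bulk_stats`.  The
    putative markers are the triple-intersection features; each carries
    the direction of effect (DN when the DN-bulk mean exceeds the SD-bulk
    mean in its strongest comparison).
    """
    dfa_selected = {
        comp: list(res.selected) if isinstance(res, DFAResult) else list(res)
        for comp, res in dfa_results.items()
    }
    if not stats_tables:
        warnings.warn("no statistics tables supplied; empty marker report")
        empty = venn3_partition(set().union(*dfa_selected.values()) if dfa_selected else set(), set(), set())
        return MarkerReport(empty, [], {}, dfa_selected, {})
    A = set().union(*dfa_selected.values()) if dfa_selected else set()
    ratios = {
        comp: tbl.set_index("feature_id")["fisher_ratio"]
        for comp, tbl in stats_tables.items()
        if not tbl.empty
    }
    per_comp_top, B = fisher_top_k(ratios, k=fisher_k)
    all_stats = pd.concat(stats_tables.values(), ignore_index=True)
    C = significant_by_ttest(all_stats, alpha=t_alpha)
    venn = venn3_partition(A, B, C)
    markers = []
    for fid in sorted(venn.triple_intersection):
        rows = all_stats[all_stats["feature_id"] == fid]
        best = rows.loc[rows["fisher_ratio"].idxmax()]
        markers.append(
            MarkerEvidence(
                feature_id=fid,
                comparisons_dfa=[c for c, s in dfa_selected.items() if fid in s],
                comparisons_fisher=[c for c, s in per_comp_top.items() if fid in s],
                comparisons_significant=sorted(
                    rows.loc[rows["p"] < t_alpha, "comparison"]
                ),
                direction="DN" if best["mean_dn"] > best["mean_sd"] else "SD",
                best_comparison=str(best["comparison"]),
                t=float(best["t"]),
                p=float(best["p"]),
                fisher_ratio=float(best["fisher_ratio"]),
            )
        )
    return MarkerReport(
        venn=venn,
        markers=markers,
        per_comparison_fisher_top=per_comp_top,
        dfa_selected=dfa_selected,
        params={"fisher_k": fisher_k, "t_alpha": t_alpha},
    )
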