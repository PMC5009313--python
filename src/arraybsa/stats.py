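"""Per-feature two-group statistics: Fisher's ratio and t-tests.

For every retained array feature and every bulk comparison (DN1-SD,
DN2-SD, DN3-SD) the 12 replicate values per bulk (2 biological x 6
technical replicates, treated as independent observations) are summarized
into group statistics and compared two ways:

* **Fisher's ratio** ``(M1 - M2)**2 / (V1 + V2)`` — a univariate
  two-class separability score (means M, sample variances V),
* an **independent-samples t-test**, pooled-variance or Welch, with the
  choice resolved by a mean-centered Levene test when ``variant="auto"``.

Treating technical replicates as independent observations follows the
original analysis convention (pooled df = n1 + n2 - 2 = 22 for 12 + 12
values); it overstates the effective sample size and the resulting
p-values should be read as ranking scores rather than strict error rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError
from .io import FeatureSignalMatrix

Variant = Literal["auto", "pooled", "welch"]


@dataclass(frozen=True)
class GroupStats:
    """Sample summary of one group: n, mean M, variance V (n-1), SD s."""

    group_id: str
    n: int
    mean: float
    variance: float

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison of one feature, oriented DN minus SD."""

    feature_id: str
    t: float
    df: float
    p: float
    variant: str
    levene_p: float | None = None
    comparison: str = ""

    @property
    def df_rounded(self) -> float:
        """df as conventionally printed: integer for pooled, 1 decimal
        for Welch."""
        if self.variant == "pooled":
            return float(int(round(self.df)))
        return round(self.df, 1)

    @property
    def significance(self) -> str:
        """Two-tier significance stamp: '**' p<0.01, '*' p<0.05, 'ns'."""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"


def group_stats(values: Sequence[float], group_id: str = "") -> GroupStats:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >=2 finite values for group statistics, got {arr.size}"
        )
    return GroupStats(
        group_id=group_id,
        n=int(arr.size),
        mean=float(arr.mean()),
        variance=float(arr.var(ddof=1)),
    )


def fisher_ratio(g1: GroupStats, g2: GroupStats) -> float:
    """(M1 - M2)^2 / (V1 + V2); symmetric in group order, nonnegative."""
    denom = g1.variance + g2.variance
    if denom == 0:
        if g1.mean == g2.mean:
            return 0.0
        raise DegenerateDataError(
            "both groups have zero variance but different means; "
            "Fisher's ratio is unbounded"
        )
    return (g1.mean - g2.mean) ** 2 / denom


def fisher_ratio_values(values1: Sequence[float], values2: Sequence[float]) -> float:
    return fisher_ratio(group_stats(values1, "1"), group_stats(values2, "2"))


def levene_test(values1: Sequence[float], values2: Sequence[float]) -> float:
    """Mean-centered Levene test for equal variances; returns the p-value.

    Degenerate inputs with zero total spread in the absolute deviations
    (e.g. both groups constant) are treated as "no evidence against
    equality": p = 1.
    """
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Levene test needs >=2 values per group")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    z = np.concatenate([za, zb])
    if np.allclose(z, z.mean()):
        return 1.0
    _, p = sps.levene(a, b, center="mean")
    if math.isnan(p):
        return 1.0
    return float(p)


def independent_t_test(
    values_dn: Sequence[float],
    values_sd: Sequence[float],
    variant: Variant = "auto",
    alpha_levene: float = 0.05,
    feature_id: str = "",
    comparison: str = "",
) -> TTestResult:
    """Two-sided independent-samples t-test, oriented DN minus SD.

    ``variant="auto"`` uses the pooled-variance test when the Levene test
    does not reject variance equality at ``alpha_levene``, otherwise the
    Welch test with Welch-Satterthwaite degrees of freedom.  A zero
    standard error with unequal means yields an infinite-t sentinel with
    p = 0.
    """
    a = np.asarray(values_dn, dtype=float)
    b = np.asarray(values_sd, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("t-test needs >=2 values per group")
    levene_p: float | None = None
    if variant == "auto":
        levene_p = levene_test(a, b)
        variant = "pooled" if levene_p >= alpha_levene else "welch"
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: scipy returns NaN; resolve by the sign of the
        # mean difference
        diff = a.mean() - b.mean()
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, diff), 0.0
        df = float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TTestResult(
        feature_id=feature_id,
        t=t,
        df=df,
        p=p,
        variant=variant,
        levene_p=levene_p,
        comparison=comparison,
    )


# ---------------------------------------------------------------------------
# matrix-level helpers
# ---------------------------------------------------------------------------

def bulk_case_values(
    matrix: FeatureSignalMatrix, bulk_id: str, feature_id: str
) -> np.ndarray:
    """All unmasked replicate values of one feature in one bulk."""
    cols = matrix.columns_for(bulk_id)
    vals = matrix.values.loc[feature_id, cols]
    ok = ~matrix.mask.loc[feature_id, cols]
    return vals[ok].to_numpy(dtype=float)


def two_bulk_stats(
    matrix: FeatureSignalMatrix,
    bulk_dn: str,
    bulk_sd: str,
    features: Sequence[str] | None = None,
    variant: Variant = "auto",
    alpha_levene: float = 0.05,
) -> pd.DataFrame:
    """Per-feature comparison table for one DN bulk against the SD bulk.

    Columns: group means/SDs/ns, Fisher's ratio, t, df (exact and as
    printed), p, resolved variant, Levene p and significance tier.
    """
    if features is None:
        features = matrix.features_of_category("subtracted")
    comparison = f"{bulk_dn}-{bulk_sd}"
    rows = []
    for fid in features:
        dn = bulk_case_values(matrix, bulk_dn, fid)
        sd = bulk_case_values(matrix, bulk_sd, fid)
        if dn.size < 2 or sd.size < 2:
            continue
        g_dn = group_stats(dn, bulk_dn)
        g_sd = group_stats(sd, bulk_sd)
        try:
            fr = fisher_ratio(g_dn, g_sd)
        except DegenerateDataError:
            fr = math.inf
        res = independent_t_test(
            dn, sd, variant=variant, alpha_levene=alpha_levene,
            feature_id=fid, comparison=comparison,
        )
        rows.append(
            {
                "feature_id": fid,
                "comparison": comparison,
                "n_dn": g_dn.n,
                "mean_dn": g_dn.mean,
                "sd_dn": g_dn.sd,
                "n_sd": g_sd.n,
                "mean_sd": g_sd.mean,
                "sd_sd": g_sd.sd,
                "fisher_ratio": fr,
                "t": res.t,
                "df": res.df,
                "df_printed": res.df_rounded,
                "p": res.p,
                "variant": res.variant,
                "levene_p": res.levene_p,
                "significance": res.significance,
            }
        )
    return pd.DataFrame(rows)
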