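"""The methylation-recovery (MR) statistic and its summaries.

For a region with normalized log2 values ``w`` (wild-type reference), ``m0``
(null baseline) and ``s`` (rescue/test sample):

    D  = w - m0          the log2 methylation deficit of the null
    S  = w - s           the residual deficit after rescue
    MR = 100 * (D - S) / D = 100 * (s - m0) / D

MR is 100 when the test sample fully restores the wild-type signal and 0 when
it stays at the baseline.  MR is only meaningful at regions where the null
actually lost methylation, so regions with D below ``d_min`` (default 1.0
log2 unit, a 2-fold deficit) are excluded — flagged, never silently dropped.
MR is not clamped by default: sampling noise legitimately produces values
outside [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .normalization import NormalizedTable
from .regions import RegionSet, SampleManifest

logger = logging.getLogger(__name__)

EXCLUDED_DEFICIT = "deficit_below_threshold"

RECORD_COLUMNS = [
    "region_id",
    "region_class",
    "sample_id",
    "D",
    "S",
    "MR",
    "excluded",
    "excluded_reason",
]


def methylation_recovery(
    w: float, m0: float, s: float, d_min: float = 1.0
) -> tuple[float, float, float | None]:
    """Return (D, S, MR) for one region; MR is None when D < d_min.

    With ``d_min = 0`` a zero deficit raises rather than dividing by zero.
    """
    for name, v in (("w", w), ("m0", m0), ("s", s)):
        if not np.isfinite(v):
            raise ValidationError(f"non-finite input {name}={v}")
    if d_min < 0:
        raise ValidationError("d_min must be >= 0")
    D = w - m0
    S = w - s
    if D < d_min:
        return D, S, None
    if D == 0:
        raise ValidationError(
            "zero deficit (D = 0) with d_min = 0: MR is undefined at this region"
        )
    return D, S, 100.0 * (D - S) / D


def recovery_table(
    norm: NormalizedTable,
    manifest: SampleManifest,
    regions: RegionSet,
    d_min: float = 1.0,
    clamp: bool = False,
) -> pd.DataFrame:
    """Per-region MR records for every test sample.

    Returns a DataFrame with one row per (region, test sample); regions whose
    deficit D < d_min carry excluded=True and excluded_reason, with MR = NaN.
    ``clamp=True`` clips MR into [0, 100] (opt-in; off by default).
    """
    for role, sample in (("reference", manifest.reference), ("baseline", manifest.baseline)):
        if sample not in norm.sample_ids:
            raise ValidationError(f"{role} sample {sample!r} missing from normalized table")
    tests = [t for t in manifest.tests if t in norm.sample_ids]
    if not tests:
        raise ValidationError("no test samples present in the normalized table")
    if d_min <= 0:
        raise ValidationError("d_min must be > 0 for table-level computation")

    w = norm.values[manifest.reference].to_numpy(dtype=float)
    m0 = norm.values[manifest.baseline].to_numpy(dtype=float)
    D = w - m0
    classes = regions.classes().reindex(norm.region_ids)
    excluded = D < d_min
    frames = []
    for sample in tests:
        s = norm.values[sample].to_numpy(dtype=float)
        S = w - s
        with np.errstate(divide="ignore", invalid="ignore"):
            mr = 100.0 * (D - S) / D
        mr = np.where(excluded, np.nan, mr)
        if clamp:
            mr = np.clip(mr, 0.0, 100.0)
        frames.append(
            pd.DataFrame(
                {
                    "region_id": norm.region_ids,
                    "region_class": classes.to_numpy(),
                    "sample_id": sample,
                    "D": D,
                    "S": S,
                    "MR": mr,
                    "excluded": excluded,
                    "excluded_reason": np.where(excluded, EXCLUDED_DEFICIT, ""),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey-style five-number summary: quartiles by linear interpolation of
    order statistics, whiskers at the most extreme observations within
    1.5 x IQR of the quartiles."""

    region_class: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


def _boxplot_summary(values: np.ndarray, region_class: str) -> BoxplotSummary:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    in_fence = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return BoxplotSummary(
        region_class=region_class,
        n=int(values.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_fence.min()),
        whisker_high=float(in_fence.max()),
    )


def summarize_recovery(
    records: pd.DataFrame, by: str = "region_class"
) -> pd.DataFrame:
    """Boxplot summaries of MR per (test sample, region class).

    Excluded records are dropped first.  Classes left empty after exclusion
    are omitted with a logged warning.
    """
    usable = records[~records["excluded"] & records["MR"].notna()]
    rows = []
    for (sample, key), group in usable.groupby(["sample_id", by], sort=True):
        summ = _boxplot_summary(group["MR"].to_numpy(dtype=float), str(key))
        rows.append({"sample_id": sample, **summ.__dict__})
    present = set(usable[by])
    for key in set(records[by]) - present:
        logger.warning("class %r has no usable records; omitted from summary", key)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out[
            ["sample_id", "region_class", "n", "median", "q1", "q3",
             "whisker_low", "whisker_high"]
        ]
    return out


@dataclass(frozen=True)
class FractionRecovered:
    percent: float
    n_recovered: int
    n_total: int
    mr_threshold: float


def fraction_recovered(
    records: pd.DataFrame, mr_threshold: float = 50.0
) -> FractionRecovered:
    """Percent of usable regions with MR >= threshold ('substantially
    recovered'), with the underlying counts."""
    usable = records[~records["excluded"] & records["MR"].notna()]
    n_total = len(usable)
    if n_total == 0:
        raise ValidationError("no usable records to compute fraction recovered")
    n_rec = int((usable["MR"] >= mr_threshold).sum())
    return FractionRecovered(
        percent=100.0 * n_rec / n_total,
        n_recovered=n_rec,
        n_total=n_total,
        mr_threshold=mr_threshold,
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho between sample methylation profiles."""

    rho: pd.DataFrame
    undefined_pairs: list[tuple[str, str]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rho.columns)

    def min_offdiagonal(self) -> float:
        vals = self.rho.to_numpy(dtype=float).copy()
        np.fill_diagonal(vals, np.nan)
        return float(np.nanmin(vals))

    def write(self, path) -> None:
        out = self.rho.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def spearman_matrix(
    norm: NormalizedTable, region_subset: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Spearman correlation matrix over regions (Pearson on average ranks).

    Constant columns make rho undefined for their pairs; those entries are
    NaN and listed in ``undefined_pairs`` rather than being forced to 0.
    The diagonal is 1 by convention.
    """
    values = norm.values
    if region_subset is not None:
        values = values.loc[list(region_subset)]
    if values.shape[0] < 3:
        raise ValidationError("need >= 3 regions for a Spearman matrix")
    if values.shape[1] < 2:
        raise ValidationError("need >= 2 samples for a Spearman matrix")
    ranks = values.rank(axis=0, method="average")
    constant = [c for c in values.columns if values[c].nunique() == 1]
    rho = ranks.corr(method="pearson")
    undefined = []
    for c in constant:
        rho.loc[c, :] = np.nan
        rho.loc[:, c] = np.nan
        undefined.extend((c, other) for other in values.columns if other != c)
    arr = rho.to_numpy(dtype=float)
    np.fill_diagonal(arr, 1.0)
    rho = pd.DataFrame(arr, index=rho.index, columns=rho.columns)
    return CorrelationMatrix(rho=rho, undefined_pairs=sorted(set(
        tuple(sorted(p)) for p in undefined
    )))
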