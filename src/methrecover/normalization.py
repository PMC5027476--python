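"""Two-step between-sample normalization of MeDIP-seq count tables.

Step 1: scale each region's count to reads per kilobase of feature
(RPK = count / (length/1000)) and move to log2 with a pseudocount.

Step 2: anchor every sample to the reference (wild-type) profile using a set
of *invariant* regions — regions known not to change methylation between the
conditions.  An ordinary least-squares line of the sample's invariant-region
log2 values on the reference's is fitted, and the sample's whole profile is
affinely transformed so that this line becomes the identity (intercept 0,
gradient 1).  Global depth and efficiency differences between MeDIP libraries
are multiplicative on counts, hence additive in log space, which is exactly
what the affine correction removes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .regions import CountTable, RegionSet, SampleManifest


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs for the log2-RPK transform and the invariant regression.

    pseudocount
        Added to RPK before log2 so zero counts stay finite. 0.5 is the
        conventional half-count.
    reference_sample
        Sample the regression is fitted against; defaults to the manifest's
        reference role.
    direction
        ``"sample_on_reference"`` (default) regresses each sample on the
        reference; ``"reference_on_sample"`` inverts the roles and applies
        the fitted line directly instead of its inverse.
    """

    pseudocount: float = 0.5
    reference_sample: str | None = None
    direction: str = "sample_on_reference"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.direction not in ("sample_on_reference", "reference_on_sample"):
            raise ValidationError(f"unknown regression direction {self.direction!r}")


@dataclass(frozen=True)
class NormalizationModel:
    """Fitted invariant-region line for one sample vs the reference."""

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_invariant: int
    slope_stderr: float = math.nan
    intercept_stderr: float = math.nan

    def __post_init__(self) -> None:
        if self.n_invariant < 3:
            raise ValidationError("an applicable model needs >= 3 invariant regions")
        if self.slope == 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: fitted slope is 0 — inspect the "
                "invariant region set"
            )

    @classmethod
    def identity(cls, sample_id: str, n_invariant: int = 3) -> "NormalizationModel":
        return cls(sample_id, slope=1.0, intercept=0.0, r_squared=1.0,
                   n_invariant=n_invariant, slope_stderr=0.0, intercept_stderr=0.0)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r_squared,
            "n_invariant": self.n_invariant,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
        }


@dataclass
class NormalizedTable:
    """log2 normalized abundance per (region, sample) plus fit provenance."""

    values: pd.DataFrame
    models: dict[str, NormalizationModel] = field(default_factory=dict)
    reference_sample: str | None = None
    pseudocount: float = 0.5

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path, models_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "region_id"
        out.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")
        if models_path is not None:
            payload = {
                "reference_sample": self.reference_sample,
                "pseudocount": self.pseudocount,
                "models": [m.to_dict() for m in self.models.values()],
            }
            with open(models_path, "w", encoding="utf-8", newline="\n") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "NormalizedTable":
        values = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(values=values)


def rpk(count: float, length_bp: int) -> float:
    """Reads per kilobase of feature: count / (length_bp / 1000)."""
    if length_bp <= 0:
        raise ValidationError(f"length_bp must be positive, got {length_bp}")
    if count < 0:
        raise ValidationError(f"count must be non-negative, got {count}")
    return count / (length_bp / 1000.0)


def log2_rpk_table(
    table: CountTable,
    regions: RegionSet,
    config: NormalizationConfig | None = None,
) -> NormalizedTable:
    """log2(RPK + pseudocount) for every cell, before any affine correction."""
    config = config or NormalizationConfig()
    missing = [rid for rid in table.region_ids if rid not in regions]
    if missing:
        raise ValidationError(
            f"{len(missing)} region_ids in the count table have no region "
            f"(first: {missing[0]!r})"
        )
    lengths = regions.lengths().reindex(table.region_ids)
    kb = lengths.to_numpy(dtype=float) / 1000.0
    values = np.log2(table.counts.to_numpy(dtype=float) / kb[:, None] + config.pseudocount)
    frame = pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns)
    return NormalizedTable(values=frame, pseudocount=config.pseudocount)


def fit_invariant_model(
    sample_values: pd.Series,
    reference_values: pd.Series,
    invariant_ids: Sequence[str],
    sample_id: str | None = None,
) -> NormalizationModel:
    """OLS of sample (dependent) on reference (independent) over invariants."""
    if len(invariant_ids) < 3:
        raise ValidationError(
            f"need >= 3 invariant regions to fit, got {len(invariant_ids)}"
        )
    x = reference_values.loc[list(invariant_ids)].to_numpy(dtype=float)
    y = sample_values.loc[list(invariant_ids)].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("reference has zero variance over the invariant set")
    fit = stats.linregress(x, y)
    if fit.slope < 0:
        raise ValidationError(
            "negative slope on the invariant set: sample is anti-correlated with "
            "the reference, which indicates corrupt input"
        )
    return NormalizationModel(
        sample_id=sample_id or str(sample_values.name),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_invariant=len(invariant_ids),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def apply_model(sample_values: pd.Series, model: NormalizationModel) -> pd.Series:
    """Invert the fitted line: value' = (value - intercept) / slope.

    After this transform, refitting the invariant regression yields slope 1
    and intercept 0 (exact by the linearity of least squares, up to floating
    point).
    """
    if model.slope == 0:
        raise ValidationError("slope 0 model cannot be applied")
    return (sample_values - model.intercept) / model.slope


def normalize_dataset(
    table: CountTable,
    regions: RegionSet,
    manifest: SampleManifest,
    config: NormalizationConfig | None = None,
) -> NormalizedTable:
    """Full normalization: log2 RPK, then per-sample invariant-line correction.

    The reference column is left as its own log2 RPK (identity model); every
    other column gets its own fitted model, recorded in the result's
    provenance.
    """
    config = config or NormalizationConfig()
    reference = config.reference_sample or manifest.reference
    if reference not in table.sample_ids:
        raise ValidationError(f"reference sample {reference!r} not in count table")
    invariant_ids = [rid for rid in regions.invariant_ids if rid in table.counts.index]
    raw = log2_rpk_table(table, regions, config)
    out = raw.values.copy()
    models: dict[str, NormalizationModel] = {}
    ref_values = raw.values[reference]
    for sample in raw.sample_ids:
        if sample == reference:
            continue
        if config.direction == "sample_on_reference":
            model = fit_invariant_model(
                raw.values[sample], ref_values, invariant_ids, sample_id=sample
            )
            out[sample] = apply_model(raw.values[sample], model)
        else:
            model = fit_invariant_model(
                ref_values, raw.values[sample], invariant_ids, sample_id=sample
            )
            out[sample] = raw.values[sample] * model.slope + model.intercept
        models[sample] = model
    return NormalizedTable(
        values=out,
        models=models,
        reference_sample=reference,
        pseudocount=config.pseudocount,
    )
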