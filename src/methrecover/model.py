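"""Model/Results front end over the normalization + recovery pipeline.

``MethylationRecovery`` is constructed from a count table, a region
annotation and a sample manifest; ``fit()`` performs the invariant-region
normalization and computes per-region methylation-recovery records,
returning a :class:`MethylationRecoveryResults` that carries the estimates,
their provenance and the usual summaries (class boxplot statistics, the
promoter-recovery fraction, the pairwise Spearman matrix and a text
``summary()`` table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__ as _version
from .exceptions import ValidationError
from .normalization import (
    NormalizationConfig,
    NormalizationModel,
    NormalizedTable,
    normalize_dataset,
)
from .recovery import (
    CorrelationMatrix,
    FractionRecovered,
    fraction_recovered,
    recovery_table,
    spearman_matrix,
    summarize_recovery,
)
from .regions import (
    CountTable,
    RegionSet,
    SampleManifest,
    read_count_table,
    read_manifest,
    read_regions,
)


class MethylationRecovery:
    """Methylation-recovery model for a rescue experiment.

    Parameters
    ----------
    counts
        Region x sample read counts with library sizes.
    regions
        Annotated regions; the invariant flag marks the normalization anchors.
    manifest
        Sample roles: one reference (wild-type), one baseline (null), any
        number of test (rescue) samples.
    config
        Normalization knobs (pseudocount, reference, regression direction).
    """

    def __init__(
        self,
        counts: CountTable,
        regions: RegionSet,
        manifest: SampleManifest,
        config: NormalizationConfig | None = None,
    ):
        missing = [s for s in manifest.sample_ids if s not in counts.sample_ids]
        if missing:
            raise ValidationError(f"manifest samples missing from counts: {missing}")
        if not regions.invariant_ids:
            raise ValidationError("no invariant regions flagged; normalization needs them")
        self.counts = counts
        self.regions = regions
        self.manifest = manifest
        self.config = config or NormalizationConfig()

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        regions_path: str | Path,
        manifest_path: str | Path,
        config: NormalizationConfig | None = None,
    ) -> "MethylationRecovery":
        return cls(
            counts=read_count_table(counts_path),
            regions=read_regions(regions_path),
            manifest=read_manifest(manifest_path),
            config=config,
        )

    def fit(self, d_min: float = 1.0, clamp: bool = False) -> "MethylationRecoveryResults":
        """Normalize and compute MR records for every test sample.

        d_min is the minimum log2 wild-type-vs-baseline deficit for a region
        to count as LSH-dependent (default 1.0 = 2-fold).
        """
        normalized = normalize_dataset(self.counts, self.regions, self.manifest, self.config)
        records = recovery_table(normalized, self.manifest, self.regions, d_min, clamp)
        return MethylationRecoveryResults(
            model=self, normalized=normalized, records=records, d_min=d_min, clamp=clamp
        )


@dataclass
class MethylationRecoveryResults:
    """Fit output: normalized table, fitted models and per-region records."""

    model: MethylationRecovery
    normalized: NormalizedTable
    records: pd.DataFrame
    d_min: float
    clamp: bool

    @property
    def normalization_models(self) -> dict[str, NormalizationModel]:
        return self.normalized.models

    def class_summaries(self, sample: str | None = None) -> pd.DataFrame:
        """Boxplot summaries of MR per (sample, region class)."""
        out = summarize_recovery(self.records)
        if sample is not None:
            out = out[out["sample_id"] == sample].reset_index(drop=True)
        return out

    def class_medians(self, sample: str) -> pd.Series:
        summ = self.class_summaries(sample)
        return summ.set_index("region_class")["median"]

    def fraction_recovered(
        self,
        mr_threshold: float = 50.0,
        region_class: str | None = None,
        sample: str | None = None,
    ) -> FractionRecovered:
        records = self.records
        if region_class is not None:
            records = records[records["region_class"] == region_class]
        if sample is not None:
            records = records[records["sample_id"] == sample]
        return fraction_recovered(records, mr_threshold)

    def correlation(self, region_subset: Sequence[str] | None = None) -> CorrelationMatrix:
        return spearman_matrix(self.normalized, region_subset)

    def exclusion_report(self) -> pd.DataFrame:
        excluded = self.records[self.records["excluded"]]
        return (
            excluded.groupby(["sample_id", "excluded_reason"])
            .size()
            .rename("n_regions")
            .reset_index()
        )

    def summary(self) -> str:
        """Human-readable fit report in the style of a regression summary."""
        lines = []
        w = 72
        lines.append("Methylation Recovery Results".center(w))
        lines.append("=" * w)
        m = self.model.manifest
        lines.append(f"Reference (wild-type):  {m.reference}")
        lines.append(f"Baseline (null):        {m.baseline}")
        lines.append(f"Test samples:           {', '.join(m.tests)}")
        lines.append(
            f"Regions: {len(self.model.regions)}   "
            f"invariant: {len(self.model.regions.invariant_ids)}   "
            f"d_min: {self.d_min:g} log2"
        )
        lines.append("-" * w)
        lines.append("Invariant-region normalization (per sample vs reference)")
        lines.append(
            f"{'sample':<12}{'slope':>10}{'(se)':>10}{'intercept':>12}{'(se)':>10}"
            f"{'r2':>8}{'n':>8}"
        )
        for mod in self.normalization_models.values():
            lines.append(
                f"{mod.sample_id:<12}{mod.slope:>10.4f}{mod.slope_stderr:>10.4f}"
                f"{mod.intercept:>12.4f}{mod.intercept_stderr:>10.4f}"
                f"{mod.r_squared:>8.3f}{mod.n_invariant:>8d}"
            )
        lines.append("-" * w)
        lines.append("Methylation recovery (MR, %) by region class")
        summ = self.class_summaries()
        lines.append(
            f"{'sample':<12}{'class':<24}{'n':>6}{'median':>9}{'q1':>8}{'q3':>8}"
        )
        for row in summ.itertuples():
            lines.append(
                f"{row.sample_id:<12}{row.region_class:<24}{row.n:>6d}"
                f"{row.median:>9.1f}{row.q1:>8.1f}{row.q3:>8.1f}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_recovery(self, ax=None):
        """Boxplots of MR by region class, one group of boxes per test sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        usable = self.records[~self.records["excluded"] & self.records["MR"].notna()]
        classes = sorted(usable["region_class"].unique())
        samples = sorted(usable["sample_id"].unique())
        width = 0.8 / max(len(samples), 1)
        for k, sample in enumerate(samples):
            data = [
                usable[(usable["sample_id"] == sample) & (usable["region_class"] == c)][
                    "MR"
                ].to_numpy()
                for c in classes
            ]
            positions = [i + (k - (len(samples) - 1) / 2) * width for i in range(len(classes))]
            ax.boxplot(data, positions=positions, widths=width * 0.9, whis=1.5,
                       showfliers=False, label=sample)
        ax.set_xticks(range(len(classes)))
        ax.set_xticklabels(classes, rotation=30, ha="right")
        ax.set_ylabel("methylation recovery (%)")
        ax.legend()
        return ax

    def to_dir(self, outdir: str | Path, mr_threshold: float = 50.0) -> dict[str, str]:
        """Write the standard output set: records, summaries, correlation,
        normalized table + model side-car and a JSON run report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": outdir / "recovery_records.tsv",
            "summaries": outdir / "recovery_summary.tsv",
            "correlation": outdir / "spearman_matrix.tsv",
            "normalized": outdir / "normalized.tsv",
            "models": outdir / "normalization_models.json",
            "report": outdir / "report.json",
        }
        records = self.records.copy()
        records.to_csv(paths["records"], sep="\t", index=False,
                       float_format="%.10g", lineterminator="\n")
        self.class_summaries().to_csv(paths["summaries"], sep="\t", index=False,
                                      float_format="%.10g", lineterminator="\n")
        corr = self.correlation()
        corr.write(paths["correlation"])
        self.normalized.write(paths["normalized"], paths["models"])
        frac = {}
        for sample in self.model.manifest.tests:
            try:
                f = self.fraction_recovered(mr_threshold, region_class="promoter",
                                            sample=sample)
                frac[sample] = {
                    "percent": f.percent,
                    "n_recovered": f.n_recovered,
                    "n_total": f.n_total,
                }
            except ValidationError:
                frac[sample] = None
        report = {
            "version": _version,
            "d_min": self.d_min,
            "clamp": self.clamp,
            "mr_threshold": mr_threshold,
            "n_regions": len(self.model.regions),
            "n_invariant": len(self.model.regions.invariant_ids),
            "promoter_fraction_recovered": frac,
            "min_offdiagonal_spearman": corr.min_offdiagonal(),
            "normalization_models": [
                m.to_dict() for m in self.normalization_models.values()
            ],
        }
        with open(paths["report"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}
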