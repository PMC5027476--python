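"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study design end to end: a four-class region
annotation (promoters, gene bodies, intergenic blocks, repeat families) with
a flagged set of invariant regions; a wild-type methylome; a null baseline
whose losses concentrate at "LSH-dependent" regions; rescue methylomes with
class-dependent partial recovery; and overdispersed MeDIP-style counts whose
mean is proportional to the methylation-driven pulldown signal.

Two modelling choices matter for interpreting the truth values:

* The pulldown signal of a region with methylation level ``m`` is
  ``background + (1 - background) * m`` — unmethylated DNA is pulled down at
  a small background rate.
* A rescue sample with recovery fraction ``rho`` interpolates between the
  baseline and wild-type *geometrically on the signal scale*
  (``s = s_baseline^(1-rho) * s_wt^rho``).  The methylation-recovery
  statistic MR is a ratio of log2 signal differences, so this choice makes
  ``rho`` the exact noise-free truth for MR/100; linear interpolation of
  methylation levels would make the truth depend on the region's deficit.
* Every region additionally carries an *enrichment propensity* — a
  multiplier on its expected count that is constant across samples,
  emulating CpG density, mappability and repeat copy-number variation.  It
  adds the same constant to each sample's log2 value at that region, so it
  cancels exactly in MR, but it gives the count table the wide per-region
  dynamic range real MeDIP data has.  Without it the invariant-region
  regression would have no leverage: all anchor points would sit in one
  narrow log2 band and the fitted slope would be dominated by measurement
  noise (textbook errors-in-variables attenuation).

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bisulfite import Amplicon
from .exceptions import ValidationError
from .regions import (
    CountTable,
    GenomicRegion,
    RegionSet,
    Sample,
    SampleManifest,
    write_count_table,
    write_regions,
)


@dataclass(frozen=True)
class SampleSim:
    """Simulation settings for one sample: its role, true recovery fraction rho
    (tests only) and optional per-class multipliers on rho."""

    sample_id: str
    role: str
    rho: float = 0.0
    class_bias: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def effective_rho(self, region_class: str) -> float:
        return float(np.clip(self.rho * self.class_bias.get(region_class, 1.0), 0.0, 1.0))


@dataclass
class SimulationParams:
    """Everything the generators need, minus the seed.

    depth is the expected read count of a fully methylated 1 kb region at
    library factor 1; dispersion is the negative-binomial overdispersion
    (variance = mu + dispersion * mu^2); background is the pulldown rate of
    unmethylated DNA relative to methylated DNA.
    """

    n_regions: dict[str, int]
    region_length: dict[str, tuple[int, int]]
    samples: list[SampleSim]
    fraction_lsh_dependent: dict[str, float] = field(
        default_factory=lambda: {"default": 0.5}
    )
    wt_methylation: tuple[float, float] = (0.55, 0.95)
    invariant_methylation: tuple[float, float] = (0.05, 0.95)
    region_effect_log2_range: tuple[float, float] = (0.0, 6.0)
    loss_fraction: float = 0.95
    depth: float = 200.0
    dispersion: float = 0.2
    background: float = 0.05
    n_invariant: int = 100
    library_factor_range: tuple[float, float] = (0.5, 2.0)
    n_clones: int = 50
    conversion_failure: float = 0.02
    seq_error: float = 0.002
    qpcr_ct_sd: float = 0.1
    hplc_area_sigma: float = 0.02

    def __post_init__(self) -> None:
        for name, p in (
            ("loss_fraction", self.loss_fraction),
            ("background", self.background),
            ("conversion_failure", self.conversion_failure),
            ("seq_error", self.seq_error),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for cls, n in self.n_regions.items():
            if n <= 0:
                raise ValidationError(f"zero regions requested in class {cls!r}")

    def dependent_fraction(self, region_class: str) -> float:
        return self.fraction_lsh_dependent.get(
            region_class, self.fraction_lsh_dependent.get("default", 0.5)
        )

    def manifest(self) -> SampleManifest:
        return SampleManifest(
            samples=[Sample(s.sample_id, s.role, s.label) for s in self.samples]
        )

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationParams":
        payload = dict(payload)
        samples = [
            SampleSim(
                sample_id=str(e["id"]),
                role=str(e["role"]),
                rho=float(e.get("rho", 0.0)),
                class_bias=dict(e.get("class_bias", {})),
                label=str(e.get("label", "")),
            )
            for e in payload.pop("samples")
        ]
        bis = payload.pop("bisulfite", {})
        assay = payload.pop("assays", {})
        return cls(
            n_regions={k: int(v) for k, v in payload.pop("n_regions").items()},
            region_length={
                k: (int(v[0]), int(v[1]))
                for k, v in payload.pop("region_length").items()
            },
            samples=samples,
            fraction_lsh_dependent={
                k: float(v)
                for k, v in payload.pop("fraction_lsh_dependent", {"default": 0.5}).items()
            },
            wt_methylation=tuple(payload.pop("wt_methylation", (0.55, 0.95))),
            invariant_methylation=tuple(
                payload.pop("invariant_methylation", (0.05, 0.95))
            ),
            region_effect_log2_range=tuple(
                payload.pop("region_effect_log2_range", (0.0, 6.0))
            ),
            loss_fraction=float(payload.pop("loss_fraction", 0.95)),
            depth=float(payload.pop("depth", 200.0)),
            dispersion=float(payload.pop("dispersion", 0.2)),
            background=float(payload.pop("background", 0.05)),
            n_invariant=int(payload.pop("n_invariant", 100)),
            library_factor_range=tuple(payload.pop("library_factor_range", (0.5, 2.0))),
            n_clones=int(bis.get("n_clones", 50)),
            conversion_failure=float(bis.get("conversion_failure", 0.02)),
            seq_error=float(bis.get("seq_error", 0.002)),
            qpcr_ct_sd=float(assay.get("qpcr_ct_sd", 0.1)),
            hplc_area_sigma=float(assay.get("hplc_area_sigma", 0.02)),
        )

    @classmethod
    def lsh_rescue(cls) -> "SimulationParams":
        """The default preset echoing the study's four-sample design."""
        ref = importlib.resources.files("methrecover") / "presets" / "lsh_rescue.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthTable:
    """Ground-truth methylation per (region, sample) plus region metadata."""

    methylation: pd.DataFrame  # regions x samples, values in [0, 1]
    region_info: pd.DataFrame  # columns: region_class, length, lsh_dependent, invariant

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_info": self.region_info.reset_index().to_dict(orient="list"),
            "methylation": {
                s: [float(v) for v in self.methylation[s]]
                for s in self.methylation.columns
            },
            "region_ids": list(self.methylation.index),
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")


def _region_id(region_class: str, i: int) -> str:
    return f"{region_class.replace(':', '_')}_{i:05d}"


def simulate_annotation(params: SimulationParams, seed: int) -> RegionSet:
    """Lay out the requested regions on a toy genome and flag invariants.

    Regions are placed sequentially with gaps (no overlap), lengths drawn
    uniformly per class; LSH-dependent flags are drawn per class at the
    configured fraction and the invariant set is sampled from the
    non-dependent remainder (invariant regions must not change between
    samples by construction).
    """
    rng = np.random.default_rng(seed)
    regions: list[GenomicRegion] = []
    dependent: dict[str, bool] = {}
    cursor = 1000
    for region_class, n in params.n_regions.items():
        lo, hi = params.region_length.get(region_class, (1000, 5000))
        lengths = rng.integers(lo, hi + 1, size=n)
        n_dep = int(round(params.dependent_fraction(region_class) * n))
        dep_flags = np.zeros(n, dtype=bool)
        dep_flags[rng.choice(n, size=n_dep, replace=False)] = True
        for i in range(n):
            rid = _region_id(region_class, i)
            regions.append(
                GenomicRegion(
                    chrom="chr1",
                    start=cursor,
                    end=cursor + int(lengths[i]),
                    region_id=rid,
                    region_class=region_class,
                )
            )
            dependent[rid] = bool(dep_flags[i])
            cursor += int(lengths[i]) + 500
    non_dep = [r.region_id for r in regions if not dependent[r.region_id]]
    if params.n_invariant > len(non_dep):
        raise ValidationError(
            f"cannot flag {params.n_invariant} invariant regions: only "
            f"{len(non_dep)} non-LSH-dependent regions available"
        )
    invariant_ids = rng.choice(non_dep, size=params.n_invariant, replace=False)
    region_set = RegionSet(regions).with_invariants(invariant_ids)
    region_set._dependent = dependent  # carried for simulate_methylomes
    return region_set


def region_info(regions: RegionSet) -> pd.DataFrame:
    dependent = getattr(regions, "_dependent", {})
    return pd.DataFrame(
        {
            "region_class": [r.region_class for r in regions],
            "length": [r.length for r in regions],
            "lsh_dependent": [bool(dependent.get(r.region_id, False)) for r in regions],
            "invariant": [r.invariant for r in regions],
        },
        index=pd.Index(regions.ids, name="region_id"),
    )


def pulldown_signal(methylation: np.ndarray, background: float) -> np.ndarray:
    """Relative MeDIP pulldown rate of a region at a given methylation."""
    return background + (1.0 - background) * methylation


def simulate_methylomes(
    regions: RegionSet, params: SimulationParams, seed: int
) -> TruthTable:
    """Draw the wild-type methylome and derive baseline and rescue samples.

    Baseline = WT * (1 - loss_fraction) at LSH-dependent regions, = WT
    elsewhere.  Each test sample interpolates geometrically on the signal
    scale with its effective rho (rho times the class bias, clipped to
    [0, 1]), so its true MR equals 100 * effective_rho exactly.
    """
    rng = np.random.default_rng(seed)
    info = region_info(regions)
    n = len(regions)
    lo, hi = params.wt_methylation
    wt = rng.uniform(lo, hi, size=n)
    inv = info["invariant"].to_numpy()
    ilo, ihi = params.invariant_methylation
    wt[inv] = rng.uniform(ilo, ihi, size=int(inv.sum()))
    elo, ehi = params.region_effect_log2_range
    info["effect_log2"] = rng.uniform(elo, ehi, size=n)
    dep = info["lsh_dependent"].to_numpy()
    baseline = np.where(dep, wt * (1.0 - params.loss_fraction), wt)
    manifest = params.manifest()
    columns: dict[str, np.ndarray] = {}
    sig_wt = pulldown_signal(wt, params.background)
    sig_base = pulldown_signal(baseline, params.background)
    classes = info["region_class"].to_numpy()
    for s in params.samples:
        if s.role == "reference":
            columns[s.sample_id] = wt
        elif s.role == "baseline":
            columns[s.sample_id] = baseline
        else:
            rho_eff = np.array([s.effective_rho(c) for c in classes])
            sig = sig_base ** (1.0 - rho_eff) * sig_wt**rho_eff
            meth = (sig - params.background) / (1.0 - params.background)
            columns[s.sample_id] = np.clip(meth, 0.0, 1.0)
    methylation = pd.DataFrame(
        columns, index=info.index, columns=manifest.sample_ids
    )
    return TruthTable(methylation=methylation, region_info=info)


def simulate_medip_counts(
    truth: TruthTable, params: SimulationParams, seed: int
) -> CountTable:
    """Overdispersed counts: mean = library_factor * kb * depth * signal.

    Counts are negative-binomial with variance mu + dispersion * mu^2
    (Poisson when dispersion is 0).  Per-sample library factors are drawn
    uniformly from ``library_factor_range`` to force the invariant-region
    normalization to do real work.
    """
    rng = np.random.default_rng(seed)
    kb = truth.region_info["length"].to_numpy(dtype=float) / 1000.0
    if "effect_log2" in truth.region_info.columns:
        effect = 2.0 ** truth.region_info["effect_log2"].to_numpy(dtype=float)
    else:
        effect = np.ones(len(kb))
    samples = list(truth.methylation.columns)
    lib = rng.uniform(*params.library_factor_range, size=len(samples))
    counts = {}
    for j, sample in enumerate(samples):
        sig = pulldown_signal(truth.methylation[sample].to_numpy(), params.background)
        mu = lib[j] * kb * params.depth * sig * effect
        if params.dispersion > 0:
            size = 1.0 / params.dispersion
            p = size / (size + mu)
            counts[sample] = rng.negative_binomial(size, p)
        else:
            counts[sample] = rng.poisson(mu)
    frame = pd.DataFrame(counts, index=truth.methylation.index)
    return CountTable(counts=frame)


def emit_reads(
    regions: RegionSet,
    counts: CountTable,
    sample_id: str,
    read_length: int = 50,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Read intervals that reproduce one count column when re-counted.

    Each region gets its count's worth of reads placed fully inside it
    (regions from :func:`simulate_annotation` never overlap, so interval
    counting recovers the column exactly).
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, int, int]] = []
    for r in regions:
        c = int(counts.counts.loc[r.region_id, sample_id])
        rl = min(read_length, r.length)
        starts = rng.integers(r.start, r.end - rl + 1, size=c)
        reads.extend((r.chrom, int(s), int(s) + rl) for s in starts)
    return reads


def simulate_amplicon(
    name: str, length: int = 400, n_cpgs: int = 12, seed: int = 0
) -> Amplicon:
    """A random amplicon with exactly ``n_cpgs`` CpGs and no accidental ones."""
    if length < 4 * n_cpgs + 10:
        raise ValidationError("amplicon too short for the requested CpG count")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = []
    for _ in range(length):
        prev = seq[-1] if seq else ""
        choices = "ACT" if prev == "C" else bases  # never create CG by chance
        seq.append(choices[rng.integers(len(choices))])
    # drop CpG dinucleotides at evenly spread, non-adjacent positions
    positions = np.linspace(5, length - 5, n_cpgs).astype(int)
    for p in positions:
        seq[p] = "C"
        seq[p + 1] = "G"
        if p + 2 < length and seq[p + 2] == "G":
            seq[p + 2] = "A"  # guard: G after the CpG is fine, C before is not
        if seq[p - 1] == "C":
            seq[p - 1] = "A"
    amp = Amplicon.from_sequence(name, "".join(seq))
    if amp.n_cpgs != n_cpgs:
        raise AssertionError("amplicon construction produced stray CpGs")
    return amp


def simulate_bisulfite_clones(
    amplicon: Amplicon,
    per_cpg_probabilities: Sequence[float],
    n_clones: int,
    conversion_failure: float = 0.0,
    seq_error: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Simulate bisulfite-converted clone sequences.

    Each CpG C is retained (methylated) with its probability, otherwise read
    as T; every non-CpG C converts to T except with ``conversion_failure``
    probability; uniform base errors are applied at ``seq_error`` per base.
    Returns (clones, truth) where truth[i, k] is clone i's methylation state
    at CpG k before sequencing errors.
    """
    probs = np.asarray(per_cpg_probabilities, dtype=float)
    if probs.shape != (amplicon.n_cpgs,):
        raise ValidationError(
            f"need {amplicon.n_cpgs} CpG probabilities, got {probs.shape}"
        )
    if ((probs < 0) | (probs > 1)).any():
        raise ValidationError("CpG probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = amplicon.reference_sequence
    cpg_set = set(amplicon.cpg_positions)
    truth = np.zeros((n_clones, amplicon.n_cpgs), dtype=bool)
    clones: list[tuple[str, str]] = []
    bases = "ACGT"
    for i in range(n_clones):
        seq = list(ref)
        for k, p in enumerate(amplicon.cpg_positions):
            methylated = rng.random() < probs[k]
            truth[i, k] = methylated
            if not methylated:
                seq[p] = "T"
        for p, base in enumerate(ref):
            if base == "C" and p not in cpg_set:
                if rng.random() >= conversion_failure:
                    seq[p] = "T"
        if seq_error > 0:
            for p in range(len(seq)):
                if rng.random() < seq_error:
                    seq[p] = bases[(bases.index(seq[p]) + rng.integers(1, 4)) % 4]
        clones.append((f"clone_{i + 1:03d}", "".join(seq)))
    return clones, truth


def simulate_assays(
    params: SimulationParams, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """qPCR Ct table and HPLC peak-area table with their ground truth.

    qPCR: targets with known fold changes; observed delta-Cts carry Gaussian
    cycle noise of sd ``qpcr_ct_sd``.  HPLC: per-sample true percent 5mC of
    the cytosine pool; peak areas are molar amounts times the extinction
    coefficients with multiplicative lognormal noise.
    """
    from .assays import EPS_5MDCMP, EPS_DCMP

    rng = np.random.default_rng(seed)
    true_folds = {"Rhox2": 6.0, "Rhox4": 3.5, "Dazl": 0.4, "Hoxb1": 1.0}
    e_target, e_reference = 1.95, 2.0
    qpcr_rows = []
    for target, fold in true_folds.items():
        dct_ref = rng.uniform(-0.5, 0.5)
        dct_t = (np.log(fold) + dct_ref * np.log(e_reference)) / np.log(e_target)
        qpcr_rows.append(
            {
                "target": target,
                "e_target": e_target,
                "e_reference": e_reference,
                "delta_ct_target": dct_t + rng.normal(0, params.qpcr_ct_sd),
                "delta_ct_reference": dct_ref + rng.normal(0, params.qpcr_ct_sd),
            }
        )
    true_5mc = {"WT": 3.3, "MSCV": 1.72, "LSH": 2.48, "K237Q": 1.80}
    hplc_rows = []
    for sample, pct in true_5mc.items():
        n_5mc = pct / 100.0
        n_c = 1.0 - n_5mc
        hplc_rows.append(
            {
                "sample": sample,
                "area_c": n_c * EPS_DCMP * rng.lognormal(0, params.hplc_area_sigma),
                "area_5mc": n_5mc
                * EPS_5MDCMP
                * rng.lognormal(0, params.hplc_area_sigma),
            }
        )
    truth = {"fold_changes": true_folds, "percent_5mc": true_5mc}
    return pd.DataFrame(qpcr_rows), pd.DataFrame(hplc_rows), truth


@dataclass
class SimulatedDataset:
    regions: RegionSet
    manifest: SampleManifest
    truth: TruthTable
    counts: CountTable

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "regions": outdir / "regions.bed",
            "counts": outdir / "counts.tsv",
            "manifest": outdir / "manifest.yaml",
            "truth": outdir / "truth.json",
        }
        write_regions(self.regions, paths["regions"])
        write_count_table(self.counts, paths["counts"])
        self.manifest.to_yaml(paths["manifest"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def simulate_dataset(params: SimulationParams, seed: int) -> SimulatedDataset:
    """Annotation + methylomes + counts in one call (sub-seeds derived)."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    regions = simulate_annotation(params, seeds[0])
    truth = simulate_methylomes(regions, params, seeds[1])
    counts = simulate_medip_counts(truth, params, seeds[2])
    return SimulatedDataset(
        regions=regions, manifest=params.manifest(), truth=truth, counts=counts
    )
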