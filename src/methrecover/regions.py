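"""Genomic region annotations, BED / count-table IO and interval counting.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Callers holding 1-based inclusive intervals must convert before entry.

Region classes are free strings from the vocabulary
``{promoter, gene_body, intergenic, repeat:<family>}``; repeat families are
open-ended (``repeat:IAP``, ``repeat:minor_satellite`` ...).  The ``invariant``
flag marks regions whose methylation is assumed identical across samples;
these anchor the between-sample normalization.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .exceptions import ParseError, ValidationError

KNOWN_BASE_CLASSES = ("promoter", "gene_body", "intergenic")
DEFAULT_CLASS = "intergenic"

_INVARIANT_TRUE = {"1", "invariant", "true", "yes"}
_INVARIANT_FALSE = {"0", ".", "false", "no", ""}


def _valid_class(region_class: str) -> bool:
    return region_class in KNOWN_BASE_CLASSES or region_class.startswith("repeat:")


@dataclass(frozen=True)
class GenomicRegion:
    """One interval with a class label and an invariant flag."""

    chrom: str
    start: int
    end: int
    region_id: str
    region_class: str = DEFAULT_CLASS
    invariant: bool = False

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"region {self.region_id!r}: empty chromosome name")
        if self.start < 0:
            raise ValidationError(
                f"region {self.region_id!r}: negative start {self.start}"
            )
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.region_id!r}: start {self.start} >= end {self.end}"
            )
        if not _valid_class(self.region_class):
            raise ValidationError(
                f"region {self.region_id!r}: unknown class {self.region_class!r} "
                f"(expected one of {KNOWN_BASE_CLASSES} or 'repeat:<family>')"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


class RegionSet:
    """Ordered collection of :class:`GenomicRegion` with unique ids.

    Regions may overlap each other (repeats nested in genes are legitimate).
    """

    def __init__(self, regions: Iterable[GenomicRegion], genome: str | None = None):
        self.regions: list[GenomicRegion] = list(regions)
        self.genome = genome
        seen: set[str] = set()
        for r in self.regions:
            if r.region_id in seen:
                raise ValidationError(f"duplicate region_id {r.region_id!r}")
            seen.add(r.region_id)
        self._by_id = {r.region_id: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, region_id: str) -> GenomicRegion:
        return self._by_id[region_id]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def invariant_ids(self) -> list[str]:
        return [r.region_id for r in self.regions if r.invariant]

    def lengths(self) -> pd.Series:
        return pd.Series(
            [r.length for r in self.regions], index=self.ids, name="length"
        )

    def classes(self) -> pd.Series:
        return pd.Series(
            [r.region_class for r in self.regions], index=self.ids, name="region_class"
        )

    def subset(self, region_ids: Sequence[str]) -> "RegionSet":
        return RegionSet([self._by_id[i] for i in region_ids], genome=self.genome)

    def with_invariants(self, invariant_ids: Iterable[str]) -> "RegionSet":
        """Return a copy with the invariant flag set on the given ids."""
        wanted = set(invariant_ids)
        unknown = wanted - set(self._by_id)
        if unknown:
            raise ValidationError(f"unknown invariant region ids: {sorted(unknown)!r}")
        return RegionSet(
            [replace(r, invariant=r.region_id in wanted) for r in self.regions],
            genome=self.genome,
        )


def read_regions(
    path: str | Path,
    class_map: Mapping[str, int] | None = None,
    default_class: str = DEFAULT_CLASS,
) -> RegionSet:
    """Read a BED file (>= 3 columns) into a :class:`RegionSet`.

    Columns 1-4 are chrom / start / end / name.  By default column 5 carries
    the region class and column 6 the invariant flag; ``class_map`` may remap
    those via 0-based indices, e.g. ``{"region_class": 5, "invariant": 6}``.
    Missing name columns auto-generate ids ``region_0001`` in file order.
    """
    class_col = 4 if class_map is None else class_map.get("region_class", 4)
    inv_col = 5 if class_map is None else class_map.get("invariant", 5)
    regions: list[GenomicRegion] = []
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated BED fields, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line_number=lineno)
            region_id = (
                fields[3]
                if len(fields) > 3 and fields[3]
                else f"region_{len(regions) + 1:04d}"
            )
            region_class = (
                fields[class_col]
                if len(fields) > class_col and fields[class_col]
                else default_class
            )
            invariant = False
            if len(fields) > inv_col:
                flag = fields[inv_col].strip().lower()
                if flag in _INVARIANT_TRUE:
                    invariant = True
                elif flag not in _INVARIANT_FALSE:
                    raise ParseError(
                        f"unrecognized invariant flag {fields[inv_col]!r}",
                        line_number=lineno,
                    )
            try:
                regions.append(
                    GenomicRegion(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        region_id=region_id,
                        region_class=region_class,
                        invariant=invariant,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} line {lineno}: {exc}") from exc
    return RegionSet(regions)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write BED with columns chrom/start/end/id/class[/invariant].

    The invariant column (1/0) is emitted only when at least one region is
    flagged, so canonical 5-column files round-trip byte-identically.
    """
    any_invariant = any(r.invariant for r in regions)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end), r.region_id, r.region_class]
            if any_invariant:
                fields.append("1" if r.invariant else "0")
            fh.write("\t".join(fields) + "\n")


def read_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read plain (chrom, start, end) intervals from a BED file, e.g. reads."""
    out: list[tuple[str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 BED fields", line_number=lineno)
            try:
                out.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", line_number=lineno)
    return out


def write_intervals(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class CountTable:
    """Region x sample matrix of read counts plus per-sample library sizes.

    ``counts`` is indexed by region_id with one integer column per sample.
    ``library_size`` is the total mapped reads per sample; it may exceed the
    column sum (reads falling outside the region universe are normal).
    """

    counts: pd.DataFrame
    library_size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate region_ids in count table")
        if not self.library_size:
            self.library_size = {
                s: int(self.counts[s].sum()) for s in self.counts.columns
            }
        missing = set(self.counts.columns) - set(self.library_size)
        if missing:
            raise ValidationError(f"library_size missing for samples {sorted(missing)}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def join(self, other: "CountTable") -> "CountTable":
        """Column-bind two tables over identical region universes."""
        if list(other.counts.index) != list(self.counts.index):
            raise ValidationError("cannot join count tables over different regions")
        return CountTable(
            counts=pd.concat([self.counts, other.counts], axis=1),
            library_size={**self.library_size, **other.library_size},
        )


def count_reads_in_regions(
    reads: Iterable[tuple[str, int, int]],
    regions: RegionSet,
    min_overlap_bp: int = 1,
    sample_id: str = "sample",
) -> CountTable:
    """Count read intervals overlapping each region by >= ``min_overlap_bp``.

    A read overlapping k regions contributes to all k (no fractional
    assignment), mirroring default coverage-counter behaviour.  Strand is
    ignored: MeDIP enrichment is strand-agnostic.
    """
    if len(regions) == 0:
        raise ValidationError("empty RegionSet")
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    n_reads = 0
    for i, (chrom, start, end) in enumerate(reads):
        if start < 0 or start >= end:
            raise ValidationError(f"read {i}: bad interval ({chrom}, {start}, {end})")
        trees[chrom].addi(start, end, i)  # data=i keeps duplicate intervals distinct
        n_reads += 1
    counts = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            counts.append(0)
            continue
        n = sum(
            1
            for iv in tree.overlap(r.start, r.end)
            if min(iv.end, r.end) - max(iv.begin, r.start) >= min_overlap_bp
        )
        counts.append(n)
    frame = pd.DataFrame({sample_id: counts}, index=pd.Index(regions.ids, name="region_id"))
    return CountTable(counts=frame, library_size={sample_id: n_reads})


_LIBSIZE_PREFIX = "#library_size"


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        sizes = "\t".join(f"{s}={table.library_size[s]}" for s in table.sample_ids)
        fh.write(f"{_LIBSIZE_PREFIX}\t{sizes}\n")
        fh.write("region_id\t" + "\t".join(table.sample_ids) + "\n")
        for region_id, row in table.counts.iterrows():
            fh.write(region_id + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (header ``region_id<TAB>sample...``).

    An optional first comment line ``#library_size<TAB>S1=n<TAB>...`` carries
    total mapped reads per sample; absent that, column sums are used.
    """
    library_size: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lineno = 0
    if lines and lines[0].startswith(_LIBSIZE_PREFIX):
        for item in lines[0].split("\t")[1:]:
            sample, _, value = item.partition("=")
            try:
                library_size[sample] = int(value)
            except ValueError:
                raise ParseError(f"bad library_size entry {item!r}", line_number=1)
        lineno = 1
        lines = lines[1:]
    if not lines or not lines[0].startswith("region_id\t"):
        raise ParseError(
            "missing header: first non-comment line must start with 'region_id<TAB>'",
            line_number=lineno + 1,
        )
    samples = lines[0].split("\t")[1:]
    if len(set(samples)) != len(samples):
        raise ParseError("duplicate sample ids in header", line_number=lineno + 1)
    region_ids: list[str] = []
    rows: list[list[int]] = []
    for offset, line in enumerate(lines[1:], start=lineno + 2):
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"ragged row: expected {len(samples) + 1} fields, got {len(fields)}",
                line_number=offset,
            )
        try:
            values = [int(v) for v in fields[1:]]
        except ValueError:
            raise ParseError(f"non-integer count in row {fields[0]!r}", line_number=offset)
        if any(v < 0 for v in values):
            raise ParseError(f"negative count in row {fields[0]!r}", line_number=offset)
        region_ids.append(fields[0])
        rows.append(values)
    counts = pd.DataFrame(rows, index=pd.Index(region_ids, name="region_id"), columns=samples)
    return CountTable(counts=counts, library_size=library_size)


ROLES = ("reference", "baseline", "test")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )


@dataclass
class SampleManifest:
    """Sample roles: exactly one reference (wild-type), exactly one baseline
    (empty-vector null) and any number of rescue/test samples."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in manifest")
        n_ref = sum(s.role == "reference" for s in self.samples)
        n_base = sum(s.role == "baseline" for s in self.samples)
        if n_ref != 1:
            raise ValidationError(f"manifest needs exactly one reference sample, got {n_ref}")
        if n_base != 1:
            raise ValidationError(f"manifest needs exactly one baseline sample, got {n_base}")

    @property
    def reference(self) -> str:
        return next(s.sample_id for s in self.samples if s.role == "reference")

    @property
    def baseline(self) -> str:
        return next(s.sample_id for s in self.samples if s.role == "baseline")

    @property
    def tests(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == "test"]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def label(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.label or s.sample_id
        raise KeyError(sample_id)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "samples": [
                {"id": s.sample_id, "role": s.role, "label": s.label}
                for s in self.samples
            ]
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a YAML manifest: ``samples: [{id, role, label}, ...]``."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "samples" not in payload:
        raise ParseError("manifest must be a mapping with a 'samples' list")
    samples = []
    for entry in payload["samples"]:
        if not isinstance(entry, dict) or "id" not in entry or "role" not in entry:
            raise ParseError(f"manifest sample entry needs 'id' and 'role': {entry!r}")
        samples.append(
            Sample(
                sample_id=str(entry["id"]),
                role=str(entry["role"]),
                label=str(entry.get("label", "")),
            )
        )
    return SampleManifest(samples=samples)
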