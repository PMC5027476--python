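"""Clone-based bisulfite sequencing analysis.

Sanger-sequenced clones of a bisulfite-PCR amplicon are aligned to the
*unconverted* genomic reference.  Bisulfite chemistry converts unmethylated
cytosine to uracil (read as thymine) while 5-methylcytosine is protected, so
at each CpG cytosine a clone base C means methylated and T means
unmethylated.  Non-CpG cytosines should essentially all read T; the fraction
that do is the clone's conversion rate, a QC for complete chemistry.  Only
the top strand is analyzed (one strand per lollipop row).

The global aligner is a plain Needleman–Wunsch with linear gap penalties and
a fixed traceback tie-break (diagonal, then up, then left) so that calls are
bit-reproducible.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import ValidationError

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
MISSING = "missing"

_ALPHABET = set("ACGTN")
_GAP = "-"

_LOLLIPOP = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "·"}


@dataclass(frozen=True)
class Amplicon:
    """A bisulfite-PCR amplicon: unconverted reference plus CpG positions.

    ``cpg_positions`` are 0-based indices of the C of each CpG dinucleotide.
    """

    name: str
    reference_sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.reference_sequence
        if not seq or set(seq) - _ALPHABET:
            raise ValidationError(
                f"amplicon {self.name!r}: reference must be non-empty A/C/G/T/N"
            )
        if list(self.cpg_positions) != sorted(set(self.cpg_positions)):
            raise ValidationError("cpg_positions must be strictly increasing")
        for p in self.cpg_positions:
            if p < 0 or p + 1 >= len(seq) or seq[p] != "C" or seq[p + 1] != "G":
                raise ValidationError(
                    f"amplicon {self.name!r}: position {p} is not the C of a CpG"
                )

    @classmethod
    def from_sequence(cls, name: str, reference_sequence: str) -> "Amplicon":
        """Auto-detect CpG positions from the reference."""
        seq = reference_sequence.upper()
        positions = tuple(
            i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
        return cls(name=name, reference_sequence=seq, cpg_positions=positions)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment of clone (query) vs reference."""

    query_aligned: str
    ref_aligned: str
    score: int

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.query_aligned, self.ref_aligned)


def align_global(
    query: str,
    reference: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Alignment:
    """Needleman–Wunsch global alignment with linear gap penalty.

    Traceback ties are broken deterministically: diagonal (consume both),
    then up (gap in reference), then left (gap in query).
    """
    q, r = query.upper(), reference.upper()
    if not q or not r:
        raise ValidationError("sequences must be non-empty")
    for seq, name in ((q, "query"), (r, "reference")):
        if set(seq) - _ALPHABET:
            raise ValidationError(f"{name} contains characters outside A/C/G/T/N")
    n, m = len(q), len(r)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    sub = np.where(
        np.frombuffer(q.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(r.encode(), dtype=np.uint8)[None, :],
        match,
        mismatch,
    )
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + sub[i - 1]
        up = F[i - 1, 1:] + gap
        row = F[i]
        row[0] = gap * i
        for j in range(1, m + 1):
            row[j] = max(diag[j - 1], up[j - 1], row[j - 1] + gap)
    qa: list[str] = []
    ra: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            qa.append(q[i - 1]); ra.append(r[j - 1]); i -= 1; j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            qa.append(q[i - 1]); ra.append(_GAP); i -= 1
        else:
            qa.append(_GAP); ra.append(r[j - 1]); j -= 1
    return Alignment(
        query_aligned="".join(reversed(qa)),
        ref_aligned="".join(reversed(ra)),
        score=int(F[n, m]),
    )


@dataclass(frozen=True)
class CloneCall:
    """Per-clone methylation states and QC metrics.

    conversion_rate: fraction of non-CpG reference C positions read as T
    (T / (C + T)); NaN when the amplicon offers no informative position.
    identity: fraction of non-C reference positions where the clone matches;
    bisulfite-expected C→T changes never count as mismatches.
    """

    clone_id: str
    states: tuple[str, ...]
    conversion_rate: float
    identity: float
    aligned: bool = True

    def __post_init__(self) -> None:
        for s in self.states:
            if s not in (METHYLATED, UNMETHYLATED, MISSING):
                raise ValidationError(f"unknown CpG state {s!r}")

    @property
    def n_methylated(self) -> int:
        return sum(s == METHYLATED for s in self.states)


def call_methylation(
    alignment: Alignment, amplicon: Amplicon, clone_id: str = "clone"
) -> CloneCall:
    """Read off CpG states and QC metrics from a clone-vs-reference alignment.

    At each CpG C: clone C → methylated, T → unmethylated, gap/other →
    missing.
    """
    ref_ungapped = alignment.ref_aligned.replace(_GAP, "")
    if ref_ungapped != amplicon.reference_sequence:
        raise ValidationError(
            "alignment reference does not match the amplicon reference sequence"
        )
    cpg_set = set(amplicon.cpg_positions)
    state_at: dict[int, str] = {}
    conv_c = conv_t = 0
    ident_match = ident_total = 0
    ref_pos = 0
    for q_base, r_base in alignment.columns():
        if r_base == _GAP:
            continue
        if r_base == "C":
            if ref_pos in cpg_set:
                if q_base == "C":
                    state_at[ref_pos] = METHYLATED
                elif q_base == "T":
                    state_at[ref_pos] = UNMETHYLATED
                else:
                    state_at[ref_pos] = MISSING
            else:
                if q_base == "C":
                    conv_c += 1
                elif q_base == "T":
                    conv_t += 1
        else:
            ident_total += 1
            if q_base == r_base:
                ident_match += 1
        ref_pos += 1
    states = tuple(state_at.get(p, MISSING) for p in amplicon.cpg_positions)
    conversion = conv_t / (conv_c + conv_t) if (conv_c + conv_t) else math.nan
    identity = ident_match / ident_total if ident_total else math.nan
    return CloneCall(
        clone_id=clone_id,
        states=states,
        conversion_rate=conversion,
        identity=identity,
    )


@dataclass
class MethylationPattern:
    """QC-passing clone calls for one amplicon with summary percentages."""

    amplicon: Amplicon
    calls: list[CloneCall]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (clone_id, reason)

    @property
    def per_cpg_percent(self) -> list[float]:
        out = []
        for k in range(self.amplicon.n_cpgs):
            meth = sum(c.states[k] == METHYLATED for c in self.calls)
            unmeth = sum(c.states[k] == UNMETHYLATED for c in self.calls)
            out.append(100.0 * meth / (meth + unmeth) if meth + unmeth else math.nan)
        return out

    @property
    def overall_percent(self) -> float:
        meth = sum(c.n_methylated for c in self.calls)
        called = sum(
            s != MISSING for c in self.calls for s in c.states
        )
        if called == 0:
            raise ValidationError("pattern has no called CpG states")
        return 100.0 * meth / called


def build_pattern(
    amplicon: Amplicon,
    calls: Sequence[CloneCall],
    min_conversion: float = 0.95,
    min_identity: float = 0.80,
) -> MethylationPattern:
    """Apply QC thresholds and assemble a pattern from clone calls.

    Clones failing the conversion-rate or identity threshold (or offering no
    evidence for one of them) are excluded with a named reason.  If every
    clone fails, the error names the dominant reason.
    """
    if not calls:
        raise ValidationError("need at least one clone call")
    passing: list[CloneCall] = []
    excluded: list[tuple[str, str]] = []
    for c in calls:
        if len(c.states) != amplicon.n_cpgs:
            raise ValidationError(
                f"clone {c.clone_id!r}: {len(c.states)} states for an amplicon "
                f"with {amplicon.n_cpgs} CpGs"
            )
        if math.isnan(c.conversion_rate):
            excluded.append((c.clone_id, "no_conversion_information"))
        elif c.conversion_rate < min_conversion:
            excluded.append((c.clone_id, "conversion"))
        elif math.isnan(c.identity) or c.identity < min_identity:
            excluded.append((c.clone_id, "identity"))
        else:
            passing.append(c)
    if not passing:
        dominant = collections.Counter(r for _, r in excluded).most_common(1)[0][0]
        raise ValidationError(
            f"all {len(excluded)} clones failed QC; dominant reason: {dominant}"
        )
    return MethylationPattern(amplicon=amplicon, calls=passing, excluded=excluded)


@dataclass(frozen=True)
class PatternComparison:
    difference: float  # b - a, percentage points
    ci_low: float
    ci_high: float
    n_bootstrap: int


def compare_patterns(
    a: MethylationPattern,
    b: MethylationPattern,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> PatternComparison:
    """Difference in overall percent (b - a) with a clone-resampling
    bootstrap percentile interval."""
    if a.amplicon.name != b.amplicon.name or (
        a.amplicon.reference_sequence != b.amplicon.reference_sequence
    ):
        raise ValidationError("patterns compare different amplicons")
    rng = np.random.default_rng(seed)

    def _overall(calls: list[CloneCall]) -> float:
        meth = sum(c.n_methylated for c in calls)
        called = sum(s != MISSING for c in calls for s in c.states)
        return 100.0 * meth / called if called else math.nan

    diff = b.overall_percent - a.overall_percent
    draws = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        ra = [a.calls[k] for k in rng.integers(0, len(a.calls), len(a.calls))]
        rb = [b.calls[k] for k in rng.integers(0, len(b.calls), len(b.calls))]
        draws[i] = _overall(rb) - _overall(ra)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanquantile(draws, [alpha, 1.0 - alpha])
    return PatternComparison(
        difference=float(diff), ci_low=float(lo), ci_high=float(hi),
        n_bootstrap=n_bootstrap,
    )


def render_lollipop_text(pattern: MethylationPattern) -> str:
    """One row per clone: ● methylated, ○ unmethylated, · missing."""
    lines = [
        "".join(_LOLLIPOP[s] for s in c.states) for c in pattern.calls
    ]
    return "\n".join(lines)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def analyze_clones(
    amplicon: Amplicon,
    clones: Sequence[tuple[str, str]],
    min_conversion: float = 0.95,
    min_identity: float = 0.80,
) -> MethylationPattern:
    """Align each clone, call methylation, and build a QC-filtered pattern."""
    calls = [
        call_methylation(
            align_global(seq, amplicon.reference_sequence), amplicon, clone_id=name
        )
        for name, seq in clones
    ]
    return build_pattern(amplicon, calls, min_conversion, min_identity)
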