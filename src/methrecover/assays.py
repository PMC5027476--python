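"""Closed-form calculators for the companion wet-lab quantifications.

Pfaffl relative expression
    fold = E_target**ΔCt_target / E_ref**ΔCt_ref, with efficiencies expressed
    as amplification factor per cycle (2 = perfect doubling) and
    ΔCt = Ct(control) − Ct(sample).  Reduces to the classic 2^(−ΔΔCt) when
    both efficiencies are 2.

HPLC percent 5mC
    Peak areas at the extinction maxima (dCMP 276 nm, 5mdCMP 282 nm) are
    converted to molar amounts via the extinction coefficients
    (dCMP 8.86e3, 5mdCMP 9.0e3) and reported as the 5mC share of the
    cytosine pool: 100 * n_5mC / (n_C + n_5mC).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

EPS_DCMP = 8.86e3
EPS_5MDCMP = 9.0e3
WAVELENGTH_DCMP_NM = 276
WAVELENGTH_5MDCMP_NM = 282

_EFFICIENCY_RANGE = (1.0, 2.2)  # amplification factor per cycle, sanity bound


@dataclass(frozen=True)
class QpcrMeasurement:
    """Efficiency-corrected qPCR inputs; ΔCt = Ct(control) − Ct(sample).

    Technical-replicate Cts should be averaged before constructing ΔCt.
    Efficiencies given as percentages (e.g. 95) are rejected, not rescaled.
    """

    e_target: float
    e_reference: float
    delta_ct_target: float
    delta_ct_reference: float

    def __post_init__(self) -> None:
        lo, hi = _EFFICIENCY_RANGE
        for name, e in (("e_target", self.e_target), ("e_reference", self.e_reference)):
            if not lo <= e <= hi:
                raise ValidationError(
                    f"{name}={e} outside [{lo}, {hi}]; efficiencies are "
                    "amplification factors per cycle (2 = perfect doubling), "
                    "not percentages"
                )
        for name, ct in (
            ("delta_ct_target", self.delta_ct_target),
            ("delta_ct_reference", self.delta_ct_reference),
        ):
            if not pd.notna(ct) or abs(ct) == float("inf"):
                raise ValidationError(f"{name} must be finite")


def pfaffl_fold_change(m: QpcrMeasurement) -> float:
    """Relative expression of the target gene normalized to the reference."""
    return m.e_target**m.delta_ct_target / m.e_reference**m.delta_ct_reference


@dataclass(frozen=True)
class HplcPeaks:
    """Chromatogram peak areas for dCMP and 5mdCMP with their extinction
    coefficients; wavelengths are carried as metadata only."""

    area_c: float
    area_5mc: float
    eps_c: float = EPS_DCMP
    eps_5mc: float = EPS_5MDCMP
    wavelength_c_nm: float = WAVELENGTH_DCMP_NM
    wavelength_5mc_nm: float = WAVELENGTH_5MDCMP_NM

    def __post_init__(self) -> None:
        if self.area_c < 0 or self.area_5mc < 0:
            raise ValidationError("peak areas must be non-negative")
        if self.eps_c <= 0 or self.eps_5mc <= 0:
            raise ValidationError("extinction coefficients must be positive")


def hplc_5mc_percent(p: HplcPeaks) -> float:
    """Percent of the cytosine pool that is 5mC: 100·n_5mC/(n_C + n_5mC)."""
    if p.area_c + p.area_5mc == 0:
        raise ValidationError("both peak areas are zero; percent 5mC undefined")
    n_c = p.area_c / p.eps_c
    n_5mc = p.area_5mc / p.eps_5mc
    return 100.0 * n_5mc / (n_c + n_5mc)


def qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR TSV (columns target, e_target, e_reference,
    delta_ct_target, delta_ct_reference) and append the fold change."""
    df = pd.read_csv(path, sep="\t")
    required = {"e_target", "e_reference", "delta_ct_target", "delta_ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns {sorted(missing)}")
    df["fold_change"] = [
        pfaffl_fold_change(
            QpcrMeasurement(
                e_target=row.e_target,
                e_reference=row.e_reference,
                delta_ct_target=row.delta_ct_target,
                delta_ct_reference=row.delta_ct_reference,
            )
        )
        for row in df.itertuples()
    ]
    return df


def hplc_table(path: str | Path) -> pd.DataFrame:
    """Read an HPLC TSV (columns sample, area_c, area_5mc and optionally
    eps_c, eps_5mc) and append percent 5mC."""
    df = pd.read_csv(path, sep="\t")
    missing = {"area_c", "area_5mc"} - set(df.columns)
    if missing:
        raise ValidationError(f"HPLC table missing columns {sorted(missing)}")
    percents = []
    for row in df.itertuples():
        kwargs = {"area_c": row.area_c, "area_5mc": row.area_5mc}
        if "eps_c" in df.columns:
            kwargs["eps_c"] = row.eps_c
        if "eps_5mc" in df.columns:
            kwargs["eps_5mc"] = row.eps_5mc
        percents.append(hplc_5mc_percent(HplcPeaks(**kwargs)))
    df["percent_5mc"] = percents
    return df
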