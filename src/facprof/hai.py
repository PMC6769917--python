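"""Hemagglutination and hemagglutination-inhibition (HAI) logic.

A saccharide is serially diluted (default 2-fold) across a microtiter row
and mixed with a fixed lectin dose; the minimum inhibitory concentration
(MIC) is the lowest saccharide concentration that still abolishes
agglutination.  When even the starting well fails to inhibit, the result
is censored and reported as "> start" — censored values never compare
equal to uncensored ones.  Exact dilution values are stored (7.8125 mM,
not 7.8); display rounding is applied only at report time.

Lectin titers are the mirror image: the last well of the leading
agglutination-positive run at dilution 2^-n gives titer 2^-n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class DilutionSeries:
    """One plate row: start concentration, dilution factor, well outcomes.

    ``outcomes[k]`` is True when the well at concentration
    ``start_conc / factor**k`` shows complete inhibition (negative
    hemagglutination).
    """

    start_conc: float
    unit: str
    outcomes: tuple[bool, ...]
    factor: float = 2.0

    def __post_init__(self) -> None:
        if not self.start_conc > 0:
            raise ValidationError("start_conc must be positive")
        if not self.factor > 1:
            raise ValidationError("dilution factor must exceed 1")
        if not self.outcomes:
            raise ValidationError("outcomes must be non-empty")
        object.__setattr__(self, "outcomes", tuple(bool(o) for o in self.outcomes))

    def concentration(self, well: int) -> float:
        return self.start_conc / self.factor**well

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(self.concentration(k) for k in range(len(self.outcomes)))


@dataclass(frozen=True)
class CensoredConc:
    """A concentration that may be right-censored ("> value")."""

    value: float
    censored: bool
    unit: str

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError("concentration must be positive")

    def display(self, sig_figs: int = 2) -> str:
        shown = round_sig(self.value, sig_figs)
        # exact short values (6.25, 12.5) are printed in full, matching the
        # mixed 2-3 s.f. convention of assay tables
        if round_sig(self.value, 3) == self.value:
            shown = self.value
        text = f"{shown:g}"
        return f">{text}" if self.censored else text

    def __str__(self) -> str:
        return self.display()


@dataclass(frozen=True)
class TiterResult:
    """Hemagglutination titer 2^-n of a lectin dilution series."""

    titer_exponent: int
    positive_at_start: bool

    def __post_init__(self) -> None:
        if self.titer_exponent < 0:
            raise ValidationError("titer exponent must be >= 0")

    @property
    def titer(self) -> float:
        return 2.0**-self.titer_exponent


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def mic(series: DilutionSeries) -> CensoredConc:
    """Minimum inhibitory concentration of a dilution series.

    The MIC is the concentration of the last well in the leading
    contiguous inhibiting block (all higher-concentration wells inhibit
    too).  No inhibition at the starting well yields a censored
    "> start_conc" result.  Non-monotone patterns (an inhibiting well
    below a non-inhibiting one) are resolved conservatively with a
    warning, assuming a monotone dose response.
    """
    out = series.outcomes
    if not out[0]:
        if any(out):
            warnings.warn(
                "inhibiting well(s) below a non-inhibiting start well; "
                "reporting censored result",
                stacklevel=2,
            )
        return CensoredConc(value=series.start_conc, censored=True, unit=series.unit)
    last = 0
    while last + 1 < len(out) and out[last + 1]:
        last += 1
    if any(out[last + 1 :]):
        warnings.warn(
            "non-contiguous inhibition pattern; using topmost contiguous block",
            stacklevel=2,
        )
    return CensoredConc(
        value=series.concentration(last), censored=False, unit=series.unit
    )


def titer(outcomes: Sequence[bool]) -> TiterResult:
    """Titer from agglutination-positive wells (True = agglutination).

    n is the index of the last positive well in the leading contiguous
    positive run; the titer is 2^-n.  With no positive wells n = 0 and
    ``positive_at_start`` is False.
    """
    outcomes = tuple(bool(o) for o in outcomes)
    if not outcomes:
        raise ValidationError("outcomes must be non-empty")
    if not outcomes[0]:
        return TiterResult(titer_exponent=0, positive_at_start=False)
    n = 0
    while n + 1 < len(outcomes) and outcomes[n + 1]:
        n += 1
    return TiterResult(titer_exponent=n, positive_at_start=True)


def read_hai_csv(path) -> list[dict]:
    """Read HAI records: saccharide, lectin, start_conc, unit, outcomes.

    ``outcomes`` is a string of 0/1 per well, e.g. "111111000".
    """
    df = pd.read_csv(path, dtype={"outcomes": str})
    required = {"saccharide", "lectin", "start_conc", "unit", "outcomes"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"HAI file {path} missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        wells = tuple(c == "1" for c in str(row.outcomes))
        records.append(
            {
                "saccharide": row.saccharide,
                "lectin": row.lectin,
                "series": DilutionSeries(
                    start_conc=float(row.start_conc),
                    unit=str(row.unit),
                    outcomes=wells,
                ),
            }
        )
    return records


def hai_report(records: list[dict]) -> pd.DataFrame:
    """Saccharide x lectin MIC table with ">" censoring, ready for TSV."""
    rows: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in records:
        result = mic(rec["series"])
        sacch = rec["saccharide"]
        if sacch not in rows:
            rows[sacch] = {}
            order.append(sacch)
        rows[sacch][rec["lectin"]] = result.display()
    df = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    df.index.name = "saccharide"
    return df
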