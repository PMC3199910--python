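"""Score-band to logit-window crosswalk.

The central mapping step: a raw-score band on the CAT (e.g. "Medium Impact",
scores 11-20) is translated, through a raw-score-to-logit conversion table,
into a half-open window on the common Rasch logit metric.  SGRQ-C item
severities (logits) are then assigned to whichever window contains them,
grouping descriptive items by CAT severity category.

Boundary convention
-------------------
A band covering raw scores ``lo..hi`` (inclusive) maps to the logit window
``(logit(lo - 1), logit(hi)]`` — lower-exclusive, upper-inclusive.  Windows
built from a contiguous band set therefore tile the severity axis without
gaps, and an item whose severity falls exactly on a shared boundary is
assigned to the lower-severity band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ConversionTable",
    "CategoryBand",
    "BandWindow",
    "ItemSeverityRecord",
    "MismatchReport",
    "DEFAULT_BANDS",
    "BELOW_RANGE",
    "ABOVE_RANGE",
    "score_to_logit",
    "band_windows",
    "assign_items",
    "validate_assignment",
]

#: Assignment markers for severities outside every window.
BELOW_RANGE = "below-range"
ABOVE_RANGE = "above-range"


@dataclass(frozen=True)
class ConversionTable:
    """Monotone raw-score <-> logit lookup (one row per tabulated score).

    Rows must be strictly increasing in both raw score and logit; this is
    what makes the table invertible and interpolation meaningful.
    """

    rows: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("conversion table needs at least two rows")
        scores = [r[0] for r in self.rows]
        logits = [r[1] for r in self.rows]
        if any(not math.isfinite(v) for v in logits):
            raise ValueError("conversion table logits must be finite")
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise ValueError("conversion table scores must be strictly increasing")
        if any(b <= a for a, b in zip(logits, logits[1:])):
            raise ValueError("conversion table logits must be strictly increasing")

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(r[0] for r in self.rows)

    @property
    def logits(self) -> tuple[float, ...]:
        return tuple(r[1] for r in self.rows)

    @property
    def min_score(self) -> int:
        return self.rows[0][0]

    @property
    def max_score(self) -> int:
        return self.rows[-1][0]


@dataclass(frozen=True)
class CategoryBand:
    """A named raw-score band, inclusive at both ends (e.g. Low Impact, 1-10)."""

    name: str
    score_lo: int
    score_hi: int

    def __post_init__(self) -> None:
        if self.score_lo > self.score_hi:
            raise ValueError(f"band {self.name!r}: score_lo > score_hi")


#: The four CAT impact bands from the CAT user guide.
DEFAULT_BANDS: tuple[CategoryBand, ...] = (
    CategoryBand("Low Impact", 1, 10),
    CategoryBand("Medium Impact", 11, 20),
    CategoryBand("High Impact", 21, 30),
    CategoryBand("Very High Impact", 31, 40),
)


@dataclass(frozen=True)
class BandWindow:
    """A band's image on the logit axis: lower-exclusive, upper-inclusive."""

    name: str
    logit_lo: float
    logit_hi: float

    def __post_init__(self) -> None:
        if not self.logit_lo < self.logit_hi:
            raise ValueError(f"window {self.name!r}: logit_lo must be < logit_hi")

    def contains(self, logit: float) -> bool:
        return self.logit_lo < logit <= self.logit_hi


@dataclass(frozen=True)
class ItemSeverityRecord:
    """One descriptive item (or one response category of a polytomous item)
    with its severity in logits; ``reference_band`` optionally carries a
    printed band membership for validation."""

    label: str
    logit: float
    reference_band: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.logit):
            raise ValueError(f"record {self.label!r}: logit must be finite")


@dataclass(frozen=True)
class MismatchReport:
    """Outcome of checking a computed assignment against reference bands."""

    n_checked: int
    mismatches: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)
    # each mismatch: (label, expected_band, computed_band)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    @property
    def ok(self) -> bool:
        return not self.mismatches


def score_to_logit(table: ConversionTable, score: float, interpolate: bool = True) -> float:
    """Convert a raw score to logits through *table*.

    Tabulated scores return the tabulated logit exactly.  Other scores are
    linearly interpolated between the bracketing rows when *interpolate* is
    true, and rejected otherwise.  Scores outside the table's range always
    raise ``ValueError``.
    """
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if score < table.min_score or score > table.max_score:
        raise ValueError(
            f"score {score} outside table range "
            f"[{table.min_score}, {table.max_score}]"
        )
    for s, lg in table.rows:
        if score == s:
            return lg
    if not interpolate:
        raise ValueError(f"score {score} is not tabulated and interpolation is off")
    return float(np.interp(score, table.scores, table.logits))


def band_windows(
    bands: Sequence[CategoryBand], table: ConversionTable
) -> list[BandWindow]:
    """Translate raw-score bands into contiguous half-open logit windows.

    Band ``lo..hi`` becomes ``(logit(lo - 1), logit(hi)]`` so that adjacent
    bands share a boundary logit and tile the axis.  Bands must be sorted and
    contiguous; boundary scores must be resolvable through *table* (the
    packaged abbreviated table tabulates every multiple of 5, which covers
    all published band boundaries).
    """
    if not bands:
        raise ValueError("no bands given")
    ordered = sorted(bands, key=lambda b: b.score_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.score_lo != a.score_hi + 1:
            raise ValueError(
                f"bands {a.name!r} and {b.name!r} are not contiguous"
            )
    windows = []
    for band in ordered:
        lo = score_to_logit(table, band.score_lo - 1)
        hi = score_to_logit(table, band.score_hi)
        windows.append(BandWindow(band.name, lo, hi))
    return windows


def assign_items(
    records: Sequence[ItemSeverityRecord], windows: Sequence[BandWindow]
) -> dict[ItemSeverityRecord, str]:
    """Assign each item severity to the window containing it.

    Returns an insertion-ordered mapping from record to band name.  A
    severity at or below the global lower bound gets the ``below-range``
    marker; one above the global upper bound gets ``above-range``.  Nothing
    is ever silently dropped.
    """
    if not windows:
        raise ValueError("no windows given")
    ordered = sorted(windows, key=lambda w: w.logit_lo)
    for a, b in zip(ordered, ordered[1:]):
        if not math.isclose(a.logit_hi, b.logit_lo, abs_tol=1e-12):
            raise ValueError(f"windows {a.name!r} and {b.name!r} do not tile")
    out: dict[ItemSeverityRecord, str] = {}
    lo_bound = ordered[0].logit_lo
    hi_bound = ordered[-1].logit_hi
    for rec in records:
        if rec.logit <= lo_bound:
            out[rec] = BELOW_RANGE
        elif rec.logit > hi_bound:
            out[rec] = ABOVE_RANGE
        else:
            for w in ordered:
                if w.contains(rec.logit):
                    out[rec] = w.name
                    break
    return out


def validate_assignment(
    computed: Mapping[ItemSeverityRecord, str],
    reference: Sequence[ItemSeverityRecord],
    band_names: Optional[Sequence[str]] = None,
) -> MismatchReport:
    """Compare a computed assignment with printed reference bands.

    Records in *reference* must carry ``reference_band``.  Known band names
    default to those appearing in *computed* (plus the out-of-range
    markers); an unknown reference band name raises.  An empty mismatch
    list means the printed grouping is reproduced exactly.
    """
    if band_names is None:
        known = set(computed.values())
    else:
        known = set(band_names)
    known |= {BELOW_RANGE, ABOVE_RANGE}
    mismatches = []
    n = 0
    by_key = {(r.label, r.logit): band for r, band in computed.items()}
    for rec in reference:
        if rec.reference_band is None:
            continue
        if rec.reference_band not in known:
            raise ValueError(f"unknown reference band {rec.reference_band!r}")
        n += 1
        got = by_key.get((rec.label, rec.logit))
        if got is None:
            mismatches.append((rec.label, rec.reference_band, "<unassigned>"))
        elif got != rec.reference_band:
            mismatches.append((rec.label, rec.reference_band, got))
    return MismatchReport(n_checked=n, mismatches=tuple(mismatches))
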