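"""Descriptive scenarios and the ladder of severity.

A scenario is the set of descriptive items whose severities fall inside one
CAT band's logit window, listed mildest first.  The ladder attaches to each
5-point CAT score the k unused items closest to that score's logit — an
ordered sequence of exemplar health-status effects along the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .crosswalk import (
    ABOVE_RANGE,
    BELOW_RANGE,
    ConversionTable,
    ItemSeverityRecord,
    score_to_logit,
)

__all__ = ["Scenario", "ScenarioSet", "LadderStep", "build_scenarios", "build_ladder"]


@dataclass(frozen=True)
class Scenario:
    """One band's descriptive items, (label, logit), ascending by severity."""

    band_name: str
    items: tuple[tuple[str, float], ...]

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ScenarioSet:
    scenarios: tuple[Scenario, ...]
    counts: dict[str, int]
    out_of_range: tuple[tuple[str, float, str], ...]  # (label, logit, marker)


@dataclass(frozen=True)
class LadderStep:
    """Exemplar items for one score step; ``short`` flags steps that could
    not be filled to k because the item pool ran out."""

    cat_score: int
    step_logit: float
    items: tuple[tuple[str, float], ...]
    short: bool = False


def build_scenarios(
    assignment: Mapping[ItemSeverityRecord, str],
    band_names: Optional[Sequence[str]] = None,
) -> ScenarioSet:
    """Group an item-to-band assignment into per-band scenarios.

    One scenario per band (empty bands allowed), items sorted ascending by
    logit then label; records assigned an out-of-range marker are reported
    separately, never dropped.  Band order defaults to first appearance in
    the assignment.
    """
    if band_names is None:
        seen: dict[str, None] = {}
        for band in assignment.values():
            if band not in (BELOW_RANGE, ABOVE_RANGE):
                seen.setdefault(band)
        band_names = list(seen)
    grouped: dict[str, list[tuple[str, float]]] = {b: [] for b in band_names}
    oor = []
    for rec, band in assignment.items():
        if band in (BELOW_RANGE, ABOVE_RANGE):
            oor.append((rec.label, rec.logit, band))
        elif band in grouped:
            grouped[band].append((rec.label, rec.logit))
        else:
            raise ValueError(f"assignment contains unlisted band {band!r}")
    scenarios = tuple(
        Scenario(b, tuple(sorted(grouped[b], key=lambda t: (t[1], t[0]))))
        for b in band_names
    )
    counts = {s.band_name: s.n_items for s in scenarios}
    return ScenarioSet(scenarios=scenarios, counts=counts, out_of_range=tuple(oor))


def build_ladder(
    records: Sequence[ItemSeverityRecord],
    table: ConversionTable,
    step: int = 5,
    k: int = 3,
) -> list[LadderStep]:
    """Pick exemplar items for each *step*-point score along the scale.

    Steps are filled from the most severe score downwards; each step takes
    the k remaining items nearest its logit (by absolute distance, ties
    toward the more severe item), and an item is used at most once across
    the whole ladder.  Steps left short by pool exhaustion are flagged.
    Returned in descending score order, items within a step ordered
    nearest-first.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    max_score = table.max_score
    scores = list(range((max_score // step) * step, 0, -step))
    remaining = list(records)
    ladder = []
    for s in scores:
        target = score_to_logit(table, s)
        remaining.sort(key=lambda r: (abs(r.logit - target), -r.logit, r.label))
        chosen = remaining[:k]
        remaining = remaining[k:]
        ladder.append(
            LadderStep(
                cat_score=s,
                step_logit=target,
                items=tuple((r.label, r.logit) for r in chosen),
                short=len(chosen) < k,
            )
        )
    return ladder
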