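"""CSV readers/writers and packaged reference tables.

All formats are plain UTF-8 comma-delimited CSV with a mandatory header.
Readers validate on the way in (monotonicity, category ranges, duplicates)
and report the offending line number; writers produce exactly what the
readers accept, so write-then-read is an identity on valid data.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .agreement import PairedScores
from .crosswalk import ConversionTable, ItemSeverityRecord
from .rasch import ItemBank, ItemDefinition, ResponseMatrix

__all__ = [
    "ParseError",
    "read_conversion_table",
    "write_conversion_table",
    "read_item_severities",
    "write_item_severities",
    "read_response_matrix",
    "write_response_matrix",
    "read_paired_scores",
    "write_paired_scores",
    "read_item_bank",
    "write_item_bank",
    "load_table1_conversion",
    "load_table2_items",
    "load_table3_ladder",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _rows(path: PathLike, expected_header: list[str], optional: int = 0):
    """Yield (line_number, row) after checking the header; the last
    *optional* header columns may be absent."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header")
        header = [h.strip() for h in header]
        acceptable = [expected_header[: len(expected_header) - k]
                      for k in range(optional + 1)]
        if header not in acceptable:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {expected_header!r}"
            )
        for ln, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            yield ln, [c.strip() for c in row], len(header)


def _num(path, ln, value, caster, what):
    try:
        return caster(value)
    except ValueError:
        raise ParseError(f"{path}: line {ln}: {what} {value!r} is not numeric")


# -- conversion tables ------------------------------------------------------


def read_conversion_table(path: PathLike) -> ConversionTable:
    """Read a ``score,logit`` table, enforcing strict monotonicity."""
    rows = []
    prev = None
    for ln, row, _ in _rows(path, ["score", "logit"]):
        if len(row) != 2:
            raise ParseError(f"{path}: line {ln}: expected 2 fields")
        score = _num(path, ln, row[0], int, "score")
        logit = _num(path, ln, row[1], float, "logit")
        if prev is not None:
            if score == prev[0]:
                raise ParseError(f"{path}: line {ln}: duplicate score {score}")
            if score < prev[0] or logit <= prev[1]:
                raise ParseError(
                    f"{path}: line {ln}: rows must be strictly increasing "
                    f"in score and logit"
                )
        prev = (score, logit)
        rows.append((score, logit))
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least two data rows")
    return ConversionTable(tuple(rows))


def write_conversion_table(table: ConversionTable, path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["score", "logit"])
        for s, lg in table.rows:
            w.writerow([s, repr(lg)])


# -- item severities --------------------------------------------------------


def read_item_severities(path: PathLike) -> list[ItemSeverityRecord]:
    """Read ``label,logit[,reference_band]`` severity records.

    Duplicate labels are allowed when the logits differ (a polytomous item
    contributes one record per response category); an exact duplicate
    (label, logit) pair is rejected.
    """
    records = []
    seen = set()
    for ln, row, width in _rows(path, ["label", "logit", "reference_band"],
                                optional=1):
        if len(row) < 2:
            raise ParseError(f"{path}: line {ln}: expected at least 2 fields")
        label = row[0]
        logit = _num(path, ln, row[1], float, "logit")
        band = row[2] if len(row) > 2 and row[2] else None
        key = (label, logit)
        if key in seen:
            raise ParseError(
                f"{path}: line {ln}: duplicate record {label!r} at logit {logit}"
            )
        seen.add(key)
        records.append(ItemSeverityRecord(label, logit, band))
    return records


def write_item_severities(
    records: Sequence[ItemSeverityRecord], path: PathLike
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "logit", "reference_band"])
        for r in records:
            w.writerow([r.label, repr(r.logit), r.reference_band or ""])


# -- response matrices ------------------------------------------------------


def read_response_matrix(path: PathLike) -> ResponseMatrix:
    """Read ``person_id,<item_1>,...`` integer responses; empty cell = missing."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header")
        if len(header) < 2 or header[0].strip() != "person_id":
            raise ParseError(f"{path}: header must be person_id,<item ids...>")
        item_ids = [h.strip() for h in header[1:]]
        person_ids, data = [], []
        for ln, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(f"{path}: line {ln}: expected {len(header)} fields")
            person_ids.append(row[0].strip())
            vals = []
            for c in row[1:]:
                c = c.strip()
                if not c:
                    vals.append(np.nan)
                else:
                    v = _num(path, ln, c, int, "response")
                    if v < 0:
                        raise ParseError(f"{path}: line {ln}: negative response")
                    vals.append(float(v))
            data.append(vals)
    if not person_ids:
        raise ParseError(f"{path}: no data rows")
    return ResponseMatrix(person_ids, item_ids, np.array(data))


def write_response_matrix(matrix: ResponseMatrix, path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", *matrix.item_ids])
        for pid, row in zip(matrix.person_ids, matrix.responses):
            w.writerow([pid, *("" if np.isnan(v) else int(v) for v in row)])


# -- paired scores ----------------------------------------------------------


def read_paired_scores(path: PathLike) -> list[PairedScores]:
    """Read ``person_id,sgrq,cat`` pairs; the CAT column is on 0-40 and is
    harmonized onto 0-100 (adjCAT) on the way in."""
    from .agreement import cat_to_adjcat

    pairs = []
    for ln, row, _ in _rows(path, ["person_id", "sgrq", "cat"]):
        if len(row) != 3:
            raise ParseError(f"{path}: line {ln}: expected 3 fields")
        sgrq = _num(path, ln, row[1], float, "sgrq")
        cat = _num(path, ln, row[2], float, "cat")
        try:
            pairs.append(PairedScores(row[0], sgrq, cat_to_adjcat(cat)))
        except ValueError as e:
            raise ParseError(f"{path}: line {ln}: {e}")
    return pairs


def write_paired_scores(pairs: Sequence[PairedScores], path: PathLike) -> None:
    """Write pairs back in ``person_id,sgrq,cat`` form (CAT on 0-40)."""
    from .agreement import adjcat_to_cat

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "sgrq", "cat"])
        for p in pairs:
            w.writerow([p.person_id, repr(p.score_a), repr(adjcat_to_cat(p.score_b))])


# -- item banks -------------------------------------------------------------


def read_item_bank(path: PathLike) -> ItemBank:
    """Read a long-format bank: one row per threshold, ordered by index."""
    header = ["instrument_id", "item_id", "label", "threshold_index",
              "threshold_logit"]
    per_item: dict[str, dict] = {}
    instrument = None
    for ln, row, _ in _rows(path, header):
        if len(row) != 5:
            raise ParseError(f"{path}: line {ln}: expected 5 fields")
        inst, iid, label = row[0], row[1], row[2]
        idx = _num(path, ln, row[3], int, "threshold_index")
        logit = _num(path, ln, row[4], float, "threshold_logit")
        instrument = instrument or inst
        entry = per_item.setdefault(iid, {"label": label, "inst": inst, "thr": {}})
        if idx in entry["thr"]:
            raise ParseError(f"{path}: line {ln}: duplicate threshold index {idx}")
        entry["thr"][idx] = logit
    if not per_item:
        raise ParseError(f"{path}: no data rows")
    items = []
    for iid, entry in per_item.items():
        idxs = sorted(entry["thr"])
        if idxs != list(range(1, len(idxs) + 1)):
            raise ParseError(f"{path}: item {iid!r}: threshold indices must be 1..m")
        items.append(
            ItemDefinition(iid, entry["inst"], entry["label"],
                           tuple(entry["thr"][i] for i in idxs))
        )
    bank = ItemBank(instrument or "bank", tuple(items))
    mean = float(np.mean(bank.all_thresholds()))
    if abs(mean) <= 1e-9:
        bank = ItemBank(bank.instrument_id, bank.items, centred=True)
    return bank


def write_item_bank(bank: ItemBank, path: PathLike) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["instrument_id", "item_id", "label", "threshold_index",
                    "threshold_logit"])
        for it in bank.items:
            for idx, t in enumerate(it.thresholds, start=1):
                w.writerow([it.instrument_id, it.item_id, it.label, idx, repr(t)])


# -- packaged reference tables ----------------------------------------------


def _data_path(name: str):
    return resources.files("catwalk.data").joinpath(name)


def load_table1_conversion() -> ConversionTable:
    """The published abbreviated CAT score-to-logit table (9 rows, every
    multiple of 5 from 0 to 40)."""
    with resources.as_file(_data_path("table1_conversion.csv")) as p:
        return read_conversion_table(p)


def load_table2_items() -> list[ItemSeverityRecord]:
    """The 55 published SGRQ-C item severities with their printed CAT-band
    membership as ``reference_band``."""
    with resources.as_file(_data_path("table2_items.csv")) as p:
        return read_item_severities(p)


def load_table3_ladder() -> list[tuple[int, int, str]]:
    """The published ladder of severity, for qualitative comparison only:
    (cat_score, rank, description) rows."""
    out = []
    with resources.as_file(_data_path("table3_ladder.csv")) as p:
        for ln, row, _ in _rows(p, ["cat_score", "rank", "description"]):
            out.append((int(row[0]), int(row[1]), row[2]))
    return out
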