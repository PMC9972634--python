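"""Epidemiologic rate parsing, per-100,000 normalization, and the curated
comparison filters.

Published rates come in a handful of surface forms — "1 in 40,760",
"17.1/100,000", "1.36 per million inhabitants", "4.5%" — all of which are
a numerator over a denominator. Normalizing to a fixed per-100,000 basis
(value = numerator / denominator x 100,000, reported to three significant
figures) makes extracted rates comparable with curated registry entries,
which quote either point values or opaque range classes such as
"1-9/100,000" (ranges are compared as strings, not parsed).

Records lacking any location are assigned "Worldwide", matching the
registry's extrapolation convention.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RateForm",
    "RateExpression",
    "NormalizedRate",
    "ComparisonRecord",
    "RateParseError",
    "parse_rate",
    "normalize_per_100k",
    "default_location",
    "filter_for_comparison",
]


class RateParseError(ValueError):
    """No supported rate surface form found in the text."""


class RateForm(str, Enum):
    X_IN_Y = "x_in_y"
    X_PER_Y = "x_per_y"
    SLASH = "slash"
    PERCENT = "percent"
    PER_MILLION = "per_million"


@dataclass(frozen=True)
class RateExpression:
    numerator: float
    denominator: float
    form: RateForm
    surface: str

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")


@dataclass(frozen=True)
class NormalizedRate:
    """A rate on the fixed per-100,000 scale."""

    value: float
    sigfigs: int = 3

    def __str__(self) -> str:
        return f"{self.value:g} per 100,000"


# numbers may carry thousand separators as commas or single spaces ("25 000")
_NUM = r"\d{1,3}(?:[, \u00a0]\d{3})+(?:\.\d+)?|\d+(?:\.\d+)?"
_PATTERNS: list[tuple[re.Pattern, RateForm]] = [
    (re.compile(rf"({_NUM})\s*%"), RateForm.PERCENT),
    (re.compile(rf"({_NUM})\s*(?:per|/)\s*million", re.I), RateForm.PER_MILLION),
    (re.compile(rf"({_NUM})\s+in\s+(?:every\s+)?({_NUM})", re.I), RateForm.X_IN_Y),
    (re.compile(rf"({_NUM})\s*:\s*({_NUM})"), RateForm.X_IN_Y),
    (re.compile(rf"({_NUM})\s*/\s*({_NUM})"), RateForm.SLASH),
    (re.compile(rf"({_NUM})\s+per\s+({_NUM})", re.I), RateForm.X_PER_Y),
]


def _to_number(text: str) -> float:
    return float(re.sub(r"[, \u00a0]", "", text))


def parse_rate(text: str) -> RateExpression:
    """Parse the first supported rate expression in ``text``.

    Thousand separators (commas or single spaces) inside numbers are
    tolerated; trailing population nouns ("births", "inhabitants", ...)
    are simply not consumed.
    """
    best: tuple[int, re.Match, RateForm] | None = None
    for pattern, form in _PATTERNS:
        m = pattern.search(text)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), m, form)
    if best is None:
        raise RateParseError(f"no parsable rate in {text!r}")
    _, m, form = best
    numerator = _to_number(m.group(1))
    if form is RateForm.PERCENT:
        denominator = 100.0
    elif form is RateForm.PER_MILLION:
        denominator = 1_000_000.0
    else:
        denominator = _to_number(m.group(2))
    return RateExpression(numerator, denominator, form, surface=m.group(0))


def _round_sig(value: float, sigfigs: int) -> float:
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, sigfigs - 1 - magnitude)


def normalize_per_100k(rate: RateExpression, sigfigs: int = 3) -> NormalizedRate:
    """numerator / denominator x 100,000, to ``sigfigs`` significant figures."""
    return NormalizedRate(
        _round_sig(rate.numerator / rate.denominator * 100_000, sigfigs),
        sigfigs,
    )


def default_location(record) -> str:
    """The record's first extracted location, else "Worldwide"."""
    locs = record.entities.get("LOC", []) if hasattr(record, "entities") else []
    return locs[0] if locs else "Worldwide"


@dataclass
class ComparisonRecord:
    gard_id: str
    pmid: str
    our_stat: list[NormalizedRate]
    our_stat_surfaces: list[str]
    our_loc: str
    orphanet_stat: str
    orphanet_loc: str
    orphanet_epi_type: str


_ORPHANET_COLUMNS = ("disease", "pmid", "source_type", "epi_type", "rate", "location")


def filter_for_comparison(
    extractions: Sequence[tuple],
    orphanet: pd.DataFrame | Iterable[dict],
) -> list[ComparisonRecord]:
    """Join pipeline extractions against curated entries under the
    comparison filters.

    The curated side drops expert-opinion-sourced rows and rows missing a
    PMID or a rate; our side keeps only records with at least one STAT and
    at most one identified disease ID. The join key is the PMID.

    ``extractions`` is a sequence of ``(ExtractionRecord, gard_ids)`` pairs.
    """
    if not isinstance(orphanet, pd.DataFrame):
        orphanet = pd.DataFrame(list(orphanet))
    missing = set(_ORPHANET_COLUMNS) - set(orphanet.columns)
    if missing:
        raise ValueError(f"curated table lacks columns {sorted(missing)}")

    curated: dict[str, dict] = {}
    for _, row in orphanet.iterrows():
        pmid = str(row["pmid"]).strip() if pd.notna(row["pmid"]) else ""
        rate = str(row["rate"]).strip() if pd.notna(row["rate"]) else ""
        source = str(row["source_type"]).strip().lower()
        if not pmid or not rate or "expert" in source:
            continue
        curated[pmid] = row.to_dict()

    out: list[ComparisonRecord] = []
    for record, gard_ids in extractions:
        stats = record.entities.get("STAT", [])
        if not stats or len(gard_ids) > 1:
            continue
        row = curated.get(str(record.pmid))
        if row is None:
            continue
        normalized, surfaces = [], []
        for s in stats:
            try:
                normalized.append(normalize_per_100k(parse_rate(s)))
                surfaces.append(s)
            except RateParseError as exc:
                warnings.warn(f"PMID {record.pmid}: {exc}", stacklevel=2)
        out.append(
            ComparisonRecord(
                gard_id=gard_ids[0] if gard_ids else "",
                pmid=str(record.pmid),
                our_stat=normalized,
                our_stat_surfaces=surfaces,
                our_loc=default_location(record),
                orphanet_stat=str(row["rate"]),
                orphanet_loc=str(row["location"]),
                orphanet_epi_type=str(row["epi_type"]),
            )
        )
    return out
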