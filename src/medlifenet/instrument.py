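"""Questionnaire instrument: item coding, adherence scoring, quartile strata.

The MEDLIFE index dichotomizes 28 lifestyle-questionnaire items spread over
three domains (food consumption, dietary habits, lifestyle). Four coding
categories are supported:

``moderate``
    foods where excess breaks the pattern — indicator 1 for intake within
    the moderate range, 0 for abuse;
``recommended``
    foods where insufficient intake breaks the pattern — 1 for adequate
    intake, 0 for under-consumption;
``tripartite``
    items with three ordered consumption levels, recoded into three
    mutually exclusive one-hot indicators (low / moderate / high), the
    moderate level carrying the adherence point;
``limit``
    active dietary-restraint behaviours — 1 for limitation, 0 for
    unrestricted consumption;
``simple``
    plain presence/absence indicators.

The total adherence score is the sum of the 28 score-contributing
indicators (integer 0–28). Respondents are stratified by score quartiles:
strictly below the first quartile is *low* adherence, strictly above the
third is *high*, everything else *intermediate*. Quartiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemDefinition",
    "InstrumentDefinition",
    "ResponseRecord",
    "IndicatorMatrix",
    "AdherenceScore",
    "load_instrument",
    "default_instrument",
    "encode_item",
    "encode_cohort",
    "medlife_score",
    "score_matrix",
    "stratify_quartiles",
    "group_percentages",
    "read_cohort_csv",
    "records_to_frame",
]

DOMAINS = ("food_consumption", "dietary_habits", "lifestyle")
CODINGS = ("moderate", "recommended", "tripartite", "limit", "simple")
TRIPARTITE_LEVELS = ("low", "moderate", "high")


class CodingError(ValueError):
    """Raised when a raw answer cannot be encoded under an item's rule."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item and its dichotomization rule."""

    item_id: str
    domain: str
    coding: str
    response_levels: tuple[str, ...]
    adherent_levels: tuple[str, ...] = ()   # empty for tripartite items
    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for item {self.item_id!r}")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r} for item {self.item_id!r}")
        if self.coding == "tripartite":
            if tuple(self.response_levels) != TRIPARTITE_LEVELS:
                raise ValueError(
                    f"tripartite item {self.item_id!r} must use levels {TRIPARTITE_LEVELS}"
                )
        else:
            if not self.adherent_levels:
                raise ValueError(f"item {self.item_id!r} declares no adherent levels")
            unknown = set(self.adherent_levels) - set(self.response_levels)
            if unknown:
                raise ValueError(f"item {self.item_id!r}: adherent levels {unknown} not admissible")

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        """Emitted indicator column names, in instrument order."""
        if self.coding == "tripartite":
            return tuple(f"{self.item_id}.{lvl}" for lvl in TRIPARTITE_LEVELS)
        return (self.item_id,)

    @property
    def score_indicator(self) -> str:
        """The single indicator contributing this item's score point."""
        if self.coding == "tripartite":
            return f"{self.item_id}.moderate"
        return self.item_id


@dataclass(frozen=True)
class InstrumentDefinition:
    """Ordered catalogue of items; the default instrument has 28 of them."""

    items: tuple[ItemDefinition, ...]
    version: str = "custom"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_ids in instrument")

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(ind for it in self.items for ind in it.indicator_ids)

    @property
    def score_indicators(self) -> tuple[str, ...]:
        return tuple(it.score_indicator for it in self.items)

    @property
    def tripartite_items(self) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items if it.coding == "tripartite")

    def domain_sizes(self) -> dict[str, int]:
        sizes = {d: 0 for d in DOMAINS}
        for it in self.items:
            sizes[it.domain] += 1
        return sizes

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


@dataclass(frozen=True)
class ResponseRecord:
    """One respondent's raw answers plus sociodemographics."""

    respondent_id: str
    age: float
    sex: str                      # "female" / "male"
    bmi: float
    smoking: bool
    item_answers: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class IndicatorMatrix:
    """Respondents x binary indicators; the substrate of every later stage."""

    respondent_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    values: np.ndarray            # shape (n_respondents, n_indicators), dtype int8

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.respondent_ids), len(self.indicator_ids)):
            raise ValueError("indicator matrix shape mismatch")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("indicator matrix entries must be 0/1")

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.respondent_ids), columns=list(self.indicator_ids)
        ).rename_axis("respondent_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IndicatorMatrix":
        df = pd.read_csv(path, sep="\t", index_col="respondent_id")
        return cls(
            respondent_ids=tuple(str(i) for i in df.index),
            indicator_ids=tuple(df.columns),
            values=df.to_numpy(dtype=np.int8),
        )


@dataclass(frozen=True)
class AdherenceScore:
    respondent_id: str
    score: int
    group: str | None = None      # "low" / "intermediate" / "high"


def load_instrument(path: str | Path) -> InstrumentDefinition:
    """Read an instrument-definition JSON file.

    Schema: ``{version, items: [{id, domain, coding, levels, rule, scores}]}``
    where ``rule`` holds ``{"adherent_levels": [...]}`` for dichotomous items
    and a level→indicator map for tripartite ones.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return _instrument_from_dict(raw)


def _instrument_from_dict(raw: dict) -> InstrumentDefinition:
    items = []
    for spec in raw["items"]:
        coding = spec["coding"]
        adherent = tuple(spec["rule"].get("adherent_levels", ())) if coding != "tripartite" else ()
        items.append(
            ItemDefinition(
                item_id=spec["id"],
                domain=spec["domain"],
                coding=coding,
                response_levels=tuple(spec["levels"]),
                adherent_levels=adherent,
            )
        )
    return InstrumentDefinition(items=tuple(items), version=raw.get("version", "custom"))


def default_instrument() -> InstrumentDefinition:
    """The bundled 28-item instrument (15/7/6 across domains, 32 indicators)."""
    ref = resources.files("medlifenet.data").joinpath("default_instrument.json")
    with ref.open(encoding="utf-8") as fh:
        return _instrument_from_dict(json.load(fh))


def encode_item(defn: ItemDefinition, answer: str) -> tuple[int, ...]:
    """Encode a raw answer to one binary value (three for tripartite items).

    Tripartite answers are one-hot over (low, moderate, high); any other
    coding yields a single 0/1 according to the item's adherent levels.
    """
    if answer not in defn.response_levels:
        raise CodingError(
            f"item {defn.item_id!r}: answer {answer!r} not among admissible "
            f"levels {list(defn.response_levels)}"
        )
    if defn.coding == "tripartite":
        return tuple(int(answer == lvl) for lvl in TRIPARTITE_LEVELS)
    return (int(answer in defn.adherent_levels),)


def encode_cohort(
    instrument: InstrumentDefinition, records: Sequence[ResponseRecord]
) -> IndicatorMatrix:
    """Encode a cohort of raw responses into the binary indicator matrix.

    Column order follows the instrument's item order (tripartite items expand
    in place to their low/moderate/high triple).
    """
    if not records:
        raise ValueError("empty cohort")
    ids = [r.respondent_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate respondent_id(s): {dupes}")
    rows = np.empty((len(records), len(instrument.indicator_ids)), dtype=np.int8)
    for i, rec in enumerate(records):
        col = 0
        for it in instrument.items:
            if it.item_id not in rec.item_answers:
                raise CodingError(
                    f"respondent {rec.respondent_id!r} missing answer for item {it.item_id!r}"
                )
            vals = encode_item(it, rec.item_answers[it.item_id])
            rows[i, col : col + len(vals)] = vals
            col += len(vals)
    return IndicatorMatrix(tuple(ids), instrument.indicator_ids, rows)


def medlife_score(instrument: InstrumentDefinition, record: ResponseRecord) -> int:
    """Total adherence score: the sum of the score-contributing indicators."""
    total = 0
    for it in instrument.items:
        if it.item_id not in record.item_answers:
            raise CodingError(
                f"respondent {record.respondent_id!r} missing answer for item {it.item_id!r}"
            )
        vals = encode_item(it, record.item_answers[it.item_id])
        if it.coding == "tripartite":
            total += vals[TRIPARTITE_LEVELS.index("moderate")]
        else:
            total += vals[0]
    return total


def score_matrix(instrument: InstrumentDefinition, X: IndicatorMatrix) -> np.ndarray:
    """Vector of adherence scores computed from an already-encoded matrix."""
    idx = [X.indicator_ids.index(s) for s in instrument.score_indicators]
    return X.values[:, idx].sum(axis=1)


def stratify_quartiles(scores: Sequence[int]) -> list[str]:
    """Assign low / intermediate / high adherence groups by score quartiles.

    Low means strictly below the first quartile, high strictly above the
    third; scores falling exactly on a quartile are intermediate. Quartiles
    are estimated with linear interpolation between order statistics.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need at least 4 respondents to form quartile strata")
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    if q1 == q3:
        warnings.warn("all score quartiles coincide; every respondent is intermediate")
    labels = np.where(scores < q1, "low", np.where(scores > q3, "high", "intermediate"))
    return labels.tolist()


def group_percentages(counts: Mapping[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentage share of each adherence group, for reporting.

    Rounds by largest remainder so that the printed shares sum to exactly
    100 (plain per-entry rounding can drift to 99.9 or 100.1).
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty cohort")
    scale = 10**decimals
    raw = {k: 100.0 * scale * v / total for k, v in counts.items()}
    floored = {k: math.floor(r) for k, r in raw.items()}
    shortfall = round(100 * scale - sum(floored.values()))
    order = sorted(raw, key=lambda k: raw[k] - floored[k], reverse=True)
    for k in order[:shortfall]:
        floored[k] += 1
    return {k: floored[k] / scale for k in counts}


# --- raw-cohort CSV round-trip -------------------------------------------

_DEMO_COLS = ["respondent_id", "age", "sex", "bmi", "smoking"]


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "respondent_id": r.respondent_id,
            "age": r.age,
            "sex": r.sex,
            "bmi": r.bmi,
            "smoking": int(r.smoking),
        }
        row.update(r.item_answers)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[ResponseRecord], path: str | Path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_cohort_csv(path: str | Path, sep: str = ",") -> list[ResponseRecord]:
    """Read a raw cohort table (one row per respondent, header row)."""
    df = pd.read_csv(path, sep=sep, dtype={"respondent_id": str})
    missing = [c for c in _DEMO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    item_cols = [c for c in df.columns if c not in _DEMO_COLS]
    records = []
    for _, row in df.iterrows():
        records.append(
            ResponseRecord(
                respondent_id=str(row["respondent_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                smoking=bool(int(row["smoking"])),
                item_answers={c: str(row[c]) for c in item_cols},
            )
        )
    return records
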