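"""Food-frequency questionnaire (FFQ) parsing and frequency coding.

The instrument records, for each of 52 food items, how often the item was
consumed during the past month on a 7-level ordinal scale ranging from
"not at all" to "more than once a day".  Each level maps to a fixed weekly
consumption frequency (times/week); food-group frequencies used by the
diet-quality index are sums of member-item weekly frequencies.  Portion
sizes are not part of the instrument, so no energy or nutrient quantities
are derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "FREQUENCY_LABELS",
    "WEEKLY_VALUES",
    "FFQRecord",
    "FFQSchema",
    "FFQParseError",
    "frequency_to_weekly",
    "read_ffq_table",
    "write_ffq_table",
    "records_to_frame",
    "weekly_frame",
    "aggregate_group",
    "load_default_schema",
]

#: Canonical English labels of the 7 ordered frequency levels (codes 0-6).
FREQUENCY_LABELS: tuple[str, ...] = (
    "not at all",
    "less than once a month",
    "1-3 d per month",
    "1-2 d per week",
    "3-5 d per week",
    "daily or almost daily",
    "more than once a day",
)

#: Weekly consumption frequency (times/week) for each level code.
WEEKLY_VALUES: tuple[float, ...] = (0.0, 0.12, 0.47, 1.5, 4.0, 6.0, 8.0)

_DASHES = str.maketrans({"–": "-", "—": "-", "‒": "-"})


def _normalise_label(text: str) -> str:
    return " ".join(str(text).translate(_DASHES).strip().lower().split())


_LABEL_TO_CODE: dict[str, int] = {
    _normalise_label(lab): code for code, lab in enumerate(FREQUENCY_LABELS)
}


class FFQParseError(ValueError):
    """Raised for malformed FFQ tables (unknown labels, bad schema...)."""


def frequency_to_weekly(level: int | str) -> float:
    """Convert one frequency level (code 0-6 or label) to times/week.

    The map is strictly increasing: 0, 0.12, 0.47, 1.5, 4, 6, 8.
    """
    code = parse_level(level)
    return WEEKLY_VALUES[code]


def parse_level(value: int | str) -> int:
    """Return the ordinal code 0-6 for an integer code or a level label."""
    if isinstance(value, str):
        norm = _normalise_label(value)
        if norm in _LABEL_TO_CODE:
            return _LABEL_TO_CODE[norm]
        if norm.lstrip("-").isdigit():
            value = int(norm)
        else:
            raise FFQParseError(
                f"unknown frequency label {value!r}; expected one of "
                f"{list(FREQUENCY_LABELS)} or a code 0-6"
            )
    code = int(value)
    if not 0 <= code <= 6:
        raise FFQParseError(f"frequency code {code} outside 0-6")
    return code


@dataclass(frozen=True)
class FFQSchema:
    """Declares the item universe of the questionnaire (52 item ids)."""

    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise FFQParseError("duplicate item ids in FFQ schema")

    @classmethod
    def from_yaml(cls, path) -> "FFQSchema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(items=tuple(doc["items"]))


@dataclass
class FFQRecord:
    """One participant's item-level responses plus derived weekly values.

    ``responses`` maps item_id -> level code 0-6; items the participant
    left blank are absent from the map.  ``weekly`` mirrors ``responses``
    with the fixed weekly conversion applied.
    """

    participant_id: str
    responses: dict[str, int] = field(default_factory=dict)

    @property
    def weekly(self) -> dict[str, float]:
        return {item: WEEKLY_VALUES[code] for item, code in self.responses.items()}

    def weekly_for(self, item: str) -> float | None:
        code = self.responses.get(item)
        return None if code is None else WEEKLY_VALUES[code]


def read_ffq_table(
    path, item_schema: Sequence[str] | FFQSchema | None = None
) -> list[FFQRecord]:
    """Read a one-row-per-participant CSV of FFQ responses.

    Columns are item ids (plus an optional ``participant_id`` column);
    cells hold level labels or integer codes 0-6; empty cells are missing.
    Unknown labels raise :class:`FFQParseError` naming the row and column.
    """
    df = pd.read_csv(path, dtype=str)
    return parse_ffq_frame(df, item_schema)


def parse_ffq_frame(
    df: pd.DataFrame, item_schema: Sequence[str] | FFQSchema | None = None
) -> list[FFQRecord]:
    if isinstance(item_schema, FFQSchema):
        schema_items = list(item_schema.items)
    elif item_schema is not None:
        schema_items = list(item_schema)
    else:
        schema_items = [c for c in df.columns if c != "participant_id"]

    item_cols = [c for c in df.columns if c != "participant_id"]
    unknown = sorted(set(item_cols) - set(schema_items))
    if unknown:
        raise FFQParseError(f"columns not in the FFQ item schema: {unknown}")

    has_pid = "participant_id" in df.columns
    records: list[FFQRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        pid = str(row["participant_id"]) if has_pid else str(i)
        responses: dict[str, int] = {}
        for item in item_cols:
            cell = row[item]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                responses[item] = parse_level(cell)
            except FFQParseError as exc:
                raise FFQParseError(
                    f"row {i} (participant {pid}), column {item!r}: {exc}"
                ) from exc
        records.append(FFQRecord(participant_id=pid, responses=responses))
    return records


def records_to_frame(records: Iterable[FFQRecord]) -> pd.DataFrame:
    """Integer-code frame (pandas nullable Int64), one row per participant."""
    rows = {r.participant_id: r.responses for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index").astype("Int64")
    df.index.name = "participant_id"
    return df.sort_index(axis=1)


def write_ffq_table(records: Iterable[FFQRecord], path) -> None:
    """Write records as CSV of integer codes; round-trips with the reader."""
    records_to_frame(records).to_csv(path)


def weekly_frame(codes: pd.DataFrame) -> pd.DataFrame:
    """Map a frame of level codes 0-6 (NA allowed) to weekly frequencies."""
    mapping = {i: v for i, v in enumerate(WEEKLY_VALUES)}
    out = codes.apply(lambda col: col.map(mapping))
    return out.astype(float)


def aggregate_group(
    record: FFQRecord | Mapping[str, float], items: Sequence[str]
) -> float | None:
    """Weekly food-group frequency: sum of member items' weekly values.

    Missing member items are ignored (a partially answered group is scored
    on its observed items); returns None when every member item is missing.
    """
    weekly = record.weekly if isinstance(record, FFQRecord) else record
    observed = [weekly[i] for i in items if weekly.get(i) is not None]
    if not observed:
        return None
    return float(sum(observed))


def load_default_schema() -> FFQSchema:
    """The package's bundled 52-item schema (synthetic stand-in item list)."""
    ref = resources.files("mhfii_foodsec.data") / "ffq_schema_synthetic.yaml"
    with resources.as_file(ref) as path:
        return FFQSchema.from_yaml(path)


class FFQWeeklyConverter:
    """sklearn-style transformer: level codes 0-6 -> weekly frequencies.

    Stateless; operates column-wise on a DataFrame of integer codes with
    NA allowed.  Compatible with sklearn pipelines via duck typing (fit /
    transform / get_params / set_params).
    """

    def fit(self, X: pd.DataFrame, y=None) -> "FFQWeeklyConverter":
        bad = X.apply(lambda c: ((c < 0) | (c > 6)).any())
        if bad.any():
            raise FFQParseError(
                f"codes outside 0-6 in columns {list(X.columns[bad])}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return weekly_frame(X)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "FFQWeeklyConverter":
        return self
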