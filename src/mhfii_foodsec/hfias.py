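"""HFIAS food-insecurity scoring (individual-level, 30-day recall).

The Household Food Insecurity Access Scale asks nine occurrence questions
(worry about food; compromises in quality — Q2-Q4; compromises in quantity
— Q5-Q9, up to going a whole day without eating) with a 30-day frequency
follow-up for each: never / rarely / sometimes / often.  Responses are
collapsed into four ordered food-insecurity (FI) categories — food secure,
mild, moderate, severe — by the standard HFIA-category decision rules:

* severe    — Q5 or Q6 often, or any of Q7-Q9 at least rarely;
* moderate  — Q3 or Q4 at least sometimes, or Q5 or Q6 rarely/sometimes;
* mild      — Q1 at least sometimes, or Q2 at least rarely, or
              Q3 or Q4 rarely;
* food secure otherwise (Q1 at most rarely, everything else never).

The most severe triggered category wins, so the map is total and unique.
The variant used with individual (rather than household) wording changes
question text only; the category algorithm is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ITEMS",
    "FREQUENCY_LABELS",
    "CATEGORY_LABELS",
    "HFIASResponse",
    "HFIASError",
    "categorize_hfias",
    "categorize_many",
    "hfias_score",
    "read_hfias_table",
    "enumerate_patterns",
]

N_ITEMS = 9
FREQUENCY_LABELS: tuple[str, ...] = ("never", "rarely", "sometimes", "often")
CATEGORY_LABELS: tuple[str, ...] = ("food_secure", "mild", "moderate", "severe")

_FREQ_TO_CODE = {lab: i for i, lab in enumerate(FREQUENCY_LABELS)}


class HFIASError(ValueError):
    """Raised for invalid or inconsistent HFIAS responses."""


@dataclass(frozen=True)
class HFIASResponse:
    """One participant's nine occurrence/frequency item responses.

    ``frequency`` holds codes 0-3 (never/rarely/sometimes/often); the
    occurrence answer is implied (occurred iff frequency > never) and, when
    supplied separately, must be consistent with it.
    """

    participant_id: str
    frequency: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.frequency) != N_ITEMS:
            raise HFIASError(
                f"expected {N_ITEMS} items, got {len(self.frequency)}"
            )
        if any(f is None or not 0 <= int(f) <= 3 for f in self.frequency):
            raise HFIASError("frequency codes must be 0-3")

    @property
    def category(self) -> str:
        return CATEGORY_LABELS[categorize_hfias(self.frequency)]

    @property
    def score(self) -> int:
        return hfias_score(self.frequency)


def categorize_hfias(frequency: Sequence[int]) -> int:
    """FI category code 0-3 for one complete 9-item frequency vector."""
    q = [int(f) for f in frequency]
    if len(q) != N_ITEMS:
        raise HFIASError(f"expected {N_ITEMS} items, got {len(q)}")
    if any(not 0 <= f <= 3 for f in q):
        raise HFIASError("frequency codes must be 0-3")
    q1, q2, q3, q4, q5, q6, q7, q8, q9 = q
    if q5 == 3 or q6 == 3 or q7 >= 1 or q8 >= 1 or q9 >= 1:
        return 3
    if q3 >= 2 or q4 >= 2 or q5 in (1, 2) or q6 in (1, 2):
        return 2
    if q1 >= 2 or q2 >= 1 or q3 == 1 or q4 == 1:
        return 1
    return 0


def categorize_many(frequency: np.ndarray) -> np.ndarray:
    """Vectorised categorisation of an (n, 9) array of frequency codes."""
    f = np.asarray(frequency)
    if f.ndim != 2 or f.shape[1] != N_ITEMS:
        raise HFIASError(f"expected an (n, {N_ITEMS}) array")
    if f.min(initial=0) < 0 or f.max(initial=0) > 3:
        raise HFIASError("frequency codes must be 0-3")
    q = [f[:, i] for i in range(N_ITEMS)]
    severe = (q[4] == 3) | (q[5] == 3) | (q[6] >= 1) | (q[7] >= 1) | (q[8] >= 1)
    moderate = (
        (q[2] >= 2)
        | (q[3] >= 2)
        | ((q[4] >= 1) & (q[4] <= 2))
        | ((q[5] >= 1) & (q[5] <= 2))
    )
    mild = (q[0] >= 2) | (q[1] >= 1) | (q[2] == 1) | (q[3] == 1)
    out = np.zeros(len(f), dtype=np.int8)
    out[mild] = 1
    out[moderate] = 2
    out[severe] = 3
    return out


def hfias_score(frequency: Sequence[int]) -> int:
    """Continuous HFIAS score 0-27 (sum of the nine frequency codes)."""
    return int(sum(int(f) for f in frequency))


def _parse_freq(value) -> int:
    if isinstance(value, str):
        norm = value.strip().lower()
        if norm in _FREQ_TO_CODE:
            return _FREQ_TO_CODE[norm]
        if norm.isdigit():
            return int(norm)
        raise HFIASError(f"unknown frequency value {value!r}")
    return int(value)


def read_hfias_table(path) -> list[HFIASResponse]:
    """Read a CSV of HFIAS responses, one row per participant.

    Accepts either nine combined columns ``q1..q9`` coded
    never/rarely/sometimes/often (or 0-3), or eighteen columns
    ``q1_occ..q9_occ`` (0/1 or true/false) plus ``q1_freq..q9_freq``.
    Occurrence/frequency inconsistencies raise :class:`HFIASError`
    listing the offending rows.
    """
    df = pd.read_csv(path, dtype=str)
    combined = [f"q{i}" for i in range(1, N_ITEMS + 1)]
    occ_cols = [f"q{i}_occ" for i in range(1, N_ITEMS + 1)]
    freq_cols = [f"q{i}_freq" for i in range(1, N_ITEMS + 1)]

    if all(c in df.columns for c in combined):
        use_occ = False
    elif all(c in df.columns for c in occ_cols + freq_cols):
        use_occ = True
    else:
        raise HFIASError(
            "expected columns q1..q9 or q1_occ..q9_occ plus q1_freq..q9_freq"
        )

    responses: list[HFIASResponse] = []
    bad_rows: list[int] = []
    truthy = {"1", "true", "yes", "y"}
    for i, (_, row) in enumerate(df.iterrows()):
        pid = str(row["participant_id"]) if "participant_id" in df.columns else str(i)
        if use_occ:
            freqs = []
            consistent = True
            for oc, fc in zip(occ_cols, freq_cols):
                occurred = str(row[oc]).strip().lower() in truthy
                freq = _parse_freq(row[fc])
                if occurred != (freq > 0):
                    consistent = False
                freqs.append(freq)
            if not consistent:
                bad_rows.append(i)
                continue
        else:
            freqs = [_parse_freq(row[c]) for c in combined]
        responses.append(HFIASResponse(participant_id=pid, frequency=tuple(freqs)))

    if bad_rows:
        raise HFIASError(
            f"occurrence/frequency inconsistency in rows {bad_rows}"
        )
    return responses


@lru_cache(maxsize=1)
def enumerate_patterns() -> tuple[np.ndarray, np.ndarray]:
    """All 4^9 = 262144 frequency patterns and their FI categories.

    Returns ``(patterns, categories)`` with ``patterns`` of shape
    (262144, 9) in int8.  Used both as the sampling pool for synthetic
    cohorts (draw a pattern consistent with a given category) and as the
    exhaustive ground for decision-table checks.
    """
    grid = np.indices((4,) * N_ITEMS).reshape(N_ITEMS, -1).T.astype(np.int8)
    return grid, categorize_many(grid)


class HFIASCategorizer:
    """sklearn-style transformer applying the HFIA-category decision rules.

    ``transform``/``predict`` take an (n, 9) array or DataFrame of
    frequency codes 0-3 and return category codes 0-3 (food secure ...
    severe).  The rule set is fixed, so ``fit`` only validates input.
    """

    def fit(self, X, y=None) -> "HFIASCategorizer":
        categorize_many(np.asarray(X))
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return categorize_many(np.asarray(X))

    predict = transform

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "HFIASCategorizer":
        return self


def responses_to_frame(responses: Iterable[HFIASResponse]) -> pd.DataFrame:
    rows = {
        r.participant_id: dict(
            {f"q{i+1}": f for i, f in enumerate(r.frequency)},
            category=r.category,
            hfias_score=r.score,
        )
        for r in responses
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df
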