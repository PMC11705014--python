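"""Modified Healthy Food Intake Index (mHFII) scoring.

The index awards points for 11 food groups based on weekly consumption
frequency: favourable groups (vegetables, fruits and berries, fibre-rich
grains, fish, vegetable oil, nuts and seeds, milk, fat spreads) score
higher with more frequent consumption; limiting groups (red and processed
meat, sugar-sweetened beverages, snacks) score higher with less frequent
consumption.  Seven groups carry a maximum of 2 points and four a maximum
of 1 point, so the total ranges 0-18, higher meaning closer to the Nordic
food-based dietary guidelines.

The component definitions (member items, direction, thresholds, maximum
points) are configuration, not code: they live in a YAML scoring table so
alternative index versions are alternative configs.  The bundled default
table is a synthetic stand-in (see ``data/scoring_table_synthetic.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .ffq import FFQRecord, aggregate_group

__all__ = [
    "ComponentRule",
    "ScoringTable",
    "MHFIIResult",
    "ScoringError",
    "ValidationReport",
    "score_component",
    "score_mhfii",
    "score_cohort",
    "validate_scoring_table",
    "load_default_scoring_table",
    "MHFIIScorer",
]

TOTAL_MAX = 18
N_COMPONENTS = 11

#: Food groups every valid scoring table must cover.
REQUIRED_COMPONENTS = frozenset(
    {
        "vegetables",
        "fruits_berries",
        "fibre_rich_grains",
        "fish",
        "vegetable_oil",
        "nuts_seeds",
        "milk",
        "fat_spreads",
        "red_processed_meat",
        "sugar_sweetened_beverages",
        "snacks",
    }
)


class ScoringError(ValueError):
    """Raised for invalid scoring tables or out-of-domain frequencies."""


@dataclass(frozen=True)
class ComponentRule:
    """Scoring rule for one food group.

    ``thresholds`` are strictly increasing weekly frequencies, one per
    point.  Favourable: points = number of thresholds at or below the
    observed frequency.  Limiting: points = number of thresholds at or
    above it.  A frequency exactly at a threshold earns the point in both
    directions ("at least" / "at most" convention).
    """

    name: str
    items: tuple[str, ...]
    direction: str  # 'favourable' | 'limiting'
    thresholds: tuple[float, ...]
    max_points: int

    def __post_init__(self) -> None:
        if self.direction not in ("favourable", "limiting"):
            raise ScoringError(
                f"component {self.name!r}: direction must be 'favourable' "
                f"or 'limiting', got {self.direction!r}"
            )
        if self.max_points not in (1, 2):
            raise ScoringError(
                f"component {self.name!r}: max_points must be 1 or 2"
            )
        if len(self.thresholds) != self.max_points:
            raise ScoringError(
                f"component {self.name!r}: need one threshold per point"
            )
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ScoringError(
                f"component {self.name!r}: thresholds must strictly increase"
            )


@dataclass(frozen=True)
class ScoringTable:
    """Declarative definition of the 11 index components."""

    components: tuple[ComponentRule, ...]
    name: str = "mhfii"

    @classmethod
    def from_yaml(cls, path) -> "ScoringTable":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        comps = tuple(
            ComponentRule(
                name=c["name"],
                items=tuple(c["items"]),
                direction=c["direction"],
                thresholds=tuple(float(t) for t in c["thresholds"]),
                max_points=int(c["max_points"]),
            )
            for c in doc["components"]
        )
        return cls(components=comps, name=doc.get("name", "mhfii"))

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "components": [
                {
                    "name": c.name,
                    "direction": c.direction,
                    "max_points": c.max_points,
                    "thresholds": list(c.thresholds),
                    "items": list(c.items),
                }
                for c in self.components
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    def __getitem__(self, name: str) -> ComponentRule:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def max_total(self) -> int:
        return sum(c.max_points for c in self.components)


@dataclass
class MHFIIResult:
    participant_id: str
    component_scores: dict[str, int | None]
    n_missing_components: int = 0

    @property
    def complete(self) -> bool:
        return self.n_missing_components == 0

    @property
    def total(self) -> int | None:
        if not self.complete:
            return None
        return int(sum(v for v in self.component_scores.values()))


@dataclass
class ValidationReport:
    passed: bool = True
    messages: list[str] = field(default_factory=list)

    def fail(self, msg: str) -> None:
        self.passed = False
        self.messages.append(msg)


def validate_scoring_table(
    table: ScoringTable, schema_items: Sequence[str] | None = None
) -> ValidationReport:
    """Structural checks: 11 components, point budget 18, names, coverage."""
    report = ValidationReport()
    n = len(table.components)
    if n != N_COMPONENTS:
        report.fail(f"expected {N_COMPONENTS} components, found {n}")
    total = table.max_total
    if total != TOTAL_MAX:
        report.fail(f"max points must sum to {TOTAL_MAX}, found {total}")
    n_two = sum(1 for c in table.components if c.max_points == 2)
    if n == N_COMPONENTS and total == TOTAL_MAX and n_two != 7:
        report.fail(f"expected 7 two-point components, found {n_two}")
    names = set(table.component_names)
    missing = REQUIRED_COMPONENTS - names
    if missing:
        report.fail(f"missing required components: {sorted(missing)}")
    if len(names) != n:
        report.fail("duplicate component names")
    seen: set[str] = set()
    for c in table.components:
        overlap = seen & set(c.items)
        if overlap:
            report.fail(f"items in multiple components: {sorted(overlap)}")
        seen |= set(c.items)
        if schema_items is not None:
            unknown = set(c.items) - set(schema_items)
            if unknown:
                report.fail(
                    f"component {c.name!r} references unknown items: "
                    f"{sorted(unknown)}"
                )
    return report


def score_component(weekly_freq: float, rule: ComponentRule) -> int:
    """Points for one food group given its weekly frequency."""
    if weekly_freq < 0:
        raise ScoringError(
            f"component {rule.name!r}: negative weekly frequency "
            f"{weekly_freq}"
        )
    if rule.direction == "favourable":
        pts = sum(1 for t in rule.thresholds if weekly_freq >= t)
    else:
        pts = sum(1 for t in rule.thresholds if weekly_freq <= t)
    return int(min(pts, rule.max_points))


def score_mhfii(record: FFQRecord, table: ScoringTable) -> MHFIIResult:
    """Score one participant: 11 component scores and the 0-18 total.

    A component whose member items are all missing is left unscored and
    the participant is flagged incomplete (total None); downstream
    analyses exclude incomplete participants listwise.  Partially missing
    components are scored on the observed items.
    """
    _check_table(table)
    scores: dict[str, int | None] = {}
    n_missing = 0
    for rule in table.components:
        freq = aggregate_group(record, rule.items)
        if freq is None:
            scores[rule.name] = None
            n_missing += 1
        else:
            scores[rule.name] = score_component(freq, rule)
    return MHFIIResult(
        participant_id=record.participant_id,
        component_scores=scores,
        n_missing_components=n_missing,
    )


def score_cohort(
    records: Iterable[FFQRecord], table: ScoringTable
) -> pd.DataFrame:
    """Component scores + total for many participants (NA = unscorable)."""
    results = [score_mhfii(r, table) for r in records]
    rows = {
        r.participant_id: dict(r.component_scores, mhfii_total=r.total)
        for r in results
    }
    df = pd.DataFrame.from_dict(rows, orient="index").astype("Int64")
    df.index.name = "participant_id"
    return df


def _check_table(table: ScoringTable) -> None:
    report = validate_scoring_table(table)
    if not report.passed:
        raise ScoringError("; ".join(report.messages))


def load_default_scoring_table() -> ScoringTable:
    """The bundled default (synthetic stand-in) scoring table."""
    ref = resources.files("mhfii_foodsec.data") / "scoring_table_synthetic.yaml"
    with resources.as_file(ref) as path:
        return ScoringTable.from_yaml(path)


class MHFIIScorer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: weekly group frequencies -> index scores.

    ``transform`` accepts a DataFrame of item-level weekly frequencies
    (columns = item ids, NaN = missing) and returns the 11 component
    scores plus ``mhfii_total``.  Stateless apart from the scoring table;
    ``fit`` only validates the configuration.
    """

    def __init__(self, scoring_table: ScoringTable | None = None):
        self.scoring_table = scoring_table

    def _table(self) -> ScoringTable:
        return self.scoring_table or load_default_scoring_table()

    def fit(self, X: pd.DataFrame, y=None) -> "MHFIIScorer":
        table = self._table()
        report = validate_scoring_table(table, schema_items=list(X.columns))
        if not report.passed:
            raise ScoringError("; ".join(report.messages))
        self.scoring_table_ = table
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table = getattr(self, "scoring_table_", None) or self._table()
        out = {}
        for rule in table.components:
            sub = X[list(rule.items)].astype(float)
            freq = sub.sum(axis=1, min_count=1)
            if (freq.dropna() < 0).any():
                raise ScoringError(
                    f"component {rule.name!r}: negative weekly frequency"
                )
            if rule.direction == "favourable":
                pts = sum((freq >= t).astype(float) for t in rule.thresholds)
            else:
                pts = sum((freq <= t).astype(float) for t in rule.thresholds)
            pts = np.minimum(pts, rule.max_points)
            pts[freq.isna()] = np.nan
            out[rule.name] = pts
        df = pd.DataFrame(out, index=X.index)
        df["mhfii_total"] = df.sum(axis=1, skipna=False)
        return df.astype("Int64")
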