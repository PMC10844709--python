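"""Five-class river-health grading of index values.

Each index has an ordered scheme of five classes (Excellent … Very poor)
over right-closed intervals "(a, b]"; BI runs the other way (low BI means a
clean, intolerant community). The packaged scheme resolves two gaps in the
printed criteria by extending the lower class — see
``data/grading_scheme.yaml`` — so grading is a total function over each
index's attainable range. Sites with an undefined index value receive no
class and are excluded from summary denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

CLASS_LABELS = ("Excellent", "Good", "Fair", "Poor", "Very poor")


@dataclass(frozen=True)
class ClassInterval:
    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool

    def contains(self, value: float) -> bool:
        above = value >= self.lower if self.lower_closed else value > self.lower
        below = value <= self.upper if self.upper_closed else value < self.upper
        return above and below


@dataclass(frozen=True)
class GradingScheme:
    index_name: str
    direction: str  # higher_is_better | lower_is_better
    intervals: tuple[ClassInterval, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"bad direction {self.direction!r}")
        labels = tuple(iv.label for iv in self.intervals)
        if sorted(labels) != sorted(CLASS_LABELS):
            raise ValueError("scheme must define exactly the five classes")


def load_schemes(path: str | Path | None = None) -> dict[str, GradingScheme]:
    """Load grading schemes from YAML (packaged criteria by default)."""
    if path is None:
        path = resources.files(__package__) / "data" / "grading_scheme.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    schemes = {}
    for name, entry in raw["schemes"].items():
        ivs = tuple(ClassInterval(c["label"], float(c["lower"]),
                                  float(c["upper"]), bool(c["lower_closed"]),
                                  bool(c["upper_closed"]))
                    for c in entry["classes"])
        schemes[name] = GradingScheme(name, entry["direction"], ivs)
    return schemes


def grade(value: float, scheme: GradingScheme) -> str | None:
    """Class label for one index value; None when the value is undefined."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    for iv in scheme.intervals:
        if iv.contains(value):
            return iv.label
    raise ValueError(f"{scheme.index_name}: value {value!r} falls outside "
                     f"every grading interval")


def grade_series(values: pd.Series, scheme: GradingScheme) -> pd.Series:
    """Vectorised :func:`grade`; undefined values stay missing."""
    return values.map(lambda v: grade(v, scheme))


@dataclass
class GradeSummary:
    """Per-class counts and percentages over sites with a defined value."""

    index_name: str
    counts: pd.Series       # per class label, ordered Excellent..Very poor
    percentages: pd.Series  # counts / denominator * 100
    denominator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts,
                             "percent": self.percentages})


def summarize_grades(values: pd.Series, scheme: GradingScheme) -> GradeSummary:
    """Grade a column of index values and tabulate class proportions."""
    labels = grade_series(values, scheme).dropna()
    if len(labels) == 0:
        raise ValueError(f"{scheme.index_name}: no defined values to grade")
    counts = labels.value_counts().reindex(CLASS_LABELS, fill_value=0)
    counts.index.name = "class"
    pct = counts / len(labels) * 100.0
    return GradeSummary(index_name=scheme.index_name, counts=counts,
                        percentages=pct, denominator=int(len(labels)))
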