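"""Sample-design tables and cross-layer consistency checks.

A design is a :class:`pandas.DataFrame` with columns ``sample_id``,
``cell_line``, ``day`` and ``replicate``, one row per array/sequencing
sample.  Every omic layer (expression, metabolomics, methylation) carries
its own design; the pipeline validates that they share a day grid and meet
replicate minima before integrating results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DESIGN_COLUMNS = ("sample_id", "cell_line", "day", "replicate")

#: Time points (days of induction) used throughout the default study layout.
DEFAULT_DAYS = (0, 3, 6, 9)

#: Known cell-model labels; free-form labels are accepted as "custom".
CELL_LINES = ("DN-POLG", "NDI1/AOX")


def make_design(
    cell_line: str = "DN-POLG",
    days: Sequence[int] = DEFAULT_DAYS,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Build a balanced time-course design with ``n_reps`` replicates per day."""
    rows = []
    tag = cell_line.replace("/", "-")
    for day in days:
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{tag}_d{day}_r{rep}",
                    "cell_line": cell_line,
                    "day": int(day),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


@dataclass
class DesignVerdict:
    """Structured outcome of design validation; falsy when any check failed."""

    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def check_design(design: pd.DataFrame, baseline_day: int = 0) -> list[str]:
    """Check a single design table; returns a list of violations (empty = pass)."""
    errors: list[str] = []
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        return [f"missing design columns: {missing}"]
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        errors.append(f"duplicate sample ids: {dupes}")
    for cell_line, sub in design.groupby("cell_line"):
        if baseline_day not in set(sub["day"]):
            errors.append(f"cell line {cell_line!r} lacks baseline day {baseline_day}")
        small = sub.groupby("day").size()
        for day, n in small.items():
            if n < 2:
                errors.append(
                    f"cell line {cell_line!r} day {day} has {n} replicate(s); need >= 2"
                )
    return errors


def validate_design(
    designs: Iterable[pd.DataFrame], baseline_day: int = 0
) -> DesignVerdict:
    """Validate one or more layer designs for pipeline consistency.

    Checks each layer individually (unique ids, baseline present, replicate
    minima) and, across layers, that all share the same day grid.
    """
    designs = list(designs)
    if not designs:
        return DesignVerdict(errors=["no designs supplied"])
    verdict = DesignVerdict()
    grids = []
    for i, design in enumerate(designs):
        for err in check_design(design, baseline_day=baseline_day):
            verdict.errors.append(f"layer {i}: {err}")
        if "day" in design.columns:
            grids.append(tuple(sorted(set(design["day"]))))
    if len(set(grids)) > 1:
        verdict.errors.append(f"layers disagree on day grid: {sorted(set(grids))}")
    return verdict


def day_groups(design: pd.DataFrame) -> dict[int, list[str]]:
    """Map day -> ordered sample_id list (samples pooled across cell lines)."""
    return {
        int(day): sub["sample_id"].tolist()
        for day, sub in design.groupby("day", sort=True)
    }
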