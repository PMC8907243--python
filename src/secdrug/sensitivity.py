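"""Tertile S/N/R categorization of per-drug ln(IC50) and universe building.

For each drug the cell lines are ranked by ln(IC50); the lowest floor(n/3)
are called S (sensitive), the highest floor(n/3) R (resistant), and the
remainder N (neutral / intermediate).  The "universe" is the set of lines a
secondary-drug combination must cover: either the primary drug's N u R
lines, or its R lines only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response_data import DoseResponseMatrix

CATEGORY_S = "S"
CATEGORY_N = "N"
CATEGORY_R = "R"


@dataclass(frozen=True)
class SensitivityCalls:
    """Per-drug tertile categories with the thresholds that separate them."""

    drug_id: str
    categories: dict[str, str]  # cell_line_id -> S / N / R
    lower_threshold: float  # max ln(IC50) among S lines
    upper_threshold: float  # min ln(IC50) among R lines

    @property
    def n_s(self) -> int:
        return sum(1 for c in self.categories.values() if c == CATEGORY_S)

    @property
    def n_n(self) -> int:
        return sum(1 for c in self.categories.values() if c == CATEGORY_N)

    @property
    def n_r(self) -> int:
        return sum(1 for c in self.categories.values() if c == CATEGORY_R)

    @property
    def n(self) -> int:
        return len(self.categories)

    def lines_in(self, category: str) -> frozenset[str]:
        return frozenset(c for c, cat in self.categories.items() if cat == category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line_id": list(self.categories),
                "drug_id": self.drug_id,
                "category": list(self.categories.values()),
            }
        )


@dataclass(frozen=True)
class Universe:
    """Cell lines a combination must cover, plus the coverage denominator.

    ``n_total`` is the count of all filtered lines, not just the members:
    the primary drug's own S lines count toward coverage at step 0, so the
    reported fractions use the full panel as denominator.
    """

    mode: str  # neutral_and_resistant | resistant_only
    members: frozenset[str]
    n_total: int

    def __post_init__(self) -> None:
        if self.mode not in ("neutral_and_resistant", "resistant_only"):
            raise ValueError(f"unknown universe mode: {self.mode!r}")
        if len(self.members) > self.n_total:
            raise ValueError("universe members exceed the filtered line count")


def call_sensitivity(m: DoseResponseMatrix, drug: str) -> SensitivityCalls:
    """Assign S/N/R tertile categories for one drug.

    With n lines and q = floor(n/3), the q lowest-ln(IC50) lines are S and
    the q highest are R.  Ties are broken by ascending value then
    lexicographic cell-line id, so the partition is deterministic under any
    input ordering.
    """
    row = m.drug_row(drug)
    if row.isna().any():
        raise ValueError(f"matrix must be fully imputed before calling ({drug!r})")
    n = len(row)
    if n < 3:
        raise ValueError(f"need at least 3 cell lines to form tertiles, got {n}")
    order = sorted(row.index, key=lambda cl: (row[cl], cl))
    q = n // 3
    categories: dict[str, str] = {}
    for i, cl in enumerate(order):
        if i < q:
            categories[cl] = CATEGORY_S
        elif i >= n - q:
            categories[cl] = CATEGORY_R
        else:
            categories[cl] = CATEGORY_N
    lower = float(row[order[q - 1]])
    upper = float(row[order[n - q]])
    # preserve the matrix's column order in the mapping for stable exports
    categories = {cl: categories[cl] for cl in row.index}
    return SensitivityCalls(drug, categories, lower, upper)


def call_all(m: DoseResponseMatrix) -> dict[str, SensitivityCalls]:
    """Tertile calls for every drug in the matrix."""
    return {d: call_sensitivity(m, d) for d in m.drug_ids}


def build_universe(calls: SensitivityCalls, mode: str = "neutral_and_resistant") -> Universe:
    """Universe of lines the secondary drugs must cover for this primary drug."""
    if mode == "neutral_and_resistant":
        members = calls.lines_in(CATEGORY_N) | calls.lines_in(CATEGORY_R)
    elif mode == "resistant_only":
        members = calls.lines_in(CATEGORY_R)
    else:
        raise ValueError(f"unknown universe mode: {mode!r}")
    return Universe(mode=mode, members=frozenset(members), n_total=calls.n)


def export_calls(calls: dict[str, SensitivityCalls], m: DoseResponseMatrix, path) -> None:
    """Write all calls as a long TSV (cell_line_id, drug_id, category, ln_ic50)."""
    frames = []
    for drug, c in calls.items():
        f = c.to_frame()
        f["ln_ic50"] = [float(m.values.loc[drug, cl]) for cl in f["cell_line_id"]]
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
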