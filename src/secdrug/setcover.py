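"""Regularized greedy maximum coverage over secondary-drug kill sets.

A candidate secondary drug's *kill set* is the subset of the universe (the
cell lines neutral or resistant to the primary drug) that the candidate is
predicted to kill, i.e. the universe lines falling in the candidate's own
sensitive tertile.  The greedy engine repeatedly selects the candidate with
the largest marginal coverage of still-uncovered universe lines; a
minimum-marginal-gain threshold lambda * |universe| acts as a
sparsity-inducing regularizer (lambda = 0 is pure greedy).  An exhaustive
enumerator serves as a brute-force oracle on small instances, and a
cell-line bootstrap converts selection stability into a confidence score.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response_data import DoseResponseMatrix
from .sensitivity import (
    CATEGORY_S,
    SensitivityCalls,
    Universe,
    build_universe,
    call_all,
)


@dataclass(frozen=True)
class CoverSolution:
    """An ordered secondary-drug selection with per-step cumulative coverage.

    Step 0 is the primary drug alone: its covered set is its own sensitive
    tertile and the coverage fraction uses the full filtered panel
    (``n_total``) as denominator.  Each subsequent step adds one secondary
    drug's newly covered universe lines.
    """

    primary_drug: str
    selected: tuple[str, ...]
    covered_by_step: tuple[frozenset[str], ...]  # cumulative, step 0 first
    coverage_fraction_by_step: tuple[float, ...]
    n_total: int
    k_max: int
    lam: float
    confidence: float | None = None
    no_candidates: bool = False  # warning flag: empty candidate set

    def __post_init__(self) -> None:
        fr = self.coverage_fraction_by_step
        if any(b < a - 1e-12 for a, b in zip(fr, fr[1:])):
            raise ValueError("coverage fractions must be non-decreasing")
        if len(self.selected) > self.k_max:
            raise ValueError("selection longer than k_max")

    def fraction_at(self, k: int) -> float:
        """Cumulative coverage fraction after k secondary drugs (clamped)."""
        idx = min(k, len(self.selected))
        return self.coverage_fraction_by_step[idx]

    def to_dict(self) -> dict:
        return {
            "primary_drug": self.primary_drug,
            "selected": list(self.selected),
            "covered_by_step": [sorted(s) for s in self.covered_by_step],
            "coverage_fraction_by_step": list(self.coverage_fraction_by_step),
            "n_total": self.n_total,
            "k_max": self.k_max,
            "lambda": self.lam,
            "confidence": self.confidence,
        }


def drug_kill_sets(
    calls_all: dict[str, SensitivityCalls],
    universe: Universe,
    candidates: list[str],
) -> dict[str, frozenset[str]]:
    """Universe lines each candidate drug is predicted to kill (S tertile)."""
    kill: dict[str, frozenset[str]] = {}
    for d in candidates:
        if d not in calls_all:
            raise KeyError(f"no sensitivity calls for candidate drug {d!r}")
        kill[d] = calls_all[d].lines_in(CATEGORY_S) & universe.members
    return kill


def _steps(
    primary_s: frozenset[str], picks: list[tuple[str, frozenset[str]]], n_total: int
) -> tuple[tuple[frozenset[str], ...], tuple[float, ...]]:
    covered = frozenset(primary_s)
    covered_by_step = [covered]
    fractions = [len(covered) / n_total]
    for _, gain in picks:
        covered = covered | gain
        covered_by_step.append(covered)
        fractions.append(len(covered) / n_total)
    return tuple(covered_by_step), tuple(fractions)


def greedy_cover(
    kill_sets: dict[str, frozenset[str]],
    universe: Universe,
    k_max: int,
    lam: float = 0.0,
    primary_drug: str = "",
    primary_s_set: frozenset[str] = frozenset(),
) -> CoverSolution:
    """Greedy maximum coverage with a minimum-marginal-gain stopping rule.

    Selection stops at ``k_max`` drugs, at full universe coverage, or when
    the best marginal gain is <= ``lam * |universe|``.  Ties on marginal
    gain break lexicographically on drug id, making the path deterministic.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not (0.0 <= lam < 1.0):
        raise ValueError("lambda must be in [0, 1)")
    threshold = lam * len(universe.members)
    uncovered = set(universe.members)
    picks: list[tuple[str, frozenset[str]]] = []
    remaining = sorted(kill_sets)
    no_candidates = not remaining
    while len(picks) < k_max and uncovered and remaining:
        best_drug, best_gain = None, frozenset()
        for d in remaining:  # sorted: first max wins ties lexicographically
            gain = kill_sets[d] & uncovered
            if len(gain) > len(best_gain):
                best_drug, best_gain = d, frozenset(gain)
        if best_drug is None or len(best_gain) <= threshold:
            break
        picks.append((best_drug, best_gain))
        uncovered -= best_gain
        remaining.remove(best_drug)
    covered_by_step, fractions = _steps(primary_s_set, picks, universe.n_total)
    return CoverSolution(
        primary_drug=primary_drug,
        selected=tuple(d for d, _ in picks),
        covered_by_step=covered_by_step,
        coverage_fraction_by_step=fractions,
        n_total=universe.n_total,
        k_max=k_max,
        lam=lam,
        no_candidates=no_candidates,
    )


def exhaustive_cover(
    kill_sets: dict[str, frozenset[str]],
    universe: Universe,
    k: int,
    primary_drug: str = "",
    primary_s_set: frozenset[str] = frozenset(),
    cap: int = 10**6,
) -> CoverSolution:
    """Brute-force maximum-coverage oracle over all size-k candidate subsets.

    Ties on covered-universe count break on the lexicographically smallest
    sorted drug-id tuple, so the result is deterministic.  Intended for
    validating the greedy heuristic on small instances.
    """
    drugs = sorted(kill_sets)
    k_eff = min(k, len(drugs))
    n_subsets = math.comb(len(drugs), k_eff)
    if n_subsets > cap:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration cap {cap}; "
            "use a smaller instance or the greedy engine"
        )
    best_combo: tuple[str, ...] | None = None
    best_count = -1
    for combo in itertools.combinations(drugs, k_eff):
        covered = frozenset().union(*(kill_sets[d] for d in combo)) if combo else frozenset()
        count = len(covered & universe.members)
        if count > best_count:
            best_combo, best_count = combo, count
    assert best_combo is not None or k_eff == 0
    combo = best_combo or ()
    # report steps in greedy-marginal order within the optimal subset
    uncovered = set(universe.members)
    picks: list[tuple[str, frozenset[str]]] = []
    pool = list(combo)
    while pool:
        pool.sort(key=lambda d: (-len(kill_sets[d] & uncovered), d))
        d = pool.pop(0)
        gain = frozenset(kill_sets[d] & uncovered)
        picks.append((d, gain))
        uncovered -= gain
    covered_by_step, fractions = _steps(primary_s_set, picks, universe.n_total)
    return CoverSolution(
        primary_drug=primary_drug,
        selected=tuple(d for d, _ in picks),
        covered_by_step=covered_by_step,
        coverage_fraction_by_step=fractions,
        n_total=universe.n_total,
        k_max=max(k, 1),
        lam=0.0,
    )


def greedy_restarts(
    kill_sets: dict[str, frozenset[str]],
    universe: Universe,
    k_max: int,
    lam: float = 0.0,
    n_restarts: int = 1,
    primary_drug: str = "",
    primary_s_set: frozenset[str] = frozenset(),
) -> list[CoverSolution]:
    """Repeated greedy runs, banning previously selected secondary drugs.

    Emits up to ``n_restarts`` distinct combination regimens; an
    interpretation layer for producing a ranked multi-row report rather than
    a single greedy path.
    """
    solutions: list[CoverSolution] = []
    pool = dict(kill_sets)
    for _ in range(n_restarts):
        if not pool:
            break
        sol = greedy_cover(
            pool, universe, k_max, lam, primary_drug=primary_drug, primary_s_set=primary_s_set
        )
        if not sol.selected:
            break
        solutions.append(sol)
        for d in sol.selected:
            pool.pop(d, None)
    return solutions


def _resample_matrix(
    m: DoseResponseMatrix, rng: np.random.Generator
) -> DoseResponseMatrix | None:
    """One bootstrap replicate: columns resampled with replacement.

    Returns None when fewer than 3 distinct lines were drawn (caller
    redraws).  Repeated draws of a line get a ``~i`` suffix to keep ids
    unique."""
    cols = list(m.cell_line_ids)
    draw = rng.integers(0, len(cols), size=len(cols))
    if len(set(draw.tolist())) < 3:
        return None
    seen: dict[str, int] = {}
    new_ids, src = [], []
    for j in draw:
        cl = cols[j]
        seen[cl] = seen.get(cl, 0) + 1
        new_ids.append(cl if seen[cl] == 1 else f"{cl}~{seen[cl]}")
        src.append(cl)
    sub = m.values[src].copy()
    sub.columns = new_ids
    return DoseResponseMatrix(sub)


def bootstrap_selection_frequencies(
    m: DoseResponseMatrix,
    primary: str,
    k: int,
    B: int = 1000,
    seed: int = 42,
    lam: float = 0.0,
    universe_mode: str = "neutral_and_resistant",
    max_redraws: int = 1000,
) -> tuple[dict[frozenset[str], float], int]:
    """Selection frequency of every size-k greedy solution over B bootstraps.

    Cell lines are resampled with replacement; categorization, universe
    construction, and greedy selection are recomputed on each replicate.
    Returns (frequency map over unordered selections, number of redrawn
    degenerate replicates).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if primary not in m.drug_ids:
        raise KeyError(f"primary drug {primary!r} not in matrix")
    rng = np.random.default_rng(seed)
    tally: dict[frozenset[str], int] = {}
    redrawn = 0
    candidates = [d for d in m.drug_ids if d != primary]
    for _ in range(B):
        rep = _resample_matrix(m, rng)
        while rep is None:
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            rep = _resample_matrix(m, rng)
        calls = call_all(rep)
        uni = build_universe(calls[primary], universe_mode)
        kill = drug_kill_sets(calls, uni, candidates)
        sol = greedy_cover(
            kill, uni, k_max=k, lam=lam,
            primary_drug=primary, primary_s_set=calls[primary].lines_in(CATEGORY_S),
        )
        key = frozenset(sol.selected[:k])
        tally[key] = tally.get(key, 0) + 1
    return {key: c / B for key, c in tally.items()}, redrawn


def bootstrap_confidence(
    m: DoseResponseMatrix,
    primary: str,
    combo: list[str] | tuple[str, ...],
    B: int = 1000,
    seed: int = 42,
    lam: float = 0.0,
    universe_mode: str = "neutral_and_resistant",
) -> float:
    """Fraction of bootstrap replicates whose greedy selection equals combo.

    The replicate's greedy selection is truncated to ``len(combo)`` and
    compared as an unordered set."""
    for d in combo:
        if d not in m.drug_ids:
            raise KeyError(f"combo drug {d!r} not in matrix")
    freqs, _ = bootstrap_selection_frequencies(
        m, primary, k=len(combo), B=B, seed=seed, lam=lam, universe_mode=universe_mode
    )
    return freqs.get(frozenset(combo), 0.0)


def _round_half_up_pct(fraction: float) -> float:
    """Percentage rounded half-up to one decimal (93/94 -> 98.9, 31/94 -> 33.0)."""
    return math.floor(fraction * 1000 + 0.5) / 10


def rank_report(solutions: list[CoverSolution], n_rows: int | None = None) -> pd.DataFrame:
    """Ranked combination table: primary-only, +2-drug and +3-drug coverage.

    Rows are sorted by 3-drug coverage, then 2-drug coverage, then
    confidence (descending each), then lexicographic combo; percentages are
    rounded half-up to one decimal.
    """
    rows = []
    for sol in solutions:
        combo_k2 = sol.selected[:2]
        combo_k3 = sol.selected[:3]
        rows.append(
            {
                "combo_k2": " + ".join(combo_k2),
                "combo_k3": " + ".join(combo_k3),
                "pct_primary_only": _round_half_up_pct(sol.fraction_at(0)),
                "pct_k2": _round_half_up_pct(sol.fraction_at(2)),
                "pct_k3": _round_half_up_pct(sol.fraction_at(3)),
                "confidence": sol.confidence if sol.confidence is not None else np.nan,
                "_k3_frac": sol.fraction_at(3),
                "_k2_frac": sol.fraction_at(2),
            }
        )
    cols = ["rank", "combo_k2", "combo_k3", "pct_primary_only", "pct_k2", "pct_k3", "confidence"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["_conf"] = df["confidence"].fillna(-1.0)
    df = df.sort_values(
        by=["_k3_frac", "_k2_frac", "_conf", "combo_k3"],
        ascending=[False, False, False, True],
        kind="stable",
    ).drop(columns=["_k3_frac", "_k2_frac", "_conf"])
    if n_rows is not None:
        df = df.head(n_rows)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def solutions_to_json(solutions: list[CoverSolution], path, **meta) -> None:
    """Machine-readable dump of every solution plus run metadata."""
    payload = {"meta": meta, "solutions": [s.to_dict() for s in solutions]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
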