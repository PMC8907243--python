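import math

import numpy as np
import pandas as pd
import pytest

from secdrug import (
    DoseResponseMatrix,
    bootstrap_confidence,
    bootstrap_selection_frequencies,
    drug_kill_sets,
    exhaustive_cover,
    greedy_cover,
    greedy_restarts,
    rank_report,
)
from secdrug.sensitivity import Universe, call_all, build_universe
from secdrug.setcover import _round_half_up_pct


def _uni(members, n_total=None):
    members = frozenset(members)
    return Universe("resistant_only", members, n_total or len(members))


TOY_SETS = {
    "A": frozenset({"1", "2", "3"}),
    "B": frozenset({"3", "4"}),
    "C": frozenset({"4", "5", "6"}),
    "D": frozenset({"1", "6"}),
}
TOY_UNI = _uni({"1", "2", "3", "4", "5", "6"})


def test_kill_sets_from_calls(planted_94):
    m, _, truth = planted_94
    calls = call_all(m)
    uni = build_universe(calls[truth.primary_drug], "resistant_only")
    kill = drug_kill_sets(calls, uni, [d for d in m.drug_ids if d != truth.primary_drug])
    for d, s in kill.items():
        assert s <= uni.members
        assert s == calls[d].lines_in("S") & uni.members
    with pytest.raises(KeyError):
        drug_kill_sets(calls, uni, ["not_a_drug"])


def test_greedy_solves_toy_instance():
    sol = greedy_cover(TOY_SETS, TOY_UNI, k_max=2)
    assert sol.selected == ("A", "C")
    assert sol.covered_by_step[-1] == TOY_UNI.members
    assert sol.coverage_fraction_by_step == (0.0, 0.5, 1.0)


def test_exhaustive_matches_hand_enumeration():
    sol = exhaustive_cover(TOY_SETS, TOY_UNI, k=2)
    assert set(sol.selected) == {"A", "C"}
    assert len(sol.covered_by_step[-1]) == 6


def test_exhaustive_edge_cases():
    one = exhaustive_cover(TOY_SETS, TOY_UNI, k=1)
    assert set(one.selected) in ({"A"}, {"C"})  # both cover 3; tie -> lexicographic
    assert set(one.selected) == {"A"}
    everything = exhaustive_cover(TOY_SETS, TOY_UNI, k=10)
    assert set(everything.selected) == set(TOY_SETS)
    with pytest.raises(ValueError, match="cap"):
        sets = {f"d{i}": frozenset() for i in range(40)}
        exhaustive_cover(sets, TOY_UNI, k=20, cap=10)


def test_dominant_candidate_selected_first():
    sets = {"big": TOY_UNI.members, "small": frozenset({"1"})}
    uni = Universe("resistant_only", TOY_UNI.members, 9)  # 3 primary-S lines outside
    primary_s = frozenset({"p1", "p2", "p3"})
    sol = greedy_cover(sets, uni, k_max=2, primary_s_set=primary_s)
    assert sol.selected[0] == "big"
    assert sol.coverage_fraction_by_step[1] == (3 + 6) / 9


def test_empty_candidate_set_is_warning_not_error():
    sol = greedy_cover({}, TOY_UNI, k_max=2, primary_s_set=frozenset({"x"}))
    assert sol.no_candidates and sol.selected == ()
    assert len(sol.coverage_fraction_by_step) == 1


def test_lambda_threshold_stops_selection():
    # B's marginal gain after A is 1 line = 1/6 of the universe
    sol = greedy_cover({"A": TOY_SETS["A"], "B": TOY_SETS["B"]}, TOY_UNI,
                       k_max=3, lam=0.2)
    assert sol.selected == ("A",)  # gain 1 <= 0.2*6
    sol0 = greedy_cover({"A": TOY_SETS["A"], "B": TOY_SETS["B"]}, TOY_UNI, k_max=3)
    assert sol0.selected == ("A", "B")


def test_greedy_approximation_bound_on_random_instances():
    """Greedy >= (1 - 1/e) x exhaustive optimum over 200 seeded instances."""
    bound = 1 - 1 / math.e
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n_lines = int(rng.integers(4, 16))
        n_drugs = int(rng.integers(3, 13))
        k = int(rng.integers(1, 4))
        lines = [f"L{i}" for i in range(n_lines)]
        sets = {
            f"d{j}": frozenset(
                l for l in lines if rng.random() < rng.uniform(0.1, 0.6)
            )
            for j in range(n_drugs)
        }
        uni = _uni(lines)
        g = greedy_cover(sets, uni, k_max=k)
        o = exhaustive_cover(sets, uni, k=k)
        g_cov = len(g.covered_by_step[-1])
        o_cov = len(o.covered_by_step[-1])
        assert g_cov >= bound * o_cov - 1e-9
        assert g_cov <= o_cov


def test_greedy_exact_on_separable_instances():
    """Disjoint planted kill sets: greedy equals the exhaustive optimum."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        lines = [f"L{i}" for i in range(12)]
        parts = [frozenset(lines[0:5]), frozenset(lines[5:9]), frozenset(lines[9:12])]
        sets = {f"p{i}": s for i, s in enumerate(parts)}
        for j in range(4):  # noise drugs are proper subsets of one part
            part = sorted(parts[int(rng.integers(0, 3))])
            keep = rng.random(len(part)) < 0.5
            keep[int(rng.integers(0, len(part)))] = False
            sets[f"n{j}"] = frozenset(l for l, k in zip(part, keep) if k)
        uni = _uni(lines)
        g = greedy_cover(sets, uni, k_max=3)
        o = exhaustive_cover(sets, uni, k=3)
        assert len(g.covered_by_step[-1]) == len(o.covered_by_step[-1]) == 12
        assert set(g.selected) == {"p0", "p1", "p2"}


def test_coverage_monotone_in_k(planted_94):
    m, _, truth = planted_94
    calls = call_all(m)
    uni = build_universe(calls[truth.primary_drug], "neutral_and_resistant")
    kill = drug_kill_sets(calls, uni, [d for d in m.drug_ids if d != truth.primary_drug])
    prev = None
    for k in range(1, 7):
        sol = greedy_cover(kill, uni, k_max=k,
                           primary_s_set=calls[truth.primary_drug].lines_in("S"))
        fr = sol.coverage_fraction_by_step
        assert all(b >= a for a, b in zip(fr, fr[1:]))
        if prev is not None:
            assert fr[-1] >= prev[-1]
        prev = fr


def test_restarts_ban_previous_selections():
    sols = greedy_restarts(TOY_SETS, TOY_UNI, k_max=2, n_restarts=3)
    assert sols[0].selected == ("A", "C")
    assert set(sols[0].selected).isdisjoint(sols[1].selected)


def test_bootstrap_single_replicate_is_binary(planted_94):
    m, _, truth = planted_94
    c = bootstrap_confidence(m, truth.primary_drug, truth.planted_combo, B=1, seed=3,
                             universe_mode="resistant_only")
    assert c in (0.0, 1.0)


def test_bootstrap_planted_pair_dominates(planted_94):
    m, _, truth = planted_94
    freqs, _ = bootstrap_selection_frequencies(
        m, truth.primary_drug, k=2, B=100, seed=9, universe_mode="resistant_only"
    )
    planted = frozenset(truth.planted_combo)
    others = [v for key, v in freqs.items() if key != planted]
    assert freqs.get(planted, 0.0) > max(others, default=0.0)


def test_exchangeable_null_selection_is_uniform_over_pairs():
    """With i.i.d. noise and exchangeable drugs, no pair is preferred.

    Selection frequencies are tallied over fresh noise matrices (the
    exchangeability argument applies across datasets; a bootstrap of one
    realized matrix rightly concentrates on the pairs that matrix favors).
    Candidate labels are shuffled per replicate so the deterministic
    lexicographic tie-break does not itself prefer any physical profile.
    """
    rng = np.random.default_rng(3)
    B = 200
    tally: dict[frozenset, int] = {}
    for _ in range(B):
        perm = rng.permutation(4)  # physical candidate i gets label X{perm[i]+1}
        names = ["X0"] + [f"X{perm[i] + 1}" for i in range(4)]
        df = pd.DataFrame(
            rng.normal(0, 1, (5, 30)),
            index=names,
            columns=[f"c{j}" for j in range(30)],
        )
        m = DoseResponseMatrix(df)
        calls = call_all(m)
        uni = build_universe(calls["X0"], "neutral_and_resistant")
        kill = drug_kill_sets(calls, uni, ["X1", "X2", "X3", "X4"])
        sol = greedy_cover(kill, uni, k_max=2)
        label_to_phys = {f"X{perm[i] + 1}": i for i in range(4)}
        key = frozenset(label_to_phys[d] for d in sol.selected)
        tally[key] = tally.get(key, 0) + 1
    p = 1 / 6  # 4 candidates -> 6 unordered pairs
    se = math.sqrt(p * (1 - p) / B)
    assert len(tally) == 6
    for count in tally.values():
        assert abs(count / B - p) <= 3 * se


def test_round_half_up_matches_printed_percentages():
    assert _round_half_up_pct(31 / 94) == 33.0
    assert _round_half_up_pct(0.72249) == 72.2
    assert _round_half_up_pct(0.8255) == 82.6
    assert _round_half_up_pct(0.825499) == 82.5


def test_rank_report_ordering_and_rounding():
    def sol(selected, fracs, conf):
        from secdrug.setcover import CoverSolution

        covered = [frozenset(range(int(f * 100))) for f in fracs]
        return CoverSolution(
            primary_drug="P", selected=selected,
            covered_by_step=tuple(frozenset(map(str, c)) for c in covered),
            coverage_fraction_by_step=tuple(fracs), n_total=100, k_max=3,
            lam=0.0, confidence=conf,
        )

    s1 = sol(("F", "A", "S"), (0.33, 0.55, 0.722, 0.825), 0.9)
    s2 = sol(("P4", "B", "F"), (0.33, 0.58, 0.763, 0.876), 0.8)
    rep = rank_report([s1, s2])
    assert list(rep["rank"]) == [1, 2]
    assert rep.loc[0, "combo_k3"] == "P4 + B + F"  # higher k3 coverage wins
    assert rep.loc[0, "pct_k3"] == 87.6 and rep.loc[1, "pct_k3"] == 82.5
    assert rep.loc[1, "pct_primary_only"] == 33.0
    assert (rep["pct_primary_only"] <= rep["pct_k2"]).all()
    assert (rep["pct_k2"] <= rep["pct_k3"]).all()


def test_rank_report_empty_and_single():
    assert len(rank_report([])) == 0
    one = greedy_cover(TOY_SETS, TOY_UNI, k_max=3)
    rep = rank_report([one])
    assert list(rep["rank"]) == [1]
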