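import numpy as np
import pandas as pd
import pytest

from conftest import make_calls
from homeopart.model import BiasCategory as C, EventKind
from homeopart.partitioning import (
    InsufficientDataError,
    count_reciprocal,
    detect_tss,
    events_to_frame,
    score_tss,
    score_development_tss,
    summarize_groups,
)

ALL = ("L1", "R1", "L2", "R2", "F", "S")
CATEGORIES = [c for c in C]


def brute_force_events(categories_by_tissue: dict, members):
    """Independent re-statement of the event definitions.

    ``categories_by_tissue``: {tissue: BiasCategory} for one gene x
    individual. Returns {(homeolog, kind)} plus a reciprocal flag.
    """
    measured = [t for t in members if t in categories_by_tissue]
    found = set()
    if len(measured) < 2:
        return found
    for homeolog in ("N", "9"):
        silenced, expressed = [], []
        for t in measured:
            cat = categories_by_tissue[t]
            if cat is C.NO_EXPRESSION:
                continue  # evidence for neither
            off = C.COMPLETE_9 if homeolog == "N" else C.COMPLETE_N
            if cat is off:
                silenced.append(t)
            else:
                expressed.append(t)
        if silenced and len(silenced) == len(measured):
            found.add((homeolog, "NONFUNCTIONALIZATION"))
        elif silenced and expressed:
            found.add((homeolog, "TSS"))
    if ("N", "TSS") in found and ("9", "TSS") in found:
        found.add((None, "RECIPROCAL_TSS"))
    return found


def events_as_set(events):
    return {(e.homeolog, e.kind.value) for e in events}


class TestDetectTss:
    def test_root_specific_silencing_of_one_homeolog(self):
        # the indica copy off in both root tissues, on in both leaves
        calls = make_calls(
            {
                ("HK05", "MIX_1", "MIX"): {
                    "L1": C.EQUIVALENT, "L2": C.EQUIVALENT,
                    "R1": C.COMPLETE_N, "R2": C.COMPLETE_N,
                }
            }
        )
        events = detect_tss(calls, "all")
        assert events_as_set(events) == {("9", "TSS")}
        (e,) = events
        assert e.silenced_in == ("R1", "R2")
        assert e.expressed_in == ("L1", "L2")

    def test_reciprocal_tss_in_booting_set(self):
        calls = make_calls(
            {
                ("CP02", "NN99_1", "NN99"): {
                    "L2": C.COMPLETE_9,   # N off in leaf
                    "R2": C.COMPLETE_N,   # 9 off in root
                    "F": C.EQUIVALENT,
                    "S": C.EQUIVALENT,
                }
            }
        )
        events = detect_tss(calls, "booting")
        assert events_as_set(events) == {
            ("N", "TSS"), ("9", "TSS"), (None, "RECIPROCAL_TSS"),
        }
        assert count_reciprocal(events) == 1
        assert count_reciprocal(events, ["F1"]) == 0

    def test_nonfunctionalization_not_tss(self):
        calls = make_calls(
            {
                ("CR03", "99NN_1", "99NN"): {t: C.COMPLETE_9 for t in ALL}
            }
        )
        events = detect_tss(calls, "all")
        assert events_as_set(events) == {("N", "NONFUNCTIONALIZATION")}

    def test_no_silencing_no_events(self):
        calls = make_calls(
            {("HK01", "F1_1", "F1"): {t: C.EQUIVALENT for t in ALL}}
        )
        assert detect_tss(calls, "all") == []

    def test_no_expression_is_neutral(self):
        # N silenced in one tissue, everything else dark: no contrast,
        # so neither TSS nor nonfunctionalization
        calls = make_calls(
            {
                ("HK01", "MIX_1", "MIX"): {
                    "L2": C.COMPLETE_9,
                    "R2": C.NO_EXPRESSION,
                    "F": C.NO_EXPRESSION,
                }
            }
        )
        assert detect_tss(calls, "booting") == []

    def test_single_tissue_insufficient(self):
        calls = make_calls({("HK01", "MIX_1", "MIX"): {"L2": C.COMPLETE_9}})
        assert detect_tss(calls, "booting") == []

    def test_brute_force_equivalence_random_draws(self, rng):
        """Detection agrees with an independently coded re-statement."""
        members = ("L2", "R2", "F", "S")
        for _ in range(300):
            assignment = {
                t: CATEGORIES[rng.integers(len(CATEGORIES))] for t in members
            }
            calls = make_calls({("g", "i", "MIX"): assignment})
            got = events_as_set(detect_tss(calls, "booting"))
            want = brute_force_events(assignment, members)
            assert got == want, assignment

    def test_removing_tissue_never_creates_tss(self, rng):
        """Monotone restriction: a TSS event in a subset implies the same
        silenced/expressed contrast already present in the superset."""
        for _ in range(200):
            assignment = {
                t: CATEGORIES[rng.integers(len(CATEGORIES))] for t in ALL
            }
            calls = make_calls({("g", "i", "MIX"): assignment})
            super_events = {
                (e.homeolog, t)
                for e in detect_tss(calls, "all")
                if e.kind is EventKind.TSS
                for t in e.silenced_in
            }
            for subset in (("L1", "R1"), ("L2", "R2", "F", "S"), ("L1", "L2")):
                for e in detect_tss(calls, subset):
                    if e.kind is not EventKind.TSS:
                        continue
                    for t in e.silenced_in:
                        assert (e.homeolog, t) in super_events


class TestScoreTss:
    def test_single_event_arithmetic(self):
        # 30 genes x 2 homeologs x 2 tissues = 120 triples; one homeolog
        # silenced in one tissue -> 1/120
        assignments = {
            (f"g{i:02d}", "MIX_1", "MIX"): {"L1": C.EQUIVALENT, "R1": C.EQUIVALENT}
            for i in range(30)
        }
        assignments[("g00", "MIX_1", "MIX")] = {"L1": C.EQUIVALENT, "R1": C.COMPLETE_N}
        scores = score_tss(make_calls(assignments), "tillering")
        assert scores["numerator"].iloc[0] == 1
        assert scores["denominator"].iloc[0] == 120
        assert scores["percent_tss"].iloc[0] == pytest.approx(100 / 120)

    def test_no_events_scores_zero(self):
        calls = make_calls(
            {("g1", "MIX_1", "MIX"): {"L1": C.EQUIVALENT, "R1": C.BIASED_N}}
        )
        assert score_tss(calls, "tillering")["percent_tss"].iloc[0] == 0.0

    def test_gene_unit_convention_halves_denominator(self):
        calls = make_calls(
            {("g1", "MIX_1", "MIX"): {"L1": C.EQUIVALENT, "R1": C.COMPLETE_N}}
        )
        by_homeolog = score_tss(calls, "tillering", unit="homeolog")
        by_gene = score_tss(calls, "tillering", unit="gene")
        assert by_homeolog["denominator"].iloc[0] == 4
        assert by_gene["denominator"].iloc[0] == 2
        assert by_gene["percent_tss"].iloc[0] == 2 * by_homeolog["percent_tss"].iloc[0]

    def test_insufficient_data_raises(self):
        calls = make_calls({("g1", "MIX_1", "MIX"): {"L1": C.EQUIVALENT}})
        with pytest.raises(InsufficientDataError):
            score_tss(calls, "tillering")

    def test_nonfunctionalization_not_counted_in_numerator(self):
        calls = make_calls(
            {("g1", "MIX_1", "MIX"): {t: C.COMPLETE_9 for t in ALL}}
        )
        scores = score_tss(calls, "all")
        assert scores["numerator"].iloc[0] == 0

    def test_development_tss_contract(self):
        calls = make_calls(
            {
                ("g1", "NN99_1", "NN99"): {
                    "R1": C.COMPLETE_9, "R2": C.EQUIVALENT,  # N off then on
                    "L1": C.EQUIVALENT, "L2": C.EQUIVALENT,
                }
            }
        )
        root = score_development_tss(calls, "root")
        leaf = score_development_tss(calls, "leaf")
        assert root["percent_tss"].iloc[0] == pytest.approx(100 / 4)
        assert leaf["percent_tss"].iloc[0] == 0.0
        with pytest.raises(ValueError):
            score_development_tss(calls, "stem")

    def test_percent_bounds_and_ratio_invariant(self, rng):
        assignments = {}
        for g in range(8):
            for ind, grp in (("MIX_1", "MIX"), ("F1_1", "F1")):
                assignments[(f"g{g}", ind, grp)] = {
                    t: CATEGORIES[rng.integers(len(CATEGORIES))] for t in ALL
                }
        scores = score_tss(make_calls(assignments), "all")
        assert ((scores["percent_tss"] >= 0) & (scores["percent_tss"] <= 100)).all()
        assert (scores["numerator"] <= scores["denominator"]).all()


class TestSummarizeGroups:
    def frame(self, values, group="MIX"):
        return pd.DataFrame(
            {
                "individual_id": [f"{group}_{i}" for i in range(len(values))],
                "group": group,
                "tissue_set": "all",
                "percent_tss": values,
            }
        )

    def test_mean_and_se(self):
        out = summarize_groups(self.frame([10.0, 20.0]))
        assert out["mean_percent_tss"].iloc[0] == pytest.approx(15.0)
        assert out["se"].iloc[0] == pytest.approx(5.0)
        assert out["n"].iloc[0] == 2

    def test_identical_scores_zero_se(self):
        out = summarize_groups(self.frame([7.5, 7.5, 7.5]))
        assert out["se"].iloc[0] == 0.0

    def test_singleton_group_flagged(self):
        out = summarize_groups(self.frame([12.0]))
        assert out["mean_percent_tss"].iloc[0] == 12.0
        assert np.isnan(out["se"].iloc[0])


def test_events_frame_columns():
    calls = make_calls(
        {("g1", "MIX_1", "MIX"): {"L1": C.EQUIVALENT, "R1": C.COMPLETE_N}}
    )
    frame = events_to_frame(detect_tss(calls, "tillering"))
    assert frame.loc[0, "silenced_in"] == "R1"
    assert frame.loc[0, "expressed_in"] == "L1"
    assert frame.loc[0, "kind"] == "TSS"
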