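import math

import pytest
from hypothesis import given, settings, strategies as st

from festkit.calling import (
    ExpansionProfile,
    analyze_batch,
    call_positive,
    condition_profile,
    dmso_detection_floor,
    fold_change,
    productive_frequencies,
)
from festkit.model import AnalysisParams, Condition, DegenerateInputError

from conftest import make_batch_wells, make_well


def profile(freqs, condition=Condition.S2S, params=None):
    params = params or AnalysisParams()
    vectors = [{"K": f} for f in freqs]
    return condition_profile("K", vectors, condition, params)


class TestProductiveFrequencies:
    def test_direct_ratio(self):
        well = make_well({"A" * 10: 50, "C" * 10: 30, "D" * 10: 20})
        fv = productive_frequencies(well)
        assert fv == {"A" * 10: 0.5, "C" * 10: 0.3, "D" * 10: 0.2}

    def test_single_clonotype_normalizes_to_one(self):
        assert productive_frequencies(make_well({"ACDEF": 7})) == {"ACDEF": 1.0}

    def test_nonproductive_excluded_from_numerator_and_denominator(self):
        well = make_well({"AAAAA": 50, "CCCCC": 50}, nonproductive={"CCCCC"})
        assert productive_frequencies(well) == {"AAAAA": 1.0}

    def test_zero_productive_templates_degenerate(self):
        well = make_well({"CCCCC": 10}, nonproductive={"CCCCC"})
        with pytest.raises(DegenerateInputError):
            productive_frequencies(well)

    def test_frequencies_sum_to_one(self, small_study):
        _, wells, _, _ = small_study
        for well in wells[:4]:
            assert abs(sum(productive_frequencies(well).values()) - 1.0) < 1e-9


class TestConditionProfile:
    def test_mean_over_all_replicates_and_count(self, params):
        p = profile((0.002, 0.0015, 0.0005))
        assert p.mean_frequency == pytest.approx(0.004 / 3)
        assert p.n_replicates_above_threshold == 2

    def test_absent_clone_is_all_zero(self, params):
        p = condition_profile("MISSING", [{"X": 1.0}] * 3, Condition.S2S, params)
        assert p.mean_frequency == 0.0
        assert p.n_replicates_above_threshold == 0

    def test_dropout_counts_as_zero_in_mean(self, params):
        p = profile((0.0012, 0.0, 0.0))
        assert p.mean_frequency == pytest.approx(0.0004)
        assert p.n_replicates_above_threshold == 1

    def test_mean_never_exceeds_max_replicate(self, params):
        p = profile((0.003, 0.001, 0.0))
        assert p.mean_frequency <= max(p.replicate_frequencies)


class TestFoldChange:
    def test_direct_division(self, params):
        ag = profile((0.002, 0.0015, 0.0005))
        dm = profile((0.0002, 0.0002, 0.0002), Condition.DMSO)
        assert fold_change(ag, dm, params, 0.0) == pytest.approx(6.6667, rel=1e-3)

    def test_exact_boundary(self, params):
        ag = profile((0.005, 0.005, 0.005))
        dm = profile((0.001, 0.001, 0.001), Condition.DMSO)
        assert fold_change(ag, dm, params, 0.0) == pytest.approx(5.0)

    def test_detection_floor_when_absent_from_dmso(self, params):
        # 100,000 productive DMSO templates over 3 wells -> floor 1e-5
        ag = profile((0.002, 0.002, 0.002))
        dm = profile((0.0, 0.0, 0.0), Condition.DMSO)
        floor = 1.0 / 100_000
        assert fold_change(ag, dm, params, floor) == pytest.approx(200.0)

    def test_policy_none_gives_infinite_fold(self):
        params = AnalysisParams(dmso_floor_policy="none")
        ag = profile((0.002, 0.002, 0.002))
        dm = profile((0.0, 0.0, 0.0), Condition.DMSO)
        assert fold_change(ag, dm, params, 0.0) == math.inf

    def test_floor_value_from_wells(self, params):
        wells = [make_well({"AAAAA": 40_000}, condition=Condition.DMSO, replicate=r)
                 for r in (1, 2, 3)]
        assert dmso_detection_floor(wells, params) == pytest.approx(1 / 120_000)


class TestCallPositive:
    def test_passing_all_three_clauses(self, params):
        ag = profile((0.002, 0.0015, 0.0005))
        dm = profile((0.0002, 0.0002, 0.0002), Condition.DMSO)
        call = call_positive(ag, dm, params, 0.0)
        assert call.is_positive and call.failing_criteria == []

    def test_failing_clauses_enumerated(self, params):
        ag = profile((0.0012, 0.00009, 0.00008))
        dm = profile((0.0, 0.0, 0.0), Condition.DMSO)
        call = call_positive(ag, dm, params, 1e-5)
        assert not call.is_positive
        assert set(call.failing_criteria) == {"replicates", "freq"}

    def test_exactly_five_fold_is_positive(self, params):
        ag = profile((0.005, 0.005, 0.005))
        dm = profile((0.001, 0.001, 0.001), Condition.DMSO)
        assert call_positive(ag, dm, params, 0.0).is_positive

    def test_exactly_threshold_frequency_is_negative(self, params):
        ag = profile((0.001, 0.001, 0.001))
        dm = profile((0.0, 0.0, 0.0), Condition.DMSO)
        call = call_positive(ag, dm, params, 1e-5)
        assert not call.is_positive
        assert "freq" in call.failing_criteria and "replicates" in call.failing_criteria


def brute_force_calls(wells_by_condition, params):
    """Independent re-evaluation of the three positivity clauses directly
    from raw template counts, without any festkit aggregation code."""
    def freqs(well):
        total = sum(r.templates for r in well.records if r.productive)
        return {r.cdr3_aa: r.templates / total for r in well.records if r.productive}

    dmso_wells = wells_by_condition[Condition.DMSO]
    dmso_total = sum(sum(r.templates for r in w.records if r.productive)
                     for w in dmso_wells)
    out = {}
    for cond, wells in wells_by_condition.items():
        if cond is Condition.DMSO:
            continue
        per_rep = [freqs(w) for w in sorted(wells, key=lambda w: w.replicate)]
        keys = set().union(*[set(f) for f in per_rep])
        for key in keys:
            fs = [f.get(key, 0.0) for f in per_rep]
            mean = sum(fs) / len(fs)
            n_above = sum(f > params.min_mean_frequency for f in fs)
            dmso_fs = [freqs(w).get(key, 0.0) for w in dmso_wells]
            dmso_mean = sum(dmso_fs) / len(dmso_fs)
            denom = max(dmso_mean, 1.0 / dmso_total)
            positive = (n_above >= params.min_positive_replicates
                        and mean > params.min_mean_frequency
                        and mean / denom >= params.fold_over_dmso)
            out[(cond, key)] = positive
    return out


class TestOracleEquivalence:
    def test_calls_match_brute_force_on_small_wells(self, params, rng):
        clones = ["".join("ACDEFGHIKL"[i] for i in rng.integers(0, 10, 8))
                  for _ in range(15)]
        wells_by_condition = {}
        wells = []
        for cond in (Condition.DMSO, Condition.S2S, Condition.HKU1):
            ws = []
            for rep in (1, 2, 3):
                counts = {c: int(n) for c, n in
                          zip(clones, rng.integers(0, 40, len(clones))) if n > 0}
                counts[clones[0]] = counts.get(clones[0], 0) + 1  # non-empty well
                ws.append(make_well(counts, condition=cond, replicate=rep))
            wells_by_condition[cond] = ws
            wells.extend(ws)
        expected = brute_force_calls(wells_by_condition, params)
        batch = analyze_batch(wells, params)
        for (cond, key), want in expected.items():
            got = batch.calls[cond][key].is_positive
            assert got == want, (cond, key)


class TestInvariantProperties:
    base_design = {
        Condition.DMSO: [{"CASSAAAAAF": 0.0004, "CASSCCCCCF": 0.002}] * 3,
        Condition.S2S: [
            {"CASSAAAAAF": 0.003, "CASSCCCCCF": 0.002},
            {"CASSAAAAAF": 0.0025, "CASSCCCCCF": 0.0021},
            {"CASSAAAAAF": 0.0015, "CASSCCCCCF": 0.0019},
        ],
    }

    @given(
        freq_thresh=st.floats(0.0005, 0.01),
        fold_thresh=st.floats(1.0, 50.0),
        min_reps=st.integers(1, 3),
    )
    @settings(deadline=None, max_examples=60)
    def test_raising_thresholds_never_adds_positives(
        self, freq_thresh, fold_thresh, min_reps
    ):
        wells = make_batch_wells(self.base_design)
        loose = AnalysisParams()
        strict = AnalysisParams(
            min_mean_frequency=max(freq_thresh, loose.min_mean_frequency),
            fold_over_dmso=max(fold_thresh, loose.fold_over_dmso),
            min_positive_replicates=max(min_reps, loose.min_positive_replicates),
        )
        pos_loose = analyze_batch(wells, loose).positive_set(Condition.S2S)
        pos_strict = analyze_batch(wells, strict).positive_set(Condition.S2S)
        assert pos_strict <= pos_loose

    @pytest.mark.parametrize("scale", [2, 7, 100])
    def test_scaling_all_template_counts_changes_nothing(self, params, scale):
        wells = make_batch_wells(self.base_design, depth=10_000)
        scaled = []
        for w in wells:
            counts = {r.cdr3_aa: r.templates * scale for r in w.records}
            scaled.append(make_well(counts, condition=w.condition,
                                    replicate=w.replicate))
        a = analyze_batch(wells, params)
        b = analyze_batch(scaled, params)
        assert a.positive_sets == b.positive_sets
        for cond in a.profiles:
            for key, prof in a.profiles[cond].items():
                assert prof.mean_frequency == pytest.approx(
                    b.profiles[cond][key].mean_frequency)

    def test_identical_antigen_and_dmso_wells_give_empty_sets(self, params):
        same = [{"CASSAAAAAF": 0.004, "CASSCCCCCF": 0.01}] * 3
        wells = make_batch_wells({Condition.DMSO: same, Condition.S2S: same,
                                  Condition.HKU1: same})
        batch = analyze_batch(wells, params)
        assert all(not s for s in batch.positive_sets.values())

    def test_clone_positive_in_two_conditions_appears_in_both_sets(self, params):
        hot = [{"CASSAAAAAF": 0.01}] * 3
        cold = [{"CASSAAAAAF": 0.0001}] * 3
        wells = make_batch_wells({Condition.DMSO: cold, Condition.S2S: hot,
                                  Condition.HKU1: hot})
        batch = analyze_batch(wells, params)
        assert "CASSAAAAAF" in batch.positive_set(Condition.S2S)
        assert "CASSAAAAAF" in batch.positive_set(Condition.HKU1)
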