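"""Antigen-specific expansion calling against DMSO controls.

A clonotype is called *positive* in an antigen condition when three
conjunctive clauses hold:

1. its frequency exceeds ``min_mean_frequency`` (default 0.1% of productive
   templates) in at least ``min_positive_replicates`` individual replicates,
2. its mean frequency over all replicates of the condition (absences count
   as zero) exceeds ``min_mean_frequency``, and
3. that mean is at least ``fold_over_dmso`` (default 5) times the clone's
   mean frequency in the DMSO control wells of the same assay batch.

The frequency threshold is strict (">"), the fold threshold inclusive
(">=").  A clone unobserved in DMSO would give an infinite fold; by default
the DMSO mean is floored at the batch's detection limit,
1 / (summed productive templates across the DMSO replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import (
    AnalysisParams,
    Condition,
    ANTIGEN_CONDITIONS,
    CONDITION_ORDER,
    DegenerateInputError,
    ValidationError,
    WellSample,
    clonotype_key,
)

#: Frequencies of all productive clonotypes in one well, as fractions of the
#: well's productive templates (they sum to 1).
FrequencyVector = dict


def productive_frequencies(well: WellSample) -> FrequencyVector:
    """Map each productive clonotype to templates / total productive templates.

    Non-productive clonotypes are excluded from both the numerator set and
    the denominator.
    """
    total = well.total_productive_templates
    if total < 1:
        raise DegenerateInputError(
            f"well {well.participant}/{well.condition}/{well.replicate} "
            "has zero productive templates"
        )
    return {
        clonotype_key(r, well.key_mode): r.templates / total
        for r in well.productive_records()
    }


@dataclass
class ExpansionProfile:
    """Replicate-level expansion of one clonotype in one condition."""

    key: object
    condition: Condition
    replicate_frequencies: tuple
    mean_frequency: float
    n_replicates_above_threshold: int
    fold_vs_dmso: float | None = None  # None until fold_change is applied

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_frequencies)


@dataclass
class PositiveCall:
    key: object
    condition: Condition
    is_positive: bool
    failing_criteria: list = field(default_factory=list)


def condition_profile(
    key,
    replicate_freqs: list[FrequencyVector],
    condition: Condition,
    params: AnalysisParams,
) -> ExpansionProfile:
    """Aggregate one clonotype's frequencies over the replicate wells of one
    condition.  Wells lacking the clonotype contribute frequency zero; the
    mean is taken over *all* replicates."""
    if not replicate_freqs:
        raise ValidationError("condition_profile requires at least one replicate")
    freqs = tuple(fv.get(key, 0.0) for fv in replicate_freqs)
    return ExpansionProfile(
        key=key,
        condition=condition,
        replicate_frequencies=freqs,
        mean_frequency=sum(freqs) / len(freqs),
        n_replicates_above_threshold=sum(
            1 for f in freqs if f > params.min_mean_frequency
        ),
    )


def dmso_detection_floor(dmso_wells: list[WellSample], params: AnalysisParams) -> float:
    """The smallest distinguishable DMSO mean under the configured floor
    policy (0.0 under policy ``none``)."""
    if params.dmso_floor_policy == "none":
        return 0.0
    if params.dmso_floor_policy == "fixed":
        return params.fixed_pseudo_frequency
    total = sum(w.total_productive_templates for w in dmso_wells)
    if total < 1:
        raise DegenerateInputError("DMSO wells contain no productive templates")
    return 1.0 / total


def fold_change(
    antigen_profile: ExpansionProfile,
    dmso_profile: ExpansionProfile,
    params: AnalysisParams,
    dmso_floor: float,
) -> float:
    """Antigen mean frequency over the (floored) DMSO mean frequency.

    Under floor policy ``none`` a zero DMSO mean yields ``math.inf``.
    """
    denom = max(dmso_profile.mean_frequency, dmso_floor)
    if denom == 0.0:
        return math.inf
    return antigen_profile.mean_frequency / denom


def call_positive(
    antigen_profile: ExpansionProfile,
    dmso_profile: ExpansionProfile,
    params: AnalysisParams,
    dmso_floor: float,
) -> PositiveCall:
    """Apply the three positivity clauses; ``failing_criteria`` lists every
    clause that failed ("replicates", "freq", "fold")."""
    fold = fold_change(antigen_profile, dmso_profile, params, dmso_floor)
    antigen_profile.fold_vs_dmso = fold
    failing = []
    if antigen_profile.n_replicates_above_threshold < params.min_positive_replicates:
        failing.append("replicates")
    if not antigen_profile.mean_frequency > params.min_mean_frequency:
        failing.append("freq")
    if not fold >= params.fold_over_dmso:
        failing.append("fold")
    return PositiveCall(
        key=antigen_profile.key,
        condition=antigen_profile.condition,
        is_positive=not failing,
        failing_criteria=failing,
    )


@dataclass
class BatchResult:
    """All expansion calls for one participant x assay-batch group."""

    participant: str
    assay_batch: str
    conditions: list[Condition]
    n_replicates: dict
    #: condition -> replicate-ordered frequency vectors
    frequencies: dict
    #: condition -> {key -> ExpansionProfile}; includes Condition.DMSO
    profiles: dict
    #: antigen condition -> {key -> PositiveCall}
    calls: dict
    #: antigen condition -> sorted list of positive keys
    positive_sets: dict
    #: antigen condition -> per-replicate count of positive keys detected
    replicate_detected_counts: dict
    dmso_floor: float
    #: records parsed / merged per well, for stage accounting
    stage_counts: dict

    def positive_set(self, condition: Condition) -> set:
        return set(self.positive_sets.get(condition, ()))

    def dmso_mean(self, key) -> float:
        prof = self.profiles[Condition.DMSO].get(key)
        return prof.mean_frequency if prof is not None else 0.0

    def condition_mean(self, key, condition: Condition) -> float:
        prof = self.profiles.get(condition, {}).get(key)
        return prof.mean_frequency if prof is not None else 0.0


def analyze_batch(
    wells: list[WellSample],
    params: AnalysisParams,
    min_replicates_to_test: int | None = None,
) -> BatchResult:
    """Run expansion calling for every clonotype observed in any antigen well
    of one participant/batch group.

    Clonotypes observed only in DMSO are never tested.  An antigen condition
    with fewer replicates than ``min_positive_replicates`` is skipped (the
    caller is expected to warn).
    """
    if not wells:
        raise ValidationError("analyze_batch requires at least one well")
    participants = {w.participant for w in wells}
    batches = {w.assay_batch for w in wells}
    if len(participants) > 1 or len(batches) > 1:
        raise ValidationError(
            f"analyze_batch expects one participant/batch group, got "
            f"participants={sorted(participants)} batches={sorted(batches)}"
        )
    by_condition: dict[Condition, list[WellSample]] = {}
    for w in wells:
        by_condition.setdefault(w.condition, []).append(w)
    for cond in by_condition:
        by_condition[cond].sort(key=lambda w: w.replicate)
    if Condition.DMSO not in by_condition:
        raise ValidationError("no control wells: batch lacks a DMSO condition")

    if min_replicates_to_test is None:
        min_replicates_to_test = params.min_positive_replicates

    frequencies = {
        cond: [productive_frequencies(w) for w in ws]
        for cond, ws in by_condition.items()
    }
    dmso_freqs = frequencies[Condition.DMSO]
    floor = dmso_detection_floor(by_condition[Condition.DMSO], params)

    conditions = [c for c in CONDITION_ORDER if c in by_condition]
    antigen_conditions = [
        c for c in conditions
        if c in ANTIGEN_CONDITIONS and len(by_condition[c]) >= min_replicates_to_test
    ]

    profiles: dict = {Condition.DMSO: {}}
    calls: dict = {}
    positive_sets: dict = {}
    replicate_detected_counts: dict = {}

    for cond in antigen_conditions:
        cond_freqs = frequencies[cond]
        universe = sorted(set().union(*[fv.keys() for fv in cond_freqs]))
        cond_profiles: dict = {}
        cond_calls: dict = {}
        positives = []
        for key in universe:
            prof = condition_profile(key, cond_freqs, cond, params)
            if key not in profiles[Condition.DMSO]:
                profiles[Condition.DMSO][key] = condition_profile(
                    key, dmso_freqs, Condition.DMSO, params
                )
            call = call_positive(prof, profiles[Condition.DMSO][key], params, floor)
            cond_profiles[key] = prof
            cond_calls[key] = call
            if call.is_positive:
                positives.append(key)
        profiles[cond] = cond_profiles
        calls[cond] = cond_calls
        positive_sets[cond] = positives
        replicate_detected_counts[cond] = [
            sum(1 for key in positives if fv.get(key, 0.0) > 0.0)
            for fv in cond_freqs
        ]

    stage_counts = {
        "wells": len(wells),
        "records_after_merge": sum(len(w.records) for w in wells),
        "productive_records": sum(len(w.productive_records()) for w in wells),
        "clonotypes_tested": sum(len(p) for c, p in profiles.items()
                                 if c is not Condition.DMSO),
        "positive_calls": sum(len(s) for s in positive_sets.values()),
    }

    return BatchResult(
        participant=wells[0].participant,
        assay_batch=wells[0].assay_batch,
        conditions=conditions,
        n_replicates={c: len(by_condition[c]) for c in conditions},
        frequencies=frequencies,
        profiles=profiles,
        calls=calls,
        positive_sets=positive_sets,
        replicate_detected_counts=replicate_detected_counts,
        dmso_floor=floor,
        stage_counts=stage_counts,
    )


def antigen_specific_sets(
    wells: list[WellSample], params: AnalysisParams
) -> tuple[dict, dict]:
    """Per antigen condition: the set of positive clonotype keys, plus the
    per-replicate counts of positive keys detected (nonzero frequency) in
    each replicate well — the quantity behind per-condition breadth bars
    with an SD-across-replicates error bar."""
    result = analyze_batch(wells, params)
    return (
        {c: set(keys) for c, keys in result.positive_sets.items()},
        dict(result.replicate_detected_counts),
    )
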