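"""Mono- vs cross-reactivity classification of S2S-positive clonotypes.

Labels partition the SARS-CoV-2 spike (S2S) positive set:

* ``cross_reactive``  -- positive in S2S and in at least one common-cold
  coronavirus condition of the same assay batch.
* ``mono_reactive``   -- positive only in S2S, with the S2S mean frequency at
  least ``mono_dominance_fold`` (default 5) times the clone's mean in every
  other antigen condition (a zero mean enters the ratio at the DMSO
  detection floor).
* ``unclassified``    -- positive only in S2S but lacking the dominance
  margin over some sub-threshold common-cold signal.  Neither published
  definition covers this case, so it is reported as its own bucket rather
  than forced into the dichotomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .calling import BatchResult
from .model import (
    AnalysisParams,
    COMMON_COLD_CONDITIONS,
    Condition,
    ValidationError,
)

MONO = "mono_reactive"
CROSS = "cross_reactive"
UNCLASSIFIED = "unclassified"


@dataclass
class ReactivityCall:
    key: object
    label: str
    positive_conditions: set
    #: condition -> S2S mean frequency / that condition's (floored) mean
    dominance_folds: dict = field(default_factory=dict)


@dataclass
class ReactivitySummary:
    participant: str
    assay_batch: str
    n_mono: int
    n_cross: int
    n_unclassified: int
    #: percentages over all S2S-positive clonotypes (mono+cross+unclassified)
    pct_mono: float | None
    pct_cross: float | None
    pct_unclassified: float | None
    #: secondary percentages over the mono/cross dichotomy only
    pct_mono_of_dichotomy: float | None
    pct_cross_of_dichotomy: float | None

    @property
    def n_total(self) -> int:
        return self.n_mono + self.n_cross + self.n_unclassified


def classify_reactivity(
    batch: BatchResult, key, params: AnalysisParams
) -> ReactivityCall:
    """Classify one S2S-positive clonotype across the antigen conditions of
    its assay batch."""
    if key not in batch.positive_set(Condition.S2S):
        raise ValidationError(
            f"clonotype {key!r} is not S2S-positive; reactivity is only "
            "defined for the S2S-positive set"
        )
    antigen_conditions = [c for c in batch.conditions if c is not Condition.DMSO]
    positive_conditions = {
        c for c in antigen_conditions if key in batch.positive_set(c)
    }
    s2s_mean = batch.condition_mean(key, Condition.S2S)
    dominance = {}
    for cond in antigen_conditions:
        if cond is Condition.S2S:
            continue
        denom = max(batch.condition_mean(key, cond), batch.dmso_floor)
        dominance[cond] = s2s_mean / denom if denom > 0 else math.inf

    if positive_conditions & COMMON_COLD_CONDITIONS:
        label = CROSS
    elif positive_conditions == {Condition.S2S} and all(
        f >= params.mono_dominance_fold for f in dominance.values()
    ):
        label = MONO
    else:
        label = UNCLASSIFIED
    return ReactivityCall(
        key=key,
        label=label,
        positive_conditions=positive_conditions,
        dominance_folds=dominance,
    )


def classify_batch(batch: BatchResult, params: AnalysisParams) -> list[ReactivityCall]:
    """Reactivity calls for every S2S-positive clonotype of the batch, in
    deterministic key order.  Empty when the batch has no S2S condition."""
    if Condition.S2S not in batch.positive_sets:
        return []
    return [
        classify_reactivity(batch, key, params)
        for key in sorted(batch.positive_sets[Condition.S2S])
    ]


def reactivity_summary(
    calls: list[ReactivityCall], participant: str, assay_batch: str = "batch1"
) -> ReactivitySummary:
    """Counts and percentages of the three labels for one participant/batch.

    Percentages are reported both over all S2S-positive clonotypes and over
    the mono/cross dichotomy alone; with no calls they are undefined (None).
    """
    n_mono = sum(1 for c in calls if c.label == MONO)
    n_cross = sum(1 for c in calls if c.label == CROSS)
    n_uncl = sum(1 for c in calls if c.label == UNCLASSIFIED)
    total = n_mono + n_cross + n_uncl
    dichotomy = n_mono + n_cross
    return ReactivitySummary(
        participant=participant,
        assay_batch=assay_batch,
        n_mono=n_mono,
        n_cross=n_cross,
        n_unclassified=n_uncl,
        pct_mono=100.0 * n_mono / total if total else None,
        pct_cross=100.0 * n_cross / total if total else None,
        pct_unclassified=100.0 * n_uncl / total if total else None,
        pct_mono_of_dichotomy=100.0 * n_mono / dichotomy if dichotomy else None,
        pct_cross_of_dichotomy=100.0 * n_cross / dichotomy if dichotomy else None,
    )


def cross_reactivity_breakdown(calls: list[ReactivityCall]) -> dict:
    """Per common-cold condition, the number of cross-reactive clonotypes
    whose positive set involves it, plus the count involving two or more
    common-cold conditions.  A clonotype positive for several pools counts
    toward each."""
    counts = {cond: 0 for cond in sorted(COMMON_COLD_CONDITIONS, key=lambda c: c.value)}
    multi = 0
    for call in calls:
        if call.label != CROSS:
            continue
        ccc = call.positive_conditions & COMMON_COLD_CONDITIONS
        for cond in ccc:
            counts[cond] += 1
        if len(ccc) >= 2:
            multi += 1
    counts["multi"] = multi
    return counts
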