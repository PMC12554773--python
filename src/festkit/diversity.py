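"""Subset-normalized Shannon diversity and group comparison.

The spike-specific diversity of a participant is computed per replicate:
the frequencies of the participant's S2S-positive clonotypes detected in
that replicate are renormalized to sum to one, and the Shannon index
H = -sum(p * log2 p) is taken over the renormalized vector.  Replicate
indices are then averaged per participant.  Replicates in which no subset
clone was detected contribute no index — an undefined distribution has no
entropy, and assigning 0 would conflate sampling dropout with
monoclonality.

Groups of participant means are compared with a two-sided Mann-Whitney U
test, exact when the pooled sample is small and tie-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import AnalysisParams, ValidationError

logger = logging.getLogger(__name__)

#: Largest pooled sample size for which the exact (enumeration) null
#: distribution of U is used; study-scale groups (4-10 per arm) fall well
#: inside enumeration range and printed small-n p-values depend on it.
EXACT_MW_MAX_N = 12


def normalize_to_subset(freqs: dict, subset: set) -> dict:
    """Renormalize a well's frequencies over the subset members detected in
    it, so they form a probability vector.

    Raises :class:`ValidationError` when no subset member is detected; the
    caller decides whether that is fatal or skips the replicate.
    """
    sub = {k: f for k, f in freqs.items() if k in subset and f > 0}
    if not sub:
        raise ValidationError("no subset clonotype detected in this replicate")
    total = sum(sub.values())
    return {k: f / total for k, f in sub.items()}


def shannon_index(p, log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum(p_i * log_base(p_i)), with 0*log(0) = 0.

    ``p`` may be a mapping or a sequence of probabilities; it must be
    non-negative and sum to 1 within 1e-9.
    """
    values = np.asarray(list(p.values()) if isinstance(p, dict) else p, dtype=float)
    if values.size == 0:
        raise ValidationError("empty probability vector")
    if (values < 0).any():
        raise ValidationError("probabilities must be non-negative")
    if abs(values.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"probabilities sum to {values.sum():.12g}, not 1"
        )
    # scipy normalizes internally; the sum check above keeps the contract strict
    return float(stats.entropy(values, base=log_base))


@dataclass
class DiversitySummary:
    participant: str
    group: str
    replicate_indices: list
    mean_index: float
    n_replicates_skipped: int = 0


def patient_diversity(
    replicate_freqs: list[dict],
    subset: set,
    participant: str,
    group: str = "",
    params: AnalysisParams | None = None,
) -> DiversitySummary:
    """Per-replicate Shannon indices of the subset-normalized vectors and
    their mean for one participant.

    ``replicate_freqs`` are the per-replicate frequency vectors of the wells
    supplying the subset (normally the S2S wells).  Replicates lacking every
    subset clone are skipped with a log entry; if none contributes, a
    :class:`ValidationError` is raised.
    """
    params = params or AnalysisParams()
    indices = []
    skipped = 0
    for i, freqs in enumerate(replicate_freqs, start=1):
        try:
            p = normalize_to_subset(freqs, subset)
        except ValidationError:
            logger.warning(
                "participant %s replicate %d: no subset clonotype detected; "
                "replicate contributes no diversity index", participant, i
            )
            skipped += 1
            continue
        indices.append(shannon_index(p, params.log_base))
    if not indices:
        raise ValidationError(
            f"participant {participant}: no replicate contains any subset clonotype"
        )
    return DiversitySummary(
        participant=participant,
        group=group,
        replicate_indices=indices,
        mean_index=float(np.mean(indices)),
        n_replicates_skipped=skipped,
    )


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n_a: int
    n_b: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def mann_whitney_u(group_a, group_b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups of diversity means.

    The exact null distribution (full enumeration of rank assignments) is
    used when the pooled sample size is at most ``EXACT_MW_MAX_N`` and there
    are no ties; otherwise midranks with the tie-corrected normal
    approximation.  The reported U is the statistic of ``group_a``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal_approximation"
        if np.all(pooled == pooled[0]):
            # complete tie: no separation is possible, U sits at its null mean
            return GroupComparison(
                u_statistic=a.size * b.size / 2.0,
                p_value=1.0,
                method=method,
                n_a=int(a.size),
                n_b=int(b.size),
            )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def whole_repertoire_diversity(
    replicate_freqs: list[dict], participant: str, group: str = "",
    params: AnalysisParams | None = None,
) -> DiversitySummary:
    """Shannon diversity of the full (un-subset) frequency vectors, averaged
    over replicates — the conventional whole-repertoire usage of the index."""
    params = params or AnalysisParams()
    indices = [shannon_index(list(fv.values()), params.log_base) for fv in replicate_freqs]
    if not indices:
        raise ValidationError(f"participant {participant}: no replicate wells supplied")
    return DiversitySummary(
        participant=participant,
        group=group,
        replicate_indices=indices,
        mean_index=float(np.mean(indices)),
    )
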