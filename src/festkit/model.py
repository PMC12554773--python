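"""Shared data model for FEST-style TCR repertoire analysis.

The unit of analysis is the TCR-beta clonotype, identified by its CDR3
amino-acid sequence.  A *well* is one cultured replicate of one peptide
condition; the DMSO (vehicle-only) wells of the same assay batch are the
control against which antigen-driven expansion is measured.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: '*' marks a stop codon in the translated junction of a non-productive
#: rearrangement; any record containing it must carry productive=False.
AA_ALPHABET_EXTENDED = AA_ALPHABET | {"*"}


class FestError(Exception):
    """Base class for all festkit errors."""


class FormatError(FestError):
    """An input file does not follow the expected column schema."""


class ValidationError(FestError):
    """Parsed data violates a model invariant."""


class EmptyInputError(FestError):
    """An input table contains no data rows."""


class DegenerateInputError(FestError):
    """An input is structurally valid but analytically degenerate
    (e.g. a well with zero productive templates)."""


class Condition(enum.Enum):
    """Culture conditions: vehicle control, SARS-CoV-2 spike, and the four
    common-cold coronavirus spike peptide pools."""

    DMSO = "DMSO"
    S2S = "S2S"
    NL63 = "NL63"
    E229 = "229E"
    OC43 = "OC43"
    HKU1 = "HKU1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The common-cold coronavirus (CCC) spike conditions.
COMMON_COLD_CONDITIONS = frozenset(
    {Condition.NL63, Condition.E229, Condition.OC43, Condition.HKU1}
)

#: All antigen (non-control) conditions.
ANTIGEN_CONDITIONS = frozenset({Condition.S2S}) | COMMON_COLD_CONDITIONS

#: Canonical ordering used for deterministic output.
CONDITION_ORDER = [
    Condition.DMSO,
    Condition.S2S,
    Condition.NL63,
    Condition.E229,
    Condition.OC43,
    Condition.HKU1,
]

_CONDITION_ALIASES = {
    "DMSO": Condition.DMSO,
    "S2S": Condition.S2S,
    "SARS-COV-2": Condition.S2S,
    "SARS-COV2": Condition.S2S,
    "NL63": Condition.NL63,
    "HCOV-NL63": Condition.NL63,
    "229E": Condition.E229,
    "E229": Condition.E229,
    "HCOV-229E": Condition.E229,
    "OC43": Condition.OC43,
    "HCOV-OC43": Condition.OC43,
    "HKU1": Condition.HKU1,
    "HCOV-HKU1": Condition.HKU1,
}


def parse_condition(label: str) -> Condition:
    """Normalize a condition label case-insensitively to the enum.

    Accepts the short pool names (``S2S``, ``NL63`` ...) and the
    ``HCoV-`` prefixed virus names.
    """
    key = str(label).strip().upper()
    try:
        return _CONDITION_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of "
            f"{sorted(set(a for a in _CONDITION_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class ClonotypeRecord:
    """One TCR-beta rearrangement observed in one well."""

    cdr3_aa: str
    templates: int
    productive: bool = True
    v_gene: str = ""
    j_gene: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValidationError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET_EXTENDED
        if bad:
            raise ValidationError(
                f"cdr3_aa {self.cdr3_aa!r} contains non-amino-acid characters {sorted(bad)}"
            )
        if "*" in self.cdr3_aa and self.productive:
            raise ValidationError(
                f"cdr3_aa {self.cdr3_aa!r} contains a stop codon but is flagged productive"
            )
        if not isinstance(self.templates, int) or isinstance(self.templates, bool):
            raise ValidationError(f"templates must be an integer, got {self.templates!r}")
        if self.templates < 1:
            raise ValidationError(f"templates must be >= 1, got {self.templates}")


def clonotype_key(record: ClonotypeRecord, mode: str = "cdr3") -> str | tuple[str, str]:
    """Identity key of a clonotype.

    ``cdr3``     -- the CDR3 amino-acid sequence alone (default reporting unit).
    ``cdr3_v``   -- (cdr3_aa, v_gene), for analyses that must keep convergent
                    rearrangements with different V genes apart.
    """
    if mode == "cdr3":
        return record.cdr3_aa
    if mode == "cdr3_v":
        return (record.cdr3_aa, record.v_gene)
    raise ValueError(f"unknown identity-key mode {mode!r}")


def merge_records(
    records: Iterable[ClonotypeRecord], key_mode: str = "cdr3"
) -> list[ClonotypeRecord]:
    """Collapse duplicate identity keys by summing template counts.

    Productive and non-productive records never merge with each other even
    under the same key.
    """
    merged: dict[tuple, ClonotypeRecord] = {}
    for rec in records:
        k = (clonotype_key(rec, key_mode), rec.productive)
        if k in merged:
            prev = merged[k]
            merged[k] = dataclasses.replace(prev, templates=prev.templates + rec.templates)
        else:
            merged[k] = rec
    return list(merged.values())


@dataclass
class WellSample:
    """All clonotypes sequenced from one culture well (one replicate of one
    condition).  Records are duplicate-merged at construction."""

    participant: str
    condition: Condition
    replicate: int
    records: list[ClonotypeRecord]
    assay_batch: str = "batch1"
    key_mode: str = "cdr3"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")
        self.records = merge_records(self.records, self.key_mode)

    @property
    def total_productive_templates(self) -> int:
        return sum(r.templates for r in self.records if r.productive)

    def productive_records(self) -> list[ClonotypeRecord]:
        return [r for r in self.records if r.productive]


@dataclass(frozen=True)
class ManifestEntry:
    file: str
    participant: str
    condition: Condition
    replicate: int
    assay_batch: str = "batch1"
    group: str = ""


@dataclass
class StudyManifest:
    """Maps clonotype-table files to (participant, condition, replicate,
    assay batch).  Every participant/batch group must include DMSO control
    wells."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            t = (e.participant, e.condition, e.replicate, e.assay_batch)
            if t in seen:
                raise ValidationError(f"duplicate manifest entry {t}")
            seen.add(t)
        for (participant, batch), entries in self.by_batch().items():
            if not any(e.condition is Condition.DMSO for e in entries):
                raise ValidationError(
                    f"no control wells: participant {participant!r} batch {batch!r} "
                    "has no DMSO condition"
                )

    def by_batch(self) -> dict[tuple[str, str], list[ManifestEntry]]:
        groups: dict[tuple[str, str], list[ManifestEntry]] = {}
        for e in self.entries:
            groups.setdefault((e.participant, e.assay_batch), []).append(e)
        return groups

    @property
    def participants(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.participant not in out:
                out.append(e.participant)
        return out


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds of the positivity and reactivity rules.

    min_mean_frequency : fraction
        Frequency threshold (default 0.001, i.e. 0.1% of productive
        templates).  Applied strictly (">") both per replicate and to the
        condition mean.
    min_positive_replicates : int
        Number of replicates that must individually exceed
        ``min_mean_frequency`` (default 2 of 3).
    fold_over_dmso : float
        Required ratio of the condition mean to the DMSO mean
        (default 5; inclusive, ">=").
    mono_dominance_fold : float
        A clone positive only for S2S is called mono-reactive when its S2S
        mean is at least this many fold above its mean in every other
        antigen condition (default 5; inclusive).
    dmso_floor_policy : str
        How a DMSO mean of zero enters a denominator:
        ``detection-floor`` (default) floors the DMSO mean at
        1 / (summed productive templates over the DMSO replicates);
        ``none`` returns an infinite fold; ``fixed`` floors at
        ``fixed_pseudo_frequency``.
    log_base : float
        Base of the Shannon diversity logarithm (default 2, bits).
    trim_left, trim_right : int
        Residues removed from either end of the CDR3 before Levenshtein
        comparison (default 3 and 3).
    identity_key : str
        Clonotype identity: ``cdr3`` (default) or ``cdr3_v``.
    """

    min_mean_frequency: float = 0.001
    min_positive_replicates: int = 2
    fold_over_dmso: float = 5.0
    mono_dominance_fold: float = 5.0
    dmso_floor_policy: str = "detection-floor"
    fixed_pseudo_frequency: float = 1e-6
    log_base: float = 2.0
    trim_left: int = 3
    trim_right: int = 3
    identity_key: str = "cdr3"

    def __post_init__(self) -> None:
        for name in ("min_mean_frequency", "fold_over_dmso", "mono_dominance_fold",
                     "fixed_pseudo_frequency", "log_base"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.min_positive_replicates < 1:
            raise ValidationError("min_positive_replicates must be >= 1")
        if self.dmso_floor_policy not in {"detection-floor", "none", "fixed"}:
            raise ValidationError(
                f"unknown dmso_floor_policy {self.dmso_floor_policy!r}"
            )
        if self.trim_left < 0 or self.trim_right < 0:
            raise ValidationError("trim lengths must be non-negative")
        if self.identity_key not in {"cdr3", "cdr3_v"}:
            raise ValidationError(f"unknown identity_key {self.identity_key!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
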