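"""Synthetic FEST studies with known ground truth.

A study is simulated as a fixed repertoire of clone probabilities shared by
all wells of a participant/batch: a heavy-tailed baseline (lognormal by
default) over background clones plus designed antigen-reactive clones.  In
a well of condition ``c``, every clone reactive to ``c`` has its baseline
probability multiplied by ``expansion_fold`` before renormalization;
template counts are then drawn multinomially at the configured depth.
DMSO wells sample the unmodified baseline, so they carry no antigen-driven
expansion, only the finite-depth sampling noise that the positivity rule
must see through.

The default design mirrors the scale of a vaccinated-participant spike
study: ~100 SARS-CoV-2 spike-specific clones of which a few percent are
cross-reactive (mostly with HKU1), 8-16 clones specific to each common-cold
pool, three technical replicates, and 1e5 templates per well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import BatchResult
from .model import (
    Condition,
    CONDITION_ORDER,
    ClonotypeRecord,
    ManifestEntry,
    StudyManifest,
    ValidationError,
    WellSample,
    parse_condition,
)
from .reactivity import CROSS, MONO, ReactivityCall

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Default cross-reactive designs: most involve HKU1, one spans two pools.
DEFAULT_CROSS_SETS = (("HKU1",), ("HKU1",), ("HKU1",), ("HKU1", "NL63"))

#: Default per-pool mono-reactive common-cold clone counts.
DEFAULT_MONO_CCC = {"NL63": 13, "229E": 8, "OC43": 11, "HKU1": 16}


@dataclass
class SimulationConfig:
    """Design of one simulated participant/batch study.

    expansion_fold multiplies a reactive clone's baseline probability in its
    reactive conditions; depth is the number of templates drawn per well.
    ``designed_baseline_min`` floors the baseline frequency of designed
    clones so that the default design is detectable at the default depth.
    ``overdispersion`` (a Dirichlet concentration scale) optionally adds
    culture-to-culture noise beyond multinomial resampling.
    """

    seed: int = 0
    n_background_clones: int = 2000
    baseline_distribution: str = "lognormal"  # or "zipf"
    lognormal_sigma: float = 2.0
    zipf_exponent: float = 1.5
    n_mono_s2s: int = 96
    cross_condition_sets: tuple = DEFAULT_CROSS_SETS
    n_mono_ccc: dict = field(default_factory=lambda: dict(DEFAULT_MONO_CCC))
    expansion_fold: float = 50.0
    designed_baseline_min: float = 5e-4
    depth: int = 100_000
    n_replicates: int = 3
    conditions: tuple = tuple(c.value for c in CONDITION_ORDER)
    participant: str = "SIM01"
    assay_batch: str = "batch1"
    overdispersion: float | None = None

    def __post_init__(self) -> None:
        if self.n_background_clones < 0 or self.n_mono_s2s < 0:
            raise ValidationError("clone counts must be non-negative")
        if any(n < 0 for n in self.n_mono_ccc.values()):
            raise ValidationError("clone counts must be non-negative")
        if self.expansion_fold < 1:
            raise ValidationError("expansion_fold must be >= 1")
        if self.depth < 1 or self.n_replicates < 1:
            raise ValidationError("depth and n_replicates must be >= 1")
        if self.baseline_distribution not in {"lognormal", "zipf"}:
            raise ValidationError(
                f"unknown baseline_distribution {self.baseline_distribution!r}"
            )
        if "DMSO" not in {str(c).upper() for c in self.conditions}:
            raise ValidationError("conditions must include a DMSO control")
        for cset in self.cross_condition_sets:
            conds = {parse_condition(c) for c in cset}
            if Condition.DMSO in conds or Condition.S2S in conds:
                raise ValidationError(
                    "cross_condition_sets list the common-cold pools only; "
                    "S2S membership is implicit"
                )

    @property
    def n_cross(self) -> int:
        return len(self.cross_condition_sets)

    @property
    def n_designed(self) -> int:
        return self.n_mono_s2s + self.n_cross + sum(self.n_mono_ccc.values())

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cross_condition_sets"] = [list(s) for s in self.cross_condition_sets]
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cross_condition_sets" in d:
            d["cross_condition_sets"] = tuple(tuple(s) for s in d["cross_condition_sets"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


def _random_cdr3(rng: np.random.Generator, used: set) -> str:
    """A plausible CDR3: conserved C...F flanks around a variable core,
    12-18 residues, unique within the study."""
    while True:
        core_len = int(rng.integers(5, 12))
        core = "".join(AA20[i] for i in rng.integers(0, 20, core_len))
        seq = "CASS" + core + "QYF"
        if seq not in used:
            used.add(seq)
            return seq


@dataclass
class TruthTable:
    """Ground-truth design of every simulated clone."""

    table: pd.DataFrame  # clone_id, cdr3, role, reactive_conditions, expansion_fold, baseline_prob

    def designed(self) -> pd.DataFrame:
        return self.table[self.table.role != "background"]

    def reactive_keys(self, condition: Condition) -> set:
        name = condition.value
        mask = self.table.reactive_conditions.fillna("").str.split(";").map(
            lambda conds: name in conds
        )
        return set(self.table.loc[mask, "cdr3"])

    def background_keys(self) -> set:
        return set(self.table.loc[self.table.role == "background", "cdr3"])


def generate_study(
    config: SimulationConfig,
) -> tuple[list[WellSample], StudyManifest, TruthTable]:
    """Simulate all wells of one participant/batch study.

    Returns the wells, a manifest whose file names follow
    ``{participant}_{condition}_{replicate}.tsv`` (written only by
    :func:`write_study`), and the ground-truth table.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    conditions = [parse_condition(c) for c in config.conditions]

    roles: list[tuple[str, tuple[Condition, ...]]] = []
    roles += [("mono_s2s", (Condition.S2S,))] * config.n_mono_s2s
    for cset in config.cross_condition_sets:
        roles.append(("cross", (Condition.S2S,) + tuple(parse_condition(c) for c in cset)))
    for pool, n in sorted(config.n_mono_ccc.items()):
        roles += [("mono_ccc", (parse_condition(pool),))] * n
    n_designed = len(roles)
    n_total = n_designed + config.n_background_clones

    used: set = set()
    cdr3s = [_random_cdr3(rng, used) for _ in range(n_total)]

    if config.baseline_distribution == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_total)
    else:
        ranks = rng.permutation(n_total) + 1
        weights = ranks.astype(float) ** (-config.zipf_exponent)
    # designed clones draw from the upper half of the weight distribution so
    # the default design is detectable rather than buried in the tail
    median_w = float(np.median(weights))
    for i in range(n_designed):
        while weights[i] < median_w:
            weights[i] = rng.lognormal(0.0, config.lognormal_sigma) \
                if config.baseline_distribution == "lognormal" else median_w
    baseline = weights / weights.sum()
    if config.designed_baseline_min > 0 and n_designed:
        floor = config.designed_baseline_min
        for _ in range(3):  # fixed-point: flooring changes the normalizer slightly
            baseline[:n_designed] = np.maximum(baseline[:n_designed], floor)
            baseline = baseline / baseline.sum()
        baseline[:n_designed] = np.maximum(baseline[:n_designed], floor)
        baseline = baseline / baseline.sum()

    reactive_sets = [set(conds) for _, conds in roles] + [set()] * config.n_background_clones

    wells: list[WellSample] = []
    entries: list[ManifestEntry] = []
    for cond in conditions:
        p = baseline.copy()
        for i, rs in enumerate(reactive_sets):
            if cond in rs:
                p[i] *= config.expansion_fold
        p = p / p.sum()
        for rep in range(1, config.n_replicates + 1):
            if config.overdispersion is not None:
                p_well = rng.dirichlet(p * config.overdispersion)
            else:
                p_well = p
            counts = rng.multinomial(config.depth, p_well)
            records = [
                ClonotypeRecord(cdr3_aa=cdr3s[i], templates=int(c))
                for i, c in enumerate(counts) if c > 0
            ]
            wells.append(
                WellSample(
                    participant=config.participant,
                    condition=cond,
                    replicate=rep,
                    assay_batch=config.assay_batch,
                    records=records,
                )
            )
            entries.append(
                ManifestEntry(
                    file=f"{config.participant}_{cond.value}_{rep}.tsv",
                    participant=config.participant,
                    condition=cond,
                    replicate=rep,
                    assay_batch=config.assay_batch,
                )
            )

    rows = []
    for i in range(n_total):
        if i < n_designed:
            role, conds = roles[i]
            reactive = ";".join(c.value for c in conds)
            fold = config.expansion_fold
        else:
            role, reactive, fold = "background", "", 1.0
        rows.append(
            {
                "clone_id": f"clone{i:05d}",
                "cdr3": cdr3s[i],
                "role": role,
                "reactive_conditions": reactive,
                "expansion_fold": fold,
                "baseline_prob": baseline[i],
            }
        )
    truth = TruthTable(table=pd.DataFrame(rows))
    return wells, StudyManifest(entries=entries), truth


def write_study(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a simulated study to disk: airr-dialect well tables,
    ``manifest.csv`` and ``truth.tsv``.  Returns (manifest path, truth path).
    """
    from .io import write_rearrangement_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wells, manifest, truth = generate_study(config)
    for well, entry in zip(wells, manifest.entries):
        write_rearrangement_table(well, out / entry.file)
    manifest_path = out / "manifest.csv"
    pd.DataFrame(
        [
            {
                "file": e.file,
                "participant": e.participant,
                "condition": e.condition.value,
                "replicate": e.replicate,
                "assay_batch": e.assay_batch,
            }
            for e in manifest.entries
        ]
    ).to_csv(manifest_path, index=False)
    truth_path = out / "truth.tsv"
    truth.table.to_csv(truth_path, sep="\t", index=False)
    (out / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return manifest_path, truth_path


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth scoring of one simulated study."""

    sensitivity: dict  # condition value -> fraction of designed clones recovered
    false_positive_rate: float  # positive calls among background clone tests
    n_background_tests: int
    label_confusion: dict  # (truth label, predicted label) -> count
    label_agreement: float | None  # over detected designed S2S clones

    def overall_sensitivity(self) -> float:
        vals = [v for v in self.sensitivity.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")


def evaluate_recovery(
    batch: BatchResult,
    reactivity_calls: list[ReactivityCall],
    truth: TruthTable,
) -> RecoveryReport:
    """Score positivity and mono/cross labels against the simulation design.

    Sensitivity is per condition over its designed reactive clones; the
    false-positive rate counts positive calls among background-clone tests
    across all antigen conditions.  The label confusion matrix compares the
    designed mono/cross role of each detected designed S2S clone with its
    predicted label.
    """
    truth_universe = set(truth.table.cdr3)
    tested = set()
    for cond, cond_calls in batch.calls.items():
        tested |= set(cond_calls)
    if not tested <= truth_universe:
        raise ValidationError(
            "pipeline calls contain clonotypes absent from the truth table; "
            "calls and truth must come from the same study"
        )

    sensitivity = {}
    for cond, cond_calls in batch.calls.items():
        designed = truth.reactive_keys(cond)
        if not designed:
            sensitivity[cond.value] = None
            continue
        hit = sum(1 for k in designed if k in batch.positive_set(cond))
        sensitivity[cond.value] = hit / len(designed)

    background = truth.background_keys()
    n_bg_tests = 0
    n_bg_pos = 0
    for cond, cond_calls in batch.calls.items():
        for key, call in cond_calls.items():
            if key in background:
                n_bg_tests += 1
                n_bg_pos += bool(call.is_positive)
    fpr = n_bg_pos / n_bg_tests if n_bg_tests else 0.0

    truth_s2s_label = {}
    designed = truth.designed()
    for _, row in designed.iterrows():
        conds = set(row.reactive_conditions.split(";"))
        if "S2S" in conds:
            truth_s2s_label[row.cdr3] = CROSS if len(conds) > 1 else MONO
    confusion: dict = {}
    agree = 0
    n_labeled = 0
    for call in reactivity_calls:
        t = truth_s2s_label.get(call.key)
        if t is None:
            continue
        confusion[(t, call.label)] = confusion.get((t, call.label), 0) + 1
        n_labeled += 1
        agree += call.label == t
    return RecoveryReport(
        sensitivity=sensitivity,
        false_positive_rate=fpr,
        n_background_tests=n_bg_tests,
        label_confusion=confusion,
        label_agreement=agree / n_labeled if n_labeled else None,
    )
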