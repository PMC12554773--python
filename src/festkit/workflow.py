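"""End-to-end study orchestration: load wells, call expansion, classify
reactivity, compute diversity, build the homology tree, write the bundle.

Every participant is analyzed per assay batch against that batch's own
DMSO wells; a participant with two batches gets side-by-side rows, never a
pooled positivity test.  All outputs are deterministic functions of the
input files and parameters: keys are sorted, conditions follow a fixed
order, and each table starts with a comment header naming the parameter
values used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import calling, diversity, homology, reactivity
from .io import load_study
from .model import (
    AnalysisParams,
    CONDITION_ORDER,
    Condition,
    StudyManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BatchBundle:
    batch: calling.BatchResult
    reactivity_calls: list
    summary: reactivity.ReactivitySummary
    diversity: diversity.DiversitySummary | None
    group: str = ""


@dataclasses.dataclass
class StudyResult:
    params: AnalysisParams
    bundles: list[BatchBundle]
    distance_matrix: homology.DistanceMatrix | None
    tree: object | None
    group_comparison: diversity.GroupComparison | None


def _param_header(params: AnalysisParams) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.to_dict().items())
    return f"# params: {kv}\n"


def _write_tsv(df: pd.DataFrame, path: Path, params: AnalysisParams) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header(params))
        df.to_csv(fh, sep="\t", index=False)


def analyze_study(
    wells: list, manifest: StudyManifest, params: AnalysisParams
) -> StudyResult:
    """Run the full analysis in memory (no files written)."""
    groups_by_participant = {
        e.participant: e.group for e in manifest.entries if e.group
    }
    by_batch: dict = {}
    for well in wells:
        by_batch.setdefault((well.participant, well.assay_batch), []).append(well)

    bundles: list[BatchBundle] = []
    for (participant, batch_id) in sorted(by_batch):
        batch_wells = by_batch[(participant, batch_id)]
        n_by_cond: dict = {}
        for w in batch_wells:
            n_by_cond[w.condition] = n_by_cond.get(w.condition, 0) + 1
        for cond, n in n_by_cond.items():
            if cond is not Condition.DMSO and n < params.min_positive_replicates:
                logger.warning(
                    "participant %s batch %s: condition %s has %d replicate(s), "
                    "fewer than min_positive_replicates=%d; condition skipped",
                    participant, batch_id, cond.value, n,
                    params.min_positive_replicates,
                )
        batch = calling.analyze_batch(batch_wells, params)
        calls = reactivity.classify_batch(batch, params)
        summary = reactivity.reactivity_summary(calls, participant, batch_id)
        group = groups_by_participant.get(participant, "")

        div = None
        s2s_set = batch.positive_set(Condition.S2S)
        if s2s_set and Condition.S2S in batch.frequencies:
            try:
                div = diversity.patient_diversity(
                    batch.frequencies[Condition.S2S], s2s_set,
                    participant, group, params,
                )
            except ValidationError as err:
                logger.warning("diversity skipped for %s/%s: %s",
                               participant, batch_id, err)
        bundles.append(BatchBundle(batch, calls, summary, div, group))

    # pooled homology over every S2S-positive clonotype across bundles
    pooled = []
    for b in bundles:
        for call in b.reactivity_calls:
            seq_id = f"{b.batch.participant}|{b.group or 'na'}|{call.key}"
            pooled.append((seq_id, call.key, b.batch.participant, b.group))
    trimmed = homology.trim_pool(pooled, params.trim_left, params.trim_right)
    dm = tree = None
    if len(trimmed) >= 3:
        dm = homology.pairwise_distance_matrix(trimmed)
        tree = homology.build_unrooted_tree(dm)
    elif pooled:
        logger.warning(
            "only %d trimmed spike-specific sequences; homology tree skipped",
            len(trimmed),
        )

    comparison = None
    means_by_group: dict = {}
    for b in bundles:
        if b.diversity is not None and b.group:
            means_by_group.setdefault(b.group, []).append(b.diversity.mean_index)
    if len(means_by_group) == 2:
        (ga, va), (gb, vb) = sorted(means_by_group.items())
        comparison = diversity.mann_whitney_u(va, vb)
        logger.info("diversity comparison %s vs %s: U=%.1f p=%.4g (%s)",
                    ga, gb, comparison.u_statistic, comparison.p_value,
                    comparison.method)

    return StudyResult(params, bundles, dm, tree, comparison)


def _profiles_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.bundles:
        batch = b.batch
        for cond in batch.conditions:
            if cond is Condition.DMSO:
                continue
            for key in sorted(batch.profiles.get(cond, {})):
                prof = batch.profiles[cond][key]
                call = batch.calls[cond][key]
                rows.append({
                    "participant": batch.participant,
                    "assay_batch": batch.assay_batch,
                    "clonotype": key,
                    "condition": cond.value,
                    "replicate_frequencies": ";".join(
                        f"{f:.6g}" for f in prof.replicate_frequencies),
                    "mean_frequency": prof.mean_frequency,
                    "n_replicates_above_threshold": prof.n_replicates_above_threshold,
                    "fold_vs_dmso": prof.fold_vs_dmso,
                    "is_positive": call.is_positive,
                    "failing_criteria": ";".join(call.failing_criteria),
                })
    return pd.DataFrame(rows)


def _reactivity_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.bundles:
        for call in b.reactivity_calls:
            rows.append({
                "participant": b.batch.participant,
                "assay_batch": b.batch.assay_batch,
                "clonotype": call.key,
                "label": call.label,
                "positive_conditions": ";".join(
                    c.value for c in CONDITION_ORDER if c in call.positive_conditions),
                "dominance_folds": ";".join(
                    f"{c.value}:{f:.4g}" for c, f in sorted(
                        call.dominance_folds.items(), key=lambda cf: cf[0].value)),
            })
    return pd.DataFrame(rows)


def _counts_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.bundles:
        batch = b.batch
        for cond in batch.conditions:
            if cond is Condition.DMSO:
                continue
            detected = batch.replicate_detected_counts.get(cond, [])
            rows.append({
                "participant": batch.participant,
                "assay_batch": batch.assay_batch,
                "condition": cond.value,
                "n_positive_clonotypes": len(batch.positive_sets.get(cond, [])),
                "per_replicate_detected": ";".join(str(n) for n in detected),
            })
    return pd.DataFrame(rows)


def _diversity_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.bundles:
        if b.diversity is None:
            continue
        rows.append({
            "participant": b.diversity.participant,
            "assay_batch": b.batch.assay_batch,
            "group": b.diversity.group,
            "replicate_indices": ";".join(f"{h:.6g}" for h in b.diversity.replicate_indices),
            "mean_index": b.diversity.mean_index,
        })
    return pd.DataFrame(rows)


def _summary_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.bundles:
        s = b.summary
        rows.append({
            "participant": s.participant,
            "assay_batch": s.assay_batch,
            "n_mono": s.n_mono, "n_cross": s.n_cross,
            "n_unclassified": s.n_unclassified,
            "pct_mono": s.pct_mono, "pct_cross": s.pct_cross,
            "pct_unclassified": s.pct_unclassified,
            "pct_mono_of_dichotomy": s.pct_mono_of_dichotomy,
            "pct_cross_of_dichotomy": s.pct_cross_of_dichotomy,
        })
    return pd.DataFrame(rows)


def run_fest_study(
    manifest: StudyManifest,
    params: AnalysisParams,
    out_dir: str | Path,
    dialect: str = "airr",
) -> StudyResult:
    """Run the full pipeline from a manifest and write the result bundle.

    Outputs: expansion_profiles.tsv, reactivity_calls.tsv,
    reactivity_summary.tsv, antigen_counts.tsv, diversity.tsv,
    comparison.json (when two groups exist), cdr3_distances.tsv, tree.nwk,
    run_config.json.  Missing input files abort the run before anything is
    written.
    """
    wells = load_study(manifest, dialect=dialect, key_mode=params.identity_key)
    result = analyze_study(wells, manifest, params)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(_profiles_frame(result), out / "expansion_profiles.tsv", params)
    _write_tsv(_reactivity_frame(result), out / "reactivity_calls.tsv", params)
    _write_tsv(_summary_frame(result), out / "reactivity_summary.tsv", params)
    _write_tsv(_counts_frame(result), out / "antigen_counts.tsv", params)
    _write_tsv(_diversity_frame(result), out / "diversity.tsv", params)
    if result.distance_matrix is not None:
        dm = result.distance_matrix
        df = pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids)
        with open(out / "cdr3_distances.tsv", "w") as fh:
            fh.write(_param_header(params))
            df.to_csv(fh, sep="\t")
        (out / "tree.nwk").write_text(homology.tree_to_newick(result.tree))
    if result.group_comparison is not None:
        c = result.group_comparison
        (out / "comparison.json").write_text(json.dumps({
            "u_statistic": c.u_statistic, "p_value": c.p_value,
            "method": c.method, "n_a": c.n_a, "n_b": c.n_b,
            "alpha": c.alpha,
        }, indent=2))
    (out / "run_config.json").write_text(json.dumps({
        "params": params.to_dict(),
        "dialect": dialect,
        "n_wells": len(wells),
        "stage_counts": {
            f"{b.batch.participant}/{b.batch.assay_batch}": b.batch.stage_counts
            for b in result.bundles
        },
    }, indent=2))
    for b in result.bundles:
        logger.info("stage counts %s/%s: %s", b.batch.participant,
                    b.batch.assay_batch, b.batch.stage_counts)
    return result


def write_clade(
    result: StudyResult, node_id: str, out_dir: str | Path, side: str = "auto"
) -> Path:
    """Export one clade of the homology tree as a heatmap-ready distance
    submatrix (clade_<node>.tsv) with the fixed color-scale range recorded
    in its header."""
    if result.tree is None or result.distance_matrix is None:
        raise ValidationError("study has no homology tree")
    leaves, sub, meta = homology.extract_clade(
        result.tree, node_id, result.distance_matrix, side=side
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"clade_{node_id}.tsv"
    df = pd.DataFrame(sub.matrix, index=sub.ids, columns=sub.ids)
    with open(path, "w") as fh:
        fh.write(f"# clade: {json.dumps(meta)}\n")
        df.to_csv(fh, sep="\t")
    return path
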