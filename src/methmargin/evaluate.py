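"""End-to-end pipeline runs on synthetic cohorts and recovery scoring.

These helpers chain the full analysis — block partitioning, block scoring,
marker selection, K classification — on an in-memory cohort and compare the
outcome against the generating truth, yielding block-level sensitivity,
empirical FDR and steep/gradual classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, differential, mhb
from .simulate import SimCohort


@dataclass
class PipelineResult:
    blocks: list[mhb.Block]
    scores: pd.DataFrame
    markers: pd.DataFrame
    position_means: pd.DataFrame
    classes: pd.DataFrame


def run_block_pipeline(
    cohort: SimCohort,
    *,
    r2_min: float = 0.5,
    min_cpgs: int = 3,
    min_pair_reads: int = 5,
    q_max: float = 0.05,
    effect_min: float = 0.2,
    min_group_n: int = 5,
) -> PipelineResult:
    """Blocks → six-metric score matrix → marker selection → K classes."""
    pooled = [h for reads in cohort.haplotypes.values() for h in reads]
    blocks = mhb.partition_mhb(
        pooled, cohort.index, r2_min=r2_min, min_cpgs=min_cpgs, min_pair_reads=min_pair_reads
    )
    scores = mhb.score_matrix(cohort.haplotypes, blocks)
    markers = differential.select_markers_from_scores(
        scores, cohort.sample_sheet, q_max=q_max, effect_min=effect_min, min_group_n=min_group_n
    )
    pm = classify.position_means(scores, cohort.sample_sheet, min_group_n=min_group_n)
    classes = classify.classify_markers(markers, pm)
    return PipelineResult(blocks, scores, markers, pm, classes)


def _block_of(marker_id: str) -> str:
    return marker_id.split("|", 1)[1] if "|" in marker_id else marker_id


def evaluate_recovery(cohort: SimCohort, result: PipelineResult | None = None, **kwargs) -> dict:
    """Score a pipeline run against the cohort's generating truth.

    A planted block counts as *recovered* when any of its six metric rows
    passes marker selection; a null block similarly counts as a false
    discovery.  For each recovered non-null block the metric row with the
    smallest q represents it, and its K class is compared with the truth
    archetype's class (S-* → S, G-* → G); blocks whose representative row
    cannot be classified count as misclassified.
    """
    if result is None:
        result = run_block_pipeline(cohort, **kwargs)
    truth = cohort.truth.set_index("block_id")
    signal_ids = set(truth.index[truth["archetype"] != "null"])
    null_ids = set(truth.index[truth["archetype"] == "null"])

    markers = result.markers
    discovered_blocks = {_block_of(m) for m in markers["marker_id"]}
    tp = discovered_blocks & signal_ids
    fp = discovered_blocks & null_ids
    sensitivity = len(tp) / len(signal_ids) if signal_ids else float("nan")
    fdr = len(fp) / len(discovered_blocks) if discovered_blocks else 0.0

    classes = result.classes.set_index("marker_id")
    n_correct = 0
    per_block = []
    for bid in sorted(tp):
        rows = markers[[_block_of(m) == bid for m in markers["marker_id"]]]
        best = rows.sort_values(["q", "marker_id"], kind="stable").iloc[0]
        pred = classes.loc[best["marker_id"], "class"]
        true_class = truth.loc[bid, "archetype"][0]  # 'S' or 'G'
        correct = pred == true_class
        n_correct += bool(correct)
        per_block.append((bid, truth.loc[bid, "archetype"], best["marker_id"], pred, correct))
    accuracy = n_correct / len(tp) if tp else float("nan")
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "class_accuracy": accuracy,
        "n_signal": len(signal_ids),
        "n_recovered": len(tp),
        "n_false": len(fp),
        "n_class_correct": n_correct,
        "per_block": pd.DataFrame(
            per_block, columns=["block_id", "archetype", "marker_id", "predicted", "correct"]
        ),
    }
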