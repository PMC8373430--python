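"""Spatial decay classification of methylation markers across the margin.

Each selected marker carries a mean score per sampling position (TC, TE,
P5, P10, P15, P20, PN).  Its decay shape entering the para-tumor tissue is
summarised by the statistic K = k1/k2 where, after orienting scores so that
the tumor core is the high end (d = +1 for high-score markers, −1 for
low-score markers),

    k1 = d · (M_TC − M_TE)        (drop from core to histological edge)
    k2 = d · (M_TE − M_P5)        (drop from edge to 5 mm beyond)

Markers with K < 1 are "Steep" (S): their score falls off sharply right at
the margin.  Markers with K >= 1 are "Gradual" (G): the decay from core to
edge already matches or exceeds the decay beyond it.  When k2 <= 0 but
k1 > 0 the marker keeps decaying only inside the tumor, which reads as
Gradual (K = +inf); when both are <= 0 the marker is non-monotone and left
unclassified rather than silently binned.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test
from .io import POSITIONS

__all__ = [
    "position_means",
    "compute_k",
    "classify_markers",
    "pairwise_position_tests",
    "trend_summary",
    "KClassification",
]


def position_means(
    scores: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    *,
    min_group_n: int = 5,
    positions: Sequence[str] = POSITIONS,
) -> pd.DataFrame:
    """Arithmetic mean score per marker and position (over patients).

    Cells backed by fewer than ``min_group_n`` non-missing samples are NaN,
    which propagates to a missing K downstream.
    """
    present = set(sample_sheet["position"])
    absent = [p for p in positions if p not in present]
    if absent:
        raise ValueError(f"positions {absent} missing from the sample sheet")
    out = pd.DataFrame(np.nan, index=scores.index, columns=list(positions))
    for pos in positions:
        sids = [
            s for s in sample_sheet.loc[sample_sheet["position"] == pos, "sample_id"]
            if s in scores.columns
        ]
        sub = scores[sids]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        out[pos] = mean.where(n >= min_group_n)
    return out


@dataclass(frozen=True)
class KClassification:
    marker_id: str
    direction: str
    k1: float
    k2: float
    K: float
    klass: str | None  # "S", "G", or None when unclassifiable
    non_monotone: bool = False


def compute_k(
    means: Mapping[str, float] | pd.Series,
    direction: str,
    *,
    marker_id: str = "",
) -> KClassification:
    """Classify one marker from its TC/TE/P5 position means.

    ``direction`` is "high" when the marker scores higher in the tumor core
    than in peripheral normal tissue, "low" otherwise; low markers are
    sign-flipped so both kinds decay downward.  K = k1/k2 when k2 > 0;
    K = +inf (Gradual) when k2 <= 0 < k1; non-monotone otherwise.
    The boundary K = 1 classifies as Gradual.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    tc, te, p5 = (float(means[k]) for k in ("TC", "TE", "P5"))
    if any(math.isnan(v) for v in (tc, te, p5)):
        return KClassification(marker_id, direction, math.nan, math.nan, math.nan, None)
    d = 1.0 if direction == "high" else -1.0
    k1 = d * (tc - te)
    k2 = d * (te - p5)
    if k2 > 0:
        K = k1 / k2
        klass = "S" if K < 1 else "G"
        return KClassification(marker_id, direction, k1, k2, K, klass)
    if k1 > 0:
        return KClassification(marker_id, direction, k1, k2, math.inf, "G")
    return KClassification(marker_id, direction, k1, k2, math.nan, None, non_monotone=True)


def classify_markers(
    markers: pd.DataFrame,
    pm: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every marker row (needs ``marker_id`` and ``direction``).

    ``pm`` is the position-mean table indexed by marker_id.  Returns a frame
    with k1, k2, K and class ("S"/"G"; empty when non-monotone or missing).
    """
    rows = []
    for _, rec in markers.iterrows():
        mid = rec["marker_id"]
        if mid in pm.index:
            kc = compute_k(pm.loc[mid], rec["direction"], marker_id=mid)
        else:
            kc = KClassification(mid, rec["direction"], math.nan, math.nan, math.nan, None)
        rows.append((mid, rec.get("feature_type", ""), rec["direction"],
                     kc.k1, kc.k2, kc.K, kc.klass or "", kc.non_monotone))
    return pd.DataFrame(
        rows,
        columns=["marker_id", "feature_type", "direction", "k1", "k2", "K",
                 "class", "non_monotone"],
    )


def pairwise_position_tests(
    scores: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    *,
    positions: Sequence[str] = POSITIONS,
    min_group_n: int = 5,
    set_id: str = "",
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests between every pair of sampling positions.

    The marker set is collapsed to one value per sample (the mean score over
    the set's markers, missing cells dropped); each of the 21 position pairs
    is tested two-sided and BH adjustment is applied across the emitted
    pairs.  Pairs with fewer than ``min_group_n`` samples on either side
    are omitted.
    """
    per_sample = scores.mean(axis=0, skipna=True)
    by_pos = {
        pos: per_sample[
            [s for s in sample_sheet.loc[sample_sheet["position"] == pos, "sample_id"]
             if s in per_sample.index]
        ].dropna().to_numpy()
        for pos in positions
    }
    rows = []
    for a, b in combinations(positions, 2):
        x, y = by_pos[a], by_pos[b]
        if len(x) < min_group_n or len(y) < min_group_n:
            continue
        stat, p = rank_sum_test(x, y)
        rows.append((set_id, a, b, stat, p))
    out = pd.DataFrame(rows, columns=["set_id", "pos_a", "pos_b", "statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.empty(0)
    return out


def trend_summary(
    scores: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    classes: pd.DataFrame,
    *,
    positions: Sequence[str] = POSITIONS,
    min_group_n: int = 1,
) -> pd.DataFrame:
    """Per (direction, class) group: mean ± SD methylation score by position.

    For each marker the per-position mean over samples is computed first;
    the group summary is the mean and SD of those per-marker profiles, so a
    single-marker group reproduces that marker's profile verbatim.  Empty
    groups are omitted.
    """
    pm = position_means(scores, sample_sheet, min_group_n=min_group_n, positions=positions)
    rows = []
    labelled = classes[classes["class"].isin(["S", "G"])]
    for (direction, klass), grp in labelled.groupby(["direction", "class"], sort=True):
        ids = [m for m in grp["marker_id"] if m in pm.index]
        if not ids:
            continue
        prof = pm.loc[ids]
        for pos in positions:
            vals = prof[pos].dropna()
            if vals.empty:
                continue
            rows.append((
                f"{direction}-{klass}", pos, len(vals),
                float(vals.mean()),
                float(vals.std(ddof=0)) if len(vals) > 1 else 0.0,
            ))
    return pd.DataFrame(rows, columns=["group", "position", "n_markers", "mean", "sd"])
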