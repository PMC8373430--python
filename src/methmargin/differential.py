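"""Differential methylation between tumor core (TC) and peripheral normal (PN).

Three feature layers share one selection standard — FDR < 0.05 and an
absolute group-mean difference above 0.2:

* DMCs: per-CpG beta-binomial Wald test on methylated/total counts.  Group
  proportions are coverage-weighted pools; the per-site overdispersion is
  estimated by the method of moments and shrunk toward the genome-wide
  median with an empirical-Bayes weight m/(m + n_samples).  No smoothing
  across sites is applied (the intended input is RRBS, where covered CpGs
  are clustered and sparse between clusters).
* DMRs: runs of nearby tested CpGs, merged when consecutive sites are at
  most ``max_gap_bp`` apart, kept when they carry >=3 CpGs of which more
  than 10% are individually significant at the per-site alpha.
* MHB score markers: per-marker Wilcoxon rank-sum across samples on the
  block score matrix.

A marker's direction is "high" when its TC group mean exceeds the PN mean.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._stats import bh_adjust, rank_sum_test

__all__ = [
    "bh_adjust",
    "fit_dmc",
    "fit_dmc_arrays",
    "call_dmr",
    "select_markers",
    "select_markers_from_scores",
    "select_markers_from_sites",
]

log = logging.getLogger(__name__)

DMC_COLUMNS = [
    "contig", "slot", "pos", "beta_tc", "beta_pn", "delta_beta",
    "phi", "wald", "p", "q", "n_total",
]


# ---------------------------------------------------------------------------
# DMC calling


def _group_moments(m: np.ndarray, n: np.ndarray):
    """Per-site pooled proportion and method-of-moments pieces for one group.

    ``m``/``n`` are (sites, samples); samples with zero coverage at a site
    are treated as missing there.
    """
    mask = n > 0
    n_sum = np.where(mask, n, 0).sum(axis=1).astype(float)
    m_sum = np.where(mask, m, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_sum > 0, m_sum / n_sum, np.nan)
        frac = np.where(mask, m / np.where(mask, n, 1), np.nan)
        resid = np.nansum((frac - p[:, None]) ** 2, axis=1)
        inv_n = np.where(mask, 1.0 / np.where(mask, n, 1), 0.0).sum(axis=1)
        frac_nm1 = np.where(mask, (n - 1.0) / np.where(mask, n, 1), 0.0).sum(axis=1)
    return p, n_sum, mask.sum(axis=1), resid, inv_n, frac_nm1, mask


def fit_dmc_arrays(
    m_tc: np.ndarray,
    n_tc: np.ndarray,
    m_pn: np.ndarray,
    n_pn: np.ndarray,
    *,
    shrinkage_mass: float = 4.0,
    min_samples: int = 2,
) -> dict[str, np.ndarray]:
    """Vectorised beta-binomial Wald test over a (sites × samples) grid.

    Returns per-site arrays plus a boolean ``tested`` mask; sites covered by
    fewer than ``min_samples`` samples in either group are not tested.
    """
    m_tc, n_tc, m_pn, n_pn = (np.asarray(a, dtype=float) for a in (m_tc, n_tc, m_pn, n_pn))
    p1, nsum1, cov1, r1, a1, b1, mask1 = _group_moments(m_tc, n_tc)
    p2, nsum2, cov2, r2, a2, b2, mask2 = _group_moments(m_pn, n_pn)
    tested = (cov1 >= min_samples) & (cov2 >= min_samples)
    # residuals around the pooled estimate lose one df per group; rescale by
    # k/(k-1) so the moment dispersion estimate is not biased low
    r1 = r1 * np.where(cov1 > 1, cov1 / np.maximum(cov1 - 1.0, 1.0), 1.0)
    r2 = r2 * np.where(cov2 > 1, cov2 / np.maximum(cov2 - 1.0, 1.0), 1.0)

    pq1 = p1 * (1.0 - p1)
    pq2 = p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (r1 - pq1 * a1) + (r2 - pq2 * a2)
        den = pq1 * b1 + pq2 * b2
        phi = np.where(den > 0, num / den, np.nan)
    phi = np.clip(phi, 0.0, 0.99)
    finite = np.isfinite(phi) & tested
    phi_med = float(np.median(phi[finite])) if finite.any() else 0.0
    n_s = (cov1 + cov2).astype(float)
    phi_site = np.where(np.isfinite(phi), phi, phi_med)
    phi_shrunk = (n_s * phi_site + shrinkage_mass * phi_med) / (n_s + shrinkage_mass)

    def group_var(n, mask, pq, nsum, phi_s):
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = np.where(mask, n * (1.0 + (n - 1.0) * phi_s[:, None]), 0.0).sum(axis=1)
            return pq * eff / np.where(nsum > 0, nsum, 1) ** 2

    var = group_var(n_tc, mask1, pq1, nsum1, phi_shrunk) + group_var(
        n_pn, mask2, pq2, nsum2, phi_shrunk
    )
    delta = p1 - p2
    se = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.sign(delta) * np.inf))
    p = 2.0 * norm.sf(np.abs(wald))
    return {
        "tested": tested,
        "beta_tc": p1,
        "beta_pn": p2,
        "delta_beta": delta,
        "phi": phi_shrunk,
        "wald": wald,
        "p": p,
        "n_total": nsum1 + nsum2,
    }


def _stack_counts(counts: Mapping[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.concat(
        [df.assign(sample=sid) for sid, df in counts.items()], ignore_index=True
    )
    m = long.pivot(index=["contig", "slot", "pos"], columns="sample", values="n_meth")
    n = long.pivot(index=["contig", "slot", "pos"], columns="sample", values="n_total")
    return m, n


def fit_dmc(
    counts_tc: Mapping[str, pd.DataFrame],
    counts_pn: Mapping[str, pd.DataFrame],
    *,
    shrinkage_mass: float = 4.0,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Call differentially methylated CpGs from per-sample count tables.

    ``counts_*`` map sample_id to the ``contig/slot/pos/n_meth/n_total``
    frames produced by :func:`methmargin.io.read_counts_table`.  Sites
    covered by fewer than ``min_samples`` samples in either group are
    skipped (and logged).  Returns a frame with one row per tested CpG and
    BH-adjusted q-values.
    """
    if not counts_tc or not counts_pn:
        raise ValueError("both groups need at least one sample")
    m_all, n_all = _stack_counts({**counts_tc, **counts_pn})
    tc_cols = [c for c in m_all.columns if c in counts_tc]
    pn_cols = [c for c in m_all.columns if c in counts_pn]
    res = fit_dmc_arrays(
        m_all[tc_cols].to_numpy(), n_all[tc_cols].fillna(0).to_numpy(),
        m_all[pn_cols].to_numpy(), n_all[pn_cols].fillna(0).to_numpy(),
        shrinkage_mass=shrinkage_mass, min_samples=min_samples,
    )
    sites = m_all.index.to_frame(index=False)
    tested = res["tested"]
    n_skipped = int((~tested).sum())
    if n_skipped:
        log.info("fit_dmc: skipped %d sites with insufficient group coverage", n_skipped)
    out = sites.loc[tested].reset_index(drop=True)
    for col in ("beta_tc", "beta_pn", "delta_beta", "phi", "wald", "p", "n_total"):
        out[col] = res[col][tested]
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.empty(0)
    out = out.sort_values(["contig", "slot"], kind="stable").reset_index(drop=True)
    return out[DMC_COLUMNS]


# ---------------------------------------------------------------------------
# DMR calling


def _stouffer(p: np.ndarray, delta: np.ndarray, weights: np.ndarray) -> float:
    """Directional Stouffer combination of two-sided per-site p-values."""
    p = np.clip(p, 1e-300, 1.0)
    z = norm.isf(p / 2.0) * np.where(delta < 0, -1.0, 1.0)
    zsum = float((weights * z).sum() / np.sqrt((weights**2).sum()))
    return float(2.0 * norm.sf(abs(zsum)))


def call_dmr(
    dmc: pd.DataFrame,
    *,
    max_gap_bp: int = 100,
    alpha_site: float = 0.05,
    min_cpg: int = 3,
    min_frac_sig: float = 0.1,
) -> pd.DataFrame:
    """Merge tested CpGs into differentially methylated regions.

    Consecutive tested CpGs on the same contig at most ``max_gap_bp`` apart
    form a candidate chain; a chain is emitted when it contains at least one
    site with p < ``alpha_site``, at least ``min_cpg`` CpGs, and a
    significant-site fraction strictly greater than ``min_frac_sig``.  No
    base-pair length cap is applied.  The region effect is the unweighted
    mean of member Δβ; the region p combines member p-values by a
    directional Stouffer sum weighted by the square root of site coverage,
    and q is BH-adjusted across emitted regions.
    """
    cols = ["contig", "start_slot", "end_slot", "start", "end", "n_cpg",
            "n_sig", "frac_sig", "mean_delta_beta", "combined_p", "q"]
    if dmc.empty:
        return pd.DataFrame(columns=cols)
    dmc = dmc.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)
    regions = []
    for contig, grp in dmc.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for lo, hi in zip(starts, ends):
            chunk = grp.iloc[lo : hi + 1]
            n_cpg = len(chunk)
            n_sig = int((chunk["p"] < alpha_site).sum())
            if n_sig == 0 or n_cpg < min_cpg:
                continue
            frac_sig = n_sig / n_cpg
            if not frac_sig > min_frac_sig:
                continue
            regions.append({
                "contig": contig,
                "start_slot": int(chunk["slot"].iloc[0]),
                "end_slot": int(chunk["slot"].iloc[-1]),
                "start": int(chunk["pos"].iloc[0]),
                "end": int(chunk["pos"].iloc[-1]) + 2,
                "n_cpg": n_cpg,
                "n_sig": n_sig,
                "frac_sig": frac_sig,
                "mean_delta_beta": float(chunk["delta_beta"].mean()),
                "combined_p": _stouffer(
                    chunk["p"].to_numpy(),
                    chunk["delta_beta"].to_numpy(),
                    np.sqrt(chunk["n_total"].to_numpy(dtype=float)),
                ),
            })
    out = pd.DataFrame(regions, columns=cols[:-1])
    out["q"] = bh_adjust(out["combined_p"].to_numpy()) if len(out) else np.empty(0)
    return out


# ---------------------------------------------------------------------------
# Marker selection


@dataclass(frozen=True)
class MarkerRecord:
    marker_id: str
    feature_type: str  # "MHB", "DMC" or "DMR"
    direction: str  # "high" iff TC group mean exceeds PN
    effect: float
    p: float
    q: float
    mean_tc: float
    mean_pn: float


MARKER_COLUMNS = ["marker_id", "feature_type", "direction", "effect", "p", "q",
                  "mean_tc", "mean_pn"]


def select_markers_from_scores(
    scores: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    *,
    q_max: float = 0.05,
    effect_min: float = 0.2,
    min_group_n: int = 5,
    group_tc: str = "TC",
    group_pn: str = "PN",
) -> pd.DataFrame:
    """Select MHB score markers by rank-sum test between TC and PN samples.

    ``scores`` is the markers × samples matrix from
    :func:`methmargin.mhb.score_matrix`.  Markers with fewer than
    ``min_group_n`` non-missing values in either group are excluded (and
    logged); the rest are BH-adjusted together and kept when q < ``q_max``
    and |mean_TC − mean_PN| > ``effect_min``.
    """
    tc_samples = sample_sheet.loc[sample_sheet["position"] == group_tc, "sample_id"]
    pn_samples = sample_sheet.loc[sample_sheet["position"] == group_pn, "sample_id"]
    tc = scores[[s for s in tc_samples if s in scores.columns]]
    pn = scores[[s for s in pn_samples if s in scores.columns]]
    rows = []
    for marker_id in scores.index:
        x = tc.loc[marker_id].dropna().to_numpy()
        y = pn.loc[marker_id].dropna().to_numpy()
        if len(x) < min_group_n or len(y) < min_group_n:
            log.info("select_markers: %s excluded (support %d vs %d)", marker_id, len(x), len(y))
            continue
        _, p = rank_sum_test(x, y)
        rows.append((marker_id, float(x.mean()), float(y.mean()), p))
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    df = pd.DataFrame(rows, columns=["marker_id", "mean_tc", "mean_pn", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["effect"] = df["mean_tc"] - df["mean_pn"]
    df["direction"] = np.where(df["effect"] > 0, "high", "low")
    df["feature_type"] = "MHB"
    keep = (df["q"] < q_max) & (df["effect"].abs() > effect_min)
    return df.loc[keep, MARKER_COLUMNS].reset_index(drop=True)


def select_markers_from_sites(
    records: pd.DataFrame,
    *,
    feature_type: str,
    q_max: float = 0.05,
    effect_min: float = 0.2,
) -> pd.DataFrame:
    """Apply the final selection standard to DMC or DMR record tables."""
    if feature_type == "DMC":
        effect = records["delta_beta"]
        marker_id = records["contig"].astype(str) + ":" + records["pos"].astype(str)
        p = records["p"]
        mean_tc, mean_pn = records["beta_tc"], records["beta_pn"]
    elif feature_type == "DMR":
        effect = records["mean_delta_beta"]
        marker_id = (
            records["contig"].astype(str)
            + ":" + records["start"].astype(str)
            + ":" + records["end"].astype(str)
        )
        p = records["combined_p"]
        mean_tc = mean_pn = pd.Series(np.nan, index=records.index)
    else:
        raise ValueError("feature_type must be 'DMC' or 'DMR'")
    df = pd.DataFrame({
        "marker_id": marker_id,
        "feature_type": feature_type,
        "direction": np.where(effect > 0, "high", "low"),
        "effect": effect.astype(float),
        "p": p.astype(float),
        "q": records["q"].astype(float),
        "mean_tc": mean_tc,
        "mean_pn": mean_pn,
    })
    keep = (df["q"] < q_max) & (df["effect"].abs() > effect_min)
    return df.loc[keep, MARKER_COLUMNS].reset_index(drop=True)


def select_markers(
    data: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
    *,
    q_max: float = 0.05,
    effect_min: float = 0.2,
    min_group_n: int = 5,
) -> pd.DataFrame:
    """Dispatch marker selection on the input's shape.

    DMC tables (``delta_beta`` column) and DMR tables (``mean_delta_beta``)
    carry their own statistics; any other frame is treated as an MHB score
    matrix and needs the sample sheet.
    """
    if "mean_delta_beta" in data.columns:
        return select_markers_from_sites(data, feature_type="DMR", q_max=q_max, effect_min=effect_min)
    if "delta_beta" in data.columns:
        return select_markers_from_sites(data, feature_type="DMC", q_max=q_max, effect_min=effect_min)
    if sample_sheet is None:
        raise ValueError("a sample sheet is required to select markers from a score matrix")
    return select_markers_from_scores(
        data, sample_sheet, q_max=q_max, effect_min=effect_min, min_group_n=min_group_n
    )
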