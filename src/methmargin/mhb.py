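"""Methylation haplotype blocks and their read-level scores.

A methylation haplotype block (MHB) is a run of adjacent CpG sites whose
methylation states travel together on individual sequencing fragments.
Blocks are found by computing the squared correlation (r²) of the paired
methylation calls of every adjacent CpG pair and greedily extending runs of
tightly linked pairs.  Each block is then scored per sample with six
read-level metrics:

AMF
    average methylation fraction — methylated calls over informative calls.
MHL / MHL3
    methylated haplotype load — length-weighted average, over substring
    lengths l = 1..L, of the fraction of observed length-l gapless call
    substrings that are fully methylated; MHL uses weight l, MHL3 uses l³,
    so longer fully methylated runs dominate the cubic variant.
UMHL / UMHL3
    the same loads for fully *unmethylated* substrings.
PDR
    proportion of discordant reads — among reads with at least
    ``min_read_cpgs`` informative calls in the block, the fraction carrying
    both an M and a U call (an epiallele-heterogeneity signal).

All six scores live in [0, 1] and are NaN (missing, not zero) when the
supporting evidence falls below threshold.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CpGIndex, ReadHaplotype

METRICS = ("AMF", "MHL", "MHL3", "UMHL", "UMHL3", "PDR")

_M, _U, _GAP = 1, 0, -1


def encode_calls(reads: Iterable[str]) -> np.ndarray:
    """Encode equal-length call strings as an int8 matrix (M=1, U=0, '.'=-1)."""
    reads = list(reads)
    if not reads:
        return np.empty((0, 0), dtype=np.int8)
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise ValueError("all call strings in a block must have equal length")
    raw = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8).reshape(len(reads), L)
    mat = np.full(raw.shape, _GAP, dtype=np.int8)
    mat[raw == ord("M")] = _M
    mat[raw == ord("U")] = _U
    if np.any((raw != ord("M")) & (raw != ord("U")) & (raw != ord("."))):
        raise ValueError("call strings may only contain M, U and '.'")
    return mat


def complement(reads: Iterable[str]) -> list[str]:
    """Swap M and U calls ('.' unchanged)."""
    table = str.maketrans("MU", "UM")
    return [r.translate(table) for r in reads]


# ---------------------------------------------------------------------------
# Block partitioning


@dataclass(frozen=True)
class Block:
    """A run of linked CpG slots scored as a unit.

    ``first_slot``/``last_slot`` are inclusive CpG indices; ``start``/``end``
    are half-open genomic coordinates spanning the first C through the final
    G of the block.
    """

    contig: str
    first_slot: int
    last_slot: int
    start: int
    end: int

    @property
    def n_cpg(self) -> int:
        return self.last_slot - self.first_slot + 1

    @property
    def block_id(self) -> str:
        return f"{self.contig}:{self.start}:{self.end}"


def pair_r2(n11: int, n10: int, n01: int, n00: int, *, min_pair_reads: int = 5) -> float:
    """Squared correlation of paired methylation calls at two adjacent CpGs.

    ``n11`` counts reads methylated at both sites, ``n10`` methylated at the
    first only, etc.  Returns NaN when fewer than ``min_pair_reads`` reads
    cover both sites or when either margin is monomorphic (r² undefined).
    """
    total = n11 + n10 + n01 + n00
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("pair counts must be nonnegative")
    if total < min_pair_reads:
        return math.nan
    p11 = n11 / total
    pa = (n11 + n10) / total
    pb = (n11 + n01) / total
    denom = pa * (1.0 - pa) * pb * (1.0 - pb)
    if denom == 0.0:
        return math.nan
    return (p11 - pa * pb) ** 2 / denom


def adjacent_pair_counts(
    haplotypes: Iterable[ReadHaplotype], index: CpGIndex
) -> dict[str, np.ndarray]:
    """Joint call counts for every adjacent CpG pair, per contig.

    Returns contig -> (n_pairs, 4) int64 array with columns
    (n11, n10, n01, n00); row i describes slots (i, i+1).
    """
    counts = {
        c: np.zeros((max(index.n_sites(c) - 1, 0), 4), dtype=np.int64)
        for c in index.contigs
    }
    for h in haplotypes:
        mat = counts[h.contig]
        arr = np.frombuffer(h.calls.encode("ascii"), dtype=np.uint8)
        a, b = arr[:-1], arr[1:]
        valid = ((a == ord("M")) | (a == ord("U"))) & ((b == ord("M")) | (b == ord("U")))
        if not valid.any():
            continue
        offs = np.flatnonzero(valid)
        # column order (11, 10, 01, 00): "1" = methylated at that site
        col = (a[offs] != ord("M")) * 2 + (b[offs] != ord("M"))
        np.add.at(mat, (h.start_slot + offs, col), 1)
    return counts


def partition_mhb(
    haplotypes: Iterable[ReadHaplotype],
    index: CpGIndex,
    *,
    r2_min: float = 0.5,
    min_cpgs: int = 3,
    min_pair_reads: int = 5,
) -> list[Block]:
    """Greedy left-to-right partition of the CpG landscape into blocks.

    A block grows while the next adjacent pair has a defined r² at least
    ``r2_min``; runs shorter than ``min_cpgs`` CpGs are dropped.  Blocks
    never span contigs, and a pair with no (or sub-threshold) joint read
    coverage breaks any run.  Haplotypes are normally pooled over all
    samples so that the resulting blocks are shared coordinates.
    """
    counts = adjacent_pair_counts(haplotypes, index)
    blocks: list[Block] = []
    for contig in index.contigs:
        mat = counts[contig]
        n_pairs = mat.shape[0]
        linked = np.zeros(n_pairs, dtype=bool)
        for i in range(n_pairs):
            r2 = pair_r2(*mat[i], min_pair_reads=min_pair_reads)
            linked[i] = (not math.isnan(r2)) and r2 >= r2_min
        i = 0
        while i < n_pairs:
            if not linked[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_pairs and linked[j + 1]:
                j += 1
            first, last = i, j + 1  # slots
            if last - first + 1 >= min_cpgs:
                blocks.append(
                    Block(
                        contig,
                        first,
                        last,
                        index.pos_of(contig, first),
                        index.pos_of(contig, last) + 2,
                    )
                )
            i = j + 2
    return blocks


def block_reads(
    haplotypes: Iterable[ReadHaplotype], block: Block
) -> list[str]:
    """Restrict reads to a block's slots, '.'-padded to the block length.

    Reads with no informative call inside the block are dropped.
    """
    L = block.n_cpg
    out: list[str] = []
    for h in haplotypes:
        if h.contig != block.contig:
            continue
        if h.start_slot > block.last_slot or h.end_slot < block.first_slot:
            continue
        lo = max(h.start_slot, block.first_slot)
        hi = min(h.end_slot, block.last_slot)
        sub = h.calls[lo - h.start_slot : hi - h.start_slot + 1]
        if set(sub) <= {"."}:
            continue
        padded = "." * (lo - block.first_slot) + sub + "." * (block.last_slot - hi)
        assert len(padded) == L
        out.append(padded)
    return out


# ---------------------------------------------------------------------------
# Scores


def _load_from_matrix(mat: np.ndarray, state: int, weight_exponent: int) -> float:
    n, L = mat.shape
    if n == 0:
        return math.nan
    num = 0.0
    den = 0.0
    for l in range(1, L + 1):
        win = np.lib.stride_tricks.sliding_window_view(mat, l, axis=1)
        valid = (win != _GAP).all(axis=-1)
        d = int(valid.sum())
        if d == 0:
            continue
        m = int(((win == state).all(axis=-1)).sum())
        w = float(l**weight_exponent)
        num += w * (m / d)
        den += w
    return num / den if den > 0 else math.nan


def haplotype_load(
    reads: Sequence[str], state: str = "M", weight_exponent: int = 1
) -> float:
    """Length-weighted fraction of fully-``state`` gapless call substrings.

    For each substring length l = 1..L (L = block CpG count), P_l is the
    fraction of observed length-l substrings containing no '.' whose calls
    are all ``state``; the load is Σ w_l·P_l / Σ w_l with w_l = l**
    ``weight_exponent``, the sums running over lengths with at least one
    observed substring.  NaN when no eligible substring exists.
    """
    if state not in ("M", "U"):
        raise ValueError("state must be 'M' or 'U'")
    if weight_exponent not in (1, 3):
        raise ValueError("weight_exponent must be 1 or 3")
    mat = encode_calls(reads)
    return _load_from_matrix(mat, _M if state == "M" else _U, weight_exponent)


def amf(reads: Sequence[str]) -> float:
    """Average methylation fraction: M calls over informative (M or U) calls."""
    mat = encode_calls(reads)
    informative = int((mat != _GAP).sum())
    if informative == 0:
        return math.nan
    return int((mat == _M).sum()) / informative


def pdr(reads: Sequence[str], *, min_read_cpgs: int = 4) -> float:
    """Proportion of discordant reads among reads with enough informative calls.

    A read qualifies when it carries at least ``min_read_cpgs`` M/U calls in
    the block; it is discordant when it carries both an M and a U.
    """
    mat = encode_calls(reads)
    if mat.size == 0:
        return math.nan
    n_m = (mat == _M).sum(axis=1)
    n_u = (mat == _U).sum(axis=1)
    qualifying = (n_m + n_u) >= min_read_cpgs
    if not qualifying.any():
        return math.nan
    discordant = (n_m > 0) & (n_u > 0)
    return float(discordant[qualifying].mean())


def _score_cell(mat: np.ndarray, pdr_min_read_cpgs: int) -> dict[str, float]:
    informative = int((mat != _GAP).sum())
    out = {m: math.nan for m in METRICS}
    if mat.shape[0] == 0 or informative == 0:
        return out
    out["AMF"] = int((mat == _M).sum()) / informative
    out["MHL"] = _load_from_matrix(mat, _M, 1)
    out["MHL3"] = _load_from_matrix(mat, _M, 3)
    out["UMHL"] = _load_from_matrix(mat, _U, 1)
    out["UMHL3"] = _load_from_matrix(mat, _U, 3)
    n_m = (mat == _M).sum(axis=1)
    n_u = (mat == _U).sum(axis=1)
    qualifying = (n_m + n_u) >= pdr_min_read_cpgs
    if qualifying.any():
        out["PDR"] = float(((n_m > 0) & (n_u > 0))[qualifying].mean())
    return out


def score_matrix(
    sample_haplotypes: Mapping[str, Sequence[ReadHaplotype]],
    blocks: Sequence[Block],
    *,
    metrics: Sequence[str] = METRICS,
    min_reads: int = 1,
    pdr_min_read_cpgs: int = 4,
) -> pd.DataFrame:
    """Per-(block, metric) × per-sample score matrix.

    Rows are labelled ``METRIC|contig:start:end`` so a block contributes one
    marker row per metric; entries are NaN wherever support thresholds fail.
    """
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    samples = list(sample_haplotypes)
    rows = [f"{m}|{b.block_id}" for b in blocks for m in metrics]
    out = pd.DataFrame(np.nan, index=rows, columns=samples)
    # bucket reads by contig with vectorised span lookups: candidate reads for
    # a block are found by masking start/end arrays instead of a Python scan
    for sid in samples:
        by_contig: dict[str, tuple[np.ndarray, np.ndarray, list[ReadHaplotype]]] = {}
        grouped: dict[str, list[ReadHaplotype]] = {}
        for h in sample_haplotypes[sid]:
            grouped.setdefault(h.contig, []).append(h)
        for contig, reads in grouped.items():
            starts = np.array([h.start_slot for h in reads], dtype=np.int64)
            ends = np.array([h.end_slot for h in reads], dtype=np.int64)
            by_contig[contig] = (starts, ends, reads)
        for b in blocks:
            if b.contig not in by_contig:
                continue
            starts, ends, reads = by_contig[b.contig]
            hit = np.flatnonzero((starts <= b.last_slot) & (ends >= b.first_slot))
            strings = block_reads((reads[i] for i in hit), b)
            if len(strings) < min_reads:
                continue
            cell = _score_cell(encode_calls(strings), pdr_min_read_cpgs)
            for m in metrics:
                out.loc[f"{m}|{b.block_id}", sid] = cell[m]
    return out


def write_blocks_bed(blocks: Sequence[Block], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.block_id}\n")
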