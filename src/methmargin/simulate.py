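"""Seeded synthetic cohorts with planted spatial-marker archetypes.

The generator emulates the sampling design of a tumor surgical-margin
methylation study: ``n_patients`` patients, each contributing seven samples
along a spatial transect — tumor core (TC), tumor edge (TE), 5/10/15/20 mm
beyond the tumor (P5..P20) and peripheral normal tissue (PN).  CpGs are laid
out in blocks; each block follows one archetype:

* ``S-high`` — high in the tumor, collapsing sharply at 5 mm past the edge.
* ``G-high`` — high in the tumor, decaying gradually from core outward.
* ``S-low`` / ``G-low`` — the mirrored hypomethylated versions (1 − high).
* ``null`` — flat 0.5 everywhere.

The default archetype mixture (6 S-high, 6 S-low, 1 G-high, 1 G-low, 26
null) reproduces the roughly 86%/14% steep/gradual composition reported for
this marker class, so cohort-level summaries resemble the study design
rather than an artificial 50/50 mixture.

Reads follow a two-epiallele model: with probability equal to the block's
effective mean a fragment comes from a methylated epiallele (each CpG
methylated with rate 0.95), otherwise from an unmethylated epiallele (rate
0.05).  This concentrates methylation on whole fragments, so haplotype-load
metrics (MHL family) respond more strongly than the per-CpG average — the
premise that makes block-level scoring worthwhile.  Incomplete bisulfite
conversion flips U calls to M with the (small) failure probability.
Patient baselines are drawn once per (patient, block) on the logit scale
and shared across positions, emulating the paired transect design.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import POSITIONS, CpGIndex, ReadHaplotype, write_haplotype_table
from .mhb import Block

ARCHETYPES = ("S-high", "S-low", "G-high", "G-low", "null")

_HIGH_TEMPLATES = {
    "S-high": np.array([0.80, 0.75, 0.20, 0.20, 0.20, 0.20, 0.20]),
    "G-high": np.array([0.80, 0.55, 0.32, 0.22, 0.20, 0.20, 0.20]),
    "null": np.full(7, 0.5),
}

DEFAULT_N_BLOCKS: dict[str, int] = {
    "S-high": 6, "S-low": 6, "G-high": 1, "G-low": 1, "null": 26,
}


def archetype_profile(
    archetype: str,
    overrides: Mapping[str, Sequence[float]] | None = None,
) -> np.ndarray:
    """Per-position mean methylation template for one archetype.

    Low archetypes are the elementwise complement of their high partner.
    """
    if overrides and archetype in overrides:
        vec = np.asarray(overrides[archetype], dtype=float)
        if vec.shape != (len(POSITIONS),):
            raise ValueError(f"profile for {archetype!r} must have {len(POSITIONS)} entries")
        return vec.copy()
    if archetype in _HIGH_TEMPLATES:
        return _HIGH_TEMPLATES[archetype].copy()
    if archetype.endswith("-low"):
        return 1.0 - archetype_profile(archetype.replace("-low", "-high"), overrides)
    raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated design: 15 patients × 7 positions, block
    depth ~ Poisson(30) reads, between-patient logit-scale SD 0.3, and a
    0.7% bisulfite conversion-failure rate (99.3% conversion).
    """

    seed: int
    n_patients: int = 15
    positions: tuple[str, ...] = POSITIONS
    n_blocks: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_BLOCKS))
    cpgs_per_block: tuple[int, int] = (4, 8)
    depth_mean: float = 30.0
    patient_sd: float = 0.3
    conversion_failure: float = 0.007
    epiallele_meth_rate: float = 0.95
    profile_overrides: Mapping[str, Sequence[float]] | None = None
    contig: str = "chr1"
    cpg_spacing: int = 20
    block_gap: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible cohorts")
        for name, val in (("depth_mean", self.depth_mean),):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("conversion_failure", "epiallele_meth_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        unknown = set(self.n_blocks) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in n_blocks: {sorted(unknown)}")
        lo, hi = self.cpgs_per_block
        if not (1 <= lo <= hi):
            raise ValueError("cpgs_per_block must be an increasing positive range")


@dataclass
class SimCohort:
    """In-memory synthetic cohort plus its generating truth."""

    config: SimConfig
    index: CpGIndex
    blocks: list[Block]
    sample_sheet: pd.DataFrame
    haplotypes: dict[str, list[ReadHaplotype]]
    counts: dict[str, pd.DataFrame]
    truth: pd.DataFrame  # block_id, archetype, m_TC..m_PN


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate one seeded cohort (haplotypes, counts, sample sheet, truth)."""
    total_blocks = sum(config.n_blocks.values())
    if total_blocks == 0 or config.n_patients == 0:
        raise ValueError("need at least one block and one patient")
    rng = np.random.default_rng(config.seed)

    # --- genome layout: blocks of 4-8 CpGs, wide gaps between blocks
    archetypes = [a for a in ARCHETYPES for _ in range(config.n_blocks.get(a, 0))]
    lo, hi = config.cpgs_per_block
    sizes = rng.integers(lo, hi + 1, size=total_blocks)
    positions: list[int] = []
    blocks: list[Block] = []
    cursor, slot = 1000, 0
    for L in sizes:
        pos = [cursor + i * config.cpg_spacing for i in range(L)]
        positions.extend(pos)
        blocks.append(Block(config.contig, slot, slot + int(L) - 1, pos[0], pos[-1] + 2))
        slot += int(L)
        cursor = pos[-1] + config.block_gap
    index = CpGIndex({config.contig: np.asarray(positions, dtype=np.int64)})

    profiles = {
        a: archetype_profile(a, config.profile_overrides)
        for a in dict.fromkeys(archetypes)
    }
    truth = pd.DataFrame({
        "block_id": [b.block_id for b in blocks],
        "archetype": archetypes,
    })
    for j, pos_label in enumerate(config.positions):
        truth[f"m_{pos_label}"] = [profiles[a][j] for a in archetypes]

    # --- sample sheet
    patients = [f"PT{p + 1:02d}" for p in range(config.n_patients)]
    sheet = pd.DataFrame(
        [(f"{pt}_{pos}", pt, pos) for pt in patients for pos in config.positions],
        columns=["sample_id", "patient_id", "position"],
    )

    haplotypes: dict[str, list[ReadHaplotype]] = {s: [] for s in sheet["sample_id"]}
    n_meth = {s: np.zeros(len(positions), dtype=np.int64) for s in sheet["sample_id"]}
    n_tot = {s: np.zeros(len(positions), dtype=np.int64) for s in sheet["sample_id"]}

    for b, arch in zip(blocks, archetypes):
        template = np.clip(profiles[arch], 1e-6, 1 - 1e-6)
        base_logit = logit(template)
        L = b.n_cpg
        for pt in patients:
            u = rng.normal(0.0, config.patient_sd)
            mu = expit(base_logit + u)
            for j, pos_label in enumerate(config.positions):
                sid = f"{pt}_{pos_label}"
                depth = int(rng.poisson(config.depth_mean))
                if depth == 0:
                    continue
                from_meth = rng.random(depth) < mu[j]
                p_m = np.where(from_meth, config.epiallele_meth_rate,
                               1.0 - config.epiallele_meth_rate)
                calls = rng.random((depth, L)) < p_m[:, None]
                if config.conversion_failure > 0:
                    flips = rng.random((depth, L)) < config.conversion_failure
                    calls |= ~calls & flips
                for row in calls:
                    s = "".join("M" if c else "U" for c in row)
                    haplotypes[sid].append(ReadHaplotype(config.contig, b.first_slot, s))
                sl = slice(b.first_slot, b.last_slot + 1)
                n_meth[sid][sl] += calls.sum(axis=0)
                n_tot[sid][sl] += depth

    counts: dict[str, pd.DataFrame] = {}
    pos_arr = np.asarray(positions, dtype=np.int64)
    for sid in sheet["sample_id"]:
        covered = n_tot[sid] > 0
        counts[sid] = pd.DataFrame({
            "contig": config.contig,
            "slot": np.flatnonzero(covered),
            "pos": pos_arr[covered],
            "n_meth": n_meth[sid][covered],
            "n_total": n_tot[sid][covered],
        })
    return SimCohort(config, index, blocks, sheet, haplotypes, counts, truth)


def write_cohort(cohort: SimCohort, out_dir: str | Path) -> Path:
    """Write a cohort in the package's on-disk dialects.

    Layout: ``cpg_index.bed``, ``sample_sheet.tsv`` (with relative paths),
    ``haplotypes/<sample>.tsv``, ``counts/<sample>.tsv``, ``truth.tsv``.
    Returns the path to the sample sheet.
    """
    out = Path(out_dir)
    (out / "haplotypes").mkdir(parents=True, exist_ok=True)
    (out / "counts").mkdir(exist_ok=True)
    cohort.index.to_bed(out / "cpg_index.bed")
    sheet = cohort.sample_sheet.copy()
    sheet["haplotype_path"] = ["haplotypes/" + s + ".tsv" for s in sheet["sample_id"]]
    sheet["counts_path"] = ["counts/" + s + ".tsv" for s in sheet["sample_id"]]
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    for sid in sheet["sample_id"]:
        write_haplotype_table(cohort.haplotypes[sid], out / "haplotypes" / f"{sid}.tsv")
        cohort.counts[sid][["contig", "pos", "n_meth", "n_total"]].to_csv(
            out / "counts" / f"{sid}.tsv", sep="\t", index=False
        )
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out / "sample_sheet.tsv"


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy a config with a different seed (for replicate studies)."""
    return replace(config, seed=seed)
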