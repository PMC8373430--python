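"""Reference CpG indexing, cohort table ingestion with validation, and QC summaries.

Coordinate conventions
----------------------
All genomic coordinates are 0-based; BED output is half-open.  A CpG site is
identified by the position of the C of the CpG dinucleotide on the plus
strand; evidence from the reverse strand is assumed to have been collapsed
onto the plus-strand C upstream of this package (methylation at CpG sites is
symmetric).  Within a contig, CpG sites are addressed by their *slot*: the
0-based rank of the site in the sorted position list.

Read-level methylation calls use the alphabet ``M`` (methylated), ``U``
(unmethylated) and ``.`` (no call).  A ``.`` contributes to no metric and to
no depth.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

POSITIONS = ("TC", "TE", "P5", "P10", "P15", "P20", "PN")
"""The seven sampling positions: tumor core, tumor edge, para-tumor tissue
5/10/15/20 mm beyond the tumor, and peripheral normal tissue."""

CALL_ALPHABET = frozenset("MU.")

_CALLS_RE = re.compile(r"^[MU.]+$")
_SEQ_RE = re.compile(r"^[ACGTNacgtn]*$")


class FormatError(ValueError):
    """Raised when an input file or record violates its documented format."""


# ---------------------------------------------------------------------------
# CpG index


@dataclass(frozen=True)
class CpGIndex:
    """Ordered plus-strand CpG positions per contig.

    ``positions`` maps contig name to a strictly increasing int64 array of
    genomic coordinates of the C of each CpG dinucleotide.
    """

    positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for contig, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise FormatError(f"{contig}: positions must be 1-D")
            if arr.size and (np.any(arr[1:] <= arr[:-1]) or arr[0] < 0):
                raise FormatError(
                    f"{contig}: CpG positions must be nonnegative and strictly increasing"
                )
            clean[contig] = arr
        object.__setattr__(self, "positions", clean)

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def n_sites(self, contig: str) -> int:
        return int(self.positions[contig].size)

    def __len__(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def pos_of(self, contig: str, slot: int) -> int:
        return int(self.positions[contig][slot])

    def slot_of(self, contig: str, pos: int) -> int:
        """Slot of the CpG whose C sits at genomic position ``pos``."""
        arr = self.positions[contig]
        i = int(np.searchsorted(arr, pos))
        if i >= arr.size or arr[i] != pos:
            raise FormatError(f"{contig}:{pos} is not a CpG position in the index")
        return i

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, arr in self.positions.items():
                for p in arr:
                    fh.write(f"{contig}\t{p}\t{p + 2}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "CpGIndex":
        pos: dict[str, list[int]] = {}
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            pos.setdefault(fields[0], []).append(int(fields[1]))
        return cls({c: np.asarray(sorted(v), dtype=np.int64) for c, v in pos.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CpGIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: build_cpg_index(str(fa[name][:])) for name in fa.keys()})


def build_cpg_index(sequence: str) -> np.ndarray:
    """Scan one contig's sequence for plus-strand CpG dinucleotides.

    Returns the sorted array of 0-based positions of each C in a CG pair.
    Case-insensitive; ``N`` is tolerated, any other character is a
    :class:`FormatError`.
    """
    if not _SEQ_RE.match(sequence):
        bad = sorted(set(sequence) - set("ACGTNacgtn"))
        raise FormatError(f"non-nucleotide characters in sequence: {bad!r}")
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(mask).astype(np.int64)


# ---------------------------------------------------------------------------
# Read haplotypes


@dataclass(frozen=True)
class ReadHaplotype:
    """One sequenced fragment's methylation calls over consecutive CpG slots."""

    contig: str
    start_slot: int
    calls: str

    def validate(self, index: CpGIndex) -> None:
        if self.contig not in index.positions:
            raise FormatError(f"unknown contig {self.contig!r}")
        if self.start_slot < 0:
            raise FormatError(f"start_slot {self.start_slot} < 0")
        if not _CALLS_RE.match(self.calls):
            bad = sorted(set(self.calls) - CALL_ALPHABET)
            raise FormatError(f"invalid call symbols {bad!r} (alphabet is M/U/.)")
        if set(self.calls) == {"."}:
            raise FormatError("haplotype has no informative call")
        if self.start_slot + len(self.calls) > index.n_sites(self.contig):
            raise FormatError(
                f"haplotype spans slots {self.start_slot}..{self.start_slot + len(self.calls) - 1} "
                f"but {self.contig} has {index.n_sites(self.contig)} CpGs"
            )

    @property
    def end_slot(self) -> int:
        """Last covered slot, inclusive."""
        return self.start_slot + len(self.calls) - 1


def read_haplotype_table(path: str | Path, index: CpGIndex) -> list[ReadHaplotype]:
    """Load a haplotype TSV (``contig  start_slot  calls``), gzip-transparent.

    Every record is validated against the CpG index; malformed rows are
    reported with their line numbers in a single :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "calls": str}, comment="#")
    required = ["contig", "start_slot", "calls"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    out: list[ReadHaplotype] = []
    errors: list[str] = []
    for i, (contig, slot, calls) in enumerate(
        zip(df["contig"], df["start_slot"], df["calls"])
    ):
        lineno = i + 2  # header is line 1
        try:
            hap = ReadHaplotype(str(contig), int(slot), str(calls))
            hap.validate(index)
        except (FormatError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        out.append(hap)
    if errors:
        shown = "\n".join(errors[:20])
        raise FormatError(f"{path}: {len(errors)} invalid haplotype rows\n{shown}")
    return out


def write_haplotype_table(haplotypes: Iterable[ReadHaplotype], path: str | Path) -> None:
    df = pd.DataFrame(
        [(h.contig, h.start_slot, h.calls) for h in haplotypes],
        columns=["contig", "start_slot", "calls"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-CpG counts and the sample sheet


def read_counts_table(path: str | Path, index: CpGIndex) -> pd.DataFrame:
    """Load a per-CpG count TSV (``contig  pos  n_meth  n_total``) for one sample.

    ``pos`` is the plus-strand C coordinate (Bismark coverage dialect after
    strand collapsing).  Returns a DataFrame with columns
    ``contig, slot, pos, n_meth, n_total`` sorted by coordinate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str}, comment="#")
    required = ["contig", "pos", "n_meth", "n_total"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    errors: list[str] = []
    slots = np.empty(len(df), dtype=np.int64)
    for i, (contig, pos, m, n) in enumerate(
        zip(df["contig"], df["pos"], df["n_meth"], df["n_total"])
    ):
        lineno = i + 2
        try:
            if not (0 <= m <= n):
                raise FormatError(f"counts violate 0 <= n_meth <= n_total ({m}/{n})")
            slots[i] = index.slot_of(str(contig), int(pos))
        except FormatError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        shown = "\n".join(errors[:20])
        raise FormatError(f"{path}: {len(errors)} invalid count rows\n{shown}")
    out = df.loc[:, required].copy()
    out.insert(1, "slot", slots)
    out["n_meth"] = out["n_meth"].astype(np.int64)
    out["n_total"] = out["n_total"].astype(np.int64)
    return out.sort_values(["contig", "slot"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    position: str

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise FormatError(
                f"sample {self.sample_id!r}: position {self.position!r} not in {POSITIONS}"
            )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load and validate the sample sheet.

    Required columns: ``sample_id  patient_id  position``; optional
    ``haplotype_path  counts_path`` (resolved relative to the sheet's
    directory).  Positions must come from the seven-label vocabulary and
    (patient_id, position) pairs must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample_id", "patient_id", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    bad = sorted(set(df["position"]) - set(POSITIONS))
    if bad:
        raise FormatError(f"{path}: unknown position labels {bad}; expected {POSITIONS}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample_id {dup}")
    pp = df[["patient_id", "position"]]
    if pp.duplicated().any():
        dup = pp[pp.duplicated()].to_records(index=False).tolist()
        raise FormatError(f"{path}: duplicated (patient_id, position) pairs {dup}")
    base = Path(path).parent
    for col in ("haplotype_path", "counts_path"):
        if col in df.columns:
            df[col] = [
                str(base / p) if p and not Path(p).is_absolute() else p
                for p in df[col].fillna("")
            ]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCReport:
    """Per-library quality summary.

    ``n_cpg_10x``: CpG slots with read depth >= 10 (a '.' call adds no depth).
    ``n_cgi_10x``: annotated CpG islands whose mean CpG depth is >= 10; None
    when no island annotation was supplied.  ``conversion_rate``: fraction of
    non-CpG cytosine control calls that were converted; None when no control
    counts were supplied (the estimation protocol is lab-specific and is not
    guessed here).
    """

    sample_id: str
    n_cpg_10x: int
    n_cgi_10x: int | None
    conversion_rate: float | None


def depth_by_slot(
    haplotypes: Iterable[ReadHaplotype], index: CpGIndex
) -> dict[str, np.ndarray]:
    """Per-contig read depth at each CpG slot (non-'.' calls only)."""
    depth = {c: np.zeros(index.n_sites(c), dtype=np.int64) for c in index.contigs}
    for h in haplotypes:
        arr = np.frombuffer(h.calls.encode("ascii"), dtype=np.uint8)
        covered = np.flatnonzero(arr != ord("."))
        depth[h.contig][h.start_slot + covered] += 1
    return depth


def qc_summary(
    haplotypes: Iterable[ReadHaplotype],
    index: CpGIndex,
    cgi_annotation: Sequence[tuple[str, int, int]] | None = None,
    *,
    sample_id: str = "",
    control_converted: int | None = None,
    control_total: int | None = None,
    depth_min: int = 10,
) -> QCReport:
    depth = depth_by_slot(haplotypes, index)
    n_cpg = sum(int((d >= depth_min).sum()) for d in depth.values())
    n_cgi: int | None = None
    if cgi_annotation is not None:
        n_cgi = 0
        for contig, start, end in cgi_annotation:
            if contig not in index.positions:
                continue
            pos = index.positions[contig]
            lo, hi = np.searchsorted(pos, [start, end])
            if hi > lo and depth[contig][lo:hi].mean() >= depth_min:
                n_cgi += 1
    rate: float | None = None
    if control_total:
        if control_converted is None or not (0 <= control_converted <= control_total):
            raise FormatError("control_converted must satisfy 0 <= converted <= total")
        rate = control_converted / control_total
    return QCReport(sample_id, n_cpg, n_cgi, rate)


# ---------------------------------------------------------------------------
# Small shared writers


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for lineno, line in enumerate(open(path), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    header_lines: Sequence[str] = (),
    index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write a TSV with optional '#'-prefixed header comments (no timestamps,
    so identical inputs produce identical bytes)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, float_format="%.10g")
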