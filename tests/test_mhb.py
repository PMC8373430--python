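import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methmargin.io import CpGIndex, ReadHaplotype
from methmargin.mhb import (
    METRICS,
    amf,
    block_reads,
    complement,
    haplotype_load,
    pair_r2,
    partition_mhb,
    pdr,
    score_matrix,
)

from _oracles import brute_haplotype_load

call_strings = st.lists(
    st.text(alphabet="MU.", min_size=1, max_size=8), min_size=1, max_size=20
).map(lambda rs: [r.ljust(max(len(x) for x in rs), ".") for r in rs])


# ---------------------------------------------------------------------------
# pair r² and block partitioning


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((5, 0, 0, 5), 1.0),  # perfect linkage
        ((5, 5, 5, 5), 0.0),  # independence
        ((4, 1, 1, 4), 0.36),
    ],
)
def test_pair_r2_values(counts, expected):
    assert pair_r2(*counts) == pytest.approx(expected)


def test_pair_r2_matches_squared_pearson_of_indicators():
    # brute force: expand (4,1,1,4) to its ten paired indicator observations
    a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    b = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
    r = np.corrcoef(a, b)[0, 1]
    assert pair_r2(4, 1, 1, 4) == pytest.approx(r**2)


def test_pair_r2_undefined_cases():
    assert math.isnan(pair_r2(0, 0, 0, 0))  # no reads
    assert math.isnan(pair_r2(2, 1, 0, 1))  # below min_pair_reads
    assert math.isnan(pair_r2(10, 0, 10, 0))  # monomorphic second margin


def _index(n):
    return CpGIndex({"chr1": np.arange(n) * 20 + 100})


def test_partition_one_block_under_perfect_linkage():
    idx = _index(4)
    haps = [ReadHaplotype("chr1", 0, "MMMM")] * 20 + [ReadHaplotype("chr1", 0, "UUUU")] * 20
    blocks = partition_mhb(haps, idx)
    assert len(blocks) == 1
    assert (blocks[0].first_slot, blocks[0].last_slot) == (0, 3)
    assert blocks[0].block_id == "chr1:100:162"


def test_partition_no_block_for_independent_sites():
    idx = _index(4)
    rng = np.random.default_rng(5)
    haps = [
        ReadHaplotype("chr1", 0, "".join("M" if c else "U" for c in rng.random(4) < 0.5))
        for _ in range(200)
    ]
    # with per-site independent calls no adjacent pair should reach r2 = 0.5
    assert partition_mhb(haps, idx) == []


def test_partition_broken_middle_pair_leaves_no_block():
    # linked 0-1 and 2-3 pairs, independent 1-2 pair: runs of 2 CpGs < min 3
    idx = _index(4)
    haps = (
        [ReadHaplotype("chr1", 0, "MM")] * 3
        + [ReadHaplotype("chr1", 0, "UU")] * 3
        + [ReadHaplotype("chr1", 1, "MM")] * 2
        + [ReadHaplotype("chr1", 1, "MU")] * 2
        + [ReadHaplotype("chr1", 1, "UM")] * 2
        + [ReadHaplotype("chr1", 1, "UU")] * 2
        + [ReadHaplotype("chr1", 2, "MM")] * 3
        + [ReadHaplotype("chr1", 2, "UU")] * 3
    )
    assert partition_mhb(haps, idx) == []


def test_partition_blocks_are_disjoint_ordered_and_internally_linked(default_cohort):
    pooled = [h for reads in default_cohort.haplotypes.values() for h in reads]
    blocks = partition_mhb(pooled, default_cohort.index)
    assert blocks, "pooled cohort reads should yield blocks"
    last_end = -1
    from methmargin.mhb import adjacent_pair_counts

    counts = adjacent_pair_counts(pooled, default_cohort.index)
    for b in blocks:
        assert b.first_slot > last_end
        last_end = b.last_slot
        for s in range(b.first_slot, b.last_slot):
            r2 = pair_r2(*counts[b.contig][s])
            assert r2 >= 0.5


# ---------------------------------------------------------------------------
# haplotype loads


@pytest.mark.parametrize(
    "reads, state, exp, expected",
    [
        (["MMM", "MMM"], "M", 1, 1.0),
        (["MUM"], "M", 1, (2 / 3) / 6),
        (["MUM"], "M", 3, (2 / 3) / 36),
        (["UUU"], "U", 1, 1.0),
    ],
)
def test_haplotype_load_worked_examples(reads, state, exp, expected):
    assert haplotype_load(reads, state, exp) == pytest.approx(expected, abs=1e-12)
    assert brute_haplotype_load(reads, state, exp) == pytest.approx(expected, abs=1e-12)


def test_haplotype_load_missing_when_no_eligible_substring():
    assert math.isnan(haplotype_load([".."], "M", 1))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(call_strings)
def test_haplotype_load_matches_brute_force_enumerator(reads):
    for state in "MU":
        for exp in (1, 3):
            got = haplotype_load(reads, state, exp)
            want = brute_haplotype_load(reads, state, exp)
            assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                want, abs=1e-12
            )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(call_strings)
def test_unmethylated_load_is_methylated_load_of_complement(reads):
    for exp in (1, 3):
        u = haplotype_load(reads, "U", exp)
        m = haplotype_load(complement(reads), "M", exp)
        assert (math.isnan(u) and math.isnan(m)) or u == m


def test_loads_bounded_and_extremes():
    reads = ["MMMM"] * 5
    assert haplotype_load(reads, "M", 1) == 1.0
    assert haplotype_load(reads, "U", 1) == 0.0


# ---------------------------------------------------------------------------
# AMF / PDR


@pytest.mark.parametrize(
    "reads, expected",
    [(["MM", "UU"], 0.5), (["M.U", "MMM"], 0.8), (["UUU"], 0.0)],
)
def test_amf_examples(reads, expected):
    assert amf(reads) == pytest.approx(expected)


def test_amf_nondecreasing_when_flipping_u_to_m():
    rng = np.random.default_rng(11)
    reads = ["".join(rng.choice(list("MU."), size=6)) for _ in range(20)]
    reads = [r if set(r) != {"."} else "M....." for r in reads]
    base = amf(reads)
    for i, r in enumerate(reads):
        for j, c in enumerate(r):
            if c == "U":
                flipped = list(reads)
                flipped[i] = r[:j] + "M" + r[j + 1 :]
                assert amf(flipped) >= base


@pytest.mark.parametrize(
    "reads, kwargs, expected",
    [
        (["MMMM", "UUUU"], {}, 0.0),
        (["MUMM", "MMMM"], {}, 0.5),
        (["MUM"], {}, math.nan),  # below the 4-CpG read support floor
        (["MUM"], {"min_read_cpgs": 3}, 1.0),
    ],
)
def test_pdr_examples(reads, kwargs, expected):
    got = pdr(reads, **kwargs)
    assert math.isnan(got) if math.isnan(expected) else got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# score matrix


def test_score_matrix_composes_scalar_metrics(small_index):
    from methmargin.mhb import Block

    block = Block("chr1", 0, 2, 10, 52)
    haps = {
        "s1": [ReadHaplotype("chr1", 0, "MUM")],
        "s2": [ReadHaplotype("chr1", 0, "MMM")],
        "s3": [],
    }
    mat = score_matrix(haps, [block])
    bid = block.block_id
    assert mat.loc[f"MHL|{bid}", "s1"] == pytest.approx((2 / 3) / 6)
    assert mat.loc[f"MHL3|{bid}", "s1"] == pytest.approx((2 / 3) / 36)
    assert mat.loc[f"AMF|{bid}", "s2"] == 1.0
    assert mat.loc[f"UMHL|{bid}", "s2"] == 0.0
    assert mat.loc[f"AMF|{bid}", "s3"] != mat.loc[f"AMF|{bid}", "s3"]  # NaN
    assert set(mat.index) == {f"{m}|{bid}" for m in METRICS}


def test_score_matrix_values_lie_in_unit_interval(default_pipeline):
    vals = default_pipeline.scores.to_numpy()
    finite = vals[~np.isnan(vals)]
    assert finite.min() >= 0.0 and finite.max() <= 1.0


def test_block_reads_pads_partial_overlap(small_index):
    from methmargin.mhb import Block

    block = Block("chr1", 1, 3, 30, 72)
    reads = [
        ReadHaplotype("chr1", 0, "MM"),  # covers slots 0-1 -> "M.."
        ReadHaplotype("chr1", 3, "UM"),  # covers slots 3-4 -> "..U"
        ReadHaplotype("chr1", 4, "MM"),  # entirely outside the block
    ]
    assert block_reads(reads, block) == ["M..", "..U"]
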