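"""Junction microhomology, circularization detection and the nonrandomness
test."""

import numpy as np
import pytest

from circsat._seq import revcomp
from circsat.errors import ParameterError
from circsat.junctions import (Junction, OverlapDistribution,
                               annotate_junctions,
                               detect_circularization_junction,
                               junction_overlap, overlap_distribution)
from circsat.junctions import test_nonrandom as nonrandom_test
from circsat.segmap import (DomainChain, HybridReference, SegmentAlignment,
                            align_segments, chain_domains)


def _seg(mid, q0, q1, contig, t0, t1, strand="+"):
    n = q1 - q0
    return SegmentAlignment(mid, q0, q1, contig, t0, t1, strand,
                            [("=", n)], n, 0, [], [], [])


def make_junction_fixture(rng, k, strand_up="+", strand_down="+",
                          gap=0, insert=""):
    """Build a reference pair sharing exactly a k-mer at the junction and the
    read realizing it once; returns (ref, up, down, read)."""
    A = "".join(rng.choice(list("ACGT"), 1200))
    B = "".join(rng.choice(list("ACGT"), 1200))
    La, Lb = 300, 300
    xa = 600          # upstream domain ends at A[xa] (plus-strand sense)
    yb = 500          # downstream domain starts at B[yb]
    if k:
        B = B[:yb] + A[xa - k:xa] + B[yb + k:]
    ref = {"A": A, "B": B}
    up_seq = A[xa - La:xa] if strand_up == "+" else revcomp(A[xa - La:xa])
    down_seq = B[yb:yb + Lb] if strand_down == "+" else revcomp(B[yb:yb + Lb])
    # realize homology once: read carries up's suffix, not down's prefix copy
    read = A[xa - La:xa] + insert + B[yb + k:yb + Lb]
    hr = HybridReference(ref, "A")
    up = _seg("m", 0, La, "A", xa - La, xa, "+")
    down = _seg("m", La + len(insert), La + len(insert) + Lb - k, "B",
                yb + k, yb + Lb, "+")
    return hr, up, down, read


def oracle_overlap(up, down, read, ref, window=400):
    """Exhaustive check per definition: the maximal run of read bases
    spanning the junction matching both the upstream-locus continuation and
    the downstream-locus preamble, anchored on the two alignments."""
    def up_base(rpos):
        d = rpos - up.q_end
        c = ref.contigs[up.contig]
        if up.strand == "+":
            p = up.t_end + d
            return c[p] if 0 <= p < len(c) else None
        p = up.t_start - 1 - d
        return revcomp(c[p]) if 0 <= p < len(c) else None

    def down_base(rpos):
        d = rpos - down.q_start
        c = ref.contigs[down.contig]
        if down.strand == "+":
            p = down.t_start + d
            return c[p] if 0 <= p < len(c) else None
        p = down.t_end - 1 - d
        return revcomp(c[p]) if 0 <= p < len(c) else None

    lo = max(0, min(up.q_end, down.q_start) - window)
    hi = min(len(read), max(up.q_end, down.q_start) + window)
    both = [up_base(r) == read[r] and down_base(r) == read[r]
            and up_base(r) is not None
            for r in range(lo, hi)]
    # longest all-true run that spans the junction region
    j0, j1 = min(up.q_end, down.q_start), max(up.q_end, down.q_start)
    best = 0
    run_start = None
    for i, ok in enumerate(both + [False]):
        r = lo + i
        if ok and run_start is None:
            run_start = r
        elif not ok and run_start is not None:
            if run_start <= j1 and r >= j0:  # touches the junction
                best = max(best, r - run_start)
            run_start = None
    return best


def test_zero_overlap_junction(rng):
    ref, up, down, read = make_junction_fixture(rng, 0)
    call = junction_overlap(up, down, read, ref)
    assert call.overlap_len == oracle_overlap(up, down, read, ref)
    assert call.inserted_len == 0


def test_repeated_pentamer_overlap(rng):
    """A junction sealed through a shared 5-mer reports that 5-mer."""
    for attempt in range(50):
        r = np.random.default_rng(1000 + attempt)
        ref, up, down, read = make_junction_fixture(r, 5)
        if oracle_overlap(up, down, read, ref) != 5:
            continue  # chance extension beyond the planted 5-mer
        call = junction_overlap(up, down, read, ref)
        assert call.overlap_len == 5
        assert call.overlap_seq == ref.contigs["A"][595:600]
        return
    pytest.fail("no clean fixture found")


def test_nontemplated_insertion_returned(rng):
    ins = "TTAACCGGTTAACCGG"
    for attempt in range(50):
        r = np.random.default_rng(2000 + attempt)
        ref, up, down, read = make_junction_fixture(r, 0, insert=ins)
        call = junction_overlap(up, down, read, ref)
        if call.inserted_len == len(ins):
            assert call.inserted_seq == ins
            assert call.overlap_len == 0
            return
    pytest.fail("insertion never recovered cleanly")


def test_overlap_matches_bruteforce_battery(rng):
    n_checked = 0
    for trial in range(300):
        r = np.random.default_rng(trial)
        k = int(r.integers(0, 30))
        ref, up, down, read = make_junction_fixture(r, k)
        call = junction_overlap(up, down, read, ref)
        assert call.overlap_len == oracle_overlap(up, down, read, ref), \
            f"trial {trial} k={k}"
        n_checked += 1
    assert n_checked == 300


def test_overlap_symmetric_under_reverse_complement(rng):
    """Recomputing on the reverse-complemented monomer with the mirrored
    chain yields identical overlap lengths."""
    for trial in range(30):
        r = np.random.default_rng(3000 + trial)
        k = int(r.integers(0, 20))
        ref, up, down, read = make_junction_fixture(r, k)
        fwd = junction_overlap(up, down, read, ref).overlap_len
        L = len(read)
        rc_read = revcomp(read)
        # mirrored chain: roles swap and strands flip
        up2 = SegmentAlignment("m", L - down.q_end, L - down.q_start,
                               down.contig, down.t_start, down.t_end, "-",
                               down.cigar, down.n_match, 0, [], [], [])
        down2 = SegmentAlignment("m", L - up.q_end, L - up.q_start,
                                 up.contig, up.t_start, up.t_end, "-",
                                 up.cigar, up.n_match, 0, [], [], [])
        assert junction_overlap(up2, down2, rc_read, ref).overlap_len == fwd


# ---------------------------------------------------------------------------
# Circularization junction
# ---------------------------------------------------------------------------

def test_frt_circularization_detected(frt_dataset, frt_analysis):
    for mid, cj in frt_analysis.circ_junctions.items():
        assert cj.junction_class == "circularization"
        assert cj.overlap_len == 48
        assert cj.mediating_repeat == "frt"
    assert len(frt_analysis.circ_junctions) == len(frt_analysis.chains)


def test_single_domain_chain_has_no_circularization(rng):
    ref = HybridReference({"ES": "".join(rng.choice(list("ACGT"), 2000))},
                          "ES")
    ch = DomainChain("m", [_seg("m", 0, 500, "ES", 100, 600)], [], [])
    assert detect_circularization_junction(ch, [], ref) is None


def test_zero_overlap_closure_is_other(rng):
    """A circle closed at unique sequence with no overlap reports no
    mediating repeat."""
    es = "".join(rng.choice(list("ACGT"), 4000))
    ref = HybridReference({"ES": es}, "ES")
    # read jumps from downstream-most end back to upstream-most start
    up = _seg("m", 0, 300, "ES", 3000, 3300)
    down = _seg("m", 300, 600, "ES", 200, 500)
    read = es[3000:3300] + es[200:500]
    ch = DomainChain("m", [up, down], [0], [])
    js = annotate_junctions(ch, read, ref)
    cj = detect_circularization_junction(ch, js, ref)
    assert cj is not None
    assert cj.mediating_repeat == "other"


def test_alu_tail_closure_subannotated(rng):
    """A circle sealed inside the Alu poly-T tail is annotated alu/tail and
    the lost d(T) bases are logged."""
    import pandas as pd
    r = rng
    body_a = "".join(r.choice(list("ACG"), 282))
    alu = body_a + "T" * 29
    left = "".join(r.choice(list("ACG"), 800))
    mid = "".join(r.choice(list("ACG"), 600))
    right = "".join(r.choice(list("ACG"), 800))
    # two alu copies; the junction seals within the shared poly-T tails,
    # deleting 3 T's from the combined run
    es = left + alu + mid + alu + right
    ref = HybridReference({"ES": es}, "ES")
    alu1 = (len(left), len(left) + 311)
    alu2 = (len(left) + 311 + 600, len(left) + 311 + 600 + 311)
    feats = pd.DataFrame([
        {"name": "alu_1", "kind": "alu", "start": alu1[0], "end": alu1[1],
         "strand": "+"},
        {"name": "alu_2", "kind": "alu", "start": alu2[0], "end": alu2[1],
         "strand": "+"},
    ])
    # upstream domain carries 26 of copy-2's 29 tail T's; downstream resumes
    # right after copy-1's tail, so the sealed circle lost 3 d(T) bases and
    # the junction homology is the shared 26-T run
    cut2 = alu2[1] - 3
    cut1 = alu1[1]
    up = _seg("m", 0, 400, "ES", cut2 - 400, cut2)
    down = _seg("m", 400, 800, "ES", cut1, cut1 + 400)
    read = es[cut2 - 400:cut2] + es[cut1:cut1 + 400]
    ch = DomainChain("m", [up, down], [0], [])
    js = annotate_junctions(ch, read, ref)
    cj = detect_circularization_junction(ch, js, ref, feats)
    assert cj is not None
    assert cj.mediating_repeat == "alu"
    assert cj.in_alu_tail
    assert cj.overlap_len == 26           # the shared poly-T homology
    assert cj.tail_deletion == 3          # 2-4 d(T) bases lost at the seal


# ---------------------------------------------------------------------------
# Overlap distributions and nonrandomness
# ---------------------------------------------------------------------------

def _junctions(values, cls="intra_es"):
    return [Junction("c", 0, 1, v, "A" * v, 0, "", cls) for v in values]


def test_distribution_mode_and_mean():
    d = overlap_distribution(_junctions([6] * 10))
    assert d.mode_set == {6}
    assert d.mean == 6


def test_distribution_bimodal_sampling(rng):
    vals = rng.choice([2, 5], size=500).tolist()
    d = overlap_distribution(_junctions(vals))
    assert d.mode_set <= {2, 5}
    hist = d.histogram()
    assert abs(hist[2] - 250) < 60 and abs(hist[5] - 250) < 60


def test_distribution_per_class_split():
    js = _junctions([6] * 30, "intra_es") + _junctions([43, 77, 101] * 5,
                                                       "nonallelic")
    d = overlap_distribution(js)
    assert set(d.per_class) == {"intra_es", "nonallelic"}
    assert max(d.per_class["intra_es"]) == 6
    assert min(d.per_class["nonallelic"]) >= 43
    only_nona = overlap_distribution(js, classes=["nonallelic"])
    assert len(only_nona.values) == 15


def test_empty_distribution():
    d = overlap_distribution([])
    assert d.values == [] and d.mode_set == set()


def test_nonrandom_constant_vs_uniform_null():
    rep = nonrandom_test([14] * 60, null_model=("uniform", 0, 50),
                         n_perm=499, seed=1)
    assert rep["perm_p"] < 0.01
    assert rep["t_p"] < 0.01


def test_nonrandom_degenerate_flags_t_test():
    # both samples constant and equal: zero variance everywhere
    rep = nonrandom_test([7, 7, 7, 7], null_model=("uniform", 7, 7),
                         n_perm=99, seed=2)
    assert rep["t_applicable"] is False
    assert 0 < rep["perm_p"] <= 1


def test_nonrandom_requires_two_observations():
    with pytest.raises(ParameterError):
        nonrandom_test([3])


def test_nonrandom_null_draws_not_significant_typically(rng):
    ps = []
    for i in range(40):
        r = np.random.default_rng(i)
        vals = r.integers(0, 51, 80).tolist()
        ps.append(nonrandom_test(vals, null_model=("uniform", 0, 50),
                                 n_perm=199, seed=7000 + i)["perm_p"])
    assert np.mean(np.asarray(ps) <= 0.05) < 0.2
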