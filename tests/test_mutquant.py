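"""Pileup, mutation-rate, threshold and substitution-signature tests."""

import re
import shutil
import subprocess

import numpy as np
import pytest

from circsat._seq import revcomp
from circsat.errors import CircsatError, ParameterError
from circsat.mutquant import (ReadMutationStats, SIGNATURE_CHANNELS,
                              apply_mutation_threshold, chain_mutation_stats,
                              fold_substitution, mutation_rates,
                              per_kb_deletion_metrics, pileup,
                              rate_table_frame, trinucleotide_signature)
from circsat.pipeline import (ECCDNA_RATE_PRESETS, PipelineParams,
                              SimulationConfig, analyze_reads,
                              mutation_model_from_rates, simulate_dataset)
from circsat.segmap import DomainChain, HybridReference, SegmentAlignment


def _seg(contig, t0, cigar_ops, q0=0, mid="m"):
    """Synthetic segment from explicit ops; event lists derived from them."""
    n_match = n_mis = 0
    mism, ins, dels = [], [], []
    qp, tp = q0, t0
    for op, n, payload in cigar_ops:
        if op == "=":
            n_match += n
            qp += n
            tp += n
        elif op == "X":
            for j in range(n):
                mism.append((tp + j, payload[0], payload[1]))
            n_mis += n
            qp += n
            tp += n
        elif op == "I":
            ins.append((tp, payload))
            qp += n
        else:
            dels.append((tp, n))
            tp += n
    cigar = [(op, n) for op, n, _ in cigar_ops]
    return SegmentAlignment(mid, q0, qp, contig, t0, tp, "+", cigar,
                            n_match, n_mis, mism, ins, dels)


@pytest.fixture()
def small_ref(rng):
    return HybridReference({"ES": "".join(rng.choice(list("ACGT"), 2000))},
                          "ES")


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def test_single_deletion_event_counts(small_ref):
    seg = _seg("ES", 100, [("=", 50, None), ("D", 3, None), ("=", 50, None)])
    ch = DomainChain("m", [seg], [], [])
    p = pileup([ch], small_ref)
    t = p.totals()
    assert t["del_events"] == 1 and t["del_nt"] == 3
    assert t["aligned_bp"] == 103
    col = next(c for c in p.columns() if c.position == 150)
    assert col.del_event_starts == 1 and col.deleted_coverage == 1


def test_pileup_totals_equal_event_log_sums(small_ref, rng):
    """Column tallies equal an independent summation over each read's
    event list (conservation)."""
    chains = []
    want = {"mismatches": 0, "del_events": 0, "del_nt": 0,
            "ins_events": 0, "ins_nt": 0}
    for i in range(5):
        ops = [("=", 40, None)]
        for _ in range(int(rng.integers(1, 4))):
            kind = rng.choice(["X", "I", "D"])
            if kind == "X":
                ops += [("X", 1, ("A", "G")), ("=", 30, None)]
                want["mismatches"] += 1
            elif kind == "I":
                L = int(rng.integers(1, 5))
                ops += [("I", L, "T" * L), ("=", 30, None)]
                want["ins_events"] += 1
                want["ins_nt"] += L
            else:
                L = int(rng.integers(1, 8))
                ops += [("D", L, None), ("=", 30, None)]
                want["del_events"] += 1
                want["del_nt"] += L
        chains.append(DomainChain(f"m{i}",
                                  [_seg("ES", 100 + 13 * i, ops,
                                        mid=f"m{i}")], [], []))
    t = pileup(chains, small_ref).totals()
    for k, v in want.items():
        assert t[k] == v, k


def test_pileup_requires_edit_operations(small_ref):
    seg = _seg("ES", 100, [("=", 50, None)])
    seg.cigar = []
    ch = DomainChain("m", [seg], [], [])
    with pytest.raises(CircsatError):
        pileup([ch], small_ref)


@pytest.mark.skipif(shutil.which("samtools") is None,
                    reason="samtools not on PATH")
def test_pileup_matches_samtools_mpileup(tmp_path):
    """Per-event totals agree with an external pileup of the same SAM."""
    from circsat import segmap
    from circsat.refsim import MutationModel, write_fasta
    mm = MutationModel(mismatch_rate=3e-5, del_event_rate=8e-6,
                       del_len_mean=10.9, ins_event_rate=7e-6,
                       ins_len_mean=2.3, generations=200)
    cfg = SimulationConfig(seed=21, n_circles=5, reads_per_circle=1,
                           n_domains=1, mutation_model=mm,
                           monomers_per_read={1: 1.0}, n_donors=0)
    b = simulate_dataset(cfg)
    res = analyze_reads(b.reads, b.reference, b.fwd, b.rev,
                        PipelineParams(generations=200),
                        site_table=b.site_table)
    seqs = {m.monomer_id: m.sequence for m in res.monomers}
    sam = tmp_path / "chains.sam"
    segmap.write_sam(list(res.chains.values()), seqs, b.reference, sam)
    fa = tmp_path / "ref.fa"
    write_fasta(fa, b.contigs.items())
    subprocess.run(["samtools", "faidx", str(fa)], check=True)
    sorted_sam = tmp_path / "sorted.sam"
    subprocess.run(["samtools", "sort", "-O", "sam", "-o", str(sorted_sam),
                    str(sam)], check=True)
    out = subprocess.run(
        ["samtools", "mpileup", "-f", str(fa), "-B", "-Q", "0",
         "-d", "10000", str(sorted_sam)],
        capture_output=True, text=True, check=True)

    def parse(s):
        mis = dels = ins = 0
        i = 0
        while i < len(s):
            c = s[i]
            if c == "^":
                i += 2
                continue
            if c == "$":
                i += 1
                continue
            if c in "+-":
                m = re.match(r"[+-](\d+)", s[i:])
                n = int(m.group(1))
                ins += c == "+"
                dels += c == "-"
                i += m.end() + n
                continue
            if c in "ACGTNacgtn":
                mis += 1
            i += 1
        return mis, dels, ins

    M = D = I = 0
    for ln in out.stdout.strip().split("\n"):
        m, d, i = parse(ln.split("\t")[4])
        M += m
        D += d
        I += i
    t = res.pile.totals()
    assert (M, D, I) == (t["mismatches"], t["del_events"], t["ins_events"])


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------

def test_rate_arithmetic():
    totals = {"mismatches": 100, "del_events": 0, "del_nt": 0,
              "ins_events": 0, "ins_nt": 0}
    r = mutation_rates(totals, aligned_bp=5_000_000, generations=200)
    assert r.A == pytest.approx(1.0e-7)
    assert np.isnan(r.D) and np.isnan(r.G)
    assert r.H == pytest.approx(r.A)


@pytest.mark.parametrize("preset,ratio,want", [
    ("CAG102_c10", "D", 10.9),   # deleted nucleotides per deletion event
    ("G4_c6", "G", 2.5),         # inserted nucleotides per insertion event
])
def test_published_rate_ratios(preset, ratio, want):
    """The per-event ratios recomputed from the published event and
    nucleotide rates round to the printed values."""
    p = ECCDNA_RATE_PRESETS[preset]
    bp, gens = 10**7, int(p["generations"])
    denom = bp * gens
    totals = {"mismatches": p["A"] * denom, "del_events": p["B"] * denom,
              "del_nt": p["C"] * denom, "ins_events": p["E"] * denom,
              "ins_nt": p["F"] * denom}
    r = mutation_rates(totals, aligned_bp=bp, generations=gens)
    assert round(getattr(r, ratio), 1) == want


def test_generation_scaling():
    totals = {"mismatches": 50, "del_events": 10, "del_nt": 100,
              "ins_events": 8, "ins_nt": 20}
    r1 = mutation_rates(totals, aligned_bp=10**6, generations=100)
    r2 = mutation_rates(totals, aligned_bp=10**6, generations=200)
    for k in "ABCEF":
        assert getattr(r2, k) == pytest.approx(getattr(r1, k) / 2)
    for k in "DG":
        assert getattr(r2, k) == pytest.approx(getattr(r1, k))
    assert r1.D == pytest.approx(r1.C / r1.B)
    assert r1.G == pytest.approx(r1.F / r1.E)


def test_rate_table_frame_layout():
    totals = {"mismatches": 50, "del_events": 10, "del_nt": 100,
              "ins_events": 8, "ins_nt": 20}
    r = mutation_rates(totals, aligned_bp=10**6, generations=100)
    df = rate_table_frame({"c10": r, "c13": r})
    assert list(df.columns) == ["c10", "c13"]
    assert df.index[0].startswith("A. Mismatches")
    assert df.index[-1].startswith("H. Indels + Substitutions")


def test_bad_generations():
    with pytest.raises(ParameterError):
        mutation_rates({"mismatches": 0, "del_events": 0, "del_nt": 0,
                        "ins_events": 0, "ins_nt": 0}, aligned_bp=100,
                       generations=0)


# ---------------------------------------------------------------------------
# Per-kb deletion metrics
# ---------------------------------------------------------------------------

def test_per_kb_deletion_metrics():
    totals = {"del_nt": 84, "del_events": 10}
    assert per_kb_deletion_metrics(totals, aligned_bp=10_000) == (8.4, 1.0)
    zero = {"del_nt": 0, "del_events": 0}
    assert per_kb_deletion_metrics(zero, aligned_bp=10_000) == (0.0, 0.0)


def test_polh_style_contrast_deeper_but_not_more_deletions(rng):
    """Doubling deletion length at constant event rate raises deleted
    bases/kb while leaving deletion events/kb essentially unchanged."""
    out = {}
    for name, dlen in (("control", 5.0), ("depleted", 10.0)):
        from circsat.refsim import MutationModel
        mm = MutationModel(del_event_rate=8e-6, del_len_mean=dlen,
                           generations=200)
        cfg = SimulationConfig(seed=31, n_circles=150, reads_per_circle=1,
                               n_domains=1, mutation_model=mm,
                               monomers_per_read={1: 1.0}, n_donors=0)
        b = simulate_dataset(cfg)
        res = analyze_reads(b.reads, b.reference, b.fwd, b.rev,
                            PipelineParams(generations=200),
                            site_table=b.site_table)
        out[name] = per_kb_deletion_metrics(res.pile.totals())
    assert out["depleted"][0] > out["control"][0] * 1.5
    assert abs(out["depleted"][1] - out["control"][1]) \
        < 0.25 * out["control"][1]


# ---------------------------------------------------------------------------
# Per-read threshold
# ---------------------------------------------------------------------------

def test_threshold_boundary_cases():
    low = ReadMutationStats("a", 1, 1000)    # 1 mutation/kb -> removed
    high = ReadMutationStats("b", 5, 1000)   # 5 mutations/kb -> kept
    kept, removed = apply_mutation_threshold([low, high], 2.0)
    assert [s.read_id for s in kept] == ["b"]
    assert [s.read_id for s in removed] == ["a"]


def test_threshold_fixture_counts(rng):
    stats = [ReadMutationStats(f"lo{i}", int(rng.integers(0, 2)), 1000)
             for i in range(18)]
    stats += [ReadMutationStats(f"hi{i}", int(rng.integers(3, 9)), 1000)
              for i in range(32)]
    kept, removed = apply_mutation_threshold(stats, 2.0)
    assert len(kept) == 32 and len(removed) == 18


def test_threshold_negative_rejected():
    with pytest.raises(ParameterError):
        apply_mutation_threshold([], -1)


# ---------------------------------------------------------------------------
# Trinucleotide signatures
# ---------------------------------------------------------------------------

def _fold_oracle(five, ref, alt, three):
    """Independent complement-enumeration folding."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return (f"{comp[three]}[{comp[ref]}>{comp[alt]}]{comp[five]}")


def test_fold_covers_all_192_raw_combinations():
    seen = set()
    for five in "ACGT":
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                for three in "ACGT":
                    got = fold_substitution(five, ref, alt, three)
                    assert got is not None
                    assert got[0] == _fold_oracle(five, ref, alt, three)
                    seen.add(got[0])
    assert seen == set(SIGNATURE_CHANNELS)
    assert len(SIGNATURE_CHANNELS) == 96


def test_signature_single_call(small_ref):
    es = small_ref.contigs["ES"]
    pos = next(i for i in range(1, len(es) - 1) if es[i] == "C")
    sig = trinucleotide_signature([("ES", pos, "C", "T", 1)], small_ref)
    channel = f"{es[pos-1]}[C>T]{es[pos+1]}"
    assert sig.counts[channel] == 1
    assert sig.total == 1
    assert sig.class_marginals["C>T"] == 1


def test_signature_purine_folding(small_ref):
    es = small_ref.contigs["ES"]
    pos = next(i for i in range(1, len(es) - 1) if es[i] == "G")
    sig = trinucleotide_signature([("ES", pos, "G", "A", 2)], small_ref)
    channel = _fold_oracle(es[pos - 1], "G", "A", es[pos + 1])
    assert sig.counts[channel] == 2
    assert sig.class_marginals["C>T"] == 2


def test_signature_counts_sum_and_edge_skip(small_ref, rng):
    es = small_ref.contigs["ES"]
    calls = [("ES", 0, es[0], "A" if es[0] != "A" else "C", 1)]  # edge
    n_good = 0
    for _ in range(50):
        pos = int(rng.integers(1, len(es) - 1))
        ref = es[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        calls.append(("ES", pos, ref, alt, 1))
        n_good += 1
    sig = trinucleotide_signature(calls, small_ref)
    assert sig.total == n_good
    assert sig.skipped_edge == 1
    assert sig.fractions.sum() == pytest.approx(1.0)


def test_ct_dominated_fixture_elevates_ct_marginal(small_ref, rng):
    """A C/G>T/A-dominated call set yields an elevated C>T class marginal
    (the deamination-like readout)."""
    es = small_ref.contigs["ES"]
    calls = []
    for pos in range(1, len(es) - 1):
        if es[pos] == "C" and rng.random() < 0.3:
            calls.append(("ES", pos, "C", "T", 1))
        elif es[pos] == "G" and rng.random() < 0.3:
            calls.append(("ES", pos, "G", "A", 1))
        elif rng.random() < 0.02:
            alt = str(rng.choice([b for b in "ACGT" if b != es[pos]]))
            calls.append(("ES", pos, es[pos], alt, 1))
    sig = trinucleotide_signature(calls, small_ref)
    marg = sig.class_marginals
    assert marg["C>T"] > 0.6 * marg.sum()


def test_chain_mutation_stats():
    seg = _seg("ES", 100, [("=", 400, None), ("X", 1, ("A", "G")),
                           ("=", 99, None), ("D", 4, None),
                           ("=", 200, None), ("I", 2, "AT"),
                           ("=", 300, None)])
    ch = DomainChain("m", [seg], [], [])
    st = chain_mutation_stats(ch)
    assert st.mutations == 3
    assert st.aligned_bp == 400 + 1 + 99 + 4 + 200 + 300
    assert st.per_kb == pytest.approx(3 * 1000 / st.aligned_bp)
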