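"""Microhomology at template-switch and circularization junctions.

The overlap at a junction is measured in reference space: it is the maximal
block of read bases spanning the junction that aligns exactly both to the
reference continuation of the upstream donor locus and to the reference
sequence preceding the downstream donor locus — sequence shared by the two
loci but realized once in the read.  Read bases between the two mapped
segments matching neither flank are a nontemplated insertion; a junction
carries either an overlap or an insertion (when flanking micro-overlap and
insertion co-occur, the larger feature classifies the junction and both are
recorded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._seq import revcomp
from .errors import ParameterError
from .segmap import DomainChain, HybridReference, SegmentAlignment


def _flank_after(seg: SegmentAlignment, ref: HybridReference, i: int) -> str:
    """Reference base i positions past the segment's 3' (read-order) end."""
    c = ref.contigs[seg.contig]
    if seg.strand == "+":
        p = seg.t_end + i
        return c[p] if 0 <= p < len(c) else ""
    p = seg.t_start - 1 - i
    return revcomp(c[p]) if 0 <= p < len(c) else ""


def _flank_before(seg: SegmentAlignment, ref: HybridReference, i: int) -> str:
    """Reference base i positions before the segment's 5' (read-order) start."""
    c = ref.contigs[seg.contig]
    if seg.strand == "+":
        p = seg.t_start - 1 - i
        return c[p] if 0 <= p < len(c) else ""
    p = seg.t_end + i
    return revcomp(c[p]) if 0 <= p < len(c) else ""


@dataclass
class JunctionCall:
    overlap_len: int
    overlap_seq: str
    inserted_len: int
    inserted_seq: str


def junction_overlap(up: SegmentAlignment, down: SegmentAlignment,
                     monomer_seq: str, ref: HybridReference,
                     max_extend: int = 400) -> JunctionCall:
    """Microhomology overlap (or nontemplated insertion) between two
    query-adjacent domains of one chain, by bidirectional extension in
    reference space."""
    j_u, j_d = up.q_end, down.q_start
    # how far the read continues to match the upstream locus past its end
    h_right = 0
    while h_right < max_extend:
        qpos = j_u + h_right
        b = _flank_after(up, ref, h_right)
        if not b or qpos >= len(monomer_seq) or monomer_seq[qpos] != b:
            break
        h_right += 1
    # how far the read matches the downstream locus before its start
    h_left = 0
    while h_left < max_extend:
        qpos = j_d - 1 - h_left
        b = _flank_before(down, ref, h_left)
        if not b or qpos < 0 or monomer_seq[qpos] != b:
            break
        h_left += 1
    if j_d <= j_u:  # aligner already double-mapped o = j_u - j_d bases
        o = j_u - j_d
        start, end = j_d - h_left, j_u + h_right
        return JunctionCall(o + h_left + h_right,
                            monomer_seq[start:end], 0, "")
    gap = j_d - j_u
    if h_left + h_right >= gap:
        ov = h_left + h_right - gap
        start = j_d - h_left
        return JunctionCall(ov, monomer_seq[start:start + ov], 0, "")
    ins = monomer_seq[j_u + h_right:j_d - h_left]
    return JunctionCall(0, "", len(ins), ins)


@dataclass
class Junction:
    chain_id: str
    up_index: int
    down_index: int
    overlap_len: int
    overlap_seq: str
    inserted_len: int
    inserted_seq: str
    junction_class: str            # intra_es | nonallelic | circularization
    mediating_repeat: str | None = None   # frt | alu | other
    in_alu_tail: bool = False
    tail_deletion: int | None = None


def annotate_junctions(chain: DomainChain, monomer_seq: str,
                       ref: HybridReference) -> list[Junction]:
    """Compute the overlap call for every junction of a chain and classify
    it by the contigs it joins."""
    out = []
    es = ref.es_contig_name
    for i, (a, b) in enumerate(zip(chain.domains, chain.domains[1:])):
        call = junction_overlap(a, b, monomer_seq, ref)
        jclass = ("nonallelic" if (a.contig != es or b.contig != es)
                  else "intra_es")
        out.append(Junction(chain.monomer_id, i, i + 1, call.overlap_len,
                            call.overlap_seq, call.inserted_len,
                            call.inserted_seq, jclass))
    return out


def detect_circularization_junction(
        chain: DomainChain, junctions: list[Junction],
        ref: HybridReference,
        features: pd.DataFrame | None = None) -> Junction | None:
    """Identify the circle-closing junction of a monomer chain.

    In inverse-PCR geometry the amplicon traverses every junction of the
    eccDNA except the unamplified primer gap, and the sealed fragment ends
    are the downstream-most domain end joined back to the upstream-most
    domain start.  The circularization junction is therefore the junction
    between ectopic-site domains with the maximal backward jump in
    ectopic-site coordinates.  Its ``mediating_repeat`` is the annotated
    feature (frt / alu) containing the majority of the overlap, with the Alu
    poly-T tail sub-annotated and its base loss logged.
    """
    if len(chain.domains) < 2:
        return None
    es = ref.es_contig_name
    best, best_jump = None, 0
    for j in junctions:
        up, down = chain.domains[j.up_index], chain.domains[j.down_index]
        if up.contig != es or down.contig != es:
            continue
        up_end = up.t_end if up.strand == "+" else up.t_start
        down_start = down.t_start if down.strand == "+" else down.t_end
        jump = up_end - down_start
        if jump > best_jump:
            best, best_jump = j, jump
    if best is None:
        return None
    best.junction_class = "circularization"
    if features is not None:
        _annotate_mediator(best, chain, features)
    else:
        best.mediating_repeat = "other"
    return best


def _annotate_mediator(j: Junction, chain: DomainChain,
                       features: pd.DataFrame) -> None:
    up = chain.domains[j.up_index]
    k = j.overlap_len
    if k <= 0:
        j.mediating_repeat = "other"
        return
    # overlap interval in reference space, taken at the upstream locus
    if up.strand == "+":
        ov = (up.t_end - k, up.t_end)
    else:
        ov = (up.t_start, up.t_start + k)
    j.mediating_repeat = "other"
    for _, r in features.iterrows():
        if r["kind"] not in ("frt", "alu"):
            continue
        inter = min(ov[1], r["end"]) - max(ov[0], r["start"])
        if inter > k / 2:
            j.mediating_repeat = r["kind"]
            if r["kind"] == "alu":
                tail_start = r["end"] - 29
                if ov[0] >= tail_start:
                    j.in_alu_tail = True
                    # poly-T bases lost at the seal: reference run length
                    # minus the run observed in the read around the junction
                    run = len(j.overlap_seq) - len(j.overlap_seq.rstrip("T"))
                    ref_run = 29
                    j.tail_deletion = max(0, ref_run - _read_t_run(
                        j.overlap_seq))
            break


def _read_t_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "T" else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Overlap-length distributions and the nonrandomness test
# ---------------------------------------------------------------------------

@dataclass
class OverlapDistribution:
    values: list[int]
    per_class: dict[str, list[int]]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def mode_set(self) -> set[int]:
        if not self.values:
            return set()
        counts = pd.Series(self.values).value_counts()
        top = counts.max()
        return set(counts[counts == top].index)

    def histogram(self) -> pd.Series:
        return pd.Series(self.values, dtype=int).value_counts().sort_index()


def overlap_distribution(junctions: Iterable[Junction],
                         classes: Sequence[str] | None = None,
                         ) -> OverlapDistribution:
    """Multiset of overlap lengths, one event per junction (a read with
    several template switches contributes several events)."""
    values, per_class = [], {}
    for j in junctions:
        if classes is not None and j.junction_class not in classes:
            continue
        if j.overlap_len < 0:
            continue
        values.append(j.overlap_len)
        per_class.setdefault(j.junction_class, []).append(j.overlap_len)
    return OverlapDistribution(values, per_class)


def test_nonrandom(dist: OverlapDistribution | Sequence[int],
                   null_model: tuple[str, float, float] | None = None,
                   n_perm: int = 999, seed: int = 1729) -> dict:
    """Test observed overlap lengths against a seeded random null array.

    Computes the two-sample Student's t statistic against a random array
    drawn from ``null_model`` (default: uniform integers on [0, max
    observed]), plus a label-permutation p-value on the absolute mean
    difference, which is the recommended primary result.  The report records
    the null-model parameters and seed.  A zero-variance degenerate case
    flags the t-test inapplicable; the permutation result is still returned.
    """
    values = np.asarray(dist.values if isinstance(dist, OverlapDistribution)
                        else dist, dtype=float)
    if values.size < 2:
        raise ParameterError("need >= 2 observations")
    if null_model is None:
        null_model = ("uniform", 0.0, float(values.max()))
    kind, lo, hi = null_model
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        null = rng.integers(int(lo), int(hi) + 1, size=values.size).astype(float)
    elif kind == "normal":
        null = rng.normal(lo, hi, size=values.size)
    else:
        raise ParameterError(f"unknown null model {kind!r}")
    degenerate = values.std() == 0 and null.std() == 0
    if degenerate:
        t_stat, t_p = float("nan"), float("nan")
    else:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, t_p = sps.ttest_ind(values, null, equal_var=False)
    pooled = np.concatenate([values, null])
    obs = abs(values.mean() - null.mean())
    n = values.size
    perm = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(pooled)
        perm[i] = abs(pooled[:n].mean() - pooled[n:].mean())
    perm_p = (1.0 + np.sum(perm >= obs)) / (n_perm + 1.0)
    return {
        "n": int(n),
        "t_stat": float(t_stat),
        "t_p": float(t_p),
        "t_applicable": not degenerate,
        "perm_p": float(perm_p),
        "n_perm": int(n_perm),
        "null_model": {"kind": kind, "lo": float(lo), "hi": float(hi)},
        "seed": int(seed),
    }


def junction_table(junctions: Iterable[Junction]) -> pd.DataFrame:
    rows = [{
        "chain": j.chain_id, "class": j.junction_class,
        "up": j.up_index, "down": j.down_index,
        "overlap_len": j.overlap_len, "overlap_seq": j.overlap_seq,
        "inserted_len": j.inserted_len, "inserted_seq": j.inserted_seq,
        "mediating_repeat": j.mediating_repeat or "",
        "in_alu_tail": j.in_alu_tail,
    } for j in junctions]
    return pd.DataFrame(rows, columns=[
        "chain", "class", "up", "down", "overlap_len", "overlap_seq",
        "inserted_len", "inserted_seq", "mediating_repeat", "in_alu_tail"])
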