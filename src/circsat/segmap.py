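"""Align monomers to the hybrid reference and chain template-switch domains.

A monomer that underwent template switching maps as several local segments
that are contiguous in the read but discontiguous in the reference.  The
internal aligner is an exact-seed (k=15) + extension design: seed matches are
clustered by diagonal, extended with banded edit-distance alignment (edlib)
and trimmed at the position of maximal local score, then finalized with a
global alignment of the chosen spans so every segment carries full edit
operations.  Alignments from external mappers can be imported from SAM or
PAF instead.

Chaining selects the maximal-score, query-colinear subset of segments by
dynamic programming; adjacent selected segments may overlap on the query by
up to the microhomology allowance.  After selection the double-mapped
microhomology bases are assigned to the upstream domain.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import CircsatError, ParameterError, ValidationError

SEED_K = 15
MAX_SEED_OCC = 12       # skip seeds from low-complexity / repeat saturation
                        # (poly-T tails and microsatellite units far exceed
                        # this; genuine repeat copies stay well under it)
CLUSTER_DIAG_BAND = 250  # tolerated diagonal drift (absorbs indels)
CLUSTER_MAX_QGAP = 100   # below any plausible domain length: a longer seed
                         # desert means a template switch, not mutations
EXT_WINDOW = 2000
EXT_MATCH, EXT_MISMATCH = 1, -2
EXT_GAP_OPEN, EXT_GAP_EXT = 4.0, 0.5   # affine: long deletions stay cheap
EXT_XDROP = 40.0                       # stop once score falls this far below
                                       # the running maximum (junction break)


class HybridReference:
    """Named contigs (ectopic-site contig + host/donor contigs) with a seed
    index for the internal aligner."""

    def __init__(self, contigs: dict[str, str], es_contig_name: str,
                 seed_k: int = SEED_K):
        if es_contig_name not in contigs:
            raise ValidationError(
                f"es_contig_name {es_contig_name!r} not among contigs")
        if not contigs:
            raise ValidationError("empty reference")
        self.contigs = {n: s.upper() for n, s in contigs.items()}
        self.es_contig_name = es_contig_name
        self.seed_k = seed_k
        self._index: dict[str, list[tuple[str, int]]] | None = None
        self._es_kmers: dict[int, set[str]] = {}

    @classmethod
    def from_fasta(cls, path, es_contig_name: str) -> "HybridReference":
        from Bio import SeqIO
        contigs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs, es_contig_name)

    @property
    def index(self) -> dict[str, list[tuple[str, int]]]:
        if self._index is None:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            k = self.seed_k
            for name, seq in self.contigs.items():
                for i in range(len(seq) - k + 1):
                    idx[seq[i:i + k]].append((name, i))
            self._index = idx
        return self._index

    def es_kmers(self, k: int) -> set[str]:
        """All k-mers of the ectopic-site contig, both strands (cached)."""
        if k not in self._es_kmers:
            es = self.contigs[self.es_contig_name]
            kmers = {es[i:i + k] for i in range(len(es) - k + 1)}
            rc = revcomp(es)
            kmers |= {rc[i:i + k] for i in range(len(rc) - k + 1)}
            self._es_kmers[k] = kmers
        return self._es_kmers[k]


@dataclass
class SegmentAlignment:
    """One local alignment of a monomer segment to one reference locus.

    Query coordinates are always on the original (orientation-normalized)
    monomer; the cigar runs along the forward target strand, i.e. along the
    reverse-complemented monomer for strand "-".
    """

    monomer_id: str
    q_start: int
    q_end: int
    contig: str
    t_start: int
    t_end: int
    strand: str
    cigar: list[tuple[str, int]]           # ops in {=, X, I, D}
    n_match: int
    n_mismatch: int
    mismatches: list[tuple[int, str, str]]  # (target pos, ref base, read base)
    insertions: list[tuple[int, str]]       # (anchor target pos, inserted seq)
    deletions: list[tuple[int, int]]        # (target pos, length)

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def gap_cols(self) -> int:
        return sum(n for op, n in self.cigar if op in "ID")

    @property
    def aln_cols(self) -> int:
        return sum(n for op, n in self.cigar if op != "")

    @property
    def identity(self) -> float:
        cols = self.aln_cols
        return self.n_match / cols if cols else 0.0

    @property
    def score(self) -> int:
        return self.n_match - self.n_mismatch - self.gap_cols

    def is_nonallelic(self, es_name: str) -> bool:
        return self.contig != es_name

    @property
    def copy_direction(self) -> str:
        """Direction of copying along the donor chromosome: coordinates
        increase p->q, so a plus-strand domain is copied p->q and a
        minus-strand domain q->p."""
        return "p->q" if self.strand == "+" else "q->p"


def _cigar_from_str(s: str) -> list[tuple[str, int]]:
    out, num = [], ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _cigar_to_str(cig: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cig)


def _collect_seed_clusters(q: str, ref: HybridReference):
    k = ref.seed_k
    idx = ref.index
    clusters: list[dict] = []
    for qpos in range(0, len(q) - k + 1):
        hits = idx.get(q[qpos:qpos + k])
        if not hits or len(hits) > MAX_SEED_OCC:
            continue
        for contig, tpos in hits:
            diag = tpos - qpos
            placed = False
            for cl in reversed(clusters):
                if (cl["contig"] == contig
                        and 0 <= qpos - cl["last_q"] <= CLUSTER_MAX_QGAP
                        and tpos >= cl["last_t"]
                        and abs(diag - cl["last_diag"]) <= CLUSTER_DIAG_BAND):
                    cl["last_q"], cl["last_t"], cl["last_diag"] = qpos, tpos, diag
                    cl["q1"], cl["t1"] = qpos + k, tpos + k
                    cl["n"] += 1
                    placed = True
                    break
            if not placed:
                clusters.append(dict(contig=contig, q0=qpos, t0=tpos,
                                     q1=qpos + k, t1=tpos + k, last_q=qpos,
                                     last_t=tpos, last_diag=diag, n=1))
    return clusters


def _walk_best_prefix(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    """Consumed (query, target) lengths at the maximal-score prefix.

    Match/mismatch are walked per base so the cut can land inside a run; the
    walk aborts (X-drop) once the score falls EXT_XDROP below its running
    maximum, which stops extension at template-switch boundaries while still
    crossing ordinary indels (affine gap cost keeps long deletions cheap).
    """
    best, best_qt = 0.0, (0, 0)
    score, qc, tc = 0.0, 0, 0
    for op, n in cigar:
        if op in "=X":
            step = EXT_MATCH if op == "=" else EXT_MISMATCH
            for _ in range(n):
                score += step
                qc += 1
                tc += 1
                if score > best:
                    best, best_qt = score, (qc, tc)
                if score < best - EXT_XDROP:
                    return best_qt
        else:
            score -= EXT_GAP_OPEN + EXT_GAP_EXT * n
            if op == "I":
                qc += n
            else:
                tc += n
            if score < best - EXT_XDROP:
                return best_qt
    return best_qt


def _extend(q: str, t: str, qpos: int, tpos: int, direction: int,
            ) -> tuple[int, int]:
    """Maximal-local-score extension from (qpos, tpos); returns consumed
    (query, target) lengths in the given direction."""
    if direction > 0:
        qs = q[qpos:qpos + EXT_WINDOW]
        ts = t[tpos:tpos + EXT_WINDOW + 200]
    else:
        qs = q[max(0, qpos - EXT_WINDOW):qpos][::-1]
        ts = t[max(0, tpos - EXT_WINDOW - 200):tpos][::-1]
    if not qs or not ts:
        return 0, 0
    res = edlib.align(qs, ts, mode="SHW", task="path")
    return _walk_best_prefix(_cigar_from_str(res["cigar"]))


MERGE_WINDOW = 15   # '=' runs up to this length join neighbouring events
AFFINE_MISMATCH, AFFINE_OPEN, AFFINE_EXT = 4.0, 6.0, 1.0
MAX_REALIGN = 500    # clusters beyond this size keep the minimal-edit path


def _interleave(qs: str, ts: str) -> list[tuple[str, int]]:
    """Run-length =/X comparison of two equal-length strings."""
    out: list[tuple[str, int]] = []
    for a, b in zip(qs, ts):
        op = "=" if a == b else "X"
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _affine_realign(qs: str, ts: str) -> list[tuple[str, int]] | None:
    """Global alignment with affine gap penalties (Gotoh), so one biological
    indel is one contiguous run rather than the fragmented equal-cost path a
    unit-cost aligner may emit.  Returns run-length ops or None if the
    window is too large."""
    a, b = len(qs), len(ts)
    if a > MAX_REALIGN or b > MAX_REALIGN:
        return None
    INF = 1e9
    qa = np.frombuffer(qs.encode(), dtype=np.uint8)
    ta = np.frombuffer(ts.encode(), dtype=np.uint8)
    jj = np.arange(b + 1, dtype=np.float64)
    M = np.full((a + 1, b + 1), INF)
    D = np.full((a + 1, b + 1), INF)   # gap consuming target
    I = np.full((a + 1, b + 1), INF)   # gap consuming query
    M[0, 0] = 0.0
    D[0, 1:] = AFFINE_OPEN + AFFINE_EXT * jj[1:]
    for i in range(1, a + 1):
        I[i, :] = np.minimum(M[i - 1, :] + AFFINE_OPEN + AFFINE_EXT,
                             I[i - 1, :] + AFFINE_EXT)
        sub = np.where(ta != qa[i - 1], AFFINE_MISMATCH, 0.0)
        prev = np.minimum(np.minimum(M[i - 1, :-1], D[i - 1, :-1]),
                          I[i - 1, :-1])
        M[i, 1:] = sub + prev
        # D row: open once from some M[i, l] (or I[i, l]) and extend
        base = np.minimum(M[i, :], I[i, :]) + AFFINE_OPEN - AFFINE_EXT * jj
        D[i, :] = AFFINE_EXT * jj + np.minimum.accumulate(base)
        D[i, 0] = INF
    # traceback (recomputes the argmin decisions from the stored matrices)
    ops: list[str] = []
    i, j = a, b
    state = int(np.argmin([M[a, b], D[a, b], I[a, b]]))
    while i > 0 or j > 0:
        if i == 0:
            state = 1
        elif j == 0:
            state = 2
        if state == 0:
            ops.append("=" if qa[i - 1] == ta[j - 1] else "X")
            i, j = i - 1, j - 1
            if i > 0 or j > 0:
                state = int(np.argmin([M[i, j], D[i, j], I[i, j]]))
        elif state == 1:
            ops.append("D")
            j -= 1
            if j > 0 or i > 0:
                cand = [M[i, j] + AFFINE_OPEN + AFFINE_EXT,
                        D[i, j] + AFFINE_EXT,
                        I[i, j] + AFFINE_OPEN + AFFINE_EXT]
                state = int(np.argmin(cand))
        else:
            ops.append("I")
            i -= 1
            if i > 0 or j > 0:
                cand = [M[i, j] + AFFINE_OPEN + AFFINE_EXT,
                        INF,
                        I[i, j] + AFFINE_EXT]
                state = int(np.argmin(cand))
    out: list[tuple[str, int]] = []
    for op in reversed(ops):
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _consolidate_cigar(cigar: list[tuple[str, int]], q: str, t: str,
                       q0: int, t0: int) -> list[tuple[str, int]]:
    """Re-represent local event clusters as single contiguous indels.

    A minimal-unit-cost path may split one deletion/insertion into several
    runs interleaved with chance matches, inflating event counts.  Within
    each cluster of operations separated by short match runs, the single
    contiguous indel placed at the minimal-mismatch position replaces the
    fragmented path whenever its cost is no worse (within a small
    tolerance).  Ties left-align the indel.
    """
    # annotate ops with query/target offsets
    blocks = []
    qp, tp = q0, t0
    for op, n in cigar:
        blocks.append((op, n, qp, tp))
        if op in "=X":
            qp += n
            tp += n
        elif op == "I":
            qp += n
        else:
            tp += n
    # cluster boundaries at long '=' runs
    clusters: list[list[int]] = []
    cur: list[int] = []
    for idx, (op, n, _, _) in enumerate(blocks):
        if op == "=" and n > MERGE_WINDOW:
            if cur:
                clusters.append(cur)
            cur = []
        else:
            cur.append(idx)
    if cur:
        clusters.append(cur)

    out: list[tuple[str, int]] = []
    consumed = 0

    def emit(op, n):
        if n <= 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))

    cluster_by_start = {c[0]: c for c in clusters
                        if any(blocks[i][0] in "ID" for i in c)
                        and sum(blocks[i][0] in "ID" for i in c) >= 1}
    idx = 0
    while idx < len(blocks):
        c = cluster_by_start.get(idx)
        if c is None:
            op, n, _, _ = blocks[idx]
            emit(op, n)
            idx += 1
            continue
        first, last = c[0], c[-1]
        qs = blocks[first][2]
        ts = blocks[first][3]
        op_l, n_l, q_l, t_l = blocks[last]
        qe = q_l + (n_l if op_l in "=XI" else 0)
        te = t_l + (n_l if op_l in "=XD" else 0)
        qseg, tseg = q[qs:qe], t[ts:te]
        ops_new = _affine_realign(qseg, tseg)
        if ops_new is not None:
            for op, n in ops_new:
                emit(op, n)
        else:
            for i in c:
                emit(blocks[i][0], blocks[i][1])
        idx = last + 1
    return out


def _strip_boundary_gaps(cigar: list[tuple[str, int]], q0: int, q1: int,
                         t0: int, t1: int) -> tuple[list[tuple[str, int]],
                                                    int, int, int, int]:
    """Remove gap operations at the alignment boundaries (a segment should
    start and end on aligned bases), shrinking the intervals accordingly."""
    cigar = list(cigar)
    while cigar and cigar[0][0] in "ID":
        op, n = cigar.pop(0)
        if op == "I":
            q0 += n
        else:
            t0 += n
    while cigar and cigar[-1][0] in "ID":
        op, n = cigar.pop()
        if op == "I":
            q1 -= n
        else:
            t1 -= n
    return cigar, q0, q1, t0, t1


def _finalize(monomer_id: str, q: str, contig_name: str, t: str,
              q0: int, q1: int, t0: int, t1: int, strand: str, qlen_full: int,
              ) -> SegmentAlignment | None:
    if q1 - q0 < 1 or t1 - t0 < 1:
        return None
    res = edlib.align(q[q0:q1], t[t0:t1], mode="NW", task="path")
    cigar = _cigar_from_str(res["cigar"])
    cigar = _consolidate_cigar(cigar, q, t, q0, t0)
    cigar, q0, q1, t0, t1 = _strip_boundary_gaps(cigar, q0, q1, t0, t1)
    if q1 - q0 < 1 or t1 - t0 < 1:
        return None
    n_match = n_mis = 0
    mismatches, insertions, deletions = [], [], []
    qp, tp = q0, t0
    for op, n in cigar:
        if op == "=":
            n_match += n
            qp += n
            tp += n
        elif op == "X":
            for j in range(n):
                mismatches.append((tp + j, t[tp + j], q[qp + j]))
            n_mis += n
            qp += n
            tp += n
        elif op == "I":
            insertions.append((tp, q[qp:qp + n]))
            qp += n
        elif op == "D":
            deletions.append((tp, n))
            tp += n
    if strand == "+":
        qs_orig, qe_orig = q0, q1
    else:
        qs_orig, qe_orig = qlen_full - q1, qlen_full - q0
    return SegmentAlignment(
        monomer_id=monomer_id, q_start=qs_orig, q_end=qe_orig,
        contig=contig_name, t_start=t0, t_end=t1, strand=strand,
        cigar=cigar, n_match=n_match, n_mismatch=n_mis,
        mismatches=mismatches, insertions=insertions, deletions=deletions)


def align_segments(monomer_id: str, seq: str, ref: HybridReference,
                   min_len: int = 30, min_identity: float = 0.8,
                   ) -> list[SegmentAlignment]:
    """All local alignments of the monomer with aligned length >= ``min_len``
    and identity >= ``min_identity``, on both strands; deterministic."""
    if not ref.contigs:
        raise ValidationError("empty reference")
    if len(seq) < min_len:
        return []
    seq = seq.upper()
    L = len(seq)
    segments: list[SegmentAlignment] = []
    for strand in "+-":
        q = seq if strand == "+" else revcomp(seq)
        for cl in _collect_seed_clusters(q, ref):
            t = ref.contigs[cl["contig"]]
            q0, q1, t0, t1 = cl["q0"], cl["q1"], cl["t0"], cl["t1"]
            dq, dt = _extend(q, t, q0, t0, -1)
            q0, t0 = q0 - dq, t0 - dt
            dq, dt = _extend(q, t, q1, t1, +1)
            q1, t1 = q1 + dq, t1 + dt
            seg = _finalize(monomer_id, q, cl["contig"], t,
                            q0, q1, t0, t1, strand, L)
            if seg is None:
                continue
            if seg.q_len >= min_len and seg.identity >= min_identity:
                segments.append(seg)
    return _dedup_segments(segments)


def _dedup_segments(segs: list[SegmentAlignment]) -> list[SegmentAlignment]:
    segs = sorted(segs, key=lambda s: (-s.score, s.q_start, s.contig,
                                       s.t_start, s.strand))
    kept: list[SegmentAlignment] = []
    for s in segs:
        redundant = False
        for k in kept:
            if (k.contig == s.contig and k.strand == s.strand
                    and k.q_start <= s.q_start and s.q_end <= k.q_end
                    and k.t_start <= s.t_start and s.t_end <= k.t_end):
                redundant = True
                break
        if not redundant:
            kept.append(s)
    return sorted(kept, key=lambda s: (s.q_start, s.q_end, s.contig,
                                       s.t_start))


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

@dataclass
class DomainChain:
    monomer_id: str
    domains: list[SegmentAlignment]        # query-sorted, homology-trimmed
    junction_overlaps_query: list[int]     # raw query overlap per junction
    unaligned_gaps: list[tuple[int, int]]  # query intervals in no domain
    n_candidates: int = 0
    n_unselected: int = 0

    @property
    def n_junctions(self) -> int:
        return len(self.domains) - 1 if self.domains else 0


def chain_value(chain: list[SegmentAlignment]) -> int:
    """Objective for a query-colinear chain: total segment score minus
    double-counted query-overlap bases."""
    v = sum(s.score for s in chain)
    for a, b in zip(chain, chain[1:]):
        v -= max(0, a.q_end - b.q_start)
    return v


def chain_key(chain: list[SegmentAlignment]) -> tuple:
    """Ordering key: maximize value, then fewer junctions, then leftmost
    target starts."""
    return (chain_value(chain), -len(chain),
            tuple(-s.t_start for s in chain))


def _valid_link(a: SegmentAlignment, b: SegmentAlignment,
                max_query_overlap: int) -> bool:
    if not (b.q_start > a.q_start and b.q_end > a.q_end):
        return False
    return (a.q_end - b.q_start) <= max_query_overlap


def chain_domains(alignments: list[SegmentAlignment],
                  max_query_overlap: int = 300,
                  query_length: int | None = None) -> DomainChain:
    """Select the maximal-score query-colinear chain by dynamic programming.

    Ties are resolved by fewer junctions, then leftmost target start.  After
    selection the query-overlap (microhomology) bases of each junction are
    trimmed from the downstream domain, so the upstream domain owns them.
    """
    if max_query_overlap < 0:
        raise ParameterError("max_query_overlap must be >= 0")
    mono = alignments[0].monomer_id if alignments else ""
    if not alignments:
        return DomainChain(mono, [], [], [], 0, 0)
    segs = sorted(alignments, key=lambda s: (s.q_start, s.q_end, s.t_start))
    n = len(segs)
    best_chain: list[list[int]] = [[i] for i in range(n)]
    for i in range(n):
        for j in range(i):
            if _valid_link(segs[j], segs[i], max_query_overlap):
                cand = best_chain[j] + [i]
                if (chain_key([segs[x] for x in cand])
                        > chain_key([segs[x] for x in best_chain[i]])):
                    best_chain[i] = cand
    winner = max(best_chain, key=lambda ch: chain_key([segs[x] for x in ch]))
    sel = [segs[x] for x in winner]
    overlaps = [max(0, a.q_end - b.q_start) for a, b in zip(sel, sel[1:])]
    trimmed = [sel[0]]
    for ov, b in zip(overlaps, sel[1:]):
        trimmed.append(trim_front_query(b, ov) if ov > 0 else b)
    gaps = []
    qlen = query_length if query_length is not None else max(s.q_end for s in sel)
    cursor = 0
    for s in trimmed:
        if s.q_start > cursor:
            gaps.append((cursor, s.q_start))
        cursor = max(cursor, s.q_end)
    if qlen > cursor:
        gaps.append((cursor, qlen))
    return DomainChain(mono, trimmed, overlaps, gaps,
                       n_candidates=n, n_unselected=n - len(sel))


def trim_front_query(seg: SegmentAlignment, nbases: int) -> SegmentAlignment:
    """Remove ``nbases`` query bases from the 5' (original-orientation) end
    of a segment, adjusting coordinates, cigar and recorded events."""
    if nbases <= 0:
        return seg
    if nbases >= seg.q_len:
        raise ValidationError("cannot trim an entire segment")
    cigar = list(seg.cigar)
    if seg.strand == "-":
        cigar.reverse()  # walk from the query-5' side of the original monomer
    remaining, tconsumed = nbases, 0
    out = []
    for idx, (op, n) in enumerate(cigar):
        if remaining <= 0:
            out.append((op, n))
            continue
        if op in "=XI":
            take = min(n, remaining)
            remaining -= take
            if op in "=X":
                tconsumed += take
            if n - take:
                out.append((op, n - take))
        else:  # D consumes target only; trimmed region absorbs it
            tconsumed += n
    if seg.strand == "-":
        out.reverse()
        t_start, t_end = seg.t_start, seg.t_end - tconsumed
    else:
        t_start, t_end = seg.t_start + tconsumed, seg.t_end
    q_start = seg.q_start + nbases
    q_end = seg.q_end
    # a trim may leave a gap operation at the new boundary; drop it
    while out and (out[0][0] in "ID" or out[-1][0] in "ID"):
        if out[0][0] in "ID":
            op, n = out.pop(0)
            if op == "D":
                t_start += n
            elif seg.strand == "+":
                q_start += n
            else:
                q_end -= n
        else:
            op, n = out.pop()
            if op == "D":
                t_end -= n
            elif seg.strand == "+":
                q_end -= n
            else:
                q_start += n
    keep = lambda tpos: t_start <= tpos < t_end
    n_match = sum(n for op, n in out if op == "=")
    mism = [m for m in seg.mismatches if keep(m[0])]
    return replace(seg, q_start=q_start, q_end=q_end, t_start=t_start,
                   t_end=t_end, cigar=out, n_match=n_match,
                   n_mismatch=len(mism), mismatches=mism,
                   insertions=[i for i in seg.insertions if keep(i[0])],
                   deletions=[d for d in seg.deletions if keep(d[0])])


# ---------------------------------------------------------------------------
# Classification and verification
# ---------------------------------------------------------------------------

def classify_domains(chain: DomainChain, ref: HybridReference,
                     ) -> dict[str, object]:
    """Label each domain intra-ES or nonallelic; summarize counts and the
    copy direction of nonallelic domains."""
    es = ref.es_contig_name
    labels, directions = [], []
    for d in chain.domains:
        nona = d.is_nonallelic(es)
        labels.append("nonallelic" if nona else "intra_es")
        directions.append(d.copy_direction if nona else None)
    return {
        "labels": labels,
        "directions": directions,
        "counts": {"intra": labels.count("intra_es"),
                   "nonallelic": labels.count("nonallelic")},
    }


def verify_nonallelic(domain_read_seq: str, ref: HybridReference,
                      k: int = 25) -> bool | str:
    """True iff the domain's read sequence contains >= 1 k-mer absent from
    the ectopic-site contig (both strands); "indeterminate" if shorter than k.

    A nonallelic call whose sequence is fully explainable by ES k-mers is a
    potential misalignment.
    """
    if len(domain_read_seq) < k:
        return "indeterminate"
    es_kmers = ref.es_kmers(k)
    s = domain_read_seq.upper()
    return any(s[i:i + k] not in es_kmers for i in range(len(s) - k + 1))


# ---------------------------------------------------------------------------
# SAM / PAF / BED interchange
# ---------------------------------------------------------------------------

def write_paf(alignments: list[SegmentAlignment], path,
              query_lengths: dict[str, int] | None = None,
              ref: HybridReference | None = None) -> None:
    with open(path, "w") as fh:
        for s in alignments:
            qlen = (query_lengths or {}).get(s.monomer_id, s.q_end)
            tlen = len(ref.contigs[s.contig]) if ref else s.t_end
            nmatch = s.n_match
            fh.write("\t".join(map(str, [
                s.monomer_id, qlen, s.q_start, s.q_end, s.strand,
                s.contig, tlen, s.t_start, s.t_end, nmatch, s.aln_cols,
                255, f"cg:Z:{_cigar_to_str(s.cigar)}"])) + "\n")


def read_paf(path) -> list[SegmentAlignment]:
    """Lossless read of coordinates, strand and (when present) edit
    operations from PAF.  Mismatch base identities are not recoverable from
    PAF alone; X runs are recorded with unknown read base."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise CircsatError(f"malformed PAF at line {lineno}")
            cigar = []
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = _cigar_from_str(tag[5:])
            seg = _segment_from_coords(
                monomer_id=f[0], q_start=int(f[2]), q_end=int(f[3]),
                strand=f[4], contig=f[5], t_start=int(f[7]),
                t_end=int(f[8]), cigar=cigar)
            out.append(seg)
    return out


def _segment_from_coords(monomer_id, q_start, q_end, strand, contig,
                         t_start, t_end, cigar) -> SegmentAlignment:
    n_match = n_mis = 0
    mismatches, insertions, deletions = [], [], []
    tp = t_start
    for op, n in cigar:
        if op in "=M":
            n_match += n
            tp += n
        elif op == "X":
            for j in range(n):
                mismatches.append((tp + j, "N", "N"))
            n_mis += n
            tp += n
        elif op == "I":
            insertions.append((tp, "N" * n))
        elif op == "D":
            deletions.append((tp, n))
            tp += n
    return SegmentAlignment(monomer_id, q_start, q_end, contig, t_start,
                            t_end, strand, cigar, n_match, n_mis,
                            mismatches, insertions, deletions)


def read_sam(path, ref: HybridReference) -> dict[str, list[SegmentAlignment]]:
    """Group primary + supplementary SAM records of each read into one
    alignment set, with full per-base edit operations recomputed against the
    reference (chimeric reads are the analysis unit)."""
    import pysam
    out: dict[str, list[SegmentAlignment]] = defaultdict(list)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            qseq = rec.query_sequence
            if qseq is None or rec.cigartuples is None:
                continue
            strand = "-" if rec.is_reverse else "+"
            t = ref.contigs[rec.reference_name]
            # query interval in original read orientation
            qa_start = rec.query_alignment_start
            qa_end = rec.query_alignment_end
            qlen = rec.infer_read_length() or len(qseq)
            if strand == "-":
                q_start, q_end = qlen - qa_end, qlen - qa_start
            else:
                q_start, q_end = qa_start, qa_end
            # SAM stores the query already on the forward target strand,
            # matching this module's cigar convention.
            aligned_q = qseq[qa_start:qa_end]
            seg = _finalize(rec.query_name, aligned_q, rec.reference_name, t,
                            0, len(aligned_q), rec.reference_start,
                            rec.reference_end, strand, len(aligned_q))
            if seg is None:
                continue
            seg.q_start, seg.q_end = q_start, q_end
            out[rec.query_name].append(seg)
    return dict(out)


def write_sam(chains: list[DomainChain], monomer_seqs: dict[str, str],
              ref: HybridReference, path) -> None:
    """Emit each chain's domains as primary + supplementary SAM records."""
    import pysam
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": len(s)}
                     for n, s in ref.contigs.items()]}
    names = list(ref.contigs)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for ch in chains:
            for i, d in enumerate(ch.domains):
                a = pysam.AlignedSegment()
                a.query_name = d.monomer_id
                seq = monomer_seqs[d.monomer_id][d.q_start:d.q_end]
                if d.strand == "-":
                    seq = revcomp(seq)
                a.query_sequence = seq
                a.flag = (16 if d.strand == "-" else 0) | (2048 if i else 0)
                a.reference_id = names.index(d.contig)
                a.reference_start = d.t_start
                a.mapping_quality = 60
                a.cigartuples = [({"=": 7, "X": 8, "I": 1, "D": 2}[op], n)
                                 for op, n in d.cigar]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                fh.write(a)


def domains_to_bed(chains: list[DomainChain]) -> pd.DataFrame:
    rows = []
    for ch in chains:
        for d in ch.domains:
            rows.append({"contig": d.contig, "start": d.t_start,
                         "end": d.t_end, "name": d.monomer_id, "score": d.score,
                         "strand": d.strand})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name",
                                       "score", "strand"])


def links_table(chains: list[DomainChain]) -> pd.DataFrame:
    """Circos-style link table: one row per junction, the two joined loci."""
    rows = []
    for ch in chains:
        for a, b in zip(ch.domains, ch.domains[1:]):
            rows.append({"contig1": a.contig, "start1": a.t_start,
                         "end1": a.t_end, "contig2": b.contig,
                         "start2": b.t_start, "end2": b.t_end,
                         "monomer": ch.monomer_id})
    return pd.DataFrame(rows, columns=["contig1", "start1", "end1",
                                       "contig2", "start2", "end2", "monomer"])
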