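"""Decatenate concatemeric circular-consensus reads into monomer PCR products.

Inverse-PCR amplicons sequenced as circular-consensus reads arrive as tandem
concatemers.  Monomer termini are recognized from approximate occurrences of
the two iPCR primers (forward primer, and the reverse primer's reverse
complement, on either read strand); each monomer is orientation-normalized so
the forward primer sits at its 5' end, screened for ectopic-site specificity
(>= k reference bases immediately 3' of each primer), and deduplicated by
exact sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import revcomp
from .errors import ParameterError, ValidationError

MIN_PRIMER_LEN = 15  # shorter primers risk spurious approximate matches


@dataclass(frozen=True)
class PrimerHit:
    primer: str          # "fwd" | "rev"
    start: int           # half-open interval on the read
    end: int
    strand: str          # "+": primer as given; "-": reverse complement
    edits: int


@dataclass
class Monomer:
    read_id: str
    index: int
    sequence: str        # orientation-normalized: forward primer at 5' end
    fwd_span: tuple[int, int]   # primer coordinates on the monomer
    rev_span: tuple[int, int]   # reverse-complemented reverse primer
    read_strand: str     # strand of the source read the monomer came from
    specific: bool = True
    duplicate_of: str | None = None

    @property
    def monomer_id(self) -> str:
        return f"{self.read_id}/{self.index}"


@dataclass
class DecatStats:
    n_hits: int = 0
    n_monomers: int = 0
    discarded_fragments: int = 0
    discarded_bases: int = 0
    ambiguous: int = 0
    counts: dict = field(default_factory=dict)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _infix_end_distances(pattern: str, text_arr: np.ndarray) -> np.ndarray:
    """Best edit distance of ``pattern`` against a window ending at each text
    position (semi-global / infix alignment, unit costs)."""
    n = text_arr.size
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int32)
    pat = _encode(pattern)
    for c in pat:
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = prev[0] + 1
        sub = prev[:-1] + (text_arr != c)
        dele = prev[1:] + 1
        cur[1:] = np.minimum(sub, dele)
        # horizontal moves: cur[j] = min_{l<=j} cur[l] + (j - l)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return prev[1:]  # prev[j] = best distance for a window ending at text pos j


def find_primer_sites(read_seq: str, fwd: str, rev: str, max_edits: int = 2,
                      ) -> list[PrimerHit]:
    """All approximate, non-overlapping primer occurrences on both strands.

    Occurrences of the forward and reverse primers and of their reverse
    complements at <= ``max_edits`` edits (substitutions + indels, unit
    costs), sorted by position; overlapping candidates are resolved by lower
    edit distance, then leftmost position.
    """
    if len(fwd) < MIN_PRIMER_LEN or len(rev) < MIN_PRIMER_LEN:
        raise ParameterError(f"primers must be >= {MIN_PRIMER_LEN} bp")
    if max_edits < 0:
        raise ParameterError("max_edits must be >= 0")
    text = _encode(read_seq.upper())
    patterns = [("fwd", "+", fwd), ("fwd", "-", revcomp(fwd)),
                ("rev", "+", rev), ("rev", "-", revcomp(rev))]
    candidates = []
    for primer, strand, pat in patterns:
        dists = _infix_end_distances(pat, text)
        ends = np.flatnonzero(dists <= max_edits) + 1  # exclusive ends
        for end in ends:
            d = int(dists[end - 1])
            start = _refine_start(pat, read_seq, int(end), d, max_edits)
            candidates.append((d, start, int(end), primer, strand))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    chosen: list[PrimerHit] = []
    occupied: list[tuple[int, int]] = []
    for d, start, end, primer, strand in candidates:
        if any(start < oe and end > os for os, oe in occupied):
            continue
        occupied.append((start, end))
        chosen.append(PrimerHit(primer, start, end, strand, d))
    chosen.sort(key=lambda h: h.start)
    return chosen


def _refine_start(pattern: str, read_seq: str, end: int, dist: int,
                  max_edits: int) -> int:
    w0 = max(0, end - len(pattern) - max_edits)
    window = read_seq[w0:end]
    res = edlib.align(pattern, window, mode="HW", task="locations",
                      k=max_edits)
    locs = [l for l in res.get("locations") or []
            if l[1] == len(window) - 1]
    if locs:
        return w0 + locs[0][0]
    return max(0, end - len(pattern))


def decatenate(read_id: str, read_seq: str, hits: list[PrimerHit],
               ) -> tuple[list[Monomer], DecatStats]:
    """Partition a read into orientation-normalized monomers.

    A monomer runs from a forward-primer start to the end of the following
    reverse-complemented reverse primer on the same strand.  Reads whose hits
    are predominantly on the minus strand are flipped first.  Leading and
    trailing fragments lacking one of the two primers, inter-monomer gap
    sequence (rolling-circle reads), and monomers containing opposite-strand
    hits are discarded and counted.
    """
    stats = DecatStats(n_hits=len(hits))
    if not hits:
        stats.discarded_fragments = 1 if read_seq else 0
        stats.discarded_bases = len(read_seq)
        return [], stats
    plus = [h for h in hits if (h.primer, h.strand) in (("fwd", "+"), ("rev", "-"))]
    minus = [h for h in hits if (h.primer, h.strand) in (("fwd", "-"), ("rev", "+"))]
    read_strand = "+" if len(plus) >= len(minus) else "-"
    if read_strand == "-":
        L = len(read_seq)
        read_seq = revcomp(read_seq)
        hits = sorted((PrimerHit(h.primer, L - h.end, L - h.start,
                                 "+" if h.strand == "-" else "-", h.edits)
                       for h in hits), key=lambda h: h.start)
        plus = [h for h in hits
                if (h.primer, h.strand) in (("fwd", "+"), ("rev", "-"))]
        minus = [h for h in hits
                 if (h.primer, h.strand) in (("fwd", "-"), ("rev", "+"))]
    fwd_hits = [h for h in plus if h.primer == "fwd"]
    rev_hits = [h for h in plus if h.primer == "rev"]
    monomers: list[Monomer] = []
    used_bases = 0
    idx = 0
    for i, f in enumerate(fwd_hits):
        nxt = fwd_hits[i + 1].start if i + 1 < len(fwd_hits) else len(read_seq) + 1
        rs = [r for r in rev_hits if f.end <= r.start and r.end <= nxt]
        if not rs:
            stats.discarded_fragments += 1
            continue
        r = rs[-1]
        if any(m.start < r.end and m.end > f.start for m in minus):
            stats.ambiguous += 1
            continue
        seq = read_seq[f.start:r.end]
        monomers.append(Monomer(
            read_id=read_id, index=idx, sequence=seq,
            fwd_span=(0, f.end - f.start),
            rev_span=(r.start - f.start, r.end - f.start),
            read_strand=read_strand))
        idx += 1
        used_bases += len(seq)
    stats.n_monomers = len(monomers)
    stats.discarded_bases = len(read_seq) - used_bases
    # leading / trailing unassigned regions count as discarded fragments
    if fwd_hits and fwd_hits[0].start > 0:
        stats.discarded_fragments += 1
    return monomers, stats


def normalize(monomer: Monomer, fwd: str, max_edits: int = 2) -> Monomer:
    """Idempotent orientation canonicalization.

    If the forward primer is already (approximately) at the 5' end this is a
    no-op; otherwise the sequence is reverse-complemented.
    """
    head = monomer.sequence[:len(fwd) + max_edits]
    if edlib.align(fwd, head, mode="HW", k=max_edits)["editDistance"] != -1:
        return monomer
    L = len(monomer.sequence)
    return Monomer(
        read_id=monomer.read_id, index=monomer.index,
        sequence=revcomp(monomer.sequence),
        fwd_span=(L - monomer.fwd_span[1], L - monomer.fwd_span[0]),
        rev_span=(L - monomer.rev_span[1], L - monomer.rev_span[0]),
        read_strand=monomer.read_strand, specific=monomer.specific,
        duplicate_of=monomer.duplicate_of)


def expected_flanks(es_contig: str, fwd: str, rev: str, k: int,
                    ) -> tuple[str, str]:
    """The ectopic-site bases immediately 3' of each primer, in monomer space.

    The monomer reads as  FWD + [fwd 3' flank] ... [rev 3' flank, rc] + rc(REV);
    both expectations are returned on the monomer (plus) strand.
    """
    f0 = es_contig.find(fwd)
    r0 = es_contig.find(revcomp(rev))
    if f0 == -1 or r0 == -1:
        raise ValidationError("primer sites not found on the ectopic-site "
                              "contig (exact match required)")
    return (es_contig[f0 + len(fwd):f0 + len(fwd) + k],
            es_contig[r0 - k:r0])


def filter_specific(monomers: list[Monomer], es_contig: str, fwd: str,
                    rev: str, k: int = 6,
                    ) -> tuple[list[Monomer], list[Monomer]]:
    """Ectopic-site specificity filter.

    A monomer is kept iff the ``k`` bases immediately 3' of the forward
    primer and the ``k`` bases 3' of the reverse primer (on its own strand)
    both match the expected ectopic-site flanks exactly.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    want_f, want_r = expected_flanks(es_contig, fwd, rev, k)
    kept, removed = [], []
    for m in monomers:
        fe = m.fwd_span[1]
        rs = m.rev_span[0]
        ok = (m.sequence[fe:fe + k] == want_f
              and rs - k >= 0 and m.sequence[rs - k:rs] == want_r)
        m.specific = bool(ok)
        (kept if ok else removed).append(m)
    return kept, removed


def deduplicate(monomers: list[Monomer],
                ) -> tuple[list[Monomer], list[Monomer]]:
    """Collapse exact-sequence duplicates to one representative.

    The representative is the first monomer by (read id, index); duplicates
    get ``duplicate_of`` set.  Idempotent.
    """
    by_seq: dict[str, Monomer] = {}
    unique, dups = [], []
    for m in sorted(monomers, key=lambda m: (m.read_id, m.index)):
        rep = by_seq.get(m.sequence)
        if rep is None:
            by_seq[m.sequence] = m
            m.duplicate_of = None
            unique.append(m)
        else:
            m.duplicate_of = rep.monomer_id
            dups.append(m)
    return unique, dups
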