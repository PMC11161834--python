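"""Pileups over template-switch domains and eccDNA mutation metrics.

Implements the per-position pileup (mismatches, deletion events, deleted
bases, insertion events, inserted bases, restricted to template-switch
domain intervals), per-generation mutation-rate tables (rows A–H), per-kb
deletion metrics, the per-read mutations/kb threshold filter, and
pyrimidine-centered trinucleotide substitution signatures (6 substitution
classes x 16 flanking contexts = 96 channels).

A deletion event is one maximal run of contiguous deleted reference bases,
counted once at its start column; an insertion event is one contiguous
inserted string anchored between two reference positions.  Mismatches at
reference or read N are excluded from rates and signatures (counted
separately).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import CircsatError, ParameterError
from .segmap import DomainChain, HybridReference, SegmentAlignment


@dataclass
class PileupColumn:
    contig: str
    position: int
    ref_base: str
    depth: int
    mismatches: dict[str, int]
    del_event_starts: int
    deleted_coverage: int
    insertion_events: int
    inserted_seqs: list[str]


class Pileup:
    """Per-position tallies over template-switch domains.

    Depth is accumulated as dense per-contig arrays; events are sparse.
    """

    def __init__(self, ref: HybridReference):
        self.ref = ref
        self.depth = {n: np.zeros(len(s), dtype=np.int32)
                      for n, s in ref.contigs.items()}
        self.del_cov = {n: np.zeros(len(s), dtype=np.int32)
                        for n, s in ref.contigs.items()}
        self.mismatch: dict[str, dict[int, Counter]] = defaultdict(
            lambda: defaultdict(Counter))
        self.del_starts: dict[str, Counter] = defaultdict(Counter)
        self.ins: dict[str, dict[int, list[str]]] = defaultdict(
            lambda: defaultdict(list))
        self.aligned_bp = 0
        self.n_mismatch = 0
        self.n_mismatch_skipped_n = 0

    def add_segment(self, seg: SegmentAlignment) -> None:
        if not seg.cigar:
            raise CircsatError(
                "alignment carries no edit operations; re-align the monomer "
                "or import SAM with CIGAR")
        c = seg.contig
        self.depth[c][seg.t_start:seg.t_end] += 1
        self.aligned_bp += seg.t_end - seg.t_start
        for tpos, refb, readb in seg.mismatches:
            if refb == "N" or readb == "N":
                self.n_mismatch_skipped_n += 1
                continue
            self.mismatch[c][tpos][readb] += 1
            self.n_mismatch += 1
        for tpos, length in seg.deletions:
            self.del_starts[c][tpos] += 1
            self.del_cov[c][tpos:tpos + length] += 1
        for tpos, seq in seg.insertions:
            self.ins[c][tpos].append(seq)

    def add_chain(self, chain: DomainChain) -> None:
        for d in chain.domains:
            self.add_segment(d)

    def columns(self, contig: str | None = None,
                covered_only: bool = True) -> Iterator[PileupColumn]:
        names = [contig] if contig else list(self.ref.contigs)
        for name in names:
            seq = self.ref.contigs[name]
            depth = self.depth[name]
            positions = (np.flatnonzero(depth) if covered_only
                         else range(len(seq)))
            for pos in positions:
                pos = int(pos)
                ins = self.ins[name].get(pos, [])
                yield PileupColumn(
                    contig=name, position=pos, ref_base=seq[pos],
                    depth=int(depth[pos]),
                    mismatches=dict(self.mismatch[name].get(pos, {})),
                    del_event_starts=int(self.del_starts[name][pos]),
                    deleted_coverage=int(self.del_cov[name][pos]),
                    insertion_events=len(ins), inserted_seqs=list(ins))

    def totals(self) -> dict[str, float]:
        del_events = sum(sum(c.values()) for c in self.del_starts.values())
        del_nt = int(sum(int(a.sum()) for a in self.del_cov.values()))
        ins_events = sum(len(v) for d in self.ins.values()
                         for v in d.values())
        ins_nt = sum(len(s) for d in self.ins.values()
                     for v in d.values() for s in v)
        return {
            "mismatches": int(self.n_mismatch),
            "del_events": int(del_events),
            "del_nt": del_nt,
            "ins_events": int(ins_events),
            "ins_nt": int(ins_nt),
            "aligned_bp": int(self.aligned_bp),
        }

    def mismatch_calls(self) -> Iterator[tuple[str, int, str, str, int]]:
        """(contig, pos, ref base, read base, count) per observed mismatch."""
        for contig, cols in self.mismatch.items():
            seq = self.ref.contigs[contig]
            for pos in sorted(cols):
                for alt, n in sorted(cols[pos].items()):
                    yield contig, pos, seq[pos], alt, n

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "contig": c.contig, "pos": c.position, "ref": c.ref_base,
            "depth": c.depth,
            "mismatches": sum(c.mismatches.values()),
            "del_events": c.del_event_starts,
            "del_cov": c.deleted_coverage,
            "ins_events": c.insertion_events,
        } for c in self.columns()]
        return pd.DataFrame(rows, columns=["contig", "pos", "ref", "depth",
                                           "mismatches", "del_events",
                                           "del_cov", "ins_events"])


def pileup(chains: Iterable[DomainChain], ref: HybridReference) -> Pileup:
    p = Pileup(ref)
    for ch in chains:
        p.add_chain(ch)
    return p


# ---------------------------------------------------------------------------
# Rate table (rows A–H)
# ---------------------------------------------------------------------------

ROW_LABELS = {
    "A": "Mismatches/bp/generation",
    "B": "Deletion events/bp/generation",
    "C": "Deleted nucleotides/bp/generation",
    "D": "Deleted nucleotides/deletion event",
    "E": "Insertion events/bp/generation",
    "F": "Inserted nucleotides/bp/generation",
    "G": "Inserted nucleotides/insertion event",
    "H": "Indels + Substitutions (A + C + F)",
}


@dataclass
class RateTable:
    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    aligned_bp: int
    generations: int

    def as_series(self, name: str = "rates") -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in "ABCDEFGH"}, name=name)


def mutation_rates(totals: dict[str, float], aligned_bp: int | None = None,
                   generations: int = 200) -> RateTable:
    """Rates per aligned bp per generation; D and G are per-event ratios,
    H is the literal sum A + C + F."""
    if generations <= 0:
        raise ParameterError("generations must be > 0")
    bp = int(totals.get("aligned_bp", 0) if aligned_bp is None else aligned_bp)
    if bp <= 0:
        raise ParameterError("aligned_bp must be > 0")
    denom = bp * generations
    A = totals["mismatches"] / denom
    B = totals["del_events"] / denom
    C = totals["del_nt"] / denom
    E = totals["ins_events"] / denom
    F = totals["ins_nt"] / denom
    D = C / B if B > 0 else float("nan")
    G = F / E if E > 0 else float("nan")
    return RateTable(A, B, C, D, E, F, G, A + C + F, bp, generations)


def rate_table_frame(tables: dict[str, RateTable]) -> pd.DataFrame:
    """One column per sample/condition, rows A–H with their printed labels."""
    df = pd.DataFrame({name: t.as_series() for name, t in tables.items()})
    df.index = [f"{k}. {ROW_LABELS[k]}" for k in df.index]
    return df


def per_kb_deletion_metrics(totals: dict[str, float],
                            aligned_bp: int | None = None,
                            ) -> tuple[float, float]:
    """(deleted bases/kb, deletion events/kb) over aligned reference bases,
    with no generation normalization."""
    bp = int(totals.get("aligned_bp", 0) if aligned_bp is None else aligned_bp)
    if bp <= 0:
        raise ParameterError("aligned_bp must be > 0")
    return (totals["del_nt"] * 1000.0 / bp,
            totals["del_events"] * 1000.0 / bp)


# ---------------------------------------------------------------------------
# Per-read mutation threshold
# ---------------------------------------------------------------------------

@dataclass
class ReadMutationStats:
    read_id: str
    mutations: int          # mismatches + deletion events + insertion events
    aligned_bp: int

    @property
    def per_kb(self) -> float:
        return self.mutations * 1000.0 / self.aligned_bp if self.aligned_bp else 0.0


def chain_mutation_stats(chain: DomainChain) -> ReadMutationStats:
    muts = sum(d.n_mismatch + len(d.deletions) + len(d.insertions)
               for d in chain.domains)
    bp = sum(d.t_end - d.t_start for d in chain.domains)
    return ReadMutationStats(chain.monomer_id, muts, bp)


def apply_mutation_threshold(stats: Iterable[ReadMutationStats],
                             threshold: float = 2.0,
                             ) -> tuple[list[ReadMutationStats],
                                        list[ReadMutationStats]]:
    """Remove reads below ``threshold`` mutations per aligned kb."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    kept, removed = [], []
    for s in stats:
        (kept if s.per_kb >= threshold else removed).append(s)
    return kept, removed


# ---------------------------------------------------------------------------
# Trinucleotide substitution signatures
# ---------------------------------------------------------------------------

SUB_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_CONTEXT_BASES = "ACGT"

SIGNATURE_CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in _CONTEXT_BASES
    for three in _CONTEXT_BASES
]


def fold_substitution(five: str, ref: str, alt: str, three: str,
                      ) -> tuple[str, str] | None:
    """Fold any substitution-with-context onto the pyrimidine-centered
    convention; returns (channel, substitution class) or None for N's."""
    bases = set(five + ref + alt + three)
    if not bases <= set("ACGT") or ref == alt:
        return None
    if ref in "AG":
        five, ref, alt, three = (revcomp(three), revcomp(ref), revcomp(alt),
                                 revcomp(five))
    sub = f"{ref}>{alt}"
    return f"{five}[{sub}]{three}", sub


@dataclass
class SignatureVector:
    counts: pd.Series                     # 96 channels
    skipped_edge: int = 0
    skipped_n: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> pd.Series:
        t = self.total
        return self.counts / t if t else self.counts.astype(float)

    @property
    def class_marginals(self) -> pd.Series:
        classes = self.counts.index.str.extract(r"\[(.>.)\]", expand=False)
        return self.counts.groupby(classes).sum().reindex(SUB_CLASSES,
                                                          fill_value=0)


def trinucleotide_signature(
        calls: Iterable[tuple[str, int, str, str, int]],
        ref: HybridReference) -> SignatureVector:
    """96-channel substitution signature from contexted mismatch calls.

    ``calls`` yields (contig, position, ref base, read base, count); flanking
    context comes from the reference.  Purine-reference substitutions are
    recorded at the reverse-complement context (e.g. G>A at NGN counts as
    C>T at the complementary trinucleotide).  Edge positions and N-containing
    contexts are skipped and counted.
    """
    counts = pd.Series(0, index=SIGNATURE_CHANNELS, dtype=int)
    skipped_edge = skipped_n = 0
    for contig, pos, refb, altb, n in calls:
        seq = ref.contigs[contig]
        if pos < 1 or pos + 1 >= len(seq):
            skipped_edge += n
            continue
        folded = fold_substitution(seq[pos - 1], refb, altb, seq[pos + 1])
        if folded is None:
            skipped_n += n
            continue
        counts[folded[0]] += n
    return SignatureVector(counts, skipped_edge, skipped_n)
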