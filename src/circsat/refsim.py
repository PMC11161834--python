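"""Synthetic references, eccDNA structures and inverse-PCR reads.

This module builds a parameterized ectopic-site contig (reporter genes,
replication-origin cassette, a non-B microsatellite insert, repeated 48-bp
FRT sites, Alu-like repeats ending in a poly-T tail, and the two inverse-PCR
primer sites), simulates extrachromosomal circular DNAs (eccDNAs) assembled
from template-switch domains joined at microhomologies, injects mismatch and
indel mutations at configurable per-generation rates, and emits rolling-circle
concatemer reads with full ground truth.

Coordinates are 0-based, half-open throughout.  Strand "-" means the reverse
complement of the named interval.  At every junction the shared microhomology
is realized once in the circle and, by convention, belongs to the *upstream*
domain; the generator places domains so the realized maximal homology equals
the requested length exactly (the bases flanking the shared block differ on
both sides).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, child_rng, random_dna, revcomp, validate_dna
from .errors import GenerationError, ParameterError, ValidationError

# Full-length FLP recombinase target: two 13-bp repeats, 8-bp spacer, one
# inverted 13-bp repeat plus the leading repeat copy -- 48 bp in total.
FRT_SITE = "GAAGTTCCTATTCCGAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"
assert len(FRT_SITE) == 48

# Default inverse-PCR primers: fixed 24-mers with no self- or
# cross-complementarity (primer sequences are normally user-supplied).
DEFAULT_FWD_PRIMER = "ACATCGGATAGTTCAGGACCTTAC"
DEFAULT_REV_PRIMER = "AGGTTCTTGATCACCTTGAGCTAC"

ALU_TAIL_LEN = 29  # d(T)29 tail terminating each Alu-like repeat

FEATURE_KINDS = {"reporter", "origin", "microsatellite", "frt", "alu",
                 "primer_site", "spacer"}

MICROSATELLITE_PRESETS = {
    # unit, copies, generations of clonal outgrowth
    "CAG102": ("CAG", 102, 200),
    "ATTCT47": ("ATTCT", 47, 200),
    # quadruplex-forming insert: five matches to the canonical consensus
    "G4": ("GGGAGGGAGGGAGGGT", 5, 150),
    # homopurine/homopyrimidine mirror repeat (triplex-forming)
    "H3": ("GAAGAGGAAGGAGAAG", 5, 150),
}


@dataclass
class FeatureSpec:
    """One ordered feature of the ectopic site."""

    name: str
    kind: str
    sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if not self.sequence:
            raise ValidationError(f"feature {self.name!r} has empty sequence")
        validate_dna(self.sequence, what=f"feature {self.name!r}")
        if self.strand not in "+-":
            raise ValidationError(f"feature {self.name!r}: bad strand")


@dataclass
class EctopicSiteSpec:
    """Ordered feature inventory of one ectopic-site contig."""

    contig_name: str
    features: list[FeatureSpec]

    def validate(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate feature names: {dup}")
        frts = [f.sequence for f in self.features if f.kind == "frt"]
        if len(set(frts)) > 1:
            raise ValidationError("frt features must be identical in sequence")
        for f in self.features:
            if f.kind == "alu":
                tail = len(f.sequence) - len(f.sequence.rstrip("T"))
                if tail < 20:
                    raise ValidationError(
                        f"alu feature {f.name!r} must end in >=20 T's "
                        f"(has {tail})")


def build_ectopic_site(spec: EctopicSiteSpec) -> tuple[str, pd.DataFrame]:
    """Assemble the ectopic-site contig and its per-feature interval table.

    The intervals are non-overlapping, sorted, and tile the contig exactly,
    so concatenating the extracted intervals reproduces the contig.
    """
    spec.validate()
    rows, parts, pos = [], [], 0
    for f in spec.features:
        seq = f.sequence if f.strand == "+" else revcomp(f.sequence)
        rows.append({"name": f.name, "kind": f.kind, "start": pos,
                     "end": pos + len(seq), "strand": f.strand})
        parts.append(seq)
        pos += len(seq)
    table = pd.DataFrame(rows, columns=["name", "kind", "start", "end",
                                        "strand"])
    return "".join(parts), table


def microsatellite(unit: str, copies: int, name: str = "microsat") -> FeatureSpec:
    return FeatureSpec(name, "microsatellite", unit * copies)


def make_alu(rng: np.random.Generator, body_len: int = 282) -> str:
    """An Alu-like repeat body ending in the d(T)29 tail (311 bp default)."""
    body = random_dna(rng, body_len)
    # the tail must be a clean poly-T run: the base preceding it is not T
    if body.endswith("T"):
        body = body[:-1] + rng.choice([b for b in "ACG"])
    return body + "T" * ALU_TAIL_LEN


def default_ectopic_site(preset: str = "CAG102", seed: int = 0,
                         fwd_primer: str = DEFAULT_FWD_PRIMER,
                         rev_primer: str = DEFAULT_REV_PRIMER,
                         ) -> tuple[EctopicSiteSpec, str, pd.DataFrame]:
    """Build the default desk-scale ectopic site for one microsatellite preset.

    Layout (5' -> 3'): spacer, FRT, dTom reporter, Alu, origin cassette,
    reverse-primer site (minus strand), microsatellite, forward-primer site,
    eGFP reporter, Alu, TK cassette, FRT, Alu, spacer.  The two FRT copies are
    byte-identical; the Alu copies share one body.  The iPCR primers face away
    from each other so only circular templates amplify; the microsatellite
    lies between their 5' ends (the unamplified gap).
    """
    if preset not in MICROSATELLITE_PRESETS:
        raise ParameterError(
            f"unknown preset {preset!r}; options: {sorted(MICROSATELLITE_PRESETS)}")
    unit, copies, _ = MICROSATELLITE_PRESETS[preset]
    rng = child_rng(seed, 11)
    alu = make_alu(rng)
    features = [
        FeatureSpec("spacer_up", "spacer", random_dna(rng, 520)),
        FeatureSpec("frt_1", "frt", FRT_SITE),
        FeatureSpec("dTom", "reporter", random_dna(rng, 680)),
        FeatureSpec("alu_1", "alu", alu),
        FeatureSpec("myc_origin", "origin", random_dna(rng, 420)),
        FeatureSpec("primer_R", "primer_site", rev_primer, strand="-"),
        microsatellite(unit, copies),
        FeatureSpec("primer_F", "primer_site", fwd_primer),
        FeatureSpec("eGFP", "reporter", random_dna(rng, 920)),
        FeatureSpec("alu_2", "alu", alu),
        FeatureSpec("TK", "reporter", random_dna(rng, 840)),
        FeatureSpec("frt_2", "frt", FRT_SITE),
        FeatureSpec("alu_3", "alu", alu),
        FeatureSpec("spacer_down", "spacer", random_dna(rng, 520)),
    ]
    spec = EctopicSiteSpec(f"ES_{preset}", features)
    _fix_repeat_boundaries(spec, rng)
    seq, table = build_ectopic_site(spec)
    return spec, seq, table


def _fix_repeat_boundaries(spec: EctopicSiteSpec, rng: np.random.Generator) -> None:
    """Make the bases flanking repeated FRT/Alu copies differ between copies.

    This pins the maximal shared homology of each repeat pair to exactly the
    repeat itself, so a junction sealed through the repeat has a well-defined
    overlap length.  Only randomly generated neighbours are edited.
    """
    feats = spec.features
    editable = {"spacer", "reporter", "origin"}

    PIN = 3  # flanking bases pinned distinct on each side of a repeat pair

    def set_char(i, pos, avoid):
        f = feats[i]
        alt = rng.choice([b for b in BASES if b != avoid])
        f.sequence = f.sequence[:pos] + alt + f.sequence[pos + 1:]

    for kind in ("frt", "alu"):
        idxs = [i for i, f in enumerate(feats) if f.kind == kind]
        for a, b in zip(idxs, idxs[1:]):
            # the PIN bases after (and before) each copy must differ between
            # the copies position-by-position, so the maximal shared homology
            # of the pair is the repeat itself and an aligner cannot creep
            # past it on chance matches
            na, nb = a + 1, b + 1
            for i in range(PIN):
                if nb >= len(feats):
                    break
                ca, cb = feats[na].sequence[i], feats[nb].sequence[i]
                if ca == cb:
                    if feats[nb].kind in editable:
                        set_char(nb, i, ca)
                    elif feats[na].kind in editable:
                        set_char(na, i, cb)
            pa, pb = a - 1, b - 1
            for i in range(PIN):
                if pa < 0:
                    break
                ca = feats[pa].sequence[-1 - i]
                cb = feats[pb].sequence[-1 - i]
                if ca == cb:
                    if feats[pb].kind in editable:
                        set_char(pb, len(feats[pb].sequence) - 1 - i, ca)
                    elif feats[pa].kind in editable:
                        set_char(pa, len(feats[pa].sequence) - 1 - i, cb)


def make_donor_contigs(rng: np.random.Generator, n: int = 2,
                       length: int = 3000, alu: str | None = None,
                       ) -> dict[str, str]:
    """Nonallelic donor contigs; each optionally carries one Alu copy."""
    donors = {}
    for i in range(n):
        seq = random_dna(rng, length)
        if alu:
            p = int(rng.integers(200, length - 200 - len(alu)))
            seq = seq[:p] + alu + seq[p + len(alu):]
        donors[f"donor_chr{8 + i}"] = seq
    return donors


# ---------------------------------------------------------------------------
# G-quadruplex consensus scanning
# ---------------------------------------------------------------------------

def scan_g4_consensus(seq: str, max_loop: int = 7) -> list[tuple[int, int, str]]:
    """All maximal, non-nested matches to the canonical G4 consensus.

    The consensus is four tracts of >=3 G separated by loops of 1..max_loop
    arbitrary bases.  Matches on the complementary strand (C-tracts on the
    given sequence) are reported with strand "-" in the coordinates of the
    input sequence.  Returns sorted (start, end, strand) half-open intervals.
    """
    if max_loop < 1:
        raise ParameterError("max_loop must be >= 1")
    seq = seq.upper()
    validate_dna(seq, what="sequence")
    out: list[tuple[int, int, str]] = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        matches = _scan_g4_plus(s, max_loop)
        if strand == "-":
            matches = [(n - e, n - b) for b, e in matches]
        out.extend((b, e, strand) for b, e in _drop_nested(sorted(matches)))
    return sorted(out)


def _scan_g4_plus(s: str, max_loop: int) -> list[tuple[int, int]]:
    n = len(s)
    # g_run[i] = length of the G run starting at i
    g_run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        g_run[i] = g_run[i + 1] + 1 if s[i] == "G" else 0

    memo: dict[tuple[int, int], int] = {}

    def best_end(pos: int, tracts: int) -> int:
        """Maximal end of `tracts` G-tracts (loops between) starting at pos."""
        key = (pos, tracts)
        if key in memo:
            return memo[key]
        best = -1
        g = g_run[pos] if pos < n else 0
        if g >= 3:
            if tracts == 1:
                best = pos + g  # the final tract swallows its whole G run
            else:
                for c in range(3, g + 1):
                    tract_end = pos + c
                    for loop in range(1, max_loop + 1):
                        nxt = tract_end + loop
                        if nxt + 3 > n:
                            break
                        e = best_end(nxt, tracts - 1)
                        if e > best:
                            best = e
        memo[key] = best
        return best

    matches = []
    for i in range(n - 11):
        if g_run[i] >= 3 and (i == 0 or s[i - 1] != "G"):
            # starts inside a G run are nested in the run-start match
            e = best_end(i, 4)
            if e > 0:
                matches.append((i, e))
    return matches


def _drop_nested(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    keep = []
    for b, e in ivals:
        if any((b2 <= b and e <= e2) and (b2, e2) != (b, e) for b2, e2 in ivals):
            continue
        keep.append((b, e))
    return keep


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

@dataclass
class MutationModel:
    """Per-generation mutation rates applied over a circle.

    Rates are events (or substituted bases) per bp per generation, matching
    the scale on which eccDNA mutation burdens are quantified.  Deletion and
    insertion lengths are geometric with the given means; insertions draw
    random bases unless ``tandem_dup_fraction`` routes them to duplications
    of the preceding sequence.
    """

    mismatch_rate: float = 0.0
    del_event_rate: float = 0.0
    del_len_mean: float = 10.9
    ins_event_rate: float = 0.0
    ins_len_mean: float = 2.3
    generations: int = 200
    tandem_dup_fraction: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.del_event_rate, self.ins_event_rate):
            if r < 0:
                raise ValidationError("mutation rates must be >= 0")
        if self.del_len_mean < 1 or self.ins_len_mean < 1:
            raise ValidationError("length distributions must support >= 1 bp")
        if self.generations <= 0:
            raise ValidationError("generations must be > 0")


NULL_MUTATIONS = MutationModel()


@dataclass
class MutationEvent:
    pos: int            # 0-based position in the un-mutated circle
    kind: str           # mismatch | deletion | insertion
    length: int
    ref: str            # deleted / substituted reference bases
    alt: str            # substituted / inserted bases


def inject_mutations(seq: str, model: MutationModel, rng: np.random.Generator,
                     ) -> tuple[str, list[MutationEvent]]:
    """Place Poisson-distributed mutation events uniformly over ``seq``.

    Expected event counts are rate x length x generations.  Events drawn on
    top of an earlier deletion tract are dropped (not re-placed); only applied
    events are returned, in position order.
    """
    L = len(seq)
    scale = L * model.generations
    events: list[MutationEvent] = []
    n_mis = rng.poisson(model.mismatch_rate * scale)
    n_del = rng.poisson(model.del_event_rate * scale)
    n_ins = rng.poisson(model.ins_event_rate * scale)
    draws = []
    for pos in rng.integers(0, L, n_mis):
        draws.append(("mismatch", int(pos), 1))
    for pos in rng.integers(0, L, n_del):
        dlen = int(min(rng.geometric(1.0 / model.del_len_mean), L - int(pos)))
        draws.append(("deletion", int(pos), dlen))
    for pos in rng.integers(0, L, n_ins):
        ilen = int(rng.geometric(1.0 / model.ins_len_mean))
        draws.append(("insertion", int(pos), ilen))
    rng.shuffle(draws)          # drop order is random when events collide
    draws.sort(key=lambda d: (d[1], d[0]))
    blocked_until = -1
    for kind, pos, length in draws:
        if pos < blocked_until:
            continue
        if kind == "mismatch":
            ref = seq[pos]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            events.append(MutationEvent(pos, kind, 1, ref, alt))
            blocked_until = max(blocked_until, pos + 1)
        elif kind == "deletion":
            events.append(MutationEvent(pos, kind, length,
                                        seq[pos:pos + length], ""))
            blocked_until = max(blocked_until, pos + length)
        else:
            if model.tandem_dup_fraction and rng.random() < model.tandem_dup_fraction:
                alt = seq[max(0, pos - length):pos]
                alt = alt or random_dna(rng, length)
            else:
                alt = random_dna(rng, length)
            events.append(MutationEvent(pos, kind, len(alt), "", alt))
            blocked_until = max(blocked_until, pos)  # insertion blocks nothing
    out, cur = [], 0
    for ev in events:
        out.append(seq[cur:ev.pos])
        if ev.kind == "mismatch":
            out.append(ev.alt)
            cur = ev.pos + 1
        elif ev.kind == "deletion":
            cur = ev.pos + ev.length
        else:
            out.append(ev.alt)
            cur = ev.pos
    out.append(seq[cur:])
    return "".join(out), events


# ---------------------------------------------------------------------------
# eccDNA structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpec:
    """One template-switch domain: a reference interval with orientation."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def length(self) -> int:
        return self.end - self.start


@dataclass
class EccDNAModel:
    """Structure of one simulated eccDNA.

    ``junction_homologies[i]`` is the intended microhomology (bp) at the
    junction joining ``domains[i]`` to ``domains[(i+1) % n]``; the junction
    count therefore equals the domain count (the molecule is circular).
    ``circ_junction_index`` marks the circle-closing junction.
    """

    domains: list[DomainSpec]
    junction_homologies: list[int]
    circ_junction_index: int | None = None
    mutation_model: MutationModel = field(default_factory=MutationModel)

    def validate(self) -> None:
        n = len(self.domains)
        if n < 1:
            raise ValidationError("need >= 1 domain")
        if len(self.junction_homologies) != n:
            raise ValidationError(
                "junction count must equal domain count (circular molecule)")
        for i, k in enumerate(self.junction_homologies):
            up = self.domains[i]
            down = self.domains[(i + 1) % n]
            if k < 0 or k > min(up.length(), down.length()):
                raise ValidationError(
                    f"junction {i}: overlap {k} outside [0, shorter domain]")


@dataclass
class DomainTruth:
    source: DomainSpec          # full source interval (homology included)
    circle_start: int           # footprint on the circle, homology-trimmed
    circle_end: int
    trimmed_front: int          # upstream-junction homology removed from 5' end


@dataclass
class JunctionTruth:
    index: int
    circle_pos: int             # junction anchor on the circle
    intended_overlap: int
    realized_overlap: int
    up_domain: int
    down_domain: int
    is_circularization: bool


@dataclass
class EccdnaTruth:
    domains: list[DomainTruth]
    junctions: list[JunctionTruth]
    mutations: list[MutationEvent]
    circle_len: int             # after mutation
    premut_len: int


def _domain_seq(ref: dict[str, str], d: DomainSpec) -> str:
    s = ref[d.contig][d.start:d.end]
    return s if d.strand == "+" else revcomp(s)


def _flank_after(ref: dict[str, str], d: DomainSpec, i: int) -> str:
    """Reference base i positions after the 3' end of domain d ('' off-contig)."""
    c = ref[d.contig]
    if d.strand == "+":
        p = d.end + i
        return c[p] if 0 <= p < len(c) else ""
    p = d.start - 1 - i
    return revcomp(c[p]) if 0 <= p < len(c) else ""


def _flank_before(ref: dict[str, str], d: DomainSpec, i: int) -> str:
    """Reference base i positions before the 5' start of domain d."""
    c = ref[d.contig]
    if d.strand == "+":
        p = d.start - 1 - i
        return c[p] if 0 <= p < len(c) else ""
    p = d.end + i
    return revcomp(c[p]) if 0 <= p < len(c) else ""


def realized_overlap(ref: dict[str, str], up: DomainSpec, down: DomainSpec,
                     intended: int) -> int:
    """Maximal shared homology at a junction sealed with ``intended`` overlap.

    Counts how far the shared block extends beyond the intended length on
    either side; equals ``intended`` when the generator pinned the boundaries.
    """
    up_seq = _domain_seq(ref, up)
    down_seq = _domain_seq(ref, down)
    k = intended
    extra_r = 0
    while (k + extra_r < len(down_seq)
           and _flank_after(ref, up, extra_r)
           and down_seq[k + extra_r] == _flank_after(ref, up, extra_r)):
        extra_r += 1
    extra_l = 0
    while (k + extra_l < len(up_seq)
           and _flank_before(ref, down, extra_l)
           and up_seq[-(k + 1 + extra_l)] == _flank_before(ref, down, extra_l)):
        extra_l += 1
    return k + extra_r + extra_l


def junction_pinned(ref: dict[str, str], up: DomainSpec, down: DomainSpec,
                    k: int, depth: int = 3) -> bool:
    """True iff the shared homology at the junction is exactly ``k`` bp with
    the next ``depth`` flanking bases differing position-by-position on both
    sides (so neither boundary can drift on chance matches)."""
    up_seq = _domain_seq(ref, up)
    down_seq = _domain_seq(ref, down)
    if k and up_seq[-k:] != down_seq[:k]:
        return False
    for i in range(depth):
        b = _flank_after(ref, up, i)
        if k + i >= len(down_seq) or not b or down_seq[k + i] == b:
            return False
        b = _flank_before(ref, down, i)
        if k + i >= len(up_seq) or not b or up_seq[-(k + 1 + i)] == b:
            return False
    return True


def simulate_eccdna(ref: dict[str, str], model: EccDNAModel,
                    rng: np.random.Generator | int = 0,
                    ) -> tuple[str, EccdnaTruth]:
    """Assemble the circle from its domains and inject mutations.

    Each junction's shared homology must actually be present at both flanking
    reference loci (``GenerationError`` otherwise) and is realized once in the
    circle, assigned to the upstream domain.
    """
    rng = rng if isinstance(rng, np.random.Generator) else child_rng(rng, 23)
    model.validate()
    n = len(model.domains)
    dseqs = [_domain_seq(ref, d) for d in model.domains]
    for i, k in enumerate(model.junction_homologies):
        up, down = dseqs[i], dseqs[(i + 1) % n]
        if k and up[-k:] != down[:k]:
            raise GenerationError(
                f"junction {i}: flanking loci do not share the requested "
                f"{k} bp homology")
    parts, truth_domains, pos = [], [], 0
    for i in range(n):
        trim = model.junction_homologies[(i - 1) % n]
        part = dseqs[i][trim:]
        truth_domains.append(DomainTruth(model.domains[i], pos,
                                         pos + len(part), trim))
        parts.append(part)
        pos += len(part)
    circle = "".join(parts)
    truth_junctions = []
    for i in range(n):
        j = (i + 1) % n
        anchor = truth_domains[i].circle_end % len(circle)
        truth_junctions.append(JunctionTruth(
            index=i, circle_pos=anchor,
            intended_overlap=model.junction_homologies[i],
            realized_overlap=realized_overlap(
                ref, model.domains[i], model.domains[j],
                model.junction_homologies[i]),
            up_domain=i, down_domain=j,
            is_circularization=(model.circ_junction_index == i)))
    mutated, events = inject_mutations(circle, model.mutation_model, rng)
    truth = EccdnaTruth(truth_domains, truth_junctions, events,
                        circle_len=len(mutated), premut_len=len(circle))
    return mutated, truth


# ---------------------------------------------------------------------------
# Random eccDNA structures with exactly-realizable microhomology
# ---------------------------------------------------------------------------

def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def random_eccdna_model(
    ref: dict[str, str],
    es_name: str,
    site_table: pd.DataFrame,
    rng: np.random.Generator,
    n_domains: int = 3,
    overlap_choices: Sequence[int] = (0, 1, 2, 3, 4, 5, 6),
    closing: str = "frt",
    mutation_model: MutationModel | None = None,
    donor_fraction: float = 0.0,
    domain_len: tuple[int, int] = (300, 800),
    max_tries: int = 300,
) -> EccDNAModel:
    """Sample an eccDNA whose junction homologies are exactly realizable.

    The first domain starts at the first FRT copy and contains the iPCR primer
    block; internal junctions are placed by searching for a shared k-mer whose
    flanking bases differ on both sides (so the realized homology equals the
    request).  ``closing='frt'`` seals the circle through the two identical
    FRT copies (48 bp); ``closing='blunt'`` seals it with zero overlap.
    """
    es = ref[es_name]
    feats = {r["name"]: (r["start"], r["end"]) for _, r in site_table.iterrows()}
    for needed in ("frt_1", "frt_2", "primer_R", "primer_F"):
        if needed not in feats:
            raise GenerationError(f"site table lacks feature {needed!r}")
    frt1, frt2 = feats["frt_1"], feats["frt_2"]
    pblock = (feats["primer_R"][0], feats["primer_F"][1])
    lo, hi = domain_len
    mm = mutation_model or NULL_MUTATIONS

    # Junction endpoints inside or near a repeated feature (FRT / Alu copies,
    # in the site or planted in donors) are intrinsically ambiguous to map —
    # an aligner can bridge a short unique stretch into the repeat copy at
    # the other locus.  Random junctions keep a wide berth; the circle-closing
    # FRT junction is exempt (repeat-mediated by design).
    margin = 120
    rep_seqs = {es[r["start"]:r["end"]]
                for _, r in site_table.iterrows() if r["kind"] in ("frt", "alu")}
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for cname, cseq in ref.items():
        ivals = []
        for rs in rep_seqs:
            for p in _find_all(cseq, rs):
                ivals.append((p - margin, p + len(rs) + margin))
        forbidden[cname] = ivals

    def in_repeat(contig: str, pos: int) -> bool:
        return any(a <= pos < b for a, b in forbidden[contig])

    # A same-contig template switch with a small coordinate jump is
    # indistinguishable from a plain deletion/duplication; require switches
    # to skip a sizeable region, as observed ones do.
    MIN_JUMP = 450

    def jump_ok(up: DomainSpec, tname: str, p: int) -> bool:
        if up.contig != tname:
            return True
        up_end = up.end if up.strand == "+" else up.start
        return abs(p - up_end) >= MIN_JUMP

    def overlaps_primers(contig: str, s: int, e: int) -> bool:
        return contig == es_name and s < pblock[1] and e > pblock[0]

    for _attempt in range(max_tries):
        try:
            domains: list[DomainSpec] = []
            homs: list[int] = []
            d0_end = int(rng.integers(pblock[1] + 120, pblock[1] + 320))
            domains.append(DomainSpec(es_name, frt1[0], d0_end))
            # internal domains 1 .. n-2 (free), last domain ends at frt_2 end
            for i in range(1, n_domains):
                k = int(rng.choice(list(overlap_choices)))
                up = domains[-1]
                last = i == n_domains - 1
                placed = False
                for _try in range(60):
                    use_donor = (not last and donor_fraction
                                 and rng.random() < donor_fraction)
                    tname = (str(rng.choice([c for c in ref if c != es_name]))
                             if use_donor else es_name)
                    tseq = ref[tname]
                    if last:
                        # must end at frt_2 end and leave room before it
                        length = frt2[1] - 0
                        window = (d0_end + 50, frt2[1] - 180)
                    else:
                        window = (d0_end + 50, (len(tseq) if use_donor
                                                else frt2[1]) - lo - 10)
                        if use_donor:
                            window = (lo, len(tseq) - lo - 10)
                    if window[1] <= window[0]:
                        continue
                    up_seq = _domain_seq(ref, up)
                    # internal ES domains stay inside the excised fragment
                    cap = len(tseq) - 1 if use_donor else frt2[1]

                    def domain_end(s: int) -> int:
                        if last:
                            return frt2[1]
                        e = min(s + int(rng.integers(lo, hi)), cap)
                        return e

                    def endpoint_ok(s: int, e: int) -> bool:
                        if overlaps_primers(tname, s, e):
                            return False
                        if e - s < max(120, k + 40):
                            return False
                        if in_repeat(tname, s) or not jump_ok(up, tname, s):
                            return False
                        # the forced frt_2 terminus of the last domain is the
                        # designated repeat-mediated closure
                        if not last and in_repeat(tname, e):
                            return False
                        return True

                    if k == 0:
                        s = int(rng.integers(*window))
                        e = domain_end(s)
                        cand = DomainSpec(tname, s, e)
                        if not endpoint_ok(s, e):
                            continue
                        if not junction_pinned(ref, up, cand, 0):
                            continue
                        domains.append(cand)
                        homs.append(0)
                        placed = True
                        break
                    h = up_seq[-k:]
                    occs = [p for p in _find_all(tseq, h)
                            if window[0] <= p < window[1]]
                    rng.shuffle(occs)
                    for p in occs:
                        s = p
                        e = domain_end(s)
                        cand = DomainSpec(tname, s, e)
                        if not endpoint_ok(s, e):
                            continue
                        if not junction_pinned(ref, up, cand, k):
                            continue
                        domains.append(cand)
                        homs.append(k)
                        placed = True
                        break
                    if placed:
                        break
                if not placed:
                    raise GenerationError("no valid placement")
            # closing junction: last domain ends at frt_2, domain 0 starts at
            # frt_1; the identical 48-bp copies provide the homology.
            if closing == "frt":
                homs.append(frt1[1] - frt1[0])
            elif closing == "blunt":
                if realized_overlap(ref, domains[-1], domains[0], 0) != 0:
                    raise GenerationError("blunt closure not clean")
                homs.append(0)
            else:
                raise ParameterError(f"unknown closing {closing!r}")
            model = EccDNAModel(domains, homs,
                                circ_junction_index=n_domains - 1,
                                mutation_model=mm)
            model.validate()
            if closing == "frt":
                real = realized_overlap(ref, domains[-1], domains[0], homs[-1])
                if real != homs[-1]:
                    raise GenerationError("FRT closure homology not pinned")
            return model
        except GenerationError:
            continue
    raise GenerationError(
        f"could not realize an eccDNA with the requested homologies "
        f"after {max_tries} attempts")


def single_domain_frt_model(site_table: pd.DataFrame,
                            mutation_model: MutationModel | None = None,
                            es_name: str = "ES",
                            ) -> EccDNAModel:
    """The canonical FRT-sealed circle: one domain from FRT copy 1 through
    FRT copy 2, closed through the full 48-bp FRT homology."""
    feats = {r["name"]: (r["start"], r["end"]) for _, r in site_table.iterrows()}
    frt1, frt2 = feats["frt_1"], feats["frt_2"]
    return EccDNAModel(
        domains=[DomainSpec(es_name, frt1[0], frt2[1])],
        junction_homologies=[frt1[1] - frt1[0]],
        circ_junction_index=0,
        mutation_model=mutation_model or NULL_MUTATIONS)


# ---------------------------------------------------------------------------
# Inverse-PCR concatemer reads
# ---------------------------------------------------------------------------

@dataclass
class ReadModel:
    """Concatemer read generator parameters.

    ``monomers_per_read`` maps monomer count (1..8) to probability;
    ``seq_error_rate`` is substitutions per kb (the circular-consensus
    control bound is <0.2/kb); ``spanning_fraction`` is the probability that
    a read rolls through the unamplified gap between the primer 5' ends.
    """

    monomers_per_read: dict[int, float] = field(default_factory=lambda: {
        1: 0.50, 2: 0.25, 3: 0.12, 4: 0.07, 5: 0.03, 6: 0.02, 7: 0.005,
        8: 0.005})
    seq_error_rate: float = 0.1
    spanning_fraction: float = 0.02
    n_reads: int = 100

    def __post_init__(self) -> None:
        if self.seq_error_rate < 0:
            raise ValidationError("seq_error_rate must be >= 0")
        if self.n_reads <= 0:
            raise ValidationError("n_reads must be > 0")
        if not self.monomers_per_read:
            raise ValidationError("monomers_per_read empty")
        if any(m < 1 or m > 8 for m in self.monomers_per_read):
            raise ValidationError("monomer counts must be in 1..8")
        tot = sum(self.monomers_per_read.values())
        if tot <= 0:
            raise ValidationError("monomer distribution has no mass")
        self.monomers_per_read = {m: p / tot
                                  for m, p in self.monomers_per_read.items()}


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class ReadTruth:
    read_id: str
    strand: str                     # orientation of the emitted read
    spanning: bool
    n_monomers: int
    monomer_bounds: list[tuple[int, int]]  # in emitted-read coordinates
    error_positions: list[int]
    amplicon_len: int


def simulate_ipcr_reads(circle: str, primers: tuple[str, str],
                        model: ReadModel, rng: np.random.Generator | int = 0,
                        read_prefix: str = "sim",
                        ) -> tuple[list[SimRead], list[ReadTruth]]:
    """Emit tandem-concatemer reads of the primer-to-primer amplicon.

    Each read carries 1..8 monomer copies of the amplicon (the circle minus
    the gap between the primer 5' ends); a ``spanning_fraction`` subset rolls
    through the gap so its repeated unit is the full circle.  Substitution
    errors are Poisson at ``seq_error_rate`` per kb.  Reads are emitted on a
    random strand; the truth records boundaries in emitted coordinates.
    """
    rng = rng if isinstance(rng, np.random.Generator) else child_rng(rng, 31)
    fwd, rev = primers
    L = len(circle)
    doubled = circle + circle
    pf = doubled.find(fwd)
    rr = revcomp(rev)
    if pf == -1 or pf >= L:
        raise GenerationError("forward primer not found on circle")
    rotated = doubled[pf:pf + L]
    pr = rotated.find(rr)
    if pr == -1:
        raise GenerationError("reverse primer (as reverse complement) not "
                              "found on circle; primers must be head-to-head")
    amp_len = pr + len(rr)
    amplicon = rotated[:amp_len]
    counts = sorted(model.monomers_per_read)
    probs = [model.monomers_per_read[c] for c in counts]
    reads, truths = [], []
    for i in range(model.n_reads):
        m = int(rng.choice(counts, p=probs))
        spanning = bool(rng.random() < model.spanning_fraction)
        unit = rotated if spanning else amplicon
        seq = unit * m
        n_err = rng.poisson(model.seq_error_rate * len(seq) / 1000.0)
        err_pos = sorted(int(p) for p in rng.integers(0, len(seq), n_err))
        if err_pos:
            sl = list(seq)
            for p in err_pos:
                sl[p] = str(rng.choice([b for b in BASES if b != sl[p]]))
            seq = "".join(sl)
        strand = "+" if rng.random() < 0.5 else "-"
        bounds = [(j * len(unit), j * len(unit) + amp_len) for j in range(m)]
        if strand == "-":
            seq_out = revcomp(seq)
            n = len(seq)
            bounds = [(n - e, n - s) for s, e in reversed(bounds)]
            err_out = sorted(n - 1 - p for p in err_pos)
        else:
            seq_out, err_out = seq, err_pos
        rid = f"{read_prefix}/{i}"
        reads.append(SimRead(rid, seq_out, "I" * len(seq_out)))
        truths.append(ReadTruth(rid, strand, spanning, m, bounds, err_out,
                                amp_len))
    return reads, truths


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq(path, reads: Iterable[SimRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_feature_bed(path, contig: str, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, r in table.iterrows():
            fh.write(f"{contig}\t{r['start']}\t{r['end']}\t{r['name']}\t0\t"
                     f"{r['strand']}\n")


def truth_to_json(path, circle_truths: list[EccdnaTruth],
                  read_truths: list[list[ReadTruth]]) -> None:
    payload = {
        "circles": [asdict(t) for t in circle_truths],
        "reads": [[asdict(t) for t in rts] for rts in read_truths],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=int)
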