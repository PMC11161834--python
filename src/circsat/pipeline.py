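"""End-to-end orchestration: simulate -> decat -> segmap -> junctions -> mutquant.

`simulate_dataset` builds a reference (ectopic site + donors), samples eccDNA
structures with realizable microhomology junctions, mutagenizes them and emits
concatemer reads with truth.  `analyze_reads` runs the full analysis on any
read set against a hybrid reference and returns per-stage objects plus a
count-consistent report.  `run_pipeline` wires both to the filesystem,
`compare_conditions` contrasts runs, and `make_fixtures` writes deterministic
desk-scale bundles.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decat, junctions as junc, mutquant, refsim, segmap
from ._seq import child_rng
from .errors import CircsatError, GenerationError, ValidationError
from .refsim import (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER, EccdnaTruth,
                     MutationModel, NULL_MUTATIONS, ReadModel, ReadTruth,
                     SimRead)
from .segmap import DomainChain, HybridReference


# Published per-generation eccDNA mutation rates for each microsatellite
# clone (rows A–G of the quantitation table; generations of outgrowth).
ECCDNA_RATE_PRESETS: dict[str, dict[str, float]] = {
    "CAG102_c10": dict(A=1.28e-6, B=8.00e-6, C=8.75e-5, D=10.9, E=7.15e-6,
                       F=1.67e-5, G=2.3, H=1.04e-4, generations=200),
    "CAG102_c13": dict(A=2.46e-6, B=8.72e-6, C=4.07e-5, D=4.7, E=6.09e-6,
                       F=9.07e-6, G=1.5, H=5.37e-5, generations=200),
    "CAG102_c13_polH_kd": dict(A=2.16e-6, B=8.10e-6, C=4.21e-5, D=5.2,
                               E=5.43e-6, F=4.79e-5, G=8.8, H=9.22e-5,
                               generations=200),
    "G4_c1": dict(A=4.70e-6, B=5.81e-6, C=1.27e-5, D=2.2, E=8.00e-6,
                  F=1.02e-5, G=1.3, H=7.30e-5, generations=150),
    "G4_c6": dict(A=5.00e-6, B=1.70e-6, C=8.58e-6, D=5.0, E=8.58e-6,
                  F=2.16e-5, G=2.5, H=4.36e-5, generations=150),
    "H3": dict(A=3.99e-6, B=1.40e-6, C=8.35e-6, D=6.0, E=9.98e-6,
               F=2.05e-5, G=2.1, H=3.85e-5, generations=150),
    "ATTCT47": dict(A=4.22e-6, B=4.72e-6, C=7.78e-6, D=1.7, E=4.42e-6,
                    F=5.27e-6, G=1.2, H=5.67e-5, generations=200),
}


def mutation_model_from_rates(preset: str | dict[str, float],
                              ) -> MutationModel:
    """Build a MutationModel matching a measured rate column: event rates are
    taken directly, length means are the per-event ratios C/B and F/E."""
    r = ECCDNA_RATE_PRESETS[preset] if isinstance(preset, str) else preset
    return MutationModel(
        mismatch_rate=r["A"], del_event_rate=r["B"],
        del_len_mean=r["C"] / r["B"], ins_event_rate=r["E"],
        ins_len_mean=r["F"] / r["E"], generations=int(r["generations"]))


# ---------------------------------------------------------------------------
# Simulation bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    preset: str = "CAG102"
    seed: int = 0
    n_circles: int = 10
    reads_per_circle: int = 4
    n_domains: int = 3
    overlap_choices: tuple = (0, 1, 2, 3, 4, 5, 6)
    closing: str = "frt"
    donor_fraction: float = 0.0
    n_donors: int = 2
    mutation_model: MutationModel = field(default_factory=MutationModel)
    monomers_per_read: dict | None = None
    seq_error_rate: float = 0.0
    spanning_fraction: float = 0.0
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER


@dataclass
class SimBundle:
    config: SimulationConfig
    es_name: str
    site_table: pd.DataFrame
    contigs: dict[str, str]
    fwd: str
    rev: str
    circles: list[str]
    circle_truths: list[EccdnaTruth]
    reads: list[SimRead]
    read_truths: list[ReadTruth]
    read_circle: dict[str, int]
    n_unamplified: int = 0

    @property
    def reference(self) -> HybridReference:
        return HybridReference(self.contigs, self.es_name)


def simulate_dataset(config: SimulationConfig) -> SimBundle:
    """Deterministic full simulation under one seed."""
    site_rng = child_rng(config.seed, 1)
    spec, es_seq, table = refsim.default_ectopic_site(
        config.preset, seed=int(site_rng.integers(0, 2**31 - 1)),
        fwd_primer=config.fwd_primer, rev_primer=config.rev_primer)
    es_name = spec.contig_name
    contigs = {es_name: es_seq}
    if config.n_donors:
        alu = next(f.sequence for f in spec.features if f.kind == "alu")
        contigs.update(refsim.make_donor_contigs(
            child_rng(config.seed, 2), n=config.n_donors, alu=alu))
    circles, truths, reads, read_truths, read_circle = [], [], [], [], {}
    n_unamplified = 0
    for ci in range(config.n_circles):
        rng = child_rng(config.seed, 100 + ci)
        if config.n_domains == 1:
            model = refsim.single_domain_frt_model(
                table, config.mutation_model, es_name=es_name)
        else:
            model = refsim.random_eccdna_model(
                contigs, es_name, table, rng,
                n_domains=config.n_domains,
                overlap_choices=config.overlap_choices,
                closing=config.closing,
                mutation_model=config.mutation_model,
                donor_fraction=config.donor_fraction)
        circle, truth = refsim.simulate_eccdna(contigs, model, rng)
        circles.append(circle)
        truths.append(truth)
        rmodel = ReadModel(
            monomers_per_read=config.monomers_per_read or {1: 0.6, 2: 0.25,
                                                           3: 0.15},
            seq_error_rate=config.seq_error_rate,
            spanning_fraction=config.spanning_fraction,
            n_reads=config.reads_per_circle)
        try:
            c_reads, c_truths = refsim.simulate_ipcr_reads(
                circle, (config.fwd_primer, config.rev_primer), rmodel,
                child_rng(config.seed, 5000 + ci), read_prefix=f"ecc{ci}")
        except GenerationError:
            # a mutation hit a primer site: the circle does not amplify
            n_unamplified += 1
            continue
        reads.extend(c_reads)
        read_truths.extend(c_truths)
        for r in c_reads:
            read_circle[r.read_id] = ci
    return SimBundle(config, es_name, table, contigs, config.fwd_primer,
                     config.rev_primer, circles, truths, reads, read_truths,
                     read_circle, n_unamplified)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    max_edits: int = 2
    min_len: int = 30
    min_identity: float = 0.8
    specificity_k: int = 6
    verify_k: int = 25
    max_query_overlap: int = 300
    generations: int = 200
    threshold: float | None = None  # mutations/kb; None = no read filter


@dataclass
class AnalysisResult:
    monomers: list
    nonspecific: list
    duplicates: list
    chains: dict[str, DomainChain]
    unmapped: list[str]
    junctions: list
    circ_junctions: dict[str, object]
    pile: mutquant.Pileup
    rates: mutquant.RateTable
    rates_thresholded: mutquant.RateTable | None
    signature: mutquant.SignatureVector
    read_stats: list
    report: dict


def analyze_reads(reads: list[tuple[str, str]] | list[SimRead],
                  ref: HybridReference, fwd: str, rev: str,
                  params: PipelineParams | None = None,
                  site_table: pd.DataFrame | None = None) -> AnalysisResult:
    """Run decatenation, specificity filtering, deduplication, segmentation,
    junction quantitation and mutation metrics on a read set."""
    params = params or PipelineParams()
    pairs = [(r.read_id, r.sequence) if isinstance(r, SimRead) else tuple(r)
             for r in reads]
    es_seq = ref.contigs[ref.es_contig_name]

    monomers, decat_stats = [], []
    for rid, seq in pairs:
        hits = decat.find_primer_sites(seq, fwd, rev, params.max_edits)
        ms, st = decat.decatenate(rid, seq, hits)
        monomers.extend(ms)
        decat_stats.append(st)
    kept, nonspecific = decat.filter_specific(
        monomers, es_seq, fwd, rev, params.specificity_k)
    unique, duplicates = decat.deduplicate(kept)

    chains: dict[str, DomainChain] = {}
    unmapped: list[str] = []
    monomer_seqs: dict[str, str] = {}
    for m in unique:
        monomer_seqs[m.monomer_id] = m.sequence
        segs = segmap.align_segments(m.monomer_id, m.sequence, ref,
                                     params.min_len, params.min_identity)
        ch = segmap.chain_domains(segs, params.max_query_overlap,
                                  query_length=len(m.sequence))
        if ch.domains:
            chains[m.monomer_id] = ch
        else:
            unmapped.append(m.monomer_id)

    all_junctions, circ = [], {}
    for mid, ch in chains.items():
        js = junc.annotate_junctions(ch, monomer_seqs[mid], ref)
        cj = junc.detect_circularization_junction(ch, js, ref, site_table)
        if cj is not None:
            circ[mid] = cj
        all_junctions.extend(js)

    pile = mutquant.pileup(chains.values(), ref)
    totals = pile.totals()
    rates = (mutquant.mutation_rates(totals, generations=params.generations)
             if totals["aligned_bp"] else None)
    read_stats = [mutquant.chain_mutation_stats(ch) for ch in chains.values()]
    rates_thr = None
    if params.threshold is not None and chains:
        kept_stats, _ = mutquant.apply_mutation_threshold(
            read_stats, params.threshold)
        keep_ids = {s.read_id for s in kept_stats}
        pile_thr = mutquant.pileup(
            (ch for mid, ch in chains.items() if mid in keep_ids), ref)
        t2 = pile_thr.totals()
        if t2["aligned_bp"]:
            rates_thr = mutquant.mutation_rates(
                t2, generations=params.generations)
    signature = mutquant.trinucleotide_signature(pile.mismatch_calls(), ref)

    report = _build_report(pairs, decat_stats, monomers, nonspecific,
                           duplicates, unique, chains, unmapped,
                           all_junctions, circ, totals, rates, signature,
                           params)
    return AnalysisResult(unique, nonspecific, duplicates, chains, unmapped,
                          all_junctions, circ, pile,
                          rates, rates_thr, signature, read_stats, report)


def _build_report(pairs, decat_stats, monomers, nonspecific, duplicates,
                  unique, chains, unmapped, all_junctions, circ, totals,
                  rates, signature, params) -> dict:
    n_monomers = len(monomers)
    counts = {
        "reads": len(pairs),
        "monomers": n_monomers,
        "nonspecific": len(nonspecific),
        "specific": n_monomers - len(nonspecific),
        "duplicates": len(duplicates),
        "unique": len(unique),
        "mapped": len(chains),
        "unmapped": len(unmapped),
        "discarded_fragments": sum(s.discarded_fragments for s in decat_stats),
        "ambiguous": sum(s.ambiguous for s in decat_stats),
    }
    # conservation: every stage's inputs equal outputs + removals
    if counts["specific"] != counts["unique"] + counts["duplicates"]:
        raise CircsatError("stage count mismatch: dedup")
    if counts["unique"] != counts["mapped"] + counts["unmapped"]:
        raise CircsatError("stage count mismatch: mapping")
    ovl = junc.overlap_distribution(all_junctions)
    return {
        "counts": counts,
        "totals": totals,
        "rates": (rates.as_series().to_dict() if rates else None),
        "junctions": {
            "n": len(all_junctions),
            "n_circularization": len(circ),
            "by_class": pd.Series(
                [j.junction_class for j in all_junctions]
            ).value_counts().to_dict() if all_junctions else {},
            "overlap_lengths": ovl.values,
            "mean_overlap": ovl.mean if ovl.values else None,
        },
        "signature_classes": signature.class_marginals.to_dict(),
        "params": asdict(params),
    }


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    reads: str | None = None            # FASTQ/FASTA; None -> simulate
    reference: str | None = None        # hybrid FASTA; None -> simulate
    es_contig: str | None = None
    fwd: str = DEFAULT_FWD_PRIMER
    rev: str = DEFAULT_REV_PRIMER
    params: PipelineParams = field(default_factory=PipelineParams)
    simulate: SimulationConfig | None = None


def _read_seqs(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO
    fmt = "fastq" if str(path).endswith(("fq", "fastq")) else "fasta"
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write per-stage outputs and a machine-readable report
    under ``config.outdir``; rerunning with identical config and seeds is
    byte-identical."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    site_table = None
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed if sim.seed == 0 else sim.seed
        bundle = simulate_dataset(sim)
        ref = bundle.reference
        reads = [(r.read_id, r.sequence) for r in bundle.reads]
        fwd, rev = bundle.fwd, bundle.rev
        site_table = bundle.site_table
        refsim.write_fasta(out / "reference.fa", bundle.contigs.items())
        refsim.write_fastq(out / "reads.fq", bundle.reads)
        refsim.write_feature_bed(out / "features.bed", bundle.es_name,
                                 bundle.site_table)
        refsim.truth_to_json(out / "truth.json", bundle.circle_truths,
                             [bundle.read_truths])
    else:
        if not (config.reads and config.reference and config.es_contig):
            raise ValidationError(
                "reads, reference and es_contig are required when not "
                "simulating")
        for p in (config.reads, config.reference):
            if not Path(p).exists():
                raise ValidationError(f"input does not exist: {p}")
        ref = HybridReference.from_fasta(config.reference, config.es_contig)
        reads = _read_seqs(config.reads)
        fwd, rev = config.fwd, config.rev
    res = analyze_reads(reads, ref, fwd, rev, config.params, site_table)

    refsim.write_fasta(
        out / "monomers.fa",
        ((f"{m.monomer_id}|strand={m.read_strand}|specific={m.specific}",
          m.sequence) for m in res.monomers))
    qlens = {m.monomer_id: len(m.sequence) for m in res.monomers}
    segmap.write_paf([d for ch in res.chains.values() for d in ch.domains],
                     out / "domains.paf", qlens, ref)
    segmap.domains_to_bed(list(res.chains.values())).to_csv(
        out / "domains.bed", sep="\t", header=False, index=False)
    segmap.links_table(list(res.chains.values())).to_csv(
        out / "links.tsv", sep="\t", index=False)
    junc.junction_table(res.junctions).to_csv(
        out / "junctions.tsv", sep="\t", index=False)
    if res.rates is not None:
        mutquant.rate_table_frame({"sample": res.rates}).to_csv(
            out / "rates.tsv", sep="\t")
    res.signature.counts.rename("count").to_csv(out / "signature.tsv",
                                                sep="\t")
    report = dict(res.report)
    report["provenance"] = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str)
            .encode()).hexdigest()[:16],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("outdir", None)  # hash reflects the analysis, not where it lands
    return d


def compare_conditions(reports: list[dict], names: list[str] | None = None,
                       seed: int = 1729) -> pd.DataFrame:
    """Side-by-side rates, junction-class frequencies and overlap summaries
    across runs, with pairwise permutation tests on overlap lengths."""
    if len(reports) < 2:
        raise ValidationError("need >= 2 reports to compare")
    names = names or [f"cond{i}" for i in range(len(reports))]
    rows = {}
    for name, rep in zip(names, reports):
        r = rep.get("rates") or {}
        j = rep.get("junctions", {})
        rows[name] = {
            **{f"rate_{k}": r.get(k) for k in "ABCDEFGH"},
            "n_junctions": j.get("n"),
            "mean_overlap": j.get("mean_overlap"),
            **{f"class_{k}": v for k, v in (j.get("by_class") or {}).items()},
        }
    df = pd.DataFrame(rows)
    for i, (na, ra) in enumerate(zip(names, reports)):
        for nb, rb in list(zip(names, reports))[i + 1:]:
            va = ra["junctions"].get("overlap_lengths") or []
            vb = rb["junctions"].get("overlap_lengths") or []
            if len(va) >= 2 and len(vb) >= 2:
                p = _perm_p(np.asarray(va, float), np.asarray(vb, float),
                            seed)
                df.loc[f"perm_p_vs_{nb}", na] = p
                df.loc[f"perm_p_vs_{na}", nb] = p
    return df


def _perm_p(a: np.ndarray, b: np.ndarray, seed: int,
            n_perm: int = 999) -> float:
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = a.size
    cnt = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n].mean() - pooled[n:].mean()) >= obs:
            cnt += 1
    return (1.0 + cnt) / (n_perm + 1.0)


def make_fixtures(outdir: str, scale: str = "tiny", seed: int = 0) -> dict:
    """Deterministic packaged test inputs (site FASTA, reads FASTQ, truth
    JSON, feature BED)."""
    if scale == "tiny":
        cfg = SimulationConfig(seed=seed, n_circles=2, reads_per_circle=4,
                               n_domains=1)
    elif scale == "demo":
        cfg = SimulationConfig(
            seed=seed, n_circles=25, reads_per_circle=4, n_domains=3,
            mutation_model=mutation_model_from_rates("CAG102_c10"),
            donor_fraction=0.3, seq_error_rate=0.1, spanning_fraction=0.02)
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_dataset(cfg)
    refsim.write_fasta(out / "reference.fa", bundle.contigs.items())
    refsim.write_fastq(out / "reads.fq", bundle.reads)
    refsim.write_feature_bed(out / "features.bed", bundle.es_name,
                             bundle.site_table)
    refsim.truth_to_json(out / "truth.json", bundle.circle_truths,
                         [bundle.read_truths])
    return {"reference": str(out / "reference.fa"),
            "reads": str(out / "reads.fq"),
            "features": str(out / "features.bed"),
            "truth": str(out / "truth.json"),
            "es_contig": bundle.es_name,
            "fwd": bundle.fwd, "rev": bundle.rev}
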