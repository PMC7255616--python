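"""End-to-end pipeline: simulate -> probes -> map-ends -> model -> identity
-> retroscan -> synteny, driven by a single structured configuration.

Every stage writes TSV/GFF3/BED/FASTA outputs stamped with the run seed and
a hash of the configuration, and draws its randomness from a named
substream of the one seed, so stages are independently reproducible and two
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as lio
from .expression import (call_five_prime, call_three_prime, count_probe_hits,
                         paralog_expression_ratio)
from .identity import exon_identity_table, protein_identity_table
from .models import (GeneModel, extract_cds, model_lengths, splice_transcript,
                     translate_cds, validate_reported_totals)
from .probes import discriminating_probes, tile_probes
from .retrocopy import chain_blocks, classify_retrocopy, exon_homology_scan
from .simulate import (SimulationConfig, mutate_sequence, plant_retrocopy,
                       simulate_gene, simulate_neighborhood, simulate_reads,
                       substream)
from .synteny import compare_loci

__all__ = ["RunConfig", "run_pipeline", "structure_frame"]

STAGES = ("simulate", "probes", "map_ends", "model", "identity",
          "retroscan", "synteny")


@dataclass
class RunConfig:
    """Run configuration: stage toggles, module parameters, paths, seed."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    probe_length: int = 60
    probe_step: Optional[int] = None
    max_mismatches: int = 2
    boundary_pad: int = 200
    plant_retrocopy_divergence: Optional[float] = 0.05
    retrocopy_insertion_point: Optional[int] = None  # default: 500 nt from 3' flank end
    clade_divergences: tuple[float, ...] = (0.05, 0.10)
    other_locus: tuple[tuple[str, str, int], ...] = (
        ("Slbp2", "-", 2000), ("Zmat2", "+", 2337), ("Lcp2a", "+", 4000),
    )
    genome_fasta: Optional[str] = None
    annotation_gff3: Optional[str] = None
    reads_fastq: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # the simulation inherits the run seed
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        for key in ("exon_lengths", "intron_lengths", "isoform_weights",
                    "neighbor_genes"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in sim[key])
        if "isoforms" in sim and sim["isoforms"] is not None:
            sim["isoforms"] = tuple(tuple(i) for i in sim["isoforms"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "other_locus" in raw:
            raw["other_locus"] = tuple(tuple(g) for g in raw["other_locus"])
        if "clade_divergences" in raw:
            raw["clade_divergences"] = tuple(raw["clade_divergences"])
        return cls(simulation=SimulationConfig(**sim), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def metadata(self) -> dict:
        # hash the scientific parameters only, not where files live
        params = self.to_dict()
        for key in ("out_dir", "genome_fasta", "annotation_gff3", "reads_fastq"):
            params.pop(key, None)
        return {"seed": self.seed, "config": lio.config_hash(params)}


def structure_frame(models: list[GeneModel]) -> pd.DataFrame:
    """Gene-structure summary: exon/intron lengths alternating, then total."""
    n_max = max(m.n_exons for m in models)
    columns = []
    for k in range(1, n_max + 1):
        columns.append(f"Exon {k}")
        if k < n_max:
            columns.append(f"Intron {k}")
    columns.append("Total Length")
    rows = {}
    for m in models:
        row = {}
        for k, exon in enumerate(m.exons, start=1):
            row[f"Exon {k}"] = exon.length
            if k <= len(m.introns):
                row[f"Intron {k}"] = m.introns[k - 1]
        row["Total Length"] = model_lengths(m).gene_length
        rows[m.name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns output paths and key objects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    ctx: dict = {"outputs": {}, "metadata": meta}

    def _stage(name):
        return name in config.stages

    def _run(name, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    # ---- inputs / simulation ----
    def do_simulate():
        cfg = config.simulation
        genome, truth = simulate_gene(cfg)
        if config.plant_retrocopy_divergence is not None:
            point = config.retrocopy_insertion_point
            if point is None:
                point = len(genome) - 500
            genome, truth = plant_retrocopy(
                genome, truth, config.plant_retrocopy_divergence, point)
        reads = simulate_reads(genome, truth, cfg)
        ctx.update(genome=genome, truth=truth, reads=reads,
                   model=truth.gene_model)
        lio.write_fasta(out / "genome.fa", {"chr1": genome})
        lio.write_gff3(out / "model.gff3", truth.isoform_models, metadata=meta)
        lio.write_fastq(out / "reads.fastq", reads)
        truth_frame = pd.DataFrame([{
            "tss": truth.tss_position,
            "cleavage": truth.cleavage_position,
            "hexamer": truth.hexamer_position,
            "retrocopy_start": truth.retrocopy_span[0] if truth.retrocopy_span else "",
            "retrocopy_end": truth.retrocopy_span[1] if truth.retrocopy_span else "",
        }])
        lio.write_tsv(out / "truth.tsv", truth_frame, metadata=meta, index=False)
        ctx["outputs"]["simulate"] = ["genome.fa", "model.gff3", "reads.fastq",
                                      "truth.tsv"]

    if _stage("simulate"):
        _run("simulate", do_simulate)
    else:
        if config.genome_fasta:
            ctx["genome"] = next(iter(lio.read_fasta(config.genome_fasta).values()))
        if config.annotation_gff3:
            models = lio.read_gff3(config.annotation_gff3)
            ctx["model"] = models[0]
            ctx["truth"] = None
        if config.reads_fastq:
            ctx["reads"] = lio.read_fastq(config.reads_fastq)

    # ---- probes ----
    def do_probes():
        genome, model = ctx["genome"], ctx["model"]
        spans = model.exon_genomic_spans()
        pad = config.boundary_pad
        r5_lo = max(0, spans[0][0] - pad)
        region5 = genome[r5_lo : spans[0][1] + 50]
        r3_lo = max(0, spans[-1][0] - 50)
        region3 = genome[r3_lo : min(len(genome), spans[-1][1] + pad)]
        p5 = tile_probes(region5, config.probe_length, config.probe_step, "exon1")
        p3 = tile_probes(region3, config.probe_length, config.probe_step, "exon_last")
        ctx.update(region5=region5, region5_offset=r5_lo,
                   region3=region3, region3_offset=r3_lo,
                   probes5=p5, probes3=p3)
        lio.probes_to_bed(out / "probes_5p.bed", p5, region_offset=r5_lo)
        lio.probes_to_bed(out / "probes_3p.bed", p3, region_offset=r3_lo)
        lio.write_probe_fasta(out / "probes_5p.fa", p5)
        lio.write_probe_fasta(out / "probes_3p.fa", p3)
        ctx["outputs"]["probes"] = ["probes_5p.bed", "probes_3p.bed",
                                    "probes_5p.fa", "probes_3p.fa"]

    if _stage("probes") and "genome" in ctx and "model" in ctx:
        _run("probes", do_probes)

    # ---- map ends ----
    def do_map_ends():
        reads = ctx["reads"]
        model = ctx["model"]
        atg = config.boundary_pad + model.exons[0].utr5  # region5 coordinate
        call5 = call_five_prime(ctx["region5"], reads,
                                max_mismatches=config.max_mismatches,
                                atg_position=atg)
        call3, site = call_three_prime(ctx["region3"], reads,
                                       max_mismatches=config.max_mismatches)
        prof5 = count_probe_hits(ctx["probes5"], reads, config.max_mismatches)
        prof3 = count_probe_hits(ctx["probes3"], reads, config.max_mismatches)
        rows = [
            {"side": "5'", "position": ctx["region5_offset"] + call5.position,
             "method": call5.method, "support": call5.support_reads,
             "confidence": call5.confidence, "utr_length": call5.utr_length},
            {"side": "3'", "position": ctx["region3_offset"] + call3.position,
             "method": call3.method, "support": call3.support_reads,
             "confidence": call3.confidence, "utr_length": ""},
        ]
        lio.write_tsv(out / "boundaries.tsv", pd.DataFrame(rows), metadata=meta,
                      index=False)
        profile_frame = pd.DataFrame(
            [{"probe": k, "hits": v, "region": "5'"} for k, v in prof5.counts.items()]
            + [{"probe": k, "hits": v, "region": "3'"} for k, v in prof3.counts.items()]
        )
        lio.write_tsv(out / "probe_hits.tsv", profile_frame, metadata=meta,
                      index=False)
        if site is not None:
            g_hex = ctx["region3_offset"] + site.hexamer_position
            g_cle = ctx["region3_offset"] + site.cleavage_position
            lio.write_bed(out / "polya.bed",
                          [(g_hex, g_hex + 6, f"polyA_signal_{site.hexamer}"),
                           (g_cle, g_cle + 1, "cleavage_site")])
        ctx.update(call5=call5, call3=call3, polya=site)
        ctx["outputs"]["map_ends"] = ["boundaries.tsv", "probe_hits.tsv", "polya.bed"]

    if _stage("map_ends") and "reads" in ctx and "region5" in ctx:
        _run("map_ends", do_map_ends)

    # ---- model arithmetic ----
    def do_model():
        model = ctx["model"]
        frame = structure_frame([model])
        lio.write_tsv(out / "gene_structure.tsv", frame, metadata=meta)
        lengths = model_lengths(model)
        report = validate_reported_totals(model, lengths.gene_length,
                                          lengths.mrna_length)
        lio.write_tsv(out / "model_validation.tsv",
                      pd.DataFrame(report.comparisons), metadata=meta, index=False)
        ctx["outputs"]["model"] = ["gene_structure.tsv", "model_validation.tsv"]

    if _stage("model") and "model" in ctx:
        _run("model", do_model)

    # ---- identity tables on a simulated clade ----
    def do_identity():
        genome, model = ctx["genome"], ctx["model"]
        rng = substream(config.seed, "clade")
        spans = model.exon_genomic_spans()
        ref_exons = {f"exon{k}": genome[s:e]
                     for k, (s, e) in enumerate(spans, start=1)}
        others = {}
        for div in config.clade_divergences:
            others[f"clade_{div:g}"] = {
                label: mutate_sequence(seq, div, rng)
                for label, seq in ref_exons.items()
            }
        exon_table = exon_identity_table(ref_exons, others)
        lio.write_tsv(out / "exon_identity.tsv", exon_table, metadata=meta)
        transcript = splice_transcript(genome, model)
        if model.translatable:
            ref_prot = translate_cds(extract_cds(transcript, model)).sequence
            prot_others = {}
            for div in config.clade_divergences:
                # protein-level divergence emulated directly
                mutated = list(ref_prot)
                hits = rng.random(len(mutated)) < div
                aas = "ARNDCQEGHILKMFPSTWYV"
                for i, hit in enumerate(hits):
                    if hit:
                        choices = aas.replace(mutated[i], "")
                        mutated[i] = choices[rng.integers(0, len(choices))]
                prot_others[f"clade_{div:g}"] = "".join(mutated)
            prot_table = protein_identity_table(("reference", ref_prot), prot_others)
            lio.write_tsv(out / "protein_identity.tsv", prot_table, metadata=meta)
        ctx["outputs"]["identity"] = ["exon_identity.tsv", "protein_identity.tsv"]

    if _stage("identity") and "genome" in ctx and "model" in ctx:
        _run("identity", do_identity)

    # ---- retrocopy scan ----
    def do_retroscan():
        genome, model = ctx["genome"], ctx["model"]
        spans = model.exon_genomic_spans()
        exon_seqs = [genome[s:e] for s, e in spans]
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        exon_lengths = [e.length for e in model.exons]
        blocks = exon_homology_scan(exon_seqs, genome, exclude_span=(lo, hi))
        chains = chain_blocks(blocks)
        calls = []
        for chain in chains:
            ratio = None
            profile = None
            if "reads" in ctx and chain.intronless(exon_lengths=exon_lengths):
                # discriminating probes between parent transcript and copy
                transcript = splice_transcript(genome, model)
                copy_seq = genome[chain.span[0] : chain.span[1]]
                d_parent = discriminating_probes(transcript, copy_seq,
                                                 config.probe_length,
                                                 source="parent")[:6]
                d_copy = discriminating_probes(copy_seq, transcript,
                                               config.probe_length,
                                               source="copy")[:6]
                if d_parent and d_copy:
                    prof_parent = count_probe_hits(
                        d_parent, ctx["reads"], config.max_mismatches,
                        min_overlap=config.probe_length)
                    profile = count_probe_hits(
                        d_copy, ctx["reads"], config.max_mismatches,
                        min_overlap=config.probe_length)
                    ratio = paralog_expression_ratio(prof_parent, profile)
            calls.append(classify_retrocopy(chain, expression_profile=profile,
                                            ratio=ratio,
                                            exon_lengths=exon_lengths))
        rows = [{
            "classification": c.classification,
            "start": c.blocks[0].start,
            "end": c.blocks[-1].end,
            "strand": c.blocks[0].strand,
            "n_exon_blocks": len(c.blocks),
            "intronless": c.intronless,
            "max_gap": c.max_gap_observed,
            "expressed": c.expressed,
            "expression_ratio_pct": "" if c.expression_ratio is None
            else round(c.expression_ratio, 1),
            "mean_identity_pct": round(
                sum(b.identity for b in c.blocks) / len(c.blocks), 1),
        } for c in calls]
        lio.write_tsv(out / "retrocopy_calls.tsv", pd.DataFrame(rows),
                      metadata=meta, index=False)
        with open(out / "retrocopy.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for k, c in enumerate(calls, 1):
                ftype = "gene" if c.classification == "retrocopy" else "pseudogene"
                g1, g2 = lio.to_gff3_interval(c.blocks[0].start, c.blocks[-1].end)
                fh.write(f"chr1\tlocuskit\t{ftype}\t{g1}\t{g2}\t.\t"
                         f"{c.blocks[0].strand}\t.\t"
                         f"ID={c.classification}:{k}\n")
        ctx["retrocopy_calls"] = calls
        ctx["outputs"]["retroscan"] = ["retrocopy_calls.tsv", "retrocopy.gff3"]

    if _stage("retroscan") and "genome" in ctx and "model" in ctx:
        _run("retroscan", do_retroscan)

    # ---- synteny ----
    def do_synteny():
        cfg = config.simulation
        _, map_a = simulate_neighborhood(cfg)
        other = dataclasses.replace(
            cfg, neighbor_genes=config.other_locus,
            chromosome_length=max(cfg.chromosome_length,
                                  2 * sum(l for _, _, l in config.other_locus)))
        _, map_b = simulate_neighborhood(other)
        comparison = compare_loci(map_a, map_b, synonyms={"lcp2a": "lcp2"})
        frame = pd.DataFrame([{
            "shared": ",".join(sorted(comparison.shared)),
            "n_shared": len(comparison.shared),
            "order_congruent": comparison.order_congruent,
            "orientation_flips": ",".join(comparison.orientation_flips),
            "jaccard": round(comparison.jaccard, 3),
        }])
        lio.write_tsv(out / "synteny.tsv", frame, metadata=meta, index=False)
        ctx["synteny"] = comparison
        ctx["outputs"]["synteny"] = ["synteny.tsv"]

    if _stage("synteny"):
        _run("synteny", do_synteny)

    # ---- report ----
    report = {
        "seed": config.seed,
        "config_hash": meta["config"],
        "stages_run": [s for s in config.stages if s in ctx["outputs"]],
        "outputs": ctx["outputs"],
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    ctx["report"] = report
    return ctx
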