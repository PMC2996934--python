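"""Pipeline configuration and end-to-end orchestration.

``run_pipeline`` executes simulate -> call -> stats -> panel -> validate on a
synthetic population and writes every artifact of the workflow: reference
FASTA, truth VCF, reads (FASTQ + SAM), called-sites VCF, per-cat rate table,
per-chromosome category table, window bedGraph, occupancy curve, panel BED
and summary, validation report and a machine-readable summary JSON.  All
randomness flows from the single config seed through stable hash-derived
child seeds, and no artifact embeds a timestamp, so identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import nqs, panel as panel_mod, stats as stats_mod, validation as val_mod
from .io import (
    ReferenceAssembly,
    VcfRecord,
    ensure_dir,
    site_to_vcf_alleles,
    vcf_alleles_to_site,
    read_vcf,
    write_bed,
    write_bedgraph,
    write_tsv,
    write_vcf,
)
from .nqs import NqsParams, VariantSite
from .simulate import (
    PopulationModel,
    ReadModel,
    simulate_population,
    simulate_reads,
    write_truth,
)

log = logging.getLogger("felsnp")


@dataclass
class StatsConfig:
    window: int = 1_000_000
    low_threshold: int = 100
    occupancy_sizes: tuple[int, ...] = (2_000, 5_000, 15_000, 50_000)
    include_unmapped: bool = False


@dataclass
class PanelConfig:
    spacing: int = 15_000
    backfill: bool = True
    method: str = "window"


@dataclass
class ValidationConfig:
    n: int = 94
    min_gap_distance: int = 750


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "felsnp_out"
    log_level: str = "INFO"
    population: PopulationModel = field(default_factory=PopulationModel)
    reads: ReadModel = field(default_factory=ReadModel)
    nqs: NqsParams = field(default_factory=NqsParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "population" in d and not isinstance(d["population"], PopulationModel):
            pop = dict(d["population"])
            if "individuals" in pop:
                pop["individuals"] = [
                    i if not isinstance(i, dict) else _individual_from_dict(i)
                    for i in pop["individuals"]
                ]
            d["population"] = PopulationModel(**pop)
        for key, typ in (
            ("reads", ReadModel),
            ("nqs", NqsParams),
            ("stats", StatsConfig),
            ("panel", PanelConfig),
            ("validation", ValidationConfig),
        ):
            if key in d and not isinstance(d[key], typ):
                sub = dict(d[key])
                if key == "stats" and "occupancy_sizes" in sub:
                    sub["occupancy_sizes"] = tuple(sub["occupancy_sizes"])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _individual_from_dict(d: dict):
    from .simulate import Individual

    return Individual(name=d["name"], sex=d["sex"], klass=d["klass"])


# ---------------------------------------------------------------------------
# VCF <-> VariantSite
# ---------------------------------------------------------------------------


def calls_vcf_records(sites, assembly: ReferenceAssembly) -> list[VcfRecord]:
    records = []
    order = {n: i for i, n in enumerate(assembly.names)}
    for site in sorted(sites, key=lambda s: (order.get(s.chrom, 1 << 30), s.pos, s.alt)):
        pos, ref, alt = site_to_vcf_alleles(
            assembly, site.chrom, site.pos, site.vtype, site.ref, site.alt
        )
        disc = sorted(site.support)
        records.append(
            VcfRecord(
                chrom=site.chrom,
                pos=pos,
                ref=ref,
                alt=alt if alt else ".",
                info={
                    "TYPE": site.vtype,
                    "DISC": disc,
                    "SUP": [site.support[d] for d in disc],
                },
            )
        )
    return records


def sites_from_vcf(path) -> list[VariantSite]:
    """Read a calls VCF (DISC/SUP/TYPE INFO) back into VariantSites."""
    records, _ = read_vcf(path)
    sites = []
    for rec in records:
        pos, vtype, ref, alt = vcf_alleles_to_site(rec.pos, rec.ref, rec.alt)
        disc = rec.info.get("DISC", [])
        if isinstance(disc, str):
            disc = [disc]
        sup = rec.info.get("SUP", [])
        if isinstance(sup, int):
            sup = [sup]
        support = {d: int(s) for d, s in zip(disc, sup)} or {d: 1 for d in disc}
        sites.append(
            VariantSite(
                chrom=rec.chrom, pos=pos, vtype=vtype, ref=ref, alt=alt, support=support
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _category_table(
    partition: stats_mod.CategoryPartition, assembly: ReferenceAssembly
) -> pd.DataFrame:
    per_chrom = {r["chromosome"]: r for _, r in partition.counts_by_chrom().iterrows()}
    rows = []
    tot = {"A": 0, "B": 0, "C": 0}
    for chrom in assembly.names:
        counts = per_chrom.get(chrom, {"A": 0, "B": 0, "C": 0})
        non_n = assembly.non_n[chrom]
        row = {"chromosome": chrom, "non_n_bases": non_n}
        for cat in "ABC":
            c = int(counts[cat])
            tot[cat] += c
            row[f"count_{cat}"] = c
            bps = stats_mod.bases_per_snp(non_n, c)
            row[f"bases_per_snp_{cat}"] = "NA" if bps is None else bps
        rows.append(row)
    row = {"chromosome": "Total", "non_n_bases": assembly.total_non_n}
    for cat in "ABC":
        row[f"count_{cat}"] = tot[cat]
        bps = stats_mod.bases_per_snp(assembly.total_non_n, tot[cat])
        row[f"bases_per_snp_{cat}"] = "NA" if bps is None else bps
    rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir=None, seed=None) -> dict:
    """Run simulate -> call -> stats -> panel -> validate; return the summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = ensure_dir(out_dir or config.out_dir)
    seed = config.seed if seed is None else seed
    report: dict = {"seed": seed, "out_dir": str(out)}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                timings[name] = dt
                if exc is not None:
                    log.error("stage %s: failed after %.1fs", name, dt)
                    raise StageError(name, exc) from exc
                log.info("stage %s: done in %.1fs", name, dt)

        return _Ctx()

    # --- simulate -----------------------------------------------------------
    with stage("simulate"):
        truth = simulate_population(config.population, seed)
        reads = simulate_reads(truth, config.reads, seed)
        write_truth(truth, out, reads=reads)
        report["genome_length"] = truth.reference.total_length
        report["truth_variants"] = sum(len(v) for v in truth.variants.values())
        report["reads"] = len(reads)
        report["truth_homozygous_fraction"] = truth.truth_homozygous_fraction()

    assembly = truth.reference
    individuals = [i.name for i in config.population.individuals]

    # --- call ---------------------------------------------------------------
    with stage("call"):
        pileup = nqs.build_pileup(reads, assembly, config.nqs)
        snp_records = nqs.call_snps(pileup)
        dip_records = nqs.call_dips(reads, assembly, config.nqs, pileup=pileup)
        sites = nqs.merge_sites(snp_records + dip_records)
        snp_sites = [s for s in sites if s.vtype == "SNP"]
        dip_sites = [s for s in sites if s.vtype == "DIP"]
        write_vcf(
            calls_vcf_records(sites, assembly),
            out / "calls.vcf",
            contigs={n: assembly.length(n) for n in assembly.names},
        )
        rates = nqs.rate_report(reads, snp_records, assembly, config.nqs)
        write_tsv(rates, out / "rates.tsv")
        per_cat = nqs.per_individual_site_counts(snp_sites)
        report["snp_sites_non_redundant"] = len(snp_sites)
        report["dip_sites_non_redundant"] = len(dip_sites)
        report["per_cat_snp_sites"] = {n: per_cat.get(n, 0) for n in individuals}
        report["per_cat_snp_sum"] = sum(per_cat.values())

    # --- stats --------------------------------------------------------------
    with stage("stats"):
        special = {
            i.name
            for i in config.population.individuals
            if i.klass in ("inbred", "wildcat")
        }
        primary = {
            i.name for i in config.population.individuals if i.klass == "inbred"
        }
        partition = stats_mod.categorize(
            snp_sites, special=special, primary_special=primary,
            known_individuals=individuals,
        )
        write_tsv(_category_table(partition, assembly), out / "category_counts.tsv")
        windows = stats_mod.window_density(
            snp_sites, assembly, config.stats.window, config.stats.low_threshold
        )
        write_bedgraph(windows.bedgraph_rows(), out / "windows.bedgraph")
        occupancy = stats_mod.occupancy_curve(
            partition.sites_in("A"),
            assembly,
            config.stats.occupancy_sizes,
            include_unmapped=config.stats.include_unmapped,
        )
        write_tsv(occupancy, out / "occupancy.tsv")
        report["category_counts"] = partition.counts()
        report["window_summary"] = windows.summary
        inbred = config.population.by_class("inbred")
        if inbred:
            report["inbred_homozygous_fraction_estimate"] = (
                stats_mod.estimate_homozygous_fraction(
                    snp_sites, inbred[0].name, assembly
                )
            )

    # --- panel --------------------------------------------------------------
    with stage("panel"):
        design = panel_mod.design_panel(
            partition,
            assembly,
            spacing=config.panel.spacing,
            backfill=config.panel.backfill,
            method=config.panel.method,
        )
        write_bed(panel_mod.panel_bed_rows(design), out / "panel.bed")
        summary = panel_mod.panel_summary(design)
        write_tsv(pd.DataFrame([summary]), out / "panel_summary.tsv")
        report["panel"] = summary

    # --- validate -----------------------------------------------------------
    with stage("validate"):
        domestic = [i.name for i in config.population.by_class("domestic")]
        eligible = [s for s in snp_sites if s.discoverers & set(domestic)]
        n = min(config.validation.n, len(eligible))
        report["validation"] = {}
        if n > 0:
            sample = val_mod.sample_candidates(
                eligible, n, domestic, child_seed_for(seed, "validation")
            )
            testable = val_mod.filter_gap_distance(
                sample, assembly, config.validation.min_gap_distance
            )
            records = val_mod.score_against_truth(testable, truth)
            rows = [
                {
                    "chrom": r.site.chrom,
                    "pos": r.site.pos,
                    "type": r.site.vtype,
                    "alt": r.site.alt,
                    "discovered_in": ",".join(sorted(r.site.discoverers)),
                    "status": r.amplimer_status,
                    "confirmed": int(r.confirmed),
                }
                for r in records
            ]
            write_tsv(pd.DataFrame(rows), out / "validation.tsv")
            if records:
                rate = val_mod.confirmation_rate(records, "SNP")
                report["validation"] = {
                    "sampled": n,
                    "testable": len(testable),
                    "confirmed": rate.numerator,
                    "rate_pct": rate.pct,
                }

    report["timings"] = timings
    with open(out / "summary.json", "w") as fh:
        summary_out = {
            k: v for k, v in report.items() if k not in ("timings", "out_dir")
        }
        json.dump(summary_out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def child_seed_for(seed: int, *tags) -> int:
    from .io import child_seed

    return child_seed(seed, *tags)
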