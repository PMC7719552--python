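"""End-to-end orchestration of the parent-of-origin analysis.

``run_all`` drives either of two entry points:

* ``counts`` mode (default): simulate SNP-resolution allelic counts for the
  full 4-colony reciprocal-cross design, apply the count-filter cascade,
  run the per-status quasibinomial inference, the per-tissue differential
  expression and the downstream set statistics, and compare every call
  against the simulator's truth table.
* ``reads`` mode: simulate one colony at sequence level, run the variant
  filters, build the parental alternate genomes, assign reads by exact
  matching and audit the assignments against per-read truth.

All outputs are TSV plus one machine-readable ``summary.json``; given the
same config and seed, consecutive runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import pandas as pd

from . import counts as ac
from . import diffexpr, io, poe, setstats
from .simulate import (
    SimConfig,
    make_design,
    simulate_allelic_counts,
    simulate_expression_counts,
    simulate_sequences,
)
from .variants import apply_snps, filter_snps, select_queen_homalt, unique_snps

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Thresholds and inputs of a full pipeline run.

    Defaults are the analysis constants of the study design this package
    implements: SNP filters qual>=20 / depth>=5 / alt-obs>=2, >=2 SNPs per
    gene, POE gates q<0.05 with proportion >0.6 / <0.4, DE at q<0.01 with
    a minimum total count of 10, enrichment at q<0.05 and RBH orthologs at
    e-value <= 1e-3.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    mode: str = "counts"  # "counts" | "reads"
    q_poe: float = 0.05
    prop_hi: float = 0.6
    prop_lo: float = 0.4
    q_de: float = 0.01
    q_go: float = 0.05
    min_snps: int = 2
    snp_qual: float = 20.0
    snp_depth: int = 5
    snp_alt_obs: int = 2
    de_min_total: int = 10
    rbh_evalue: float = 1e-3
    apply_zero_maternal_filter: bool | None = None  # default: reads mode only

    def validate(self) -> None:
        self.sim.validate()
        if self.mode not in ("counts", "reads"):
            raise ConfigError(f"invalid mode {self.mode!r}")
        for name in ("q_poe", "q_de", "q_go"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1); got {v}")
        if not 0.5 <= self.prop_hi < 1:
            raise ConfigError("prop_hi must lie in [0.5, 1)")
        if not 0 < self.prop_lo <= 0.5:
            raise ConfigError("prop_lo must lie in (0, 0.5]")
        if self.min_snps < 1 or self.snp_depth < 0 or self.snp_alt_obs < 0:
            raise ConfigError("count thresholds must be non-negative")
        if self.rbh_evalue <= 0:
            raise ConfigError("rbh_evalue must be positive")


def _recovery_metrics(report: pd.DataFrame, truth: pd.DataFrame) -> Dict[str, float]:
    merged = report.merge(truth, on="gene_id")
    out: Dict[str, float] = {}
    for cls in ("MATERNAL", "PATERNAL"):
        is_true = merged["true_class"] == cls
        called = merged["label"] == cls
        out[f"sensitivity_{cls.lower()}"] = (
            float((is_true & called).sum() / is_true.sum()) if is_true.any() else float("nan")
        )
        out[f"false_{cls.lower()}_calls"] = int((called & ~is_true).sum())
    lineage_true = merged["true_class"].isin(["LINEAGE_A", "LINEAGE_B"])
    parent_called = merged["label"].isin(["MATERNAL", "PATERNAL"])
    out["lineage_leakage"] = int((lineage_true & parent_called).sum())
    return out


def _run_counts_mode(config: RunConfig, outdir: Path) -> Dict:
    design = make_design(config.sim)
    snp_table, truth = simulate_allelic_counts(config.sim, design)
    io.write_table(outdir / "design.tsv", design)
    io.write_table(outdir / "truth.tsv", truth)
    io.write_table(outdir / "allelic_counts_snp.tsv", snp_table)

    zero_filter = config.apply_zero_maternal_filter
    if zero_filter is None:
        # the filter guards against queen-genotype miscalls, a sequence-level
        # artifact the count-level generator does not produce
        zero_filter = False
    if zero_filter:
        snp_table = ac.drop_zero_maternal_snps(
            snp_table, libraries=design["library_id"].tolist()
        )
    universe = ac.gene_universe(snp_table, design, min_snps=config.min_snps)
    gene_table = ac.gene_level_counts(snp_table[snp_table["gene_id"].isin(universe)])
    gene_table = ac.substitute_paternal_zero(gene_table)
    io.write_table(outdir / "allelic_counts_gene.tsv", gene_table)

    summary: Dict = {
        "n_genes_simulated": int(config.sim.n_genes),
        "n_genes_universe": len(universe),
        "n_paternal_zero_substituted": gene_table.attrs["n_paternal_zero_substituted"],
    }

    poe_lists: Dict[str, Dict[str, set]] = {}
    for status in ("reproductive", "sterile"):
        report = poe.run_poe(
            gene_table, design, status=status,
            q_thresh=config.q_poe, prop_hi=config.prop_hi, prop_lo=config.prop_lo,
        )
        io.write_table(outdir / f"poe_{status}.tsv", report)
        label_counts = report["label"].value_counts().to_dict()
        summary[f"poe_{status}"] = {
            "n_analyzed": len(report),
            "labels": {k: int(v) for k, v in sorted(label_counts.items())},
            **_recovery_metrics(report, truth),
        }
        poe_lists[status] = {
            "maternal": set(report.loc[report["label"] == "MATERNAL", "gene_id"]),
            "paternal": set(report.loc[report["label"] == "PATERNAL", "gene_id"]),
            "universe": set(report["gene_id"]),
        }

    # label-count chi-squared summary (maternal vs paternal per status; 2x2)
    chisq: Dict = {}
    gof_counts = {}
    for status in ("reproductive", "sterile"):
        nm = len(poe_lists[status]["maternal"])
        npat = len(poe_lists[status]["paternal"])
        gof_counts[status] = (nm, npat)
        if nm + npat > 0:
            stat, df, p = setstats.chisq_gof_equal((nm, npat))
            chisq[f"gof_{status}"] = {"statistic": stat, "df": df, "p": p}
    if all(sum(v) > 0 for v in gof_counts.values()):
        table = [list(gof_counts["reproductive"]), list(gof_counts["sterile"])]
        try:
            stat, df, p = setstats.chisq_independence_2x2(table)
            chisq["independence"] = {"statistic": stat, "df": df, "p": p}
        except ValueError as exc:
            chisq["independence"] = {"error": str(exc)}
    summary["chisq"] = chisq

    shared_universe = poe_lists["reproductive"]["universe"] & poe_lists["sterile"]["universe"]
    overlaps: Dict = {}
    for side in ("maternal", "paternal"):
        a = poe_lists["reproductive"][side] & shared_universe
        b = poe_lists["sterile"][side] & shared_universe
        k, p = setstats.overlap_test(a, b, shared_universe)
        overlaps[side] = {"overlap": k, "p": p, "n_reproductive": len(a), "n_sterile": len(b)}
    summary["overlap_reproductive_vs_sterile"] = overlaps

    expr, _ = simulate_expression_counts(config.sim, design, truth)
    io.write_table(outdir / "expression_counts.tsv", expr.reset_index())
    de_summary: Dict = {}
    for tissue in config.sim.tissues:
        libs = design.loc[design["tissue"] == tissue, "library_id"]
        res = diffexpr.de_test(
            expr[libs], design[design["tissue"] == tissue],
            min_total=config.de_min_total, q_thresh=config.q_de,
        )
        io.write_table(outdir / f"de_{tissue}.tsv", res)
        sig = res[res["significant"]]
        truth_de = truth.set_index("gene_id")["de_status"]
        true_de = truth_de.reindex(sig["gene_id"]) != "none"
        de_summary[tissue] = {
            "n_tested": len(res),
            "n_significant": int(len(sig)),
            "n_true_positive": int(true_de.sum()),
        }
    summary["diffexpr"] = de_summary
    return summary


def _run_reads_mode(config: RunConfig, outdir: Path) -> Dict:
    sim = simulate_sequences(config.sim)
    io.write_fasta(outdir / "reference.fa", sim.reference)
    contig_lengths = {c: len(s) for c, s in sim.reference.items()}
    io.write_vcf(outdir / "queen.vcf", sim.queen_records, contig_lengths, sample="queen")
    io.write_vcf(outdir / "drone.vcf", sim.drone_records, contig_lengths, sample="drone")
    io.write_bed(outdir / "genes.bed", sim.gene_models)

    queen = select_queen_homalt(
        filter_snps(sim.queen_records, config.snp_qual, config.snp_depth, config.snp_alt_obs)
    )
    drone = filter_snps(sim.drone_records, config.snp_qual, config.snp_depth, config.snp_alt_obs)
    mat_unique, pat_unique = unique_snps(queen, drone)
    informative = mat_unique + pat_unique
    io.write_informative_snps(outdir / "informative_snps.tsv", informative)
    maternal_genome = apply_snps(sim.reference, mat_unique)
    paternal_genome = apply_snps(sim.reference, pat_unique)
    io.write_fasta(outdir / "maternal_genome.fa", maternal_genome)
    io.write_fasta(outdir / "paternal_genome.fa", paternal_genome)

    assignments = []
    n_discarded = 0
    n_reads = 0
    for lib, reads in sim.reads.items():
        a, d = ac.assign_reads(reads, lib, maternal_genome, paternal_genome, informative)
        assignments.extend(a)
        n_discarded += d
        n_reads += len(reads)
    truth_parent = sim.read_truth.set_index("read_id")["parent"]
    n_correct = sum(truth_parent[a.read_id] == a.parent for a in assignments)

    snp_table = ac.count_by_snp(assignments, sim.gene_models)
    io.write_table(outdir / "allelic_counts_snp.tsv", snp_table)
    if config.apply_zero_maternal_filter is not False:
        snp_table = ac.drop_zero_maternal_snps(
            snp_table, libraries=sim.design["library_id"].tolist()
        )
    gene_table = ac.gene_level_counts(
        snp_table, assignments, sim.gene_models, dedup=True
    )
    io.write_table(outdir / "allelic_counts_gene.tsv", gene_table)

    return {
        "n_reads": n_reads,
        "n_assigned": len(assignments),
        "n_discarded": n_discarded,
        "assignment_accuracy": (n_correct / len(assignments)) if assignments else float("nan"),
        "n_snps_retained": int(snp_table["snp_id"].nunique()),
        "n_genes_with_counts": int(gene_table["gene_id"].nunique()),
    }


def run_all(config: RunConfig, outdir: str | Path) -> Dict:
    """Run the configured pipeline and write tables plus ``summary.json``.

    Returns the summary dict.  The summary is fully determined by the
    config (including its seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "mode": config.mode,
        "seed": config.sim.seed,
        "thresholds": {
            "q_poe": config.q_poe, "prop_hi": config.prop_hi, "prop_lo": config.prop_lo,
            "q_de": config.q_de, "q_go": config.q_go, "min_snps": config.min_snps,
            "snp_qual": config.snp_qual, "snp_depth": config.snp_depth,
            "snp_alt_obs": config.snp_alt_obs, "de_min_total": config.de_min_total,
            "rbh_evalue": config.rbh_evalue,
        },
    }
    if config.mode == "counts":
        summary.update(_run_counts_mode(config, outdir))
    else:
        summary.update(_run_reads_mode(config, outdir))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def config_from_dict(data: Dict) -> RunConfig:
    """Build a RunConfig from a flat mapping (YAML-friendly)."""
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    run_fields = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    sim_kwargs = {}
    run_kwargs = {}
    for key, value in data.items():
        if key in sim_fields:
            sim_kwargs[key] = value
        elif key in run_fields:
            run_kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    if "directions" in sim_kwargs:
        sim_kwargs["directions"] = tuple(sim_kwargs["directions"])
    if "tissues" in sim_kwargs:
        sim_kwargs["tissues"] = tuple(sim_kwargs["tissues"])
    return RunConfig(sim=SimConfig(**sim_kwargs), **run_kwargs)
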