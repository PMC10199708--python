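"""End-to-end orchestration: simulate -> scan -> call -> report.

A :class:`RunConfig` (usually loaded from YAML) either points at real
inputs (FASTA/GFF3/domains/hits/VCF) or embeds a simulation section, in
which case the synthetic genome is generated first and truth-recovery
metrics are appended to the report.  Every stage writes its tabular
output under the run directory; the report carries a provenance block
(parameters, seed, package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import read_fasta, read_gff3, read_vcf, write_bed
from .repeats import (
    arrays_to_dataframe,
    group_harmonics,
    scan_genome,
    summarize_repeat_units,
)
from .telomeres import call_telomeres, find_telomere_unit, telomeres_to_dataframe
from .centromeres import call_centromeres, captured_genes, centromeres_to_dataframe
from .clusters import (
    build_gene_records,
    classify_r_genes,
    clusters_to_dataframe,
    filter_similarity_hits,
    find_domain_clusters,
    read_domains_tsv,
    read_hits_tsv,
)
from .hetscan import (
    FilterConfig,
    call_hotspots,
    filter_variants,
    hotspots_to_dataframe,
    partition_sharing,
    window_heterozygosity,
    windows_to_dataframe,
)
from .simulate import (
    CentromerePlan,
    ClusterPlan,
    GenePlan,
    SimulationSpec,
    SNPPlan,
    TelomerePlan,
    TEPlan,
    simulate_genome,
    simulate_snp_samples,
)

logger = logging.getLogger(__name__)


@dataclass
class Params:
    """All stage parameters, with the study-standard defaults."""

    terminal_window: int = 150_000
    min_unit: int = 5
    max_unit: int = 12
    telomere_min_copies: float = 50
    min_period: int = 30
    max_period: int = 500
    min_copies: float = 2.0
    min_identity: float = 0.80
    min_array_bp: int = 50_000
    max_gap: int = 500_000
    override_factor: float = 2.0
    max_evalue: float = 1e-5
    min_hit_identity: float = 30.0
    seed_run: int = 3
    extend: int = 30
    min_gq: int = 30
    min_maf: float = 0.01
    window: int = 100_000
    top_fraction: float = 0.05


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    fasta: str | None = None
    gff3: str | None = None
    domains: str | None = None
    hits: str | None = None
    vcf: str | None = None
    simulate: dict | None = None
    params: Params = field(default_factory=Params)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = Params(**raw.pop("params", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(params=params, **raw)


def spec_from_dict(d: dict, seed: int) -> SimulationSpec:
    """Build a :class:`SimulationSpec` from a plain config mapping."""
    d = dict(d)
    plans = {
        "telomeres": TelomerePlan,
        "centromeres": CentromerePlan,
        "tes": TEPlan,
        "genes": GenePlan,
        "snps": SNPPlan,
    }
    kwargs: dict = {"chrom_lengths": tuple(d.pop("chrom_lengths")), "seed": d.pop("seed", seed)}
    if "chrom_prefix" in d:
        kwargs["chrom_prefix"] = d.pop("chrom_prefix")
    for key, cls_ in plans.items():
        sub = dict(d.pop(key, {}))
        if key == "telomeres" and "missing_arms" in sub:
            sub["missing_arms"] = tuple((int(i), str(a)) for i, a in sub["missing_arms"])
        if key == "genes" and "clusters" in sub:
            sub["clusters"] = tuple(ClusterPlan(**c) for c in sub["clusters"])
        if key == "snps" and "hotspots" in sub:
            sub["hotspots"] = tuple((str(c), int(s), int(e), float(m)) for c, s, e, m in sub["hotspots"])
        for rk in ("copies_range", "array_bp", "length_range", "domains_per_gene",
                   "gq_range", "gq_fail_range"):
            if rk in sub:
                sub[rk] = tuple(sub[rk])
        if "array_bp_overrides" in sub:
            sub["array_bp_overrides"] = {int(k): int(v) for k, v in sub["array_bp_overrides"].items()}
        if "alt_monomer_lengths" in sub:
            sub["alt_monomer_lengths"] = {int(k): int(v) for k, v in sub["alt_monomer_lengths"].items()}
        if "families" in sub:
            sub["families"] = tuple(sub["families"])
        if "vocabulary" in sub:
            sub["vocabulary"] = tuple(sub["vocabulary"])
        kwargs[key] = cls_(**sub)
    if d:
        raise ValueError(f"unknown simulation config keys: {sorted(d)}")
    return SimulationSpec(**kwargs)


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def run_all(config: RunConfig) -> dict:
    """Run every stage; return (and write) the report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "params": dataclasses.asdict(p),
        }
    }
    truth = None
    sim = None
    vcf_table = None

    if config.simulate is not None:
        spec = spec_from_dict(config.simulate, config.seed)
        sim = simulate_genome(spec)
        sim.write(out / "sim")
        truth = sim.truth
        genome = sim.genome
        features = sim.features
        domains = sim.domains
        hits = None
        if spec.snps.hotspots or spec.snps.background_rate > 0:
            vcf_table, snp_truth = simulate_snp_samples(
                sim.chrom_lengths, spec.snps, seed=spec.seed + 1
            )
            truth.hotspots = snp_truth.hotspots
            truth.sharing_class = snp_truth.sharing_class
    else:
        if not config.fasta:
            raise FileNotFoundError("config provides neither a fasta path nor a simulation section")
        genome = read_fasta(config.fasta)
        features = read_gff3(config.gff3) if config.gff3 else []
        domains = read_domains_tsv(config.domains) if config.domains else {}
        hits = read_hits_tsv(config.hits) if config.hits else None
        if config.vcf:
            vcf_table, _ = read_vcf(config.vcf)

    chrom_lengths = {g.chrom_id: g.length for g in genome}

    # --- telomeres ---------------------------------------------------------
    unit_result = find_telomere_unit(genome, p.terminal_window, p.min_unit, p.max_unit)
    if unit_result.unit is not None:
        tel_calls = call_telomeres(
            genome, unit_result.unit, p.terminal_window, p.telomere_min_copies
        )
    else:
        tel_calls = []
    tel_df = telomeres_to_dataframe(tel_calls)
    tel_df.to_csv(out / "telomeres.tsv", sep="\t", index=False)
    present = [c for c in tel_calls if c.present]
    write_bed([(c.chrom_id, c.array_start, c.array_end, f"telomere_{c.arm}") for c in present],
              out / "telomeres.bed")
    report["telomeres"] = {
        "unit": unit_result.unit,
        "arms_total": 2 * len(genome),
        "arms_present": len(present),
        "longest_bp": int(max((c.array_length for c in present), default=0)),
        "shortest_bp": int(min((c.array_length for c in present), default=0)),
    }

    # --- tandem repeats ----------------------------------------------------
    arrays = scan_genome(genome, p.min_period, p.max_period, p.min_copies, p.min_identity)
    families = group_harmonics(arrays, identity_min=p.min_identity)
    genome_length = sum(chrom_lengths.values())
    summary = summarize_repeat_units(arrays, genome_length)
    arrays_to_dataframe(arrays, families).to_csv(out / "tandem_arrays.tsv", sep="\t", index=False)
    summary.to_csv(out / "repeat_units.tsv", sep="\t", index=False)
    report["tandem"] = {
        "n_arrays": len(arrays),
        "n_families": len(families),
        "top_units": summary.head(5).to_dict("records"),
    }

    # --- centromeres -------------------------------------------------------
    cen_calls, diagnostics = call_centromeres(
        chrom_lengths, arrays, families, features,
        min_array_bp=p.min_array_bp, max_gap=p.max_gap, override_factor=p.override_factor,
    )
    centromeres_to_dataframe(cen_calls).to_csv(out / "centromeres.tsv", sep="\t", index=False)
    write_bed([(c.chrom_id, c.start, c.end, f"centromere_p{c.family_base}") for c in cen_calls],
              out / "centromeres.bed")
    genes = [f for f in features if f.kind == "gene"]
    captured, n_captured = captured_genes(cen_calls, genes)
    with open(out / "captured_genes.tsv", "w") as fh:
        fh.write("chrom\tgene_id\tstart\tend\n")
        for chrom, gl in captured.items():
            for g in gl:
                fh.write(f"{chrom}\t{g.id}\t{g.start}\t{g.end}\n")
    report["centromeres"] = {
        "n_called": len(cen_calls),
        "n_chromosomes": len(genome),
        "captured_genes": n_captured,
    }

    # --- gene clusters -----------------------------------------------------
    gene_records = build_gene_records(genes, domains)
    kept_hits = filter_similarity_hits(hits, gene_records, p.max_evalue, p.min_hit_identity) if hits else None
    clusters = find_domain_clusters(gene_records, p.seed_run, p.extend)
    clusters_to_dataframe(clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    rflags, n_r = classify_r_genes(gene_records)
    report["clusters"] = {
        "n_clusters": len(clusters),
        "n_clustered_genes": len({g.gene_id for c in clusters for g in c.members}),
        "n_hits_kept": len(kept_hits) if kept_hits is not None else None,
        "n_r_genes": n_r,
    }

    # --- heterozygosity ----------------------------------------------------
    if vcf_table is not None:
        fcfg = FilterConfig(min_gq=p.min_gq, min_maf=p.min_maf)
        filtered, tally = filter_variants(vcf_table, fcfg)
        sharing = partition_sharing(filtered)
        profile = window_heterozygosity(filtered, chrom_lengths, p.window)
        windows_to_dataframe(profile).to_csv(out / "windows.tsv", sep="\t", index=False)
        fragments = call_hotspots(profile, p.top_fraction) if profile.total_windows >= 20 else []
        hotspots_to_dataframe(fragments).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        write_bed([(f.chrom_id, f.start, f.end, "hotspot") for f in fragments], out / "hotspots.bed")
        report["heterozygosity"] = {
            "sites_input": len(vcf_table),
            "filter_tally": tally,
            "shared_all": sharing.shared_all,
            "partial": sharing.partial,
            "percent_shared": sharing.percent_shared,
            "n_hotspot_fragments": len(fragments),
        }

    # --- truth recovery ----------------------------------------------------
    if truth is not None:
        report["recovery"] = _recovery_metrics(truth, tel_calls, cen_calls, clusters,
                                               report.get("heterozygosity"), out)

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    _write_text_report(report, out / "report.txt")
    return report


def _recovery_metrics(truth, tel_calls, cen_calls, clusters, het_report, out) -> dict:
    rec: dict = {}
    truth_arms = {(t["chrom"], t["arm"]) for t in truth.telomeres}
    called_arms = {(c.chrom_id, c.arm) for c in tel_calls if c.present}
    rec["telomere_truth_arms"] = len(truth_arms)
    rec["telomere_called_arms"] = len(called_arms)
    rec["telomere_recovered"] = len(truth_arms & called_arms)
    jac = []
    for c in cen_calls:
        t = truth.centromeres.get(c.chrom_id)
        if t:
            jac.append(round(_jaccard((c.start, c.end), (t["start"], t["end"])), 4))
    rec["centromere_truth"] = len(truth.centromeres)
    rec["centromere_called"] = len(cen_calls)
    rec["centromere_jaccards"] = jac
    rec["centromere_frac_jaccard_ge_0.8"] = (
        round(sum(j >= 0.8 for j in jac) / len(truth.centromeres), 4) if truth.centromeres else None
    )
    if truth.clusters:
        by_acc = {}
        for c in clusters:
            by_acc.setdefault(c.accession, set()).update(c.member_ids)
        exact = sum(
            1 for acc, ids in truth.clusters.items() if by_acc.get(acc, set()) == set(ids)
        )
        rec["clusters_planted"] = len(truth.clusters)
        rec["clusters_exact"] = exact
    if truth.hotspots and het_report is not None:
        rec["hotspots_planted"] = len(truth.hotspots)
        rec["hotspot_fragments_called"] = het_report["n_hotspot_fragments"]
    return rec


def _write_text_report(report: dict, path: Path) -> None:
    lines = [f"t2tannot {report['provenance']['version']} run report",
             f"seed: {report['provenance']['seed']}", ""]
    tel = report.get("telomeres", {})
    lines.append(
        f"Telomeres: unit {tel.get('unit')}, {tel.get('arms_present')} of "
        f"{tel.get('arms_total')} arms present "
        f"(longest {tel.get('longest_bp')} bp, shortest {tel.get('shortest_bp')} bp)"
    )
    tan = report.get("tandem", {})
    lines.append(f"Tandem arrays: {tan.get('n_arrays')} arrays in {tan.get('n_families')} monomer families")
    for row in tan.get("top_units", []):
        lines.append(
            f"  period {row['period']:>4} bp: {row['total_bp']:>10} bp "
            f"({100 * row['genome_fraction']:.2f}% of genome)"
        )
    cen = report.get("centromeres", {})
    lines.append(
        f"Centromeres: {cen.get('n_called')} of {cen.get('n_chromosomes')} chromosomes called; "
        f"{cen.get('captured_genes')} captured genes"
    )
    clu = report.get("clusters", {})
    lines.append(
        f"Gene clusters: {clu.get('n_clusters')} clusters over {clu.get('n_clustered_genes')} genes; "
        f"{clu.get('n_r_genes')} R genes"
    )
    het = report.get("heterozygosity")
    if het:
        lines.append(
            f"Heterozygosity: {het['filter_tally']['passed']} sites pass filters; "
            f"{het['percent_shared']}% shared in all samples; "
            f"{het['n_hotspot_fragments']} hotspot fragments"
        )
    recv = report.get("recovery")
    if recv:
        lines.append("Truth recovery: " + json.dumps(recv, default=str))
    Path(path).write_text("\n".join(lines) + "\n")
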