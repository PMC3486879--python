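"""End-to-end orchestration: scan → skipped exons → links → SI → association →
enrichment → distances, with a JSON/Markdown report of per-stage counts.

Exon expression features are named ``gene_id:start-end`` so that sequence-model
exons, expression features and association results join on one key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import distances as dist
from . import enrichment as enrich
from . import motifs as mot
from . import splicing as spl
from . import transcripts as tx
from .io import (
    GeneModel,
    GenomeAccessor,
    GenotypeMatrix,
    MotifSet,
    SnpRecord,
    TraitSnpCatalog,
    read_expression,
    read_fasta,
    read_gene_models,
    read_genotypes,
    read_motif_set,
    read_snps,
    read_trait_catalog,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "links_to_frame", "profiles_to_frame"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for the full analysis.

    Defaults are the analysis' standard operating values: 5-base flank (11-mer
    windows), SI skip band (0.8, 1.2), reporting filter p<0.05 / FDR<0.10 /
    R²>0.03, 1000 matched draws, distance strata 60/200/1000/5000 bp, 4 Mb cis
    window and cis-eQTL p<0.01 for the annotation filter.
    """

    genome_fasta: str = ""
    annotation: str = ""
    annotation_dialect: str = "genepred"
    snps: str = ""
    snp_dialect: str = "tabular"
    motifs: tuple[str, ...] = ()
    exon_expr: str = ""
    gene_expr: str = ""
    genotypes: str = ""
    trait_catalog: str = ""
    out_dir: str = "exonskip_out"

    flank: int = 5
    strand_mode: str = "gene"
    strict_cassette: bool = False
    si_mode: str = "ratio"
    si_lower: float = 0.8
    si_upper: float = 1.2
    top_fraction: float = 0.10
    min_individuals: int | None = None
    p_max: float = 0.05
    fdr_max: float = 0.10
    r2_min: float = 0.03
    matching_mode: str = "maf"
    n_sets: int = 1000
    maf_bin_width: float = 0.05
    n_distance_bins: int = 8
    distance_strata: tuple[float, ...] = (60, 200, 1000, 5000)
    cis_window_bp: int = 4_000_000
    cis_eqtl_p_max: float = 0.01
    seed: int = 0

    _PATH_FIELDS = ("genome_fasta", "annotation", "snps", "motifs", "exon_expr",
                    "gene_expr", "genotypes", "trait_catalog", "out_dir")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded), to surface deviations
        from the standard settings across runs."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: dict
    profiles: dict[str, mot.AlleleMotifProfile]
    skipped: dict[str, list[tx.SkippedExon]]
    links: list[tx.SkippedExonLink]
    si: spl.SIMatrix | None
    associations: list[assoc.AssociationResult]
    hits: list[assoc.AssociationResult]
    enrichment: enrich.EnrichmentResult | None
    distance_summary: pd.DataFrame | None


def profiles_to_frame(profiles: Mapping[str, mot.AlleleMotifProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles.values():
        for h in p.all_hits:
            rows.append(
                (h.snp_id, h.allele, h.allele_base, h.motif, h.snp_pos_in_motif,
                 h.genomic_start, p.effect_class)
            )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "allele", "allele_base", "motif", "snp_pos_in_motif",
                 "genomic_start", "effect_class"],
    )


def links_to_frame(links: Sequence[tx.SkippedExonLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.snp_id, l.gene_id, l.exon_start, l.exon_end, l.side, l.distance_bp, l.is_skipped)
         for l in links],
        columns=["snp_id", "gene_id", "exon_start", "exon_end", "side", "distance_bp", "is_skipped"],
    )


def associations_to_frame(results: Sequence[assoc.AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.snp_id, r.exon_id, r.beta, r.intercept, r.p_value, r.q_value, r.r_squared,
          r.skipping_allele, r.n_used, r.testable)
         for r in results],
        columns=["snp_id", "exon_id", "beta", "intercept", "p_value", "q_value",
                 "r_squared", "skipping_allele", "n_used", "testable"],
    )


def run_all(
    config: PipelineConfig,
    *,
    genome: GenomeAccessor | None = None,
    genes: list[GeneModel] | None = None,
    snps: list[SnpRecord] | None = None,
    motif_set: MotifSet | None = None,
    exon_expr=None,
    gene_expr=None,
    genotypes: GenotypeMatrix | None = None,
    trait_catalog: TraitSnpCatalog | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the full analysis; inputs may be passed in-memory or read from paths.

    Stage order and the per-stage counts in the report: ISE SNP scan, skipped
    exon detection, SNP→exon linking, SI computation and skip calls,
    genotype association with FDR filter, trait-catalog enrichment, distance
    summaries.
    """
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    if genome is None:
        genome = read_fasta(config.genome_fasta)
    if genes is None:
        genes = read_gene_models(config.annotation, dialect=config.annotation_dialect)
    if snps is None:
        snps = read_snps(config.snps, dialect=config.snp_dialect)
    if motif_set is None:
        sets = [read_motif_set(p) for p in config.motifs]
        if not sets:
            raise ValueError("no motif files supplied")
        motif_set = sets[0]
        for s in sets[1:]:
            motif_set = motif_set.union(s)
    if exon_expr is None and config.exon_expr:
        exon_expr = read_expression(config.exon_expr)
    if gene_expr is None and config.gene_expr:
        gene_expr = read_expression(config.gene_expr)
    if genotypes is None and config.genotypes:
        genotypes = read_genotypes(config.genotypes)
    if trait_catalog is None and config.trait_catalog:
        trait_catalog = read_trait_catalog(config.trait_catalog)

    snp_by_id = {s.snp_id: s for s in snps}
    report: dict = {
        "config_hash": config.config_hash(),
        "n_snps": len(snps),
        "n_genes": len(genes),
        "n_motifs": len(motif_set),
    }

    # 1. motif scan
    profiles = mot.call_ise_snps(
        snps, genome, motif_set, require_class="intronic", flank=config.flank,
        gene_models=genes, strand_mode=config.strand_mode,
    )
    report["n_ise_snps"] = len(profiles)

    # 2. skipped exons
    skipped = {g.gene_id: tx.find_skipped_exons(g, strict_cassette=config.strict_cassette)
               for g in genes}
    report["n_skipped_exons"] = sum(len(v) for v in skipped.values())

    # 3. link ISE SNPs to adjacent exons
    links: list[tx.SkippedExonLink] = []
    for sid in sorted(profiles):
        links.extend(tx.link_ise_snp_to_exons(snp_by_id[sid], genes, skipped))
    skip_links = [l for l in links if l.is_skipped]
    es_ise_snps = sorted({l.snp_id for l in skip_links})
    report["n_links"] = len(links)
    report["n_exon_skipping_ise_snps"] = len(es_ise_snps)

    # 4. splicing index
    si = None
    skip_counts = None
    if exon_expr is not None and gene_expr is not None:
        exon_to_gene = {e: e.split(":", 1)[0] for e in exon_expr.feature_ids}
        si = spl.compute_si(exon_expr, gene_expr, exon_to_gene, mode=config.si_mode)
        calls, skip_counts = spl.call_skipped(si, lower=config.si_lower, upper=config.si_upper)
        frequent = spl.select_frequently_skipped(
            skip_counts, len(si.sample_ids),
            top_fraction=config.top_fraction, min_individuals=config.min_individuals,
        )
        report["n_si_exons"] = len(si.exon_ids)
        report["n_frequently_skipped_exons"] = len(frequent)

    # 5. association
    associations: list[assoc.AssociationResult] = []
    hits: list[assoc.AssociationResult] = []
    if si is not None and genotypes is not None:
        associations = assoc.associate(genotypes, si, skip_links, snp_records=snp_by_id)
        hits = assoc.filter_hits(
            associations, p_max=config.p_max, fdr_max=config.fdr_max, r2_min=config.r2_min
        )
        report["n_association_tests"] = sum(r.testable for r in associations)
        report["n_association_hits"] = len(hits)

    # 6. enrichment of exon-skipping ISE SNPs among trait-catalog SNPs
    enr = None
    if trait_catalog is not None:
        background = {s.snp_id: s.maf for s in snps
                      if s.snp_class == "intronic" and s.maf is not None}
        query = {sid for sid in trait_catalog.snp_ids if sid in background}
        if query:
            kwargs = {}
            if config.matching_mode == "maf_and_distance":
                bg_dist = {
                    sid: d
                    for sid in background
                    if (d := dist.nearest_exon_distance(snp_by_id[sid], genes)) is not None
                }
                background = {s: background[s] for s in bg_dist}
                query = {s for s in query if s in bg_dist}
                kwargs = {"query_distance": bg_dist, "background_distance": bg_dist}
            enr = enrich.enrichment_test(
                query, set(es_ise_snps), background,
                matching_mode=config.matching_mode, n_sets=config.n_sets,
                seed=config.seed, maf_bin_width=config.maf_bin_width,
                n_distance_bins=config.n_distance_bins, **kwargs,
            )
            report["enrichment"] = enr.summary()

    # 7. distances
    intronic = [s for s in snps if s.snp_class == "intronic"]
    groups = {sid: "ise_snp" for sid in profiles}
    groups.update({sid: "exon_skipping_ise_snp" for sid in es_ise_snps})
    table = dist.distance_table(intronic, genes, links=skip_links, group_labels=groups)
    summary = dist.summarize(table, value_col="distance_to_nearest_exon") if not table.empty else None
    if summary is not None:
        report["distance_summary"] = summary.reset_index().to_dict(orient="records")

    if write_outputs:
        profiles_to_frame(profiles).to_csv(out_dir / "scan.tsv", sep="\t", index=False)
        links_to_frame(links).to_csv(out_dir / "links.tsv", sep="\t", index=False)
        if si is not None:
            si.values.to_csv(out_dir / "si.tsv", sep="\t", index_label="exon_id")
        if associations:
            associations_to_frame(associations).to_csv(out_dir / "associations.tsv", sep="\t", index=False)
        if not table.empty:
            table.to_csv(out_dir / "distances.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
        (out_dir / "report.md").write_text(_report_markdown(report))
    return PipelineResult(report, profiles, skipped, links, si, associations, hits, enr,
                          summary)


def _report_markdown(report: dict) -> str:
    lines = ["# exonskip pipeline report", ""]
    for key in ("config_hash", "n_snps", "n_genes", "n_motifs", "n_ise_snps",
                "n_skipped_exons", "n_links", "n_exon_skipping_ise_snps",
                "n_si_exons", "n_frequently_skipped_exons",
                "n_association_tests", "n_association_hits"):
        if key in report:
            lines.append(f"- **{key}**: {report[key]}")
    if "enrichment" in report:
        e = report["enrichment"]
        lines.append(
            f"- **enrichment**: observed {e['observed']} vs null mean "
            f"{e['null_mean']:.2f} (p = {e['empirical_p']:.4g}, {e['n_sets']} sets, "
            f"{e['matching_mode']})"
        )
    return "\n".join(lines) + "\n"
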