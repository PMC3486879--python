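"""Synthetic data with the statistical structure the analysis assumes.

Emulated inputs: a genome with multi-isoform genes containing cassette exons,
intronic SNPs planted inside ISE hexamer motifs adjacent to those cassette
exons (the reference allele carries the motif; the alternate disrupts it),
Hardy–Weinberg genotypes, exon/gene expression in which the skipping magnitude
|1−SI| grows additively with disrupting-allele dosage, and a trait-SNP catalog
in which planted exon-skipping ISE SNPs are enriched by a configurable odds
multiplier.

Every generator is a pure function of a numpy Generator; `simulate_all(config)`
derives all streams from `config.seed`, so identical configs give identical
outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    MotifSet,
    SnpRecord,
    TraitSnpCatalog,
    TranscriptModel,
)
from .association import default_exon_id
from .motifs import SnpWindow, match_motifs, reverse_complement

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedSnp",
    "SimData",
    "simulate_motif_set",
    "simulate_genome_and_annotation",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_trait_catalog",
    "simulate_snp_universe",
    "simulate_ld_pair",
    "simulate_all",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analyzed cohort where a value is dictated (176 samples;
    skipping effect 0.15 per disrupting-allele copy with noise sd 0.05) and
    field-plausible architecture elsewhere (exon/intron sizes, uniform folded
    MAF spectrum on [0.05, 0.5]).
    """

    seed: int = 0
    n_genes: int = 30
    isoforms_per_gene: tuple[int, int] = (2, 4)
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (300, 1500)
    cassette_fraction: float = 0.5
    motif_set_size: int = 64
    plant_rate: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_samples: int = 176
    si_noise_sd: float = 0.05
    beta_skip: float = 0.15
    trait_base_rate: float = 0.05
    trait_enrichment_odds: float = 5.0
    background_snps_per_gene: int = 4
    exonic_snp_rate: float = 0.3
    minus_strand_fraction: float = 0.3
    gene_spacing: int = 500
    chrom: str = "1"

    def __post_init__(self) -> None:
        for name in ("cassette_fraction", "plant_rate", "trait_base_rate",
                     "exonic_snp_rate", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.beta_skip < 0:
            raise ValueError("beta_skip must be ≥ 0")
        for name in ("isoforms_per_gene", "exons_per_gene", "exon_len", "intron_len", "maf_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is inverted: {(lo, hi)}")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need ≥3 exons for an internal cassette exon")
        if self.intron_len[0] < 30:
            raise ValueError("introns shorter than 30 bp leave no room for planted SNPs")


@dataclass(frozen=True)
class PlantedSnp:
    """Ground truth for one SNP planted inside an ISE motif."""

    snp_id: str
    gene_id: str
    motif: str
    snp_pos_in_motif: int
    exon: tuple[int, int]  # the linked cassette exon
    side: str  # exon_upstream_of_snp / exon_downstream_of_snp (genomic)
    distance_bp: int


@dataclass
class SimTruth:
    """What the generator planted, for recovery checks downstream."""

    planted: dict[str, PlantedSnp] = field(default_factory=dict)
    cassette_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    trait_members: set[str] = field(default_factory=set)

    @property
    def planted_ids(self) -> set[str]:
        return set(self.planted)


@dataclass
class SimData:
    """Bundle of all simulated inputs plus ground truth."""

    config: SimConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    snps: list[SnpRecord]
    motif_set: MotifSet
    truth: SimTruth
    genotypes: GenotypeMatrix | None = None
    exon_expr: ExpressionMatrix | None = None
    gene_expr: ExpressionMatrix | None = None
    exon_to_gene: dict[str, str] | None = None
    trait_catalog: TraitSnpCatalog | None = None


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def simulate_motif_set(config: SimConfig, rng: np.random.Generator) -> MotifSet:
    """A random set of distinct hexamers standing in for an ISE motif resource."""
    motifs: set[str] = set()
    while len(motifs) < config.motif_set_size:
        motifs.add("".join(_rand_seq(rng, 6)))
    return MotifSet("ISE_synthetic", frozenset(motifs))


def _scan_hits(window_ref: str, window_alt: str, motif_set: MotifSet):
    w = SnpWindow("tmp", "1", 1000, window_ref, window_alt)
    return match_motifs(w, "ref", motif_set), match_motifs(w, "alt", motif_set)


def _plant_window(
    rng: np.random.Generator, motif: str, k: int, motif_set: MotifSet, max_tries: int = 200
) -> tuple[str, str] | None:
    """Build an 11-mer sense context for a SNP at motif position ``k`` (1-based).

    The reference window embeds the motif (SNP base = motif[k−1]); the
    alternate allele is chosen so the alternate window matches *no* motif, and
    the flanking context is resampled until the reference window's only hits
    are the planted motif's frames.  Returns (ref_window, alt_window) or None
    when no clean context was found.
    """
    left_pad = 5 - (k - 1)  # bases before the motif within the 11-mer
    for _ in range(max_tries):
        left = "".join(_rand_seq(rng, left_pad))
        right = "".join(_rand_seq(rng, 5 - (6 - k)))
        ref_w = left + motif + right
        ref_hits, _ = _scan_hits(ref_w, ref_w[:5] + ("A" if ref_w[5] != "A" else "C") + ref_w[6:], motif_set)
        if {h.motif for h in ref_hits} != {motif} or len(ref_hits) != 1:
            continue
        alts = [b for b in "ACGT" if b != motif[k - 1]]
        rng.shuffle(alts)
        for alt_base in alts:
            alt_w = ref_w[:5] + alt_base + ref_w[6:]
            _, alt_hits = _scan_hits(ref_w, alt_w, motif_set)
            if not alt_hits:
                return ref_w, alt_w
    return None


def simulate_genome_and_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimData:
    """Generate the genome FASTA content, gene models, SNP list and truth.

    Genes are laid out along one chromosome with ≥2 isoforms wherever cassette
    exons were drawn; each cassette exon's adjacent intron receives, with
    probability ``plant_rate``, a SNP whose reference allele completes a motif
    from the set (a motif-loss SNP).  Background intronic and occasional exonic
    SNPs are added as nulls.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    motif_set = simulate_motif_set(config, rng)

    chrom_parts: list[np.ndarray] = []
    cursor = 0
    genes: list[GeneModel] = []
    snps: list[SnpRecord] = []
    truth = SimTruth()
    snp_counter = itertools.count(1)
    occupied: list[tuple[int, int]] = []  # planted windows, to keep background SNPs away

    for gi in range(config.n_genes):
        gid = f"G{gi + 1}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_ex)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=n_ex - 1)

        gap = _rand_seq(rng, config.gene_spacing)
        chrom_parts.append(gap)
        cursor += config.gene_spacing

        exons: list[tuple[int, int]] = []
        for i in range(n_ex):
            start = cursor
            cursor += int(exon_lens[i])
            exons.append((start, cursor))
            chrom_parts.append(_rand_seq(rng, int(exon_lens[i])))
            if i < n_ex - 1:
                chrom_parts.append(_rand_seq(rng, int(intron_lens[i])))
                cursor += int(intron_lens[i])

        internal = list(range(1, n_ex - 1))
        cassette_idx = [i for i in internal if rng.random() < config.cassette_fraction]
        max_skip_isoforms = config.isoforms_per_gene[1] - 1
        if len(cassette_idx) > max_skip_isoforms:
            cassette_idx = list(rng.choice(cassette_idx, size=max_skip_isoforms, replace=False))
            cassette_idx.sort()
        transcripts = [TranscriptModel(f"{gid}.t0", gid, config.chrom, strand, tuple(exons))]
        for j, ci in enumerate(cassette_idx, start=1):
            kept = tuple(ex for i, ex in enumerate(exons) if i != ci)
            transcripts.append(TranscriptModel(f"{gid}.t{j}", gid, config.chrom, strand, kept))
        genes.append(GeneModel(gid, tuple(transcripts)))
        truth.cassette_exons[gid] = [exons[i] for i in cassette_idx]

        # plant motif SNPs in introns adjacent to cassette exons
        for ci in cassette_idx:
            if rng.random() >= config.plant_rate:
                continue
            sides = []
            if ci >= 1:
                sides.append("left")  # intron between exon ci-1 and ci
            if ci <= n_ex - 2:
                sides.append("right")
            side = sides[int(rng.integers(0, len(sides)))]
            if side == "left":
                ilen = int(intron_lens[ci - 1])
            else:
                ilen = int(intron_lens[ci])
            dmax = min(400, ilen - 12)
            d = int(round(10 ** rng.uniform(np.log10(6), np.log10(max(dmax, 7)))))
            d = min(d, ilen - 12)
            if side == "left":
                pos = exons[ci][0] - 1 - d
                link_side = "exon_downstream_of_snp"
            else:
                pos = exons[ci][1] + d
                link_side = "exon_upstream_of_snp"
            if any(a <= pos + 5 and pos - 5 < b for a, b in occupied):
                continue  # would overwrite an earlier planted window

            motif = sorted(motif_set.motifs)[int(rng.integers(0, len(motif_set)))]
            k = int(rng.integers(1, 7))
            planted = _plant_window(rng, motif, k, motif_set)
            if planted is None:
                continue
            ref_w, alt_w = planted
            if strand == "+":
                genome_segment = ref_w
                ref_base, alt_base = ref_w[5], alt_w[5]
            else:
                genome_segment = reverse_complement(ref_w)
                ref_base = reverse_complement(ref_w[5])
                alt_base = reverse_complement(alt_w[5])
            _write_segment(chrom_parts, pos - 5, genome_segment)
            snp_id = f"rsS{next(snp_counter)}"
            snps.append(
                SnpRecord(snp_id, config.chrom, pos, ref_base, alt_base,
                          snp_class="intronic", maf=_draw_maf(rng, config), strand=strand)
            )
            occupied.append((pos - 11, pos + 11))
            truth.planted[snp_id] = PlantedSnp(
                snp_id, gid, motif, k, exons[ci], link_side, d
            )

        # background intronic SNPs (nulls) and occasional exonic SNPs
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(n_ex - 1)]
        for _ in range(config.background_snps_per_gene):
            s, e = introns[int(rng.integers(0, len(introns)))]
            if e - s < 14:
                continue
            pos = int(rng.integers(s + 6, e - 6))
            if any(a <= pos < b for a, b in occupied):
                continue
            snps.append(_background_snp(rng, config, chrom_parts, pos, next(snp_counter), "intronic", strand))
        if rng.random() < config.exonic_snp_rate:
            ex = exons[int(rng.integers(0, n_ex))]
            pos = int(rng.integers(ex[0], ex[1]))
            snps.append(_background_snp(rng, config, chrom_parts, pos, next(snp_counter), "exonic", strand))

    sequence = "".join("".join(part) for part in chrom_parts)
    return SimData(config, {config.chrom: sequence}, genes, snps, motif_set, truth)


def _draw_maf(rng: np.random.Generator, config: SimConfig) -> float:
    return float(np.round(rng.uniform(*config.maf_range), 6))


def _write_segment(parts: list[np.ndarray], start: int, segment: str) -> None:
    """Overwrite genome bases [start, start+len) across the part list."""
    offset = 0
    remaining = [(i, len(p)) for i, p in enumerate(parts)]
    pos = start
    consumed = 0
    for i, plen in remaining:
        if pos < consumed + plen and pos + len(segment) - offset > consumed:
            local = max(pos - consumed, 0)
            take = min(plen - local, len(segment) - offset)
            parts[i][local : local + take] = list(segment[offset : offset + take])
            offset += take
            pos += take
            if offset == len(segment):
                return
        consumed += plen
    if offset != len(segment):
        raise IndexError("segment extends past the simulated chromosome")


def _background_snp(rng, config, parts, pos, counter, snp_class, strand) -> SnpRecord:
    ref = _base_at(parts, pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return SnpRecord(f"rsS{counter}", config.chrom, pos, ref, alt,
                     snp_class=snp_class, maf=_draw_maf(rng, config), strand=strand)


def _base_at(parts: Sequence[np.ndarray], pos: int) -> str:
    consumed = 0
    for p in parts:
        if pos < consumed + len(p):
            return str(p[pos - consumed])
        consumed += len(p)
    raise IndexError(pos)


def simulate_genotypes(
    snps: Sequence[SnpRecord], n_samples: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Hardy–Weinberg dosages: alt-allele copies ~ Binomial(2, MAF), independent SNPs."""
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    rows = {}
    counted = {}
    for snp in snps:
        maf = snp.maf if snp.maf is not None else 0.0
        rows[snp.snp_id] = rng.binomial(2, maf, size=n_samples).astype(float)
        counted[snp.snp_id] = snp.alt_allele
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return GenotypeMatrix(df, counted)


def simulate_expression(
    config: SimConfig,
    genes: Sequence[GeneModel],
    truth: SimTruth,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, str]]:
    """Exon- and gene-level intensity matrices with genotype-dependent skipping.

    Gene intensity is log-normal.  For a cassette exon carrying a planted SNP,
    the skipping magnitude is beta_skip·dosage + |N(0, si_noise_sd)| and
    SI = 1 − magnitude (floored at 0.01): |1−SI| is linear in dosage by
    construction, with half-normal noise.  Cassette exons without a planted SNP
    get genotype-independent half-normal skipping; constitutive exons get
    symmetric Gaussian wobble around SI = 1.
    """
    sample_ids = genotypes.sample_ids
    n = len(sample_ids)
    planted_by_exon: dict[tuple[str, tuple[int, int]], str] = {
        (p.gene_id, p.exon): sid for sid, p in truth.planted.items()
    }
    gene_rows = {}
    exon_rows = {}
    exon_to_gene: dict[str, str] = {}
    for g in genes:
        base = rng.lognormal(mean=np.log(500.0), sigma=0.3)
        gene_int = base * rng.lognormal(mean=0.0, sigma=0.1, size=n)
        gene_rows[g.gene_id] = gene_int
        cassettes = set(map(tuple, truth.cassette_exons.get(g.gene_id, ())))
        for ex in g.exon_union:
            eid = default_exon_id(g.gene_id, ex)
            if ex in cassettes:
                snp_id = planted_by_exon.get((g.gene_id, ex))
                dosage = (
                    genotypes.dosages.loc[snp_id, sample_ids].to_numpy(dtype=float)
                    if snp_id is not None
                    else np.zeros(n)
                )
                magnitude = config.beta_skip * dosage + np.abs(rng.normal(0.0, config.si_noise_sd, size=n))
                si = np.maximum(1.0 - magnitude, 0.01)
            else:
                si = np.maximum(1.0 + rng.normal(0.0, config.si_noise_sd, size=n), 0.01)
            exon_rows[eid] = gene_int * si
            exon_to_gene[eid] = g.gene_id
    gene_expr = ExpressionMatrix(pd.DataFrame.from_dict(gene_rows, orient="index", columns=sample_ids))
    exon_expr = ExpressionMatrix(pd.DataFrame.from_dict(exon_rows, orient="index", columns=sample_ids))
    return exon_expr, gene_expr, exon_to_gene


def simulate_trait_catalog(
    snp_ids: Sequence[str],
    enriched_ids: set[str],
    rng: np.random.Generator,
    base_rate: float = 0.05,
    enrichment_odds: float = 1.0,
    trait: str = "synthetic_trait",
) -> TraitSnpCatalog:
    """Bernoulli catalog membership with odds multiplied for ``enriched_ids``.

    Membership probability is ``base_rate`` for ordinary SNPs and
    odds·q0/(1−q0+odds·q0) for enriched ones, so enrichment_odds = 1 gives a
    null catalog.
    """
    q0 = base_rate
    q1 = enrichment_odds * q0 / (1.0 - q0 + enrichment_odds * q0)
    rows = []
    for sid in snp_ids:
        p = q1 if sid in enriched_ids else q0
        if rng.random() < p:
            rows.append((sid, trait))
    return TraitSnpCatalog(pd.DataFrame(rows, columns=["snp_id", "trait"]))


def simulate_snp_universe(
    rng: np.random.Generator,
    n_snps: int = 2000,
    annotation_rate: float = 0.10,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[dict[str, float], set[str]]:
    """A lightweight SNP universe for enrichment calibration studies.

    Returns (snp_id -> MAF, annotated ids).  Annotation membership is
    independent of MAF, the null the matched test must not reject.
    """
    mafs = {f"u{i}": float(rng.uniform(*maf_range)) for i in range(n_snps)}
    flags = rng.random(n_snps) < annotation_rate
    annotated = {f"u{i}" for i in range(n_snps) if flags[i]}
    return mafs, annotated


def simulate_ld_pair(
    rng: np.random.Generator,
    n_samples: int,
    p_a: float,
    p_b: float,
    r: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors with haplotype correlation ``r`` (feasibility-clipped).

    Haplotypes are drawn from the two-locus distribution with
    D = r·sqrt(pA(1−pA)pB(1−pB)); genotypes are sums of two haplotypes.
    """
    d = r * np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    lo = max(-p_a * p_b, -(1 - p_a) * (1 - p_b))
    hi = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d = float(np.clip(d, lo, hi))
    probs = np.array(
        [p_a * p_b + d, p_a * (1 - p_b) - d, (1 - p_a) * p_b - d, (1 - p_a) * (1 - p_b) + d]
    )
    haps = rng.multinomial(1, probs, size=(n_samples, 2))  # (sample, chromosome, hap type)
    a = haps[:, :, 0] + haps[:, :, 1]  # haplotypes carrying allele 1 at locus A
    b = haps[:, :, 0] + haps[:, :, 2]
    return a.sum(axis=1).astype(float), b.sum(axis=1).astype(float)


def simulate_all(config: SimConfig) -> SimData:
    """Run every generator stage from ``config.seed`` and bundle the outputs."""
    rng = np.random.default_rng(config.seed)
    data = simulate_genome_and_annotation(config, rng)
    data.genotypes = simulate_genotypes(data.snps, config.n_samples, rng)
    data.exon_expr, data.gene_expr, data.exon_to_gene = simulate_expression(
        config, data.genes, data.truth, data.genotypes, rng
    )
    data.trait_catalog = simulate_trait_catalog(
        [s.snp_id for s in data.snps],
        data.truth.planted_ids,
        rng,
        base_rate=config.trait_base_rate,
        enrichment_odds=config.trait_enrichment_odds,
    )
    data.truth.trait_members = data.trait_catalog.snp_ids
    return data
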