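"""Skipped-exon (cassette exon) detection from transcript models, and linking of
ISE SNPs to the adjacent exons they putatively regulate.

An internal exon is "skipped" when some isoform of the gene contains it (as an
internal exon) and at least one other isoform of the same gene lacks any exon
with identical coordinates.  First and last exons of an isoform never count as
skipped nor as inclusion evidence: by definition they are neither skipped nor
included.  In strict cassette mode the excluding isoform must additionally
contain both exons flanking the candidate, which removes alternative-first/last
artifacts of the lenient rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import GeneModel, SnpRecord, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "SkippedExon",
    "SkippedExonLink",
    "find_skipped_exons",
    "link_ise_snp_to_exons",
    "merge_as_sources",
    "host_genes",
    "intron_of",
]


@dataclass(frozen=True)
class SkippedExon:
    """A cassette exon with its inclusion and exclusion isoform evidence."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    inclusion_isoforms: tuple[str, ...]
    exclusion_isoforms: tuple[str, ...]
    internal: bool = True

    def __post_init__(self) -> None:
        if not self.inclusion_isoforms or not self.exclusion_isoforms:
            raise ValueError("skipped exon requires both inclusion and exclusion isoforms")
        if set(self.inclusion_isoforms) & set(self.exclusion_isoforms):
            raise ValueError("inclusion and exclusion isoform sets overlap")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SkippedExonLink:
    """An ISE SNP tied to the nearest exon on one side of its host intron.

    ``side`` is genomic: the exon lies at lower ("exon_upstream_of_snp") or
    higher ("exon_downstream_of_snp") coordinates than the SNP.  ``distance_bp``
    counts the bases strictly between the SNP and the nearer exon boundary, so a
    SNP at the first intronic base has distance 0.
    """

    snp_id: str
    gene_id: str
    exon_start: int
    exon_end: int
    side: str
    distance_bp: int
    is_skipped: bool

    def __post_init__(self) -> None:
        if self.side not in {"exon_upstream_of_snp", "exon_downstream_of_snp"}:
            raise ValueError(f"unknown side {self.side!r}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be ≥ 0")

    @property
    def exon_interval(self) -> tuple[int, int]:
        return (self.exon_start, self.exon_end)


def find_skipped_exons(gene: GeneModel, strict_cassette: bool = False) -> list[SkippedExon]:
    """Detect skipped exons by comparing all isoform pairs of one gene.

    Exon identity is exact coordinate match.  Returns one SkippedExon per
    distinct exon interval, sorted by position; single-isoform genes yield none.
    """
    if len(gene.transcripts) < 2:
        return []
    exon_sets = {t.transcript_id: set(t.exons) for t in gene.transcripts}
    candidates: dict[tuple[int, int], set[str]] = {}
    flanks: dict[tuple[int, int], set[tuple[tuple[int, int], tuple[int, int]]]] = {}
    for t in gene.transcripts:
        for i, ex in enumerate(t.exons):
            if i == 0 or i == len(t.exons) - 1:
                continue  # first/last exons are never skipped candidates
            candidates.setdefault(ex, set()).add(t.transcript_id)
            flanks.setdefault(ex, set()).add((t.exons[i - 1], t.exons[i + 1]))
    out = []
    for ex in sorted(candidates):
        including = candidates[ex]
        excluding = set()
        for t in gene.transcripts:
            if ex in exon_sets[t.transcript_id]:
                continue
            if strict_cassette:
                ok = any(
                    up in exon_sets[t.transcript_id] and dn in exon_sets[t.transcript_id]
                    for up, dn in flanks[ex]
                )
                if not ok:
                    continue
            excluding.add(t.transcript_id)
        if excluding:
            out.append(
                SkippedExon(
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=ex[0],
                    end=ex[1],
                    inclusion_isoforms=tuple(sorted(including)),
                    exclusion_isoforms=tuple(sorted(excluding)),
                )
            )
    return out


def intron_of(transcript: TranscriptModel, pos: int) -> tuple[int, int] | None:
    """The intron of ``transcript`` containing ``pos``, or None."""
    for s, e in transcript.introns:
        if s <= pos < e:
            return (s, e)
    return None


def host_genes(snp: SnpRecord, genes: Iterable[GeneModel], strand_filter: bool = True) -> list[GeneModel]:
    """Genes in one of whose transcripts' introns the SNP lies.

    With ``strand_filter`` only genes on the SNP's reported strand qualify,
    mirroring the same-strand extraction of isoforms.
    """
    hosts = []
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        if strand_filter and snp.strand is not None and g.strand != snp.strand:
            continue
        if any(intron_of(t, snp.pos) is not None for t in g.transcripts):
            hosts.append(g)
    return hosts


def _nearest_exons_by_side(
    gene: GeneModel, pos: int
) -> dict[str, tuple[tuple[int, int], int]]:
    """Nearest exon (gene-union) strictly left and right of an intronic position.

    Returns side -> (exon interval, gap).  Gap is the count of bases strictly
    between the SNP and the nearer exon boundary.
    """
    out: dict[str, tuple[tuple[int, int], int]] = {}
    left = [ex for ex in gene.exon_union if ex[1] <= pos]
    right = [ex for ex in gene.exon_union if ex[0] > pos]
    if left:
        ex = max(left, key=lambda ex: ex[1])
        out["exon_upstream_of_snp"] = (ex, pos - ex[1])
    if right:
        ex = min(right, key=lambda ex: ex[0])
        out["exon_downstream_of_snp"] = (ex, ex[0] - pos - 1)
    return out


def link_ise_snp_to_exons(
    snp: SnpRecord,
    genes: Sequence[GeneModel],
    skipped: Mapping[str, Sequence[SkippedExon]] | Sequence[SkippedExon],
    strand_filter: bool = True,
) -> list[SkippedExonLink]:
    """Link an ISE SNP to the nearest exon on each side of its host intron.

    ``skipped`` is either a flat list of SkippedExon or a mapping
    gene_id -> list.  For each host gene a link is emitted per side, with
    ``is_skipped`` set when the nearest exon exactly matches a skipped exon of
    that gene.  A SNP that is not intronic in any gene yields no links.
    """
    if not isinstance(skipped, Mapping):
        by_gene: dict[str, list[SkippedExon]] = {}
        for se in skipped:
            by_gene.setdefault(se.gene_id, []).append(se)
        skipped = by_gene
    hosts = host_genes(snp, genes, strand_filter=strand_filter)
    if not hosts:
        log.debug("%s: not intronic in any supplied gene; no links", snp.snp_id)
        return []
    links = []
    for g in hosts:
        skipped_ivals = {se.interval for se in skipped.get(g.gene_id, ())}
        for side, (ex, gap) in _nearest_exons_by_side(g, snp.pos).items():
            links.append(
                SkippedExonLink(
                    snp_id=snp.snp_id,
                    gene_id=g.gene_id,
                    exon_start=ex[0],
                    exon_end=ex[1],
                    side=side,
                    distance_bp=gap,
                    is_skipped=ex in skipped_ivals,
                )
            )
    return links


def merge_as_sources(
    sources: Sequence[Sequence[GeneModel]],
    cluster_by_overlap: bool = False,
) -> list[GeneModel]:
    """Pool transcripts from several annotation sources into unified GeneModels.

    Transcripts are pooled by gene_id; duplicate isoforms (identical exon
    structure on the same chrom/strand) collapse to one.  A gene_id that appears
    on two chromosomes is an error.  With ``cluster_by_overlap`` genes on the
    same chrom/strand whose spans overlap are merged under the lexicographically
    first gene_id (for sources with discordant gene naming).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    chrom_of: dict[str, tuple[str, str]] = {}
    for source in sources:
        for g in source:
            key = (g.chrom, g.strand)
            if g.gene_id in chrom_of and chrom_of[g.gene_id][0] != g.chrom:
                raise ValueError(
                    f"gene_id {g.gene_id} appears on chromosomes "
                    f"{chrom_of[g.gene_id][0]} and {g.chrom}"
                )
            chrom_of[g.gene_id] = key
            by_gene.setdefault(g.gene_id, []).extend(g.transcripts)

    if cluster_by_overlap:
        # union-find over genes whose transcript spans overlap on the same strand
        gene_ids = sorted(by_gene)
        parent = {g: g for g in gene_ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        spans = {
            g: (
                chrom_of[g],
                min(t.span[0] for t in by_gene[g]),
                max(t.span[1] for t in by_gene[g]),
            )
            for g in gene_ids
        }
        for i, a in enumerate(gene_ids):
            for b in gene_ids[i + 1 :]:
                (ka, sa, ea), (kb, sb, eb) = spans[a], spans[b]
                if ka == kb and sa < eb and sb < ea:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        merged: dict[str, list[TranscriptModel]] = {}
        for g in gene_ids:
            merged.setdefault(find(g), []).extend(by_gene[g])
        by_gene = merged

    out = []
    for gid in sorted(by_gene):
        seen: set[tuple] = set()
        uniq = []
        for t in by_gene[gid]:
            key = (t.chrom, t.strand, t.exons)
            if key in seen:
                continue
            seen.add(key)
            if t.gene_id != gid:
                t = TranscriptModel(t.transcript_id, gid, t.chrom, t.strand, t.exons)
            uniq.append(t)
        out.append(GeneModel(gid, tuple(uniq)))
    return out
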