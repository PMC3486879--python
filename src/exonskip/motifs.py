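"""Allele-aware hexamer motif scanning around intronic SNPs.

An intronic splicing enhancer (ISE) is represented as an exact 6-mer.  For a SNP
we take 5 bases of flanking sequence on each side (an 11-mer with the variant
base at the center), enumerate the six hexamer frames that contain the variant
base, and test each frame for exact membership in the motif set — once for each
allele.  A SNP with at least one hit on either allele is an "ISE SNP".

Scanning operates on the pre-mRNA sense strand: for a SNP hosted by a
minus-strand gene the window is reverse-complemented (after allele substitution,
which is specified on the plus strand as in VCF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import GeneModel, GenomeAccessor, MotifSet, SnpRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "SnpWindow",
    "MotifHit",
    "AlleleMotifProfile",
    "reverse_complement",
    "extract_window",
    "enumerate_frames",
    "match_motifs",
    "profile_alleles",
    "call_ise_snps",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SnpWindow:
    """Sense-strand sequence context of a SNP: one window per allele.

    Both windows have length ``2·flank + 1`` and differ exactly at the center
    index.  ``strand`` records the scanning strand; on '-' the genomic
    coordinates of a hit run rightward from the *complementary* frame, which
    ``MotifHit.genomic_start`` accounts for.
    """

    snp_id: str
    chrom: str
    pos: int
    window_seq_ref: str
    window_seq_alt: str
    strand: str = "+"
    flank: int = 5

    def __post_init__(self) -> None:
        n = 2 * self.flank + 1
        if len(self.window_seq_ref) != n or len(self.window_seq_alt) != n:
            raise ValueError(f"{self.snp_id}: windows must have length {n}")
        c = self.flank
        if self.window_seq_ref[c] == self.window_seq_alt[c]:
            raise ValueError(f"{self.snp_id}: ref and alt windows agree at the center")
        for i, (a, b) in enumerate(zip(self.window_seq_ref, self.window_seq_alt)):
            if i != c and a != b:
                raise ValueError(f"{self.snp_id}: windows differ off-center at index {i}")

    def seq(self, allele: str) -> str:
        if allele == "ref":
            return self.window_seq_ref
        if allele == "alt":
            return self.window_seq_alt
        raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")


@dataclass(frozen=True)
class MotifHit:
    """One exact motif match covering the SNP base.

    ``snp_pos_in_motif`` is the 1-based position of the variant base within the
    matched hexamer; ``genomic_start`` is the 0-based plus-strand start of the
    matched hexamer's footprint.
    """

    snp_id: str
    allele: str  # "ref" or "alt"
    allele_base: str  # sense-strand base at the SNP
    motif: str
    snp_pos_in_motif: int
    genomic_start: int

    def __post_init__(self) -> None:
        if not 1 <= self.snp_pos_in_motif <= 6:
            raise ValueError("snp_pos_in_motif must be in 1..6")
        if self.motif[self.snp_pos_in_motif - 1] != self.allele_base:
            raise ValueError(
                f"{self.snp_id}: motif {self.motif} position {self.snp_pos_in_motif} "
                f"is not the allele base {self.allele_base}"
            )


@dataclass(frozen=True)
class AlleleMotifProfile:
    """Motif hits for both alleles of one SNP and the implied allelic effect.

    effect_class: "loss" (only the reference allele sits in a motif), "gain"
    (only the alternate does), "retention_shift" (both do, not necessarily the
    same motifs), or "none".
    """

    snp_id: str
    hits_ref: tuple[MotifHit, ...]
    hits_alt: tuple[MotifHit, ...]

    @property
    def effect_class(self) -> str:
        if self.hits_ref and not self.hits_alt:
            return "loss"
        if self.hits_alt and not self.hits_ref:
            return "gain"
        if self.hits_ref and self.hits_alt:
            return "retention_shift"
        return "none"

    @property
    def is_ise_snp(self) -> bool:
        return bool(self.hits_ref or self.hits_alt)

    @property
    def all_hits(self) -> tuple[MotifHit, ...]:
        return self.hits_ref + self.hits_alt


def extract_window(genome: GenomeAccessor, snp: SnpRecord, flank: int = 5, strand: str = "+") -> SnpWindow:
    """Build the per-allele sense-strand windows around a SNP.

    Bases beyond the contig are padded with N.  If the genome base at the SNP
    position disagrees with the declared reference allele, a warning is logged
    and both declared alleles are substituted into the observed context anyway.
    """
    if snp.chrom not in genome:
        raise KeyError(f"chromosome {snp.chrom!r} absent from genome")
    plus = genome.fetch(snp.chrom, snp.pos - flank, snp.pos + flank + 1)
    observed = plus[flank]
    if observed != snp.ref_allele:
        log.warning(
            "%s: genome base %s at %s:%d differs from declared ref %s",
            snp.snp_id, observed, snp.chrom, snp.pos, snp.ref_allele,
        )
    ref_plus = plus[:flank] + snp.ref_allele + plus[flank + 1 :]
    alt_plus = plus[:flank] + snp.alt_allele + plus[flank + 1 :]
    if strand == "-":
        ref_plus, alt_plus = reverse_complement(ref_plus), reverse_complement(alt_plus)
    return SnpWindow(snp.snp_id, snp.chrom, snp.pos, ref_plus, alt_plus, strand=strand, flank=flank)


def enumerate_frames(window: SnpWindow, allele: str) -> list[tuple[str, int, bool]]:
    """Enumerate the 6 hexamer frames containing the SNP base.

    Returns (hexamer, snp_pos_in_hexamer, eligible) triples with
    snp_pos_in_hexamer descending 6..1 — the frame starts with the SNP in the
    last position and shifts upstream one base at a time.  Frames containing N
    are returned but flagged ineligible for matching.
    """
    seq = window.seq(allele)
    c = window.flank
    frames = []
    for pos_in_hex in range(6, 0, -1):
        start = c - pos_in_hex + 1
        hexamer = seq[start : start + 6]
        frames.append((hexamer, pos_in_hex, "N" not in hexamer))
    return frames


def _hit_genomic_start(window: SnpWindow, pos_in_hex: int) -> int:
    # plus strand: motif runs rightward from pos - (k-1); minus strand: the
    # sense hexamer's plus-strand footprint ends (k-1) bases *after* the SNP.
    if window.strand == "+":
        return window.pos - (pos_in_hex - 1)
    return window.pos + (pos_in_hex - 1) - 5


def match_motifs(window: SnpWindow, allele: str, motif_set: MotifSet) -> list[MotifHit]:
    """Exact-match the SNP-containing frames of one allele against a motif set."""
    hits = []
    for hexamer, pos_in_hex, eligible in enumerate_frames(window, allele):
        if eligible and hexamer in motif_set:
            hits.append(
                MotifHit(
                    snp_id=window.snp_id,
                    allele=allele,
                    allele_base=hexamer[pos_in_hex - 1],
                    motif=hexamer,
                    snp_pos_in_motif=pos_in_hex,
                    genomic_start=_hit_genomic_start(window, pos_in_hex),
                )
            )
    return hits


def profile_alleles(
    snp: SnpRecord,
    genome: GenomeAccessor,
    motif_set: MotifSet,
    flank: int = 5,
    strand: str = "+",
) -> AlleleMotifProfile:
    """Scan both alleles of a SNP and classify the allelic effect on the motif."""
    window = extract_window(genome, snp, flank=flank, strand=strand)
    return AlleleMotifProfile(
        snp_id=snp.snp_id,
        hits_ref=tuple(match_motifs(window, "ref", motif_set)),
        hits_alt=tuple(match_motifs(window, "alt", motif_set)),
    )


def _strand_lookup(gene_models: Sequence[GeneModel] | None) -> dict[str, list[tuple[int, int, str]]]:
    """chrom -> list of (span_start, span_end, strand) over all transcripts."""
    table: dict[str, list[tuple[int, int, str]]] = {}
    for g in gene_models or ():
        for t in g.transcripts:
            s, e = t.span
            table.setdefault(g.chrom, []).append((s, e, g.strand))
    return table


def call_ise_snps(
    snps: Iterable[SnpRecord],
    genome: GenomeAccessor,
    motif_set: MotifSet,
    require_class: str | None = "intronic",
    flank: int = 5,
    gene_models: Sequence[GeneModel] | None = None,
    strand_mode: str = "gene",
) -> dict[str, AlleleMotifProfile]:
    """Scan a SNP list and return profiles for the SNPs with ≥1 motif hit.

    Only SNPs of ``require_class`` are scanned (None scans all).  With
    ``strand_mode='gene'`` and gene models supplied, each SNP is scanned on the
    strand of the gene whose span contains it (plus strand when no gene does, or
    on both strands' genes when they overlap — the sense scan of the host gene
    is what defines the ISE).  ``strand_mode='plus'`` forces plus-strand-only.
    """
    if strand_mode not in {"gene", "plus"}:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    spans = _strand_lookup(gene_models) if strand_mode == "gene" else {}
    out: dict[str, AlleleMotifProfile] = {}
    for snp in snps:
        if require_class is not None and snp.snp_class != require_class:
            continue
        strands = {"+"}
        if strand_mode == "gene" and spans:
            hosting = {
                st for (s, e, st) in spans.get(snp.chrom, ()) if s <= snp.pos < e
            }
            if hosting:
                strands = hosting
        profiles = [profile_alleles(snp, genome, motif_set, flank=flank, strand=st) for st in sorted(strands)]
        merged = AlleleMotifProfile(
            snp_id=snp.snp_id,
            hits_ref=tuple(h for p in profiles for h in p.hits_ref),
            hits_alt=tuple(h for p in profiles for h in p.hits_alt),
        )
        if merged.is_ise_snp:
            out[snp.snp_id] = merged
    return out
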