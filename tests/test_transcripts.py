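"""Skipped-exon detection (with a brute-force all-pairs oracle), SNP→exon
linking, and annotation-source merging."""

from __future__ import annotations

import numpy as np
import pytest

from exonskip.io import GeneModel, SnpRecord, TranscriptModel
from exonskip.transcripts import (
    SkippedExonLink,
    find_skipped_exons,
    host_genes,
    link_ise_snp_to_exons,
    merge_as_sources,
)
from tests.conftest import gene, transcript

E1, E2, E3, E4 = (100, 200), (300, 400), (500, 600), (700, 800)


def brute_force_skipped(g: GeneModel) -> set[tuple[int, int]]:
    """All-pairs comparison: internal exon of A absent from B."""
    out = set()
    for a in g.transcripts:
        for b in g.transcripts:
            if a is b:
                continue
            for i, ex in enumerate(a.exons):
                if 0 < i < len(a.exons) - 1 and ex not in set(b.exons):
                    out.add(ex)
    return out


def random_gene(rng: np.random.Generator) -> GeneModel:
    n_exons = int(rng.integers(2, 9))
    starts = np.cumsum(rng.integers(50, 200, size=n_exons * 2))
    universe = [(int(starts[2 * i]), int(starts[2 * i + 1])) for i in range(n_exons)]
    n_iso = int(rng.integers(1, 6))
    transcripts = []
    for j in range(n_iso):
        keep = [ex for ex in universe if rng.random() < 0.7]
        if not keep:
            keep = [universe[0]]
        transcripts.append(transcript(f"T{j}", keep))
    return gene(transcripts)


def test_canonical_cassette_exon():
    g = gene([transcript("A", [E1, E2, E3]), transcript("B", [E1, E3])])
    (se,) = find_skipped_exons(g)
    assert se.interval == E2
    assert se.inclusion_isoforms == ("A",) and se.exclusion_isoforms == ("B",)


def test_single_isoform_gene_yields_nothing():
    g = gene([transcript("A", [E1, E2, E3])])
    assert find_skipped_exons(g) == []


def test_first_and_last_exons_never_reported_skipped():
    g = gene([transcript("A", [E1, E2, E3]), transcript("B", [E2, E3]),
              transcript("C", [E1, E2])])
    got = {se.interval for se in find_skipped_exons(g)}
    # E1 and E3 are each missing from one isoform but are terminal everywhere
    assert E1 not in got and E3 not in got


def test_strict_cassette_requires_flanking_exons():
    lenient_only = gene([transcript("A", [E1, E2, E3]), transcript("B", [E1, E4])])
    assert {se.interval for se in find_skipped_exons(lenient_only)} == {E2}
    assert find_skipped_exons(lenient_only, strict_cassette=True) == []
    true_cassette = gene([transcript("A", [E1, E2, E3]), transcript("B", [E1, E3])])
    assert {se.interval for se in find_skipped_exons(true_cassette, strict_cassette=True)} == {E2}


def test_order_invariance():
    ts = [transcript("A", [E1, E2, E3]), transcript("B", [E1, E3]),
          transcript("C", [E1, E2, E4])]
    a = find_skipped_exons(gene(ts))
    b = find_skipped_exons(gene(ts[::-1]))
    assert {se.interval for se in a} == {se.interval for se in b}


def test_matches_brute_force_oracle_on_random_genes(rng):
    for _ in range(400):
        g = random_gene(rng)
        got = {se.interval for se in find_skipped_exons(g)}
        assert got == brute_force_skipped(g)


# --- linking ---------------------------------------------------------------


def cassette_gene():
    return gene([transcript("A", [E1, E2, E3]), transcript("B", [E1, E3])])


def test_link_intronic_snp_to_adjacent_cassette():
    g = cassette_gene()
    snp = SnpRecord("rs", "1", 250, "A", "G")  # intron between E1 and E2
    links = link_ise_snp_to_exons(snp, [g], find_skipped_exons(g))
    by_side = {l.side: l for l in links}
    down = by_side["exon_downstream_of_snp"]
    assert down.exon_interval == E2 and down.is_skipped
    assert down.distance_bp == 300 - 250 - 1
    up = by_side["exon_upstream_of_snp"]
    assert up.exon_interval == E1 and not up.is_skipped
    assert up.distance_bp == 250 - 200


def test_snp_with_constitutive_neighbours_is_not_exon_skipping():
    g = gene([transcript("A", [E1, E2, E3, E4]), transcript("B", [E1, E3, E4])])
    snp = SnpRecord("rs", "1", 650, "A", "G")  # intron between E3 and E4
    links = link_ise_snp_to_exons(snp, [g], find_skipped_exons(g))
    assert links and all(not l.is_skipped for l in links)


def test_non_intronic_snp_yields_no_links():
    g = cassette_gene()
    snp = SnpRecord("rs", "1", 150, "A", "G")  # inside E1
    assert link_ise_snp_to_exons(snp, [g], find_skipped_exons(g)) == []


def test_strand_filter_restricts_host_genes():
    plus = cassette_gene()
    minus = GeneModel("G2", (TranscriptModel("M1", "G2", "1", "-", (E1, E2, E3)),
                             TranscriptModel("M2", "G2", "1", "-", (E1, E3))))
    snp = SnpRecord("rs", "1", 250, "A", "G", strand="+")
    links = link_ise_snp_to_exons(snp, [plus, minus], [])
    assert {l.gene_id for l in links} == {"G1"}
    assert {g.gene_id for g in host_genes(snp, [plus, minus], strand_filter=False)} == {"G1", "G2"}


def test_boundary_adjacent_snp_has_distance_zero():
    g = cassette_gene()
    first_intronic = SnpRecord("rs", "1", 200, "A", "G")  # first base after E1
    links = link_ise_snp_to_exons(first_intronic, [g], [])
    up = {l.side: l for l in links}["exon_upstream_of_snp"]
    assert up.distance_bp == 0


# --- merging ---------------------------------------------------------------


def test_merge_collapses_duplicate_transcripts():
    a = [gene([transcript("A", [E1, E2, E3])])]
    b = [gene([transcript("A2", [E1, E2, E3]), transcript("B", [E1, E3])])]
    (merged,) = merge_as_sources([a, b])
    assert len(merged.transcripts) == 2
    # skipped exon only detectable after pooling the two sources
    assert {se.interval for se in find_skipped_exons(merged)} == {E2}


def test_merge_cross_chromosome_collision_is_error():
    a = [gene([transcript("A", [E1, E2, E3])])]
    b = [GeneModel("G1", (TranscriptModel("B", "G1", "2", "+", (E1, E2)),))]
    with pytest.raises(ValueError, match="chromosomes"):
        merge_as_sources([a, b])


def test_merge_overlap_clustering_unifies_discordant_gene_ids():
    a = [gene([transcript("A", [E1, E2, E3])], gene_id="G1")]
    t = TranscriptModel("B", "GX", "1", "+", (E1, E3))
    b = [GeneModel("GX", (t,))]
    merged = merge_as_sources([a, b], cluster_by_overlap=True)
    assert len(merged) == 1 and len(merged[0].transcripts) == 2
    assert {se.interval for se in find_skipped_exons(merged[0])} == {E2}
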