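"""Allele-aware hexamer scanning: frame enumeration, worked variant examples,
brute-force oracle equivalence, strand handling and effect classes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonskip.io import GeneModel, MotifSet, SnpRecord, TranscriptModel
from exonskip.motifs import (
    AlleleMotifProfile,
    SnpWindow,
    call_ise_snps,
    enumerate_frames,
    extract_window,
    match_motifs,
    profile_alleles,
    reverse_complement,
)

BASES = "ACGT"


def brute_force_hits(window: str, motif_set: set[str]) -> list[tuple[str, int]]:
    """Slide a 6-wide frame over the 11-mer, keep frames covering index 5."""
    out = []
    for start in range(len(window) - 5):
        hexamer = window[start : start + 6]
        if start <= 5 <= start + 5 and "N" not in hexamer and hexamer in motif_set:
            out.append((hexamer, 5 - start + 1))
    return out


def make_window(offsets: dict[int, str], center: str, fill: str = "A") -> str:
    """11-mer with given bases at offsets −5..+5 relative to the SNP."""
    return "".join(
        center if o == 0 else offsets.get(o, fill) for o in range(-5, 6)
    )


# Worked examples: windows reconstructed from the reported motif positions.
FIG4_CASES = [
    # rs339408 (A/G): G allele at sites 2/3/4 of AGGGAT, CAGGGA, TCAGGG
    ("rs339408", {-3: "T", -2: "C", -1: "A", 1: "G", 2: "G", 3: "A", 4: "T"},
     "G", "A", {"AGGGAT", "CAGGGA", "TCAGGG"},
     {("AGGGAT", 2), ("CAGGGA", 3), ("TCAGGG", 4)}),
    # rs6436071 (A/T): T allele at sites 2/3 of CTTGGC and GCTTGG
    ("rs6436071", {-2: "G", -1: "C", 1: "T", 2: "G", 3: "G", 4: "C"},
     "T", "A", {"CTTGGC", "GCTTGG"},
     {("CTTGGC", 2), ("GCTTGG", 3)}),
    # rs1265112 (A/G): A allele at site 4 of CACACT
    ("rs1265112", {-3: "C", -2: "A", -1: "C", 1: "C", 2: "T"},
     "A", "G", {"CACACT"}, {("CACACT", 4)}),
    # rs12599391 (C/T): T allele at site 3 of AATTGT
    ("rs12599391", {-2: "A", -1: "A", 1: "T", 2: "G", 3: "T"},
     "T", "C", {"AATTGT"}, {("AATTGT", 3)}),
    # rs12924138 (G/T): T allele at site 5 of AGCCTG
    ("rs12924138", {-4: "A", -3: "G", -2: "C", -1: "C", 1: "G"},
     "T", "G", {"AGCCTG"}, {("AGCCTG", 5)}),
]


@pytest.mark.parametrize("snp_id,offsets,motif_allele,other_allele,motifs,expected",
                         FIG4_CASES, ids=[c[0] for c in FIG4_CASES])
def test_worked_variant_examples(window_factory, snp_id, offsets, motif_allele,
                                 other_allele, motifs, expected):
    """Reconstructed windows reproduce each reported motif hit and its position."""
    window = make_window(offsets, motif_allele, fill="A")
    genome, pos = window_factory(window)
    snp = SnpRecord(snp_id, "1", pos, motif_allele, other_allele, snp_class="intronic")
    profile = profile_alleles(snp, genome, MotifSet("ise", frozenset(motifs)))
    got = {(h.motif, h.snp_pos_in_motif) for h in profile.hits_ref}
    assert got == expected
    # the other allele destroys every one of these motifs
    assert profile.hits_alt == ()
    assert profile.effect_class == "loss"


def test_window_length_and_center_difference(window_factory):
    genome, pos = window_factory("CCCCCTCCCCC")
    snp = SnpRecord("rs1", "1", pos, "T", "G")
    w = extract_window(genome, snp, flank=5)
    assert len(w.window_seq_ref) == 11 == len(w.window_seq_alt)
    diffs = [i for i, (a, b) in enumerate(zip(w.window_seq_ref, w.window_seq_alt)) if a != b]
    assert diffs == [5]


def test_edge_snp_window_pads_with_n(genome_factory):
    genome = genome_factory({"1": "ACGTACGTACGTACGT"})
    snp = SnpRecord("rs1", "1", 2, "G", "T")
    w = extract_window(genome, snp, flank=5)
    assert w.window_seq_ref == "NNNACGTACGT"
    frames = enumerate_frames(w, "ref")
    assert len(frames) == 6
    # frames reaching into the padding are ineligible but still enumerated
    assert [f[2] for f in frames] == [True, True, True, False, False, False][::-1]


def test_frame_enumeration_matches_documented_order(window_factory):
    genome, pos = window_factory("AAAAAGAAAAA")
    snp = SnpRecord("rs1", "1", pos, "G", "C")
    w = extract_window(genome, snp)
    frames = enumerate_frames(w, "ref")
    assert [(h, p) for h, p, _ in frames] == [
        ("AAAAAG", 6), ("AAAAGA", 5), ("AAAGAA", 4),
        ("AAGAAA", 3), ("AGAAAA", 2), ("GAAAAA", 1),
    ]


@given(
    window11=st.text(alphabet=BASES, min_size=5, max_size=5).flatmap(
        lambda left: st.tuples(
            st.just(left),
            st.sampled_from(BASES),
            st.text(alphabet=BASES, min_size=5, max_size=5),
        )
    ),
    motifs=st.sets(st.text(alphabet=BASES, min_size=6, max_size=6), min_size=0, max_size=64),
)
@settings(max_examples=300, deadline=None)
def test_matching_equals_brute_force_slide(window11, motifs):
    """Frame matching equals a brute-force 6-wide slide keeping SNP-covering frames."""
    left, center, right = window11
    alt_center = "C" if center != "C" else "G"
    w = SnpWindow("rs", "1", 100, left + center + right, left + alt_center + right)
    ms = MotifSet("m", frozenset(motifs))
    got = {(h.motif, h.snp_pos_in_motif) for h in match_motifs(w, "ref", ms)}
    assert got == set(brute_force_hits(left + center + right, set(motifs)))


def test_hit_genomic_start_invariant(window_factory):
    genome, pos = window_factory(make_window({-1: "A", 1: "G", 2: "G", 3: "A", 4: "T"}, "G"))
    snp = SnpRecord("rs", "1", pos, "G", "C")
    profile = profile_alleles(snp, genome, MotifSet("m", frozenset({"AGGGAT"})))
    (hit,) = profile.hits_ref
    assert hit.genomic_start == pos - (hit.snp_pos_in_motif - 1)


def test_minus_strand_scan_equals_plus_scan_of_revcomp(window_factory, rng):
    """Scanning strand '-' equals plus-strand scanning of the reverse complement."""
    for _ in range(25):
        window = "".join(rng.choice(list(BASES), size=11))
        genome, pos = window_factory(window)
        ref = window[5]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        snp = SnpRecord("rs", "1", pos, ref, alt)
        motifs = MotifSet("m", frozenset(
            "".join(rng.choice(list(BASES), size=6)) for _ in range(40)))
        minus = profile_alleles(snp, genome, motifs, strand="-")
        w = extract_window(genome, snp, strand="+")
        rc = SnpWindow("rs", "1", pos,
                       reverse_complement(w.window_seq_ref),
                       reverse_complement(w.window_seq_alt))
        expect_ref = {(h.motif, h.snp_pos_in_motif) for h in match_motifs(rc, "ref", motifs)}
        assert {(h.motif, h.snp_pos_in_motif) for h in minus.hits_ref} == expect_ref


def test_gain_effect_class(window_factory):
    """An alt allele that completes a motif absent for ref is a gain."""
    window = make_window({-1: "A", 1: "G", 2: "G", 3: "A", 4: "T"}, "C")  # ref C breaks AGGGAT
    genome, pos = window_factory(window)
    snp = SnpRecord("rs", "1", pos, "C", "G")
    profile = profile_alleles(snp, genome, MotifSet("m", frozenset({"AGGGAT"})))
    assert profile.effect_class == "gain"
    assert profile.hits_ref == () and len(profile.hits_alt) == 1


def test_no_motif_context_is_none_class(window_factory):
    genome, pos = window_factory("CCCCCTCCCCC")
    snp = SnpRecord("rs", "1", pos, "T", "G")
    profile = profile_alleles(snp, genome, MotifSet("m", frozenset({"AAAAAA"})))
    assert profile.effect_class == "none" and not profile.is_ise_snp


def test_call_ise_snps_class_filter_and_planting(window_factory, genome_factory):
    seq = "A" * 45 + make_window({-1: "A", 1: "G", 2: "G", 3: "A", 4: "T"}, "G") + "A" * 44
    genome = genome_factory({"1": seq})
    motifs = MotifSet("m", frozenset({"AGGGAT"}))
    snps = [SnpRecord("planted", "1", 50, "G", "C", snp_class="intronic")]
    snps += [SnpRecord(f"null{i}", "1", 10 + i, "A", "T", snp_class="intronic") for i in range(9)]
    snps += [SnpRecord("exonic", "1", 50, "G", "C", snp_class="exonic")]
    called = call_ise_snps(snps, genome, motifs, strand_mode="plus")
    assert set(called) == {"planted"}


def test_result_invariant_under_motif_input_order(window_factory):
    genome, pos = window_factory(make_window(
        {-3: "T", -2: "C", -1: "A", 1: "G", 2: "G", 3: "A", 4: "T"}, "G"))
    snp = SnpRecord("rs", "1", pos, "G", "A")
    trio = ["AGGGAT", "CAGGGA", "TCAGGG"]
    p1 = profile_alleles(snp, genome, MotifSet("a", frozenset(trio)))
    p2 = profile_alleles(snp, genome, MotifSet("b", frozenset(reversed(trio))))
    assert {(h.motif, h.snp_pos_in_motif) for h in p1.hits_ref} == \
           {(h.motif, h.snp_pos_in_motif) for h in p2.hits_ref}


def test_host_gene_strand_used_when_models_supplied(genome_factory):
    """A motif readable only on the minus strand is found for a minus-strand gene."""
    sense = make_window({-1: "A", 1: "G", 2: "G", 3: "A", 4: "T"}, "G")  # AGGGAT at sense
    plus_seq = "G" * 45 + reverse_complement(sense) + "G" * 250
    genome = genome_factory({"1": plus_seq})
    pos = 50  # center of the embedded revcomp window
    ref_plus = plus_seq[pos]
    alt_plus = "A" if ref_plus != "A" else "T"
    snp = SnpRecord("rs", "1", pos, ref_plus, alt_plus, snp_class="intronic")
    t = TranscriptModel("T1", "G1", "1", "-", ((10, 30), (200, 260)))
    gene = GeneModel("G1", (t,))
    motifs = MotifSet("m", frozenset({"AGGGAT"}))
    with_models = call_ise_snps([snp], genome, motifs, gene_models=[gene], strand_mode="gene")
    plus_only = call_ise_snps([snp], genome, motifs, strand_mode="plus")
    assert set(with_models) == {"rs"} and plus_only == {}
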