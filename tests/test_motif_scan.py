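"""Premature-stop scanning and motif characterization."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from prfbscan.genome_io import GeneRecord
from prfbscan.motif_scan import (
    MotifParams,
    PrematureStop,
    UnscannableSequence,
    characterize_motif,
    classify_prfb,
    find_premature_stops,
    score_sd_like,
    stop_codons_of_table,
)


def oracle_stops(seq, table_id, codon_start=1):
    """Independent check: translate codon by codon with Biopython."""
    framed = seq[codon_start - 1 :]
    out = []
    n = len(framed) // 3
    for i in range(n - 1):
        codon = framed[3 * i : 3 * i + 3]
        if "N" in codon:
            continue
        if str(Seq(codon).translate(table=table_id)) == "*":
            out.append((i + 1, codon))
    return out


# -- stop codon registry -----------------------------------------------------


def test_stop_codon_tables():
    assert stop_codons_of_table(11) == {"TAA", "TAG", "TGA"}
    assert stop_codons_of_table(4) == {"TAA", "TAG"}  # TGA reads Trp
    with pytest.raises(ValueError, match="known tables"):
        stop_codons_of_table(99)


# -- premature stop scanning -------------------------------------------------


def test_internal_tga_found_terminal_taa_excluded():
    stops = find_premature_stops("ATGAAATGAAAATAA", 11)
    assert stops == [PrematureStop(codon_index=3, nt_offset=6, identity="TGA")]


def test_tga_is_not_a_stop_under_table_4():
    assert find_premature_stops("ATGAAATGAAAATAA", 4) == []


def test_codon_start_trims_leading_bases():
    stops = find_premature_stops("G" + "ATGAAATGAAAATAA", 11, codon_start=2)
    assert stops == [PrematureStop(codon_index=3, nt_offset=7, identity="TGA")]
    seq = "G" + "ATGAAATGAAAATAA"
    assert seq[7:10] == "TGA"


def test_n_containing_codons_never_match():
    assert find_premature_stops("ATGTGNAAATAA", 11) == []


def test_unscannable_and_empty_inputs():
    with pytest.raises(UnscannableSequence):
        find_premature_stops("ATGAAATGAAAATA", 11)  # not divisible by 3
    with pytest.raises(UnscannableSequence):
        find_premature_stops("ATG", 11)  # shorter than two codons
    with pytest.raises(ValueError):
        find_premature_stops("", 11)


def test_scanner_matches_translation_oracle(rng):
    bases = np.array(list("ACGT"))
    for _ in range(300):
        n_codons = int(rng.integers(10, 101))
        seq = "".join(bases[rng.integers(0, 4, size=3 * n_codons)])
        for table in (11, 4):
            ours = [(s.codon_index, s.identity) for s in find_premature_stops(seq, table)]
            assert ours == oracle_stops(seq, table)


@given(st.integers(0, 2**31 - 1))
def test_appending_sense_codons_preserves_detected_stops(seed):
    """Monotonicity: extra sense codons before the terminal stop never
    remove a previously detected premature stop."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    body = "".join(bases[rng.integers(0, 4, size=30)])
    seq = "ATG" + body + "TAA"
    before = {(s.codon_index, s.identity) for s in find_premature_stops(seq, 11)}
    sense = ["AAA", "CCC", "GGC", "ATC"]
    insert = "".join(sense[int(rng.integers(0, 4))] for _ in range(3))
    extended = "ATG" + body + insert + "TAA"
    after = {(s.codon_index, s.identity) for s in find_premature_stops(extended, 11)}
    assert before <= after


# -- SD-like scoring ---------------------------------------------------------


def test_sd_score_agggggg_is_maximal_with_wobble():
    m = score_sd_like("AGGGGG")
    assert m is not None and m.score == 6 and m.seq == "AGGGGG"


def test_sd_score_canonical_sd_is_also_maximal():
    m = score_sd_like("AGGAGG")
    assert m is not None and m.score == 6


def test_sd_score_below_threshold_is_none():
    assert score_sd_like("ACACAC") is None


def test_sd_brute_force_over_offsets(rng):
    """Best score equals exhaustive enumeration of all full placements."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    bases = np.array(list("ACGT"))
    anti = "TCCTCC"
    for _ in range(200):
        window = "".join(bases[rng.integers(0, 4, size=int(rng.integers(6, 20)))])
        best = max(
            sum((window[s + i], anti[i]) in pairs for i in range(6))
            for s in range(len(window) - 5)
        )
        m = score_sd_like(window, min_score=0)
        assert m.score == best


def test_sd_tie_breaks_toward_stop_proximal():
    # two perfect SD copies; the 3'-most placement must win
    m = score_sd_like("AGGAGGTTAGGAGG")
    assert m.start == 8


# -- motif characterization --------------------------------------------------


def test_characterize_canonical_motif():
    cds = "ATGGAAAGGGGGTATCTTTGACGCAAATAA"
    stop = find_premature_stops(cds, 11)[0]
    assert (stop.codon_index, stop.identity) == (7, "TGA")
    m = characterize_motif(cds, stop)
    assert m.slippery == "CTTT" and m.slippery_canonical
    assert m.following_nt == "C"
    assert m.sd_match == "AGGGGG" and m.sd_score == 6 and m.sd_spacer == 3
    assert m.window_seq == cds[3:23] and m.window_anchor == 15


def test_characterize_polyt_slippery_reported_noncanonical():
    cds = "ATGGAAAGGGGGTATTTTTGACGCAAATAA"
    stop = find_premature_stops(cds, 11)[0]
    m = characterize_motif(cds, stop)
    assert m.slippery == "TTTT"
    assert not m.slippery_canonical  # long poly-T tract, still reported


def test_characterize_boundary_stop_near_start():
    cds = "ATGTGAAAATAA"
    stop = find_premature_stops(cds, 11)[0]
    assert (stop.codon_index, stop.nt_offset) == (2, 3)
    m = characterize_motif(cds, stop)
    # a codon-2 stop has exactly 3 nt upstream: the slippery window is full
    assert m.slippery == "ATGT"
    assert m.sd_match is None
    assert m.following_nt == "A"


def test_characterize_pads_slippery_when_frame_starts_inside():
    # codon_start=3 puts the first full codon at offset 2 -> stop offset 2 < 3
    seq = "CC" + "TGA" + "AAA" + "TAA"
    stop = find_premature_stops(seq, 11, codon_start=3)[0]
    assert stop.nt_offset == 2
    m = characterize_motif(seq, stop)
    assert m.slippery == ".CCT"


def test_characterize_rejects_inconsistent_stop():
    with pytest.raises(ValueError, match="inconsistent"):
        characterize_motif("ATGAAATAA", PrematureStop(2, 3, "TGA"))


# -- classification ----------------------------------------------------------


def _gene(seq, table=11):
    return GeneRecord(gene_name="prfB", product="peptide chain release factor 2",
                      replicon_id="r", start=1, end=len(seq), strand="+",
                      segments=[(1, len(seq))], transl_table=table, cds_seq=seq)


def test_classify_motif_bearing_gene():
    call = classify_prfb(_gene("ATGGAAAGGGGGTATCTTTGACGCAAATAA"))
    assert call.status == "frameshift"
    assert call.primary_motif.stop.identity == "TGA"


def test_classify_no_frameshift_and_absent():
    assert classify_prfb(_gene("ATGAAACGTTAA")).status == "no_frameshift"
    assert classify_prfb(None).status == "gene_absent"


def test_classify_unscannable_records_note():
    call = classify_prfb(_gene("ATGAAACGTTA"))  # length 11
    assert call.status == "unscannable"
    assert call.notes


def test_table_consistency_tga_only_gene():
    seq = "ATGAAATGAAAATAA"  # internal TGA only
    assert classify_prfb(_gene(seq, table=11)).status == "frameshift"
    assert classify_prfb(_gene(seq, table=4)).status == "no_frameshift"


def test_multiple_stops_primary_is_five_prime_most():
    seq = "ATG" + "TGA" + "AAA" + "TAG" + "CCC" + "TAA"
    call = classify_prfb(_gene(seq))
    assert [s.codon_index for s in call.stops] == [2, 4]
    assert call.primary_motif.stop.codon_index == 2


def test_planted_tag_is_reported_not_filtered():
    """A TAG premature stop must surface in the call (no silent filtering)."""
    seq = "ATGGAAAGGGGGTATCTTTAGACGCAATAA"
    call = classify_prfb(_gene(seq))
    assert call.status == "frameshift"
    assert call.primary_motif.stop.identity == "TAG"
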