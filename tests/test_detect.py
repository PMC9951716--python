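import numpy as np
import pytest

from avissr.detect import (DetectorParams, detect_all, find_compound_ssrs,
                           find_imperfect_ssrs, find_perfect_ssrs)
from avissr.motifs import reverse_complement
from oracles import regex_perfect_oracle, repeat_rich_sequence

BG = "GATGCTGACCTGATCGGATCCAGTCGAGTACGTTAGC"  # repeat-free padding


@pytest.mark.parametrize("motif,threshold", [
    ("A", 12), ("AC", 7), ("ACG", 5), ("AAGC", 4), ("AACGT", 4),
    ("AACGTC", 4),
])
def test_minimum_repeat_thresholds(motif, threshold):
    """Arrays at the class threshold are reported; one copy fewer is not."""
    # padding chosen so it cannot phase-extend the planted array
    left = BG + ("T" if motif[-1] != "T" else "G")
    right = ("T" if motif[0] != "T" else "G") + BG
    at = left + motif * threshold + right
    below = left + motif * (threshold - 1) + right
    hits = find_perfect_ssrs(at)
    assert [(l.motif, l.repeats) for l in hits] == [(motif, threshold)]
    assert hits[0].start == len(left)
    assert hits[0].length_bp == len(motif) * threshold
    assert find_perfect_ssrs(below) == []


def test_mono_example_boundary():
    assert len(find_perfect_ssrs("G" + "A" * 12 + "C")) == 1
    assert find_perfect_ssrs("G" + "A" * 11 + "C") == []


def test_shortest_primitive_period_wins():
    """(ACAC)x4 is a dinucleotide locus with 8 copies, never tetra."""
    [l] = find_perfect_ssrs("ACAC" * 4)
    assert (l.motif, l.repeats, l.motif_len) == ("AC", 8, 2)


def test_runs_never_span_n():
    seq = "A" * 12 + "N" + "A" * 12
    loci = find_perfect_ssrs(seq)
    assert [(l.start, l.end) for l in loci] == [(0, 12), (13, 25)]


def test_invalid_character_names_position():
    with pytest.raises(ValueError, match="position 3"):
        find_perfect_ssrs("ACGXACGT")


def test_empty_sequence_is_empty_result():
    assert find_perfect_ssrs("") == []
    assert find_imperfect_ssrs("") == []


def test_overlapping_runs_leftmost_wins():
    # 12 A's then (CA)n: the mono locus is accepted first, the dinucleotide
    # run is rescanned from its end
    seq = "A" * 12 + "CA" * 7 + "GG"
    loci = find_perfect_ssrs(seq)
    assert [(l.start, l.end, l.motif) for l in loci] == [
        (0, 12, "A"), (12, 26, "CA")]


def test_oracle_equivalence_random_and_spiked():
    """Scanner output equals the regex restart oracle exactly."""
    rng = np.random.default_rng(42)
    n_loci = 0
    for i in range(120):
        if i % 2:
            seq = repeat_rich_sequence(rng, 3000)
        else:
            seq = "".join(rng.choice(list("ACGT"), size=3000))
        got = [(l.start, l.end, l.motif, l.repeats)
               for l in find_perfect_ssrs(seq)]
        assert got == regex_perfect_oracle(seq)
        n_loci += len(got)
    assert n_loci > 100  # the corpus genuinely exercises the scanner


def test_strand_symmetry():
    """Reverse-complement detection mirrors loci up to the truncation phase.

    Partial trailing motif copies are truncated at the left-anchored side,
    so mirrored coordinates may shift by up to motif_len - 1 bases; the
    canonical motif and repeat count are strand-invariant.
    """
    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = repeat_rich_sequence(rng, 4000)
        fwd = find_perfect_ssrs(seq)
        rev = find_perfect_ssrs(reverse_complement(seq))
        n = len(seq)
        mirrored = sorted(((n - l.end, n - l.start), l.canonical, l.repeats)
                          for l in fwd)
        direct = sorted(((l.start, l.end), l.canonical, l.repeats)
                        for l in rev)
        assert len(mirrored) == len(direct)
        for (ma, ca, ra), (da, cb, rb) in zip(mirrored, direct):
            assert (ca, ra) == (cb, rb)
            assert abs(ma[0] - da[0]) < len(ca) and abs(ma[1] - da[1]) < len(ca)


def test_no_base_in_two_perfect_loci():
    rng = np.random.default_rng(3)
    for _ in range(20):
        loci = find_perfect_ssrs(repeat_rich_sequence(rng, 4000))
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start


# ---------------------------------------------------------------------------
# imperfect
# ---------------------------------------------------------------------------

def test_imperfect_single_substitution_hand_trace():
    """Two 8-base A runs bridged by one substitution: 17 bp, score 15."""
    [l] = find_imperfect_ssrs("A" * 8 + "C" + "A" * 8)
    assert (l.start, l.end, l.motif, l.n_edits) == (0, 17, "A", 1)
    assert l.score == 8 + 8 - 1  # 16 matches, one mismatch at -1


def test_pure_run_is_not_imperfect():
    assert find_imperfect_ssrs("A" * 12) == []


def test_low_score_not_reported():
    # (AC)x3 is only 6 bases: below the 8-base seed minimum, nothing to extend
    seq = "ACACAC" + "TT" + "GGATCCGTAGGCTAGCATTACG"
    assert find_imperfect_ssrs(seq) == []


def test_imperfect_with_insertion_and_deletion():
    core = "AGT" * 10
    with_ins = core[:15] + "C" + core[15:]
    [l] = find_imperfect_ssrs(with_ins)
    assert (l.start, l.end, l.n_edits) == (0, 31, 1)
    with_del = core[:15] + core[16:]
    [l] = find_imperfect_ssrs(with_del)
    assert (l.start, l.end, l.n_edits) == (0, 29, 1)


# ---------------------------------------------------------------------------
# compound
# ---------------------------------------------------------------------------

def _perfect_pair(gap):
    seq = "AC" * 7 + "T" * 0 + "G" * 0
    spacer = "GTTGA GTTGA".replace(" ", "")[:gap]
    return find_perfect_ssrs("AC" * 7 + spacer + "AG" * 8)


def test_compound_within_gap_limit():
    [c] = find_compound_ssrs(_perfect_pair(gap=5))
    assert len(c.members) == 2
    assert all(m.in_compound for m in c.members)


def test_compound_beyond_gap_limit():
    seq = "AC" * 7 + "CGTTCGTTCGT" + "AG" * 8  # 11-base spacer
    perfect = find_perfect_ssrs(seq)
    assert len(perfect) == 2
    assert find_compound_ssrs(perfect) == []


def test_compound_chain_of_three():
    seq = "AC" * 7 + "GTT" + "AG" * 8 + "GTTGAGTT" + "AAC" * 6
    perfect = find_perfect_ssrs(seq)
    assert len(perfect) == 3
    [c] = find_compound_ssrs(perfect)
    assert len(c.members) == 3
    assert (c.start, c.end) == (perfect[0].start, perfect[2].end)


def test_detect_all_counts_each_genomic_locus_once():
    seq = "AC" * 7 + "GTT" + "AG" * 8
    loci = detect_all(seq)
    once = [l for l in loci if not (l.ssr_type == "perfect" and l.in_compound)]
    assert [l.ssr_type for l in once] == ["compound"]
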