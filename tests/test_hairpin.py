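import numpy as np
import pytest

from estmir.folding import FoldResult, fold
from estmir.hairpin import (
    TAG_AU_HIGH,
    TAG_AU_LOW,
    TAG_MFEI_HIGH,
    TAG_MFEI_LOW,
    TAG_NO_STEM,
    TAG_NOT_IN_ARM,
    TAG_STAR_LOOP_OR_BREAK,
    TAG_STAR_MISMATCHES,
    CriteriaConfig,
    NoStemError,
    count_duplex_mismatches,
    derive_star,
    evaluate,
    find_hairpin_loop,
    locate_arm,
)
from estmir.precursor import PrecursorCandidate
from estmir.seqio import reverse_complement
from estmir.simulate import make_precursor, random_rna

from conftest import perfect_hairpin


def _candidate(sequence, mature_offset, mature_len, cid="c1"):
    return PrecursorCandidate(
        candidate_id=cid, est_id="e1", mirna_id="m1", strand="+",
        window_start=0, window_end=len(sequence), sequence=sequence,
        mature_offset=mature_offset, mature_len=mature_len,
    )


# --- terminal loop -----------------------------------------------------


def test_single_stem_loop():
    fr = FoldResult("GGGGAAAACCCC", "((((....))))", -5.4)
    assert find_hairpin_loop(fr) == (4, 8)


def test_no_stem_raises():
    with pytest.raises(NoStemError):
        find_hairpin_loop(FoldResult("ACAC", "....", 0.0))


def test_two_stem_tie_breaks_to_leftmost():
    fr = FoldResult("GCAAGCGGAAAACC", "((..))((....))", -3.0)
    assert find_hairpin_loop(fr) == (2, 4)


def test_dominant_stem_wins():
    # 2-pair first stem vs 4-pair second stem
    seq = "GCAAGC" + "GGGGAAAACCCC"
    struct = "((..))" + "((((....))))"
    assert find_hairpin_loop(FoldResult(seq, struct, -6.0)) == (10, 14)


# --- arm location ------------------------------------------------------

ARM_FOLD = FoldResult("GGGGGGGGAAAACCCCCCCC", "((((((((....))))))))", -10.0)


@pytest.mark.parametrize(
    "mature,expected",
    [((0, 6), "5p"), ((6, 4), "loop_spanning"), ((12, 6), "3p")],
)
def test_locate_arm(mature, expected):
    off, length = mature
    assert locate_arm(ARM_FOLD, (8, 12), off, length) == expected


def test_locate_arm_unpaired():
    fr = FoldResult("GGGAAAACCC" + "ACACACACAC", "(((....)))" + "." * 10, -3.0)
    assert locate_arm(fr, (3, 7), 10, 10) == "unpaired"


# --- star derivation and duplex mismatches -----------------------------


def test_derive_star_perfect_construct():
    """On mature + GAAA + revcomp(mature), the star is the revcomp of the
    mature offset by the 2-nt 3' overhang (clipped at the precursor end)."""
    mature = "GCCUGGCUCCCUGUAUGCCA"  # 20 nt
    fr = perfect_hairpin(mature, "GAAA")
    start, length, star, broken = derive_star(fr, 0, 20)
    expected = reverse_complement(mature, "rna")
    # partners span [24, 44); +2 shift clips at the 44-nt precursor end
    assert start == 26
    assert star == expected[2:]
    assert length == 18 and not broken
    assert count_duplex_mismatches(fr, 0, 20) == 0


def test_star_reciprocity():
    """Deriving the star of the star recovers an interval covering the mature."""
    mature = "GCCUGGCUCCCUGUAUGCCA"
    fr = perfect_hairpin(mature, "GAAA")
    s_start, s_len, _, _ = derive_star(fr, 0, 20)
    m_start, m_len, m_seq, _ = derive_star(fr, s_start, s_len)
    assert m_start <= 0 + 2  # covers the mature up to the overhang shift
    assert m_start + m_len >= 18


def test_star_spanning_loop_is_flagged():
    """A 3p mature flush against the loop pushes its star's 3' overhang
    into the terminal loop: no Dicer duplex, flagged."""
    mature = "GCCUGGCUCCCUGUAUGCCA"
    fr = perfect_hairpin(mature, "GAAA")
    star_off = len(mature) + 4
    _, _, _, broken = derive_star(fr, star_off, 20)
    assert broken


def test_fully_unpaired_mature():
    fr = FoldResult("GGGAAAACCC" + "ACACACACAC", "(((....)))" + "." * 10, -3.0)
    assert count_duplex_mismatches(fr, 10, 10) == 10


@pytest.mark.parametrize("k", range(0, 9))
def test_planted_star_mutations_count_exactly(k, backend):
    """k planted star mutations produce exactly k duplex mismatches; a
    single interior gap (k=1) is not a break."""
    rng = np.random.default_rng(11)
    mature = random_rna(21, rng)
    pre, off = make_precursor(mature, 8, k, rng, backend)
    fr = fold(pre, backend)
    assert count_duplex_mismatches(fr, off, 21) == k
    if k <= 2:
        _, _, _, broken = derive_star(fr, off, 21)
        assert not broken


# --- evaluate: the six criteria ----------------------------------------


def _eval_synthetic(backend, k=0, seed=11, cfg=None):
    rng = np.random.default_rng(seed)
    mature = random_rna(21, rng)
    pre, off = make_precursor(mature, 8, k, rng, backend)
    cand = _candidate(pre, off, 21)
    return evaluate(cand, fold(pre, backend), cfg)


def test_evaluate_structural_pass(backend):
    ev = _eval_synthetic(backend, k=2)
    structural = {TAG_NO_STEM, TAG_NOT_IN_ARM, TAG_STAR_MISMATCHES,
                  TAG_STAR_LOOP_OR_BREAK}
    assert not structural & set(ev.failure_reasons)
    assert ev.arm == "5p" and ev.star_mismatches == 2


def test_criterion_flip_at_six(backend):
    """'Less than 6 mismatches': criterion 3 rejects at exactly k=6."""
    for k in (5, 6):
        ev = _eval_synthetic(backend, k=k)
        assert (TAG_STAR_MISMATCHES in ev.failure_reasons) == (k == 6)


def test_no_stem_tag():
    seq = "GACU" * 10
    cand = _candidate(seq, 5, 20)
    ev = evaluate(cand, FoldResult(seq, "." * 40, 0.0))
    assert TAG_NO_STEM in ev.failure_reasons
    assert TAG_NOT_IN_ARM in ev.failure_reasons
    assert not ev.passed and ev.arm == "unpaired"


def test_loop_spanning_mature_never_passes():
    mature = "GCCUGGCUCCCUGUAUGCCA"
    fr = perfect_hairpin(mature, "GAAA")
    # mature interval straddling the terminal loop
    cand = _candidate(fr.sequence, 12, 16)
    ev = evaluate(cand, fr)
    assert not ev.passed
    assert TAG_NOT_IN_ARM in ev.failure_reasons


def test_mfei_tags_and_rounding():
    mature = "GCCUGGCUCCCUGUAUGCCA"
    fr_ok = perfect_hairpin(mature, "GAAA")  # gc ~59%, L=44
    gc = 100.0 * (fr_ok.sequence.count("G") + fr_ok.sequence.count("C")) / 44
    # choose MFE so that MFEI is exactly in/below/above the band
    mfe_in = -(0.75 * gc * 44 / 100)
    mfe_low = -(0.40 * gc * 44 / 100)
    mfe_high = -(1.50 * gc * 44 / 100)
    cand = _candidate(fr_ok.sequence, 0, 20)
    for mfe, tag in [(mfe_low, TAG_MFEI_LOW), (mfe_high, TAG_MFEI_HIGH)]:
        ev = evaluate(cand, FoldResult(fr_ok.sequence, fr_ok.structure, mfe))
        assert tag in ev.failure_reasons
    ev = evaluate(cand, FoldResult(fr_ok.sequence, fr_ok.structure, mfe_in))
    assert not {TAG_MFEI_LOW, TAG_MFEI_HIGH} & set(ev.failure_reasons)
    # rounding: MFEI 0.8536 passes the 0.85 ceiling after 2-dp rounding...
    mfe_margin = -(0.8536 * gc * 44 / 100)
    ev = evaluate(cand, FoldResult(fr_ok.sequence, fr_ok.structure, mfe_margin))
    assert TAG_MFEI_HIGH not in ev.failure_reasons
    # ...but 0.856 rounds to 0.86 and fails
    mfe_out = -(0.856 * gc * 44 / 100)
    ev = evaluate(cand, FoldResult(fr_ok.sequence, fr_ok.structure, mfe_out))
    assert TAG_MFEI_HIGH in ev.failure_reasons


def test_au_tags():
    au_rich = "AAUAUUAUAAUUAUAUAAUGG"  # AU ~ 88% overall
    fr = perfect_hairpin(au_rich, "AAACAAAC")
    ev = evaluate(_candidate(fr.sequence, 0, 21), fr)
    assert TAG_AU_HIGH in ev.failure_reasons
    gc_rich = "GGCGGCCGCGGCCGGCCGCAA"  # AU ~ 12%
    fr2 = perfect_hairpin(gc_rich, "AAACAAAC")
    ev2 = evaluate(_candidate(fr2.sequence, 0, 21), fr2)
    assert TAG_AU_LOW in ev2.failure_reasons


def test_all_failures_reported_together():
    """No short-circuit: AU and mismatch violations are both listed."""
    au_rich = "AAUAUUAUAAUUAUAUAAUGG"
    seq = au_rich + "AAACAAAC" + "AUAUAUAUAUAUAUAUAUAUA"  # star won't pair
    n = len(seq)
    # only a tiny stem at the very ends so a stem exists
    structure = "((" + "." * (n - 4) + "))"
    # make ends pairable: force sequence ends
    seq = "GC" + seq[2:-2] + "GC"
    ev = evaluate(
        _candidate(seq, 0, 21), FoldResult(seq, structure, -80.0)
    )
    assert TAG_STAR_MISMATCHES in ev.failure_reasons
    assert TAG_AU_HIGH in ev.failure_reasons
    assert len(ev.failure_reasons) >= 2


def test_evaluate_rejects_mismatched_fold():
    fr = perfect_hairpin("GCCUGGCUCCCUGUAUGCCA", "GAAA")
    cand = _candidate("ACGU" * 11, 0, 20)
    with pytest.raises(ValueError):
        evaluate(cand, fr)


def test_criteria_config_validation():
    with pytest.raises(ValueError):
        CriteriaConfig(mfei_min=0.9, mfei_max=0.8)
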