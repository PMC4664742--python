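import itertools

import numpy as np
import pytest

from estmir.seqio import SequenceRecord, reverse_complement, transcribe
from estmir.simulate import make_target_transcripts, random_rna
from estmir.targets import (
    CLEAVAGE,
    TRANSLATION,
    TargetParams,
    classify_inhibition,
    scan_transcripts,
    score_duplex,
)

MIR = "UGACAGAAGAGAGUGAGCAC"  # 20 nt
SITE = reverse_complement(MIR, "rna")

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def oracle_expectation(mirna: str, site: str, params: TargetParams) -> float:
    """Independent re-derivation of the duplex expectation.

    Enumerates band-1 alignments with itertools and sums penalties from
    first principles; shares no code with the implementation.
    """
    mirna = mirna.upper().replace("T", "U")[: params.hsp_size]
    rev = site.upper().replace("T", "U")[::-1]

    def score(m_aln, t_aln):
        total = 0.0
        for col, (m, t) in enumerate(zip(m_aln, t_aln), start=1):
            if m == "-" or t == "-":
                pen = params.gap_penalty
            elif (m, t) in _PAIRS:
                pen = 0.0
            elif (m, t) in _WOBBLE:
                pen = params.gu_penalty
            else:
                pen = params.mismatch_penalty
            if params.seed_region[0] <= col <= params.seed_region[1]:
                pen *= params.seed_multiplier
            total += pen
        return total

    n, s = len(mirna), len(rev)
    if n == s:
        alns = [(mirna, rev)]
    elif s == n - 1:
        alns = [(mirna, rev[:k] + "-" + rev[k:]) for k in range(s + 1)]
    else:
        alns = [(mirna[:k] + "-" + mirna[k:], rev) for k in range(n + 1)]
    return min(score(m, t) for m, t in alns)


def _mutate(site: str, mir_pos: int, to: str) -> str:
    """Replace the site base opposite 1-based miRNA position ``mir_pos``."""
    idx = len(MIR) - mir_pos
    return site[:idx] + to + site[idx + 1:]


def test_perfect_duplex_scores_zero():
    assert score_duplex(MIR, SITE).expectation == 0.0


def test_gu_outside_seed_scores_half():
    # miRNA position 15 is G; opposite site base C -> U gives a wobble
    assert MIR[14] == "G"
    site = _mutate(SITE, 15, "U")
    score = score_duplex(MIR, site)
    assert score.expectation == 0.5 and score.n_gu == 1


def test_mismatch_inside_seed_doubles():
    # position 5 lies in the seed region 2-13: penalty 1.0 * 2
    m_base = MIR[4]
    bad = {"A": "C", "U": "C", "G": "A", "C": "A"}[m_base]
    site = _mutate(SITE, 5, bad)
    score = score_duplex(MIR, site)
    assert score.expectation == 2.0 and score.n_mismatch == 1


def test_gap_variants_scored():
    # deleting one site base forces a band-1 gap costing >= gap_penalty
    site = SITE[:10] + SITE[11:]
    score = score_duplex(MIR, site)
    assert score.n_gap == 1
    assert score.expectation >= 2.0
    params = TargetParams()
    assert score.expectation == oracle_expectation(MIR, site, params)


def test_expectation_monotone_under_added_mismatches():
    rng = np.random.default_rng(2)
    for _ in range(20):
        mir = random_rna(20, rng)
        site = reverse_complement(mir, "rna")
        prev = score_duplex(mir, site).expectation
        positions = rng.permutation(20)[:6] + 1
        for pos in positions:
            m_base = mir[pos - 1]
            bad = {"A": "C", "U": "C", "G": "A", "C": "A"}[m_base]
            site = _mutate_generic(site, mir, int(pos), bad)
            cur = score_duplex(mir, site).expectation
            assert cur >= prev
            prev = cur


def _mutate_generic(site, mir, mir_pos, to):
    idx = len(mir) - mir_pos
    return site[:idx] + to + site[idx + 1:]


def test_scan_finds_planted_perfect_site(rng):
    mirs = [SequenceRecord(id="m1", sequence=random_rna(21, rng))]
    txs, truth = make_target_transcripts(mirs, 1, None, rng)
    hits = scan_transcripts(mirs, txs)
    assert len(hits) == 1
    h = hits[0]
    assert h.expectation == 0.0 and h.inhibition == CLEAVAGE
    row = truth.iloc[0]
    assert h.target_start >= row.site_start and h.target_end <= row.site_end + 1


def test_central_mismatch_classified_as_translation(rng):
    mirs = [SequenceRecord(id="m1", sequence=random_rna(21, rng))]
    txs, _ = make_target_transcripts(mirs, 1, [("mismatch", 10)], rng)
    hits = scan_transcripts(mirs, txs)
    assert len(hits) == 1
    assert hits[0].inhibition == TRANSLATION
    assert hits[0].expectation == 2.0  # position 10 is inside the seed region


def test_high_expectation_sites_not_reported(rng):
    edits = [("mismatch", p) for p in (3, 6, 10)]  # 3 seed mismatches = 6.0
    mirs = [SequenceRecord(id="m1", sequence=random_rna(21, rng))]
    txs, _ = make_target_transcripts(mirs, 1, edits, rng)
    assert scan_transcripts(mirs, txs) == []


@pytest.mark.parametrize("seed", range(10))
def test_scan_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    params = TargetParams()
    mirs = [
        SequenceRecord(id=f"m{i}", sequence=random_rna(20 + i % 2, rng))
        for i in range(2)
    ]
    txs, _ = make_target_transcripts(
        mirs, 1, [("mismatch", 15)], rng, transcript_len=300
    )

    def oracle_hits():
        found = []
        for tx in txs:
            seq = transcribe(tx.sequence)
            for mir in mirs:
                n = min(len(mir.sequence), params.hsp_size)
                for wlen in (n - 1, n, n + 1):
                    for start in range(len(seq) - wlen + 1):
                        e = oracle_expectation(
                            mir.sequence, seq[start : start + wlen], params
                        )
                        if e <= params.max_expectation:
                            found.append((mir.id, tx.id, start, start + wlen, e))
        # same overlap-merge policy, re-derived independently
        merged = []
        for (mid, tid), grp in itertools.groupby(
            sorted(found, key=lambda r: (r[0], r[1], r[2], r[3])),
            key=lambda r: (r[0], r[1]),
        ):
            grp = list(grp)
            clusters, cur, end = [], [], -1
            for r in grp:
                if cur and r[2] >= end:
                    clusters.append(cur)
                    cur = []
                cur.append(r)
                end = max(end, r[3])
            if cur:
                clusters.append(cur)
            for cl in clusters:
                merged.append(min(cl, key=lambda r: (r[4], r[2], r[3])))
        return set(merged)

    got = {
        (h.mirna_id, h.transcript_id, h.target_start, h.target_end, h.expectation)
        for h in scan_transcripts(mirs, txs, params)
    }
    assert got == oracle_hits()


def test_classify_inhibition_rule():
    params = TargetParams()
    site = _mutate(SITE, 10, {"A": "C", "U": "C", "G": "A", "C": "A"}[MIR[9]])
    assert classify_inhibition(score_duplex(MIR, site, params), params) == TRANSLATION
    site = _mutate(SITE, 15, {"A": "C", "U": "C", "G": "A", "C": "A"}[MIR[14]])
    assert classify_inhibition(score_duplex(MIR, site, params), params) == CLEAVAGE


def test_params_validation():
    with pytest.raises(ValueError):
        TargetParams(seed_region=(0, 13))
    with pytest.raises(ValueError):
        TargetParams(gap_penalty=-1)
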