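"""Hairpin validation of candidate precursors.

A candidate passes when it behaves like a canonical plant pre-miRNA:

1. ``no_stem``                  — the fold must contain a stem-loop;
2. ``mature_not_in_arm``        — the mature must sit on one arm (5p or
   3p) of the dominant stem, neither spanning the terminal loop nor
   mostly unpaired;
3. ``too_many_star_mismatches`` — at most 5 mature positions may be
   unpaired or mispaired against the star arm ("less than 6
   mismatches"); G-U wobble counts as paired;
4. ``star_loop_or_break``       — the star sequence may not overlap the
   terminal loop nor contain a break (a run of more than 2 consecutive
   positions without a valid partner in the mature);
5. ``mfei_below_min`` / ``mfei_above_max`` — MFEI, rounded to 2 dp,
   within [0.65, 0.85] inclusive;
6. ``au_below_min`` / ``au_above_max``     — AU% within [30, 70].

All criteria are evaluated on every candidate (no short-circuit) so the
report explains every failure.  The star sequence is derived from the
pairing partners of the mature with the canonical 2-nt 3' overhang of
the Dicer duplex; duplex mismatches are counted against the unshifted
pairing span so a perfectly paired mature scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .folding import FoldResult, FoldStats, compute_stats, pair_table
from .precursor import PrecursorCandidate

# criterion tags, in evaluation order
TAG_NO_STEM = "no_stem"
TAG_NOT_IN_ARM = "mature_not_in_arm"
TAG_STAR_MISMATCHES = "too_many_star_mismatches"
TAG_STAR_LOOP_OR_BREAK = "star_loop_or_break"
TAG_MFEI_LOW = "mfei_below_min"
TAG_MFEI_HIGH = "mfei_above_max"
TAG_AU_LOW = "au_below_min"
TAG_AU_HIGH = "au_above_max"


class NoStemError(ValueError):
    """The structure has no base pairs at all."""


class UnpairedMatureError(ValueError):
    """Every mature position is unpaired; no star can be derived."""


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the six homolog criteria."""

    mfei_min: float = 0.65
    mfei_max: float = 0.85
    au_min_pct: float = 30.0
    au_max_pct: float = 70.0
    max_star_mismatches: int = 5  # "less than 6"
    mfei_round_dp: int = 2

    def __post_init__(self) -> None:
        if not self.mfei_min < self.mfei_max:
            raise ValueError("mfei_min must be < mfei_max")
        if not self.au_min_pct < self.au_max_pct:
            raise ValueError("au_min_pct must be < au_max_pct")


@dataclass(frozen=True)
class HairpinEvaluation:
    """Per-candidate verdict with all statistics, passed or not."""

    candidate_id: str
    arm: str  # 5p | 3p | loop_spanning | unpaired
    star_sequence: str
    star_start: int
    star_mismatches: int
    star_has_loop_or_break: bool
    stats: FoldStats
    mfe: float
    passed: bool
    failure_reasons: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failure_reasons) == 0)
        if self.passed:
            assert self.arm in ("5p", "3p")

    @property
    def star_len(self) -> int:
        return len(self.star_sequence)


def find_hairpin_loop(fold: FoldResult) -> tuple[int, int]:
    """Terminal loop of the dominant stem, as a half-open interval.

    A hairpin loop is the region enclosed by an innermost pair (one with
    no paired position inside).  Each such loop owns a stem: the pairs
    that enclose it and no other hairpin loop.  The loop of the stem
    with the most pairs is returned; ties break toward the stem whose
    closing (innermost) pair has the smallest opening index.
    """
    pt = pair_table(fold.structure)
    pairs = [(i, j) for i, j in enumerate(pt) if j is not None and i < j]
    if not pairs:
        raise NoStemError("structure contains no base pairs")
    hairpins = [
        (i, j)
        for i, j in pairs
        if all(pt[k] is None for k in range(i + 1, j))
    ]
    # attribute each pair to the hairpin loop it exclusively encloses
    stem_size = {h: 0 for h in hairpins}
    for a, b in pairs:
        inside = [h for h in hairpins if a <= h[0] and h[1] <= b]
        if len(inside) == 1:
            stem_size[inside[0]] += 1
    i, j = min(hairpins, key=lambda h: (-stem_size[h], h[0]))
    return (i + 1, j)


def locate_arm(
    fold: FoldResult, loop: tuple[int, int], mature_offset: int, mature_len: int
) -> str:
    """Which arm of the hairpin carries the mature sequence.

    ``unpaired`` when fewer than half the mature positions are paired;
    otherwise ``5p`` if the mature ends at or before the loop, ``3p`` if
    it starts at or after it, ``loop_spanning`` if it overlaps the loop.
    """
    pt = pair_table(fold.structure)
    mature = range(mature_offset, mature_offset + mature_len)
    n_paired = sum(pt[k] is not None for k in mature)
    if 2 * n_paired < mature_len:
        return "unpaired"
    loop_start, loop_end = loop
    if mature_offset + mature_len <= loop_start:
        return "5p"
    if mature_offset >= loop_end:
        return "3p"
    return "loop_spanning"


def _duplex_span(pt: list[int | None], mature_offset: int, mature_len: int) -> tuple[int, int]:
    partners = [
        pt[k]
        for k in range(mature_offset, mature_offset + mature_len)
        if pt[k] is not None
    ]
    if not partners:
        raise UnpairedMatureError("mature sequence is entirely unpaired")
    return min(partners), max(partners) + 1


def derive_star(
    fold: FoldResult, mature_offset: int, mature_len: int
) -> tuple[int, int, str, bool]:
    """Derive the star sequence of a mature on one arm.

    The star interval is the span of the mature's pairing partners
    shifted 2 nt toward the star's 3' end (the Dicer duplex leaves a
    2-nt 3' overhang on both strands), clipped to the precursor.
    Returns (star_start, star_len, star_sequence, star_has_loop_or_break);
    the loop-or-break flag is set when the star overlaps the terminal
    loop or contains a run of more than 2 consecutive positions whose
    partners are absent or outside the mature.
    """
    pt = pair_table(fold.structure)
    lo, hi = _duplex_span(pt, mature_offset, mature_len)
    # 5'->3' runs left to right on both arms, so the star's 3' side is
    # always the high-coordinate side
    star_start = min(max(0, lo + 2), len(fold.sequence))
    star_end = min(hi + 2, len(fold.sequence))
    star_seq = fold.sequence[star_start:star_end]
    loop_start, loop_end = find_hairpin_loop(fold)
    overlaps_loop = star_start < loop_end and star_end > loop_start
    mature_range = range(mature_offset, mature_offset + mature_len)
    run = worst = 0
    for k in range(star_start, star_end):
        if pt[k] is None or pt[k] not in mature_range:
            run += 1
            worst = max(worst, run)
        else:
            run = 0
    return star_start, star_end - star_start, star_seq, overlaps_loop or worst > 2


def count_duplex_mismatches(fold: FoldResult, mature_offset: int, mature_len: int) -> int:
    """Mature positions unpaired or paired outside the star's pairing span.

    G-U wobble pairs are structural pairs and do not count as
    mismatches.  A fully unpaired mature scores ``mature_len``.
    """
    pt = pair_table(fold.structure)
    try:
        lo, hi = _duplex_span(pt, mature_offset, mature_len)
    except UnpairedMatureError:
        return mature_len
    bad = 0
    for k in range(mature_offset, mature_offset + mature_len):
        if pt[k] is None or not (lo <= pt[k] < hi):
            bad += 1
    return bad


def evaluate(
    candidate: PrecursorCandidate,
    fold: FoldResult,
    cfg: CriteriaConfig | None = None,
) -> HairpinEvaluation:
    """Apply all six homolog criteria to one folded candidate."""
    cfg = cfg or CriteriaConfig()
    if fold.sequence != candidate.sequence:
        raise ValueError(
            f"fold does not correspond to candidate {candidate.candidate_id!r}"
        )
    stats = compute_stats(candidate.sequence, fold.mfe)
    reasons: list[str] = []

    try:
        loop = find_hairpin_loop(fold)
    except NoStemError:
        loop = None
        reasons.append(TAG_NO_STEM)

    if loop is not None:
        arm = locate_arm(fold, loop, candidate.mature_offset, candidate.mature_len)
    else:
        arm = "unpaired"
    if arm not in ("5p", "3p"):
        reasons.append(TAG_NOT_IN_ARM)

    mismatches = count_duplex_mismatches(
        fold, candidate.mature_offset, candidate.mature_len
    )
    if mismatches > cfg.max_star_mismatches:
        reasons.append(TAG_STAR_MISMATCHES)

    star_start, star_seq, loop_or_break = -1, "", True
    if loop is not None:
        try:
            star_start, _, star_seq, loop_or_break = derive_star(
                fold, candidate.mature_offset, candidate.mature_len
            )
        except UnpairedMatureError:
            pass  # no star derivable; criterion 3 already counts every position
    if loop_or_break:
        reasons.append(TAG_STAR_LOOP_OR_BREAK)

    mfei_rounded = round(stats.mfei, cfg.mfei_round_dp)
    if mfei_rounded < cfg.mfei_min:
        reasons.append(TAG_MFEI_LOW)
    elif mfei_rounded > cfg.mfei_max:
        reasons.append(TAG_MFEI_HIGH)

    if stats.au_pct < cfg.au_min_pct:
        reasons.append(TAG_AU_LOW)
    elif stats.au_pct > cfg.au_max_pct:
        reasons.append(TAG_AU_HIGH)

    return HairpinEvaluation(
        candidate_id=candidate.candidate_id,
        arm=arm,
        star_sequence=star_seq,
        star_start=star_start,
        star_mismatches=mismatches,
        star_has_loop_or_break=loop_or_break,
        stats=stats,
        mfe=fold.mfe,
        passed=not reasons,
        failure_reasons=tuple(reasons),
    )
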