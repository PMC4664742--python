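"""miRNA target prediction by complementarity expectation scoring.

A target site is scored the way plant small-RNA target servers score a
miRNA/mRNA duplex: the site (read 5'->3' on the transcript) is aligned
antiparallel to the miRNA and each alignment column contributes a
penalty — 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for any
other mismatch, 2 for a gap — with penalties doubled inside the seed
region (miRNA positions 2-13 by default).  The *expectation* is the
penalty sum; sites at or below the expectation threshold (default 3)
are reported.  Complementarity is scored over the 5'-most ``hsp_size``
nucleotides of the miRNA.

Sites with any penalized column opposite miRNA positions 9-11 (the
slicing site of the RISC-guided cleavage reaction) are classified as
acting by translational inhibition; fully complementary central regions
imply transcript cleavage.

Gaps are handled by a band-1 alignment: a site one nucleotide shorter
or longer than the miRNA is scored over all single-gap placements and
the cheapest one is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SequenceRecord, transcribe

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

CLEAVAGE = "cleavage"
TRANSLATION = "translation"


@dataclass(frozen=True)
class TargetParams:
    """Scoring schema and thresholds of the target search."""

    max_expectation: float = 3.0
    hsp_size: int = 20
    central_mismatch_range: tuple[int, int] = (9, 11)  # 1-based, inclusive
    seed_region: tuple[int, int] = (2, 13)  # 1-based, inclusive
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_multiplier: float = 2.0
    upe_max: float = 25.0  # recorded for config fidelity; accessibility is off

    def __post_init__(self) -> None:
        for p in (self.mismatch_penalty, self.gu_penalty, self.gap_penalty):
            if p < 0:
                raise ValueError("penalties must be >= 0")
        for lo, hi in (self.central_mismatch_range, self.seed_region):
            if not (1 <= lo <= hi <= self.hsp_size):
                raise ValueError("position ranges must lie within [1, hsp_size]")


@dataclass(frozen=True)
class TargetHit:
    """A predicted miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    target_start: int  # 0-based half-open on the transcript
    target_end: int
    expectation: float
    n_mismatch: int
    n_gu: int
    n_gap: int
    inhibition: str  # cleavage | translation
    aligned_mirna: str
    aligned_target: str


@dataclass(frozen=True)
class DuplexScore:
    expectation: float
    n_mismatch: int
    n_gu: int
    n_gap: int
    # 1-based miRNA-side column positions (from the miRNA 5' end) of
    # every penalized column
    penalized_positions: tuple[int, ...]
    aligned_mirna: str
    aligned_target: str


def _column_penalty(m: str, t: str, params: TargetParams) -> tuple[float, str]:
    """Penalty and kind ('wc'|'gu'|'mm'|'gap') for one alignment column."""
    if m == "-" or t == "-":
        return params.gap_penalty, "gap"
    if (m, t) in _WC:
        return 0.0, "wc"
    if (m, t) in _GU:
        return params.gu_penalty, "gu"
    return params.mismatch_penalty, "mm"


def _score_alignment(
    mirna: str, target_rev: str, params: TargetParams
) -> DuplexScore:
    """Score one gapped alignment of miRNA (5'->3') vs reversed site."""
    assert len(mirna) == len(target_rev)
    seed_lo, seed_hi = params.seed_region
    total = 0.0
    n_mm = n_gu = n_gap = 0
    penalized: list[int] = []
    for col, (m, t) in enumerate(zip(mirna, target_rev), start=1):
        pen, kind = _column_penalty(m, t, params)
        if seed_lo <= col <= seed_hi:
            pen *= params.seed_multiplier
        if kind == "mm":
            n_mm += 1
        elif kind == "gu":
            n_gu += 1
        elif kind == "gap":
            n_gap += 1
        if pen > 0:
            penalized.append(col)
            total += pen
    return DuplexScore(
        expectation=total,
        n_mismatch=n_mm,
        n_gu=n_gu,
        n_gap=n_gap,
        penalized_positions=tuple(penalized),
        aligned_mirna=mirna,
        aligned_target=target_rev,
    )


def _gap_variants(mirna: str, site_rev: str) -> list[tuple[str, str]]:
    """All band-1 alignments of the miRNA against the reversed site."""
    lm, ls = len(mirna), len(site_rev)
    if lm == ls:
        return [(mirna, site_rev)]
    if ls == lm - 1:  # one gap in the target strand
        return [
            (mirna, site_rev[:k] + "-" + site_rev[k:]) for k in range(ls + 1)
        ]
    if ls == lm + 1:  # one gap in the miRNA (target bulge)
        return [
            (mirna[:k] + "-" + mirna[k:], site_rev) for k in range(lm + 1)
        ]
    raise ValueError(
        f"site length {ls} outside the band-1 range of miRNA length {lm}"
    )


def score_duplex(mirna: str, site: str, params: TargetParams | None = None) -> DuplexScore:
    """Score a miRNA against one candidate site (both given 5'->3', RNA).

    The site is reversed so alignment columns run from the miRNA 5' end;
    band-1 gapped variants are enumerated when lengths differ by one and
    the minimum-expectation alignment is returned (ties: first placement).
    """
    params = params or TargetParams()
    mirna = mirna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")
    for name, seq in (("miRNA", mirna), ("site", site)):
        if set(seq) - set("ACGUN"):
            raise ValueError(f"{name} has characters outside the RNA alphabet")
    mirna = mirna[: params.hsp_size]
    variants = _gap_variants(mirna, site[::-1])
    best = None
    for m_aln, t_aln in variants:
        score = _score_alignment(m_aln, t_aln, params)
        if best is None or score.expectation < best.expectation:
            best = score
    assert best is not None
    return best


def classify_inhibition(score: DuplexScore, params: TargetParams) -> str:
    """Cleavage unless a penalized column sits in the central-mismatch range."""
    lo, hi = params.central_mismatch_range
    if any(lo <= p <= hi for p in score.penalized_positions):
        return TRANSLATION
    return CLEAVAGE


def scan_transcripts(
    mirnas: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    params: TargetParams | None = None,
) -> list[TargetHit]:
    """Slide every miRNA over every transcript and report scoring sites.

    Windows of the scored-miRNA length and its band-1 variants are
    scored at every offset; hits with expectation <= max_expectation are
    kept, overlapping hits of the same (miRNA, transcript) collapse to
    the lowest expectation (ties: leftmost, then shortest).  Output
    order: (transcript_id, target_start, mirna_id).
    """
    params = params or TargetParams()
    raw: list[TargetHit] = []
    for tx in transcripts:
        seq = transcribe(tx.sequence)
        for mir in mirnas:
            eff_len = min(len(mir.sequence), params.hsp_size)
            lengths = {eff_len - 1, eff_len, eff_len + 1}
            for wlen in sorted(lengths):
                if wlen < 1 or wlen > len(seq):
                    continue
                for start in range(len(seq) - wlen + 1):
                    site = seq[start : start + wlen]
                    score = score_duplex(mir.sequence, site, params)
                    if score.expectation <= params.max_expectation:
                        raw.append(
                            TargetHit(
                                mirna_id=mir.id,
                                transcript_id=tx.id,
                                target_start=start,
                                target_end=start + wlen,
                                expectation=score.expectation,
                                n_mismatch=score.n_mismatch,
                                n_gu=score.n_gu,
                                n_gap=score.n_gap,
                                inhibition=classify_inhibition(score, params),
                                aligned_mirna=score.aligned_mirna,
                                aligned_target=score.aligned_target,
                            )
                        )
    return _merge_target_hits(raw)


def _merge_target_hits(raw: list[TargetHit]) -> list[TargetHit]:
    groups: dict[tuple[str, str], list[TargetHit]] = {}
    for h in raw:
        groups.setdefault((h.mirna_id, h.transcript_id), []).append(h)
    out: list[TargetHit] = []
    for hits in groups.values():
        hits.sort(key=lambda h: (h.target_start, h.target_end))
        cluster: list[TargetHit] = []
        cluster_end = -1
        for h in hits:
            if cluster and h.target_start >= cluster_end:
                out.append(_best_hit(cluster))
                cluster = []
            cluster.append(h)
            cluster_end = max(cluster_end, h.target_end)
        if cluster:
            out.append(_best_hit(cluster))
    out.sort(key=lambda h: (h.transcript_id, h.target_start, h.mirna_id))
    return out


def _best_hit(cluster: list[TargetHit]) -> TargetHit:
    return min(
        cluster, key=lambda h: (h.expectation, h.target_start, h.target_end)
    )


def write_targets_tsv(hits: Iterable[TargetHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\ttranscript_id\ttarget_start\ttarget_end\texpectation\t"
            "n_mismatch\tn_gu\tn_gap\tinhibition\taligned_mirna\taligned_target\n"
        )
        for h in hits:
            fh.write(
                f"{h.mirna_id}\t{h.transcript_id}\t{h.target_start + 1}\t"
                f"{h.target_end}\t{h.expectation:.2f}\t{h.n_mismatch}\t{h.n_gu}\t"
                f"{h.n_gap}\t{h.inhibition}\t{h.aligned_mirna}\t{h.aligned_target}\n"
            )


def write_edge_table(hits: Iterable[TargetHit], path: str | Path) -> None:
    """Two-column miRNA -> transcript edge list for chord/graph plotting."""
    seen: set[tuple[str, str]] = set()
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\n")
        for h in hits:
            edge = (h.mirna_id, h.transcript_id)
            if edge not in seen:
                seen.add(edge)
                fh.write(f"{edge[0]}\t{edge[1]}\n")
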