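"""Homology search for mature miRNAs inside EST sequences.

The search mirrors a short-word BLASTN run with the constraints used for
plant miRNA homolog mining: ungapped matches of 18-24 nt, identity
strictly above 85%, fewer than 4 mismatches, seeded by exact 7-mer words,
both strands.  A *hit* is an ungapped alignment window that

* has length within ``[min_len, max_len]``,
* has at most ``max_mismatches`` mismatches,
* has percent identity strictly above ``min_identity_pct``, and
* contains at least one exact run of ``word_size`` consecutive matches
  (the seeding requirement; windows whose mismatches break every word
  are invisible to a word-seeded search and are not hits).

Overlapping windows of the same (miRNA, EST, strand) are collapsed to the
single best one (most identities, then leftmost, then shortest, then
smallest query offset).  :func:`brute_force_hits` applies the identical
definition by exhaustive window enumeration and is the testing oracle for
the seeded :func:`find_hits`; the two agree exactly by construction.

Coordinates are 0-based half-open on the forward EST strand throughout;
minus-strand hits are reported in forward coordinates with ``strand='-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord, back_transcribe, reverse_complement

_DNA = frozenset("ACGTN")


@dataclass(frozen=True)
class SearchParams:
    """Constraints of the homology search.

    Defaults are the published mining parameters: word size 7, identity
    > 85% (strict), mismatches < 4, mature match length 18-24 nt, both
    strands.
    """

    word_size: int = 7
    min_identity_pct: float = 85.0  # exclusive bound
    max_mismatches: int = 3
    min_len: int = 18
    max_len: int = 24
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True, order=True)
class HomologyHit:
    """An ungapped match of a mature miRNA on an EST.

    ``est_start``/``est_end`` are 0-based half-open on the forward EST
    strand; ``query_start``/``query_end`` likewise on the mature miRNA.
    """

    est_id: str
    est_start: int
    mirna_id: str
    strand: str
    est_end: int
    aln_len: int
    mismatches: int
    identity_pct: float
    query_start: int
    query_end: int

    def __post_init__(self) -> None:
        assert self.est_end - self.est_start == self.aln_len, "hit must be ungapped"
        assert self.query_end - self.query_start == self.aln_len
        expected = 100.0 * (self.aln_len - self.mismatches) / self.aln_len
        assert abs(self.identity_pct - expected) < 1e-9


def _check_bounds(hit: HomologyHit, params: SearchParams) -> None:
    assert params.min_len <= hit.aln_len <= params.max_len
    assert hit.mismatches <= params.max_mismatches
    assert hit.identity_pct > params.min_identity_pct


def _longest_match_run(matches: Sequence[bool]) -> int:
    best = run = 0
    for m in matches:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _window_ok(mismatches: int, length: int, max_run: int, params: SearchParams) -> bool:
    if not (params.min_len <= length <= params.max_len):
        return False
    if mismatches > params.max_mismatches:
        return False
    if 100.0 * (length - mismatches) / length <= params.min_identity_pct:
        return False
    return max_run >= params.word_size


def _merge_candidates(cands: list[HomologyHit]) -> list[HomologyHit]:
    """Collapse transitively-overlapping windows per (miRNA, EST, strand).

    Keeps the window with the most identities; ties go to the smallest
    est_start, then smallest est_end, then smallest query_start.
    """
    groups: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for h in cands:
        groups.setdefault((h.mirna_id, h.est_id, h.strand), []).append(h)
    out: list[HomologyHit] = []
    for hits in groups.values():
        hits.sort(key=lambda h: (h.est_start, h.est_end))
        cluster: list[HomologyHit] = []
        cluster_end = -1
        for h in hits:
            if cluster and h.est_start >= cluster_end:
                out.append(_best_of(cluster))
                cluster = []
            cluster.append(h)
            cluster_end = max(cluster_end, h.est_end)
        if cluster:
            out.append(_best_of(cluster))
    out.sort(key=lambda h: (h.est_id, h.est_start, h.mirna_id, h.strand))
    return out


def _best_of(cluster: list[HomologyHit]) -> HomologyHit:
    return min(
        cluster,
        key=lambda h: (
            -(h.aln_len - h.mismatches),  # most identities
            h.est_start,
            h.est_end,
            h.query_start,
        ),
    )


def _validate_inputs(
    mirnas: Sequence[SequenceRecord], ests: Sequence[SequenceRecord]
) -> None:
    for m in mirnas:
        if "T" in m.sequence:
            raise ValueError(f"miRNA {m.id!r} is not in the RNA alphabet")
    for e in ests:
        if "U" in e.sequence:
            raise ValueError(f"EST {e.id!r} is not in the DNA alphabet")
        if set(e.sequence) - _DNA:
            raise ValueError(f"EST {e.id!r} has characters outside the DNA alphabet")


def _strand_views(est: SequenceRecord, params: SearchParams) -> list[tuple[str, str]]:
    views = [("+", est.sequence)]
    if params.search_both_strands:
        views.append(("-", reverse_complement(est.sequence, "dna")))
    return views


def _make_hit(
    mirna_id: str,
    est_id: str,
    strand: str,
    est_len: int,
    s0: int,  # start on the searched (possibly reverse-complemented) strand
    q0: int,
    length: int,
    mismatches: int,
) -> HomologyHit:
    if strand == "+":
        fwd_start = s0
    else:
        fwd_start = est_len - (s0 + length)
    return HomologyHit(
        mirna_id=mirna_id,
        est_id=est_id,
        strand=strand,
        est_start=fwd_start,
        est_end=fwd_start + length,
        aln_len=length,
        mismatches=mismatches,
        identity_pct=100.0 * (length - mismatches) / length,
        query_start=q0,
        query_end=q0 + length,
    )


def find_hits(
    mirnas: Sequence[SequenceRecord],
    ests: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[HomologyHit]:
    """Seeded homology search of mature miRNAs against ESTs.

    Exact ``word_size``-mer seeding (U treated as T) locates candidate
    diagonals; every ungapped window on a seeded diagonal satisfying the
    hit definition is collected, then overlapping windows are merged.
    Output order is deterministic: (est_id, est_start, mirna_id, strand).
    """
    params = params or SearchParams()
    _validate_inputs(mirnas, ests)
    cands: list[HomologyHit] = []
    queries = [(m, back_transcribe(m.sequence)) for m in mirnas]
    for est in ests:
        est_len = len(est.sequence)
        for strand, subject in _strand_views(est, params):
            # index subject word_size-mers
            word_index: dict[str, list[int]] = {}
            w = params.word_size
            for i in range(est_len - w + 1):
                word_index.setdefault(subject[i : i + w], []).append(i)
            for mirna, query in queries:
                lq = len(query)
                if lq < params.min_len:
                    continue
                diagonals: set[int] = set()
                for q in range(lq - w + 1):
                    for s in word_index.get(query[q : q + w], ()):
                        diagonals.add(s - q)
                for d in diagonals:
                    cands.extend(
                        _diagonal_windows(
                            mirna.id, est.id, strand, est_len, query, subject, d, params
                        )
                    )
    hits = _merge_candidates(cands)
    for h in hits:
        _check_bounds(h, params)
    return hits


def _diagonal_windows(
    mirna_id: str,
    est_id: str,
    strand: str,
    est_len: int,
    query: str,
    subject: str,
    diag: int,
    params: SearchParams,
) -> list[HomologyHit]:
    lq, ls = len(query), len(subject)
    out = []
    max_l = min(params.max_len, lq)
    for length in range(params.min_len, max_l + 1):
        for q0 in range(0, lq - length + 1):
            s0 = q0 + diag
            if s0 < 0 or s0 + length > ls:
                continue
            matches = [query[q0 + k] == subject[s0 + k] for k in range(length)]
            mm = length - sum(matches)
            if _window_ok(mm, length, _longest_match_run(matches), params):
                out.append(
                    _make_hit(mirna_id, est_id, strand, est_len, s0, q0, length, mm)
                )
    return out


def brute_force_hits(
    mirnas: Sequence[SequenceRecord],
    ests: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[HomologyHit]:
    """Exhaustive-window reference search (testing oracle for :func:`find_hits`).

    Enumerates every ungapped window of every length in [min_len, max_len]
    at every (query, subject) offset on both strands and applies the hit
    definition directly, then the same overlap merge.  Vectorized with
    numpy so the oracle is usable on kilobase-scale instances.
    """
    params = params or SearchParams()
    _validate_inputs(mirnas, ests)
    cands: list[HomologyHit] = []
    for est in ests:
        est_len = len(est.sequence)
        for strand, subject in _strand_views(est, params):
            subj_arr = np.frombuffer(subject.encode(), dtype=np.uint8)
            for mirna in mirnas:
                query = back_transcribe(mirna.sequence)
                lq = len(query)
                q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
                max_l = min(params.max_len, lq, est_len)
                for length in range(params.min_len, max_l + 1):
                    if est_len < length:
                        continue
                    windows = np.lib.stride_tricks.sliding_window_view(
                        subj_arr, length
                    )
                    for q0 in range(0, lq - length + 1):
                        eq = windows == q_arr[q0 : q0 + length]  # (n_win, length)
                        mm = length - eq.sum(axis=1)
                        # longest run of matches per window
                        run = np.zeros(eq.shape[0], dtype=np.int32)
                        best = np.zeros(eq.shape[0], dtype=np.int32)
                        for k in range(length):
                            run = np.where(eq[:, k], run + 1, 0)
                            np.maximum(best, run, out=best)
                        ident_ok = (
                            100.0 * (length - mm) / length > params.min_identity_pct
                        )
                        keep = (
                            (mm <= params.max_mismatches)
                            & ident_ok
                            & (best >= params.word_size)
                        )
                        for s0 in np.nonzero(keep)[0]:
                            cands.append(
                                _make_hit(
                                    mirna.id,
                                    est.id,
                                    strand,
                                    est_len,
                                    int(s0),
                                    q0,
                                    length,
                                    int(mm[s0]),
                                )
                            )
    hits = _merge_candidates(cands)
    for h in hits:
        _check_bounds(h, params)
    return hits


def write_hits_tsv(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits as TSV with 1-based inclusive EST coordinates (report convention)."""
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\test_id\tstrand\test_start\test_end\t"
            "aln_len\tmismatches\tidentity_pct\n"
        )
        for h in hits:
            fh.write(
                f"{h.mirna_id}\t{h.est_id}\t{h.strand}\t{h.est_start + 1}\t"
                f"{h.est_end}\t{h.aln_len}\t{h.mismatches}\t{h.identity_pct:.2f}\n"
            )
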