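"""Candidate pre-miRNA extraction around homology hits.

The putative precursor is the EST window spanning 100 nt upstream and
100 nt downstream of the hit (so a 20-nt mature yields a 220-nt
precursor); ESTs shorter than 200 nt contribute their entire sequence.
Flanks truncated by the EST boundary are kept rather than discarded.
Minus-strand hits are reverse-complemented so the precursor always reads
5'->3' with the mature on the sense strand, and the sequence is
transcribed to RNA for folding.

Protein-coding screening is pluggable: an id exclusion list (for users
who align precursors against a protein database externally) plus an
optional built-in ORF-length heuristic, off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .homology import HomologyHit
from .seqio import SequenceRecord, back_transcribe, reverse_complement, transcribe

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 100
# below this EST length the whole EST is used as the precursor window
MIN_FULL_WINDOW = 200

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PrecursorCandidate:
    """An extracted precursor window with the mature's position inside it.

    ``window_start``/``window_end`` are 0-based half-open forward-strand
    EST coordinates; ``sequence`` is RNA, oriented so the mature reads
    5'->3' (reverse-complemented for minus-strand hits);
    ``mature_offset`` indexes into the oriented sequence.
    """

    candidate_id: str
    est_id: str
    mirna_id: str
    strand: str
    window_start: int
    window_end: int
    sequence: str
    mature_offset: int
    mature_len: int

    def __post_init__(self) -> None:
        assert self.precursor_len == len(self.sequence)
        assert 0 <= self.mature_offset
        assert self.mature_offset + self.mature_len <= self.precursor_len

    @property
    def precursor_len(self) -> int:
        return self.window_end - self.window_start

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.mature_len]


def extract_precursor(
    est: SequenceRecord, hit: HomologyHit, flank: int = DEFAULT_FLANK
) -> PrecursorCandidate:
    """Extract the precursor window around a homology hit.

    Window = [est_start - flank, est_end + flank) clipped to the EST;
    if the EST is shorter than ``MIN_FULL_WINDOW`` the entire EST is the
    window.  The returned sequence is RNA, oriented to the hit strand.
    """
    est_len = len(est.sequence)
    if hit.est_id != est.id:
        raise ValueError(f"hit is on EST {hit.est_id!r}, not {est.id!r}")
    if not (0 <= hit.est_start < hit.est_end <= est_len):
        raise ValueError(
            f"hit [{hit.est_start},{hit.est_end}) outside EST {est.id!r} "
            f"of length {est_len}"
        )
    if est_len < MIN_FULL_WINDOW:
        start, end = 0, est_len
    else:
        start = max(0, hit.est_start - flank)
        end = min(est_len, hit.est_end + flank)
    window_dna = est.sequence[start:end]
    if hit.strand == "+":
        oriented = window_dna
        mature_offset = hit.est_start - start
    else:
        oriented = reverse_complement(window_dna, "dna")
        mature_offset = end - hit.est_end
    cid = f"{hit.mirna_id}|{est.id}|{start}-{end}|{hit.strand}"
    return PrecursorCandidate(
        candidate_id=cid,
        est_id=est.id,
        mirna_id=hit.mirna_id,
        strand=hit.strand,
        window_start=start,
        window_end=end,
        sequence=transcribe(oriented),
        mature_offset=mature_offset,
        mature_len=hit.aln_len,
    )


def longest_orf_aa(sequence_rna: str) -> int:
    """Longest ATG-to-stop open reading frame, in codons excluding the stop.

    Scans the three forward frames of the DNA transliteration of the
    oriented precursor.  ORFs without an in-frame stop inside the window
    are not counted (a precursor is a short window; an open-ended run is
    not evidence of a coding region).
    """
    dna = back_transcribe(sequence_rna)
    best = 0
    for frame in range(3):
        codons = [dna[i : i + 3] for i in range(frame, len(dna) - 2, 3)]
        start = None
        for idx, codon in enumerate(codons):
            if start is None:
                if codon == "ATG":
                    start = idx
            elif codon in _STOPS:
                best = max(best, idx - start)
                start = None
    return best


def apply_coding_filter(
    candidates: Sequence[PrecursorCandidate],
    excluded_est_ids: set[str] | frozenset[str] = frozenset(),
    orf_screen: bool = False,
    min_orf_aa: int = 80,
) -> list[PrecursorCandidate]:
    """Drop candidates flagged as protein-coding.

    A candidate is removed when its EST id is in ``excluded_est_ids``, or,
    if ``orf_screen`` is on, when its precursor contains an open reading
    frame of at least ``min_orf_aa`` codons.  Each removal is logged.
    """
    kept: list[PrecursorCandidate] = []
    for cand in candidates:
        if cand.est_id in excluded_est_ids:
            logger.info("coding-filter drop %s: est id excluded", cand.candidate_id)
            continue
        if orf_screen:
            orf = longest_orf_aa(cand.sequence)
            if orf >= min_orf_aa:
                logger.info(
                    "coding-filter drop %s: ORF of %d aa >= %d",
                    cand.candidate_id,
                    orf,
                    min_orf_aa,
                )
                continue
        logger.debug("coding-filter keep %s", cand.candidate_id)
        kept.append(cand)
    return kept


def candidates_to_records(
    candidates: Iterable[PrecursorCandidate],
) -> list[SequenceRecord]:
    """Render candidates as FASTA records with a structured description."""
    return [
        SequenceRecord(
            id=c.candidate_id,
            sequence=c.sequence,
            description=(
                f"mirna={c.mirna_id} est={c.est_id} strand={c.strand} "
                f"window={c.window_start}-{c.window_end} "
                f"mature_offset={c.mature_offset} mature_len={c.mature_len}"
            ),
        )
        for c in candidates
    ]
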