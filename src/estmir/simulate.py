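"""Synthetic reference miRNAs, ESTs with planted precursors, and target
transcripts.

Every pipeline stage is exercised offline by generating the inputs it
expects: reference mature sequences; positive ESTs that embed a planted
hairpin precursor (mature arm + unpairable-biased loop + mutated reverse
complement of the arm) at a known position and strand; negative ESTs
that are either iid-random or dinucleotide-shuffled copies of positives
(shuffling preserves composition and dinucleotide frequencies but
destroys the planted hairpin); and transcripts embedding
reverse-complement target sites with controlled edits.

Planted hairpins are verified at generation time: the precursor is
folded and must show a dominant stem with the mature on the 5' arm and
exactly the requested number of duplex mismatches, otherwise the draw is
retried.  Planted mutations inside the mature region of an EST are
confined to positions after the first 8 nt so an exact seed word always
survives and the homology stage can find the locus.

All randomness flows from a single ``numpy`` generator per seed, drawn
in documented order (matures, then positives in order, then negatives),
so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .folding import FoldingBackend, ViennaBackend, fold
from .hairpin import count_duplex_mismatches, find_hairpin_loop, locate_arm, NoStemError
from .seqio import SequenceRecord, back_transcribe, reverse_complement

_RNA_BASES = np.array(list("ACGU"))
_DNA_BASES = np.array(list("ACGT"))

# star bases that neither Watson-Crick nor wobble pair with the mature base
_NONPAIRING = {"A": "ACG", "U": "CU", "G": "AG", "C": "ACU"}

# first SEED_SAFE_NT nt of a planted mature are never mutated, so a
# word-size-7 seed always survives
SEED_SAFE_NT = 8


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    EST lengths span the typical single-pass cDNA read range (300-900
    nt); matures are 21 nt, the modal plant mature length; the loop is
    8 nt; base composition targets 45% G+C, a mid-range plant EST
    value.  ``planted_mismatches`` is the per-EST range (inclusive) of
    substitutions planted inside the mature copy.
    """

    seed: int = 0
    n_mirnas: int = 5
    mature_len: int = 21
    n_positive_ests: int = 10
    n_negative_ests: int = 10
    est_len_range: tuple[int, int] = (300, 900)
    planted_mismatches: tuple[int, int] = (0, 3)
    loop_len: int = 8
    star_mutations: int = 0
    gc_target_pct: float = 45.0

    def __post_init__(self) -> None:
        if min(
            self.n_mirnas, self.n_positive_ests, self.n_negative_ests,
            self.mature_len, self.loop_len,
        ) < 0:
            raise ValueError("counts and lengths must be >= 0")
        if self.est_len_range[0] < 2 * self.mature_len + self.loop_len:
            raise ValueError("ESTs must be long enough to hold a precursor")


def random_rna(length: int, rng: np.random.Generator, gc_pct: float = 45.0) -> str:
    g = gc_pct / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G U
    return "".join(rng.choice(_RNA_BASES, size=length, p=p))


def random_dna(length: int, rng: np.random.Generator, gc_pct: float = 45.0) -> str:
    g = gc_pct / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    return "".join(rng.choice(_DNA_BASES, size=length, p=p))


def _mutate_star(star: str, k: int, rng: np.random.Generator, mature: str) -> str:
    """Plant k non-pairing substitutions at interior star positions.

    Star position p pairs mature position (len-1-p); the substitute base
    is chosen to pair with that mature base neither canonically nor by
    wobble.  No 3 consecutive positions are mutated (a longer gap would
    read as a break rather than mismatches) and the 2 positions at each
    end are left intact so the duplex ends stay anchored.
    """
    n = len(star)
    interior = list(range(2, n - 2))
    if k > len(interior):
        raise ValueError("too many star mutations for this mature length")
    while True:
        pos = sorted(rng.choice(interior, size=k, replace=False))
        if all(
            not (pos[i + 2] - pos[i] == 2) for i in range(len(pos) - 2)
        ):
            break
    out = list(star)
    for p in pos:
        partner_base = mature[n - 1 - p]
        choices = _NONPAIRING[partner_base]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_precursor(
    mature: str,
    loop_len: int = 8,
    star_mutations: int = 0,
    rng: np.random.Generator | None = None,
    backend: FoldingBackend | None = None,
    max_attempts: int = 50,
) -> tuple[str, int]:
    """Build a hairpin precursor around a mature sequence.

    Layout: GC clamp + mature (5p arm) + loop + mutated reverse
    complement of the mature (3p arm) + complementary clamp.  The 3-bp
    clamp anchors the helix end so the mature duplex is interior (a
    weak terminal A-U pair would otherwise be left open by the folding
    model and read as a spurious mismatch); the loop is biased to A/C
    so it rarely pairs with the stem.  The product is folded and
    accepted only if the dominant stem carries the mature on its 5' arm
    with exactly ``star_mutations`` duplex mismatches; otherwise the
    loop and mutation positions are redrawn, up to ``max_attempts``
    times.

    Returns (precursor RNA sequence, mature offset).
    """
    if len(mature) < 18:
        raise ValueError("mature must be >= 18 nt")
    rng = rng if rng is not None else np.random.default_rng(0)
    backend = backend if backend is not None else ViennaBackend()
    mature = mature.upper().replace("T", "U")
    star0 = reverse_complement(mature, "rna")
    clamp5, clamp3 = "GGC", "GCC"
    offset = len(clamp5)
    last_err: str = ""
    for _ in range(max_attempts):
        loop = "".join(
            "AC"[rng.integers(2)] if rng.random() < 0.85 else "U"
            for _ in range(loop_len)
        )
        star = _mutate_star(star0, star_mutations, rng, mature)
        precursor = clamp5 + mature + loop + star + clamp3
        result = fold(precursor, backend)
        try:
            hp = find_hairpin_loop(result)
        except NoStemError:
            last_err = "no stem"
            continue
        if locate_arm(result, hp, offset, len(mature)) != "5p":
            last_err = "mature not on 5p arm"
            continue
        mm = count_duplex_mismatches(result, offset, len(mature))
        if mm != star_mutations:
            last_err = f"duplex mismatches {mm} != requested {star_mutations}"
            continue
        return precursor, offset
    raise RuntimeError(
        f"could not generate a verified precursor in {max_attempts} attempts "
        f"(last failure: {last_err})"
    )


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Eulerian-path method).

    The sequence is a walk on the graph whose edges are its adjacent
    base pairs; a uniform-ish shuffle is another Eulerian walk with the
    same start and end vertex.  For each non-terminal vertex one
    outgoing edge is reserved as the last departure such that the
    reserved edges form a tree into the terminal vertex (rejection
    sampled), the remaining edge lists are permuted, and the walk is
    replayed.
    """
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | {sequence[-1]})
    last = sequence[-1]
    if len(vertices) == 1:
        return sequence
    # reserve a last-edge per non-terminal vertex forming a tree into `last`
    for _ in range(1000):
        reserved = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in vertices
            if v != last and edges.get(v)
        }
        ok = True
        for v in reserved:
            seen = {v}
            cur = v
            while cur != last:
                cur = reserved.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection sampling virtually always succeeds
        return sequence
    shuffled: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in reserved:
            rest.remove(reserved[v])
        perm = [rest[i] for i in rng.permutation(len(rest))] if rest else []
        if v in reserved:
            perm.append(reserved[v])
        shuffled[v] = perm
    out = [sequence[0]]
    cursors = {v: 0 for v in shuffled}
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = shuffled[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class SimulatedData:
    """Generated benchmark: inputs plus the truth table."""

    mirnas: list[SequenceRecord]
    ests: list[SequenceRecord]
    truth: pd.DataFrame = field(repr=False)


def make_est_set(cfg: SimConfig, backend: FoldingBackend | None = None) -> SimulatedData:
    """Generate the miRNA reference set and an EST collection.

    Each positive EST embeds one verified precursor at a random offset;
    every other positive is reverse-complemented so half the planted
    loci sit on the minus strand.  Negatives alternate between
    iid-random sequences and dinucleotide-shuffled copies of positives.
    The truth table records, per positive EST: mirna_id, forward-strand
    mature coordinates (0-based half-open), strand, the number of
    planted mature mismatches and star mutations.
    """
    rng = np.random.default_rng(cfg.seed)
    backend = backend if backend is not None else ViennaBackend()
    mirnas = [
        SequenceRecord(
            id=f"mir-{i + 1:03d}",
            sequence=random_rna(cfg.mature_len, rng, cfg.gc_target_pct),
        )
        for i in range(cfg.n_mirnas)
    ]
    ests: list[SequenceRecord] = []
    rows: list[dict] = []
    positives_dna: list[str] = []
    lo, hi = cfg.planted_mismatches
    for i in range(cfg.n_positive_ests):
        mir = mirnas[i % cfg.n_mirnas]
        precursor, pre_off = make_precursor(
            mir.sequence, cfg.loop_len, cfg.star_mutations, rng, backend
        )
        pre_dna = back_transcribe(precursor)
        est_len = int(rng.integers(cfg.est_len_range[0], cfg.est_len_range[1] + 1))
        offset = int(rng.integers(0, est_len - len(pre_dna) + 1))
        background = random_dna(est_len, rng, cfg.gc_target_pct)
        est_seq = background[:offset] + pre_dna + background[offset + len(pre_dna):]
        # plant mismatches inside the mature copy, sparing the seed prefix
        k = int(rng.integers(lo, hi + 1))
        mature_start = offset + pre_off  # mature is the 5' arm of the precursor
        est_list = list(est_seq)
        mut_positions = (
            sorted(
                rng.choice(
                    np.arange(SEED_SAFE_NT, cfg.mature_len), size=k, replace=False
                )
            )
            if k
            else []
        )
        for p in mut_positions:
            old = est_list[mature_start + p]
            alts = [b for b in "ACGT" if b != old]
            est_list[mature_start + p] = alts[rng.integers(3)]
        est_seq = "".join(est_list)
        strand = "+" if i % 2 == 0 else "-"
        if strand == "-":
            est_seq = reverse_complement(est_seq, "dna")
            m_start = est_len - (mature_start + cfg.mature_len)
        else:
            m_start = mature_start
        est_id = f"est-pos-{i + 1:04d}"
        ests.append(SequenceRecord(id=est_id, sequence=est_seq))
        positives_dna.append(est_seq)
        rows.append(
            {
                "est_id": est_id,
                "mirna_id": mir.id,
                "mature_start": m_start,
                "mature_end": m_start + cfg.mature_len,
                "strand": strand,
                "planted_mismatches": k,
                "star_mutations": cfg.star_mutations,
            }
        )
    for i in range(cfg.n_negative_ests):
        if positives_dna and i % 2 == 1:
            src = positives_dna[i % len(positives_dna)]
            seq = dinucleotide_shuffle(src, rng)
            kind = "shuffled"
        else:
            length = int(rng.integers(cfg.est_len_range[0], cfg.est_len_range[1] + 1))
            seq = random_dna(length, rng, cfg.gc_target_pct)
            kind = "random"
        ests.append(SequenceRecord(id=f"est-neg-{kind}-{i + 1:04d}", sequence=seq))
    truth = pd.DataFrame(
        rows,
        columns=[
            "est_id", "mirna_id", "mature_start", "mature_end", "strand",
            "planted_mismatches", "star_mutations",
        ],
    )
    return SimulatedData(mirnas=mirnas, ests=ests, truth=truth)


_GU_PARTNER = {"G": "U", "U": "G"}  # site base giving a wobble pair


def _edit_site(
    site: str, mirna: str, edits: list[tuple[str, int]], rng: np.random.Generator
) -> str:
    """Apply controlled edits to a perfect site.

    ``edits`` are (kind, miRNA position 1-based): kind 'mismatch'
    substitutes a non-pairing base opposite that miRNA position, 'gu'
    substitutes the wobble partner (miRNA base must be G or U), 'gap'
    deletes the opposite site base.
    """
    n = len(mirna)
    out = list(site)
    deletions: list[int] = []
    for kind, pos in edits:
        if not 1 <= pos <= n:
            raise ValueError(f"miRNA position {pos} out of range")
        idx = n - pos  # site index opposite miRNA position `pos`
        m_base = mirna[pos - 1]
        if kind == "mismatch":
            choices = _NONPAIRING[m_base]
            out[idx] = choices[rng.integers(len(choices))]
        elif kind == "gu":
            if m_base not in _GU_PARTNER:
                raise ValueError(
                    f"no wobble pair opposite miRNA base {m_base!r} at {pos}"
                )
            out[idx] = _GU_PARTNER[m_base]
        elif kind == "gap":
            deletions.append(idx)
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    for idx in sorted(deletions, reverse=True):
        del out[idx]
    return "".join(out)


def make_target_transcripts(
    mirnas: list[SequenceRecord],
    n_sites_per_mirna: int = 1,
    site_edits: list[tuple[str, int]] | None = None,
    rng: np.random.Generator | None = None,
    transcript_len: int = 400,
    gc_pct: float = 45.0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Transcripts embedding reverse-complement target sites.

    Each transcript carries one site (the reverse complement of the
    miRNA with ``site_edits`` applied) at a random position; the truth
    table records transcript_id, mirna_id and site coordinates.
    Transcripts are DNA records, as EST-derived collections are.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    edits = site_edits or []
    transcripts: list[SequenceRecord] = []
    rows: list[dict] = []
    counter = 0
    for mir in mirnas:
        for _ in range(n_sites_per_mirna):
            counter += 1
            site = reverse_complement(mir.sequence, "rna")
            site = _edit_site(site, mir.sequence, edits, rng)
            site_dna = back_transcribe(site)
            pad = transcript_len - len(site_dna)
            offset = int(rng.integers(0, pad + 1))
            background = random_dna(transcript_len, rng, gc_pct)
            seq = (
                background[:offset]
                + site_dna
                + background[offset + len(site_dna):]
            )
            tx_id = f"tx-{counter:04d}"
            transcripts.append(SequenceRecord(id=tx_id, sequence=seq))
            rows.append(
                {
                    "transcript_id": tx_id,
                    "mirna_id": mir.id,
                    "site_start": offset,
                    "site_end": offset + len(site_dna),
                    "n_edits": len(edits),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=["transcript_id", "mirna_id", "site_start", "site_end", "n_edits"],
    )
    return transcripts, truth
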