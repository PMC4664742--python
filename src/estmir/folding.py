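"""Secondary-structure prediction and thermodynamic statistics.

Folding goes through a pluggable backend with a one-method contract:
sequence in, minimum-free-energy dot-bracket structure plus MFE
(kcal/mol, 37 degC) out.  The reference backend wraps the ViennaRNA
programs library; a precomputed-folds file (Vienna triplet text: id
line, sequence line, structure line ending with the energy in
parentheses) can stand in wherever a backend is expected, so folds
computed elsewhere can be replayed without any folding library.

The filter statistics are:

* G+C% — 100*(G+C)/L, with N counted in the denominator only;
* AU%  — 100*(A+U)/L;
* AMFE — MFE normalized per 100 nt: (MFE/L)*100, sign preserved;
* MFEI — |AMFE| / G+C%, reported as a positive magnitude.

The MFEI of genuine plant pre-miRNAs concentrates around 0.65-0.85,
well above tRNA/rRNA/mRNA values, which makes it the workhorse filter
for separating miRNA hairpins from other folded RNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

_VALID_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),  # wobble
}


class FoldingError(RuntimeError):
    """Raised when no structure can be produced for a sequence."""


class FoldingBackend(Protocol):
    """Contract for structure-prediction engines."""

    def fold(self, sequence: str) -> tuple[str, float]:
        """Return (dot-bracket structure, MFE in kcal/mol) for an RNA sequence."""
        ...


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its predicted MFE structure."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError(
                f"structure length {len(self.structure)} != sequence length "
                f"{len(self.sequence)}"
            )
        pt = pair_table(self.structure)  # raises on unbalanced brackets
        for i, j in enumerate(pt):
            if j is not None and i < j:
                pair = (self.sequence[i], self.sequence[j])
                if pair not in _VALID_PAIRS:
                    raise ValueError(
                        f"invalid base pair {pair[0]}-{pair[1]} at ({i},{j})"
                    )

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


def pair_table(structure: str) -> list[int | None]:
    """Map each position of a dot-bracket string to its partner (or None).

    The mapping is symmetric; unbalanced structures raise ``ValueError``.
    """
    pt: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


class ViennaBackend:
    """MFE folding via the ViennaRNA programs library (default 37 degC)."""

    def __init__(self, temperature: float = 37.0) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - import guard
            raise FoldingError(
                "the ViennaRNA python bindings are not importable; fold the "
                "candidates elsewhere and supply a precomputed-folds file"
            ) from exc
        self._RNA = RNA
        self.temperature = temperature

    def fold(self, sequence: str) -> tuple[str, float]:
        md = self._RNA.md()
        md.temperature = self.temperature
        fc = self._RNA.fold_compound(sequence, md)
        structure, mfe = fc.mfe()
        # energies are defined in 0.01 kcal/mol units; rounding removes
        # float32 noise so written folds replay byte-identically
        return structure, round(float(mfe), 2)


class PrecomputedFolds:
    """Folding backend replaying structures from a Vienna triplet file.

    File format, repeated per record::

        >some_id
        GGGGAAAACCCC
        ((((....)))) (-5.30)

    Lookup is by exact sequence; a sequence absent from the file raises
    :class:`FoldingError`.
    """

    def __init__(self, path: str | Path) -> None:
        self._by_sequence: dict[str, FoldResult] = {}
        self.ids: dict[str, str] = {}  # id -> sequence
        lines = [
            ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()
        ]
        if len(lines) % 3:
            raise ValueError(f"{path}: expected id/sequence/structure triplets")
        for k in range(0, len(lines), 3):
            header, seq, struct_line = lines[k], lines[k + 1], lines[k + 2]
            if not header.startswith(">"):
                raise ValueError(f"{path}: expected '>' header, got {header!r}")
            rec_id = header[1:].split()[0]
            seq = seq.strip().upper().replace("T", "U")
            try:
                structure, _, energy = struct_line.strip().rpartition(" ")
                mfe = float(energy.strip("()"))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: bad structure line for {rec_id!r}: {struct_line!r}"
                ) from exc
            result = FoldResult(sequence=seq, structure=structure.strip(), mfe=mfe)
            self._by_sequence[seq] = result
            self.ids[rec_id] = seq

    def fold(self, sequence: str) -> tuple[str, float]:
        sequence = sequence.upper().replace("T", "U")
        try:
            res = self._by_sequence[sequence]
        except KeyError:
            raise FoldingError(
                "sequence not present in the precomputed-folds file; refold "
                "with a live backend or extend the file"
            ) from None
        return res.structure, res.mfe


def write_folds(folds: dict[str, FoldResult], path: str | Path) -> None:
    """Write id -> FoldResult as a Vienna triplet file readable by PrecomputedFolds."""
    with open(path, "w") as fh:
        for rec_id, res in folds.items():
            fh.write(f">{rec_id}\n{res.sequence}\n{res.structure} ({res.mfe:.2f})\n")


def fold(sequence: str, backend: FoldingBackend) -> FoldResult:
    """Fold one RNA sequence with the given backend and validate the result."""
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    if len(sequence) > 10_000:
        raise ValueError("sequence longer than 10 kb; not a plausible precursor")
    if set(sequence) - set("ACGUN"):
        raise ValueError(
            f"invalid RNA characters {sorted(set(sequence) - set('ACGUN'))!r}"
        )
    structure, mfe = backend.fold(sequence)
    return FoldResult(sequence=sequence, structure=structure, mfe=mfe)


@dataclass(frozen=True)
class FoldStats:
    """Composition and energy statistics of a folded precursor."""

    gc_pct: float
    au_pct: float
    amfe: float
    mfei: float


def gc_content(sequence: str) -> float:
    """G+C percentage; N counts toward length but not toward G+C."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def au_content(sequence: str) -> float:
    """A+U percentage (T counted as U); N counts toward length only."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return 100.0 * (seq.count("A") + seq.count("U") + seq.count("T")) / len(seq)


def compute_amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: (MFE / length) * 100 kcal/mol per 100 nt, sign preserved."""
    if length <= 0:
        raise ValueError("length must be positive")
    return mfe / length * 100.0


def compute_mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimal folding free energy index: |AMFE| / G+C%, a positive magnitude."""
    if gc_pct == 0:
        raise ValueError("MFEI undefined for G+C == 0")
    return abs(compute_amfe(mfe, length)) / gc_pct


def compute_stats(sequence: str, mfe: float) -> FoldStats:
    """All filter statistics for one folded precursor."""
    gc = gc_content(sequence)
    return FoldStats(
        gc_pct=gc,
        au_pct=au_content(sequence),
        amfe=compute_amfe(mfe, len(sequence)),
        mfei=compute_mfei(mfe, len(sequence), gc) if gc > 0 else float("nan"),
    )
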