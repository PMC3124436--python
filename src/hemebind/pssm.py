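"""PSI-BLAST position-specific scoring matrices: parsing, scaling, conservation.

The profile is consumed as an input artifact in the ASCII dialect written
by ``psiblast -out_ascii_pssm`` (three iterations against a large sequence
database is the conventional way to produce one).  Raw substitution scores
are squashed to (0,1) by the logistic function before entering any feature
vector; the diagonal element (the score of the query's own residue type)
is used directly as a per-position conservation score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AA_ORDER",
    "PssmMatrix",
    "ScaledProfile",
    "PssmFormatError",
    "parse_pssm",
    "write_pssm",
    "scale_pssm",
    "conservation_score",
]

# PSI-BLAST column order of the 20 substitution-score columns.
AA_ORDER = "ARNDCQEGHILKMFPSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class PssmFormatError(ValueError):
    """Raised when the ASCII PSSM block cannot be parsed."""


@dataclass
class PssmMatrix:
    """Raw PSI-BLAST substitution scores for one query chain."""

    sequence: str
    scores: np.ndarray  # (length, 20) integers

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise PssmFormatError("score matrix must have 20 columns")
        if self.scores.shape[0] != len(self.sequence):
            raise PssmFormatError(
                f"{self.scores.shape[0]} score rows for {len(self.sequence)} residues"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ScaledProfile:
    """Logistic-scaled profile, every value strictly in (0,1)."""

    values: np.ndarray  # (length, 20) floats


def parse_pssm(text: str) -> PssmMatrix:
    """Parse the 20-column substitution-score block of an ASCII PSSM.

    Rows look like ``"   12 C    -1  -3 ... 9"``: a 1-based position, the
    query residue, then at least 20 integer scores (the weighted-percentage
    and information columns, when present, are ignored).
    """
    seq_chars: list[str] = []
    rows: list[list[int]] = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit() or len(parts[1]) != 1:
            if parts and parts[0].isdigit() and len(parts) > 2 and len(parts[1]) == 1:
                # looks like a data row but is short: corrupt input
                raise PssmFormatError(f"truncated PSSM row: {line!r}")
            continue
        try:
            scores = [int(v) for v in parts[2:22]]
        except ValueError as exc:
            raise PssmFormatError(f"non-integer score in row: {line!r}") from exc
        seq_chars.append(parts[1].upper())
        rows.append(scores)
    if not rows:
        raise PssmFormatError("no PSSM score rows found")
    return PssmMatrix(sequence="".join(seq_chars), scores=np.array(rows, dtype=int))


def write_pssm(pssm: PssmMatrix) -> str:
    """Serialize to the PSI-BLAST ASCII dialect (score block only)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pct = " ".join("  0" for _ in range(20))
        lines.append(f"{i:5d} {aa} {scores}  {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", ""]
    return "\n".join(lines) + "\n"


def scale_pssm(pssm: PssmMatrix) -> ScaledProfile:
    """Elementwise logistic scaling 1/(1+e^-x) of the raw scores."""
    return ScaledProfile(values=1.0 / (1.0 + np.exp(-pssm.scores.astype(float))))


def conservation_score(pssm: PssmMatrix, position: int) -> int:
    """Diagonal PSSM element: the score of the query residue's own type.

    High values mean the native residue is strongly preferred across the
    homolog alignment, i.e. the position is evolutionarily conserved.
    """
    if not 0 <= position < pssm.length:
        raise IndexError(f"position {position} out of range 0..{pssm.length - 1}")
    aa = pssm.sequence[position]
    if aa not in AA_INDEX:
        raise ValueError(f"no conservation score for non-standard residue {aa!r}")
    return int(pssm.scores[position, AA_INDEX[aa]])
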