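"""Assembly of per-residue SVM input vectors.

Two encodings are provided.  The structure path uses a *spatial window*:
the target residue plus its M-1 nearest neighbors by Cα-Cα distance, each
contributing a 33-value block (20 scaled profile columns, RASA, 6 scaled
depth statistics, 6 scaled protrusion statistics), optionally restricted
by a feature mask.  The sequence path uses a *sliding window* of N
consecutive sequence positions centered on the target, encoded either as
scaled profile rows or as a 21-bit one-hot amino-acid pattern.  Window
positions beyond the termini, and spatial-window slots a short chain
cannot fill, are zero-padded: every retained feature lives in [0,1] after
scaling, so zero is the neutral value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hemebind.structure import ChainModel
from hemebind.geometry import GeometryBlock
from hemebind.pssm import ScaledProfile, AA_ORDER

__all__ = [
    "DEFAULT_SPATIAL_WINDOW",
    "DEFAULT_SLIDING_WINDOW",
    "FeatureMask",
    "SpatialWindow",
    "FeatureVector",
    "EncodingError",
    "build_spatial_window",
    "encode_structure",
    "encode_sequence_pssm",
    "encode_sequence_binary",
    "to_libsvm",
]

DEFAULT_SPATIAL_WINDOW = 15   # M, residues per spatial window
DEFAULT_SLIDING_WINDOW = 17   # N, residues per sliding window


class EncodingError(ValueError):
    """Raised when a residue cannot be encoded."""


@dataclass(frozen=True)
class FeatureMask:
    """Which of the four descriptor groups enter the structure encoding.

    The 15 non-empty combinations reproduce the single/double/triple/
    quadruple feature classifiers of the structure path.
    """

    pssm: bool = True
    rasa: bool = True
    dpx: bool = True
    cx: bool = True

    def __post_init__(self) -> None:
        if not (self.pssm or self.rasa or self.dpx or self.cx):
            raise EncodingError("feature mask selects nothing")

    @property
    def block_length(self) -> int:
        return 20 * self.pssm + 1 * self.rasa + 6 * self.dpx + 6 * self.cx

    @property
    def tag(self) -> str:
        parts = [n for n, on in
                 (("PSSM", self.pssm), ("RASA", self.rasa), ("DPX", self.dpx), ("CX", self.cx))
                 if on]
        return "+".join(parts)


@dataclass
class SpatialWindow:
    """Target residue plus nearest Cα neighbors, target first."""

    target: int
    members: list[int]


@dataclass
class FeatureVector:
    values: np.ndarray
    layout_id: str


def build_spatial_window(
    chain: ChainModel, target: int, m: int = DEFAULT_SPATIAL_WINDOW
) -> SpatialWindow:
    """Target plus its m-1 nearest residues by Cα-Cα distance.

    Neighbors are ranked by increasing distance, ties broken by smaller
    sequence index; residues without Cα are ineligible.  A chain with
    fewer than m eligible residues yields a window of all of them.
    """
    if m < 1:
        raise EncodingError("window size must be >= 1")
    ca = chain.ca_coords()
    if np.isnan(ca[target, 0]):
        raise EncodingError(f"target residue {target} has no CA atom")
    eligible = np.flatnonzero(~np.isnan(ca[:, 0]))
    dists = np.linalg.norm(ca[eligible] - ca[target], axis=1)
    order = sorted(
        (d, int(i)) for d, i in zip(dists, eligible) if i != target
    )
    members = [target] + [i for _, i in order[: m - 1]]
    return SpatialWindow(target=target, members=members)


def encode_structure(
    window: SpatialWindow,
    profile: ScaledProfile | None,
    geometry: list[GeometryBlock],
    m: int = DEFAULT_SPATIAL_WINDOW,
    mask: FeatureMask = FeatureMask(),
) -> FeatureVector:
    """Concatenate the masked 33-value blocks of the window members.

    Member order is the window order (target first); missing tail slots of
    short chains are zero-padded.  Full-feature length is 33*m.
    """
    if mask.pssm and profile is None:
        raise EncodingError("feature mask includes PSSM but no profile was given")
    blocks = []
    for i in window.members:
        if i >= len(geometry) or geometry[i] is None:
            raise EncodingError(f"no geometry for window member {i}")
        parts = []
        if mask.pssm:
            parts.append(profile.values[i])
        if mask.rasa:
            parts.append([geometry[i].rasa])
        if mask.dpx:
            parts.append(geometry[i].dpx6)
        if mask.cx:
            parts.append(geometry[i].cx6)
        blocks.append(np.concatenate(parts))
    vec = np.concatenate(blocks)
    full = np.zeros(mask.block_length * m)
    full[: len(vec)] = vec
    return FeatureVector(values=full, layout_id=f"structure-{mask.tag}-{mask.block_length}x{m}")


def _check_odd(n: int) -> None:
    if n < 1 or n % 2 == 0:
        raise EncodingError(f"sliding window size must be odd and positive, got {n}")


def encode_sequence_pssm(
    profile: ScaledProfile, target: int, n: int = DEFAULT_SLIDING_WINDOW
) -> FeatureVector:
    """Scaled profile rows of the n consecutive positions centered on the
    target; positions beyond the termini contribute 20 zeros."""
    _check_odd(n)
    length = profile.values.shape[0]
    half = (n - 1) // 2
    out = np.zeros(20 * n)
    for w, pos in enumerate(range(target - half, target + half + 1)):
        if 0 <= pos < length:
            out[20 * w : 20 * (w + 1)] = profile.values[pos]
    return FeatureVector(values=out, layout_id=f"seqPSSM-20x{n}")


def encode_sequence_binary(
    sequence: str, target: int, n: int = DEFAULT_SLIDING_WINDOW
) -> FeatureVector:
    """One-hot amino-acid pattern over the sliding window.

    Each window position is a 21-bit block: 20 amino-acid bits plus one
    bit for terminus overhang or unknown residue type.
    """
    _check_odd(n)
    half = (n - 1) // 2
    out = np.zeros(21 * n)
    for w, pos in enumerate(range(target - half, target + half + 1)):
        if 0 <= pos < len(sequence) and sequence[pos] in AA_ORDER:
            out[21 * w + AA_ORDER.index(sequence[pos])] = 1.0
        else:
            out[21 * w + 20] = 1.0
    return FeatureVector(values=out, layout_id=f"seqBinary-21x{n}")


def to_libsvm(label: int, vector: FeatureVector) -> str:
    """One LIBSVM sparse-text line: ``label index:value ...`` (1-based)."""
    pairs = [
        f"{i + 1}:{v:.6g}" for i, v in enumerate(vector.values) if v != 0.0
    ]
    return " ".join([str(int(label))] + pairs)
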