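"""Spatial false-positive filter and structure/sequence vote.

Binding residues cluster in space around the heme pocket, so an isolated
positive call is most likely wrong.  The filter makes a single pass over
the raw structure-path calls and demotes every positive whose W nearest
Cα neighbors contain fewer than T raw positives (defaults W=18, T=5).
Neighbor counts always refer to the raw track — the pass is applied
exactly once, never iterated, because repeated application would erode
cluster edges.  The ensemble is a hard AND vote between the filtered
structure call and the sequence call; no filter is applied to the
sequence path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hemebind.classify import NOT_SCORED, PredictionTrack
from hemebind.encoding import build_spatial_window
from hemebind.structure import ChainModel

__all__ = ["FilterParams", "filter_false_positives", "vote_combine"]


class CombinationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """W nearest spatial neighbors; at least T must be positive."""

    w: int = 18
    t: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.t <= self.w:
            raise ValueError(f"need 1 <= T <= W, got T={self.t}, W={self.w}")


def filter_false_positives(
    track: PredictionTrack, chain: ChainModel, params: FilterParams = FilterParams()
) -> PredictionTrack:
    """Demote spatially isolated positives to negatives (single pass).

    Positives whose W nearest Cα neighbors (target excluded) contain
    fewer than T positives *in the raw track* become negatives; negatives
    and unscored residues are never changed.  Chains smaller than W+1
    eligible residues clamp W with a warning.
    """
    if len(track.calls) != len(chain.residues):
        raise CombinationError("track does not cover the chain")
    n_eligible = int(np.sum(track.scored))
    w = params.w
    if n_eligible <= w:
        w = max(1, n_eligible - 1)
        warnings.warn(f"chain has only {n_eligible} scored residues; clamping W to {w}")
    raw = track.calls
    out = raw.copy()
    for i in np.flatnonzero(raw == 1):
        # spatial window of w+1 residues = target + its w nearest neighbors
        window = build_spatial_window(chain, int(i), w + 1)
        neighbors = [j for j in window.members if j != i and raw[j] != NOT_SCORED]
        n_pos = int(np.sum(raw[neighbors] == 1))
        if n_pos < params.t:
            out[i] = 0
    return PredictionTrack(calls=out, source="STR_filtered")


def vote_combine(str_track: PredictionTrack, seq_track: PredictionTrack) -> PredictionTrack:
    """Logical AND of the two paths' calls, per residue.

    A residue is positive only when both the (filtered) structure call
    and the sequence call are positive; unscored residues stay unscored.
    """
    if len(str_track.calls) != len(seq_track.calls):
        raise CombinationError("tracks cover different residue sets")
    if not np.array_equal(str_track.scored, seq_track.scored):
        raise CombinationError("tracks score different residue subsets")
    out = np.full(len(str_track.calls), NOT_SCORED, dtype=int)
    both = str_track.scored
    out[both] = ((str_track.calls[both] == 1) & (seq_track.calls[both] == 1)).astype(int)
    return PredictionTrack(calls=out, source="ensemble")
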