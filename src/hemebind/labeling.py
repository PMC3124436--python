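"""Heme-contact labeling of residues and descriptive interface statistics.

A residue is a binding residue when any of its heavy atoms lies within a
distance cutoff (default 4.5 Angstrom, the common heavy-atom contact proxy
in the binding-site literature) of any heavy atom of any heme in the
complex.  The module also provides the descriptive statistics used to
characterize heme interfaces: per-type interface propensity, spatial
clustering of binding residues among Cα neighbors, and a two-sample
Kolmogorov-Smirnov comparison of attribute distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from hemebind.structure import ChainModel, HemeGroup, THREE_TO_ONE

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "LabeledChain",
    "PropensityTable",
    "label_binding_residues",
    "interface_propensity",
    "neighbor_binding_count",
    "attribute_distribution_test",
    "export_labels_tsv",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Angstrom, heavy-atom contact distance
DEFAULT_NEIGHBOR_COUNT = 18

# Attribute bracket edges used for distribution summaries: RASA deciles,
# depth in 0.25 A bins, protrusion in 0.5 A bins, conservation integer bins.
RASA_BRACKETS = np.linspace(0.0, 1.0, 11)
DPX_BRACKETS = np.arange(0.0, 5.25, 0.25)
CX_BRACKETS = np.arange(0.0, 10.5, 0.5)
CONSERVATION_BRACKETS = np.arange(-5, 13)


@dataclass
class LabeledChain:
    """A chain with its per-residue binding labels (1 = heme-binding)."""

    chain: ChainModel
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.chain.residues):
            raise ValueError("one label per residue required")

    @property
    def n_binding(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonbinding(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class PropensityTable:
    """Interface propensity per residue type.

    ``ratio`` is log2(frequency in interface / frequency in the rest);
    NaN flags types absent from one of the two populations.
    """

    interface_freq: dict[str, float]
    background_freq: dict[str, float]
    log2_ratio: dict[str, float]


def label_binding_residues(
    chain: ChainModel,
    hemes: list[HemeGroup],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> LabeledChain:
    """Label residues by heavy-atom distance to any heme atom.

    With several hemes the binding set is the union over all of them.  An
    empty heme list yields all-zero labels with a warning.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    labels = np.zeros(len(chain.residues), dtype=int)
    if not hemes:
        warnings.warn("no heme groups supplied; all residues labeled non-binding")
        return LabeledChain(chain=chain, labels=labels)
    heme_tree = cKDTree(np.vstack([h.coords() for h in hemes]))
    for i, res in enumerate(chain.residues):
        d, _ = heme_tree.query(res.coords())
        if np.min(d) <= cutoff:
            labels[i] = 1
    return LabeledChain(chain=chain, labels=labels)


def interface_propensity(dataset: list[LabeledChain]) -> PropensityTable:
    """Per-type log2 ratio of interface frequency to rest-of-protein frequency."""
    interface: dict[str, int] = {aa: 0 for aa in THREE_TO_ONE.values()}
    rest: dict[str, int] = {aa: 0 for aa in THREE_TO_ONE.values()}
    for lc in dataset:
        for res, lab in zip(lc.chain.residues, lc.labels):
            aa = res.one_letter
            if aa == "X":
                continue
            (interface if lab == 1 else rest)[aa] += 1
    n_int, n_rest = sum(interface.values()), sum(rest.values())
    if n_int == 0 or n_rest == 0:
        raise ValueError("dataset must contain both binding and non-binding residues")
    f_int = {aa: c / n_int for aa, c in interface.items()}
    f_rest = {aa: c / n_rest for aa, c in rest.items()}
    ratio = {
        aa: (np.log2(f_int[aa] / f_rest[aa]) if f_int[aa] > 0 and f_rest[aa] > 0 else np.nan)
        for aa in f_int
    }
    return PropensityTable(interface_freq=f_int, background_freq=f_rest, log2_ratio=ratio)


def neighbor_binding_count(
    chain: ChainModel,
    labels: np.ndarray,
    k: int = DEFAULT_NEIGHBOR_COUNT,
) -> np.ndarray:
    """Binding residues among each residue's k nearest Cα neighbors.

    The residue itself is excluded from its own neighborhood.  Residues
    without a Cα atom get -1 (not scored) and never appear as neighbors.
    """
    labels = np.asarray(labels, dtype=int)
    ca = chain.ca_coords()
    valid = ~np.isnan(ca[:, 0])
    idx = np.flatnonzero(valid)
    if len(idx) <= k:
        raise ValueError(f"need more than k={k} residues with CA")
    coords = ca[idx]
    out = np.full(len(chain.residues), -1, dtype=int)
    # pairwise distances with sequence-index tie-break, matching the
    # spatial-window neighbor ordering used elsewhere
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    for a, i in enumerate(idx):
        order = sorted((d[a, b], idx[b]) for b in range(len(idx)) if b != a)
        neighbors = [j for _, j in order[:k]]
        out[i] = int(labels[neighbors].sum())
    return out


def attribute_distribution_test(binding_values, nonbinding_values):
    """Two-sample Kolmogorov-Smirnov test between binding and non-binding
    attribute values; returns (statistic, p-value)."""
    binding_values = np.asarray(binding_values, dtype=float)
    nonbinding_values = np.asarray(nonbinding_values, dtype=float)
    if len(binding_values) == 0 or len(nonbinding_values) == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(binding_values, nonbinding_values)
    return float(res.statistic), float(res.pvalue)


def export_labels_tsv(labeled: LabeledChain) -> str:
    """BED-like TSV: chain, residue position, aa, label."""
    lines = ["chain\tposition\taa\tlabel"]
    for res, lab in zip(labeled.chain.residues, labeled.labels):
        lines.append(f"{res.chain_id}\t{res.seq_position}\t{res.one_letter}\t{int(lab)}")
    return "\n".join(lines) + "\n"
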