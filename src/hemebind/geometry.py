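"""Per-residue structural descriptors: RASA, depth index (DPX), protrusion index (CX).

All three descriptors are computed on the *unbound* chain (heme atoms are
never part of the surface calculation).  Atom depth is the distance to the
nearest solvent-accessible atom and is zero for accessible atoms.  Atom
protrusion is the ratio of empty to protein-occupied volume inside a
fixed-radius sphere around the atom; it is high for protruding atoms and
low inside concavities.  Per-residue summaries of depth and protrusion are
six statistics each (mean/sd over all atoms, mean/sd over side-chain
atoms, min, max), squashed to (0,1) with the logistic function so they can
feed an SVM alongside the scaled sequence profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from hemebind.structure import ChainModel, ResidueUnit, StructureError

__all__ = [
    "SasaResult",
    "GeometryBlock",
    "VDW_RADII",
    "MAX_SASA",
    "compute_sasa",
    "compute_rasa",
    "compute_dpx",
    "compute_cx",
    "scale_geometry",
    "geometry_blocks",
    "export_features_tsv",
]

# Van der Waals radii (Angstrom) for protein heavy atoms.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

# Maximum accessible surface per residue type (Rost & Sander 1994), Angstrom^2.
MAX_SASA = {
    "ALA": 106.0, "ARG": 248.0, "ASN": 157.0, "ASP": 163.0, "CYS": 135.0,
    "GLN": 198.0, "GLU": 194.0, "GLY": 84.0, "HIS": 184.0, "ILE": 169.0,
    "LEU": 164.0, "LYS": 205.0, "MET": 188.0, "PHE": 197.0, "PRO": 136.0,
    "SER": 130.0, "THR": 142.0, "TRP": 227.0, "TYR": 222.0, "VAL": 142.0,
}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_CX_RADIUS = 10.0
DEFAULT_ATOM_VOLUME = 20.1
# Quadrature SASA below this is treated as zero (buried) for depth anchors.
ACCESSIBLE_SASA_MIN = 1e-6

_STAT_NAMES = ("mean_all", "sd_all", "mean_sidechain", "sd_sidechain", "min", "max")


class GeometryError(ValueError):
    """Raised on degenerate geometric input."""


@dataclass
class SasaResult:
    """Solvent accessible surface areas, per atom and summed per residue."""

    per_atom_sasa: np.ndarray          # flat over chain atoms, Angstrom^2
    per_residue_sasa: np.ndarray       # one entry per residue
    atom_residue_index: np.ndarray     # residue index of each atom


@dataclass
class GeometryBlock:
    """The 13 structural descriptor values of one residue, all in [0,1]."""

    rasa: float
    dpx6: np.ndarray  # logistic-scaled (mean, sd, mean_sc, sd_sc, min, max)
    cx6: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([[self.rasa], self.dpx6, self.cx6])


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _chain_atoms(chain: ChainModel):
    coords, radii, res_idx, sidechain = [], [], [], []
    for i, res in enumerate(chain.residues):
        for a in res.atoms:
            coords.append(a.coord)
            radii.append(VDW_RADII.get(a.element.upper(), DEFAULT_VDW))
            res_idx.append(i)
            sidechain.append(a.is_sidechain)
    return (
        np.asarray(coords, dtype=float),
        np.asarray(radii, dtype=float),
        np.asarray(res_idx, dtype=int),
        np.asarray(sidechain, dtype=bool),
    )


def compute_sasa(
    chain: ChainModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley solvent accessible surface area of every heavy atom.

    Each atom is expanded by the probe radius and sampled with ``n_points``
    quasi-uniform sphere points; a point is accessible when it falls outside
    every other expanded atom.  Residue SASA is the sum over its atoms.
    """
    if probe_radius <= 0:
        raise GeometryError("probe radius must be positive")
    coords, radii, res_idx, _ = _chain_atoms(chain)
    if len(coords) == 0:
        raise GeometryError("chain has no atoms")

    ext = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neighbors = tree.query_ball_point(coords[i], ext[i] + ext.max())
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2

    per_res = np.zeros(len(chain.residues))
    np.add.at(per_res, res_idx, per_atom)
    return SasaResult(per_atom_sasa=per_atom, per_residue_sasa=per_res, atom_residue_index=res_idx)


def compute_rasa(chain: ChainModel, sasa: SasaResult) -> np.ndarray:
    """Relative accessible surface area per residue.

    Residue SASA divided by the residue type's maximum accessible surface,
    clamped to [0,1].  UNK residues get NaN (no reference maximum exists).
    """
    out = np.empty(len(chain.residues))
    for i, res in enumerate(chain.residues):
        mx = MAX_SASA.get(res.aa_type)
        if mx is None:
            out[i] = np.nan
            continue
        out[i] = min(1.0, max(0.0, sasa.per_residue_sasa[i] / mx))
    return out


def _atom_depths(coords: np.ndarray, per_atom_sasa: np.ndarray) -> np.ndarray:
    accessible = per_atom_sasa > ACCESSIBLE_SASA_MIN
    if not accessible.any():
        raise GeometryError("no solvent-accessible atom in chain; cannot anchor depths")
    depths = np.zeros(len(coords))
    buried = ~accessible
    if buried.any():
        tree = cKDTree(coords[accessible])
        d, _ = tree.query(coords[buried])
        depths[buried] = d
    return depths


def _residue_stats(values: np.ndarray, sidechain: np.ndarray) -> np.ndarray:
    """(mean, sd, mean_sidechain, sd_sidechain, min, max); side-chain stats
    fall back to all-atom values when the residue has no side-chain atoms
    (glycine)."""
    mean_all = values.mean()
    sd_all = values.std()
    if sidechain.any():
        sc = values[sidechain]
        mean_sc, sd_sc = sc.mean(), sc.std()
    else:
        mean_sc, sd_sc = mean_all, sd_all
    return np.array([mean_all, sd_all, mean_sc, sd_sc, values.min(), values.max()])


def compute_dpx(chain: ChainModel, sasa: SasaResult) -> np.ndarray:
    """Raw depth-index statistics (Angstrom) per residue, shape (n_res, 6).

    Atom depth is 0 for solvent-accessible atoms, else the Euclidean
    distance to the closest accessible atom of the chain.
    """
    coords, _, res_idx, sidechain = _chain_atoms(chain)
    depths = _atom_depths(coords, sasa.per_atom_sasa)
    out = np.empty((len(chain.residues), 6))
    for i in range(len(chain.residues)):
        mask = res_idx == i
        out[i] = _residue_stats(depths[mask], sidechain[mask])
    return out


def compute_cx(
    chain: ChainModel,
    sphere_radius: float = DEFAULT_CX_RADIUS,
    mean_atom_volume: float = DEFAULT_ATOM_VOLUME,
) -> np.ndarray:
    """Raw protrusion-index statistics per residue, shape (n_res, 6).

    For each atom, the heavy atoms within ``sphere_radius`` (the atom
    itself included) occupy an internal volume ``count * mean_atom_volume``;
    CX is the remaining (external) sphere volume over the internal volume,
    floored at zero when the neighborhood is denser than the sphere.
    """
    if sphere_radius <= 0 or mean_atom_volume <= 0:
        raise GeometryError("sphere radius and mean atom volume must be positive")
    coords, _, res_idx, sidechain = _chain_atoms(chain)
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(c, sphere_radius)) for c in coords])
    v_sphere = 4.0 / 3.0 * np.pi * sphere_radius ** 3
    v_int = counts * mean_atom_volume
    cx = np.maximum(v_sphere - v_int, 0.0) / v_int
    out = np.empty((len(chain.residues), 6))
    for i in range(len(chain.residues)):
        mask = res_idx == i
        out[i] = _residue_stats(cx[mask], sidechain[mask])
    return out


def scale_geometry(raw6: np.ndarray) -> np.ndarray:
    """Logistic squashing 1/(1+e^-x), elementwise, to (0,1)."""
    raw6 = np.asarray(raw6, dtype=float)
    if not np.all(np.isfinite(raw6)):
        raise GeometryError("non-finite geometry statistics")
    return 1.0 / (1.0 + np.exp(-raw6))


def geometry_blocks(
    chain: ChainModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    sphere_radius: float = DEFAULT_CX_RADIUS,
    mean_atom_volume: float = DEFAULT_ATOM_VOLUME,
) -> list[GeometryBlock]:
    """Full descriptor block (RASA + scaled DPX + scaled CX) per residue."""
    sasa = compute_sasa(chain, probe_radius=probe_radius, n_points=n_points)
    rasa = compute_rasa(chain, sasa)
    dpx = compute_dpx(chain, sasa)
    cx = compute_cx(chain, sphere_radius=sphere_radius, mean_atom_volume=mean_atom_volume)
    return [
        GeometryBlock(rasa=rasa[i], dpx6=scale_geometry(dpx[i]), cx6=scale_geometry(cx[i]))
        for i in range(len(chain.residues))
    ]


def export_features_tsv(chain: ChainModel, blocks: list[GeometryBlock]) -> str:
    """TSV with one row per residue: chain, position, aa, rasa, dpx1..6, cx1..6."""
    header = ["chain", "position", "aa", "rasa"]
    header += [f"dpx_{n}" for n in _STAT_NAMES] + [f"cx_{n}" for n in _STAT_NAMES]
    lines = ["\t".join(header)]
    for res, blk in zip(chain.residues, blocks):
        row = [res.chain_id, res.seq_position, res.one_letter, f"{blk.rasa:.6f}"]
        row += [f"{v:.6f}" for v in blk.dpx6] + [f"{v:.6f}" for v in blk.cx6]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
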