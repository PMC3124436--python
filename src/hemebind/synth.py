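"""Self-contained toy heme-protein complexes and synthetic sequence profiles.

Real heme-protein benchmarks cannot be shipped or rebuilt offline (they
require a PDB snapshot and profile searches against a large sequence
database), so this module fabricates miniature complexes carrying the
statistical structure the predictor exploits:

* a polymer chain on an ideal helical or four-helix-bundle scaffold
  (3.8 Angstrom Cα spacing, backbone N/C/O plus one pseudo side-chain
  atom per residue), giving a genuine surface/core distinction;
* a planar 43-atom porphyrin-like heavy-atom ring posed tangent to the
  surface, with the side chains of the chosen binding patch (the
  ``patch_size`` residues nearest the ring) extended toward it into
  contact range, the way coordinating side chains reach for the ligand;
  every other residue keeps a safety margin beyond the contact cutoff,
  so the planted labels survive PDB coordinate rounding;
* patch residues preferentially assigned Cys/His/Met/Phe identities,
  mirroring the interface propensities observed in real heme proteins;
* synthetic profiles whose diagonal (own-residue) scores are elevated at
  patch positions, emulating the elevated evolutionary conservation of
  binding residues.

The planted truth is recorded at construction time; distance-based
labeling of the emitted structure reproduces it exactly (the closure
property the test-suite leans on).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hemebind.labeling import DEFAULT_CONTACT_CUTOFF
from hemebind.pssm import AA_ORDER, AA_INDEX, PssmMatrix, write_pssm
from hemebind.structure import (
    AtomRecord,
    ChainModel,
    HemeGroup,
    ONE_TO_THREE,
    ResidueUnit,
    write_structure,
)

__all__ = ["FixtureSpec", "FixtureError", "make_toy_complex", "synth_pssm", "make_benchmark"]

PATCH_FAVORED = "CHMF"          # Cys, His, Met, Phe
PATCH_FAVORED_PROB = 0.85
CONSERVATION_CAP = 12
BACKGROUND_SCORE_RANGE = 4      # background scores uniform in [-4, 4]
MIN_SUBSTITUTION_SCORE = -6     # floor for depressed scores in conserved columns
# Contact distances are kept this far from the cutoff so that labels are
# invariant to the 1e-3 Angstrom coordinate rounding of the PDB format.
CUTOFF_MARGIN = 0.02
MIN_HEME_CLEARANCE = 2.4
# pocket residues adopt compact rotamers: their side-chain tip is pulled
# back to this distance from the C-alpha, carving a shallow dent the
# ligand plane can nestle into
DENT_STUB_LENGTH = 0.8


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters of one toy complex / benchmark."""

    n_chains: int = 30
    residues_per_chain: int = 60
    patch_size: int = 8
    hemes_per_chain: int = 1
    conservation_boost: int = 8
    geometry_style: str = "helix-bundle"  # helix | helix-bundle
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size >= self.residues_per_chain:
            raise ValueError("patch_size must be smaller than residues_per_chain")
        if self.conservation_boost < 0:
            raise ValueError("conservation_boost must be non-negative")
        if self.geometry_style not in ("helix", "helix-bundle"):
            raise ValueError(f"unknown geometry_style {self.geometry_style!r}")


def _helix_ca(n: int, axis_xy=(0.0, 0.0), z0: float = 0.0, direction: int = 1,
              phase: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix Cα trace: 2.3 A radius, 1.5 A rise, 100 deg/residue."""
    t = np.arange(n)
    ang = np.deg2rad(100.0) * t + phase
    x = axis_xy[0] + 2.3 * np.cos(ang)
    y = axis_xy[1] + 2.3 * np.sin(ang)
    z = z0 + direction * 1.5 * t
    return np.column_stack([x, y, z])


def _scaffold(n: int, style: str) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates and per-residue outward normals (away from the local
    helix axis)."""
    if style == "helix":
        ca = _helix_ca(n)
        axes = np.zeros((n, 2))
    else:
        # four antiparallel helices on a square, one chain threaded through
        half = 4.0
        corners = [(-half, -half), (half, -half), (half, half), (-half, half)]
        seg = n // 4
        sizes = [seg, seg, seg, n - 3 * seg]
        parts, axes_list = [], []
        for k, (corner, size) in enumerate(zip(corners, sizes)):
            direction = 1 if k % 2 == 0 else -1
            z0 = 0.0 if direction == 1 else 1.5 * (size - 1)
            parts.append(_helix_ca(size, corner, z0, direction, phase=k * 1.1))
            axes_list.append(np.tile(corner, (size, 1)))
        ca = np.vstack(parts)
        axes = np.vstack(axes_list)
    normals = ca[:, :2] - axes
    normals = np.column_stack([normals, np.zeros(len(ca))])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return ca, normals


def _backbone_atoms(ca: np.ndarray, normals: np.ndarray) -> list[list[AtomRecord]]:
    """N, CA, C, O and one pseudo side-chain atom (CB) per residue."""
    n = len(ca)
    atoms_per_res: list[list[AtomRecord]] = []
    for i in range(n):
        prev_i = max(i - 1, 0)
        next_i = min(i + 1, n - 1)
        u = ca[next_i] - ca[prev_i]
        nu = np.linalg.norm(u)
        u = u / nu if nu > 0 else np.array([0.0, 0.0, 1.0])
        o = normals[i]
        atoms = [
            AtomRecord("N", "N", ca[i] - 1.45 * u),
            AtomRecord("CA", "C", ca[i]),
            AtomRecord("C", "C", ca[i] + 1.52 * u),
            AtomRecord("O", "O", ca[i] + 1.52 * u + 1.23 * o),
            AtomRecord("CB", "C", ca[i] + 2.4 * o, is_sidechain=True),
        ]
        atoms_per_res.append(atoms)
    return atoms_per_res


def _heme_template() -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Planar 43-atom porphyrin-like grid in the xy-plane: a central iron
    plus three concentric rings (6, 12 and 24 atoms at 2, 3 and 4 A)."""
    coords = [np.zeros(3)]
    names: list[tuple[str, str]] = [("FE", "FE")]
    k = 0
    for radius, count in ((2.0, 6), (3.0, 12), (4.0, 24)):
        ang = 2.0 * np.pi * np.arange(count) / count + 0.5 * radius
        for a in ang:
            coords.append(np.array([radius * np.cos(a), radius * np.sin(a), 0.0]))
            k += 1
            elem = "N" if radius == 2.0 else "C"
            names.append((f"{'N' if elem == 'N' else 'C'}{k}", elem))
    return np.array(coords), names


def _orient(template: np.ndarray, normal: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Rotate the xy-plane template so its plane normal is ``normal``,
    then translate to ``origin``."""
    z = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, z)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    return template @ rot.T + origin


def _residue_min_dists(atoms_per_res: list[list[AtomRecord]], heme_coords: np.ndarray) -> np.ndarray:
    """Minimum heavy-atom distance of every residue to the heme (brute force)."""
    out = np.empty(len(atoms_per_res))
    for i, atoms in enumerate(atoms_per_res):
        c = np.array([a.coord for a in atoms])
        d = np.linalg.norm(c[:, None, :] - heme_coords[None, :, :], axis=2)
        out[i] = d.min()
    return out


def _reach_toward(cb: np.ndarray, heme_coords: np.ndarray, target: float) -> np.ndarray:
    """Move a side-chain tip along the ray to its nearest heme atom until
    its minimum distance to the heme equals ``target`` (Angstrom)."""
    d = np.linalg.norm(heme_coords - cb, axis=1)
    h = heme_coords[np.argmin(d)]
    direction = (h - cb) / np.linalg.norm(h - cb)
    # walk in; the first step achieving min-dist <= target wins
    for s in np.arange(0.0, np.min(d), 0.02):
        p = cb + s * direction
        if np.min(np.linalg.norm(heme_coords - p, axis=1)) <= target:
            return p
    return h  # unreachable in practice


def _place_heme(
    atoms_per_res: list[list[AtomRecord]],
    ca: np.ndarray,
    normals: np.ndarray,
    patch_size: int,
    cutoff: float,
    forbidden: set[int],
    prior_hemes: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, set[int]]:
    """Carve a shallow pocket and nestle a heme plane into it.

    Anchors are drawn from outward-facing residues near the chain's
    mid-height (binding sites avoid the frayed termini).  The pocket is
    made by giving the ``patch_size`` residues around the anchor compact
    side-chain rotamers; the ring plane then descends along the surface
    normal to the pose with the most rigid contacts.  Patch members not
    already in contact get their side chain extended toward the ring to a
    randomized distance well inside the cutoff.  Accepted poses keep every
    non-patch residue beyond the cutoff plus margin, keep backbone
    clearance from the ring, and leave previously planted patches
    untouched — so the planted labels are exact by construction.
    """
    template, _ = _heme_template()
    centroid = ca.mean(axis=0)
    outwardness = np.einsum("ij,ij->i", normals, ca - centroid)
    z = ca[:, 2]
    z_mid = 0.5 * (z.max() + z.min())
    mid_band = np.abs(z - z_mid) < 0.2 * (z.max() - z.min())
    candidates = [
        int(i)
        for i in np.argsort(-outwardness)
        if outwardness[i] > 0 and mid_band[i]
    ] or [int(i) for i in np.argsort(-outwardness) if outwardness[i] > 0]
    rng.shuffle(candidates)
    # prefer poses with many rigid contacts; relax only if the scaffold
    # cannot offer them (single exposed helix)
    for min_natural in (5, 3, 1):
        for anchor in candidates:
            if anchor in forbidden:
                continue
            o = normals[anchor]
            # dent: compact side-chain rotamers under the ligand
            near = np.linalg.norm(ca - ca[anchor], axis=1)
            dent = [
                int(i)
                for i in np.argsort(near)
                if outwardness[i] > 0 and i not in forbidden
            ][:patch_size]
            saved = {i: list(atoms_per_res[i]) for i in dent}
            for i in dent:
                atoms_per_res[i][-1] = AtomRecord(
                    "CB", "C", ca[i] + DENT_STUB_LENGTH * normals[i], is_sidechain=True
                )
            best = None
            for d in np.arange(1.0, 9.0, 0.05):
                heme_coords = _orient(template, o, ca[anchor] + d * o)
                dists = _residue_min_dists(atoms_per_res, heme_coords)
                if dists.min() < MIN_HEME_CLEARANCE:
                    continue
                order = np.argsort(dists)
                # no residue may sit at the cutoff boundary, and everything
                # beyond the patch must clear the cutoff with margin
                if np.any(np.abs(dists - cutoff) < 2 * CUTOFF_MARGIN):
                    continue
                if dists[order[patch_size]] <= cutoff + 2 * CUTOFF_MARGIN:
                    continue
                if dists[order[patch_size - 1]] > cutoff + 5.0:
                    continue
                patch = set(int(i) for i in order[:patch_size])
                if patch & forbidden:
                    continue
                n_contact = int(np.sum(dists <= cutoff))
                if best is None or n_contact > best[0]:
                    best = (n_contact, heme_coords, dists, patch)
            if best is None or best[0] < min_natural:
                for i, atoms in saved.items():
                    atoms_per_res[i] = atoms
                continue
            _, heme_coords, dists, patch = best
            moved = {}
            ok = True
            for i in sorted(patch):
                if dists[i] <= cutoff:
                    continue  # already a rigid contact
                target = rng.uniform(3.1, cutoff - 0.6)
                new_cb = _reach_toward(atoms_per_res[i][-1].coord, heme_coords, target)
                # the extended tip must not contact any previously planted heme
                for prior in prior_hemes:
                    if np.min(np.linalg.norm(prior - new_cb, axis=1)) <= cutoff + 2 * CUTOFF_MARGIN:
                        ok = False
                moved[i] = new_cb
            if not ok:
                for i, atoms in saved.items():
                    atoms_per_res[i] = atoms
                continue
            for i, new_cb in moved.items():
                atoms_per_res[i][-1] = AtomRecord("CB", "C", new_cb, is_sidechain=True)
            return heme_coords, patch
    raise FixtureError(
        f"could not place a heme with a planted patch of {patch_size} residues"
    )


def make_toy_complex(
    spec: FixtureSpec, chain_seed: int | None = None
) -> tuple[ChainModel, list[HemeGroup], np.ndarray]:
    """One toy chain with planted heme(s) and the planted truth labels."""
    rng = np.random.default_rng(spec.seed if chain_seed is None else chain_seed)
    n = spec.residues_per_chain
    ca, normals = _scaffold(n, spec.geometry_style)
    atoms_per_res = _backbone_atoms(ca, normals)

    hemes: list[HemeGroup] = []
    truth = np.zeros(n, dtype=int)
    taken: set[int] = set()
    _, heme_names = _heme_template()
    prior: list[np.ndarray] = []
    for _ in range(spec.hemes_per_chain):
        heme_coords, contacts = _place_heme(
            atoms_per_res, ca, normals, spec.patch_size, spec.contact_cutoff,
            taken, prior, rng
        )
        prior.append(heme_coords)
        atoms = [
            AtomRecord(name=nm, element=el, coord=heme_coords[k])
            for k, (nm, el) in enumerate(heme_names)
        ]
        hemes.append(HemeGroup(het_code="HEM", atoms=atoms))
        truth[sorted(contacts)] = 1
        taken |= contacts

    # identities: binding patch enriched in Cys/His/Met/Phe
    letters = []
    for i in range(n):
        if truth[i] and rng.random() < PATCH_FAVORED_PROB:
            letters.append(PATCH_FAVORED[rng.integers(len(PATCH_FAVORED))])
        else:
            letters.append(AA_ORDER[rng.integers(20)])
    residues = [
        ResidueUnit(
            chain_id="A",
            seq_position=str(i + 1),
            aa_type=ONE_TO_THREE[letters[i]],
            atoms=atoms_per_res[i],
        )
        for i in range(n)
    ]
    return ChainModel(chain_id="A", residues=residues), hemes, truth


def synth_pssm(
    sequence: str, truth: np.ndarray, conservation_boost: int, seed: int
) -> PssmMatrix:
    """Synthetic profile with planted conservation at binding positions.

    Background rows are integer noise in [-4, 4].  At truth-positive
    positions the row is reshaped the way iterated profile searches shape
    conserved columns: the diagonal (own-residue) score is raised by
    ``conservation_boost`` (capped at 12) while each remaining
    substitution score is depressed by a random amount up to half the
    boost (floored at -6), since a conserved column penalizes
    substitutions — noisily, so single positions stay ambiguous and the
    sliding-window context genuinely helps.  With boost 0 the row is
    untouched, giving a clean null."""
    if conservation_boost < 0:
        raise ValueError("conservation_boost must be non-negative")
    rng = np.random.default_rng(seed)
    scores = rng.integers(
        -BACKGROUND_SCORE_RANGE, BACKGROUND_SCORE_RANGE + 1, size=(len(sequence), 20)
    )
    suppression = (conservation_boost + 1) // 2
    for i, aa in enumerate(sequence):
        if truth[i] and aa in AA_INDEX:
            j = AA_INDEX[aa]
            diag = min(CONSERVATION_CAP, int(scores[i, j]) + conservation_boost)
            drop = rng.integers(0, suppression + 1, size=20)
            scores[i] = np.clip(scores[i] - drop, MIN_SUBSTITUTION_SCORE, None)
            scores[i, j] = diag
    return PssmMatrix(sequence=sequence, scores=scores)


def _chain_seed(master_seed: int, index: int) -> int:
    """Stable per-chain sub-seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def make_benchmark(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a full benchmark directory: one PDB and one PSSM per chain
    plus a single truth table, reproducible bit-for-bit per seed.

    Layout: ``chain_000.pdb``, ``chain_000.pssm``, ..., ``truth.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_lines = ["chain\tposition\taa\tlabel"]
    for i in range(spec.n_chains):
        key = f"chain_{i:03d}"
        cseed = _chain_seed(spec.seed, i)
        chain, hemes, truth = make_toy_complex(spec, chain_seed=cseed)
        pssm = synth_pssm(chain.sequence, truth, spec.conservation_boost, seed=cseed + 1)
        (out / f"{key}.pdb").write_text(write_structure([chain], hemes))
        (out / f"{key}.pssm").write_text(write_pssm(pssm))
        for res, lab in zip(chain.residues, truth):
            truth_lines.append(f"{key}\t{res.seq_position}\t{res.one_letter}\t{int(lab)}")
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    return out
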