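"""Structural descriptors against closed forms and brute-force oracles."""

import numpy as np
import pytest

from hemebind.geometry import (
    GeometryError,
    MAX_SASA,
    SasaResult,
    compute_cx,
    compute_dpx,
    compute_rasa,
    compute_sasa,
    geometry_blocks,
    scale_geometry,
    _sphere_points,
)
from tests.conftest import make_chain

SPHERE_VOL_10 = 4.0 / 3.0 * np.pi * 1000.0


def brute_force_depths(coords, per_atom_sasa, eps=1e-6):
    """Independent all-pairs depth scan (the DPX oracle)."""
    accessible = per_atom_sasa > eps
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        if accessible[i]:
            continue
        out[i] = min(
            np.linalg.norm(coords[i] - coords[j])
            for j in range(len(coords))
            if accessible[j]
        )
    return out


def octahedral_cage(spacing=2.0):
    """Central atom surrounded by six axis atoms; the center is fully
    occluded at 2.0 A spacing (each neighbor cap spans 71 deg while the
    worst-case direction lies 55 deg from the nearest axis)."""
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    return np.vstack([[0.0, 0.0, 0.0], spacing * axes])


class TestSasa:
    def test_isolated_atom_closed_form(self):
        chain = make_chain([[0.0, 0.0, 0.0]])
        res = compute_sasa(chain)
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2
        assert res.per_atom_sasa[0] == pytest.approx(expected, rel=1e-12)

    def test_two_distant_atoms_unoccluded(self):
        chain = make_chain([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        res = compute_sasa(chain)
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(res.per_atom_sasa, expected, rtol=1e-12)

    def test_caged_central_atom_is_buried(self):
        chain = make_chain(octahedral_cage())
        res = compute_sasa(chain)
        # oracle: recount at 10x sample density
        dense = compute_sasa(chain, n_points=9600)
        assert res.per_atom_sasa[0] == 0.0
        assert dense.per_atom_sasa[0] == 0.0
        assert np.all(res.per_atom_sasa[1:] > 0)

    def test_quadrature_convergence(self, toy_complex):
        """Per-residue SASA converges with sample density.

        At the default 960 points a few partially occluded residues still
        carry up to ~5% quadrature jitter (absolute floor: a handful of
        boundary points on a ~120 A^2 sphere is ~0.5 A^2); from 1920
        points on, doubling the density moves every residue by < 2%.
        """
        chain, _, _ = toy_complex
        s480 = compute_sasa(chain, n_points=480).per_residue_sasa
        s960 = compute_sasa(chain, n_points=960).per_residue_sasa
        assert np.all(np.abs(s480 - s960) < 0.05 * s960 + 0.7)
        s1920 = compute_sasa(chain, n_points=1920).per_residue_sasa
        s3840 = compute_sasa(chain, n_points=3840).per_residue_sasa
        assert np.all(np.abs(s1920 - s3840) < np.maximum(0.02 * s3840, 0.6))

    def test_sphere_points_are_unit(self):
        pts = _sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestRasa:
    def test_zero_and_full_exposure(self):
        chain = make_chain([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]], aa="ALA")
        sasa = SasaResult(
            per_atom_sasa=np.array([0.0, MAX_SASA["ALA"]]),
            per_residue_sasa=np.array([0.0, MAX_SASA["ALA"]]),
            atom_residue_index=np.array([0, 1]),
        )
        rasa = compute_rasa(chain, sasa)
        assert rasa[0] == 0.0
        assert rasa[1] == 1.0

    def test_clamped_above_one(self):
        chain = make_chain([[0.0, 0.0, 0.0]], aa="GLY")
        sasa = SasaResult(
            per_atom_sasa=np.array([1.3 * MAX_SASA["GLY"]]),
            per_residue_sasa=np.array([1.3 * MAX_SASA["GLY"]]),
            atom_residue_index=np.array([0]),
        )
        assert compute_rasa(chain, sasa)[0] == 1.0

    def test_unk_residue_is_nan(self):
        chain = make_chain([[0.0, 0.0, 0.0]], aa="UNK")
        sasa = SasaResult(
            per_atom_sasa=np.array([10.0]),
            per_residue_sasa=np.array([10.0]),
            atom_residue_index=np.array([0]),
        )
        assert np.isnan(compute_rasa(chain, sasa)[0])


class TestDpx:
    def test_exposed_chain_all_zero(self):
        chain = make_chain([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        sasa = compute_sasa(chain)
        dpx = compute_dpx(chain, sasa)
        np.testing.assert_array_equal(dpx, 0.0)

    def test_single_residue_chain_zero(self):
        chain = make_chain([[0.0, 0.0, 0.0]])
        dpx = compute_dpx(chain, compute_sasa(chain))
        np.testing.assert_array_equal(dpx[0], 0.0)

    def test_cage_center_matches_bruteforce(self):
        coords = octahedral_cage()
        chain = make_chain(coords)
        sasa = compute_sasa(chain)
        dpx = compute_dpx(chain, sasa)
        oracle = brute_force_depths(coords, sasa.per_atom_sasa)
        # single-atom residues: all six stats equal that atom's depth
        assert dpx[0, 0] == oracle[0] == pytest.approx(2.0)
        for i in range(len(coords)):
            np.testing.assert_array_equal(dpx[i, [0, 2, 4, 5]], oracle[i])

    def test_monotone_under_occlusion(self, toy_complex):
        """Adding an occluding shell never decreases an atom's depth."""
        coords = octahedral_cage()
        shell = octahedral_cage(spacing=4.0)[1:]
        corner_shell = 4.0 / np.sqrt(3) * np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        chain_small = make_chain(coords)
        chain_big = make_chain(np.vstack([coords, shell, corner_shell]))
        d_small = compute_dpx(chain_small, compute_sasa(chain_small))
        d_big = compute_dpx(chain_big, compute_sasa(chain_big))
        assert np.all(d_big[: len(coords), 5] >= d_small[:, 5] - 1e-9)

    def test_no_accessible_atom_error(self):
        chain = make_chain([[0.0, 0.0, 0.0]])
        sasa = SasaResult(
            per_atom_sasa=np.array([0.0]),
            per_residue_sasa=np.array([0.0]),
            atom_residue_index=np.array([0]),
        )
        with pytest.raises(GeometryError):
            compute_dpx(chain, sasa)


class TestCx:
    def test_isolated_atom_closed_form(self):
        chain = make_chain([[0.0, 0.0, 0.0]])
        cx = compute_cx(chain)
        expected = (SPHERE_VOL_10 - 20.1) / 20.1
        # mean / sidechain-mean / min / max all equal the lone atom's CX
        np.testing.assert_allclose(cx[0, [0, 2, 4, 5]], expected, rtol=1e-12)
        assert expected == pytest.approx(207.4, abs=0.05)

    def test_two_atom_closed_form(self):
        chain = make_chain([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        cx = compute_cx(chain)
        expected = (SPHERE_VOL_10 - 40.2) / 40.2
        np.testing.assert_allclose(cx[:, 0], expected, rtol=1e-12)
        assert expected == pytest.approx(103.2, abs=0.05)

    def test_dense_lattice_center_below_one(self):
        grid = np.arange(-10.8, 10.9, 1.8)
        pts = np.array([[x, y, z] for x in grid for y in grid for z in grid])
        pts = pts[np.linalg.norm(pts, axis=1) < 11.0]
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        coords = np.vstack([pts[center], np.delete(pts, center, axis=0)])
        chain = make_chain(coords, residue_split=[1, len(coords) - 1])
        cx = compute_cx(chain)
        assert cx[0, 0] < 1.0
        # brute-force neighbor count oracle
        n_in = int(np.sum(np.linalg.norm(coords - coords[0], axis=1) <= 10.0))
        expected = max(SPHERE_VOL_10 - n_in * 20.1, 0.0) / (n_in * 20.1)
        assert cx[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_anti_monotone_in_density(self):
        sparse = make_chain([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        dense = make_chain([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0]])
        assert compute_cx(dense)[0, 0] < compute_cx(sparse)[0, 0]


class TestScaling:
    @pytest.mark.parametrize(
        "raw, expected",
        [(0.0, 0.5), (1.0, 0.7311), (-3.0, 0.0474), (7.0, 0.9991)],
    )
    def test_logistic_values(self, raw, expected):
        assert scale_geometry(np.array([raw]))[0] == pytest.approx(expected, abs=5e-5)

    def test_rejects_non_finite(self):
        with pytest.raises(GeometryError):
            scale_geometry(np.array([np.nan]))

    def test_all_features_in_unit_interval(self, toy_geometry):
        for block in toy_geometry:
            assert 0.0 <= block.rasa <= 1.0
            assert np.all((block.dpx6 > 0.0) & (block.dpx6 < 1.0))
            assert np.all((block.cx6 > 0.0) & (block.cx6 < 1.0))
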