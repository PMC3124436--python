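"""Shared fixtures: toy complexes, hand-built chains, and the benchmark.

Everything is generated programmatically at test time; the session-scoped
benchmark (30 chains, seed 1) backs the end-to-end and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import hemebind as hb
from hemebind.structure import AtomRecord, ChainModel, HemeGroup, ResidueUnit


def make_chain(coords, elements=None, residue_split=None, aa="ALA", names=None):
    """Build a ChainModel from bare coordinates.

    ``residue_split`` gives the residue sizes (default: one residue per
    atom); every atom is a side-chain-less CA so spatial operations work.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    if residue_split is None:
        residue_split = [1] * n
    residues = []
    k = 0
    for ri, size in enumerate(residue_split):
        atoms = []
        for j in range(size):
            name = names[k] if names else ("CA" if j == 0 else f"X{j}")
            atoms.append(
                AtomRecord(
                    name=name,
                    element=elements[k],
                    coord=coords[k],
                    is_sidechain=name not in ("N", "CA", "C", "O"),
                )
            )
            k += 1
        residues.append(
            ResidueUnit(chain_id="A", seq_position=str(ri + 1), aa_type=aa, atoms=atoms)
        )
    return ChainModel(chain_id="A", residues=residues)


def make_heme(coords):
    coords = np.asarray(coords, dtype=float)
    return HemeGroup(
        het_code="HEM",
        atoms=[AtomRecord(name=f"C{i}", element="C", coord=c) for i, c in enumerate(coords)],
    )


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic 60-residue bundle with a planted 8-residue patch."""
    return hb.make_toy_complex(hb.FixtureSpec(seed=7), chain_seed=7)


@pytest.fixture(scope="session")
def toy_geometry(toy_complex):
    chain, _, _ = toy_complex
    return hb.geometry_blocks(chain, n_points=240)


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory):
    """The 30-chain seed-1 benchmark on disk."""
    out = tmp_path_factory.mktemp("bench") / "seed1"
    hb.make_benchmark(hb.FixtureSpec(n_chains=30, seed=1), out)
    return out


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark_dir):
    from hemebind.pipeline import load_benchmark

    return load_benchmark(benchmark_dir)
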