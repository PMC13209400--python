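"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import pytest

from pankit.io import Environment, MetadataRow, MetadataTable
from pankit.simulate import (
    SyntheticPangenomeSpec,
    simulate_pangenome,
    simulate_proteomes,
)


def make_metadata(n_genomes: int = 16, n_htv: int = 2) -> MetadataTable:
    rows = []
    for i in range(n_genomes):
        gid = f"SG{i + 1:02d}"
        env = Environment.HTV if i < n_htv else Environment.NONHTV
        rows.append(MetadataRow(gid, env, gid))
    return MetadataTable(rows)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact 16-genome pan-genome with planted 5 + 7 associations."""
    spec = SyntheticPangenomeSpec(
        n_core=30, n_accessory=120, unique_rate=8.0,
        n_planted_htv=5, n_planted_nonhtv=7, seed=11,
    )
    return simulate_pangenome(spec)


@pytest.fixture(scope="session")
def study_bundle():
    """The full-scale default design: 2 vs 14 genomes, 57 + 82 planted."""
    return simulate_pangenome(SyntheticPangenomeSpec(seed=23))


@pytest.fixture(scope="session")
def proteome_bundle():
    """Per-genome proteomes: 50 families, 16 genomes, 10% divergence."""
    proteomes, labels = simulate_proteomes(
        n_genomes=16, n_families=50, divergence=0.10, seed=3
    )
    return proteomes, labels, make_metadata(16, 2)
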