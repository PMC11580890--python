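"""Shared fixtures: toy geometries, deterministic genomes, small datasets."""

from __future__ import annotations

import numpy as np
import pytest

from svdisrupt.genome import DictGenome
from svdisrupt.geometry import TOY_GEOMETRY, PredictorGeometry
from svdisrupt.predictor import DEFAULT_BOUNDARY_MOTIF, SurrogatePredictor
from svdisrupt.simulate import FixtureSpec, generate_dataset

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_sequence(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="session")
def toy_geometry() -> PredictorGeometry:
    """64 bp in, 8 bins of 4 bp out (crop 4 bins per side)."""
    return TOY_GEOMETRY


@pytest.fixture(scope="session")
def full_geometry() -> PredictorGeometry:
    return PredictorGeometry()


@pytest.fixture(scope="session")
def toy_genome() -> DictGenome:
    """200 bp random chromosome for windowed sequence construction."""
    return DictGenome({"chrT": random_sequence(11, 200)})


@pytest.fixture(scope="session")
def at_genome() -> DictGenome:
    """Strictly periodic AT chromosome: even-length, even-offset edits of
    any SV type reproduce the reference exactly (identity-null cases)."""
    return DictGenome({"chrA": "AT" * 1_200_000})


@pytest.fixture(scope="session")
def surrogate_full(full_geometry) -> SurrogatePredictor:
    return SurrogatePredictor(full_geometry)


@pytest.fixture(scope="session")
def surrogate_toy(toy_geometry) -> SurrogatePredictor:
    return SurrogatePredictor(toy_geometry)


@pytest.fixture(scope="session")
def motif_genome(full_geometry) -> tuple[DictGenome, int]:
    """2.4 Mb chromosome with a single boundary motif at 1.2 Mb."""
    seq = random_sequence(5, 2_400_000)
    pos = 1_200_000
    seq = seq[:pos] + DEFAULT_BOUNDARY_MOTIF + seq[pos + len(DEFAULT_BOUNDARY_MOTIF):]
    return DictGenome({"chrM": seq}), pos


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced toy dataset: 1 chromosome, 6 variants per cohort."""
    return generate_dataset(
        FixtureSpec(seed=3, n_chroms=1, n_variants_per_cohort=6, n_loops=12, n_genes=20)
    )
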