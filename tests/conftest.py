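"""Shared fixtures: small seeded sequences and simulated inputs.

All fixtures are generated programmatically; nothing is read from disk
except what a test itself writes to ``tmp_path``.
"""

from __future__ import annotations

import numpy as np
import pytest

from t2tannot.repeats import _BASES
from t2tannot.simulate import random_monomer


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def monomer_107(rng) -> str:
    return random_monomer(rng, 107)


@pytest.fixture
def background_10kb(rng) -> str:
    return random_dna(rng, 10_000)
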