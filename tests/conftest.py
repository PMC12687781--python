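"""Shared fixtures: small deterministic toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from cfmdock.toygen import (
    FlexPerturbSpec,
    ToyComplexSpec,
    generate_bound_complex,
    generate_chain,
    perturb_unbound,
)


@pytest.fixture(scope="session")
def bound_complex():
    """One deterministic bound toy complex (receptor 20, ligand 18 residues)."""
    return generate_bound_complex(ToyComplexSpec(seed=3))


@pytest.fixture(scope="session")
def small_chain():
    return generate_chain(14, np.random.default_rng(7), chain_id="A")


@pytest.fixture(scope="session")
def flex_library(bound_complex):
    """Holo/apo/predicted conformer library for the bound complex's chains."""
    lib = {}
    for role, chain in (
        ("receptor", bound_complex.receptor),
        ("ligand", bound_complex.ligand),
    ):
        lib[role] = {
            "holo": [chain.copy()],
            "apo": [perturb_unbound(chain, FlexPerturbSpec("apo_like", seed=11))],
            "predicted": [
                perturb_unbound(chain, FlexPerturbSpec("predicted_like", seed=12))
            ],
        }
    return lib
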