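"""Shared fixtures: one mid-size synthetic plastome and one default-condition
CDS set, generated once per session (generation is deterministic)."""

import numpy as np
import pytest

from plastcub.synthetic_data import SyntheticSpec, generate_cds_set, generate_genome


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        seed=11,
        n_genes=24,
        architecture=(22_000, 4_000, 6_000),
        ssr_implants=(("A", 12), ("T", 11), ("AT", 7), ("AAT", 5), ("AAAT", 5)),
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_genome(small_spec)


@pytest.fixture(scope="session")
def default_cds():
    """Gene complement under the default (rubber-tree-like) conditions."""
    return generate_cds_set(SyntheticSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
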