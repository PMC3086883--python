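import numpy as np
import pytest

from calpcleave import (
    AnnotatedSubstrate,
    KernelConfig,
    SyntheticConfig,
    WindowSpec,
    build_instances,
    generate,
)


@pytest.fixture
def substrate():
    """A tiny hand-built substrate: 12 residues, two cleavage sites."""
    return AnnotatedSubstrate(
        id="sub1",
        residues="ACDEFGHIKLMN",
        ss_track="CCHHHHEEECCC",
        sa_track="BAABBBAABBAA",
        cleavage_sites=[3, 8],
        calpain_types=[frozenset({"calpain-1"}),
                       frozenset({"calpain-1", "calpain-2"})],
    )


@pytest.fixture
def small_synthetic():
    """A small planted-motif substrate set shared across tests."""
    cfg = SyntheticConfig(n_sequences=12, length_range=(60, 100),
                          sites_per_sequence=(1, 2), seed=42)
    return generate(cfg)


@pytest.fixture
def small_instances(small_synthetic):
    spec = WindowSpec(6, 5)
    return build_instances(small_synthetic, spec, neg_ratio=4, rng_seed=7)


@pytest.fixture
def default_configs():
    spec = WindowSpec(6, 5)
    return [
        KernelConfig("rbf", "sequence", spec, sigma=2.1),
        KernelConfig("string", "sequence", spec, order_d=3),
        KernelConfig("spectrum", "ss", spec, order_dprime=3, gaps_g=1),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
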