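"""Shared fixtures: a tiny synthetic compendium and full demo-scale runs.

The session-scoped pipeline runs are shared across test modules so the suite
trains each configuration exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from coexfp.pipeline import demo_config, run
from coexfp.synthetic import SyntheticConfig, TermSpec, generate_compendium


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Three planted terms of graded strength over 60 genes, 3 datasets."""
    return SyntheticConfig(
        n_genes=60,
        n_datasets=3,
        conditions_per_dataset=(15, 20, 18),
        terms=(
            TermSpec("T_strong", 10, 0.9),
            TermSpec("T_mid", 10, 0.5),
            TermSpec("T_weak", 10, 0.1),
        ),
        noise_sd=0.3,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_config):
    return generate_compendium(tiny_config)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full pipeline on the demo profile (eight graded-strength terms)."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = demo_config(out, seed=7)
    run(cfg, "all")
    return cfg


@pytest.fixture(scope="session")
def drifted_run(tmp_path_factory):
    """Full pipeline trained on a drifted (mis-annotated) snapshot."""
    out = tmp_path_factory.mktemp("drifted_run")
    cfg = demo_config(out, seed=7, flip_rate=0.15)
    run(cfg, "all")
    return cfg
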