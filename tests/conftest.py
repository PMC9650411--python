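"""Shared fixtures: the default synthetic study run, reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spongemod.bundle import ExpressionBundle, TargetMatrix
from spongemod.pipeline import RunConfig, run_pipeline
from spongemod.simulate import default_spec, generate_bundle


@pytest.fixture(scope="session")
def default_study():
    """Bundle, targets, and ground truth of the default planted study."""
    return generate_bundle(default_spec(seed=1))


@pytest.fixture(scope="session")
def default_pipeline_run(default_study):
    """One full pipeline execution on the default study (shared, expensive)."""
    bundle, targets, truth = default_study
    config = RunConfig(n_null=10_000, seed=1)
    result = run_pipeline(bundle, targets, config)
    return result, truth


def make_bundle(
    n_genes: tuple[int, int, int] = (6, 4, 3),
    n_samples: int = 8,
    seed: int = 0,
) -> ExpressionBundle:
    """Small random bundle for structural tests."""
    rng = np.random.default_rng(seed)
    n_mr, n_lnc, n_mir = n_genes
    samples = [f"S{i}" for i in range(n_samples)]

    def mat(prefix, n):
        return pd.DataFrame(
            rng.normal(8, 1, (n, n_samples)),
            index=[f"{prefix}{i}" for i in range(n)],
            columns=samples,
        )

    traits = pd.DataFrame(
        {
            "diagnosis": rng.integers(1, 4, n_samples),
            "case": rng.permutation([0, 1] * (n_samples // 2))[:n_samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionBundle(
        mrna=mat("mR", n_mr), lncrna=mat("lnc", n_lnc), mirna=mat("miR", n_mir),
        traits=traits,
    )
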