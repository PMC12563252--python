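"""Shared fixtures: small seeded trials built directly from effect draws."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from forageblup.trial_data import TraitSpec, TrialDataset


def make_trial(
    q: int,
    b: int,
    m: int,
    components: tuple[float, float, float, float],
    seed: int,
    mu: float = 50.0,
    fixed_sd: float = 3.0,
    trait: str = "t",
    direction: str = "higher_is_better",
) -> TrialDataset:
    """Balanced trial with Gaussian effects drawn at the given variance
    components (sigma2_g, sigma2_perm, sigma2_gm, sigma2_e)."""
    rng = np.random.default_rng(seed)
    sg, sp, sgm, se = (math.sqrt(c) for c in components)
    g = rng.normal(0, sg, q)
    p = rng.normal(0, sp, (q, b))
    gm = rng.normal(0, sgm, (q, m))
    fx = rng.normal(0, fixed_sd, (m, b))
    rows = [
        (
            f"G{i:02d}",
            f"B{j}",
            f"H{k:02d}",
            trait,
            mu + fx[k, j] + g[i] + p[i, j] + gm[i, k] + rng.normal(0, se),
        )
        for i, j, k in itertools.product(range(q), range(b), range(m))
    ]
    df = pd.DataFrame(rows, columns=["genotype", "block", "harvest", "trait", "value"])
    return TrialDataset(df, {trait: TraitSpec(trait, direction=direction)})


@pytest.fixture(scope="session")
def tiny_trial() -> TrialDataset:
    """5 genotypes x 2 blocks x 3 harvests = 30 observations."""
    return make_trial(5, 2, 3, (1.5, 1.0, 0.8, 2.0), seed=5)


@pytest.fixture(scope="session")
def mid_trial() -> TrialDataset:
    """12 genotypes x 3 blocks x 4 harvests, comfortably interior components."""
    return make_trial(12, 3, 4, (3.0, 2.0, 2.0, 3.0), seed=11)
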