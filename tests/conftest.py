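"""Shared fixtures: scaled-down trial configurations and toy tables."""

import numpy as np
import pandas as pd
import pytest

from agscreen import SimConfig


def small_config(**overrides) -> SimConfig:
    """A miniature but structurally valid lattice trial:
    20 entries + 2 checks x 3 = 26 plots = 2 blocks x 13."""
    base = dict(
        n_entries=20,
        n_checks=2,
        check_reps_within_replication=3,
        blocks_per_replication=2,
        plots_per_block=13,
        n_markers=150,
        missing_rate=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def tiny_cfg() -> SimConfig:
    return small_config()


def toy_trait_table(n_genotypes=3, n_reps=2, seed=1, values=None,
                    blocks=False) -> pd.DataFrame:
    """Balanced single-experiment table: every genotype once per replication."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for r in range(n_reps):
        for g in range(n_genotypes):
            v = values[i] if values is not None else rng.normal(10.0, 2.0)
            rows.append(
                ("e1", "anaerobic", f"r{r + 1}",
                 f"b{g % 2 + 1}" if blocks else None,
                 f"g{g + 1:02d}", "trait", v)
            )
            i += 1
    return pd.DataFrame(
        rows,
        columns=["experiment", "condition", "replication", "block",
                 "genotype", "trait", "value"],
    )


def outlier_fixture(seed, n_planted=0, sigma_g=5.0, shift_sd=10.0):
    """Two-rep, four-block, 40-genotype cell with optional planted outliers
    (+shift_sd residual SDs, each on a distinct genotype)."""
    rng = np.random.default_rng(seed)
    effects = {f"g{i}": rng.normal(0.0, sigma_g) for i in range(40)}
    rows = []
    for r in ["r1", "r2"]:
        for b in range(4):
            for k in range(10):
                g = f"g{b * 10 + k}"
                rows.append(("e1", "anaerobic", r, f"b{b}", g, "t",
                             rng.normal(50.0, 5.0) + effects[g]))
    df = pd.DataFrame(
        rows,
        columns=["experiment", "condition", "replication", "block",
                 "genotype", "trait", "value"],
    )
    planted = []
    if n_planted:
        chosen = rng.choice(40, size=n_planted, replace=False)
        for g in chosen:
            row = rng.choice(df.index[df["genotype"] == f"g{g}"])
            df.loc[row, "value"] += shift_sd * 5.0
            planted.append(row)
    return df, planted
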