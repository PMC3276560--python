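"""Shared fixtures: small deterministic cohorts built by the generator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from memgrowth import PhenotypeTable, scenario, simulate
from memgrowth.simulate import SimConfig


@pytest.fixture(scope="session")
def small_sim():
    """Compact null-structure cohort shared by read-only tests."""
    cfg = replace(
        scenario("null", seed=11),
        n_lines=60, n_conditions=4, n_genes=200, n_snps=100, n_eqtls=40,
    )
    return simulate(cfg)


@pytest.fixture()
def toy_table():
    """Six lines, two conditions, two replicates; deterministic values."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(6):
        for j in range(2):
            for k in range(2):
                rows.append((
                    f"L{i}", "CEU" if i < 3 else "YRI",
                    "female" if i % 2 else "male",
                    f"C{j}", f"r{k}",
                    100.0 + 10 * i + 5 * j + rng.normal(0, 1),
                ))
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"],
    ))


def balanced_single_condition(n_lines: int = 12, n_reps: int = 5,
                              sigma_line: float = 4.0, sigma_resid: float = 2.0,
                              seed: int = 3) -> PhenotypeTable:
    """Balanced one-condition design for closed-form BLUP checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lines):
        u = rng.normal(0, sigma_line)
        pop = "CEU" if i % 2 == 0 else "YRI"
        gen = "female" if i < n_lines // 2 else "male"
        base = 100.0 + (5.0 if pop == "YRI" else 0.0) + (-3.0 if gen == "female" else 0.0)
        for k in range(n_reps):
            rows.append((f"L{i:02d}", pop, gen, "C0", f"r{k}",
                         base + u + rng.normal(0, sigma_resid)))
    return PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"],
    ))
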