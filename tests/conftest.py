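"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methaherd.pedigree import Pedigree, relationship_matrix
from methaherd.simulate import default_truth, simulate_pedigree, simulate_phenotypes
from methaherd.traits import build_trait_table


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Sire (1), dam (2), offspring (3)."""
    return Pedigree(np.array([1, 2, 3]), np.array([0, 0, 1]), np.array([0, 0, 2]))


@pytest.fixture(scope="session")
def small_herd():
    """40 phenotyped cows, 8 weeks each, reference truth; with trait table."""
    truth = default_truth(n_cows=40, weeks_per_cow=8, seed=11)
    ped = simulate_pedigree(30, 1, 3, seed=2)
    herd = simulate_phenotypes(ped, truth)
    table, _ = build_trait_table(herd.records)
    return ped, herd, table


def simulate_repeatability_records(
    pedigree: Pedigree,
    n_cows: int,
    n_weeks: int,
    sigma2_a: float,
    sigma2_pe: float,
    sigma2_e: float,
    seed: int,
    n_fixed_classes: int = 8,
    fixed_sd: float = 0.0,
) -> pd.DataFrame:
    """Direct repeatability-model simulation of a single trait ``y``.

    Phenotypes the last ``n_cows`` pedigree animals; used to test REML
    recovery at arbitrary component values without the raw-stream layer.
    """
    rng = np.random.default_rng(seed)
    A = relationship_matrix(pedigree).A
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    a = np.sqrt(sigma2_a) * (L @ rng.standard_normal(len(A)))
    cows = pedigree.animal[-n_cows:]
    pe = np.sqrt(sigma2_pe) * rng.standard_normal(n_cows)
    fixed = fixed_sd * rng.standard_normal(n_fixed_classes)
    rows = []
    for k, cow in enumerate(cows):
        i = pedigree.index_of(int(cow))
        cls = rng.integers(0, n_fixed_classes, size=n_weeks)
        e = np.sqrt(sigma2_e) * rng.standard_normal(n_weeks)
        for w in range(n_weeks):
            rows.append(
                {
                    "cow_id": int(cow),
                    "week_index": w + 1,
                    "eys_class": f"C{cls[w]}",
                    "lactation_week": w + 1,
                    "parity": "1",
                    "age_at_calving_months": 26.0,
                    "y": 10.0 + fixed[cls[w]] + a[i] + pe[k] + e[w],
                }
            )
    return pd.DataFrame(rows)


def simulate_bivariate_records(
    pedigree: Pedigree,
    n_cows: int,
    n_weeks: int,
    G: np.ndarray,
    PE: np.ndarray,
    E: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Two-trait repeatability simulation (traits ``y1``, ``y2``)."""
    rng = np.random.default_rng(seed)
    A = relationship_matrix(pedigree).A
    LA = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
    a = LA @ rng.standard_normal((len(A), 2)) @ np.linalg.cholesky(G).T
    cows = pedigree.animal[-n_cows:]
    pe = rng.standard_normal((n_cows, 2)) @ np.linalg.cholesky(PE).T
    rows = []
    for k, cow in enumerate(cows):
        i = pedigree.index_of(int(cow))
        e = rng.standard_normal((n_weeks, 2)) @ np.linalg.cholesky(E).T
        for w in range(n_weeks):
            y = a[i] + pe[k] + e[w]
            rows.append(
                {
                    "cow_id": int(cow),
                    "week_index": w + 1,
                    "eys_class": f"C{w % 4}",
                    "lactation_week": w + 1,
                    "parity": "1",
                    "age_at_calving_months": 26.0,
                    "y1": 5.0 + y[0],
                    "y2": -2.0 + y[1],
                }
            )
    return pd.DataFrame(rows)
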