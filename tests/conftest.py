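"""Shared fixtures and independent naive oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from kinoselect import InhibitionMatrix, SyntheticSpec, TargetSet, default_archetype_trio


# --- independent oracles: naive loop evaluations of the score formulas -----

def naive_score(target_values: list[float], offtarget_values: list[float]) -> dict:
    """Straight-from-the-definition evaluation of G, P_b, P_n, S.

    Deliberately naive (plain loops, no vectorization, no shared code with
    the package) so it can serve as an independent oracle.
    """
    if not target_values:
        raise ValueError("needs at least one measured target")
    product = 1.0
    for t in target_values:
        product *= t
    g = product ** (1.0 / len(target_values))
    m = len(offtarget_values)
    if m == 0:
        p_b = p_n = 0.0
    else:
        p_b = sum(offtarget_values) / m
        p_n = 0.0
        for i in offtarget_values:
            if i > 0:
                p_n += i * i / (i + g)
        p_n /= m
    return {"G": g, "P_b": p_b, "P_n": p_n, "S": g - p_b - p_n}


def naive_gini(values: list[float]) -> float:
    """Double-loop pairwise-difference Gini, the brute-force oracle."""
    n = len(values)
    mean = sum(values) / n
    if mean == 0.0:
        return 0.0
    total = 0.0
    for xi in values:
        for xj in values:
            total += abs(xi - xj)
    return total / (2 * n * n * mean)


# --- fixtures ---------------------------------------------------------------

@pytest.fixture
def single_target() -> TargetSet:
    return TargetSet(["AKT1"])


@pytest.fixture
def trio_spec() -> SyntheticSpec:
    """Noiseless 51-kinase panel with the three contrast archetypes."""
    return SyntheticSpec(n_kinases=51, archetypes=default_archetype_trio(), seed=7)


@pytest.fixture
def small_matrix() -> InhibitionMatrix:
    """Tiny hand-written matrix with one missing cell."""
    df = pd.DataFrame(
        {
            "AKT1": [80.0, 90.0, 0.0],
            "AKT2": [40.0, 10.0, 5.0],
            "MTOR": [20.0, np.nan, 0.0],
        },
        index=["cmpdA", "cmpdB", "cmpdC"],
    )
    return InhibitionMatrix(data=df, dataset_name="tiny")


@pytest.fixture
def matrix_csv(tmp_path):
    """A well-formed 3x4 CSV file on disk."""
    path = tmp_path / "screen.csv"
    path.write_text(
        "compound,AKT1,AKT2,MTOR,SRC\n"
        "c1,80,40,20,0\n"
        "c2,90,NA,10,55\n"
        "c3,0,5,ND,100\n"
    )
    return path


def random_row(rng: np.random.Generator, n_kinases: int) -> pd.Series:
    """Random percent-inhibition row with occasional zeros and missing cells."""
    values = rng.uniform(0.0, 100.0, size=n_kinases)
    values[rng.random(n_kinases) < 0.15] = 0.0
    values[rng.random(n_kinases) < 0.15] = np.nan
    return pd.Series(values, index=[f"K{i}" for i in range(n_kinases)])
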