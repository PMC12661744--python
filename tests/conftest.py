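"""Shared fixtures: tiny hand-built networks and reduced MCMC settings."""

from pathlib import Path

import pandas as pd
import pytest

from nmasplit import MCMCSettings, NMADataset

REFERENCE_DIR = Path(__file__).parent / "reference"


def make_dataset(rows, **kwargs) -> NMADataset:
    """Build an NMADataset from (study, treatment, events, n) tuples."""
    df = pd.DataFrame(
        rows, columns=["study", "treatment", "events", "sample_size"]
    )
    return NMADataset(df, **kwargs)


@pytest.fixture(scope="session")
def triangle_dataset() -> NMADataset:
    """Triangle A/B/C with two two-arm studies per edge (all splittable)."""
    rows = []
    for i, (a, b) in enumerate([("A", "B"), ("A", "C"), ("B", "C")]):
        for j in range(2):
            s = f"{a}{b}{j}"
            rows += [(s, a, 30 + 2 * i + j, 100), (s, b, 35 + i, 100)]
    return make_dataset(rows)


@pytest.fixture(scope="session")
def star_dataset() -> NMADataset:
    """Star A-B, A-C, A-D: no closed loop, nothing splittable."""
    rows = []
    for t in "BCD":
        rows += [(f"A{t}", "A", 30, 100), (f"A{t}", t, 40, 100)]
    return make_dataset(rows)


@pytest.fixture(scope="session")
def multiarm_plus_edge_dataset() -> NMADataset:
    """One three-arm A/B/C study plus one independent two-arm A-B study."""
    return make_dataset(
        [
            ("m1", "A", 30, 100), ("m1", "B", 40, 100), ("m1", "C", 35, 100),
            ("d1", "A", 28, 100), ("d1", "B", 42, 100),
        ]
    )


@pytest.fixture(scope="session")
def reference_dataset() -> NMADataset:
    """The 6-study triangle used for the frozen JAGS cross-check."""
    from nmasplit import read_long_format

    return read_long_format(REFERENCE_DIR / "fixture_triangle.csv")


@pytest.fixture(scope="session")
def quick_mcmc() -> MCMCSettings:
    """Reduced chain geometry for fast, still-converging unit-test fits."""
    return MCMCSettings(n_chains=3, n_iter=4000, burn_in=1000, thin=5, seed=123)
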