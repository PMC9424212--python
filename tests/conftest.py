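import numpy as np
import pytest

from pcaudit.colors import CANONICAL_COLORS, CohortConfig, ColorSpec, Dataset, generate_cohort


def color(name: str, noise_sd: float = 0.01) -> ColorSpec:
    return ColorSpec(name, CANONICAL_COLORS[name], noise_sd=noise_sd)


def simplex_cohort(n: int, noise_sd: float = 0.01, seed: int = 0) -> CohortConfig:
    """Red/Green/Blue/Black, n samples each."""
    members = tuple((color(name, noise_sd), n) for name in ("Red", "Green", "Blue", "Black"))
    return CohortConfig(members=members, seed=seed)


@pytest.fixture
def noiseless_simplex() -> Dataset:
    """The exact simplex: rows e1, e2, e3, 0."""
    return Dataset(
        values=np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]]),
        sample_labels=np.array(["Red", "Green", "Blue", "Black"], dtype=object),
        feature_ids=["R", "G", "B"],
        feature_class=["color-component"] * 3,
    )


@pytest.fixture
def noisy_simplex() -> Dataset:
    return generate_cohort(simplex_cohort(1, 0.01, seed=0))


@pytest.fixture
def separated_cohort() -> Dataset:
    """Three well-separated colours, 30 samples each (noise << separation)."""
    return generate_cohort(
        CohortConfig(
            members=tuple((color(n, 0.01), 30) for n in ("Red", "Green", "Blue")),
            seed=7,
        )
    )


def random_dataset(rng: np.random.Generator, n: int, p: int) -> Dataset:
    return Dataset(
        values=rng.normal(size=(n, p)),
        sample_labels=np.array([f"pop{i % 3}" for i in range(n)], dtype=object),
        feature_ids=[f"f{j}" for j in range(p)],
        feature_class=["color-component"] * p,
    )
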