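import numpy as np
import pytest

from cryoactin.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-design cohort (4 conditions x 3 times x 3 x 15 cells), reused
    across tests that only read it."""
    return generate_cohort(GeneratorConfig(), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def grid_filament_set(n_rows=6, n_cols=5, seed=7, spacing=(14.0, 12.0),
                      length_range=(6.0, 11.0), width_range=(0.3, 0.55)):
    """Disjoint straight filaments on a grid layout, for render/extract tests."""
    from cryoactin.metrics import FilamentSet

    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    xs, ys = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            xs.append((c - (n_cols - 1) / 2) * spacing[0])
            ys.append((r - (n_rows - 1) / 2) * spacing[1])
    return FilamentSet(
        lengths_um=rng.uniform(*length_range, n),
        widths_um=rng.uniform(*width_range, n),
        thetas_deg=rng.uniform(0, 180, n),
        x_um=np.array(xs), y_um=np.array(ys),
    )
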