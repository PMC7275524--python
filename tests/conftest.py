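import numpy as np
import pytest

from compbdt import AnalysisConfig, PairedCounts, validate_counts

# Weiner et al. (1979) coronary artery disease study: exercise test (Test 1)
# and chest-pain history (Test 2) against coronary angiography, n = 871.
WEINER_CELLS = (473, 29, 81, 25, 22, 46, 44, 151)


@pytest.fixture(scope="session")
def weiner() -> PairedCounts:
    return validate_counts(*WEINER_CELLS)


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig(alpha=0.05, seed=1, reps=10_000)


def random_tables(rng: np.random.Generator, n_tables: int,
                  low: int = 0, high: int = 30) -> list[PairedCounts]:
    """Fuzzed valid tables: uniform cells with non-empty groups."""
    tables = []
    while len(tables) < n_tables:
        cells = rng.integers(low, high + 1, size=8)
        if cells[:4].sum() == 0 or cells[4:].sum() == 0:
            continue
        tables.append(PairedCounts(*[int(x) for x in cells]))
    return tables
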