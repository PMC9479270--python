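import numpy as np
import pandas as pd
import pytest

from lncnet.io import load_reversal_lncrna_table
from lncnet.synthetic import ExpressionStudy, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def reversal_table():
    """The packaged 33-row reversed-lncRNA reference table."""
    return load_reversal_lncrna_table()


@pytest.fixture(scope="session")
def small_config():
    """A fast study: 1 key lncRNA family, a handful of decoys."""
    return SimulationConfig(n_lncrna=40, n_mrna=200, n_reversal_lncrna=3,
                            n_reversal_mrna=5, targets_per_lncrna=4,
                            low_intensity_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def build_study(matrix_rows: dict[str, list[float]],
                groups: tuple[str, ...] = ("Control", "CIA", "BZXD"),
                n_rep: int = 4,
                biotypes: dict[str, str] | None = None,
                lengths: dict[str, int] | None = None) -> ExpressionStudy:
    """Construct a toy study from explicit per-transcript intensity rows."""
    n_samples = len(groups) * n_rep
    sample_ids = [f"{g}_{r+1}" for g in groups for r in range(n_rep)]
    matrix = pd.DataFrame(matrix_rows, index=sample_ids).T
    matrix.index.name = "transcript_id"
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": [g for g in groups for _ in range(n_rep)],
        "replicate": [r + 1 for _ in groups for r in range(n_rep)],
    })
    ids = list(matrix_rows)
    annotation = pd.DataFrame({
        "biotype": [(biotypes or {}).get(t, "mRNA") for t in ids],
        "chromosome": ["chr1"] * len(ids),
        "strand": ["+"] * len(ids),
        "length_nt": [(lengths or {}).get(t, 1000) for t in ids],
        "relationship": ["Intergenic"] * len(ids),
    }, index=pd.Index(ids, name="transcript_id"))
    assert matrix.shape == (len(ids), n_samples)
    return ExpressionStudy(matrix=matrix, samples=samples,
                           annotation=annotation, group_order=tuple(groups))


@pytest.fixture
def toy_study():
    """Two groups' worth of simple deterministic intensities, 3 groups x 4."""
    rng = np.random.default_rng(5)
    rows = {f"T{i}": (2.0 ** rng.normal(10, 1, 12)).tolist() for i in range(6)}
    return build_study(rows)
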