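import numpy as np
import pandas as pd
import pytest

from ferrolimit.datamodel_io import ChipMeta, ExpressionMatrix
from ferrolimit.synthetic_data import SimulationConfig


def make_matrix(values: dict[str, list[float]], chips: list[tuple]) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {chip_id: column} plus
    (chip_id, treatment, day, biological_replicate) tuples."""
    n = len(next(iter(values.values())))
    genes = [f"g{i}" for i in range(1, n + 1)]
    df = pd.DataFrame(values, index=genes)
    return ExpressionMatrix(df, [ChipMeta(*c) for c in chips])


@pytest.fixture
def six_chip_day18():
    """3 iron-limited + 3 iron-replete chips, one day."""
    def build(limited_rows, replete_rows):
        limited = np.asarray(limited_rows, dtype=float)
        replete = np.asarray(replete_rows, dtype=float)
        values = {}
        chips = []
        for r in range(3):
            cid = f"lim_r{r+1}"
            values[cid] = limited[:, r]
            chips.append((cid, "iron_limited", 18, r + 1))
        for r in range(3):
            cid = f"rep_r{r+1}"
            values[cid] = replete[:, r]
            chips.append((cid, "iron_replete", 18, r + 1))
        return make_matrix(values, chips)
    return build


@pytest.fixture
def noise_free_config():
    """Deterministic study configuration: every stochastic knob off."""
    return SimulationConfig(
        n_genes=300,
        n_proteins=40,
        seed=7,
        noise_sd=0.0,
        protein_fold_sd=0.0,
        replicate_scale_sd=0.0,
        detected_fraction=1.0,
        ppm_jitter_sd=0.0,
        net_jitter_sd=0.0,
        decoy_fraction=0.0,
    )
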