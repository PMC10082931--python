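import numpy as np
import pandas as pd
import pytest

import ponet
from ponet.expression import _sample_columns


def make_expression(values, stages, fraction, n_rep, genes=None):
    """Build an ExpressionMatrix from a genes x (stages*reps) array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = _sample_columns(stages, fraction, n_rep)
    return ponet.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), stages)


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted dataset shared by read-only tests."""
    cfg = ponet.SimConfig(
        n_genes=150, n_de_up=25, n_de_down=12, n_regulators=5,
        targets_per_regulator=2, n_modules=2, module_size=10, seed=11,
    )
    total, polys, truth = ponet.simulate_dataset(cfg)
    return cfg, total, polys, truth


@pytest.fixture(scope="session")
def small_po(small_sim):
    _, total, polys, _ = small_sim
    t, p, _ = ponet.apply_noise_filter(total, polys)
    return ponet.compute_po(t, p)


@pytest.fixture(scope="session")
def sharp_pwm():
    """A near-deterministic 8-mer motif."""
    cols = []
    for b in "TGACGTCA":
        col = np.full(4, 0.01)
        col["ACGT".index(b)] = 0.97
        cols.append(col)
    return ponet.PWM("m1", np.array(cols).T)


@pytest.fixture(scope="session")
def transcript_set(small_sim, sharp_pwm):
    cfg, total, _, truth = small_sim
    tcfg = ponet.TranscriptConfig(seed=5)
    records = ponet.simulate_transcript_set(truth, sharp_pwm, list(total.genes), tcfg)
    return records, truth
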