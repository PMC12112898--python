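import numpy as np
import pandas as pd
import pytest

from refstab import CtDesign, CtGeneSpec, CtTable
from refstab.io import CT_COLUMNS


def make_ct_table(rows):
    """rows: (sample, gene, ct, tech_rep, bio_rep, strain, condition, timepoint)"""
    return CtTable(pd.DataFrame(rows, columns=list(CT_COLUMNS)))


@pytest.fixture
def tiny_ct_table():
    """Two samples x three genes, technical duplicates, one cell each strain."""
    rows = []
    for s, strain in (("S1", "A"), ("S2", "B")):
        for g, base in (("g1", 20.0), ("g2", 22.0), ("g3", 25.0)):
            for t in (1, 2):
                ct = base + (0.2 if s == "S2" else 0.0) + 0.1 * (t - 1)
                rows.append((s, g, ct, t, 1, strain, "glucose", "early"))
    return make_ct_table(rows)


@pytest.fixture
def random_ct_matrix():
    """Seeded 4-gene x 6-sample aggregated Ct matrix."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(18, 30, size=(4, 6))
    return pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(1, 5)],
        columns=[f"s{j}" for j in range(1, 7)],
    )


def random_ct_frames(n_matrices, seed=0, genes=(3, 6), samples=(4, 12)):
    """Stream of seeded random Ct matrices for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    for _ in range(n_matrices):
        g = int(rng.integers(genes[0], genes[1] + 1))
        s = int(rng.integers(samples[0], samples[1] + 1))
        vals = rng.uniform(15, 35, size=(g, s))
        yield pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(g)],
            columns=[f"s{j}" for j in range(s)],
        )


@pytest.fixture
def study_design():
    return CtDesign()


@pytest.fixture
def flat_panel():
    """Noise-free 3-gene panel."""
    return [
        CtGeneSpec("a", base_ct=20.0),
        CtGeneSpec("b", base_ct=22.0),
        CtGeneSpec("c", base_ct=24.0),
    ]
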