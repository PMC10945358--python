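import numpy as np
import pandas as pd
import pytest

from peatnet.otu import OtuTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_table(counts, taxa=None, samples=None, taxonomy=None) -> OtuTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"T{i}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=taxa, columns=samples)
    tax = pd.Series(taxonomy, index=taxa) if taxonomy is not None else None
    return OtuTable(frame, tax)


@pytest.fixture
def table_factory():
    return make_table


def lognormal_counts(rng, p, n, depth=5000, corr_pairs=()):
    """Counts from an independent log-normal basis, optionally with planted
    pairwise basis correlations, pushed through multinomial sampling."""
    z = rng.normal(0.0, 1.0, (p, n))
    for i, j, r in corr_pairs:
        z[j] = r * z[i] + np.sqrt(1.0 - r * r) * z[j]
    logs = z + rng.normal(0.0, 1.0, p)[:, None]
    w = np.exp(logs)
    frac = w / w.sum(axis=0)
    return np.column_stack([rng.multinomial(depth, frac[:, k]) for k in range(n)])
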