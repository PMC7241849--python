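import numpy as np
import pandas as pd
import pytest

import microvoe as mv


@pytest.fixture(scope="session")
def small_design():
    return mv.StudyDesign(n_subjects=60, samples_per_subject=(2, 4), seed=7)


@pytest.fixture(scope="session")
def small_metadata(small_design):
    return mv.generate_metadata(small_design)


@pytest.fixture(scope="session")
def blocked_signal():
    return mv.SignalSpec(
        blocks=[mv.Block(f"b{i:02d}", 5, 0.95) for i in range(8)],
        n_background_genes=10,
    )


@pytest.fixture(scope="session")
def gene_data(small_design, blocked_signal, small_metadata):
    genes, truth = mv.generate_gene_abundances(small_design, blocked_signal, small_metadata)
    return genes, truth


def two_block_matrix(seed, n_samples=40, n_per_block=5, rho=0.98):
    """Planted two-block gene matrix with near-zero cross-block correlation."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(0, 1, n_samples)
    f2 = rng.normal(0, 1, n_samples)
    sd = np.sqrt((1 - rho) / rho)
    cols = {}
    for g in range(n_per_block):
        cols[f"a{g}"] = f1 + sd * rng.normal(0, 1, n_samples)
    for g in range(n_per_block):
        cols[f"b{g}"] = f2 + sd * rng.normal(0, 1, n_samples)
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n_samples)])


def threshold_cluster_oracle(table, min_corr=0.9):
    """Brute-force oracle: connected components of the r >= min_corr graph,
    singletons dropped.  Independent of the canopy implementation."""
    corr = np.corrcoef(table.to_numpy(float).T)
    n = corr.shape[0]
    adj = corr >= min_corr
    labels = -np.ones(n, dtype=int)
    comp = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = comp
        while stack:
            j = stack.pop()
            for k2 in range(n):
                if adj[j, k2] and labels[k2] < 0:
                    labels[k2] = comp
                    stack.append(k2)
        comp += 1
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(table.columns[i])
    return sorted(frozenset(g) for g in groups.values() if len(g) >= 2)
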