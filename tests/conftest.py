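import warnings

import numpy as np
import pandas as pd
import pytest

import tomoloc as tl


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples with exact hand-computable size factors."""
    return pd.DataFrame(
        [[1, 2], [2, 4], [4, 8]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def null_scm():
    """Small all-uniform dataset (one stage, three replicate oocytes)."""
    cfg = tl.simulate.null_uniform_config(seed=0, n_genes=150)
    scm, truth = tl.generate_dataset(cfg)
    return scm, truth


@pytest.fixture(scope="session")
def temporal_bundle():
    """Mid-sized dataset with all temporal groups, analyzed once.

    Returns (scm, truth, stage profiles, replicate percentages, genes
    flagged DLT in >= 1 stage).
    """
    cfg = tl.simulate.temporal_benchmark_config(seed=1, n_per_group=25, n_background=250)
    scm, truth = tl.generate_dataset(cfg)
    factors = tl.size_factors(scm.counts)
    norm = tl.normalize(scm.counts, factors)
    profiles = tl.stage_profiles(norm, scm.samples)
    reps = tl.replicate_percentages(norm, scm.samples)
    dlt_any = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for stage in scm.stage_order:
            res = tl.detect_dlts(
                scm, "within_stage", stage=stage, precomputed_factors=factors
            )
            dlt_any |= set(res.query("is_dlt")["gene_id"])
    return scm, truth, profiles, reps, sorted(dlt_any)


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle (plain loops, no vectorization)."""
    n_genes, n_samples = counts.shape
    eligible = []
    for g in range(n_genes):
        if all(counts[g, j] > 0 for j in range(n_samples)):
            eligible.append(g)
    factors = []
    for j in range(n_samples):
        ratios = []
        for g in eligible:
            prod = 1.0
            for k in range(n_samples):
                prod *= float(counts[g, k])
            geomean = prod ** (1.0 / n_samples)
            ratios.append(counts[g, j] / geomean)
        ratios.sort()
        m = len(ratios)
        if m == 0:
            raise ValueError("no eligible gene")
        mid = m // 2
        factors.append(
            ratios[mid] if m % 2 else 0.5 * (ratios[mid - 1] + ratios[mid])
        )
    return np.array(factors)
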