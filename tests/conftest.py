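import numpy as np
import pytest

import aimsel


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated populations, mostly informative SNPs; cheap."""
    cfg = aimsel.SimulationConfig(
        populations=[
            aimsel.PopulationSpec("POP_A", 40, 0),
            aimsel.PopulationSpec("POP_B", 40, 1),
            aimsel.PopulationSpec("POP_C", 40, 2),
        ],
        n_snps=60,
        n_aims=30,
        aim_divergence=0.6,
        neutral_divergence=0.01,
        missing_rate=0.0,
        seed=11,
        aim_mode="cluster",
    )
    return aimsel.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The HapMap-like synthetic benchmark: nine groups at published training
    sizes, 5000 SNPs with 300 planted cluster-pattern AIMs."""
    cfg = aimsel.benchmark_config(n_snps=5000, n_aims=300, seed=1)
    cfg.aim_mode = "cluster"
    return aimsel.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark_dataset):
    """One full pipeline run on the benchmark (shared across acceptance tests)."""
    ds = benchmark_dataset
    train_idx, test_idx = aimsel.stratified_split(ds.labels, aimsel.SplitSpec(0.15, 1))
    cfg = aimsel.PipelineConfig(ifs_step=10, ifs_max_i=100)
    result = aimsel.run_pipeline(
        ds.genotypes.values, ds.labels, train_idx, test_idx, cfg, seed=1
    )
    return ds, train_idx, test_idx, result


def naive_cramers_v(O: np.ndarray) -> tuple[float, float]:
    """Independent double-loop oracle for chi-squared and Cramer's V."""
    O = np.asarray(O, dtype=float)
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    k, r = O.shape
    N = O.sum()
    n_i = O.sum(axis=1)
    m_j = O.sum(axis=0)
    chi2 = 0.0
    for i in range(k):
        for j in range(r):
            E = n_i[i] * m_j[j] / N
            chi2 += (O[i, j] - E) ** 2 / E
    d = min(k - 1, r - 1)
    v = np.sqrt(chi2 / N / d) if d >= 1 else 0.0
    return chi2, v


def naive_mi(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """Brute-force plug-in mutual information over explicit cells."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    total = 0.0
    for a in set(x.tolist()):
        for b in set(y.tolist()):
            pab = np.mean((x == a) & (y == b))
            if pab > 0:
                pa = np.mean(x == a)
                pb = np.mean(y == b)
                total += pab * np.log(pab / (pa * pb))
    return total / np.log(base)


def naive_mrmr_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Exhaustive step-wise evaluation of the mRMR objective (oracle)."""
    m = X.shape[1]
    relevance = [naive_mi(X[:, j], y) for j in range(m)]
    selected: list[int] = []
    remaining = list(range(m))
    while remaining:
        best, best_score = None, -np.inf
        for j in remaining:
            if selected:
                red = np.mean([naive_mi(X[:, j], X[:, s]) for s in selected])
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected
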