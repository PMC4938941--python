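import numpy as np
import pandas as pd
import pytest

from oxbs5hmc import SynthConfig, compute_hydroxy, generate_annotation, generate_paired_betas


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        seed=3,
        n_probes=800,
        n_hyper5hmc=15,
        n_hypo5hmc=15,
        n_hyper5mc=15,
        n_hypo5mc=15,
        chrom_sizes={"chr1": 2_000_000},
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(annotation, paired betas, truth, hydroxy set) for a small synthetic cohort."""
    ann = generate_annotation(small_config)
    paired, truth = generate_paired_betas(small_config, ann.probes)
    hydro = compute_hydroxy(paired)
    return ann, paired, truth, hydro


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def brute_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of rank assignments
    (no ties assumed): doubled minimal tail of the rank-sum null, capped at 1."""
    from itertools import combinations

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    w_obs = ranks[:n].sum()
    dist = [sum(c) for c in combinations(range(1, n + m + 1), n)]
    dist = np.array(dist)
    lo = (dist <= w_obs).mean()
    hi = (dist >= w_obs).mean()
    return min(1.0, 2 * min(lo, hi))


def brute_bh(p):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = min(1.0, running)
    return q


def brute_fisher_two_sided(table):
    """Two-sided Fisher p by enumerating all tables with the observed margins:
    sum of hypergeometric probabilities <= the observed one."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    r1, c1, n_tot = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n_tot, r1, c1)
    total = 0.0
    for aa in range(max(0, c1 - (c + d)), min(r1, c1) + 1):
        pk = hypergeom.pmf(aa, n_tot, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def brute_cliffs(x, y):
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))
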