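"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the model definitions, separately
from the package code paths it checks: a vectorized 2-D grid search for the
spacer-loss likelihood, exhaustive spanning-tree enumeration, exhaustive
Mantel permutation, and the textbook two-level variance-component formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def grid_loglik(n_shared, int_a, int_b, k_a, k_b, t, rho):
    """Spacer-loss log-likelihood on numpy grids, from the class probabilities.

    p = exp(-t): an ancestral spacer survives both lineages with p^2, one
    with p(1-p) each, and is unobservable with (1-p)^2 — so each observed
    spacer is conditioned on observability, P = p^2 / (1 - (1-p)^2) shared
    and p(1-p) / (1 - (1-p)^2) per unique class. Leader-unique counts are
    Poisson(rho (1-p)) per lineage.
    """
    t = np.asarray(t, dtype=float)
    rho = np.asarray(rho, dtype=float)
    p = np.exp(-t)
    q = 1.0 - p
    lam = rho * q
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = 1.0 - q**2
        ll = n_shared * np.log(p**2 / obs)
        n_int = int_a + int_b
        if n_int:
            ll = ll + n_int * np.log(p * q / obs)
        for k in (k_a, k_b):
            pois = np.where(
                lam > 0,
                k * np.log(np.where(lam > 0, lam, 1.0)) - lam - math.lgamma(k + 1),
                np.where(k == 0, 0.0, -np.inf),
            )
            ll = ll + pois
    return np.where(np.isnan(ll), -np.inf, ll)


def grid_search_oisl(
    alignment, t_max=10.0, resolution=1e-4, rho_max=50.0
) -> tuple[float, float]:
    """Argmax of the pairwise likelihood over the bounded (t, rho) domain.

    Iteratively refined 2-D grid. The second axis is the Poisson mean
    ``lam = rho (1 - exp(-t))`` rather than rho itself: the likelihood is
    separable in (t, lam), so axis-aligned refinement cannot fall off the
    curved (t, rho) ridge. The rho bound maps to the constraint
    ``lam <= rho_max (1 - exp(-t))``, enforced by masking.
    """
    n_s = alignment.n_shared
    ia, ib = alignment.internal_unique_a, alignment.internal_unique_b
    ka, kb = alignment.leader_unique_a, alignment.leader_unique_b
    k = ka + kb
    t_lo, t_hi = 1e-9, t_max
    l_lo, l_hi = 0.0, float(rho_max)
    keep = 4
    while True:
        ts = np.linspace(t_lo, t_hi, 201)
        ls = np.linspace(l_lo, l_hi, 201) if k else np.array([0.0])
        T, L = np.meshgrid(ts, ls, indexing="ij")
        q = 1.0 - np.exp(-T)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(q > 0, L / np.where(q > 0, q, 1.0), 0.0)
        ll = grid_loglik(n_s, ia, ib, ka, kb, T, R)
        ll = np.where(R <= rho_max + 1e-12, ll, -np.inf)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        step_t = ts[1] - ts[0]
        if step_t <= resolution:
            qi = 1.0 - math.exp(-ts[i])
            return float(ts[i]), float(ls[j] / qi if qi > 0 else 0.0)
        t_lo = max(1e-9, ts[max(i - keep, 0)])
        t_hi = min(t_max, ts[min(i + keep, len(ts) - 1)])
        if k:
            l_lo = max(0.0, ls[max(j - keep, 0)])
            l_hi = max(ls[min(j + keep, len(ls) - 1)], l_lo + 1e-9)


def simulate_loss_classes(n_spacers, t, n_trials, rng):
    """Monte-Carlo fates of ancestral spacers in two lineages.

    Returns observed (both, one, neither) counts over all spacer-trials.
    """
    p = math.exp(-t)
    a = rng.random((n_trials, n_spacers)) < p
    b = rng.random((n_trials, n_spacers)) < p
    both = int((a & b).sum())
    one = int((a ^ b).sum())
    neither = int((~a & ~b).sum())
    return both, one, neither


def brute_force_mst_weight(values: np.ndarray) -> float:
    """Minimum total weight over all spanning trees (n <= 7)."""
    n = values.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(values[u, v] for u, v in combo))
    return best


def exhaustive_mantel(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Pearson r of off-diagonal pairs and its exact permutation p-value."""
    n = v1.shape[0]
    iu = np.triu_indices(n, k=1)

    def r_of(perm):
        b = v2[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(v1[iu], b)[0, 1])

    r_obs = r_of(np.arange(n))
    rs = [r_of(np.array(p)) for p in itertools.permutations(range(n))]
    p = sum(r >= r_obs - 1e-12 for r in rs) / len(rs)
    return r_obs, p


def two_level_components(d2: np.ndarray, groups: np.ndarray):
    """Textbook two-level variance components from squared distances.

    SS(T) = sum_{i<j} d2 / N; SS(W) = sum_g sum_{i<j in g} d2 / n_g;
    sigma_w = MS(W); sigma_a = (MS(A) - sigma_w) / n_c with
    n_c = (N - sum n_g^2 / N) / (G - 1).
    """
    N = len(groups)
    labels = sorted(set(groups))
    G = len(labels)
    ss_t = sum(d2[i, j] for i in range(N) for j in range(i + 1, N)) / N
    ss_w = 0.0
    sizes = []
    for g in labels:
        idx = [i for i in range(N) if groups[i] == g]
        sizes.append(len(idx))
        ss_w += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]
        ) / len(idx)
    ss_a = ss_t - ss_w
    ms_a = ss_a / (G - 1)
    ms_w = ss_w / (N - G)
    n_c = (N - sum(s**2 for s in sizes) / N) / (G - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - sigma_w) / n_c
    return sigma_a, sigma_w


def random_alignment(rng):
    """A random spacer-class configuration for oracle comparisons."""
    from crisprtyper.arrays import PairAlignment

    n_s = int(rng.integers(1, 30))
    return PairAlignment(
        shared=tuple(range(1, n_s + 1)),
        internal_unique_a=int(rng.integers(0, 10)),
        internal_unique_b=int(rng.integers(0, 10)),
        leader_unique_a=int(rng.integers(0, 5)),
        leader_unique_b=int(rng.integers(0, 5)),
    )


def random_distance_matrix(rng, n, scale=1.0):
    """Random symmetric non-negative matrix with zero diagonal (metric-free)."""
    a = rng.random((n, n)) * scale
    m = (a + a.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def random_additive_matrix(rng, n):
    """Distance matrix that is exactly additive on a random binary tree.

    Built by successive random joins with positive branch lengths; returns
    (labels, matrix). NJ is consistent on such matrices.
    """
    labels = [f"T{i}" for i in range(n)]
    # leaf-to-leaf distances built from a random topology
    nodes = [{lab: 0.0 for lab in [labels[i]]} for i in range(n)]
    dist = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li = float(rng.uniform(0.05, 1.0))
        lj = float(rng.uniform(0.05, 1.0))
        a, b = nodes[i], nodes[j]
        for ta, da in a.items():
            for tb, db in b.items():
                dist[frozenset((ta, tb))] = da + li + db + lj
        merged = {t: d + li for t, d in a.items()}
        merged.update({t: d + lj for t, d in b.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist[frozenset((labels[i], labels[j]))]
    return labels, m
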