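"""Hierarchical population structure from haplotype distances.

Distance-based AMOVA partitions the variance of inter-individual squared
distances across nested strata (region > habitat > site > host > section >
replicate). Each sequencing read is treated as one individual (one symbiont
cell). Sums of squares follow the classic form ``SS(group) = sum_{i<j in
group} d_ij^2 / n_group``; variance components are obtained by equating the
observed sums of squares to their expectations under the nested
random-effects model, with coefficients computed from the (possibly
unbalanced) group sizes — on two levels this reduces to Excoffier's n_c.
Phi-statistics are ratios of components and their significance is assessed
by permutation: to test level k, whole level-(k+1) units are permuted among
level-k groups within their level-(k-1) parents (individuals when k is the
innermost grouping).

Distance matrices that are not Euclidean-embeddable (phylogenetic distances
often are not) should first be passed through :func:`lingoes_correct`, which
adds the smallest constant to the squared distances that makes the Gower
eigenvalues non-negative.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesign,
    Disconnected,
    PositionOutOfRange,
    TooFewEntries,
    UndefinedCorrelation,
)
from .oisl import DistanceMatrix

__all__ = [
    "SampleHierarchy",
    "AmovaResult",
    "FstMatrix",
    "lingoes_correct",
    "amova",
    "pairwise_fst",
    "mantel",
    "min_spanning_network",
    "count_gene_haplotypes",
]

#: Canonical nesting order, outermost first.
DEFAULT_LEVELS = ("region", "habitat", "site", "host", "section", "replicate")


class SampleHierarchy:
    """Read-level records with their nested stratum labels and haplotype.

    One row per read (individual). ``levels`` lists the stratum columns
    outermost-first; labels must be strictly nested (each inner label maps
    to exactly one outer label), which implies globally unique labels per
    level.
    """

    def __init__(self, df: pd.DataFrame, levels: Sequence[str] = DEFAULT_LEVELS):
        levels = [lv for lv in levels if lv in df.columns]
        if not levels:
            raise ValueError("no hierarchy level columns present")
        if "haplotype_id" not in df.columns:
            raise ValueError("missing haplotype_id column")
        if "count" in df.columns:
            df = df.loc[df.index.repeat(df["count"])].drop(columns="count")
        self.df = df.reset_index(drop=True)
        self.levels = list(levels)
        for outer, inner in zip(self.levels, self.levels[1:]):
            bad = self.df.groupby(inner)[outer].nunique()
            if (bad > 1).any():
                raise ValueError(
                    f"level {inner!r} is not nested within {outer!r}: "
                    f"{list(bad[bad > 1].index)}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def haplotypes(self) -> list[str]:
        return sorted(self.df["haplotype_id"].astype(str).unique())

    def to_tsv(self, path: str | Path) -> None:
        cols = self.levels + ["haplotype_id"]
        out = self.df.groupby(cols, sort=True).size().rename("count").reset_index()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, levels: Sequence[str] = DEFAULT_LEVELS):
        return cls(pd.read_csv(path, sep="\t", dtype=str).assign(
            count=lambda t: t["count"].astype(int)
        ), levels)


# ---------------------------------------------------------------------------
# Lingoes correction
# ---------------------------------------------------------------------------

def lingoes_correct(d: DistanceMatrix, tol: float = 1e-9) -> DistanceMatrix:
    """Make a distance matrix Euclidean-embeddable by the Lingoes constant.

    If the Gower-centred matrix of ``-d**2 / 2`` has smallest eigenvalue
    ``-c < 0``, the corrected squared distances are ``d'**2 = d**2 + 2c``
    off-diagonal; an already-Euclidean matrix is returned unchanged.
    """
    D = d.values
    n = len(d)
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    lmin = float(np.linalg.eigvalsh(G)[0])
    if lmin >= -tol:
        return d
    c = -lmin
    D2 = D**2 + 2.0 * c
    np.fill_diagonal(D2, 0.0)
    return DistanceMatrix(d.labels, np.sqrt(D2))


# ---------------------------------------------------------------------------
# AMOVA core
# ---------------------------------------------------------------------------

def _within_group_ss(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """``sum_g sum_{i<j in g} d2_ij / n_g`` via one-hot quadratic forms."""
    Z = np.zeros((len(codes), n_groups))
    Z[np.arange(len(codes)), codes] = 1.0
    diag = np.einsum("ig,ij,jg->g", Z, D2, Z, optimize=True)
    sizes = Z.sum(axis=0)
    return float((diag / (2.0 * sizes)).sum())


def _ems_coefficients(codes_list: list[np.ndarray], N: int) -> np.ndarray:
    """Coefficient of each variance component in E[W_l], l = 0..m.

    Rows l = 0..m index the partitions (0 = grand total); columns are
    sigma^2_1..sigma^2_m then sigma^2_within. Derived from
    ``E[d2_ij] = 2 sigma_w^2 + 2 sum_k sigma_k^2 [i, j differ at level k]``.
    """
    m = len(codes_list)
    coefW = np.zeros((m + 1, m + 1))
    for l in range(m + 1):
        if l == 0:
            gl = np.zeros(N, dtype=int)
            szl = np.array([float(N)])
        else:
            gl = codes_list[l - 1]
            szl = np.bincount(gl).astype(float)
        coefW[l, m] = N - len(szl)
        for k in range(l + 1, m + 1):
            gk = codes_list[k - 1]
            szk = np.bincount(gk).astype(float)
            parent = np.zeros(len(szk), dtype=int)
            parent[gk] = gl  # consistent because levels are nested
            S = np.bincount(parent, weights=szk**2, minlength=len(szl))
            coefW[l, k - 1] = N - float((S / szl).sum())
    return coefW


def _components(
    D2: np.ndarray, codes_list: list[np.ndarray], W: list[float] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sums of squares, degrees of freedom and variance components.

    Returns ``(SS, df, sigma)``, each of length m+1 (levels then within).
    """
    N = D2.shape[0]
    m = len(codes_list)
    if W is None:
        W = [float(D2.sum()) / (2.0 * N)] + [
            _within_group_ss(D2, c, int(c.max()) + 1) for c in codes_list
        ]
    n_groups = [1] + [int(c.max()) + 1 for c in codes_list]
    SS = np.array(
        [W[a - 1] - W[a] for a in range(1, m + 1)] + [W[m]]
    )
    df = np.array(
        [n_groups[a] - n_groups[a - 1] for a in range(1, m + 1)] + [N - n_groups[m]]
    )
    coefW = _ems_coefficients(codes_list, N)
    C = np.vstack([coefW[a - 1] - coefW[a] for a in range(1, m + 1)] + [coefW[m]])
    sigma = np.linalg.solve(C, SS)
    return SS, df, sigma


@dataclass
class AmovaResult:
    """Per-level AMOVA table plus the Phi-statistics."""

    table: pd.DataFrame  # rows: levels, Within, Total
    phi: dict[str, float]

    @property
    def phi_total(self) -> float:
        return self.phi["total"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="level")


def _individual_d2(
    h: SampleHierarchy, d: DistanceMatrix | None
) -> np.ndarray:
    haps = h.df["haplotype_id"].astype(str).to_numpy()
    if d is None:
        # haplotype-identity distance: 1 between distinct haplotypes
        return (haps[:, None] != haps[None, :]).astype(float)
    idx = np.array([d.labels.index(x) for x in haps])
    return (d.values**2)[np.ix_(idx, idx)]


def _permute_level(
    rng: np.random.Generator,
    codes_list: list[np.ndarray],
    k: int,
) -> np.ndarray:
    """Permuted level-k codes: level-(k+1) units shuffled within parents."""
    m = len(codes_list)
    N = len(codes_list[0])
    target = codes_list[k - 1]
    parent = codes_list[k - 2] if k >= 2 else np.zeros(N, dtype=int)
    unit = codes_list[k] if k < m else np.arange(N)
    n_units = int(unit.max()) + 1
    unit_target = np.zeros(n_units, dtype=int)
    unit_target[unit] = target
    unit_parent = np.zeros(n_units, dtype=int)
    unit_parent[unit] = parent
    new_target = unit_target.copy()
    for par in np.unique(unit_parent):
        members = np.flatnonzero(unit_parent == par)
        new_target[members] = unit_target[members][rng.permutation(len(members))]
    return new_target[unit]


def amova(
    h: SampleHierarchy,
    d: DistanceMatrix | None,
    levels: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance.

    Parameters
    ----------
    h:
        Read-level hierarchy; every haplotype_id must appear in ``d``.
    d:
        Haplotype distance matrix (``None`` for 0/1 haplotype identity).
        For phylogenetic distances apply :func:`lingoes_correct` first so
        squared distances behave as Euclidean ones.
    levels:
        Nesting to test, outermost first; defaults to every level of ``h``
        that has more groups than the level above it.
    n_perm, seed:
        Permutation test size and mandatory seed when ``n_perm > 0``.

    Negative variance components are reported as-is, never truncated.
    """
    if levels is None:
        levels = h.levels
    levels = list(levels)
    df_h = h.df
    N = len(df_h)
    codes_list = [pd.factorize(df_h[lv])[0] for lv in levels]
    n_groups = [int(c.max()) + 1 for c in codes_list]
    for lv, g, g_prev in zip(levels, n_groups, [1] + n_groups[:-1]):
        if g - g_prev < 1:
            raise DegenerateDesign(
                f"level {lv!r} has {g} group(s), needs more than the "
                f"{g_prev} of the enclosing level"
            )
    if N - n_groups[-1] < 1:
        raise DegenerateDesign("no residual degrees of freedom within groups")

    D2 = _individual_d2(h, d)
    W = [float(D2.sum()) / (2.0 * N)] + [
        _within_group_ss(D2, c, g) for c, g in zip(codes_list, n_groups)
    ]
    SS, dof, sigma = _components(D2, codes_list, W)
    m = len(levels)
    total_sigma = float(sigma.sum())
    percent = 100.0 * sigma / total_sigma
    phi = {
        levels[a]: float(sigma[a] / sigma[a:].sum()) for a in range(m)
    }
    phi["total"] = float(sigma[:m].sum() / total_sigma)

    pvals = np.full(m, np.nan)
    if n_perm > 0:
        if seed is None:
            raise ValueError("a seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        for a in range(m):
            k = a + 1
            obs = sigma[a]
            hits = 0
            for _ in range(n_perm):
                perm_codes = list(codes_list)
                perm_codes[a] = _permute_level(rng, codes_list, k)
                W_perm = list(W)
                W_perm[k] = _within_group_ss(D2, perm_codes[a], n_groups[a])
                _, _, sig_p = _components(D2, perm_codes, W_perm)
                if sig_p[a] >= obs - 1e-12:
                    hits += 1
            pvals[a] = (hits + 1) / (n_perm + 1)

    ms = SS / dof
    rows = levels + ["Within", "Total"]
    table = pd.DataFrame(
        {
            "df": np.append(dof, dof.sum()),
            "SS": np.append(SS, SS.sum()),
            "MS": np.append(ms, SS.sum() / dof.sum()),
            "sigma": np.append(sigma, total_sigma),
            "percent": np.append(percent, 100.0),
            "phi": [phi[lv] for lv in levels] + [phi["total"], np.nan],
            "p_value": list(pvals) + [np.nan, np.nan],
        },
        index=rows,
    )
    return AmovaResult(table=table, phi=phi)


# ---------------------------------------------------------------------------
# Pairwise FST
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Pairwise population differentiation with permutation p-values."""

    labels: tuple[str, ...]
    values: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if np.any(self.values > 1 + 1e-9):
            raise ValueError("FST cannot exceed 1")


def _two_level_fst(D2: np.ndarray, codes: np.ndarray) -> float:
    _, _, sigma = _components(D2, [codes])
    total = sigma.sum()
    return float(sigma[0] / total) if total != 0 else 0.0


def pairwise_fst(
    h: SampleHierarchy,
    level: str,
    mode: str = "haplotype-frequency",
    d: DistanceMatrix | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> FstMatrix:
    """FST (or Phi-ST) between every pair of populations at one level.

    ``mode="haplotype-frequency"`` uses the 0/1 haplotype-identity distance
    (classic haplotype-frequency FST); ``mode="distance"`` uses the supplied
    haplotype distance matrix (Phi-ST). Each pairwise value is the
    among-population fraction of a two-level variance partition, with a
    p-value from permuting individuals between the two populations.
    """
    if mode == "distance":
        if d is None:
            raise ValueError("mode='distance' requires a distance matrix")
    elif mode == "haplotype-frequency":
        d = None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pops = sorted(h.df[level].astype(str).unique())
    if len(pops) < 2:
        raise DegenerateDesign(f"level {level!r} has fewer than two populations")
    sizes = h.df.groupby(level).size()
    small = sizes[sizes < 2]
    if len(small):
        raise DegenerateDesign(
            f"populations with fewer than two reads: {list(small.index)}"
        )
    D2_all = _individual_d2(h, d)
    pop_col = h.df[level].astype(str).to_numpy()
    n = len(pops)
    fst = np.zeros((n, n))
    pvals = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(i + 1, n):
            sel = np.flatnonzero((pop_col == pops[i]) | (pop_col == pops[j]))
            codes = (pop_col[sel] == pops[j]).astype(int)
            D2 = D2_all[np.ix_(sel, sel)]
            obs = _two_level_fst(D2, codes)
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0:
                hits = sum(
                    _two_level_fst(D2, rng.permutation(codes)) >= obs - 1e-12
                    for _ in range(n_perm)
                )
                pvals[i, j] = pvals[j, i] = (hits + 1) / (n_perm + 1)
            else:
                pvals[i, j] = pvals[j, i] = np.nan
    return FstMatrix(labels=tuple(pops), values=fst, pvalues=pvals)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _as_matrix(m) -> tuple[tuple[str, ...], np.ndarray, np.ndarray | None]:
    if isinstance(m, FstMatrix):
        return m.labels, m.values, m.pvalues
    if isinstance(m, DistanceMatrix):
        return m.labels, m.values, None
    raise TypeError(f"expected FstMatrix or DistanceMatrix, got {type(m)}")


def mantel(
    m1,
    m2,
    handling: str = "zero_nonsignificant",
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    exact_max: int = 6,
) -> tuple[float, float]:
    """Matrix correlation between two population-pair matrices.

    ``handling`` controls non-significant entries (permutation p > alpha in
    the matrix's own test): ``zero_nonsignificant`` sets them — and any
    negative differentiation values — to 0; ``exclude_nonsignificant``
    drops pairs non-significant in either matrix from the correlation.

    The p-value is one-sided (observed-or-larger r) from joint row/column
    permutations of the second matrix; for ``n <= exact_max`` populations
    all ``n!`` permutations are enumerated, so p is exact and the identity
    permutation guarantees ``p >= 1/n!``.
    """
    lab1, v1, p1 = _as_matrix(m1)
    lab2, v2, p2 = _as_matrix(m2)
    if set(lab1) != set(lab2):
        raise ValueError("matrices have different population labels")
    order = [lab2.index(x) for x in lab1]
    v2 = v2[np.ix_(order, order)]
    p2 = p2[np.ix_(order, order)] if p2 is not None else None
    n = len(lab1)
    iu = np.triu_indices(n, k=1)

    def prepare(v: np.ndarray, p: np.ndarray | None) -> np.ndarray:
        v = v.copy()
        if handling == "zero_nonsignificant":
            if p is not None:
                v[p > alpha] = 0.0
            np.fill_diagonal(v, 0.0)
            return np.maximum(v, 0.0)
        if handling == "exclude_nonsignificant":
            return v
        raise ValueError(f"unknown handling {handling!r}")

    w1, w2 = prepare(v1, p1), prepare(v2, p2)
    # per-matrix significance masks (travel with their matrix under permutation)
    exclude = handling == "exclude_nonsignificant"
    sig1 = (p1 <= alpha) if (exclude and p1 is not None) else np.ones((n, n), bool)
    sig2 = (p2 <= alpha) if (exclude and p2 is not None) else np.ones((n, n), bool)

    def corr(perm: np.ndarray) -> float | None:
        b = w2[np.ix_(perm, perm)][iu]
        mask = sig1[iu] & sig2[np.ix_(perm, perm)][iu]
        a = w1[iu][mask]
        b = b[mask]
        if mask.sum() < 3:
            return None
        if a.std() == 0 or b.std() == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1])

    ident = np.arange(n)
    r_obs = corr(ident)
    if r_obs is None:
        mask_n = int((sig1[iu] & sig2[iu]).sum())
        if mask_n < 3:
            raise TooFewEntries(
                f"only {mask_n} usable pairs after exclusion (need >= 3)"
            )
        raise UndefinedCorrelation("a matrix has zero variance over usable pairs")

    if n <= exact_max:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        rs = [corr(p) for p in perms]
        hits = sum(1 for r in rs if r is not None and r >= r_obs - 1e-12)
        return r_obs, hits / len(perms)
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = corr(rng.permutation(n))
        if r is not None and r >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Minimum spanning network
# ---------------------------------------------------------------------------

def min_spanning_network(
    d: DistanceMatrix,
    node_attrs: Mapping[str, Mapping[str, int]] | None = None,
    cap: float | None = None,
) -> nx.Graph:
    """Minimum spanning tree over haplotypes with population attributes.

    Edges at or above ``cap`` (the capped no-shared-spacer distance, if one
    was used) are treated as absent; if that disconnects the graph a
    :class:`Disconnected` error is raised. Equal-weight ties are resolved
    by lexicographic endpoint order, so the result is deterministic.
    ``node_attrs`` maps haplotype -> {population: read count}; each node
    gets ``counts`` and ``total`` attributes (circle sizes in the usual
    haplotype-network figure).
    """
    labels = d.labels
    edges = sorted(
        (float(d.values[i, j]), labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if cap is None or d.values[i, j] < cap
    )
    uf = nx.utils.UnionFind(labels)
    g = nx.Graph()
    g.add_nodes_from(labels)
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            g.add_edge(u, v, weight=w)
    if g.number_of_edges() != len(labels) - 1:
        raise Disconnected(
            "distance graph splits into multiple components under the cap"
        )
    for lab in labels:
        counts = dict(node_attrs.get(lab, {})) if node_attrs else {}
        g.nodes[lab]["counts"] = counts
        g.nodes[lab]["total"] = int(sum(counts.values()))
    return g


def write_msn_tsv(g: nx.Graph, edge_path: str | Path, node_path: str | Path) -> None:
    with open(edge_path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.10g}\n")
    pops = sorted({p for _, data in g.nodes(data=True) for p in data["counts"]})
    with open(node_path, "w") as fh:
        fh.write("haplotype_id\ttotal\t" + "\t".join(pops) + "\n")
        for node, data in sorted(g.nodes(data=True)):
            row = [str(data["counts"].get(p, 0)) for p in pops]
            fh.write(f"{node}\t{data['total']}\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Two-SNP gene haplotypes
# ---------------------------------------------------------------------------

def count_gene_haplotypes(
    records,
    snp_positions: tuple[int, int],
    min_qual: int = 28,
) -> dict[str, int]:
    """Count two-locus haplotypes at two SNP columns of aligned reads.

    Bases below ``min_qual`` are conservatively masked to N; reads with an
    N (or alignment gap) at either SNP column are dropped. Records may be
    Bio.SeqRecord objects carrying ``phred_quality`` annotations, or
    ``(sequence, qualities)`` tuples.
    """
    pos_a, pos_b = snp_positions
    counts: dict[str, int] = {}
    for rec in records:
        if isinstance(rec, tuple):
            seq, quals = rec
            seq = str(seq)
        else:
            seq = str(rec.seq)
            quals = rec.letter_annotations.get("phred_quality")
        if pos_a >= len(seq) or pos_b >= len(seq) or min(pos_a, pos_b) < 0:
            raise PositionOutOfRange(
                f"SNP columns {snp_positions} outside alignment of length {len(seq)}"
            )
        hap = []
        for pos in (pos_a, pos_b):
            base = seq[pos].upper()
            if quals is not None and quals[pos] < min_qual:
                base = "N"
            if base not in "ACGT":
                base = "N"
            hap.append(base)
        if "N" in hap:
            continue
        key = "".join(hap)
        counts[key] = counts.get(key, 0) + 1
    return counts
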