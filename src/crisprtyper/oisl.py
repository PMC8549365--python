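"""Pairwise divergence under the ordered independent spacer-loss model.

Model
-----
Two haplotypes diverged from their most recent common ancestor ``t`` time
units ago (both branches of equal length ``t``). Each ancestral spacer is
lost independently at rate 1 per lineage, so it survives one branch with
probability ``p = exp(-t)``. Classifying each ancestral spacer by its fate:

* retained in both lineages (shared):        probability ``p**2``
* retained in exactly one (internal unique): probability ``p * (1 - p)``
  per lineage
* lost in both:                              unobservable

New spacers are inserted at the leader end at rate ``rho`` relative to the
per-spacer deletion rate; the number inserted after divergence and still
surviving at the tip is Poisson with mean ``rho * (1 - exp(-t))`` per
lineage (insertions during the branch survive to its end with the usual
exponential thinning).

A spacer lost in both lineages leaves no trace, so each observed ancestral
spacer is conditioned on being observable (lost in at most one lineage,
probability ``1 - (1-p)**2 = p (2 - p)``). The log-likelihood of a pairwise
alignment with ``n_s`` shared, ``n_a``/``n_b`` internal-unique and
``k_a``/``k_b`` leader-unique spacers is::

    logL = n_s log(p / (2 - p)) + (n_a + n_b) log((1 - p) / (2 - p))
           + logPois(k_a; lam) + logPois(k_b; lam),   lam = rho (1 - p)

Without the observability normalizer the estimator is inconsistent (it
converges to ``1 / (2 - p)`` instead of ``p``, shrinking all divergence
times); with it, simulated truth is recovered without bias.

The reported distance between the pair is ``2 * t_hat`` (tip to tip through
the ancestor). When no leader-unique spacers are present the MLE is closed
form: ``rho_hat = 0`` and ``p_hat = 2 n_s / (2 n_s + n_a + n_b)``.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .arrays import CrisprArray, PairAlignment, align_pair
from .errors import CollinearityError, DomainError, InvalidMatrix, NoSharedSpacers

__all__ = [
    "OislEstimate",
    "DistanceMatrix",
    "oisl_loglik",
    "estimate_pair",
    "distance_matrix",
]

#: Default upper bound on the per-branch divergence time. exp(-10) ~ 4.5e-5:
#: beyond this the likelihood is flat for any realistic array.
DEFAULT_T_MAX = 10.0

#: Upper bound on the insertion:deletion rate ratio during optimization.
#: Without it the likelihood of a pair differing only by leader insertions
#: has its supremum at t -> 0, rho -> inf (never attained); the bound keeps
#: the estimate finite and is far above any biologically plausible ratio.
DEFAULT_RHO_MAX = 50.0


@dataclass(frozen=True)
class OislEstimate:
    """Maximum-likelihood divergence estimate for one haplotype pair."""

    t_hat: float  # branch length tip -> MRCA, expected deletions per spacer
    rho_hat: float  # insertion:deletion rate ratio
    loglik: float

    @property
    def distance(self) -> float:
        """Tip-to-tip distance through the ancestor: ``2 * t_hat``."""
        return 2.0 * self.t_hat


def _ln_poisson(k: int, lam: float) -> float:
    if lam == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(lam) - lam - math.lgamma(k + 1)


def oisl_loglik(alignment: PairAlignment, t: float, rho: float) -> float:
    """Log-likelihood of a pairwise alignment at divergence ``t``, ratio ``rho``.

    Returns ``-inf`` where the parameters cannot produce the data (for
    instance ``t = 0`` with unique spacers present).
    """
    if not (math.isfinite(t) and math.isfinite(rho)):
        raise DomainError(f"t and rho must be finite, got t={t}, rho={rho}")
    if t < 0 or rho < 0:
        raise DomainError(f"t and rho must be >= 0, got t={t}, rho={rho}")
    p = math.exp(-t)
    q = -math.expm1(-t)  # 1 - p, computed stably
    n_s = alignment.n_shared
    n_int = alignment.internal_unique_a + alignment.internal_unique_b
    lam = rho * q

    if p == 0.0 and n_s > 0:
        return -math.inf
    if q == 0.0 and n_int > 0:
        return -math.inf
    # observable-spacer conditional class probabilities:
    # shared p/(2-p), unique-to-one-lineage (1-p)/(2-p) each
    ll = 0.0
    if n_s:
        ll += n_s * (math.log(p) - math.log1p(q))
    if n_int:
        ll += n_int * (math.log(q) - math.log1p(q))
    ll += _ln_poisson(alignment.leader_unique_a, lam)
    ll += _ln_poisson(alignment.leader_unique_b, lam)
    return ll


def _profile_rho(
    alignment: PairAlignment, t: float, rho_max: float = DEFAULT_RHO_MAX
) -> float:
    """rho maximizing the likelihood at fixed t (lam_hat = mean leader count)."""
    k = alignment.leader_unique_a + alignment.leader_unique_b
    if k == 0:
        return 0.0
    q = -math.expm1(-t)
    if q == 0.0:
        return 0.0
    return min(k / (2.0 * q), rho_max)


def estimate_alignment(
    alignment: PairAlignment,
    t_max: float = DEFAULT_T_MAX,
    rho_max: float = DEFAULT_RHO_MAX,
) -> OislEstimate:
    """ML estimate from a precomputed :class:`PairAlignment`."""
    n_s = alignment.n_shared
    if n_s == 0:
        raise NoSharedSpacers(
            "arrays share no spacer; divergence time is unidentifiable "
            f"(distance would be capped at {2 * t_max})"
        )
    n_int = alignment.internal_unique_a + alignment.internal_unique_b
    k = alignment.leader_unique_a + alignment.leader_unique_b

    if k == 0:
        # stationarity of d/dp [n_s log(p/(2-p)) + n_int log((1-p)/(2-p))]
        # reduces to the linear equation 2 n_s - (2 n_s + n_int) p = 0
        p_hat = 2.0 * n_s / (2.0 * n_s + n_int)
        t_hat = min(-math.log(p_hat), t_max)
        return OislEstimate(
            t_hat=t_hat, rho_hat=0.0, loglik=oisl_loglik(alignment, t_hat, 0.0)
        )

    def neg_profile(t: float) -> float:
        return -oisl_loglik(alignment, t, _profile_rho(alignment, t, rho_max))

    # coarse bracket then bounded derivative-free refinement
    grid = np.linspace(1e-9, t_max, 512)
    vals = np.array([neg_profile(t) for t in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    t_hat = float(res.x) if res.fun <= vals[i] else float(grid[i])
    rho_hat = _profile_rho(alignment, t_hat, rho_max)
    return OislEstimate(
        t_hat=t_hat, rho_hat=rho_hat, loglik=oisl_loglik(alignment, t_hat, rho_hat)
    )


def estimate_pair(
    a: CrisprArray,
    b: CrisprArray,
    t_max: float = DEFAULT_T_MAX,
    rho_max: float = DEFAULT_RHO_MAX,
) -> OislEstimate:
    """Maximum-likelihood divergence between two collinear arrays.

    The search is bounded: ``t`` in ``[0, t_max]``, ``rho`` in
    ``[0, rho_max]``.

    Raises
    ------
    NoSharedSpacers
        If the arrays have no spacer in common. :func:`distance_matrix`
        catches this and caps the pair's distance at ``2 * t_max``.
    CollinearityError
        Propagated from the alignment step.
    """
    return estimate_alignment(align_pair(a, b), t_max=t_max, rho_max=rho_max)


class DistanceMatrix:
    """Symmetric, non-negative, zero-diagonal labelled distance matrix."""

    def __init__(self, labels: Sequence[str], values) -> None:
        self.labels = tuple(str(x) for x in labels)
        self.values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidMatrix(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise InvalidMatrix("matrix is not symmetric")
        if np.any(self.values < -1e-12):
            raise InvalidMatrix("matrix has negative entries")
        if np.any(np.abs(np.diag(self.values)) > 1e-9):
            raise InvalidMatrix("matrix diagonal is not zero")
        self.values = np.maximum((self.values + self.values.T) / 2.0, 0.0)
        np.fill_diagonal(self.values, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise InvalidMatrix("duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._index[str(pair[0])], self._index[str(pair[1])]
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[str(x)] for x in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_phylip(self, path: str | Path) -> None:
        """Write as square (relaxed-name) PHYLIP."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(labels, rows)


def distance_matrix(
    haplotypes: Mapping[str, CrisprArray] | Sequence[CrisprArray],
    t_max: float = DEFAULT_T_MAX,
) -> DistanceMatrix:
    """All-pairs OISL distances; symmetric with zero diagonal by construction.

    Pairs without any shared spacer get the capped distance ``2 * t_max``.
    Collinearity failures are re-raised naming the offending pair.
    """
    if not isinstance(haplotypes, Mapping):
        haplotypes = {f"H{i + 1}": h for i, h in enumerate(haplotypes)}
    labels = list(haplotypes)
    if len(labels) < 2:
        raise ValueError("need at least two haplotypes")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = estimate_pair(haplotypes[labels[i]], haplotypes[labels[j]], t_max)
                d[i, j] = d[j, i] = est.distance
            except NoSharedSpacers:
                d[i, j] = d[j, i] = 2.0 * t_max
            except CollinearityError as err:
                raise CollinearityError(
                    f"pair ({labels[i]}, {labels[j]}): {err}"
                ) from err
    return DistanceMatrix(labels, d)
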