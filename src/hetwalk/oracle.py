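"""Independent ground truth: direct Master-equation iteration, Monte Carlo
first-passage sampling, and linear-system mean hitting times.

Everything here works directly on a (possibly perturbed) transition operator
and never touches the generating-function machinery, so the two routes
validate each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SpecificationError
from .lattice import TransitionOperator, _as_site

__all__ = [
    "TrajectoryEnsemble",
    "iterate_master",
    "sample_first_passage",
    "solve_absorbing_means",
]


def iterate_master(operator: TransitionOperator, n0, T: int) -> np.ndarray:
    """Exact occupation probabilities by repeated operator application.

    Returns an array of shape ``(T + 1, n_sites)`` over flat site indices;
    row ``t`` is the distribution at time ``t`` from a walker localized at
    ``n0``.
    """
    if T < 0:
        raise SpecificationError("horizon T must be >= 0")
    A = operator.matrix
    out = np.zeros((T + 1, operator.n_sites))
    vec = np.zeros(operator.n_sites)
    vec[operator.spec.flat(n0)] = 1.0
    out[0] = vec
    for t in range(1, T + 1):
        vec = A @ vec
        out[t] = vec
    return out


@dataclass
class TrajectoryEnsemble:
    """Summary of a seeded first-passage Monte Carlo run.

    ``first_passage_times`` holds the hitting times (steps, ``1..T``) of the
    walkers that reached a target within the horizon; the rest are censored.
    """

    walkers: int
    horizon: int
    seed: int
    targets: tuple
    n0: tuple
    first_passage_times: np.ndarray
    n_censored: int

    @property
    def fraction_censored(self) -> float:
        return self.n_censored / self.walkers

    def fp_estimate(self, T: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Empirical first-passage distribution ``F^(t)`` with binomial
        standard errors, for ``t = 0..T``."""
        T = self.horizon if T is None else T
        counts = np.bincount(self.first_passage_times, minlength=T + 1)[: T + 1]
        F = counts / self.walkers
        se = np.sqrt(F * (1.0 - F) / self.walkers)
        return F, se

    def mean_estimate(self) -> float:
        """Mean of the uncensored first-passage times (censored walkers are
        excluded; check ``fraction_censored`` before trusting this)."""
        if self.first_passage_times.size == 0:
            return float("nan")
        return float(self.first_passage_times.mean())


def sample_first_passage(
    operator: TransitionOperator,
    n0,
    targets: Sequence,
    walkers: int,
    T: int,
    seed: int,
) -> TrajectoryEnsemble:
    """Seeded Monte Carlo estimate of the first-passage time distribution.

    Walkers are statistically independent; internally they are evolved as
    per-site counts with multinomial redistribution, which is exact and much
    faster than per-trajectory sampling.  A walker starting on a target is
    *not* absorbed at ``t = 0``; first passage requires ``t >= 1``.  Walkers
    absorbed elsewhere (sub-stochastic columns) count as censored.
    """
    if walkers < 1:
        raise SpecificationError("need at least one walker")
    if seed is None:
        raise SpecificationError("an explicit seed is required")
    spec = operator.spec
    target_flat = {spec.flat(t) for t in _normalize_targets(targets, spec.d)}
    rng = np.random.default_rng(seed)
    S = operator.n_sites
    dense_cols: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}

    def column(j: int):
        if j not in dense_cols:
            col = operator.matrix[:, j]
            idx = col.nonzero()[0]
            p = np.asarray(col[idx].todense()).ravel()
            leak = 1.0 - p.sum()
            dense_cols[j] = (idx, p, max(leak, 0.0))
        return dense_cols[j]

    counts = np.zeros(S, dtype=np.int64)
    counts[spec.flat(n0)] = walkers
    hit_times: list[np.ndarray] = []
    n_leaked = 0
    for t in range(1, T + 1):
        if counts.sum() == 0:
            break
        new = np.zeros(S, dtype=np.int64)
        for j in np.nonzero(counts)[0]:
            idx, p, leak = column(int(j))
            probs = np.append(p, leak) if leak > 1e-15 else p
            draw = rng.multinomial(int(counts[j]), probs / probs.sum())
            if leak > 1e-15:
                n_leaked += int(draw[-1])
                draw = draw[:-1]
            np.add.at(new, idx, draw)
        hits = 0
        for tf in target_flat:
            hits += int(new[tf])
            new[tf] = 0
        if hits:
            hit_times.append(np.full(hits, t, dtype=np.int64))
        counts = new
    times = np.concatenate(hit_times) if hit_times else np.zeros(0, dtype=np.int64)
    n_censored = walkers - times.size
    return TrajectoryEnsemble(
        walkers=walkers,
        horizon=T,
        seed=seed,
        targets=tuple(tuple(_as_site(t)) for t in _normalize_targets(targets, spec.d)),
        n0=_as_site(n0),
        first_passage_times=times,
        n_censored=n_censored,
    )


def _normalize_targets(targets, d: int) -> list[tuple]:
    """Accept a single site or a sequence of sites."""
    if isinstance(targets, (int, np.integer)):
        return [(int(targets),)]
    targets = list(targets)
    if targets and isinstance(targets[0], (int, np.integer)):
        if d == 1:  # sequence of 1D sites
            return [(int(t),) for t in targets]
        return [tuple(int(t) for t in targets)]  # a single d-dim site
    return [_as_site(t) for t in targets]


def solve_absorbing_means(
    operator: TransitionOperator, targets: Sequence = ()
) -> np.ndarray:
    """Mean hitting times of the target/absorbing set from every site.

    Solves ``(I - Q^T) m = 1`` on the sites that can reach absorption, where
    ``Q`` is the operator restricted to non-target active sites.  Absorption
    happens on arrival at a target site or through any sub-stochastic column
    (built-in absorbing boundaries).  Entries are ``0`` on targets/absorbing
    sites and ``inf`` where absorption is not certain.
    """
    spec = operator.spec
    S = operator.n_sites
    target_flat = {spec.flat(_as_site(t)) for t in _normalize_targets(targets, spec.d)} if len(targets) else set()
    inactive = set(operator.inactive)
    live = np.array(
        [i for i in range(S) if i not in target_flat and i not in inactive],
        dtype=int,
    )
    means = np.full(S, 0.0)
    means[list(inactive)] = 0.0
    if live.size == 0:
        return means
    Q = operator.matrix[np.ix_(live, live)].tocsc()
    # absorption probability in one step from each live site
    col_sums = np.asarray(Q.sum(axis=0)).ravel()
    p_abs = 1.0 - col_sums
    # sites that can reach absorption: reverse reachability from leaky sites
    leaky = np.nonzero(p_abs > 1e-12)[0]
    if leaky.size == 0:
        means[live] = np.inf
        return means
    # breadth-first on the reversed transition graph: predecessors of the
    # frontier are the nonzero columns of its rows (dest = row, src = col)
    P = sp.csr_matrix((Q != 0).astype(np.int8))
    reach = np.zeros(live.size, dtype=bool)
    frontier = list(leaky)
    reach[leaky] = True
    while frontier:
        preds = P[frontier, :].nonzero()[1]
        fresh = [int(i) for i in np.unique(preds) if not reach[i]]
        reach[fresh] = True
        frontier = fresh
    good = np.nonzero(reach)[0]
    bad = np.nonzero(~reach)[0]
    means[live[bad]] = np.inf
    if good.size:
        Qg = Q[np.ix_(good, good)]
        I = sp.identity(good.size, format="csc")
        m = spla.spsolve((I - Qg.T).tocsc(), np.ones(good.size))
        means[live[good]] = m
    return means
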