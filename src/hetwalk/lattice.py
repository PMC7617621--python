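"""Homogeneous lattice random walks: transition operators and exact propagator
generating functions.

The walk is a discrete-time lazy nearest-neighbor random walk on a finite
``d``-dimensional box.  In dimension ``i`` the bulk per-neighbor jump
probability is ``q_i / (2 d)`` and the bulk staying probability is
``1 - (1/d) * sum_i q_i``; equivalently the ``d``-dimensional operator is the
arithmetic mean of ``d`` one-dimensional lazy-walk operators acting on the
tensor-product site space.  A second kernel ("product") describes two or more
walkers moving *simultaneously* (next-nearest / diagonal moves), used by the
coalescence scenario: there the operator is the tensor product of the 1D
operators.

Boundaries per dimension: reflecting (the blocked jump folds back into the
staying probability), periodic, or absorbing at one/both faces.  An absorbing
face site swallows the walker on arrival: its row and column are removed from
the dynamics.  Individual absorbing sites can be added on top of any boundary
combination.

The propagator generating function

    phi~_{n0}(n, z) = sum_t phi(n, t | n0) z^t
                    = sum_k psi_k(n) psi_k(n0) / (1 - z sigma_k)

is evaluated through the exact eigendecomposition of the (symmetric)
transition operator: per-dimension decompositions combined separably when the
absorbing structure is a product of faces, a dense decomposition of the
restricted operator otherwise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import DomainError, NumericalError, SpecificationError

__all__ = [
    "BOUNDARY_KINDS",
    "LatticeSpec",
    "TransitionOperator",
    "PropagatorGF",
    "build_transition_operator",
    "homogeneous_propagator_gf",
    "homogeneous_mfpt_1d",
    "series_coefficients",
]

BOUNDARY_KINDS = (
    "reflecting",
    "periodic",
    "absorbing-low",
    "absorbing-high",
    "absorbing-both",
)

#: accepted aliases for boundary kinds (long names used in configs)
_BOUNDARY_ALIASES = {
    "absorbing-at-low-face": "absorbing-low",
    "absorbing-at-high-face": "absorbing-high",
    "absorbing-both-faces": "absorbing-both",
}

Site = tuple[int, ...]


def _as_site(n: Sequence[int]) -> Site:
    if isinstance(n, (int, np.integer)):
        return (int(n),)
    return tuple(int(x) for x in n)


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry, boundary conditions and diffusion parameters of the walk.

    Parameters
    ----------
    N : tuple of int
        Sites per dimension, each >= 2.  Site indices are 1-based,
        ``1 <= n_i <= N_i``.
    q : tuple of float
        Per-dimension diffusion (movement) parameters in ``(0, 1]``.
    boundary : tuple of str
        Per-dimension boundary kind, one of ``reflecting``, ``periodic``,
        ``absorbing-low``, ``absorbing-high``, ``absorbing-both``.  For the
        one-sided absorbing kinds the opposite face is reflecting.
    absorbing_sites : tuple of site tuples
        Individually absorbing sites (swallow the walker on arrival).
    kernel : "mean" or "product"
        How the 1D operators combine: arithmetic mean (ordinary
        nearest-neighbor walk) or tensor product (simultaneous moves).
    """

    N: tuple[int, ...]
    q: tuple[float, ...]
    boundary: tuple[str, ...] = ()
    absorbing_sites: tuple[Site, ...] = ()
    kernel: str = "mean"

    def __post_init__(self) -> None:
        N = tuple(int(x) for x in self.N)
        q = tuple(float(x) for x in self.q)
        if not N:
            raise SpecificationError("lattice needs at least one dimension")
        if any(n < 2 for n in N):
            raise SpecificationError(f"every N_i must be >= 2, got {N}")
        if len(q) != len(N):
            raise SpecificationError("q must have one entry per dimension")
        if any(not (0.0 < qi <= 1.0) for qi in q):
            raise SpecificationError(f"every q_i must lie in (0, 1], got {q}")
        boundary = tuple(_BOUNDARY_ALIASES.get(b, b) for b in self.boundary)
        if not boundary:
            boundary = ("reflecting",) * len(N)
        if len(boundary) != len(N):
            raise SpecificationError("boundary must have one entry per dimension")
        for b in boundary:
            if b not in BOUNDARY_KINDS:
                raise SpecificationError(f"unknown boundary kind {b!r}")
        if self.kernel not in ("mean", "product"):
            raise SpecificationError(f"unknown kernel {self.kernel!r}")
        sites = tuple(_as_site(s) for s in self.absorbing_sites)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "boundary", boundary)
        object.__setattr__(self, "absorbing_sites", tuple(sorted(set(sites))))
        for s in self.absorbing_sites:
            self.flat(s)  # bounds check

    # -- geometry helpers -------------------------------------------------
    @property
    def d(self) -> int:
        return len(self.N)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.N))

    def contains(self, n: Sequence[int]) -> bool:
        n = _as_site(n)
        return len(n) == self.d and all(1 <= ni <= Ni for ni, Ni in zip(n, self.N))

    def flat(self, n: Sequence[int]) -> int:
        """Row-major 0-based flat index of a 1-based site tuple."""
        n = _as_site(n)
        if not self.contains(n):
            raise SpecificationError(f"site {n} outside lattice {self.N}")
        return int(np.ravel_multi_index(tuple(ni - 1 for ni in n), self.N))

    def site(self, flat: int) -> Site:
        idx = np.unravel_index(int(flat), self.N)
        return tuple(int(i) + 1 for i in idx)

    def sites(self) -> Iterable[Site]:
        for flat in range(self.n_sites):
            yield self.site(flat)

    @property
    def is_conserving(self) -> bool:
        return not self.absorbing_sites and all(
            b in ("reflecting", "periodic") for b in self.boundary
        )

    def with_absorbing(self, *extra: Sequence[int]) -> "LatticeSpec":
        """A copy with additional individually absorbing sites."""
        new = self.absorbing_sites + tuple(_as_site(s) for s in extra)
        return LatticeSpec(self.N, self.q, self.boundary, new, self.kernel)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "N": list(self.N),
            "q": list(self.q),
            "boundary": list(self.boundary),
            "absorbing_sites": [list(s) for s in self.absorbing_sites],
            "kernel": self.kernel,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LatticeSpec":
        return cls(
            N=tuple(data["N"]),
            q=tuple(data["q"]),
            boundary=tuple(data.get("boundary", ())),
            absorbing_sites=tuple(tuple(s) for s in data.get("absorbing_sites", ())),
            kernel=data.get("kernel", "mean"),
        )


def _chain_matrix(n: int, q: float, boundary: str) -> tuple[np.ndarray, np.ndarray]:
    """Dense 1D transition matrix (columns = origin) and active-site mask.

    Bulk: stay ``1 - q``, jump ``q/2`` to each neighbor.  Reflecting ends fold
    the blocked jump into the staying probability.  Absorbing faces have their
    row and column zeroed (the mask marks them inactive).
    """
    P = np.zeros((n, n))
    for j in range(n):
        P[j, j] = 1.0 - q
        for dj in (-1, 1):
            i = j + dj
            if 0 <= i < n:
                P[i, j] += q / 2.0
            elif boundary == "periodic":
                P[i % n, j] += q / 2.0
            else:
                # face; reflecting unless this face absorbs
                absorbs = (
                    boundary == "absorbing-both"
                    or (boundary == "absorbing-low" and i < 0)
                    or (boundary == "absorbing-high" and i >= n)
                )
                if not absorbs:
                    P[j, j] += q / 2.0
                # absorbing faces beyond the lattice are modelled by making
                # the face *site* absorbing (below), not by an off-lattice leak
    active = np.ones(n, dtype=bool)
    if boundary in ("absorbing-low", "absorbing-both"):
        active[0] = False
    if boundary in ("absorbing-high", "absorbing-both"):
        active[-1] = False
    return P, active


@dataclass
class TransitionOperator:
    """Sparse column-stochastic (or sub-stochastic) transition operator.

    ``matrix[i, j]`` is the probability of moving from flat site ``j`` to flat
    site ``i`` in one step.  ``inactive`` lists flat indices of absorbing
    sites; their rows and columns are identically zero.
    """

    spec: LatticeSpec
    matrix: sp.csc_matrix
    inactive: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_sites(self) -> int:
        return self.spec.n_sites

    def entry(self, dest: Sequence[int], src: Sequence[int]) -> float:
        return float(self.matrix[self.spec.flat(dest), self.spec.flat(src)])

    def column_sum(self, src: Sequence[int]) -> float:
        j = self.spec.flat(src)
        return float(self.matrix[:, j].sum())

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def neighbors(self, src: Sequence[int]) -> list[Site]:
        """Destination sites reachable in one step (excluding staying put)."""
        j = self.spec.flat(src)
        col = self.matrix[:, j]
        return [self.spec.site(i) for i in col.nonzero()[0] if i != j]

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def copy(self) -> "TransitionOperator":
        return TransitionOperator(self.spec, self.matrix.copy(), self.inactive)


def build_transition_operator(spec: LatticeSpec, masked: bool = True) -> TransitionOperator:
    """Assemble the transition operator of the homogeneous walk.

    With ``masked=False`` the rows and columns of absorbing sites are kept
    (the conserving flow template): the entries show the transition
    probability *into* an absorbing site, i.e. the absorption flux, which is
    what defect strengths are bounded by.
    """
    blocks = [
        _chain_matrix(n, q, b) for n, q, b in zip(spec.N, spec.q, spec.boundary)
    ]
    d = spec.d
    if spec.kernel == "mean":
        A = sp.csc_matrix((spec.n_sites, spec.n_sites))
        for i, (P, _) in enumerate(blocks):
            term = sp.identity(1, format="csc")
            for j, (Pj, _) in enumerate(blocks):
                factor = sp.csc_matrix(Pj) if j == i else sp.identity(
                    spec.N[j], format="csc"
                )
                term = sp.kron(term, factor, format="csc")
            A = A + term / d
    else:  # product kernel: simultaneous moves
        A = sp.identity(1, format="csc")
        for P, _ in blocks:
            A = sp.kron(A, sp.csc_matrix(P), format="csc")

    # inactive sites: faces flagged per dimension, plus individual sites
    inactive_mask = np.zeros(spec.N, dtype=bool)
    for i, (_, active) in enumerate(blocks):
        if not active.all():
            shape = [1] * d
            shape[i] = spec.N[i]
            inactive_mask |= ~active.reshape(shape)
    flat_mask = inactive_mask.ravel()
    for s in spec.absorbing_sites:
        flat_mask[spec.flat(s)] = True
    if masked and flat_mask.any():
        keep = sp.diags((~flat_mask).astype(float), format="csc")
        A = keep @ A @ keep
    A = sp.csc_matrix(A)
    A.eliminate_zeros()
    return TransitionOperator(spec, A, frozenset(np.nonzero(flat_mask)[0].tolist()))


@functools.lru_cache(maxsize=64)
def _cached_operator(spec: LatticeSpec, masked: bool = True) -> TransitionOperator:
    return build_transition_operator(spec, masked=masked)


def cached_operator(spec: LatticeSpec, masked: bool = True) -> TransitionOperator:
    """Memoized operator build (the returned object must not be mutated)."""
    return _cached_operator(spec, masked)


class PropagatorGF:
    """Evaluable propagator generating function phi~_{n0}(n, z).

    Backed by the exact eigendecomposition of the (symmetric) transition
    operator.  ``evaluate`` accepts scalar or array ``z``; sites are 1-based
    tuples.  At absorbing sites the propagator is identically zero (the walker
    is removed on arrival); ``evaluate`` at ``z = 0`` returns the initial
    condition ``delta_{n, n0}``.
    """

    def __init__(self, spec: LatticeSpec):
        self.spec = spec
        self._separable = not spec.absorbing_sites
        if self._separable:
            self._dim_bases = []
            for n, q, b in zip(spec.N, spec.q, spec.boundary):
                P, active = _chain_matrix(n, q, b)
                sub = P[np.ix_(active, active)]
                sigma, U = np.linalg.eigh(sub)
                pos = np.full(n, -1, dtype=int)
                pos[active] = np.arange(active.sum())
                self._dim_bases.append((pos, sigma, U))
            sig = None
            for _, sigma, _ in self._dim_bases:
                sig = sigma if sig is None else (
                    np.add.outer(sig, sigma).ravel()
                    if spec.kernel == "mean"
                    else np.multiply.outer(sig, sigma).ravel()
                )
            if spec.kernel == "mean":
                sig = sig / spec.d if spec.d > 1 else sig
            self.sigma = np.asarray(sig)
        else:
            op = build_transition_operator(spec)
            active = np.ones(spec.n_sites, dtype=bool)
            active[list(op.inactive)] = False
            dense = op.matrix.toarray()[np.ix_(active, active)]
            if not np.allclose(dense, dense.T, atol=1e-13):
                raise NumericalError(
                    "transition operator is not symmetric; spectral propagator "
                    "requires an unbiased walk"
                )
            sigma, U = np.linalg.eigh(dense)
            self.sigma = sigma
            self._U = U
            self._pos = np.full(spec.n_sites, -1, dtype=int)
            self._pos[active] = np.arange(active.sum())

    # -- structure ---------------------------------------------------------
    @property
    def n_modes(self) -> int:
        return self.sigma.shape[0]

    @property
    def sigma_max(self) -> float:
        return float(self.sigma.max()) if self.n_modes else 0.0

    @property
    def has_absorption(self) -> bool:
        return not self.spec.is_conserving

    def is_active(self, n: Sequence[int]) -> bool:
        n = _as_site(n)
        if self._separable:
            return all(
                pos[ni - 1] >= 0 for (pos, _, _), ni in zip(self._dim_bases, n)
            )
        return self._pos[self.spec.flat(n)] >= 0

    def basis_row(self, n: Sequence[int]) -> np.ndarray:
        """Eigenfunction values ``psi_k(n)`` over all modes (zeros if ``n``
        is absorbing)."""
        n = _as_site(n)
        if not self.spec.contains(n):
            raise SpecificationError(f"site {n} outside lattice {self.spec.N}")
        if self._separable:
            row = None
            for (pos, _, U), ni in zip(self._dim_bases, n):
                p = pos[ni - 1]
                r = U[p] if p >= 0 else np.zeros(U.shape[1])
                row = r if row is None else np.multiply.outer(row, r).ravel()
            return row
        p = self._pos[self.spec.flat(n)]
        if p < 0:
            return np.zeros(self.n_modes)
        return self._U[p]

    def total_row(self) -> np.ndarray:
        """``sum_n psi_k(n)`` over active sites, for survival sums."""
        if self._separable:
            row = None
            for pos, _, U in self._dim_bases:
                r = U.sum(axis=0)
                row = r if row is None else np.multiply.outer(row, r).ravel()
            return row
        return self._U.sum(axis=0)

    # -- evaluation ---------------------------------------------------------
    def check_z(self, z) -> np.ndarray:
        """Reject evaluation points at (or numerically on top of) a pole
        ``1 / sigma_k``.  Away from the poles the eigen-sum is the exact
        rational continuation of the series, so e.g. derivatives at ``z = 1``
        of pole-free ratios remain computable on conserving lattices."""
        z = np.asarray(z, dtype=complex)
        if np.any(np.abs(1.0 - np.multiply.outer(z, self.sigma)) < 1e-12):
            raise DomainError(
                f"z on a pole of the propagator generating function "
                f"(spectral radius {self.sigma_max:.6g})"
            )
        return z

    def resolvent(self, z) -> np.ndarray:
        """``1 / (1 - z sigma_k)`` with shape ``z.shape + (n_modes,)``."""
        z = self.check_z(z)
        return 1.0 / (1.0 - np.multiply.outer(z, self.sigma))

    def evaluate(self, n: Sequence[int], n0: Sequence[int], z):
        """phi~_{n0}(n, z); scalar in, scalar out (complex)."""
        n, n0 = _as_site(n), _as_site(n0)
        zarr = np.asarray(z, dtype=complex)
        amp = self.basis_row(n) * self.basis_row(n0)
        out = self.resolvent(zarr) @ amp
        if zarr.ndim == 0:
            out = complex(out)
            if zarr == 0:  # exact initial condition
                return complex(1.0 if n == n0 else 0.0)
        return out

    def __call__(self, n, n0, z):
        return self.evaluate(n, n0, z)

    def survival(self, n0: Sequence[int], z):
        """S~_{n0}(z) = sum_n phi~_{n0}(n, z) over active sites."""
        amp = self.total_row() * self.basis_row(n0)
        out = self.resolvent(np.asarray(z, dtype=complex)) @ amp
        return complex(out) if np.asarray(z).ndim == 0 else out


@functools.lru_cache(maxsize=64)
def _cached_gf(spec: LatticeSpec) -> PropagatorGF:
    return PropagatorGF(spec)


def homogeneous_propagator_gf(spec: LatticeSpec) -> PropagatorGF:
    """Exact homogeneous propagator generating function for ``spec``.

    Results are memoized per spec; the returned object is immutable in use.
    """
    return _cached_gf(spec)


def homogeneous_mfpt_1d(n0: int, n: int, q: float) -> float:
    """Mean first-passage time of the 1D lazy walk from ``n0`` to ``n >= n0``
    with a reflecting boundary between sites 0 and 1:
    ``(n - n0)(n + n0 - 1) / q``.
    """
    if not (0.0 < q <= 1.0):
        raise SpecificationError(f"q must be in (0, 1], got {q}")
    if n0 < 1 or n < n0:
        raise DomainError(f"requires 1 <= n0 <= n, got n0={n0}, n={n}")
    return (n - n0) * (n + n0 - 1) / q


def series_coefficients(
    gf,
    n0: Sequence[int] | None = None,
    n: Sequence[int] | None = None,
    T: int = 100,
    *,
    eps: float = 1e-4,
    imag_tol: float = 1e-8,
    clip: bool = True,
) -> np.ndarray:
    """First ``T + 1`` power-series coefficients of a generating function.

    The function is sampled on ``K = 4 (T + 1)`` points of the circle of
    radius ``r = eps ** (1 / (T + 1))`` and inverted with the radius-corrected
    inverse DFT.  Aliasing is damped by ``r**K = eps**4`` while round-off is
    amplified by at most ``1 / eps``; the default ``eps = 1e-4`` balances the
    two at ~1e-11 absolute error for horizons of a few hundred steps.

    Parameters
    ----------
    gf : PropagatorGF or callable
        Either a propagator (then ``n`` and ``n0`` select the entry) or any
        vectorized callable ``z -> value``.
    clip : bool
        After verifying coefficients are real (and, when clipping, inside
        ``[-tol, 1 + tol]``), clamp them to ``[0, 1]``.  Set to ``False`` for
        generating functions that are not probability series.
    """
    if T < 0:
        raise DomainError("horizon T must be >= 0")
    if isinstance(gf, PropagatorGF):
        if n is None or n0 is None:
            raise SpecificationError("n and n0 are required with a PropagatorGF")
        func: Callable = lambda zs: gf.evaluate(n, n0, zs)
    elif callable(gf):
        func = gf
    else:
        raise SpecificationError("gf must be a PropagatorGF or a callable")

    K = 4 * (T + 1)
    r = eps ** (1.0 / (T + 1))
    zs = r * np.exp(2j * np.pi * np.arange(K) / K)
    try:
        vals = np.asarray(func(zs), dtype=complex)
        if vals.shape != zs.shape:
            raise ValueError
    except Exception:
        vals = np.array([func(z) for z in zs], dtype=complex)
    coeff = np.fft.fft(vals) / K
    t = np.arange(T + 1)
    coeff = coeff[: T + 1] * r ** (-t.astype(float))
    resid = float(np.abs(coeff.imag).max())
    if resid > imag_tol:
        raise NumericalError(
            f"imaginary residue {resid:.3g} exceeds tolerance {imag_tol:.3g}; "
            "generating function evaluation may not have converged"
        )
    out = coeff.real
    if clip:
        if out.min() < -imag_tol or out.max() > 1.0 + imag_tol:
            raise NumericalError(
                f"series coefficients outside [0, 1] beyond tolerance: "
                f"min={out.min():.3g}, max={out.max():.3g}"
            )
        out = np.clip(out, 0.0, 1.0)
    return out
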