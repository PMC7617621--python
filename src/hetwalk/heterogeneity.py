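"""Probability-conserving perturbations of the homogeneous walk.

A *defect pair* ``{u, v}`` carries two signed parameters: ``lambda_vu`` is
subtracted from the ``u -> v`` transition probability and added to the staying
probability of ``u``; ``lambda_uv`` acts the same way on ``v -> u`` and the
staying probability of ``v``.  Every column sum is therefore untouched: the
construction conserves probability by design.  Positivity of the perturbed
operator requires, for each heterogeneous connection ``u -> w``,
``lambda_{w,u} <= A_{w,u}`` and, per site, a non-negative perturbed staying
probability ``A_{u,u} + sum_w lambda_{w,u} >= 0``.

The builders parametrize the heterogeneity types used throughout:

* barrier        lambda_{v,u} =  alpha_v A_{v,u}   (partial reflection)
* antibarrier    lambda_{v,u} = -beta_v  A_{u,u}   (enhanced crossing)
* one-way gate   barrier with alpha = 1 on one side only
* long-range     lambda_{s,u} = -beta_s  A_{u,u}   between non-neighbors
* sticky site    one-way barriers to all k neighbors, strength alpha
* slippery site  lambda_{r_i,w} = -(beta / k) A_{w,w} to all k neighbors

lambda values are resolved to numbers at construction time so validation is
concrete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import DefectValidationError, GeometryError, SpecificationError
from .lattice import LatticeSpec, Site, TransitionOperator, _as_site, cached_operator

__all__ = [
    "DefectPair",
    "HeterogeneitySet",
    "make_barrier",
    "make_antibarrier",
    "make_gate",
    "make_long_range",
    "make_sticky",
    "make_slippery",
    "apply_defects",
    "is_symmetry_preserving",
]

_TOL = 1e-12


@dataclass(frozen=True)
class DefectPair:
    """One heterogeneous connection pair.

    ``lambda_vu`` perturbs the ``u -> v`` transition, ``lambda_uv`` the
    ``v -> u`` transition.  Either may be zero (one-way modification).
    """

    u: Site
    v: Site
    lambda_vu: float
    lambda_uv: float

    def __post_init__(self):
        object.__setattr__(self, "u", _as_site(self.u))
        object.__setattr__(self, "v", _as_site(self.v))
        object.__setattr__(self, "lambda_vu", float(self.lambda_vu))
        object.__setattr__(self, "lambda_uv", float(self.lambda_uv))
        if self.u == self.v:
            raise SpecificationError(f"defect pair needs two distinct sites, got {self.u}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.u, self.v))

    def to_dict(self) -> dict:
        return {
            "u": list(self.u),
            "v": list(self.v),
            "lambda_vu": self.lambda_vu,
            "lambda_uv": self.lambda_uv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DefectPair":
        return cls(tuple(d["u"]), tuple(d["v"]), d["lambda_vu"], d["lambda_uv"])


class HeterogeneitySet:
    """An ordered collection of unique defect pairs bound to a lattice."""

    def __init__(self, spec: LatticeSpec, pairs: Iterable[DefectPair] = ()):
        self.spec = spec
        self.pairs: list[DefectPair] = []
        self._keys: set[frozenset] = set()
        for p in pairs:
            self.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def add(self, pair: DefectPair | Iterable[DefectPair]) -> "HeterogeneitySet":
        if isinstance(pair, DefectPair):
            pair = [pair]
        for p in pair:
            if not self.spec.contains(p.u) or not self.spec.contains(p.v):
                raise SpecificationError(f"pair {p.u}-{p.v} outside lattice {self.spec.N}")
            if p.key in self._keys:
                raise SpecificationError(
                    f"duplicate defect pair {{{p.u}, {p.v}}}: pairs must be unique "
                    "as unordered site pairs"
                )
            self._keys.add(p.key)
            self.pairs.append(p)
        return self

    def validate(self, operator: TransitionOperator | None = None) -> None:
        """Check the positivity constraints against the homogeneous operator.

        Raises :class:`DefectValidationError` naming the offending site or
        connection.
        """
        op = operator if operator is not None else cached_operator(self.spec, masked=False)
        stay_shift: dict[Site, float] = {}
        for p in self.pairs:
            if p.lambda_vu > op.entry(p.v, p.u) + _TOL:
                raise DefectValidationError(
                    f"lambda_vu={p.lambda_vu:.6g} exceeds A[{p.v},{p.u}]="
                    f"{op.entry(p.v, p.u):.6g} for pair {{{p.u}, {p.v}}}"
                )
            if p.lambda_uv > op.entry(p.u, p.v) + _TOL:
                raise DefectValidationError(
                    f"lambda_uv={p.lambda_uv:.6g} exceeds A[{p.u},{p.v}]="
                    f"{op.entry(p.u, p.v):.6g} for pair {{{p.u}, {p.v}}}"
                )
            stay_shift[p.u] = stay_shift.get(p.u, 0.0) + p.lambda_vu
            stay_shift[p.v] = stay_shift.get(p.v, 0.0) + p.lambda_uv
        for site, shift in stay_shift.items():
            stay = op.entry(site, site) + shift
            if stay < -_TOL:
                raise DefectValidationError(
                    f"perturbed staying probability at site {site} is negative "
                    f"({stay:.6g}); lambda values draw more than the available mass"
                )

    # -- serialization ----------------------------------------------------
    def to_json(self) -> list[dict]:
        return [p.to_dict() for p in self.pairs]

    @classmethod
    def from_json(cls, spec: LatticeSpec, data: Iterable[dict]) -> "HeterogeneitySet":
        return cls(spec, (DefectPair.from_dict(d) for d in data))

    @classmethod
    def from_declarative(cls, spec: LatticeSpec, items: Iterable[dict]) -> "HeterogeneitySet":
        """Build from declarative descriptions.

        Each item is a dict with a ``type`` key: ``barrier`` (u, v, alpha_u,
        alpha_v), ``antibarrier`` (u, v, beta_u, beta_v), ``gate`` (u, v;
        blocks u -> v), ``long_range`` (u, s, beta_u, beta_s), ``sticky``
        (w, alpha), ``slippery`` (w, beta) or ``pair`` (raw lambda values).
        """
        out = cls(spec)
        for item in items:
            kind = item.get("type", "pair")
            if kind == "barrier":
                out.add(make_barrier(spec, item["u"], item["v"],
                                     item.get("alpha_u", 1.0), item.get("alpha_v", 1.0)))
            elif kind == "antibarrier":
                out.add(make_antibarrier(spec, item["u"], item["v"],
                                         item.get("beta_u", 1.0), item.get("beta_v", 1.0)))
            elif kind == "gate":
                out.add(make_gate(spec, item["u"], item["v"]))
            elif kind == "long_range":
                out.add(make_long_range(spec, item["u"], item["s"],
                                        item.get("beta_u", 1.0), item.get("beta_s", 1.0)))
            elif kind == "sticky":
                out.add(make_sticky(spec, item["w"], item["alpha"]))
            elif kind == "slippery":
                out.add(make_slippery(spec, item["w"], item["beta"]))
            elif kind == "pair":
                out.add(DefectPair.from_dict(item))
            else:
                raise SpecificationError(f"unknown defect type {kind!r}")
        return out


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise SpecificationError(f"{name} must lie in [0, 1], got {value}")
    return value


def make_barrier(spec: LatticeSpec, u, v, alpha_u: float = 1.0,
                 alpha_v: float = 1.0) -> DefectPair:
    """Partially reflecting barrier between neighbors ``u`` and ``v``.

    ``alpha_v`` is the reflectivity seen when jumping ``u -> v`` and vice
    versa; ``alpha_u = alpha_v = 1`` is impenetrable, ``0`` homogeneous.
    """
    u, v = _as_site(u), _as_site(v)
    alpha_u, alpha_v = _check_unit("alpha_u", alpha_u), _check_unit("alpha_v", alpha_v)
    op = cached_operator(spec, masked=False)
    a_vu, a_uv = op.entry(v, u), op.entry(u, v)
    if a_vu <= 0.0 or a_uv <= 0.0:
        raise GeometryError(f"{u} and {v} are not neighbors; a barrier needs an existing connection")
    return DefectPair(u, v, alpha_v * a_vu, alpha_u * a_uv)


def make_gate(spec: LatticeSpec, u, v) -> DefectPair:
    """One-way gate: movement ``v -> u`` allowed, ``u -> v`` fully blocked."""
    return make_barrier(spec, u, v, alpha_u=0.0, alpha_v=1.0)


def make_antibarrier(spec: LatticeSpec, u, v, beta_u: float = 1.0,
                     beta_v: float = 1.0) -> DefectPair:
    """Enhanced crossing between neighbors, funded by the staying probability:
    ``lambda_{v,u} = -beta_v A_{u,u}``, ``lambda_{u,v} = -beta_u A_{v,v}``.
    """
    u, v = _as_site(u), _as_site(v)
    beta_u, beta_v = _check_unit("beta_u", beta_u), _check_unit("beta_v", beta_v)
    op = cached_operator(spec, masked=False)
    if op.entry(v, u) <= 0.0 or op.entry(u, v) <= 0.0:
        raise GeometryError(f"{u} and {v} are not neighbors; use make_long_range instead")
    return DefectPair(u, v, -beta_v * op.entry(u, u), -beta_u * op.entry(v, v))


def make_long_range(spec: LatticeSpec, u, s, beta_u: float = 1.0,
                    beta_s: float = 1.0) -> DefectPair:
    """Long-range jump channel between non-neighbors ``u`` and ``s`` drawing on
    the lazy (staying) probability of each endpoint."""
    u, s = _as_site(u), _as_site(s)
    beta_u, beta_s = _check_unit("beta_u", beta_u), _check_unit("beta_s", beta_s)
    op = cached_operator(spec, masked=False)
    if op.entry(s, u) > 0.0 or op.entry(u, s) > 0.0:
        raise GeometryError(
            f"{u} and {s} are already connected; use make_barrier/make_antibarrier"
        )
    return DefectPair(u, s, -beta_s * op.entry(u, u), -beta_u * op.entry(s, s))


def make_sticky(spec: LatticeSpec, w, alpha: float) -> list[DefectPair]:
    """Sticky site: one-way partial barriers from ``w`` to each of its ``k``
    actual neighbors, raising the staying probability by
    ``alpha * sum_i A_{r_i, w}``."""
    w = _as_site(w)
    alpha = _check_unit("alpha", alpha)
    op = cached_operator(spec, masked=False)
    return [
        DefectPair(w, r, alpha * op.entry(r, w), 0.0) for r in op.neighbors(w)
    ]


def make_slippery(spec: LatticeSpec, w, beta: float) -> list[DefectPair]:
    """Slippery site: the staying probability of ``w`` is redistributed evenly
    to its ``k`` actual neighbors (``lambda_{r_i,w} = -(beta/k) A_{w,w}``)."""
    w = _as_site(w)
    beta = _check_unit("beta", beta)
    op = cached_operator(spec, masked=False)
    nbrs = op.neighbors(w)
    if not nbrs:
        raise GeometryError(f"site {w} has no neighbors")
    stay = op.entry(w, w)
    return [DefectPair(w, r, -(beta / len(nbrs)) * stay, 0.0) for r in nbrs]


def apply_defects(hset: HeterogeneitySet,
                  operator: TransitionOperator | None = None) -> TransitionOperator:
    """Perturbed transition operator ``A'``.

    ``A'_{v,u} = A_{v,u} - lambda_{v,u}`` with the complementary mass moved to
    the diagonal; column sums are preserved exactly.  Raises
    :class:`DefectValidationError` if any resulting entry is negative.
    """
    base = operator if operator is not None else cached_operator(hset.spec)
    hset.validate()
    spec = hset.spec
    A = base.matrix.tolil(copy=True)
    for p in hset.pairs:
        iu, iv = spec.flat(p.u), spec.flat(p.v)
        u_active = iu not in base.inactive
        v_active = iv not in base.inactive
        # a lambda on a transition into an absorbing site adjusts the implicit
        # leak; only the staying probability of the active endpoint is stored
        if u_active:
            if v_active:
                A[iv, iu] -= p.lambda_vu
            A[iu, iu] += p.lambda_vu
        if v_active:
            if u_active:
                A[iu, iv] -= p.lambda_uv
            A[iv, iv] += p.lambda_uv
    A = A.tocsc()
    if A.nnz and A.data.min() < -_TOL:
        i = int(np.argmin(A.data))
        row = A.indices[i]
        raise DefectValidationError(
            f"perturbed operator has a negative entry near site "
            f"{spec.site(row)}: {A.data[i]:.6g}"
        )
    A.data[np.abs(A.data) < _TOL * 1e-2] = 0.0
    A.eliminate_zeros()
    return TransitionOperator(spec, A, base.inactive)


def is_symmetry_preserving(hset: HeterogeneitySet) -> bool:
    """True iff every pair satisfies the steady-state preserving ratio
    condition ``A_{u,v}/A_{v,u} = (A_{u,v} - lambda_{u,v})/(A_{v,u} - lambda_{v,u})``
    (0/0 counts as satisfied), in which case the perturbed walk keeps the
    stationary distribution of the homogeneous walk.
    """
    op = cached_operator(hset.spec)
    for p in hset.pairs:
        a_uv, a_vu = op.entry(p.u, p.v), op.entry(p.v, p.u)
        lhs = a_uv * (a_vu - p.lambda_vu)
        rhs = a_vu * (a_uv - p.lambda_uv)
        if abs(lhs - rhs) > _TOL:
            return False
    return True
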