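"""Application scenario builders.

Three biological applications of heterogeneous lattice walks, each expressed
as a declarative config that expands to a ``(LatticeSpec, HeterogeneitySet)``
pair plus the transport quantity the application reports:

* **Brick-and-mortar (transdermal drug delivery).**  The stratum corneum is a
  staggered pattern of impermeable "bricks" (corneocytes) separated by
  one-site mortar channels; drug molecules random-walk from the skin surface
  (reflecting top face) to the absorbing bottom face.  A microneedle puncture
  of height ``h`` and width ``w`` removes every barrier it touches.  Reported
  quantity: mean exit time (MET) versus puncture size.

* **Thigmotaxis (wall-following behavior).**  An animal confined to a disc of
  radius ``R`` (impenetrable circle inside a square arena) crosses an inner
  circle of radius ``r`` freely outward but is reflected inward with
  probability ``alpha_i`` (one-way partial barriers), concentrating the
  steady state in the annulus.  Reported quantity: steady-state mean squared
  displacement from the center, normalized by the barrier-free value.

* **Two-particle coalescence (promoter search).**  Two particles on a 1D
  segment move simultaneously; their joint dynamics is a single
  next-nearest-neighbor (diagonal-move) walker on the product 2D lattice.
  Encounter states live on the diagonal.  Barriers entering the diagonal
  (strength ``alpha_e``) model mutual exclusion, barriers leaving it
  (``1 - alpha_u``) model unbinding of the bound complex, and barriers along
  it (``1 - alpha_c``) slow the complex down.  Reported quantity: MFPT for
  both particles to reach a site together, normalized by the non-interacting
  value.

Default config values are the full-size study parameters; pass smaller
geometries for desk-scale exploration (the test-suite uses reduced variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .first_passage import limiting_distribution, met, mfpt
from .heterogeneity import DefectPair, HeterogeneitySet, make_barrier
from .lattice import (
    LatticeSpec,
    Site,
    cached_operator,
    homogeneous_propagator_gf,
)

__all__ = [
    "BrickMortarConfig",
    "ThigmotaxisConfig",
    "CoalescenceConfig",
    "build_brick_mortar",
    "met_vs_puncture",
    "build_thigmotaxis",
    "steady_state_msd",
    "thigmotaxis_msd_curve",
    "build_coalescence",
    "coalescence_mfpt_map",
]


# ---------------------------------------------------------------------------
# brick and mortar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrickMortarConfig:
    """Stratum-corneum geometry.

    ``N = (N1, N2)`` with absorbing face at ``n1 = 1``, reflecting at
    ``n1 = N1`` and periodic second dimension.  Bricks of ``brick =
    (height, width)`` sites are separated by one-site mortar channels
    (vertical period ``height + 1``, horizontal period ``width + 1``) and
    staggered by half a period per layer; layers stack from ``n1 = 2``
    upwards, leaving the absorbing row and at least the top row free.  The
    puncture rectangle (``h`` rows down from the top, ``w`` columns centered
    on the start column) removes every barrier pair it touches.
    """

    N: tuple[int, int] = (37, 36)
    brick: tuple[int, int] = (3, 5)
    h: int = 0
    w: int = 0
    alpha: float = 1.0
    q: tuple[float, float] = (0.8, 0.8)

    @property
    def n0(self) -> Site:
        return (self.N[0], self.N[1] // 2)

    def with_puncture(self, h: int, w: int) -> "BrickMortarConfig":
        return BrickMortarConfig(self.N, self.brick, h, w, self.alpha, self.q)


def _brick_cells(cfg: BrickMortarConfig) -> list[set[Site]]:
    """Site sets of the individual bricks."""
    N1, N2 = cfg.N
    bh, bw = cfg.brick
    if bh < 1 or bw < 1:
        raise SpecificationError("brick dimensions must be positive")
    if N2 % (bw + 1) != 0:
        raise SpecificationError(
            f"periodic width {N2} must be a multiple of brick width + mortar "
            f"({bw + 1}) for the pattern to tile"
        )
    n_layers = (N1 - 1) // (bh + 1)
    per_layer = N2 // (bw + 1)
    stagger = (bw + 1) // 2
    bricks = []
    for layer in range(n_layers):
        r0 = 2 + layer * (bh + 1)
        c0 = 1 + (layer * stagger) % (bw + 1)
        for b in range(per_layer):
            cells = {
                (r0 + dr, (c0 + b * (bw + 1) + dc - 1) % N2 + 1)
                for dr in range(bh)
                for dc in range(bw)
            }
            bricks.append(cells)
    return bricks


def build_brick_mortar(cfg: BrickMortarConfig) -> tuple[LatticeSpec, HeterogeneitySet]:
    """Lattice plus barrier set for the punctured brick-and-mortar pattern."""
    spec = LatticeSpec(cfg.N, cfg.q, boundary=("absorbing-low", "periodic"))
    op = cached_operator(spec)
    N1, N2 = cfg.N
    if not (0 <= cfg.h <= N1 and 0 <= cfg.w <= N2):
        raise SpecificationError("puncture must fit inside the domain")
    punct: set[Site] = set()
    if cfg.h > 0 and cfg.w > 0:
        c_mid = cfg.n0[1]
        cols = [(c_mid - cfg.w // 2 + k - 1) % N2 + 1 for k in range(cfg.w)]
        punct = {(r, c) for r in range(N1 - cfg.h + 1, N1 + 1) for c in cols}
    hset = HeterogeneitySet(spec)
    for cells in _brick_cells(cfg):
        for s in cells:
            for t in op.neighbors(s):
                if t in cells:
                    continue
                if s in punct or t in punct:
                    continue
                hset.add(make_barrier(spec, s, t, cfg.alpha, cfg.alpha))
    return spec, hset


def met_vs_puncture(
    cfg: BrickMortarConfig,
    h_range: Iterable[int],
    w_range: Iterable[int],
) -> pd.DataFrame:
    """Mean exit time for each puncture size ``(h, w)``.

    Columns: ``h``, ``w``, ``met`` (steps; ``inf`` where the walker can be
    sealed inside an intact brick -- not the case when starting on the
    surface)."""
    rows = []
    for w in w_range:
        for h in h_range:
            spec, hset = build_brick_mortar(cfg.with_puncture(h, w))
            gf = homogeneous_propagator_gf(spec)
            rows.append({"h": int(h), "w": int(w),
                         "met": met(hset, gf, cfg.n0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thigmotaxis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThigmotaxisConfig:
    """Concentric-circle arena on an ``N x N`` reflecting square.

    ``R`` confines the walker to a disc (impenetrable barriers on every edge
    crossing the circle); crossing the inner circle ``r`` is free outward and
    reflected inward with probability ``alpha_i``.  A lattice edge carries a
    barrier iff its endpoint site centers lie on opposite sides of the circle
    (Euclidean distance to the domain center)."""

    N: int = 101
    R: float = 48.0
    r: float = 24.0
    alpha_i: float = 0.95
    q: tuple[float, float] = (0.8, 0.8)

    @property
    def center(self) -> Site:
        return ((self.N + 1) // 2, (self.N + 1) // 2)

    def with_alpha(self, alpha_i: float) -> "ThigmotaxisConfig":
        return ThigmotaxisConfig(self.N, self.R, self.r, alpha_i, self.q)


def _crossing_edges(spec: LatticeSpec, center: Site, radius: float):
    """Lattice edges whose endpoints straddle the circle, as (inner, outer)."""
    op = cached_operator(spec)
    seen = set()
    for s in spec.sites():
        ds = math.dist(s, center)
        for t in op.neighbors(s):
            if frozenset((s, t)) in seen:
                continue
            dt = math.dist(t, center)
            if (ds <= radius) != (dt <= radius):
                seen.add(frozenset((s, t)))
                yield (s, t) if ds <= radius else (t, s)


def build_thigmotaxis(cfg: ThigmotaxisConfig) -> tuple[LatticeSpec, HeterogeneitySet]:
    """Lattice plus one-way barrier set for the thigmotaxis arena."""
    if not (0.0 < cfg.r < cfg.R):
        raise SpecificationError("need 0 < r < R")
    if cfg.R >= (cfg.N - 1) / 2 + 0.5:
        raise SpecificationError("outer circle does not fit inside the arena")
    spec = LatticeSpec((cfg.N, cfg.N), cfg.q)
    op = cached_operator(spec)
    hset = HeterogeneitySet(spec)
    for inner, outer in _crossing_edges(spec, cfg.center, cfg.R):
        hset.add(make_barrier(spec, inner, outer, 1.0, 1.0))
    if cfg.alpha_i > 0.0:
        for inner, outer in _crossing_edges(spec, cfg.center, cfg.r):
            # outward (inner -> outer) free; inward reflected with alpha_i
            hset.add(
                DefectPair(
                    u=outer,
                    v=inner,
                    lambda_vu=cfg.alpha_i * op.entry(inner, outer),
                    lambda_uv=0.0,
                )
            )
    return spec, hset


def steady_state_msd(hset: HeterogeneitySet, n0) -> float:
    """Steady-state mean squared displacement from ``n0`` (site units squared):
    ``sum_n ||n - n0||^2 pi_inf(n)`` with ``pi_inf`` the long-time occupation
    distribution of the perturbed (conserving) walk started at ``n0`` --
    equivalently ``sum_n ||n - n0||^2 / MRT_n`` by Kac's lemma."""
    spec = hset.spec
    pi = limiting_distribution(hset, n0)
    n0 = tuple(n0)
    msd = 0.0
    for flat in np.nonzero(pi)[0]:
        site = spec.site(int(flat))
        msd += pi[flat] * sum((a - b) ** 2 for a, b in zip(site, n0))
    return float(msd)


def thigmotaxis_msd_curve(cfg: ThigmotaxisConfig, alphas: Sequence[float]) -> pd.DataFrame:
    """Saturation MSD versus ``alpha_i``, normalized by the barrier-free value.

    Columns: ``alpha_i``, ``msd``, ``ratio`` (ratio = msd / msd(alpha_i=0))."""
    _, hset0 = build_thigmotaxis(cfg.with_alpha(0.0))
    base = steady_state_msd(hset0, cfg.center)
    rows = []
    for a in alphas:
        _, hs = build_thigmotaxis(cfg.with_alpha(float(a)))
        m = steady_state_msd(hs, cfg.center)
        rows.append({"alpha_i": float(a), "msd": m, "ratio": m / base})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-particle coalescence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescenceConfig:
    """Two simultaneously moving particles on a reflecting 1D segment of
    ``N`` sites, movement probability ``q`` each; ``target`` is the site both
    must occupy together.  ``alpha_e``: mutual exclusion (barrier against
    binding), ``alpha_u``: unbinding probability factor (``0`` = irreversible
    binding), ``alpha_c``: mobility of the bound complex (``0`` = immobile).
    ``alpha_e = 0, alpha_u = alpha_c = 1`` is the non-interacting walk."""

    N: int = 100
    q: float = 2.0 / 3.0
    alpha_e: float = 0.0
    alpha_u: float = 1.0
    alpha_c: float = 1.0
    target: int = 100

    @property
    def n0(self) -> Site:
        return (1, self.N)

    @property
    def target_state(self) -> Site:
        return (self.target, self.target)

    def with_params(self, alpha_e=None, alpha_u=None, alpha_c=None) -> "CoalescenceConfig":
        return CoalescenceConfig(
            self.N, self.q,
            self.alpha_e if alpha_e is None else float(alpha_e),
            self.alpha_u if alpha_u is None else float(alpha_u),
            self.alpha_c if alpha_c is None else float(alpha_c),
            self.target,
        )


def build_coalescence(cfg: CoalescenceConfig) -> tuple[LatticeSpec, HeterogeneitySet]:
    """Product-kernel 2D lattice plus interaction barriers.

    Diagonal states ``(m, m)`` are encounter states.  Edge classification:

    * off-diagonal <-> diagonal edges carry ``lambda = alpha_e A`` against
      entering and ``lambda = (1 - alpha_u) A`` against leaving;
    * diagonal <-> diagonal edges carry symmetric ``lambda = (1 - alpha_c) A``;
    * edges between the two off-diagonal neighbors ``(m+1, m)`` and
      ``(m, m+1)`` (particles swapping sides) carry symmetric
      ``lambda = alpha_e A`` -- crossing without meeting is excluded exactly
      when binding is.
    """
    for name in ("alpha_e", "alpha_u", "alpha_c"):
        v = getattr(cfg, name)
        if not (0.0 <= v <= 1.0):
            raise SpecificationError(f"{name} must lie in [0, 1], got {v}")
    if not (1 <= cfg.target <= cfg.N):
        raise SpecificationError("target outside the segment")
    spec = LatticeSpec((cfg.N, cfg.N), (cfg.q, cfg.q), kernel="product")
    op = cached_operator(spec)
    hset = HeterogeneitySet(spec)
    lam_in = cfg.alpha_e
    lam_out = 1.0 - cfg.alpha_u
    lam_diag = 1.0 - cfg.alpha_c
    for m in range(1, cfg.N + 1):
        y = (m, m)
        for x in op.neighbors(y):
            on_diag = x[0] == x[1]
            if on_diag:
                if x[0] > m and lam_diag > 0.0:  # each diagonal edge once
                    hset.add(DefectPair(y, x, lam_diag * op.entry(x, y),
                                        lam_diag * op.entry(y, x)))
            elif lam_in > 0.0 or lam_out > 0.0:
                hset.add(DefectPair(x, y, lam_in * op.entry(y, x),
                                    lam_out * op.entry(x, y)))
        # swap edge (m+1, m) <-> (m, m+1)
        if m < cfg.N and lam_in > 0.0:
            a, b = (m + 1, m), (m, m + 1)
            hset.add(DefectPair(a, b, lam_in * op.entry(b, a),
                                lam_in * op.entry(a, b)))
    return spec, hset


def coalescence_mfpt(cfg: CoalescenceConfig) -> float:
    """MFPT for the two particles to meet at the target site."""
    spec, hset = build_coalescence(cfg)
    gf = homogeneous_propagator_gf(spec)
    return mfpt(hset, gf, cfg.n0, cfg.target_state)


def coalescence_mfpt_map(
    cfg: CoalescenceConfig,
    alpha_u_grid: Sequence[float],
    alpha_c_grid: Sequence[float],
) -> pd.DataFrame:
    """Ratio of the interacting MFPT to the non-interacting one over an
    ``(alpha_u, alpha_c)`` grid at fixed ``alpha_e``.

    Columns: ``alpha_u``, ``alpha_c``, ``mfpt``, ``ratio``."""
    base = coalescence_mfpt(cfg.with_params(alpha_e=0.0, alpha_u=1.0, alpha_c=1.0))
    rows = []
    for au in alpha_u_grid:
        for ac in alpha_c_grid:
            val = coalescence_mfpt(cfg.with_params(alpha_u=au, alpha_c=ac))
            rows.append({
                "alpha_u": float(au), "alpha_c": float(ac),
                "mfpt": val, "ratio": val / base,
            })
    return pd.DataFrame(rows)
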