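"""First-passage, return and exit statistics: renewal relations, Kac's lemma,
and the quasi-1D single-barrier closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetwalk import (
    DefectPair,
    HeterogeneitySet,
    LatticeSpec,
    apply_defects,
    build_transition_operator,
    first_passage_distribution,
    fp_1d_barrier_gf,
    fp_gf_single,
    fp_gf_two_targets,
    homogeneous_mfpt_1d,
    homogeneous_propagator_gf,
    make_antibarrier,
    make_barrier,
    make_sticky,
    met,
    mfpt,
    mfpt_1d_barrier,
    mfpt_renewal_derivative,
    mrt,
    return_gf,
    solve_absorbing_means,
)

Q = 2.0 / 3.0
LAM = 0.975 * Q / 2.0


@pytest.fixture(scope="module")
def gf_1d():
    return homogeneous_propagator_gf(LatticeSpec((15,), (Q,)))


def barrier_set(spec, u, lam=LAM):
    return HeterogeneitySet(spec, [DefectPair((u,), (u + 1,), lam, lam)])


class TestRenewalRelation:
    def test_reduces_to_homogeneous(self, spec_2d_q02, gf_2d_q02):
        empty = HeterogeneitySet(spec_2d_q02)
        hs = HeterogeneitySet(spec_2d_q02, [DefectPair((5, 5), (5, 6), 0.0, 0.0)])
        for z in (0.4, 0.9):
            assert fp_gf_single(hs, gf_2d_q02, (6, 6), (2, 3), z) == pytest.approx(
                fp_gf_single(empty, gf_2d_q02, (6, 6), (2, 3), z), rel=1e-12
            )

    def test_impenetrable_barrier_behind_source_shifts_coordinates(self):
        """With the barrier sealed at u < n0, the walk is the homogeneous walk
        on sites shifted left by u."""
        spec = LatticeSpec((40,), (Q,))
        gf = homogeneous_propagator_gf(spec)
        u = 4
        hs = barrier_set(spec, u, Q / 2.0)
        empty = HeterogeneitySet(spec)
        for z in (0.5, 0.9):
            lhs = fp_gf_single(hs, gf, (8,), (15,), z)
            rhs = fp_gf_single(empty, gf, (8 - u,), (15 - u,), z)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_impenetrable_barrier_between_blocks(self, gf_1d):
        spec = gf_1d.spec
        hs = barrier_set(spec, 10, Q / 2.0)
        for z in (0.5, 0.9):
            assert abs(fp_gf_single(hs, gf_1d, (8,), (15,), z)) <= 1e-13
        assert mfpt(hs, gf_1d, (8,), (15,)) == math.inf


class TestReturnGF:
    def test_cannot_return_at_time_zero(self, mixed_set, gf_2d_q02):
        assert return_gf(mixed_set, gf_2d_q02, (3, 3), 0.0) == 0.0

    def test_two_site_chain_enumeration(self):
        """N=2, q=1 with the reflecting fold (stay 1/2): first-return times
        are R(1) = 1/2, R(t) = 2^-t for t >= 2, i.e. R~(z) = z/(2-z)."""
        spec = LatticeSpec((2,), (1.0,))
        gf = homogeneous_propagator_gf(spec)
        empty = HeterogeneitySet(spec)
        for z in (0.25, 0.6, 0.9):
            # enumeration oracle: z/2 + sum_{t>=2} (1/2)^t z^t
            oracle = z / 2.0 + sum((z / 2.0) ** t for t in range(2, 200))
            assert return_gf(empty, gf, (1,), z).real == pytest.approx(oracle, abs=1e-12)
            assert return_gf(empty, gf, (1,), z).real == pytest.approx(z / (2 - z))

    def test_recurrent_on_conserving_lattice(self, gf_1d):
        """R~(z) -> 1 as z -> 1 (certain return)."""
        empty = HeterogeneitySet(gf_1d.spec)
        assert return_gf(empty, gf_1d, (5,), 0.999995).real == pytest.approx(1.0, abs=1e-3)


class TestTwoTargets:
    def test_unreachable_cross_terms_add(self, gf_1d):
        """If the two targets cannot reach each other the combined GF is the
        sum of the individual ones (sealed halves)."""
        spec = gf_1d.spec
        hs = barrier_set(spec, 10, Q / 2.0)
        for z in (0.5, 0.8):
            both = fp_gf_two_targets(hs, gf_1d, (8,), (5,), (14,), z)
            one = fp_gf_single(hs, gf_1d, (8,), (5,), z)
            other = fp_gf_single(hs, gf_1d, (8,), (14,), z)
            assert both == pytest.approx(one + other, rel=1e-10)

    def test_total_mass_one_on_conserving_lattice(self, spec_2d_q02, gf_2d_q02):
        hs = HeterogeneitySet(spec_2d_q02, make_sticky(spec_2d_q02, (8, 8), 0.25))
        res = first_passage_distribution(hs, gf_2d_q02, (6, 6), [(4, 2), (10, 7)], T=80)
        assert res.reach_probability == pytest.approx(1.0, abs=1e-10)
        assert res.distribution.sum() < 1.0  # horizon-truncated

    def test_first_nonzero_time_is_shortest_path(self, spec_2d_q02, gf_2d_q02):
        """From (6,6) the closer target (10,7) is 5 steps away; the combined
        first-passage probability starts exactly there."""
        res = first_passage_distribution(
            HeterogeneitySet(spec_2d_q02), gf_2d_q02, (6, 6), [(4, 2), (10, 7)], T=12
        )
        first = int(np.nonzero(res.distribution > 1e-13)[0][0])
        assert first == 5


class TestMfpt:
    def test_disorder_indifference_values(self, gf_1d):
        """Barrier anywhere left of the source: MFPT stays at the homogeneous
        231 steps; at u=8 and u=14 it grows to 1167 and 1869."""
        spec = gf_1d.spec
        for u in range(1, 8):
            assert mfpt(barrier_set(spec, u), gf_1d, (8,), (15,)) == pytest.approx(
                231.0, abs=1e-6
            )
        assert mfpt(barrier_set(spec, 8), gf_1d, (8,), (15,)) == pytest.approx(1167.0, abs=1e-6)
        assert mfpt(barrier_set(spec, 14), gf_1d, (8,), (15,)) == pytest.approx(1869.0, abs=1e-6)

    def test_no_defects_gives_homogeneous_mean(self, gf_1d):
        empty = HeterogeneitySet(gf_1d.spec)
        assert mfpt(empty, gf_1d, (8,), (15,)) == pytest.approx(
            homogeneous_mfpt_1d(8, 15, Q), rel=1e-10
        )

    def test_agrees_with_renewal_derivative(self, gf_1d):
        """Absorbing-construction mean equals the z=1 derivative of the
        renewal ratio (Richardson extrapolated) to 1e-6 relative."""
        spec = gf_1d.spec
        for u in (3, 8, 14):
            hs = barrier_set(spec, u)
            a = mfpt(hs, gf_1d, (8,), (15,))
            b = mfpt_renewal_derivative(hs, gf_1d, (8,), (15,))
            assert b == pytest.approx(a, rel=1e-6)

    def test_agrees_with_linear_solve_on_2d_mixed_set(self, mixed_set, gf_2d_q02):
        spec = mixed_set.spec
        target = (9, 2)
        analytic = mfpt(mixed_set, gf_2d_q02, (6, 6), target)
        means = solve_absorbing_means(apply_defects(mixed_set), targets=[target])
        assert analytic == pytest.approx(means[spec.flat((6, 6))], rel=1e-8)

    def test_trap_makes_passage_uncertain(self, spec_2d_q02, gf_2d_q02):
        """A fully sticky site is an inescapable trap: infinite mean."""
        hs = HeterogeneitySet(spec_2d_q02, make_sticky(spec_2d_q02, (5, 5), 1.0))
        assert mfpt(hs, gf_2d_q02, (6, 6), (2, 2)) == math.inf


class Test1DBarrierClosedForms:
    def test_mean_formula_reference_values(self):
        assert mfpt_1d_barrier(8, 15, 4, LAM, Q) == pytest.approx(231.0)
        assert mfpt_1d_barrier(8, 15, 8, LAM, Q) == pytest.approx(1167.0)
        assert mfpt_1d_barrier(8, 15, 14, LAM, Q) == pytest.approx(1869.0)
        # per-unit-u coefficient 2*lam/(q*(q/2-lam)) = 117
        assert mfpt_1d_barrier(8, 15, 9, LAM, Q) - mfpt_1d_barrier(
            8, 15, 8, LAM, Q
        ) == pytest.approx(117.0)

    def test_zero_lambda_is_homogeneous(self):
        assert mfpt_1d_barrier(8, 15, 10, 0.0, Q) == pytest.approx(231.0)

    def test_impenetrable_ahead_diverges(self):
        assert mfpt_1d_barrier(8, 15, 10, Q / 2.0, Q) == math.inf

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n0=st.integers(min_value=1, max_value=10),
        dn=st.integers(min_value=1, max_value=8),
        u=st.integers(min_value=1, max_value=16),
        lam_frac=st.floats(min_value=-0.8, max_value=0.97),
        q=st.sampled_from([0.25, 2.0 / 3.0, 1.0]),
    )
    def test_mean_formula_matches_absorbing_chain_solve(self, n0, dn, u, lam_frac, q):
        """Closed-form mean equals the linear-solve oracle on the perturbed
        operator for arbitrary admissible placements and strengths."""
        n = n0 + dn
        if u >= n:
            u = n - 1
        lam = lam_frac * (q / 2.0) if lam_frac >= 0 else lam_frac * (1.0 - q)
        if q == 1.0 and lam < 0:
            lam = 0.0
        N = n
        spec = LatticeSpec((max(N, u + 2),), (q,), absorbing_sites=((n,),))
        op = build_transition_operator(spec)
        hs = HeterogeneitySet(spec, [DefectPair((u,), (u + 1,), lam, lam)])
        means = solve_absorbing_means(apply_defects(hs))
        assert means[n0 - 1] == pytest.approx(mfpt_1d_barrier(n0, n, u, lam, q), rel=1e-9)

    def test_gf_matches_defect_solver(self):
        """Closed-form generating function equals the defect-technique
        renewal ratio on a large truncated lattice."""
        spec = LatticeSpec((200,), (Q,))
        gf = homogeneous_propagator_gf(spec)
        zs = np.array([0.3, 0.6 + 0.2j, 0.9, 0.97])
        for u in (4, 10):
            hs = barrier_set(spec, u)
            exact = fp_gf_single(hs, gf, (8,), (15,), zs)
            closed = fp_1d_barrier_gf(8, 15, u, LAM, Q, zs)
            assert np.abs(exact - closed).max() <= 1e-12

    def test_gf_recovers_homogeneous_at_zero_lambda(self):
        zs = np.array([0.4, 0.8])
        zeta = np.arccosh(1.0 + (1.0 / zs - 1.0) / Q)
        hom = np.cosh(7.5 * zeta) / np.cosh(14.5 * zeta)
        assert np.abs(fp_1d_barrier_gf(8, 15, 5, 0.0, Q, zs) - hom).max() <= 1e-12

    def test_gf_series_matches_large_lattice_solver(self):
        """Inverted closed-form series equals the defect series on a large
        finite lattice over a long horizon."""
        from hetwalk import series_coefficients
        from hetwalk.solver import DefectSystem

        spec = LatticeSpec((200,), (Q,))
        gf = homogeneous_propagator_gf(spec)
        u = 4
        ds = DefectSystem(barrier_set(spec, u), gf)
        T = 600
        f = lambda zs: np.asarray(
            [ds.propagator((15,), (8,), z) / ds.propagator((15,), (15,), z) for z in np.atleast_1d(zs)]
        )
        a = series_coefficients(f, T=T)
        b = series_coefficients(lambda zs: fp_1d_barrier_gf(8, 15, u, LAM, Q, zs), T=T)
        assert np.abs(a - b).max() <= 1e-9


class TestDisorderIndifferenceProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(lam_frac=st.floats(min_value=-0.95, max_value=0.98))
    def test_mean_independent_of_lambda_behind_source(self, lam_frac):
        lam = lam_frac * (Q / 2.0) if lam_frac >= 0 else lam_frac * (1.0 - Q)
        spec = LatticeSpec((15,), (Q,))
        gf = homogeneous_propagator_gf(spec)
        hs = barrier_set(spec, 5, lam)
        assert mfpt(hs, gf, (8,), (15,)) == pytest.approx(231.0, abs=1e-8)

    def test_mean_strictly_increasing_in_lambda_ahead_of_source(self):
        spec = LatticeSpec((15,), (Q,))
        gf = homogeneous_propagator_gf(spec)
        lams = [-0.3, -0.1, 0.0, 0.1, 0.2, 0.3]
        vals = [mfpt(barrier_set(spec, 10, l), gf, (8,), (15,)) for l in lams]
        assert np.all(np.diff(vals) > 0)


class TestMrt:
    def test_symmetric_barrier_keeps_homogeneous_mrt(self):
        """Kac: the MRT of a 12-site segment stays 12 for any symmetric
        barrier."""
        spec = LatticeSpec((12,), (0.5,))
        gf = homogeneous_propagator_gf(spec)
        hs = HeterogeneitySet(spec, [DefectPair((5,), (6,), 0.15, 0.15)])
        assert mrt(hs, gf, (3,)) == pytest.approx(12.0, abs=1e-10)
        assert mrt(hs, gf, (9,)) == pytest.approx(12.0, abs=1e-10)

    def test_impenetrable_splits_into_segments(self):
        spec = LatticeSpec((12,), (0.5,))
        gf = homogeneous_propagator_gf(spec)
        hs = HeterogeneitySet(spec, [DefectPair((5,), (6,), 0.25, 0.25)])
        with pytest.warns(UserWarning):
            assert mrt(hs, gf, (2,)) == pytest.approx(5.0, abs=1e-10)
        with pytest.warns(UserWarning):
            assert mrt(hs, gf, (9,)) == pytest.approx(7.0, abs=1e-10)

    @pytest.mark.parametrize("l_up,l_down", [(0.1, 0.2), (0.05, 0.22), (0.24, 0.0)])
    def test_asymmetric_barrier_piecewise_formula(self, l_up, l_down):
        """Asymmetric lambda: the Kac MRT matches the piecewise closed form
        and 1/pi(n) exactly."""
        N, q, u = 12, 0.5, 5
        spec = LatticeSpec((N,), (q,))
        gf = homogeneous_propagator_gf(spec)
        hs = HeterogeneitySet(spec, [DefectPair((u,), (u + 1,), l_up, l_down)])

        def closed(n):
            if n < u + 1:
                return N * (q / 2 - l_up) / (q / 2 - l_down) - u * (l_down - l_up) / (
                    q / 2 - l_down
                )
            return N - u * (l_down - l_up) / (q / 2 - l_up)

        for n in (2, 5, 6, 11):
            assert mrt(hs, gf, (n,)) == pytest.approx(closed(n), abs=1e-10)


class TestMet:
    def test_small_chain_value(self):
        """Three sites, absorbing at 1, q=1: mean exit from site 3 is 6
        (hand-checkable 2x2 linear solve)."""
        spec = LatticeSpec((3,), (1.0,), boundary=("absorbing-low",))
        gf = homogeneous_propagator_gf(spec)
        assert met(HeterogeneitySet(spec), gf, (3,)) == pytest.approx(6.0, rel=1e-12)
        means = solve_absorbing_means(build_transition_operator(spec))
        assert means[2] == pytest.approx(6.0)
        assert means[1] == pytest.approx(4.0)

    def test_requires_absorption(self, mixed_set, gf_2d_q02):
        from hetwalk import DomainError

        with pytest.raises(DomainError):
            met(mixed_set, gf_2d_q02, (5, 5))

    def test_barriers_slow_and_antibarriers_speed_exit(self):
        """Random symmetric barriers raise the mean exit time; antibarriers
        lower it."""
        spec = LatticeSpec((9, 9), (0.8, 0.8), boundary=("absorbing-both", "absorbing-both"))
        gf = homogeneous_propagator_gf(spec)
        base = met(HeterogeneitySet(spec), gf, (5, 5))
        rng = np.random.default_rng(3)
        cols = rng.integers(2, 8, size=6)
        edges = [((r, int(c)), (r, int(c) + 1)) for r, c in zip(range(2, 8), cols)]
        hs_slow = HeterogeneitySet(spec, [make_barrier(spec, a, b, 0.8, 0.8) for a, b in edges])
        hs_fast = HeterogeneitySet(
            spec, [make_antibarrier(spec, a, b, 0.9, 0.9) for a, b in edges]
        )
        assert met(hs_slow, gf, (5, 5)) > base
        assert met(hs_fast, gf, (5, 5)) < base

    def test_sealed_start_is_infinite(self):
        """If impenetrable barriers enclose the start, the exit time is
        infinite."""
        spec = LatticeSpec((7,), (0.5,), boundary=("absorbing-low",))
        gf = homogeneous_propagator_gf(spec)
        hs = HeterogeneitySet(spec, [DefectPair((3,), (4,), 0.25, 0.25)])
        assert met(hs, gf, (5,)) == math.inf
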