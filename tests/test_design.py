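"""Covariance-sampling design comparison: feasibility geometry and summaries."""

import numpy as np
import pytest

from mrbounds import (
    CovTriple,
    MarginalTable,
    cov_feasible_interval,
    joint_from_cov,
    lp_sharp_bounds,
    multi_instrument_plausibility,
    pairwise_cov_constraint,
    plausible_one_sample_bounds,
    sample_cov_triples,
    two_sample_bounds,
    worked_example,
)


def brute_force_cov_interval(p1, q1, step=1e-3):
    """Scan covariances keeping all four 2x2 cells inside [0, 1]."""
    cov = np.arange(-1.0, 1.0 + step, step)
    p0, q0 = 1 - p1, 1 - q1
    cells = np.stack([
        p1 * q1 + cov, p0 * q0 + cov, p1 * q0 - cov, p0 * q1 - cov,
    ])
    ok = np.all((cells >= -1e-12) & (cells <= 1 + 1e-12), axis=0)
    return cov[ok].min(), cov[ok].max()


class TestCovInterval:
    def test_symmetric_case(self):
        m = MarginalTable(p_x=(0.5, 0.5, 0.5), p_y=(0.5, 0.5, 0.5))
        assert cov_feasible_interval(m, 0) == pytest.approx((-0.25, 0.25))

    def test_degenerate_exposure_pins_zero(self):
        m = MarginalTable(p_x=(0.0, 0.5, 1.0), p_y=(0.3, 0.4, 0.5))
        lo, hi = cov_feasible_interval(m, 0)
        assert lo == pytest.approx(0.0) and hi == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            p1, q1 = rng.uniform(0.02, 0.98, size=2)
            m = MarginalTable(p_x=(p1, 0.5, 0.5), p_y=(q1, 0.5, 0.5))
            lo, hi = cov_feasible_interval(m, 0)
            blo, bhi = brute_force_cov_interval(p1, q1)
            assert lo == pytest.approx(blo, abs=2e-3)
            assert hi == pytest.approx(bhi, abs=2e-3)


class TestPairwiseConstraint:
    def test_identical_levels_admit_equal_covs(self, feasible_tables):
        for m in feasible_tables[:20]:
            dup = MarginalTable(
                p_x=(m.p_x[0], m.p_x[0], m.p_x[1]),
                p_y=(m.p_y[0], m.p_y[0], m.p_y[1]),
            )
            lo, hi = pairwise_cov_constraint(dup, 0, 1)
            assert lo <= 0.0 <= hi

    def test_worked_example_nonempty(self):
        m = worked_example("A2")
        for z in range(3):
            for z2 in range(3):
                if z != z2:
                    lo, hi = pairwise_cov_constraint(m, z, z2)
                    assert lo <= hi

    def test_same_level_rejected(self, null_table):
        with pytest.raises(ValueError):
            pairwise_cov_constraint(null_table, 1, 1)

    def test_matches_brute_force(self, rng):
        # scan pairs of covariances; admissible iff cells valid at both
        # levels and the cross-level one-sample IV inequalities hold
        step = 2e-3
        for _ in range(8):
            px = rng.uniform(0.05, 0.95, size=3)
            py = rng.uniform(0.05, 0.95, size=3)
            m = MarginalTable(p_x=px, p_y=py)
            z, z2 = 0, 1
            lo0, hi0 = cov_feasible_interval(m, z)
            lo1, hi1 = cov_feasible_interval(m, z2)
            c0 = np.arange(lo0, hi0 + step, step)
            c1 = np.arange(lo1, hi1 + step, step)
            g0, g1 = np.meshgrid(c0, c1, indexing="ij")
            cells = {}
            for lev, cov in ((z, g0), (z2, g1)):
                p1, q1 = px[lev], py[lev]
                cells[lev] = {
                    (1, 1): p1 * q1 + cov,
                    (0, 0): (1 - p1) * (1 - q1) + cov,
                    (1, 0): p1 * (1 - q1) - cov,
                    (0, 1): (1 - p1) * q1 - cov,
                }
            ok = np.ones_like(g0, dtype=bool)
            for x in (0, 1):
                for y in (0, 1):
                    ok &= cells[z][(x, y)] + cells[z2][(x, 1 - y)] <= 1 + 1e-12
            if not ok.any():
                continue
            diffs = (g0 - g1)[ok]
            # the printed pairwise interval constrains the difference; the
            # achievable range is its intersection with the box differences
            lo, hi = pairwise_cov_constraint(m, z, z2)
            lo = max(lo, lo0 - hi1)
            hi = min(hi, hi0 - lo1)
            assert diffs.min() == pytest.approx(lo, abs=4e-3)
            assert diffs.max() == pytest.approx(hi, abs=4e-3)


class TestJointFromCov:
    def test_independence_at_zero_cov(self, null_table):
        joint = joint_from_cov(null_table, CovTriple(cov=np.zeros(3)))
        np.testing.assert_allclose(joint.cells, 0.25)

    def test_round_trip(self, feasible_tables, rng):
        for m in feasible_tables[:40]:
            intervals = [cov_feasible_interval(m, z) for z in range(3)]
            cov = np.array([rng.uniform(lo, hi) for lo, hi in intervals])
            joint = joint_from_cov(m, CovTriple(cov=cov))
            got = joint.marginals()
            np.testing.assert_allclose(got.p_x, m.p_x, atol=1e-12)
            np.testing.assert_allclose(got.p_y, m.p_y, atol=1e-12)
            np.testing.assert_allclose(joint.conditional_cov(), cov, atol=1e-12)

    def test_infeasible_cov_rejected(self, null_table):
        with pytest.raises(ValueError):
            joint_from_cov(null_table, CovTriple(cov=np.array([0.9, 0.0, 0.0])))


class TestSampling:
    @pytest.mark.parametrize("scheme", ["rejection", "sequential"])
    def test_samples_satisfy_all_constraints(self, scheme):
        m = worked_example("B2")
        triples = sample_cov_triples(m, 200, seed=1, scheme=scheme)
        assert len(triples) == 200
        for t in triples:
            for z in range(3):
                lo, hi = cov_feasible_interval(m, z)
                assert lo - 1e-9 <= t.cov[z] <= hi + 1e-9
                for z2 in range(3):
                    if z2 != z:
                        dlo, dhi = pairwise_cov_constraint(m, z, z2)
                        assert dlo - 1e-9 <= t.cov[z] - t.cov[z2] <= dhi + 1e-9

    def test_deterministic_given_seed(self):
        m = worked_example("A3")
        a = sample_cov_triples(m, 50, seed=7)
        b = sample_cov_triples(m, 50, seed=7)
        np.testing.assert_array_equal(
            np.array([t.cov for t in a]), np.array([t.cov for t in b])
        )

    def test_point_identified_marginals_give_constant_triples(self):
        m = MarginalTable(p_x=(0.0, 0.5, 1.0), p_y=(0.3, 0.45, 0.6))
        triples = sample_cov_triples(m, 20, seed=2)
        covs = np.array([t.cov for t in triples])
        # z=0 and z=2 are degenerate exposures: covariance pinned at 0
        np.testing.assert_allclose(covs[:, [0, 2]], 0.0, atol=1e-12)

    def test_iv_violating_marginals_rejected(self):
        m = MarginalTable(p_x=(0.01, 0.01, 0.01), p_y=(0.05, 0.9, 0.05))
        with pytest.raises(ValueError, match="IV"):
            sample_cov_triples(m, 10, seed=0)

    def test_unknown_scheme(self, null_table):
        with pytest.raises(ValueError):
            sample_cov_triples(null_table, 10, seed=0, scheme="bogus")


class TestPlausibility:
    def test_summary_accounting(self):
        s = plausible_one_sample_bounds(worked_example("A2"), n=300, seed=3)
        assert s.n_samples + s.n_infeasible == 300
        assert s.frac_excluding_zero == pytest.approx(
            s.frac_above_zero + s.frac_below_zero
        )
        assert 0.0 <= s.frac_excluding_zero <= 1.0

    def test_one_sample_draws_inside_two_sample_bound(self):
        m = worked_example("C3")
        two = two_sample_bounds(m)
        s = plausible_one_sample_bounds(m, n=200, seed=5)
        for b in s.bounds:
            assert b.lower >= two.lower - 1e-7
            assert b.upper <= two.upper + 1e-7

    def test_sampled_joints_match_lp_route(self):
        m = worked_example("B1")
        triples = sample_cov_triples(m, 30, seed=9)
        s = plausible_one_sample_bounds(m, n=30, seed=9)
        recomputed = [
            lp_sharp_bounds(joint_from_cov(m, t), "one") for t in triples
        ]
        kept = [b for b in recomputed if b is not None]
        assert len(kept) == s.n_samples
        for got, want in zip(s.bounds, kept):
            assert got.lower == pytest.approx(want.lower, abs=1e-12)

    def test_multi_instrument_reduces_to_single(self):
        m = worked_example("A3")
        multi = multi_instrument_plausibility([m], n=150, seed=11)
        assert multi.n_samples + multi.n_infeasible == 150
        assert 0.0 <= multi.frac_excluding_zero <= 1.0

    def test_intersection_no_wider_than_single_worst(self):
        ms = [worked_example("A2"), worked_example("B2")]
        multi = multi_instrument_plausibility(ms, n=100, seed=13)
        singles = [
            plausible_one_sample_bounds(m, n=100, seed=13) for m in ms
        ]
        worst = max(
            max(b.length for b in s.bounds) for s in singles
        )
        assert all(b.length <= worst + 1e-9 for b in multi.bounds)
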