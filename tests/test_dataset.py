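"""Dataset assembly: priors, tree heights, constrained resampling."""

import dendropy
import numpy as np
import pytest

from tdrp.dataset import (
    CalibrationPrior,
    CospeciationDataset,
    NodeRecord,
    SimulationFailure,
    assemble_rate_sets,
    node_heights,
    sigma_from_interval,
    simulate_calibration_times,
)


def make_chain(specs):
    """Chain dataset from (node_id, s, t_median, t_lo, t_hi) tuples, deepest first."""
    recs = []
    prev = None
    for nid, s, *cal in specs:
        calib = CalibrationPrior(*cal) if cal and cal[0] is not None else None
        recs.append(NodeRecord(nid, prev, np.atleast_1d(s), calib))
        prev = nid
    return CospeciationDataset(recs)


class TestSigma:
    @pytest.mark.parametrize(
        "median,lo,hi,expected",
        [(10, 6.08, 11.96, 2.0), (5, 3.04, 6.96, 1.0), (43.47, 43.47, 43.47, 0.0)],
    )
    def test_wider_half_interval(self, median, lo, hi, expected):
        assert sigma_from_interval(median, lo, hi) == pytest.approx(expected)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            sigma_from_interval(5, 6, 7)


class TestNodeHeights:
    def test_two_tip_tree(self):
        tree = dendropy.Tree.get(data="(A:0.3,B:0.3)N1;", schema="newick")
        assert node_heights(tree) == {"N1": pytest.approx(0.3)}

    def test_ladder_tree_against_path_enumeration(self):
        # ultrametric ladder with node heights 1, 2, 3
        nwk = "(((A:1,B:1)N1:1,C:2)N2:1,D:3)N3;"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        h = node_heights(tree)
        assert h == {"N1": pytest.approx(1.0), "N2": pytest.approx(2.0), "N3": pytest.approx(3.0)}

    def test_non_ultrametric_rejected(self):
        tree = dendropy.Tree.get(data="((A:1,B:1.1)N1:1,C:2)N2;", schema="newick")
        with pytest.raises(ValueError, match="ultrametric"):
            node_heights(tree)


class TestDatasetInvariants:
    def test_child_median_must_be_below_parent(self):
        with pytest.raises(ValueError, match="not below"):
            make_chain([("p", 0.5, 10, 8, 12), ("c", 0.3, 20, 18, 22)])

    def test_s_median_ordering_enforced(self):
        with pytest.raises(ValueError, match="s median"):
            make_chain([("p", 0.2, 10, 8, 12), ("c", 0.4, 5, 4, 6)])

    def test_single_root_required(self):
        recs = [
            NodeRecord("a", None, np.array([1.0])),
            NodeRecord("b", None, np.array([0.5])),
        ]
        with pytest.raises(ValueError, match="root"):
            CospeciationDataset(recs)


class TestSimulateTimes:
    def test_marginals_and_ordering(self):
        ds = make_chain([("p", 0.9, 100, 98.04, 101.96), ("c", 0.3, 10, 8.04, 11.96)])
        draws = simulate_calibration_times(ds, 10_000, seed=5)
        assert np.all(draws["c"] < draws["p"])
        for nid, med in (("p", 100), ("c", 10)):
            se = 1.0 / np.sqrt(10_000)
            assert abs(draws[nid].mean() - med) < 3 * se
            assert abs(draws[nid].std() - 1.0) < 0.05

    def test_child_conditional_is_truncated_normal(self):
        """Given the parent's draw, the child draw follows the parent-upper-
        truncated normal exactly: its probability-integral transform
        u = Phi((c - mu)/sd) / Phi((p - mu)/sd) must be Uniform(0, 1)."""
        from scipy import stats

        ds = make_chain([("p", 0.9, 20, 16.08, 23.92), ("c", 0.3, 16, 12.08, 19.92)])
        draws = simulate_calibration_times(ds, 20_000, seed=5)
        u = stats.norm.cdf(draws["c"], 16, 2.0) / stats.norm.cdf(draws["p"], 16, 2.0)
        assert stats.kstest(u, "uniform").pvalue > 0.01
        # and the parent's marginal is its untruncated prior
        assert stats.kstest(draws["p"], stats.norm(20, 2.0).cdf).pvalue > 0.01

    def test_infeasible_ordering_fails(self):
        # medians are ordered, but the parent's wide prior often falls below
        # the child's point-mass prior, leaving no feasible child draw
        ds = make_chain([("p", 0.9, 10, 0.2, 19.8), ("c", 0.3, 9.9, 9.9, 9.9)])
        with pytest.raises(SimulationFailure):
            simulate_calibration_times(ds, 50, seed=1)

    def test_degenerate_prior_returns_median(self):
        ds = make_chain([("only", 0.5, 43.47, 43.47, 43.47)])
        draws = simulate_calibration_times(ds, 50, seed=2)
        assert np.all(draws["only"] == 43.47)

    def test_seed_determinism(self):
        ds = make_chain([("p", 0.9, 100, 90, 110), ("c", 0.3, 10, 9, 11)])
        a = simulate_calibration_times(ds, 100, seed=7)
        b = simulate_calibration_times(ds, 100, seed=7)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


class TestAssemble:
    def test_identity_and_conservation(self, noiseless):
        data, _ = noiseless
        sets = assemble_rate_sets(data, 5, seed=3)
        assert len(sets) == 5
        dated = set(data.dated_ids)
        for pts in sets:
            assert set(pts.node_ids) == dated
            np.testing.assert_allclose(pts.rbar_per_year * pts.t_myr * 1e6, pts.s, rtol=1e-15)

    def test_zero_variance_gives_identical_sets(self, noiseless):
        data, _ = noiseless
        sets = assemble_rate_sets(data, 4, seed=3)
        for pts in sets[1:]:
            np.testing.assert_array_equal(pts.t_myr, sets[0].t_myr)
            np.testing.assert_array_equal(pts.s, sets[0].s)

    def test_invalid_count_rejected(self, noiseless):
        with pytest.raises(ValueError):
            assemble_rate_sets(noiseless[0], 0, seed=1)

    def test_seed_determinism(self):
        from tdrp import SyntheticScenario, generate_dataset

        data, _ = generate_dataset(SyntheticScenario(seed=3))
        a = assemble_rate_sets(data, 10, seed=77)
        b = assemble_rate_sets(data, 10, seed=77)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.t_myr, y.t_myr)
            np.testing.assert_array_equal(x.s, y.s)
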