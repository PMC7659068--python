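import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from codiv import (
    AssociationData,
    DistanceMatrix,
    InfectionTable,
    Observation,
    association_from_infections,
    conservative_paco,
    jackknife_links,
    link_expand,
    paco_test,
    pcoa,
    procrustes_m2,
)
from codiv.paco import PcoaResult

from helpers import procrustes_m2_oracle, random_centered


def dm_from_points(points, labels=None):
    n = len(points)
    labels = labels or tuple(f"x{i}" for i in range(n))
    return DistanceMatrix(tuple(labels), squareform(pdist(points)))


class TestPcoa:
    def test_collinear_points_give_one_axis(self):
        dm = dm_from_points(np.array([[0.0], [1.0], [2.0], [3.0]]))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 1
        gaps = np.abs(np.diff(res.coordinates[:, 0]))
        np.testing.assert_allclose(gaps, 1.0, atol=1e-10)

    def test_all_zero_matrix_is_degenerate(self):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            pcoa(dm)

    @pytest.mark.parametrize("dims", [2, 3])
    def test_euclidean_distances_recovered(self, rng, dims):
        points = rng.normal(size=(10, dims))
        dm = dm_from_points(points)
        res = pcoa(dm)
        recovered = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(recovered, dm.values, atol=1e-8)

    def test_missing_entries_refused(self):
        values = np.array(
            [[0.0, 1.0, np.nan], [1.0, 0.0, 1.0], [np.nan, 1.0, 0.0]]
        )
        dm = DistanceMatrix(("a", "b", "c"), values)
        with pytest.raises(ValueError, match="missing"):
            pcoa(dm)

    def test_eigenvalues_descending_and_positive(self, rng):
        dm = dm_from_points(rng.normal(size=(8, 3)))
        res = pcoa(dm)
        assert np.all(np.diff(res.eigenvalues) <= 0)
        assert np.all(res.eigenvalues > 0)

    def test_matches_skbio_on_euclidean_input(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        points = rng.normal(size=(7, 3))
        dm = dm_from_points(points)
        ours = pcoa(dm)
        theirs = skbio_ordination.pcoa(dm.values, method="eigh")
        np.testing.assert_allclose(
            ours.eigenvalues,
            np.asarray(theirs.eigvals)[: len(ours.eigenvalues)],
            atol=1e-8,
        )

    def test_cailliez_correction_embeds_non_euclidean_input(self):
        # A star-like non-Euclidean metric: dropping negative eigenvalues
        # loses distance; the corrected embedding preserves order.
        values = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 2.0, 2.0],
                [1.0, 2.0, 0.0, 2.0],
                [1.0, 2.0, 2.0, 0.0],
            ]
        )
        dm = DistanceMatrix(("a", "b", "c", "d"), values)
        res = pcoa(dm, correction="cailliez")
        rec = squareform(pdist(res.coordinates))
        # corrected distances = original + constant off the diagonal
        offset = rec[0, 1] - values[0, 1]
        assert offset >= 0
        np.testing.assert_allclose(
            rec, values + offset * (1 - np.eye(4)), atol=1e-6
        )


class TestLinkExpand:
    def _pcoas(self, rng):
        hx = pcoa(dm_from_points(rng.normal(size=(4, 2)), list("ABCD")))
        py = pcoa(dm_from_points(rng.normal(size=(3, 2)), list("xyz")))
        return hx, py

    def test_host_row_duplicated_per_link(self, rng):
        hx, py = self._pcoas(rng)
        links = [("A", "x"), ("A", "y"), ("B", "z")]
        xc, yc = link_expand(hx, py, links)
        assert xc.shape[0] == yc.shape[0] == 3
        np.testing.assert_allclose(xc[0], xc[1])

    def test_narrower_matrix_zero_padded(self):
        hx = PcoaResult(("A", "B", "C"), np.eye(3), np.ones(3))
        py = PcoaResult(
            ("x", "y", "z"), np.arange(6, dtype=float).reshape(3, 2), np.ones(2)
        )
        links = [("A", "x"), ("B", "y"), ("C", "z")]
        xc, yc = link_expand(hx, py, links)
        assert xc.shape == yc.shape == (3, 3)
        # padded third column of Y is zero even after centering
        np.testing.assert_array_equal(yc[:, 2], 0.0)

    def test_columns_centered(self, rng):
        hx, py = self._pcoas(rng)
        links = [("A", "x"), ("B", "y"), ("C", "z"), ("D", "x")]
        xc, yc = link_expand(hx, py, links)
        np.testing.assert_allclose(xc.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(yc.mean(axis=0), 0.0, atol=1e-12)

    def test_unknown_label_named_in_error(self, rng):
        hx, py = self._pcoas(rng)
        with pytest.raises(KeyError, match="nope"):
            link_expand(hx, py, [("nope", "x"), ("A", "y"), ("B", "z")])


class TestProcrustes:
    def test_identical_configurations_give_zero(self, rng):
        x = random_centered(rng, 6, 2)
        m2, res = procrustes_m2(x, x)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_invariance_under_rotation_and_scaling(self, rng):
        x = random_centered(rng, 8, 2)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y = 2.5 * x @ rot
        m2, _ = procrustes_m2(x, y)
        assert m2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            x = random_centered(rng, 6, 2)
            y = random_centered(rng, 6, 2)
            m2, _ = procrustes_m2(x, y)
            assert m2 == pytest.approx(procrustes_m2_oracle(x, y), abs=1e-6)

    def test_zero_parasite_configuration_rejected(self, rng):
        x = random_centered(rng, 5, 2)
        with pytest.raises(ValueError, match="scale"):
            procrustes_m2(x, np.zeros_like(x))

    def test_uncentered_input_rejected(self, rng):
        x = rng.normal(size=(5, 2)) + 10.0
        with pytest.raises(ValueError, match="centered"):
            procrustes_m2(x, x)


class TestPacoTest:
    def _congruent(self, rng, n=16):
        points = rng.normal(size=(n, 2))
        hosts = tuple(f"h{i}" for i in range(n))
        paras = tuple(f"p{i}" for i in range(n))
        dh = dm_from_points(points, hosts)
        dp = dm_from_points(points, paras)
        links = tuple(zip(hosts, paras))
        return dh, dp, links

    def test_identical_matrices_identity_links_significant(self, rng):
        dh, dp, links = self._congruent(rng)
        res = paco_test(dh, dp, links, n_perm=999, seed=7)
        assert res.p_value <= 0.01
        assert res.m2_global == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical_results(self, rng):
        dh, dp, links = self._congruent(rng, n=8)
        a = paco_test(dh, dp, links, n_perm=199, seed=11)
        b = paco_test(dh, dp, links, n_perm=199, seed=11)
        assert a == b

    def test_refuses_too_few_permutations(self, rng):
        dh, dp, links = self._congruent(rng, n=6)
        with pytest.raises(ValueError, match="force"):
            paco_test(dh, dp, links, n_perm=50)
        res = paco_test(dh, dp, links, n_perm=50, force=True)
        assert res.p_value >= 1 / 51

    def test_residuals_sum_to_global_m2(self, rng):
        n = 10
        dh = dm_from_points(rng.normal(size=(n, 2)), [f"h{i}" for i in range(n)])
        dp = dm_from_points(rng.normal(size=(n, 2)), [f"p{i}" for i in range(n)])
        links = tuple((f"h{i}", f"p{i}") for i in range(n))
        res = paco_test(dh, dp, links, n_perm=199, seed=3)
        total = sum(lr.observed for lr in res.link_residuals)
        assert total == pytest.approx(res.m2_global, abs=1e-9)

    def test_invariant_under_relabeling(self, rng):
        dh, dp, links = self._congruent(rng, n=8)
        perm = rng.permutation(len(dh))
        relabeled = DistanceMatrix(
            tuple(dh.labels[i] for i in perm), dh.values[np.ix_(perm, perm)]
        )
        a = paco_test(dh, dp, links, n_perm=199, seed=5)
        b = paco_test(relabeled, dp, links, n_perm=199, seed=5)
        assert a.m2_global == pytest.approx(b.m2_global, abs=1e-9)
        assert a.p_value == b.p_value

    def test_p_value_stable_across_permutation_counts(self, rng):
        # p from N and 10N permutations agree within 3 Monte-Carlo SEs
        n = 12
        points_h = rng.normal(size=(n, 2))
        points_p = points_h + rng.normal(scale=0.6, size=(n, 2))
        dh = dm_from_points(points_h, [f"h{i}" for i in range(n)])
        dp = dm_from_points(points_p, [f"p{i}" for i in range(n)])
        links = tuple((f"h{i}", f"p{i}") for i in range(n))
        p1 = paco_test(dh, dp, links, n_perm=499, seed=1).p_value
        p2 = paco_test(dh, dp, links, n_perm=4999, seed=2).p_value
        se = np.sqrt(p2 * (1 - p2) / 499)
        assert abs(p1 - p2) <= 3 * se + 1e-9


class TestJackknife:
    def test_congruent_data_has_near_zero_estimates(self, rng):
        n = 10
        points = rng.normal(size=(n, 2))
        dh = dm_from_points(points, [f"h{i}" for i in range(n)])
        dp = dm_from_points(points, [f"p{i}" for i in range(n)])
        links = tuple((f"h{i}", f"p{i}") for i in range(n))
        estimates, upper = jackknife_links(dh, dp, links)
        np.testing.assert_allclose(estimates, 0.0, atol=1e-9)
        assert np.all(upper >= estimates)

    def test_planted_outlier_has_largest_estimate(self, rng):
        n = 12
        points = rng.normal(size=(n, 2))
        hosts = [f"h{i}" for i in range(n)]
        paras = [f"p{i}" for i in range(n)]
        dh = dm_from_points(points, hosts)
        dp = dm_from_points(points, paras)
        # all links faithful except p0, attached to the wrong host
        far = int(np.argmax(dh.values[0]))
        links = [(f"h{far}", "p0")] + [(f"h{i}", f"p{i}") for i in range(1, n)]
        estimates, _ = jackknife_links(dh, dp, links)
        assert int(np.argmax(estimates)) == 0

    def test_estimates_track_observed_residuals(self, rng):
        n = 14
        dh = dm_from_points(rng.normal(size=(n, 3)), [f"h{i}" for i in range(n)])
        dp = dm_from_points(rng.normal(size=(n, 3)), [f"p{i}" for i in range(n)])
        links = tuple((f"h{i}", f"p{i}") for i in range(n))
        res = paco_test(dh, dp, links, n_perm=99, seed=0, force=True)
        observed = [lr.observed for lr in res.link_residuals]
        estimates = [lr.jackknife_estimate for lr in res.link_residuals]
        rho = spearmanr(observed, estimates).statistic
        assert rho > 0.8

    def test_too_few_links_rejected(self, rng):
        dh = dm_from_points(rng.normal(size=(3, 2)), ["h0", "h1", "h2"])
        dp = dm_from_points(rng.normal(size=(3, 2)), ["p0", "p1", "p2"])
        links = (("h0", "p0"), ("h1", "p1"), ("h2", "p2"))
        with pytest.raises(ValueError, match="4"):
            jackknife_links(dh, dp, links)


class TestConservativePaco:
    def _assoc(self):
        table = InfectionTable(
            (
                Observation("o1", "h0", ("pA", "pB")),   # ambiguous
                Observation("o2", "h1", ("pA", "pC")),   # ambiguous
                Observation("o3", "h2", ("pB",)),
                Observation("o4", "h3", ("pC",)),
                Observation("o5", "h4", ("pD",)),
            )
        )
        return association_from_infections(table)

    def test_ambiguity_expands_to_product_of_candidates(self):
        assoc = self._assoc()
        assert len(assoc.alternatives) == 4
        assert assoc.links in assoc.alternatives

    def test_selected_p_is_maximum(self, rng):
        assoc = self._assoc()
        labels_h = sorted({h for h, _ in assoc.links})
        labels_p = sorted({p for alt in assoc.alternatives for _, p in alt})
        dh = dm_from_points(rng.normal(size=(len(labels_h), 2)), labels_h)
        dp = dm_from_points(rng.normal(size=(len(labels_p), 2)), labels_p)
        selected, results = conservative_paco(dh, dp, assoc, n_perm=199, seed=4)
        assert selected.p_value == max(r.p_value for r in results)
        assert len(results) == 4

    def test_no_ambiguity_selected_equals_single_run(self, rng):
        table = InfectionTable(
            tuple(
                Observation(f"o{i}", f"h{i}", (f"p{i}",)) for i in range(6)
            )
        )
        assoc = association_from_infections(table)
        assert len(assoc.alternatives) == 1
        dh = dm_from_points(rng.normal(size=(6, 2)), [f"h{i}" for i in range(6)])
        dp = dm_from_points(rng.normal(size=(6, 2)), [f"p{i}" for i in range(6)])
        selected, results = conservative_paco(dh, dp, assoc, n_perm=199, seed=9)
        assert results == (selected,)

    def test_alternative_cap_enforced(self, rng):
        rows = tuple(
            Observation(f"o{i}", f"h{i}", (f"pa{i}", f"pb{i}")) for i in range(8)
        )
        assoc = association_from_infections(InfectionTable(rows))
        assert len(assoc.alternatives) == 256
        dh = dm_from_points(rng.normal(size=(8, 2)), [f"h{i}" for i in range(8)])
        labels_p = sorted({p for alt in assoc.alternatives for _, p in alt})
        dp = dm_from_points(rng.normal(size=(len(labels_p), 2)), labels_p)
        with pytest.raises(ValueError, match="cap"):
            conservative_paco(dh, dp, assoc, n_perm=199, seed=0)


class TestAssociationData:
    def test_fewer_than_three_links_rejected(self):
        with pytest.raises(ValueError, match="3"):
            AssociationData(("h0", "h1"), ("p0",), (("h0", "p0"), ("h1", "p0")))

    def test_uncovered_labels_rejected(self):
        with pytest.raises(ValueError, match="host"):
            AssociationData(
                ("h0", "h1", "h2", "h3"),
                ("p0", "p1", "p2"),
                (("h0", "p0"), ("h1", "p1"), ("h2", "p2")),
            )
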