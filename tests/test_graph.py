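"""Driver: components, coding selection, hierarchy, full multi-scale runs."""

import numpy as np
import pytest
import scipy.sparse
import scipy.sparse.csgraph

from wfclust import (
    Dataset,
    RunConfig,
    build_hierarchy,
    connected_components,
    make_mixture,
    make_planted_binary,
    default_mixture_spec,
    PlantedBinarySpec,
    run_wfc,
    run_wfc_codes,
    select_coding,
)


def csgraph_oracle(n, edges):
    """Independent component labeling via scipy's BFS-based routine."""
    edges = list(edges)
    if edges:
        i, j = zip(*edges)
    else:
        i, j = [], []
    adj = scipy.sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    _, comp = scipy.sparse.csgraph.connected_components(adj, directed=False)
    return comp


def same_partition(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    # identical grouping regardless of label values
    return len(set(zip(a.tolist(), b.tolist()))) == len(set(a.tolist())) == len(set(b.tolist()))


class TestConnectedComponents:
    def test_chain_and_singletons(self):
        sc = connected_components(5, [(0, 1), (1, 2)])
        assert sc.labels.tolist() == [0, 0, 0, 3, 4]
        assert sc.sizes == {0: 3, 3: 1, 4: 1}
        assert sc.isolated == (3, 4)

    def test_empty_graph(self):
        sc = connected_components(3, [])
        assert sc.labels.tolist() == [0, 1, 2]
        assert len(sc.isolated) == 3

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(10):
            n = 200
            m = rng.integers(0, 400)
            edges = [(int(a), int(b)) for a, b in rng.integers(0, n, size=(m, 2))]
            sc = connected_components(n, edges)
            assert same_partition(sc.labels, csgraph_oracle(n, edges))
            assert sum(sc.sizes.values()) == n

    def test_out_of_range_edge_rejected(self):
        with pytest.raises(ValueError):
            connected_components(3, [(0, 5)])

    def test_labels_are_smallest_member_index(self, rng):
        sc = connected_components(6, [(4, 5), (2, 4)])
        assert set(sc.sizes) == {0, 1, 2, 3}
        for cid in sc.sizes:
            assert sc.labels[cid] == cid
            assert (np.nonzero(sc.labels == cid)[0].min()) == cid


class TestSelectCoding:
    @pytest.mark.parametrize(
        "n,d,override,expected",
        [(10**6, 2, None, "sd"), (10**4, 2000, None, "dm"), (100, 2000, "dm", "dm")],
    )
    def test_selection(self, n, d, override, expected):
        assert select_coding(n, d, override) == expected

    def test_sd_override_infeasible_in_high_dimension(self):
        with pytest.raises(ValueError):
            select_coding(100, 2000, "sd")


class TestHierarchy:
    def test_refinement_links_children_to_root(self):
        s1 = connected_components(4, [(0, 1), (1, 2), (2, 3)], scale=1)
        s2 = connected_components(4, [(0, 1), (2, 3)], scale=2)
        h = build_hierarchy([s1, s2])
        assert len(h.roots) == 1
        kids = h.children(1, 0)
        assert sorted(k.cluster_id for k in kids) == [0, 2]
        assert all(k.size == 2 for k in kids)

    def test_single_scale_has_roots_only(self):
        s1 = connected_components(3, [(0, 1)], scale=1)
        h = build_hierarchy([s1])
        assert len(h.roots) == 2
        assert h.repaired_parents == 0

    def test_inconsistent_n_rejected(self):
        a = connected_components(3, [], scale=1)
        b = connected_components(4, [], scale=2)
        with pytest.raises(ValueError):
            build_hierarchy([a, b])

    def test_strict_mode_raises_on_non_nested_partitions(self):
        s1 = connected_components(4, [(0, 1), (2, 3)], scale=1)
        s2 = connected_components(4, [(1, 2)], scale=2)  # spans both coarse clusters
        with pytest.raises(ValueError):
            build_hierarchy([s1, s2], strict=True)
        h = build_hierarchy([s1, s2], strict=False)
        assert h.repaired_parents == 1


class TestRunWfc:
    def test_single_blob_is_one_cluster_at_scale_one(self, rng):
        X = Dataset.from_array(rng.normal(size=(120, 2)))
        res = run_wfc(X, lambda_=1.0, seed=0)
        assert res.per_scale[0].n_clusters == 1

    def test_deterministic_under_seed(self):
        codes, _ = make_planted_binary(PlantedBinarySpec(seed=3, n_clusters=3, points_per_cluster=60))
        r1 = run_wfc_codes(codes, lambda_=0.25, seed=11)
        r2 = run_wfc_codes(codes, lambda_=0.25, seed=11)
        assert np.array_equal(r1.labels_matrix(), r2.labels_matrix())
        assert r1.schedule == r2.schedule

    def test_dm_partitions_refine_across_scales(self, small_planted):
        _, codes, _ = small_planted
        res = run_wfc_codes(codes, lambda_=0.25, seed=0)
        assert res.hierarchy.repaired_parents == 0
        for prev, cur in zip(res.per_scale, res.per_scale[1:]):
            # every finer cluster lies inside one coarser cluster
            for cid in cur.sizes:
                parents = set(prev.labels[cur.labels == cid].tolist())
                assert len(parents) == 1

    def test_duplicated_points_cluster_together_at_every_scale(self):
        X = Dataset.from_array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        res = run_wfc(X, lambda_=1.0)
        for sc in res.per_scale:
            assert sc.labels[0] == sc.labels[1]
            assert sc.labels[2] == sc.labels[3]

    def test_s_end_monotone_in_lambda_on_fixed_data(self):
        X, _ = make_mixture(default_mixture_spec(seed=0))
        ends = []
        for lam in (0.25, 0.5, 1.0):
            ends.append(run_wfc(X, lambda_=lam, seed=0).schedule.s_end)
        assert ends == sorted(ends, reverse=True)

    def test_cluster_sizes_sum_to_n(self, small_planted):
        _, codes, _ = small_planted
        res = run_wfc_codes(codes, lambda_=0.5, seed=0)
        for sc in res.per_scale:
            assert sum(sc.sizes.values()) == len(codes)

    def test_log_records_every_scale(self, rng):
        X = Dataset.from_array(rng.normal(size=(60, 2)))
        res = run_wfc(X, lambda_=1.0, seed=0)
        assert [rec["scale"] for rec in res.log] == list(range(1, res.schedule.s_end + 1))
        assert all(rec["clusters"] >= 1 for rec in res.log)

    def test_invalid_lambda_rejected(self, rng):
        X = Dataset.from_array(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            run_wfc(X, lambda_=0.0)
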