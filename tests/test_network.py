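"""Growth network: Delaunay adjacency, occupancy state, dynamic insertion."""

import numpy as np
import pytest

from fibregrow import FibreSeed, build_network, update_network, add_dynamic_nodes
from fibregrow.growth import Fibre


def straight_fibre(radius=1.0, z0=0.0, z1=10.0, x=0.0, y=0.0, bundle=0):
    seed = FibreSeed([x, y, z0], [x, y, z1], 2 * radius, bundle)
    pts = np.array([[x, y, z0], [x, y, z1]], dtype=float)
    return Fibre(seed, skeleton=pts, radii=np.full(2, radius),
                 node_indices=np.array([-1, -1]), status="complete")


class TestBuildNetwork:
    def test_single_tetrahedron(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        net = build_network(pts)
        # 4 non-coplanar points -> one tetrahedron -> all 6 edges present
        degrees = [len(net.adjacency[i]) for i in range(4)]
        assert degrees == [3, 3, 3, 3]

    def test_adjacency_symmetric(self):
        rng = np.random.default_rng(0)
        net = build_network(rng.random((60, 3)))
        for i in range(len(net)):
            for j in net.adjacency[i]:
                assert i in net.adjacency[j]

    def test_empty_circumsphere_property(self):
        # every Delaunay edge belongs to a tetrahedron whose circumsphere is
        # empty; verify via scipy's own simplices against a brute-force check
        rng = np.random.default_rng(1)
        pts = rng.random((50, 3))
        from scipy.spatial import Delaunay

        tri = Delaunay(pts)
        net = build_network(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(4):
                for b in range(a + 1, 4):
                    edges.add((min(simplex[a], simplex[b]), max(simplex[a], simplex[b])))
        for i in range(len(net)):
            for j in net.adjacency[i]:
                assert (min(i, j), max(i, j)) in edges

    def test_coplanar_rejected(self):
        pts = np.random.default_rng(2).random((20, 3))
        pts[:, 2] = 0.0
        with pytest.raises(ValueError, match="oplanar|egenerate|riangulation"):
            build_network(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            build_network(np.eye(3))


class TestUpdateNetwork:
    def make_net(self):
        pts = np.array(
            [
                [3.0, 0.0, 5.0],   # clearance 2 from the fibre below
                [0.0, 0.0, 5.0],   # on the axis
                [0.5, 0.0, 5.0],   # inside the fibre
                [8.0, 8.0, 5.0],   # far away
                [0.0, 3.0, 2.0],
                [5.0, 5.0, 9.0],
                [2.0, 2.0, 1.0],
                [6.0, 1.0, 3.0],
            ]
        )
        return build_network(pts)

    def test_dc_is_twice_clearance(self):
        net = self.make_net()
        update_network(net, straight_fibre(radius=1.0))
        assert net.dc[0] == pytest.approx(4.0)
        assert net.bc[0] == 0

    def test_node_inside_fibre_occupied_with_degree_zero(self):
        net = self.make_net()
        update_network(net, straight_fibre(radius=1.0))
        assert net.occupied[1] and net.occupied[2]
        assert net.dc[1] == 0.0
        assert net.degree(1) == 0

    def test_min_rule_keeps_prior_smaller_dc(self):
        net = self.make_net()
        net.dc[0] = 1.0
        net.bc[0] = 7
        update_network(net, straight_fibre(radius=1.0))
        assert net.dc[0] == 1.0
        assert net.bc[0] == 7

    def test_far_nodes_keep_sentinel(self):
        net = self.make_net()
        update_network(net, straight_fibre(radius=1.0), max_clearance=4.0)
        assert np.isinf(net.dc[3])

    def test_idempotent(self):
        net = self.make_net()
        f = straight_fibre(radius=1.0)
        update_network(net, f)
        dc1 = net.dc.copy()
        update_network(net, f)
        assert np.array_equal(net.dc, dc1)

    def test_dc_never_increases(self):
        rng = np.random.default_rng(3)
        net = build_network(rng.random((200, 3)) * 10)
        dc_before = net.dc.copy()
        for x in (2.0, 5.0, 8.0):
            update_network(net, straight_fibre(radius=0.5, x=x, y=5.0))
            assert np.all(net.dc <= dc_before + 1e-12)
            dc_before = net.dc.copy()

    def test_no_accessible_node_inside_capsule(self):
        rng = np.random.default_rng(4)
        net = build_network(rng.random((500, 3)) * 10)
        f = straight_fibre(radius=1.2, x=5.0, y=5.0)
        update_network(net, f)
        from fibregrow.geometry import capsule_chain_distance

        accessible = ~net.occupied
        d = capsule_chain_distance(net.points[accessible], f.skeleton, f.radii)
        assert np.all(d > -1e-12)


class TestDynamicNodes:
    def test_zero_is_noop(self):
        rng = np.random.default_rng(5)
        net = build_network(rng.random((100, 3)) * 10)
        n0 = len(net)
        add_dynamic_nodes(net, straight_fibre(x=5, y=5), 0)
        assert len(net) == n0

    def test_count_and_positive_clearance(self):
        rng = np.random.default_rng(6)
        net = build_network(rng.random((300, 3)) * 10, region=(10, 10, 10))
        net.padding = 1.0
        f = straight_fibre(radius=0.8, x=5, y=5)
        n0 = len(net)
        net = add_dynamic_nodes(net, f, 400, seed=7)
        added = len(net) - n0
        assert 0 < added <= 400  # some may fall outside the padded region
        from fibregrow.geometry import capsule_chain_distance

        new_pts = net.points[n0:]
        d = capsule_chain_distance(new_pts, f.skeleton, f.radii)
        assert np.all(d > 0)
        # shell construction: within two local radii of the surface
        assert np.all(d <= 2 * 0.8 + 1e-9)

    def test_network_density_increases_near_fibre(self):
        rng = np.random.default_rng(8)
        net = build_network(rng.random((400, 3)) * 10, region=(10, 10, 10))
        net.padding = 0.0
        f = straight_fibre(radius=0.6, x=5, y=5)
        from fibregrow.geometry import capsule_chain_distance

        near_before = int((capsule_chain_distance(net.points, f.skeleton, f.radii) < 2.0).sum())
        net = add_dynamic_nodes(net, f, 500, seed=9)
        near_after = int((capsule_chain_distance(net.points, f.skeleton, f.radii) < 2.0).sum())
        assert near_after > near_before

    def test_new_node_state_reflects_existing_fibres(self):
        rng = np.random.default_rng(10)
        net = build_network(rng.random((300, 3)) * 10, region=(10, 10, 10))
        net.padding = 0.0
        f0 = straight_fibre(radius=0.7, x=4, y=5, bundle=0)
        f1 = straight_fibre(radius=0.7, x=6, y=5, bundle=1)
        update_network(net, f0)
        update_network(net, f1)
        n0 = len(net)
        net = add_dynamic_nodes(net, f1, 300, seed=11, existing_fibres=[f0, f1])
        new = slice(n0, len(net))
        assert np.all(np.isfinite(net.dc[new]))
        assert np.all(net.dc[new] >= 0)
        assert set(np.unique(net.bc[new])) <= {0, 1}
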