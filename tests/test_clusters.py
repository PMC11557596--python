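"""Cluster identification, halo membership and coordination numbers."""

import numpy as np
import pytest

from mesochrom.polymer.clusters import (
    cluster_coordination,
    first_minimum_cutoff,
    identify_clusters,
)
from mesochrom.polymer.model import EC_A, HC_B
from mesochrom.polymer.observables import ObservableCurve

SIG_BB = 25 / 18


def _mk(positions, types):
    positions = np.asarray(positions, dtype=float)
    types = np.asarray(types, dtype=np.int8)
    diam = np.where(types == EC_A, 1.0, SIG_BB)
    return positions, types, diam


def brute_force_clusters(positions, types, cutoff, min_size=4):
    """Independent oracle: all-pairs bonds + graph components over core."""
    import networkx as nx

    b = np.where(types == HC_B)[0]
    g = nx.Graph()
    g.add_nodes_from(b)
    for i in range(len(b)):
        for j in range(i + 1, len(b)):
            if np.linalg.norm(positions[b[i]] - positions[b[j]]) <= cutoff:
                g.add_edge(b[i], b[j])
    core = {n for n in g.nodes if g.degree(n) >= 3}
    comps = list(nx.connected_components(g.subgraph(core)))
    out = []
    for comp in comps:
        halo = set()
        for n in comp:
            for m in g.neighbors(n):
                if m not in core:
                    halo.add(m)
        # halo beads attach to the component of the nearest bonded core bead
        members = set(comp)
        for h in halo:
            cands = [(np.linalg.norm(positions[h] - positions[m]), m)
                     for m in g.neighbors(h) if m in core]
            best = min(cands)[1]
            if best in comp:
                members.add(h)
        if len(members) >= min_size:
            out.append(frozenset(members))
    return set(out)


class TestIdentifyClusters:
    def test_tetrahedron_is_one_cluster(self):
        # four equidistant B beads: each has exactly 3 bonded neighbours
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) * 0.5
        pos, types, diam = _mk(pts, [HC_B] * 4)
        cs = identify_clusters(pos, types, diam, bond_cutoff=2.0)
        assert len(cs) == 1
        assert cs.clusters[0].size == 4
        # volume-equivalent diameter: (4 * 25^3)^(1/3) nm
        assert cs.clusters[0].volume_equiv_diameter_nm == pytest.approx(
            (4 * 25**3) ** (1 / 3))

    def test_isolated_pair_is_no_cluster(self):
        pos, types, diam = _mk([[0, 0, 0], [1, 0, 0]], [HC_B, HC_B])
        cs = identify_clusters(pos, types, diam, bond_cutoff=1.5)
        assert len(cs) == 0

    def test_no_b_beads_empty(self):
        pos, types, diam = _mk([[0, 0, 0], [1, 0, 0]], [EC_A, EC_A])
        assert len(identify_clusters(pos, types, diam, 1.5)) == 0

    def test_matches_brute_force_oracle(self, rng):
        # oracle equivalence on many random dense configurations
        for trial in range(100):
            n = 50
            pos = rng.uniform(-3, 3, size=(n, 3))
            types = np.full(n, HC_B, dtype=np.int8)
            diam = np.full(n, SIG_BB)
            cutoff = 1.6
            cs = identify_clusters(pos, types, diam, cutoff)
            got = {frozenset(c.members.tolist()) for c in cs.clusters}
            expected = brute_force_clusters(pos, types, cutoff)
            assert got == expected, f"trial {trial}"

    def test_membership_partition(self, rng):
        pos = rng.uniform(-4, 4, size=(120, 3))
        types = np.full(120, HC_B, dtype=np.int8)
        diam = np.full(120, SIG_BB)
        cs = identify_clusters(pos, types, diam, 1.8)
        all_members = np.concatenate([c.members for c in cs.clusters]) \
            if len(cs) else np.empty(0, dtype=int)
        assert len(all_members) == len(set(all_members.tolist()))
        assert len(all_members) <= 120


class TestCoordination:
    def _chain_setup(self, cluster_a, cluster_b, link_path):
        """Build a chain whose order passes through both clusters."""
        pts = np.vstack([cluster_a, link_path, cluster_b])
        types = np.full(len(pts), HC_B, dtype=np.int8)
        types[len(cluster_a):len(cluster_a) + len(link_path)] = EC_A
        return _mk(pts, types)

    def _tetra(self, center, spacing=1.0):
        t = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float) * spacing / 2
        return t + np.asarray(center)

    def test_two_linked_clusters_counted_once(self):
        # two chain segments connect the same pair: z_c stays 1 each
        a = self._tetra([0, 0, 0])
        b = self._tetra([20, 0, 0])
        link1 = np.array([[5, 0, 0], [10, 0, 0], [15, 0, 0]], dtype=float)
        link2 = link1 + [0, 0.5, 0]
        pts = np.vstack([a, link1, b, link2[::-1], a + [0, 0, 0.1]])
        # chain: A-cluster, link, B-cluster, link back, near-A beads
        types = np.full(len(pts), HC_B, dtype=np.int8)
        types[4:7] = EC_A
        types[11:14] = EC_A
        pos, types, diam = _mk(pts, types)
        cs = identify_clusters(pos, types, diam, bond_cutoff=1.6)
        assert len(cs) == 2
        cs = cluster_coordination(cs, pos, cavity_radius=100.0,
                                  sigma_BB=SIG_BB)
        assert [c.z_c for c in cs.clusters] == [1, 1]

    def test_isolated_cluster_zero(self):
        pos, types, diam = _mk(self._tetra([0, 0, 0]), [HC_B] * 4)
        cs = identify_clusters(pos, types, diam, 2.0)
        cs = cluster_coordination(cs, pos, cavity_radius=100.0,
                                  sigma_BB=SIG_BB)
        assert cs.clusters[0].z_c == 0
        assert not cs.clusters[0].wall_contact

    def test_wall_contact_adds_one(self):
        r_cav = 3.0
        # nearest member within sigma_BB of the wall
        pos, types, diam = _mk(self._tetra([r_cav - SIG_BB - 0.4, 0, 0]),
                               [HC_B] * 4)
        cs = identify_clusters(pos, types, diam, 2.0)
        cs = cluster_coordination(cs, pos, r_cav, SIG_BB)
        assert cs.clusters[0].wall_contact
        assert cs.clusters[0].z_c == 1


class TestFirstMinimumCutoff:
    def test_finds_interior_minimum(self):
        x = np.linspace(0.2, 5, 60)
        y = np.exp(-((x - 1.2) ** 2) / 0.05) * 2 + 1 - np.exp(
            -((x - 2.0) ** 2) / 0.1) * 0.5
        c = first_minimum_cutoff(ObservableCurve(x, y, np.ones_like(x)),
                                 fallback=99.0)
        assert 1.7 < c < 2.3

    def test_fallback_when_monotone(self):
        x = np.linspace(0.2, 5, 40)
        y = np.linspace(2, 1, 40)  # hmm: monotone decreasing, no interior min
        c = first_minimum_cutoff(ObservableCurve(x, y, np.ones_like(x)),
                                 fallback=1.5 * SIG_BB)
        assert c == pytest.approx(1.5 * SIG_BB)


class TestAffinityTrend:
    def test_affinity_condenses_heterochromatin(self, traj_strong_affinity,
                                                traj_weak_affinity):
        # paired seeds: strong affinity compacts the HC/B beads — their
        # first-shell contact count is several-fold higher than at
        # near-zero affinity, and clusters are at least as large.  (At the
        # fallback bond cutoff even the weak-affinity B *fluid* percolates
        # geometrically, so bead-count comparisons alone do not
        # discriminate; contact density does, robustly.)
        from scipy.spatial import cKDTree
        from mesochrom.polymer.clusters import identify_clusters

        def contacts(traj):
            pos = traj.positions[-1][traj.bead_type == HC_B]
            pairs = cKDTree(pos).query_pairs(1.6, output_type="ndarray")
            return 2 * len(pairs) / len(pos)

        assert contacts(traj_strong_affinity) > 2 * contacts(
            traj_weak_affinity)

        cutoff = 1.5 * SIG_BB
        def mean_size(traj):
            cs = identify_clusters(traj.positions[-1], traj.bead_type,
                                   traj.bead_diameter, cutoff)
            return cs.sizes().mean() if len(cs) else 0.0

        assert mean_size(traj_strong_affinity) >= mean_size(
            traj_weak_affinity)

    def test_affinity_lowers_steady_energy(self, traj_strong_affinity,
                                           traj_weak_affinity):
        e_strong = traj_strong_affinity.energy_per_bead[-5:].mean()
        e_weak = traj_weak_affinity.energy_per_bead[-5:].mean()
        assert e_strong < e_weak
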