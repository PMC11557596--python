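"""Heterochromatin (HC/B) cluster identification and connectivity.

Pairs of HC/B beads within a bond cutoff — by default the first minimum of
the steady-state g_BB(r), falling back to 1.5 sigma_BB — are "bonded".
Beads with at least 3 bonded HC/B neighbours are *core* beads; clusters are
the connected components of the bonded graph restricted to core beads.
Bonded non-core B beads adjacent to a component are attached as *halo*
members (member, not core); size statistics are reported both ways with
core+halo the default.

Two clusters are *neighbours* when at least one chain segment links a
member of one to a member of the other without passing through a third
cluster; multiple connecting segments are not multiply counted.  A cluster
whose nearest member lies within sigma_BB of the cavity wall receives one
additional contact.  The total is the coordination number z_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from mesochrom.polymer.model import HC_B
from mesochrom.polymer.observables import ObservableCurve, confined_rdf

__all__ = ["Cluster", "ClusterSet", "identify_clusters",
           "cluster_coordination", "first_minimum_cutoff", "analyze_snapshot",
           "steady_state_bond_cutoff", "analyze_trajectory",
           "ClusterSummary"]

MIN_CLUSTER_BEADS = 4


@dataclass
class Cluster:
    members: np.ndarray          # bead indices, core + halo
    core: np.ndarray             # core bead indices
    centroid: np.ndarray
    volume_equiv_diameter_nm: float
    wall_contact: bool = False
    z_c: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    bond_cutoff: float
    membership: str = "core+halo"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=int)

    def diameters_nm(self) -> np.ndarray:
        return np.array([c.volume_equiv_diameter_nm for c in self.clusters])

    def coordination_numbers(self) -> np.ndarray:
        return np.array([c.z_c for c in self.clusters], dtype=int)

    def nn_separations(self) -> np.ndarray:
        """Centroid-to-centroid nearest-neighbour distances (reduced units)."""
        if len(self.clusters) < 2:
            return np.empty(0)
        cents = np.array([c.centroid for c in self.clusters])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)


def first_minimum_cutoff(g_bb: ObservableCurve, fallback: float,
                         smooth_bins: int = 3) -> float:
    """Bond cutoff from the first minimum of g_BB(r) after its first peak.

    The curve is smoothed with a moving average before extremum detection;
    returns ``fallback`` (1.5 sigma_BB conventionally) when no interior
    minimum exists.
    """
    y = np.array(g_bb.y, dtype=float)
    valid = np.isfinite(y)
    if valid.sum() < 5:
        return fallback
    x = g_bb.x[valid]
    y = y[valid]
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(y, kern, mode="same")
    imax = int(np.argmax(y))
    for i in range(imax + 1, len(y) - 1):
        if y[i] <= y[i - 1] and y[i] < y[i + 1]:
            return float(x[i])
    return fallback


def identify_clusters(
    positions: np.ndarray,
    bead_type: np.ndarray,
    bead_diameter: np.ndarray,
    bond_cutoff: float,
    sigma_AA_nm: float = 18.0,
    membership: str = "core+halo",
    min_size: int = MIN_CLUSTER_BEADS,
) -> ClusterSet:
    """Identify HC/B clusters in one snapshot.

    ``membership`` selects "core+halo" (default) or "core" statistics.
    Clusters with fewer than ``min_size`` members (after halo attachment)
    are discarded; the volume-equivalent diameter is the cube root of the
    summed member bead volumes, in nm.
    """
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be positive")
    b_idx = np.where(bead_type == HC_B)[0]
    if b_idx.size == 0:
        return ClusterSet([], bond_cutoff, membership)
    bpos = positions[b_idx]
    tree = cKDTree(bpos)
    pairs = tree.query_pairs(bond_cutoff, output_type="ndarray")
    nb = len(b_idx)
    degree = np.zeros(nb, dtype=int)
    if pairs.size:
        np.add.at(degree, pairs[:, 0], 1)
        np.add.at(degree, pairs[:, 1], 1)
    core = degree >= 3

    # union-find over core-core bonds
    parent = np.arange(nb)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        if core[i] and core[j]:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    comp_of = np.full(nb, -1, dtype=int)
    roots = {}
    for i in range(nb):
        if core[i]:
            r = find(i)
            comp_of[i] = roots.setdefault(r, len(roots))

    # halo attachment: non-core B bead bonded to a core bead joins the
    # component of its nearest bonded core bead
    halo_of = np.full(nb, -1, dtype=int)
    if pairs.size:
        d = np.linalg.norm(bpos[pairs[:, 0]] - bpos[pairs[:, 1]], axis=1)
        best = {}
        for (i, j), dist in zip(pairs, d):
            for a, b in ((i, j), (j, i)):
                if not core[a] and core[b]:
                    if a not in best or dist < best[a][0]:
                        best[a] = (dist, comp_of[b])
        for a, (_, comp) in best.items():
            halo_of[a] = comp

    clusters = []
    n_comp = len(roots)
    for comp in range(n_comp):
        core_members = b_idx[comp_of == comp]
        halo_members = b_idx[halo_of == comp]
        if membership == "core":
            members = core_members
        else:
            members = np.concatenate([core_members, halo_members])
        if members.size < min_size:
            continue
        sig_nm = bead_diameter[members] * sigma_AA_nm
        d_eff = float(np.sum(sig_nm**3) ** (1.0 / 3.0))
        clusters.append(
            Cluster(
                members=np.sort(members),
                core=np.sort(core_members),
                centroid=positions[members].mean(axis=0),
                volume_equiv_diameter_nm=d_eff,
            )
        )
    return ClusterSet(clusters, bond_cutoff, membership)


def cluster_coordination(
    cluster_set: ClusterSet,
    positions: np.ndarray,
    cavity_radius: float,
    sigma_BB: float,
) -> ClusterSet:
    """Fill in wall contacts and coordination numbers z_c (in place).

    Chain-link adjacency: walking the chain in order, every maximal gap
    between beads assigned to two *different* clusters contributes one
    (deduplicated) neighbour relation.  Wall contact: nearest member within
    ``sigma_BB`` of the cavity wall adds exactly one contact.
    """
    n = positions.shape[0]
    owner = np.full(n, -1, dtype=int)
    for ci, c in enumerate(cluster_set.clusters):
        owner[c.members] = ci
    assigned = np.where(owner >= 0)[0]
    neighbours: set[tuple[int, int]] = set()
    for a, b in zip(assigned[:-1], assigned[1:]):
        ca, cb = owner[a], owner[b]
        if ca != cb:
            neighbours.add((min(ca, cb), max(ca, cb)))
    adj: dict[int, set[int]] = {i: set() for i in range(len(cluster_set.clusters))}
    for a, b in neighbours:
        adj[a].add(b)
        adj[b].add(a)
    for ci, c in enumerate(cluster_set.clusters):
        r = np.linalg.norm(positions[c.members], axis=1)
        c.wall_contact = bool(np.any(cavity_radius - r <= sigma_BB))
        c.z_c = len(adj[ci]) + (1 if c.wall_contact else 0)
    cluster_set.meta["adjacency"] = {k: sorted(v) for k, v in adj.items()}
    return cluster_set


def analyze_snapshot(
    positions: np.ndarray,
    bead_type: np.ndarray,
    bead_diameter: np.ndarray,
    cavity_radius: float,
    bond_cutoff: float | None = None,
    sigma_BB: float | None = None,
    sigma_AA_nm: float = 18.0,
    membership: str = "core+halo",
) -> ClusterSet:
    """Identify clusters and their coordination numbers in one call.

    When ``bond_cutoff`` is None it is taken from the first minimum of
    g_BB(r) of this snapshot (fallback 1.5 sigma_BB).
    """
    if sigma_BB is None:
        sigma_BB = float(bead_diameter[bead_type == HC_B].max()) \
            if np.any(bead_type == HC_B) else 25.0 / 18.0
    if bond_cutoff is None:
        edges = np.arange(0.5 * sigma_BB, min(6.0, cavity_radius), 0.1)
        g = confined_rdf(positions, "BB", cavity_radius, edges, bead_type)
        bond_cutoff = first_minimum_cutoff(g, fallback=1.5 * sigma_BB)
    cs = identify_clusters(positions, bead_type, bead_diameter, bond_cutoff,
                           sigma_AA_nm, membership)
    return cluster_coordination(cs, positions, cavity_radius, sigma_BB)


def steady_state_bond_cutoff(trajectory, max_snapshots: int = 10,
                             bin_width: float = 0.05) -> float:
    """Bond cutoff from the first minimum of the pooled steady-state
    g_BB(r) (fallback 1.5 sigma_BB).

    Pooling a few steady snapshots stabilises the minimum detection
    against single-snapshot noise.
    """
    pos = trajectory.steady_positions()
    if pos.shape[0] == 0:
        pos = trajectory.positions[-1:]
    take = np.linspace(0, pos.shape[0] - 1, min(max_snapshots,
                                                pos.shape[0])).astype(int)
    # start beyond deep-overlap separations (soft cores allow stacked
    # beads, whose g(r) spike would masquerade as the first peak)
    r_lo = 0.5 * float(trajectory.bead_diameter.max())
    edges = np.arange(r_lo, 4.0, bin_width)
    gs = []
    for i in take:
        g = confined_rdf(pos[i], "BB", trajectory.cavity_radius, edges,
                         trajectory.bead_type)
        gs.append(np.where(np.isfinite(g.y), g.y, 0.0))
    pooled = ObservableCurve(g.x, np.mean(gs, axis=0),
                             np.ones_like(g.x, dtype=int))
    sigma_bb = float(trajectory.bead_diameter.max())
    return first_minimum_cutoff(pooled, fallback=1.5 * sigma_bb)


@dataclass
class ClusterSummary:
    """Cluster statistics averaged over steady-state snapshots."""

    n_snapshots: int
    bond_cutoff: float
    mean_cluster_count: float
    mean_size_beads: float
    mean_diameter_nm: float
    mean_zc: float
    mean_nn_separation_nm: float
    cluster_sets: list = None


def analyze_trajectory(trajectory, bond_cutoff: float | None = None,
                       membership: str = "core+halo",
                       max_snapshots: int | None = None) -> ClusterSummary:
    """Identify clusters on every steady-state snapshot with one shared
    bond cutoff and average sizes, coordination numbers and
    nearest-neighbour separations over snapshots."""
    if bond_cutoff is None:
        bond_cutoff = steady_state_bond_cutoff(trajectory)
    pos = trajectory.steady_positions()
    if pos.shape[0] == 0:
        raise ValueError("trajectory has no steady-state snapshots")
    idx = np.arange(pos.shape[0])
    if max_snapshots is not None and pos.shape[0] > max_snapshots:
        idx = np.linspace(0, pos.shape[0] - 1, max_snapshots).astype(int)
    sigma_bb = float(trajectory.bead_diameter.max())
    sigma_aa_nm = trajectory.unit_system.sigma_AA_nm
    sets = []
    counts, sizes, diams, zcs, nns = [], [], [], [], []
    for i in idx:
        cs = identify_clusters(pos[i], trajectory.bead_type,
                               trajectory.bead_diameter, bond_cutoff,
                               sigma_aa_nm, membership)
        cs = cluster_coordination(cs, pos[i], trajectory.cavity_radius,
                                  sigma_bb)
        sets.append(cs)
        counts.append(len(cs))
        if len(cs):
            sizes.extend(cs.sizes().tolist())
            diams.extend(cs.diameters_nm().tolist())
            zcs.extend(cs.coordination_numbers().tolist())
            nns.extend((cs.nn_separations() * sigma_aa_nm).tolist())
    return ClusterSummary(
        n_snapshots=len(idx),
        bond_cutoff=float(bond_cutoff),
        mean_cluster_count=float(np.mean(counts)),
        mean_size_beads=float(np.mean(sizes)) if sizes else np.nan,
        mean_diameter_nm=float(np.mean(diams)) if diams else np.nan,
        mean_zc=float(np.mean(zcs)) if zcs else np.nan,
        mean_nn_separation_nm=float(np.mean(nns)) if nns else np.nan,
        cluster_sets=sets,
    )
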