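"""Contact networks, betweenness (vs. exhaustive path enumeration), DCC."""

import itertools

import networkx as nx
import numpy as np
import pytest

from thermodrn.core import Trajectory
from thermodrn.network import (
    ContactNetwork, average_bc, betweenness, contact_network, dcc,
    interchain_correlation_summary, top_fraction,
)
from thermodrn.synthetic import (
    CorrelationBlock, GeneratorConfig, generate_dimer_structure,
    generate_trajectory,
)

from conftest import make_structure


def _net_from_graph(g: nx.Graph) -> ContactNetwork:
    keys = [("A", int(n), "") for n in range(g.number_of_nodes())]
    return ContactNetwork(graph=g, residue_keys=keys, threshold=6.7)


def enumerate_betweenness(g: nx.Graph) -> np.ndarray:
    """Independent oracle: DFS-enumerate all simple paths per pair, keep the
    shortest, count fractional pass-through per interior node."""
    nodes = sorted(g.nodes)
    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        stack = [(s, [s])]
        while stack:
            cur, path = stack.pop()
            if cur == t:
                paths.append(path)
                continue
            for nb in g.neighbors(cur):
                if nb not in path:
                    stack.append((nb, path + [nb]))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        best = [p for p in paths if len(p) == shortest]
        for p in best:
            for interior in p[1:-1]:
                bc[interior] += 1.0 / len(best)
    return np.array([bc[n] for n in nodes])


# ---------------------------------------------------------------------------
# contact networks
# ---------------------------------------------------------------------------

def _line_structure(xs):
    return make_structure([
        ("A", i + 1, "ALA", "CB", "C", (x, 0.0, 0.0)) for i, x in enumerate(xs)
    ] + [
        ("A", i + 1, "ALA", "CA", "C", (x, 1.5, 0.0)) for i, x in enumerate(xs)
    ])


def test_contact_edges_inclusive_threshold():
    s = _line_structure([0.0, 6.0, 12.7])
    net = contact_network(s)
    edges = set(net.graph.edges)
    assert (0, 1) in edges          # 6.0 <= 6.7
    assert (1, 2) in edges or (2, 1) in edges   # exactly 6.7: inclusive
    assert (0, 2) not in edges


def test_contact_network_matches_all_pairs_scan():
    cfg = GeneratorConfig(n_residues_per_chain=15, seed=6,
                          interface_pairs=((3, 4), (9, 10)))
    s = generate_dimer_structure(cfg)
    net = contact_network(s)
    from thermodrn.core import select_network_atoms
    sel = select_network_atoms(s)
    pts = s.coords[sel]
    expected = {
        (i, j) for i, j in itertools.combinations(range(len(sel)), 2)
        if ((pts[i] - pts[j]) ** 2).sum() <= 6.7 ** 2
    }
    got = {tuple(sorted(e)) for e in net.graph.edges}
    assert got == expected


# ---------------------------------------------------------------------------
# betweenness
# ---------------------------------------------------------------------------

def test_betweenness_path_and_star():
    path = _net_from_graph(nx.path_graph(3))
    assert list(betweenness(path)) == [0.0, 1.0, 0.0]
    star = _net_from_graph(nx.star_graph(4))
    assert list(betweenness(star)) == [6.0, 0.0, 0.0, 0.0, 0.0]


def test_betweenness_matches_enumeration_on_random_graphs():
    """Brandes equals exhaustive shortest-path enumeration, 100 random graphs."""
    rng = np.random.default_rng(202)
    for _ in range(100):
        n = int(rng.integers(4, 11))
        p = float(rng.uniform(0.2, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        got = betweenness(_net_from_graph(g))
        expected = enumerate_betweenness(g)
        assert np.allclose(got, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# average BC, normalization, top fraction
# ---------------------------------------------------------------------------

def _toy_trajectory(n_frames=10, seed=2, **kwargs):
    cfg = GeneratorConfig(n_residues_per_chain=12, n_frames=n_frames, seed=seed,
                          **kwargs)
    s = generate_dimer_structure(cfg)
    return s, generate_trajectory(s, cfg, 0)


def test_average_bc_rigid_equals_single_frame():
    cfg = GeneratorConfig(n_residues_per_chain=10, seed=2)
    s = generate_dimer_structure(cfg)
    coords = np.repeat(s.coords[None], 5, axis=0)
    traj = Trajectory(topology=s, coords=coords, frame_interval=10.0)
    profile = average_bc(traj)
    single = betweenness(contact_network(s))
    assert np.allclose(profile.raw, single)


def test_average_bc_equals_per_frame_recomputation():
    s, traj = _toy_trajectory(n_frames=10)
    profile = average_bc(traj, frame_window=0.4)
    start = int(np.floor(0.6 * traj.n_frames))
    from thermodrn.core import select_network_atoms
    sel = select_network_atoms(s)
    per_frame = [
        betweenness(contact_network(s, coords=traj.coords[t], selection=sel))
        for t in range(start, traj.n_frames)
    ]
    assert np.allclose(profile.raw, np.mean(per_frame, axis=0), atol=1e-12)


def test_average_bc_invariant_to_frame_order_within_window():
    s, traj = _toy_trajectory(n_frames=10)
    profile = average_bc(traj, frame_window=1.0)
    shuffled = Trajectory(topology=s, coords=traj.coords[::-1].copy(),
                          frame_interval=traj.frame_interval)
    assert np.allclose(profile.raw, average_bc(shuffled, frame_window=1.0).raw)


def test_normalization_range_and_degenerate_rule():
    s, traj = _toy_trajectory(n_frames=4)
    profile = average_bc(traj, frame_window=1.0)
    assert profile.normalized.min() >= 0.0
    assert profile.normalized.max() == pytest.approx(1.0)
    # constant profile -> all zeros: a complete graph has uniform (zero) BC
    s2 = make_structure([
        ("A", i + 1, "ALA", "CB", "C", (i * 1.0, 0.0, 0.0)) for i in range(4)
    ])
    coords = np.repeat(s2.coords[None], 2, axis=0)
    const = average_bc(Trajectory(topology=s2, coords=coords, frame_interval=1.0),
                       frame_window=1.0)
    assert np.allclose(const.normalized, 0.0)


def test_top_fraction_k_and_ties():
    keys = [("A", i + 1, "") for i in range(40)]
    from thermodrn.network import BCProfile
    values = np.linspace(0, 1, 40)
    profile = BCProfile(raw=values, normalized=values, residue_keys=keys,
                        frames_used=1, threshold=6.7, normalization="minmax")
    top = top_fraction(profile, fraction=0.05)
    assert sum(len(v) for v in top.values()) == 2    # ceil(0.05*40)

    keys41 = keys + [("A", 41, "")]
    v41 = np.append(values, 0.5)
    profile41 = BCProfile(raw=v41, normalized=v41, residue_keys=keys41,
                          frames_used=1, threshold=6.7, normalization="minmax")
    assert sum(len(v) for v in top_fraction(profile41).values()) == 3  # ceil(2.05)

    # tie at the cutoff value: both tied residues included
    tied = np.array([1.0, 0.8, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1,
                     0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1,
                     0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1,
                     0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05])
    keys40 = [("A", i + 1, "") for i in range(40)]
    ptied = BCProfile(raw=tied, normalized=tied, residue_keys=keys40,
                      frames_used=1, threshold=6.7, normalization="minmax")
    picked = top_fraction(ptied)   # k = 2 but ranks 2 and 3 tie at 0.8
    sizes = sum(len(v) for v in picked.values())
    assert sizes == 3
    # sort-and-scan oracle
    order = np.argsort(-tied, kind="stable")
    cutoff = tied[order[1]]
    assert sizes == int((tied >= cutoff).sum())


def test_bridge_residue_attains_normalized_one():
    # two clusters connected only through one bridge residue
    left = [(float(i), 0.0) for i in range(4)]
    right = [(float(i) + 20.0, 0.0) for i in range(4)]
    bridge_chain = [(8.0, 0.0), (14.0, 0.0)]  # path L -> b1 -> b2 -> R? too far
    coords = left + [(6.0, 0.0), (12.0, 0.0), (18.0, 0.0)] + right
    atoms = [("A", i + 1, "ALA", "CB", "C", (x, y, 0.0))
             for i, (x, y) in enumerate(coords)]
    s = make_structure(atoms)
    traj = Trajectory(topology=s, coords=np.repeat(s.coords[None], 3, axis=0),
                      frame_interval=1.0)
    profile = average_bc(traj, frame_window=1.0)
    mid = np.argmax(profile.raw)
    assert profile.normalized[mid] == 1.0


# ---------------------------------------------------------------------------
# DCC
# ---------------------------------------------------------------------------

def _shared_signal_trajectory(n_atoms=6, n_frames=200, anti=False, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3)) * 10.0
    s = make_structure([
        ("A" if i < n_atoms // 2 else "B", i % (n_atoms // 2) + 1, "ALA", "CA",
         "C", tuple(base[i])) for i in range(n_atoms)
    ])
    signal = rng.normal(size=(n_frames, 1, 3))
    signs = np.ones(n_atoms)
    if anti:
        signs[n_atoms // 2:] = -1.0
    coords = base[None] + signal * signs[None, :, None]
    return Trajectory(topology=s, coords=coords, frame_interval=1.0)


def test_dcc_all_correlated_is_one():
    traj = _shared_signal_trajectory()
    m = dcc(traj, superpose_frames=False)
    assert np.allclose(m.matrix, 1.0, atol=1e-9)


def test_dcc_antiphase_blocks_minus_one():
    traj = _shared_signal_trajectory(anti=True)
    m = dcc(traj, superpose_frames=False)
    n = len(m.residue_keys)
    cross = m.matrix[: n // 2, n // 2:]
    assert np.allclose(cross, -1.0, atol=1e-9)


def test_dcc_recovers_planted_rho():
    blk = CorrelationBlock(tuple(("A", r) for r in range(1, 11)),
                           tuple(("B", r) for r in range(1, 11)), 0.6)
    cfg = GeneratorConfig(n_residues_per_chain=25, n_frames=2000, seed=3,
                          correlation_blocks=(blk,))
    s = generate_dimer_structure(cfg)
    t = generate_trajectory(s, cfg, 0)
    m = dcc(t, superpose_frames=False)
    idx = {(k[0], k[1]): i for i, k in enumerate(m.residue_keys)}
    members = [("A", r) for r in range(1, 11)] + [("B", r) for r in range(1, 11)]
    block_c = np.array([m.matrix[idx[a], idx[b]]
                        for a, b in itertools.combinations(members, 2)])
    assert np.abs(block_c - 0.6).max() < 0.08
    independent = [m.matrix[idx[("A", 15)], idx[("B", 20)]],
                   m.matrix[idx[("A", 20)], idx[("B", 22)]],
                   m.matrix[idx[("A", 18)], idx[("A", 24)]]]
    assert np.abs(independent).max() < 0.1


def test_dcc_invariants_and_zero_variance():
    s, traj = _toy_trajectory(n_frames=50, seed=9)
    m = dcc(traj, superpose_frames=False)
    assert np.allclose(m.matrix, m.matrix.T, atol=1e-9)
    assert np.allclose(np.diag(m.matrix), 1.0)
    assert m.matrix.min() >= -1.0 and m.matrix.max() <= 1.0

    from thermodrn.core import select_ca_atoms
    ca = select_ca_atoms(s)
    frozen = traj.coords.copy()
    frozen[:, ca[0], :] = frozen[0, ca[0], :]  # zero-variance CA
    m2 = dcc(Trajectory(topology=s, coords=frozen, frame_interval=1.0),
             superpose_frames=False)
    assert m2.matrix[0, 0] == 1.0
    assert np.abs(m2.matrix[0, 1:]).max() == 0.0


def test_interchain_summary_limits():
    identical = _shared_signal_trajectory()
    m = dcc(identical, superpose_frames=False)
    summary = interchain_correlation_summary(m)
    assert summary[("A", "B")]["mean_c"] == pytest.approx(1.0, abs=1e-9)

    cfg = GeneratorConfig(n_residues_per_chain=10, n_frames=5000, seed=10)
    s = generate_dimer_structure(cfg)
    t = generate_trajectory(s, cfg, 0)
    mi = dcc(t, superpose_frames=False)
    si = interchain_correlation_summary(mi)
    assert si[("A", "B")]["mean_abs_c"] < 0.05

    # block means equal direct summation over the named sub-matrix
    chain_arr = np.array([k[0] for k in mi.residue_keys])
    block = mi.matrix[np.ix_(chain_arr == "A", chain_arr == "B")]
    assert si[("A", "B")]["mean_c"] == pytest.approx(float(block.mean()))
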