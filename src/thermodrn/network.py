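"""Dynamic residue networks and dynamic cross-correlation.

A residue contact graph is built per frame over network atoms (CB, CA for
Gly) with an inclusive 6.7 A distance threshold; unweighted shortest-path
betweenness (Brandes) is averaged over the trailing window of the
trajectory (the study computed it over the last 20 of 50 ns, i.e. the last
40% of frames), min-max normalised to [0, 1], and the top 5% of residues is
reported per chain.  Dynamic cross-correlation normalises the covariance of
C-alpha displacement vectors to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import (
    ResidueKey, Structure, Trajectory, select_ca_atoms, select_network_atoms,
    superpose,
)

__all__ = [
    "ContactNetwork", "BCProfile", "DCCMatrix",
    "contact_network", "betweenness", "average_bc", "top_fraction",
    "dcc", "interchain_correlation_summary",
]

CONTACT_THRESHOLD = 6.7       # A, network-atom contact cutoff (inclusive)
BC_FRAME_WINDOW = 0.4         # trailing fraction of frames averaged
TOP_BC_FRACTION = 0.05        # top-5% high-communication residues


@dataclass
class ContactNetwork:
    graph: nx.Graph               # nodes: selection positions 0..n-1
    residue_keys: list[ResidueKey]
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def contact_network(structure: Structure, coords: np.ndarray | None = None,
                    threshold: float = CONTACT_THRESHOLD,
                    selection: np.ndarray | None = None) -> ContactNetwork:
    """Residue contact graph: edge iff network-atom distance <= threshold.

    Squared distances are compared against the squared threshold so a pair
    placed at exactly the cutoff is an edge.
    """
    sel = select_network_atoms(structure) if selection is None else np.asarray(selection)
    pts = (structure.coords if coords is None else np.asarray(coords))[sel]
    keys = [structure.residue_key(int(i)) for i in sel]
    g = nx.Graph()
    g.add_nodes_from(range(len(sel)))
    if len(sel) > 1:
        d2 = squareform(pdist(pts, metric="sqeuclidean"))
        ii, jj = np.nonzero(np.triu(d2 <= threshold * threshold, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return ContactNetwork(graph=g, residue_keys=keys, threshold=threshold)


def betweenness(network: ContactNetwork) -> np.ndarray:
    """Unweighted shortest-path betweenness per node (Brandes).

    Unordered endpoint pairs, endpoints excluded, equal-length paths counted
    fractionally; disconnected pairs contribute nothing.
    """
    bc = nx.betweenness_centrality(network.graph, normalized=False)
    return np.array([bc[i] for i in range(network.n_nodes)])


@dataclass
class BCProfile:
    raw: np.ndarray                 # average BC per residue
    normalized: np.ndarray          # min-max scaled to [0, 1]
    residue_keys: list[ResidueKey]
    frames_used: int
    threshold: float
    normalization: str              # 'minmax' | 'max'

    def per_chain_top_fraction(self, fraction: float = TOP_BC_FRACTION,
                               scope: str = "complex") -> dict[str, list[ResidueKey]]:
        return top_fraction(self, fraction=fraction, scope=scope)


def _normalize(raw: np.ndarray, mode: str) -> np.ndarray:
    if mode == "minmax":
        span = raw.max() - raw.min()
        if span <= 0:
            return np.zeros_like(raw)  # constant profile degenerates to all-0
        return (raw - raw.min()) / span
    if mode == "max":
        return raw / raw.max() if raw.max() > 0 else np.zeros_like(raw)
    raise ValueError("normalization must be 'minmax' or 'max'")


def average_bc(trajectory: Trajectory, threshold: float = CONTACT_THRESHOLD,
               frame_window: float = BC_FRAME_WINDOW, stride: int = 1,
               normalization: str = "minmax") -> BCProfile:
    """Betweenness averaged over the trailing ``frame_window`` of frames.

    Raw per-residue values are the mean of per-frame Brandes betweenness;
    the normalised profile is min-max scaled to [0, 1] (a constant profile
    maps to all zeros).
    """
    n = trajectory.n_frames
    start = int(np.floor((1.0 - frame_window) * n))
    frame_ids = range(start, n, stride)
    if len(range(start, n, stride)) == 0:
        raise ValueError("empty frame window")
    topo = trajectory.topology
    sel = select_network_atoms(topo)
    total = np.zeros(len(sel))
    count = 0
    keys: list[ResidueKey] | None = None
    for t in frame_ids:
        net = contact_network(topo, coords=trajectory.coords[t],
                              threshold=threshold, selection=sel)
        keys = net.residue_keys
        total += betweenness(net)
        count += 1
    raw = total / count
    return BCProfile(
        raw=raw, normalized=_normalize(raw, normalization),
        residue_keys=keys, frames_used=count, threshold=threshold,
        normalization=normalization,
    )


def top_fraction(profile: BCProfile, fraction: float = TOP_BC_FRACTION,
                 scope: str = "complex") -> dict[str, list[ResidueKey]]:
    """Top-``fraction`` residues by normalised BC, reported per chain.

    k = ceil(fraction * n) within the scope ('complex': one cutoff over all
    residues; 'chain': an independent cutoff per chain); all residues tied
    at the cutoff value are included.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")

    def pick(values: np.ndarray, keys: list[ResidueKey]) -> list[ResidueKey]:
        k = int(np.ceil(fraction * len(values)))
        order = np.argsort(-values, kind="stable")
        cutoff = values[order[k - 1]]
        return [keys[i] for i in order if values[i] >= cutoff]

    chains = sorted({k[0] for k in profile.residue_keys})
    out: dict[str, list[ResidueKey]] = {c: [] for c in chains}
    if scope == "complex":
        selected = pick(profile.normalized, profile.residue_keys)
        for key in selected:
            out[key[0]].append(key)
    elif scope == "chain":
        for c in chains:
            idx = [i for i, k in enumerate(profile.residue_keys) if k[0] == c]
            out[c] = pick(profile.normalized[idx],
                          [profile.residue_keys[i] for i in idx])
    else:
        raise ValueError("scope must be 'complex' or 'chain'")
    return out


# ---------------------------------------------------------------------------
# Dynamic cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class DCCMatrix:
    matrix: np.ndarray              # (n, n) in [-1, 1], unit diagonal
    residue_keys: list[ResidueKey]
    temperature_label: float | None

    def __post_init__(self) -> None:
        m = self.matrix
        assert np.allclose(m, m.T, atol=1e-9), "DCC matrix must be symmetric"
        assert np.allclose(np.diag(m), 1.0, atol=1e-9), "DCC diagonal must be 1"
        assert (m >= -1 - 1e-9).all() and (m <= 1 + 1e-9).all()


def dcc(trajectory: Trajectory, selection: np.ndarray | None = None,
        superpose_frames: bool = True) -> DCCMatrix:
    """Dynamic cross-correlation of displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr_i(t) the
    deviation of atom i from its across-frame mean position, after optional
    superposition of every frame onto frame 1 over the selection.  Atoms
    with zero variance get zero rows/columns (diagonal stays 1).
    """
    if trajectory.n_frames < 2:
        raise ValueError("DCC needs >= 2 frames")
    topo = trajectory.topology
    sel = select_ca_atoms(topo) if selection is None else np.asarray(selection)
    frames = trajectory.coords
    if superpose_frames:
        ref = frames[0]
        X = np.empty((trajectory.n_frames, len(sel), 3))
        for t in range(trajectory.n_frames):
            full, _ = superpose(frames[t], ref, sel)
            X[t] = full[sel]
    else:
        X = frames[:, sel, :]
    D = X - X.mean(axis=0, keepdims=True)
    num = np.einsum("tik,tjk->ij", D, D) / trajectory.n_frames
    var = np.diag(num).copy()
    zero = var <= 1e-15 * max(float(var.max()), 1.0)  # numerically immobile atoms
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    C = num / denom
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    keys = [topo.residue_key(int(i)) for i in sel]
    return DCCMatrix(matrix=C, residue_keys=keys,
                     temperature_label=trajectory.temperature_label)


def interchain_correlation_summary(dcc_matrix: DCCMatrix
                                   ) -> dict[tuple[str, str], dict[str, float]]:
    """Block means of inter-chain correlations per chain pair.

    Returns {(chain_a, chain_b): {'mean_c': ..., 'mean_abs_c': ...}} over
    the off-diagonal inter-chain entries.
    """
    chains = sorted({k[0] for k in dcc_matrix.residue_keys})
    chain_arr = np.array([k[0] for k in dcc_matrix.residue_keys])
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a_i in range(len(chains)):
        for b_i in range(a_i + 1, len(chains)):
            a, b = chains[a_i], chains[b_i]
            block = dcc_matrix.matrix[np.ix_(chain_arr == a, chain_arr == b)]
            out[(a, b)] = {
                "mean_c": float(block.mean()),
                "mean_abs_c": float(np.abs(block).mean()),
            }
    return out
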