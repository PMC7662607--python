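"""Synthetic multimer structures, trajectories, vote tables and alignments.

Everything here plants a known ground truth — per-residue fluctuation
amplitudes scaling with a temperature label, inter-/intra-chain correlation
blocks, donor–acceptor hydrogen-bond timelines with chosen persistence, and
interface contacts — so every downstream estimator can be tested against the
quantity it is supposed to recover, with no trajectory download.

The defaults mirror the study conditions this package targets: homodimers,
a four-point temperature series (300/363/393/423 K), 50 ns of sampling saved
every 100 ps (500 frames), and fluctuation amplitudes that grow with
temperature.  Displacements are isotropic Gaussian and frame-independent;
see docs/methods.md for what that does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ResidueKey, Structure, Trajectory

__all__ = [
    "GeneratorConfig", "CorrelationBlock", "PlantedHBond", "GenerationError",
    "generate_dimer_structure", "generate_trajectory", "generate_vote_table",
    "generate_msa",
]


class GenerationError(ValueError):
    """Raised when planted constraints cannot be realised."""


AtomRef = tuple[str, int, str]  # (chain, residue_index, atom_name)


@dataclass(frozen=True)
class CorrelationBlock:
    """Two residue sets whose displacements share a latent mode with target rho."""

    set_a: tuple[tuple[str, int], ...]
    set_b: tuple[tuple[str, int], ...]
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class PlantedHBond:
    """A donor/acceptor atom pair held within 3.0 A in a chosen frame fraction.

    ``persistence`` may be a single fraction or one fraction per temperature
    label (an interface bond weakening as the thermostat is raised).
    """

    donor: AtomRef
    acceptor: AtomRef
    persistence: float | tuple[float, ...]

    def __post_init__(self) -> None:
        values = self.persistence if isinstance(self.persistence, tuple) \
            else (self.persistence,)
        if not all(0.0 <= p <= 1.0 for p in values):
            raise ValueError("persistence fractions must lie in [0, 1]")

    def persistence_at(self, temperature_index: int) -> float:
        if isinstance(self.persistence, tuple):
            return self.persistence[temperature_index]
        return self.persistence


@dataclass
class GeneratorConfig:
    n_chains: int = 2
    n_residues_per_chain: int = 50
    seed: int = 0
    temperature_labels: tuple[float, ...] = (300.0, 363.0, 393.0, 423.0)
    base_sigma: float = 0.4            # A, fluctuation amplitude at first temperature
    sigma_scale_per_temp: tuple[float, ...] = (1.0, 1.3, 1.7, 2.2)
    n_frames: int = 500
    frame_interval: float = 100.0      # ps; 500 frames -> 50 ns
    residue_sigma_factors: tuple[float, ...] | None = None  # per residue, all chains
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    interface_pairs: tuple[tuple[int, int], ...] = ()  # (res in chain A, res in chain B)
    pocket_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be > 0")
        if len(self.sigma_scale_per_temp) != len(self.temperature_labels):
            raise ValueError("one sigma scale per temperature label required")
        if any(s <= 0 for s in self.sigma_scale_per_temp):
            raise ValueError("sigma scales must be > 0")
        self.correlation_blocks = tuple(
            b if isinstance(b, CorrelationBlock) else CorrelationBlock(*b)
            for b in self.correlation_blocks
        )
        self.planted_hbonds = tuple(
            b if isinstance(b, PlantedHBond) else PlantedHBond(*b)
            for b in self.planted_hbonds
        )

    def sigma_factors(self) -> np.ndarray:
        """Planted per-residue amplitude factors (deterministic given seed)."""
        if self.residue_sigma_factors is not None:
            f = np.asarray(self.residue_sigma_factors, dtype=float)
            if len(f) != self.n_residues_per_chain:
                raise ValueError("need one sigma factor per residue")
            return f
        rng = np.random.default_rng([self.seed, 7919])
        return rng.uniform(0.5, 1.5, size=self.n_residues_per_chain)


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

# local heavy-atom offsets relative to CA; CB z-offset flips so the chains'
# side chains face each other across the inter-chain gap
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.60, 0.0]),
    "O": np.array([1.90, 1.60, 0.0]),
}
_CB_OFFSET = np.array([0.0, -0.95, 1.20])
_CHAIN_GAP = 12.0  # A between chain curves; keeps unplanted CB-CB > 8 A
_CONTACT_DISTANCE = 5.0  # A, planted interface CB-CB separation (within 4-6)


def _is_gly(res_id: int) -> bool:
    return res_id % 7 == 0


def _chain_label(k: int) -> str:
    return chr(ord("A") + k)


def generate_dimer_structure(config: GeneratorConfig) -> Structure:
    """Poly-alanine-like multimer on smooth curves with planted contacts.

    Each residue carries N/CA/C/O/CB (GLY, every 7th residue, has no CB).
    For every ``interface_pair`` the chain-B residue is moved so the two
    contact atoms (CB, or CA for Gly) sit ``_CONTACT_DISTANCE`` apart.  A ZN
    het atom is placed per chain at the centroid of the pocket residues.
    """
    if config.n_chains < 2:
        raise ValueError("need at least 2 chains for a multimer")
    nres = config.n_residues_per_chain

    chain_ids, res_ids, icodes, res_names, atom_names, elements, hetero, coords = \
        [], [], [], [], [], [], [], []

    def add_atom(chain: str, rid: int, rname: str, aname: str, elem: str,
                 pos: np.ndarray, het: bool = False) -> None:
        chain_ids.append(chain); res_ids.append(rid); icodes.append("")
        res_names.append(rname); atom_names.append(aname); elements.append(elem)
        hetero.append(het); coords.append(pos)

    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for k in range(config.n_chains):
        chain = _chain_label(k)
        z = _CHAIN_GAP * k
        cb_sign = 1.0 if k == 0 else -1.0  # face the first chain
        for r in range(1, nres + 1):
            ca = np.array([3.8 * (r - 1), 4.0 * math.sin((r - 1) / 3.0), z])
            ca_pos[(chain, r)] = ca
            rname = "GLY" if _is_gly(r) else "ALA"
            for aname, off in _BACKBONE_OFFSETS.items():
                add_atom(chain, r, rname, aname, aname[0], ca + off)
            if rname != "GLY":
                cb = ca + _CB_OFFSET * np.array([1.0, 1.0, cb_sign])
                add_atom(chain, r, rname, "CB", "C", cb)

    structure = Structure(
        chain_ids=np.array(chain_ids), res_ids=np.array(res_ids),
        icodes=np.array(icodes), res_names=np.array(res_names),
        atom_names=np.array(atom_names), elements=np.array(elements),
        hetero=np.array(hetero), coords=np.array(coords),
    )

    # plant interface contacts: translate the whole chain-B residue so the
    # contact atoms end up _CONTACT_DISTANCE apart along the inter-chain axis
    moved: set[int] = set()
    for ra, rb in config.interface_pairs:
        if rb in moved:
            raise GenerationError(
                f"residue B:{rb} appears in more than one interface pair"
            )
        moved.add(rb)
        atom_a = "CA" if _is_gly(ra) else "CB"
        atom_b = "CA" if _is_gly(rb) else "CB"
        ia = structure.find_atom("A", ra, atom_a)
        ib = structure.find_atom("B", rb, atom_b)
        target = structure.coords[ia] + np.array([0.0, 0.0, _CONTACT_DISTANCE])
        delta = target - structure.coords[ib]
        res_mask = (structure.chain_ids == "B") & (structure.res_ids == rb)
        structure.coords[res_mask] += delta
        d = np.linalg.norm(structure.coords[ib] - structure.coords[ia])
        if not 4.0 <= d <= 6.0:  # pragma: no cover - construction guarantees
            raise GenerationError(f"interface pair ({ra},{rb}) placed at {d:.2f} A")

    # one catalytic ZN per chain at the pocket centroid (post-placement coords)
    if config.pocket_residues:
        zn_chain, zn_coord = [], []
        for k in range(config.n_chains):
            chain = _chain_label(k)
            centroids = []
            for r in config.pocket_residues:
                ia = structure.find_atom(chain, r, "CA")
                centroids.append(structure.coords[ia])
            zn_chain.append(chain)
            zn_coord.append(np.mean(centroids, axis=0))
        nz = len(zn_chain)
        structure = Structure(
            chain_ids=np.concatenate([structure.chain_ids, np.array(zn_chain)]),
            res_ids=np.concatenate([structure.res_ids, np.full(nz, nres + 1)]),
            icodes=np.concatenate([structure.icodes, np.full(nz, "")]),
            res_names=np.concatenate([structure.res_names, np.full(nz, "ZN")]),
            atom_names=np.concatenate([structure.atom_names, np.full(nz, "ZN")]),
            elements=np.concatenate([structure.elements, np.full(nz, "ZN")]),
            hetero=np.concatenate([structure.hetero, np.full(nz, True)]),
            coords=np.vstack([structure.coords, np.array(zn_coord)]),
        )
    return structure


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def generate_trajectory(structure: Structure, config: GeneratorConfig,
                        temperature_index: int) -> Trajectory:
    """Gaussian-fluctuation trajectory with planted correlations and H-bonds.

    Frame t = reference + per-residue isotropic Gaussian displacement with
    sigma_i = base_sigma * sigma_scale[temperature_index] * factor_i, applied
    rigidly to all atoms of the residue.  Correlation blocks share a latent
    mode: displacement = sigma * (sqrt(|rho|)*L +/- sqrt(1-|rho|)*eps), the
    sign realising anti-correlated (rho < 0) blocks.  Planted hydrogen bonds
    override the acceptor atom: 2.9 A from the donor in exactly
    round(persistence * n_frames) frames, 5.0 A otherwise.
    """
    if not 0 <= temperature_index < len(config.temperature_labels):
        raise IndexError("temperature_index out of range")
    rng = np.random.default_rng([config.seed, 104729, temperature_index])
    n_frames = config.n_frames
    scale = config.base_sigma * config.sigma_scale_per_temp[temperature_index]
    factors = config.sigma_factors()

    # map residues -> atom rows and planted sigma
    res_entries = [(key, idx) for key, _, idx in structure.residues()
                   if not structure.hetero[idx[0]]]
    res_index = {(key[0], key[1]): i for i, (key, _) in enumerate(res_entries)}
    n_res = len(res_entries)
    sigma = np.empty(n_res)
    for (key, _), i in zip(res_entries, range(n_res)):
        sigma[i] = scale * factors[(key[1] - 1) % len(factors)]

    # latent-mode coefficients per residue
    coef_latent = np.zeros(n_res)
    coef_priv = np.ones(n_res)
    latent_id = np.full(n_res, -1, dtype=int)
    for b, block in enumerate(config.correlation_blocks):
        for members, sign in ((block.set_a, 1.0), (block.set_b, np.sign(block.rho) or 1.0)):
            for chain, rid in members:
                i = res_index.get((chain, rid))
                if i is None:
                    raise GenerationError(f"block residue {chain}:{rid} not in structure")
                if latent_id[i] != -1:
                    raise GenerationError(
                        f"residue {chain}:{rid} appears in more than one correlation block"
                    )
                latent_id[i] = b
                coef_latent[i] = sign * math.sqrt(abs(block.rho))
                coef_priv[i] = math.sqrt(1.0 - abs(block.rho))

    latents = rng.standard_normal((len(config.correlation_blocks), n_frames, 3))
    private = rng.standard_normal((n_frames, n_res, 3))
    disp = coef_priv[None, :, None] * private
    for i in range(n_res):
        if latent_id[i] >= 0:
            disp[:, i, :] += coef_latent[i] * latents[latent_id[i]]
    disp *= sigma[None, :, None]

    coords = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    for (key, idx), i in zip(res_entries, range(n_res)):
        coords[:, idx, :] += disp[:, i, None, :]

    # planted hydrogen bonds: override acceptor positions
    used_atoms: set[int] = set()
    donor_atoms: set[int] = set()
    for bond in config.planted_hbonds:
        dch, drid, dname = bond.donor
        ach, arid, aname = bond.acceptor
        di = structure.find_atom(dch, drid, dname)
        ai = structure.find_atom(ach, arid, aname)
        if ai in used_atoms or ai in donor_atoms or di in used_atoms:
            raise GenerationError(
                f"atom {ach}:{arid}:{aname} participates in conflicting planted bonds"
            )
        used_atoms.add(ai)
        donor_atoms.add(di)
        n_on = int(round(bond.persistence_at(temperature_index) * n_frames))
        on_frames = rng.choice(n_frames, size=n_on, replace=False)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        dist = np.full(n_frames, 5.0)
        dist[on_frames] = 2.9
        coords[:, ai, :] = coords[:, di, :] + dist[:, None] * u[None, :]

    return Trajectory(
        topology=structure,
        coords=coords,
        frame_interval=config.frame_interval,
        temperature_label=config.temperature_labels[temperature_index],
    )


# ---------------------------------------------------------------------------
# Predictor vote tables
# ---------------------------------------------------------------------------

INTERFACE_PREDICTORS = ("hotregion", "kfc", "pisa", "ppcheck", "robetta")
HOTSPOT_PREDICTORS = ("hotregion", "kfc", "ppcheck", "robetta")


def generate_vote_table(n_residues: int, planted_interface: set[int],
                        planted_hotspots: set[int], n_servers: int = 5,
                        interface_agreement: int = 4, hotspot_agreement: int = 3,
                        seed: int = 0, chain: str = "A"):
    """Per-residue boolean votes for the interface (5) and hotspot (4) panels.

    Planted interface residues receive ``interface_agreement`` positive
    interface votes (must be >= 3 of 5); planted hotspots additionally
    receive ``hotspot_agreement`` hotspot votes (>= 3 of 4).  Non-planted
    residues receive at most 2 votes in either panel, so the consensus rules
    recover exactly the planted sets.
    """
    import pandas as pd

    if n_servers != len(INTERFACE_PREDICTORS):
        raise GenerationError("interface panel is fixed at 5 predictors")
    if not planted_hotspots <= planted_interface:
        raise GenerationError("planted hotspots must be a subset of the interface")
    if not 3 <= interface_agreement <= 5 or not 3 <= hotspot_agreement <= 4:
        raise GenerationError(
            "impossible agreement pattern: consensus needs 3<=interface<=5, 3<=hotspot<=4"
        )
    if max(planted_interface, default=0) > n_residues:
        raise GenerationError("planted residue index beyond n_residues")

    rng = np.random.default_rng([seed, 52711])
    rows = []
    for rid in range(1, n_residues + 1):
        iface_votes = np.zeros(5, dtype=bool)
        hs_votes = np.zeros(4, dtype=bool)
        if rid in planted_interface:
            iface_votes[rng.choice(5, size=interface_agreement, replace=False)] = True
            if rid in planted_hotspots:
                hs_votes[rng.choice(4, size=hotspot_agreement, replace=False)] = True
            else:
                k = int(rng.integers(0, 3))
                hs_votes[rng.choice(4, size=k, replace=False)] = True
        else:
            k = int(rng.integers(0, 3))
            iface_votes[rng.choice(5, size=k, replace=False)] = True
            # hotspot panel only defined where >=1 interface vote exists
            if iface_votes.any():
                kh = int(rng.integers(0, 3))
                hs_votes[rng.choice(4, size=kh, replace=False)] = True
        row = {"chain": chain, "residue_index": rid}
        row.update({f"iface_{p}": bool(v) for p, v in zip(INTERFACE_PREDICTORS, iface_votes)})
        row.update({f"hotspot_{p}": bool(v) for p, v in zip(HOTSPOT_PREDICTORS, hs_votes)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted-identity alignments
# ---------------------------------------------------------------------------

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_msa(n_seqs: int, length: int, planted_identity_matrix,
                 seed: int = 0, ids: Sequence[str] | None = None):
    """Gapless alignment realising a planted pairwise-identity matrix.

    Column by column a partition of the sequences is chosen greedily: two
    sequences are merged into one letter class only while every cross pair
    still has identity deficit, so realised identities hit
    round(p_ij * length) / length exactly when the targets are jointly
    feasible; otherwise a GenerationError reports the leftover deficit.
    """
    from .conserve import MSA

    P = np.asarray(planted_identity_matrix, dtype=float)
    if P.shape != (n_seqs, n_seqs) or not np.allclose(P, P.T):
        raise GenerationError("planted identity matrix must be square and symmetric")
    if (P < 0).any() or (P > 1).any():
        raise GenerationError("planted identities must lie in [0, 1]")

    rng = np.random.default_rng([seed, 15485863])
    target = np.round(P * length).astype(int)
    deficit = target.astype(float)
    np.fill_diagonal(deficit, 0)

    pairs = [(i, j) for i in range(n_seqs) for j in range(i + 1, n_seqs)]
    columns = np.empty((length, n_seqs), dtype="U1")
    for c in range(length):
        remaining = length - c
        parent = list(range(n_seqs))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        # merge the most-starved pairs first; random tie-break paces
        # competing pairs that can never share a column
        order = sorted(pairs, key=lambda ij: (-deficit[ij], rng.random()))
        for i, j in order:
            if deficit[i, j] < 1:
                continue
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            members_i = [x for x in range(n_seqs) if find(x) == ri]
            members_j = [x for x in range(n_seqs) if find(x) == rj]
            if all(deficit[u, v] >= 1 for u in members_i for v in members_j):
                parent[ri] = rj
        # assign letters per class, decrement deficits within classes
        roots = {}
        for x in range(n_seqs):
            roots.setdefault(find(x), []).append(x)
        letters = rng.choice(_AA_ALPHABET, size=len(roots), replace=False)
        for letter, members in zip(letters, roots.values()):
            for u in members:
                columns[c, u] = letter
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    deficit[members[a], members[b]] -= 1
                    deficit[members[b], members[a]] -= 1

    if (np.abs(deficit) > 0.5).any():
        worst = np.unravel_index(np.argmax(np.abs(deficit)), deficit.shape)
        raise GenerationError(
            "infeasible joint identity constraints: pair "
            f"{worst} left with deficit {deficit[worst]:.0f} columns"
        )

    ids = list(ids) if ids is not None else [f"seq{i + 1}" for i in range(n_seqs)]
    rows = ["".join(columns[:, i]) for i in range(n_seqs)]
    return MSA(ids=ids, rows=rows)
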