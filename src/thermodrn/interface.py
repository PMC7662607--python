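"""Static multimer interface characterisation.

Solvent-accessible surface area (Shrake–Rupley on a deterministic
golden-spiral lattice), buried surface area in the PISA "interface area"
convention, geometric interface residues, inter-subunit hydrogen bonds and
salt bridges, disulfide pairing, the ion-pair latch motif, and consensus
interface/hotspot calling from predictor vote tables (3-of-5 / 3-of-4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ResidueKey, Structure, WATER_NAMES

__all__ = [
    "SASAResult", "InterfaceReport", "UnknownElementError",
    "VDW_RADII", "sasa", "bsa", "interface_residues_geometric",
    "static_hbonds", "salt_bridges", "disulfides", "ion_pair_latch",
    "consensus_calls", "HBond", "SaltBridge", "Disulfide",
]

#: van-der-Waals radii (A) for SASA; unknown elements are an error, never a default
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "ZN": 1.39}

DEFAULT_PROBE_RADIUS = 1.4    # A, water probe
DEFAULT_SPHERE_POINTS = 960
INTERFACE_DSASA_THRESHOLD = 0.1  # A^2; below this a residue is not interfacial

HBOND_MAX_DA = 3.5            # A, donor-acceptor heavy-atom cutoff
SALT_BRIDGE_CUTOFF = 4.0      # A, acidic O - basic N
DISULFIDE_SG_CUTOFF = 2.3     # A, SG-SG


class UnknownElementError(KeyError):
    """Raised when an atom's element has no van-der-Waals radius assigned."""


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley, golden-spiral lattice)
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SASAResult:
    per_atom: np.ndarray            # A^2, aligned with the evaluated atom subset
    atom_indices: np.ndarray        # indices into the original structure
    per_residue: dict[ResidueKey, float]
    total: float
    probe_radius: float
    n_sphere_points: int


def _sasa_atom_mask(structure: Structure) -> np.ndarray:
    """Heavy atoms only, waters excluded."""
    return (structure.elements != "H") & ~structure.is_water()


def sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_sphere_points: int = DEFAULT_SPHERE_POINTS) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each heavy atom is tested on a golden-spiral lattice of
    ``n_sphere_points`` points at radius r_vdw + probe; a point is buried if
    it falls inside any neighbour's probe-extended sphere.  The lattice is
    deterministic, so results are bit-reproducible.
    """
    mask = _sasa_atom_mask(structure)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError("no heavy atoms to evaluate")
    try:
        radii = np.array([VDW_RADII[e] for e in structure.elements[idx]])
    except KeyError as exc:
        raise UnknownElementError(
            f"no van-der-Waals radius for element {exc.args[0]!r}"
        ) from None
    coords = structure.coords[idx]
    extended = radii + probe_radius
    unit = golden_spiral_points(n_sphere_points)

    tree = cKDTree(coords)
    max_ext = extended.max()
    per_atom = np.empty(len(idx))
    for a in range(len(idx)):
        pts = coords[a] + extended[a] * unit
        neighbors = tree.query_ball_point(coords[a], extended[a] + max_ext)
        accessible = np.ones(n_sphere_points, dtype=bool)
        for b in neighbors:
            if b == a:
                continue
            d2 = ((pts - coords[b]) ** 2).sum(axis=1)
            accessible &= d2 > extended[b] ** 2
        per_atom[a] = 4.0 * np.pi * extended[a] ** 2 * accessible.mean()

    per_residue: dict[ResidueKey, float] = {}
    for a, orig in enumerate(idx):
        key = structure.residue_key(int(orig))
        per_residue[key] = per_residue.get(key, 0.0) + per_atom[a]
    return SASAResult(
        per_atom=per_atom, atom_indices=idx, per_residue=per_residue,
        total=float(per_atom.sum()), probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


# ---------------------------------------------------------------------------
# Buried surface area and geometric interface residues
# ---------------------------------------------------------------------------

def _chain_groups(structure: Structure,
                  chain_grouping: Iterable[Iterable[str]] | None) -> list[list[str]]:
    if chain_grouping is None:
        groups = [[c] for c in structure.chains]
    else:
        groups = [list(g) for g in chain_grouping]
    if len(groups) < 2:
        raise ValueError("buried-surface analysis needs >= 2 chain groups")
    return groups


def bsa(complex_structure: Structure,
        chain_grouping: Iterable[Iterable[str]] | None = None,
        probe_radius: float = DEFAULT_PROBE_RADIUS,
        n_sphere_points: int = DEFAULT_SPHERE_POINTS,
        halved: bool = True) -> tuple[float, dict[ResidueKey, float]]:
    """Buried surface area of a complex and per-residue buried area.

    BSA = (sum of isolated-group SASA - complex SASA) / 2, the PISA
    "interface area" convention; ``halved=False`` reports the unhalved sum.
    Per-residue values are isolated-minus-complex differences (unhalved).
    """
    groups = _chain_groups(complex_structure, chain_grouping)
    complex_res = sasa(complex_structure, probe_radius, n_sphere_points)
    delta: dict[ResidueKey, float] = {}
    total_isolated = 0.0
    for group in groups:
        gmask = np.isin(complex_structure.chain_ids, group)
        part = complex_structure.subset(np.nonzero(gmask)[0])
        res = sasa(part, probe_radius, n_sphere_points)
        total_isolated += res.total
        for key, area in res.per_residue.items():
            delta[key] = area - complex_res.per_residue.get(key, 0.0)
    buried = total_isolated - complex_res.total
    if buried < -1e-6:
        raise AssertionError(f"negative buried area {buried}")
    buried = max(buried, 0.0)
    return (buried / 2.0 if halved else buried), delta


def interface_residues_geometric(
        complex_structure: Structure,
        chain_grouping: Iterable[Iterable[str]] | None = None,
        threshold: float = INTERFACE_DSASA_THRESHOLD,
        **sasa_kwargs) -> dict[str, set[ResidueKey]]:
    """Residues losing more than ``threshold`` A^2 of SASA upon assembly."""
    _, delta = bsa(complex_structure, chain_grouping, **sasa_kwargs)
    out: dict[str, set[ResidueKey]] = {c: set() for c in complex_structure.chains}
    for key, d in delta.items():
        if d > threshold:
            out[key[0]].add(key)
    return out


# ---------------------------------------------------------------------------
# Donor / acceptor chemistry (rule-based, no hydrogen placement)
# ---------------------------------------------------------------------------

#: side-chain donor atoms by residue name (backbone N is always a donor)
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
}

ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BASIC_ATOMS = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIS": {"ND1", "NE2"}}


def donor_atom_indices(structure: Structure) -> np.ndarray:
    """Heavy-atom H-bond donors: backbone N plus the side-chain rule table."""
    out = []
    for i in range(structure.n_atoms):
        if structure.hetero[i] or structure.res_names[i] in WATER_NAMES:
            continue
        name = structure.atom_names[i]
        rname = structure.res_names[i]
        if name == "N":
            out.append(i)
        elif name in SIDECHAIN_DONORS.get(rname, ()):
            out.append(i)
    return np.array(out, dtype=int)


def acceptor_atom_indices(structure: Structure) -> np.ndarray:
    """Heavy-atom H-bond acceptors: any protein O; His ring N when unprotonated."""
    out = []
    his_protonated: dict[ResidueKey, set[str]] = {}
    for i in range(structure.n_atoms):
        if structure.res_names[i] == "HIS" and structure.atom_names[i] in ("HD1", "HE2"):
            key = structure.residue_key(i)
            his_protonated.setdefault(key, set()).add(structure.atom_names[i])
    for i in range(structure.n_atoms):
        if structure.hetero[i] or structure.res_names[i] in WATER_NAMES:
            continue
        if structure.elements[i] == "O":
            out.append(i)
        elif structure.res_names[i] == "HIS" and structure.atom_names[i] in ("ND1", "NE2"):
            key = structure.residue_key(i)
            h_name = "HD1" if structure.atom_names[i] == "ND1" else "HE2"
            if h_name not in his_protonated.get(key, set()):
                out.append(i)
    return np.array(out, dtype=int)


class HBond(NamedTuple):
    donor: int       # atom index
    acceptor: int
    distance: float  # A
    label: str       # 'intra' | 'inter'


def _pair_label(structure: Structure, i: int, j: int) -> str | None:
    """intra/inter partition; None when the pair is excluded (same/adjacent residue)."""
    if structure.chain_ids[i] != structure.chain_ids[j]:
        return "inter"
    if abs(int(structure.res_ids[i]) - int(structure.res_ids[j])) >= 2:
        return "intra"
    return None


def static_hbonds(structure: Structure, max_da: float = HBOND_MAX_DA,
                  partition: str | None = None) -> list[HBond]:
    """Donor–acceptor heavy-atom pairs within ``max_da``.

    Intra-chain pairs require a sequence separation of at least two
    residues; inter-chain pairs have no separation requirement.
    ``partition`` restricts the output to 'intra' or 'inter'.
    """
    donors = donor_atom_indices(structure)
    acceptors = acceptor_atom_indices(structure)
    bonds: list[HBond] = []
    if len(donors) == 0 or len(acceptors) == 0:
        return bonds
    dcoords = structure.coords[donors]
    acoords = structure.coords[acceptors]
    d2 = ((dcoords[:, None, :] - acoords[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= max_da * max_da
    for di, ai in zip(*np.nonzero(within)):
        i, j = int(donors[di]), int(acceptors[ai])
        if i == j:
            continue
        label = _pair_label(structure, i, j)
        if label is None:
            continue
        if partition is not None and label != partition:
            continue
        bonds.append(HBond(i, j, float(np.sqrt(d2[di, ai])), label))
    return bonds


class SaltBridge(NamedTuple):
    acidic: int
    basic: int
    distance: float
    label: str


def salt_bridges(structure: Structure,
                 cutoff: float = SALT_BRIDGE_CUTOFF) -> list[SaltBridge]:
    """Acidic-O / basic-N pairs within ``cutoff`` (4 A ionic-interaction rule)."""
    acidic, basic = [], []
    for i in range(structure.n_atoms):
        rname, aname = structure.res_names[i], structure.atom_names[i]
        if aname in ACIDIC_ATOMS.get(rname, ()) or aname == "OXT":
            acidic.append(i)
        if aname in BASIC_ATOMS.get(rname, ()):
            basic.append(i)
    out: list[SaltBridge] = []
    for i in acidic:
        for j in basic:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d <= cutoff:
                label = "inter" if structure.chain_ids[i] != structure.chain_ids[j] \
                    else "intra"
                out.append(SaltBridge(i, j, d, label))
    return out


class Disulfide(NamedTuple):
    sg_a: int
    sg_b: int
    distance: float
    label: str


def disulfides(structure: Structure,
               sg_cutoff: float = DISULFIDE_SG_CUTOFF) -> list[Disulfide]:
    """Cys SG–SG pairs within ``sg_cutoff``; greedy nearest-first, one bond per SG."""
    sg = [i for i in range(structure.n_atoms)
          if structure.res_names[i] == "CYS" and structure.atom_names[i] == "SG"]
    candidates = []
    for a, b in itertools.combinations(sg, 2):
        d = float(np.linalg.norm(structure.coords[a] - structure.coords[b]))
        if d <= sg_cutoff:
            candidates.append((d, a, b))
    candidates.sort()
    used: set[int] = set()
    out: list[Disulfide] = []
    for d, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        label = "inter" if structure.chain_ids[a] != structure.chain_ids[b] else "intra"
        out.append(Disulfide(a, b, d, label))
    return out


def ion_pair_latch(structure: Structure,
                   bridges: list[SaltBridge]) -> list[tuple[ResidueKey, ResidueKey, ResidueKey]]:
    """(R1, D, R2) triples: an acidic residue D bridging two distinct basic residues.

    Only intra-subunit bridges qualify, matching the latch motif bracing a
    single subunit's fold.
    """
    partners: dict[ResidueKey, set[ResidueKey]] = {}
    for br in bridges:
        if br.label != "intra":
            continue
        acid_key = structure.residue_key(br.acidic)
        base_key = structure.residue_key(br.basic)
        partners.setdefault(acid_key, set()).add(base_key)
    out = []
    for acid_key, bases in partners.items():
        for r1, r2 in itertools.combinations(sorted(bases), 2):
            out.append((r1, acid_key, r2))
    return out


# ---------------------------------------------------------------------------
# Consensus interface / hotspot calling
# ---------------------------------------------------------------------------

INTERFACE_VOTE_PREFIX = "iface_"
HOTSPOT_VOTE_PREFIX = "hotspot_"
INTERFACE_CONSENSUS = 3   # of 5 predictors
HOTSPOT_CONSENSUS = 3     # of 4 predictors


def consensus_calls(votes: pd.DataFrame) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Consensus interface (>=3 of 5) and hotspot (>=3 of 4, within interface) sets.

    ``votes`` columns: chain, residue_index, five ``iface_*`` and four
    ``hotspot_*`` boolean columns.  Returns sets of (chain, residue_index).
    """
    iface_cols = [c for c in votes.columns if c.startswith(INTERFACE_VOTE_PREFIX)]
    hs_cols = [c for c in votes.columns if c.startswith(HOTSPOT_VOTE_PREFIX)]
    if len(iface_cols) != 5:
        raise ValueError(f"expected 5 interface predictor columns, got {len(iface_cols)}")
    if len(hs_cols) != 4:
        raise ValueError(f"expected 4 hotspot predictor columns, got {len(hs_cols)}")
    for col in ("chain", "residue_index"):
        if col not in votes.columns:
            raise ValueError(f"missing column {col!r}")

    iface_votes = votes[iface_cols].astype(bool).sum(axis=1)
    hs_votes = votes[hs_cols].astype(bool).sum(axis=1)
    keys = list(zip(votes["chain"].astype(str), votes["residue_index"].astype(int)))
    interface = {k for k, v in zip(keys, iface_votes) if v >= INTERFACE_CONSENSUS}
    hotspots = {k for k, v in zip(keys, hs_votes)
                if v >= HOTSPOT_CONSENSUS and k in interface}
    return interface, hotspots


# ---------------------------------------------------------------------------
# Full interface report
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    interface_residues: dict[str, set[ResidueKey]]
    bsa: float
    per_residue_dsasa: dict[ResidueKey, float]
    inter_hbonds: list[HBond]
    salt_bridge_list: list[SaltBridge]
    disulfide_list: list[Disulfide]
    latch_hits: list[tuple[ResidueKey, ResidueKey, ResidueKey]]

    def summary(self, structure: Structure) -> str:
        lines = [
            f"BSA\t{self.bsa:.1f}",
            "interface_residues\t" + "; ".join(
                f"{c}:{len(r)}" for c, r in sorted(self.interface_residues.items())
            ),
            f"inter_subunit_hbonds\t{len(self.inter_hbonds)}",
            f"salt_bridges\t{len(self.salt_bridge_list)}",
            f"disulfides\t{len(self.disulfide_list)}",
            f"ion_pair_latches\t{len(self.latch_hits)}",
        ]
        return "\n".join(lines)


def interface_report(structure: Structure,
                     chain_grouping: Iterable[Iterable[str]] | None = None,
                     hbond_cutoff: float = HBOND_MAX_DA,
                     **sasa_kwargs) -> InterfaceReport:
    """Run the full static characterisation of a multimer interface."""
    buried, delta = bsa(structure, chain_grouping, **sasa_kwargs)
    residues: dict[str, set[ResidueKey]] = {c: set() for c in structure.chains}
    for key, d in delta.items():
        if d > INTERFACE_DSASA_THRESHOLD:
            residues[key[0]].add(key)
    bridges = salt_bridges(structure)
    return InterfaceReport(
        interface_residues=residues,
        bsa=buried,
        per_residue_dsasa=delta,
        inter_hbonds=static_hbonds(structure, hbond_cutoff, partition="inter"),
        salt_bridge_list=bridges,
        disulfide_list=disulfides(structure),
        latch_hits=ion_pair_latch(structure, bridges),
    )
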