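"""Structure and trajectory data model shared by every analysis stage.

Structures are flat arrays of atoms carrying chain, residue and element
identity in author (PDB) numbering.  Trajectories are ordered frame stacks
congruent with a reference topology; the interchange format is multi-model
PDB, so every fixture in the test suite is plain text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("thermodrn")

#: standard three-letter amino-acid codes
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: atomic masses (u) used for mass-weighted radii of gyration
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "ZN": 65.38, "SE": 78.971, "FE": 55.845, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "CA": 40.078, "K": 39.098,
}

WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class CongruenceError(ValueError):
    """Raised when trajectory models are not atom-congruent."""


class DegenerateFitError(ValueError):
    """Raised when a superposition target is under-determined (collinear / <3 atoms)."""


class SelectionError(ValueError):
    """Raised when an atom selection resolves to an empty or ill-formed set."""


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

ResidueKey = tuple[str, int, str]  # (chain_id, residue_index, insertion code)


def residue_label(key: ResidueKey) -> str:
    chain, rid, icode = key
    return f"{chain}:{rid}{icode}"


@dataclass
class Structure:
    """Flat atom table for a single conformation of a (multi-chain) assembly."""

    chain_ids: np.ndarray   # str
    res_ids: np.ndarray     # int, author numbering
    icodes: np.ndarray      # str, insertion codes ('' when absent)
    res_names: np.ndarray   # str, 3-letter codes
    atom_names: np.ndarray  # str
    elements: np.ndarray    # str, upper-case element symbols
    hetero: np.ndarray      # bool
    coords: np.ndarray      # (n, 3) float64, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.atom_names)
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array incongruent with atom annotations")
        if n == 0:
            raise ValueError("empty structure")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in sorted(idx)]

    def residue_key(self, i: int) -> ResidueKey:
        return (str(self.chain_ids[i]), int(self.res_ids[i]), str(self.icodes[i]))

    def residues(self) -> Iterator[tuple[ResidueKey, str, np.ndarray]]:
        """Yield (key, residue name, atom indices) in file order."""
        keys = list(zip(self.chain_ids, self.res_ids, self.icodes))
        start = 0
        for i in range(1, self.n_atoms + 1):
            if i == self.n_atoms or keys[i] != keys[start]:
                idx = np.arange(start, i)
                yield self.residue_key(start), str(self.res_names[start]), idx
                start = i

    def find_atoms(self, chain: str, res_id: int, atom_name: str,
                   icode: str = "") -> np.ndarray:
        mask = (
            (self.chain_ids == chain)
            & (self.res_ids == res_id)
            & (self.icodes == icode)
            & (self.atom_names == atom_name)
        )
        return np.nonzero(mask)[0]

    def find_atom(self, chain: str, res_id: int, atom_name: str,
                  icode: str = "") -> int:
        idx = self.find_atoms(chain, res_id, atom_name, icode)
        if len(idx) != 1:
            raise SelectionError(
                f"atom {chain}:{res_id}{icode}:{atom_name} resolves to "
                f"{len(idx)} atoms (expected 1)"
            )
        return int(idx[0])

    def subset(self, indices: np.ndarray) -> "Structure":
        indices = np.asarray(indices)
        return Structure(
            chain_ids=self.chain_ids[indices],
            res_ids=self.res_ids[indices],
            icodes=self.icodes[indices],
            res_names=self.res_names[indices],
            atom_names=self.atom_names[indices],
            elements=self.elements[indices],
            hetero=self.hetero[indices],
            coords=self.coords[indices],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))

    def is_water(self) -> np.ndarray:
        return np.isin(self.res_names, list(WATER_NAMES))

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[e] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no atomic mass for element {exc.args[0]!r}") from exc


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frame_interval`` is the physical time between saved frames in ps;
    ``temperature_label`` is the thermostat setting of the run in K.
    """

    topology: Structure
    coords: np.ndarray          # (n_frames, n_atoms, 3)
    frame_interval: float       # ps
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise CongruenceError(
                "frame array incongruent with topology "
                f"(expected (*, {self.topology.n_atoms}, 3), got {self.coords.shape})"
            )
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.coords[t]

    def times_ns(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval / 1000.0


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> list[int]:
    """Cheap text scan: validates coordinate fields, returns per-model atom counts.

    A file without MODEL records counts as a single model.
    """
    counts: list[int] = []
    current = 0
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if saw_model or current:
                    counts.append(current)
                current = 0
                saw_model = True
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBParseError(
                        f"{path}: malformed coordinate field on line {lineno}: "
                        f"{line.rstrip()!r}"
                    ) from None
                current += 1
    counts.append(current)
    if sum(counts) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return counts


def _structure_from_atom_array(arr: bst.AtomArray) -> Structure:
    return Structure(
        chain_ids=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        icodes=arr.ins_code.astype(str),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=np.char.upper(arr.element.astype(str)),
        hetero=arr.hetero.astype(bool),
        coords=arr.coord.astype(np.float64),
    )


def read_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file.

    Altlocs resolve to the highest-occupancy conformer (ties: first
    encountered); insertion codes are kept as residue suffix labels.
    """
    path = Path(path)
    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    return _structure_from_atom_array(arr)


def read_trajectory(path: str | Path, frame_interval: float,
                    temperature_label: float | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL block)."""
    path = Path(path)
    counts = _prescan_pdb(path)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise CongruenceError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"model 1 has {counts[0]}"
        )
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):  # single model
        stack = bst.stack([stack])
    topo = _structure_from_atom_array(stack[0])
    return Trajectory(
        topology=topo,
        coords=stack.coord.astype(np.float64),
        frame_interval=frame_interval,
        temperature_label=temperature_label,
    )


def _to_atom_array(structure: Structure, coords: np.ndarray) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_ids.astype(int)
    arr.ins_code = structure.icodes.astype("U1")
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = structure.hetero.astype(bool)
    arr.coord = np.asarray(coords, dtype=np.float32)
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure, structure.coords))
    pdb.write(str(path))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    arrays = [
        _to_atom_array(trajectory.topology, trajectory.coords[t])
        for t in range(trajectory.n_frames)
    ]
    pdb = PDBFile()
    pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_network_atoms(structure: Structure) -> np.ndarray:
    """One network atom per amino-acid residue: CB, or CA for Gly / missing CB.

    Returns atom indices in residue order.  Residues lacking both CA and CB
    are excluded with a warning.  Hetero atoms and waters never contribute.
    """
    indices: list[int] = []
    for key, res_name, idx in structure.residues():
        if structure.hetero[idx[0]] or res_name in WATER_NAMES:
            continue
        if res_name not in AMINO_ACIDS and "CA" not in structure.atom_names[idx]:
            continue
        names = structure.atom_names[idx]
        if res_name != "GLY" and "CB" in names:
            indices.append(int(idx[names == "CB"][0]))
        elif "CA" in names:
            indices.append(int(idx[names == "CA"][0]))
        else:
            logger.warning("residue %s (%s) lacks both CA and CB; excluded",
                           residue_label(key), res_name)
    return np.array(indices, dtype=int)


def select_ca_atoms(structure: Structure) -> np.ndarray:
    """All amino-acid CA atom indices in residue order."""
    mask = (structure.atom_names == "CA") & ~structure.hetero
    return np.nonzero(mask)[0]


@dataclass
class ResidueSelector:
    """Declarative atom selection: (chain pattern, residue set/range, atom rule).

    ``atoms`` is either a set of atom names or one of the role keywords
    ``network_atom`` (CB, CA for Gly), ``heavy`` (non-hydrogen) or ``all``.
    A chain pattern of '*' matches every chain; residues of ``None`` match
    every residue index.
    """

    rules: list[tuple[str, object, object]] = field(default_factory=list)

    def resolve(self, structure: Structure) -> np.ndarray:
        selected: list[int] = []
        for chain_pat, residues, atoms in self.rules:
            chain_mask = (
                np.ones(structure.n_atoms, bool)
                if chain_pat == "*" else structure.chain_ids == chain_pat
            )
            if residues is None:
                res_mask = np.ones(structure.n_atoms, bool)
            else:
                res_set = set(range(residues[0], residues[1] + 1)) \
                    if isinstance(residues, tuple) else set(residues)
                res_mask = np.isin(structure.res_ids, list(res_set))
            base = np.nonzero(chain_mask & res_mask)[0]
            if atoms == "all":
                selected.extend(base.tolist())
            elif atoms == "heavy":
                selected.extend(base[structure.elements[base] != "H"].tolist())
            elif atoms == "network_atom":
                sub = select_network_atoms(structure)
                allowed = set(base.tolist())
                selected.extend(i for i in sub.tolist() if i in allowed)
            else:
                name_mask = np.isin(structure.atom_names[base], list(atoms))
                selected.extend(base[name_mask].tolist())
        if not selected:
            raise SelectionError("selector resolves to an empty atom set")
        if len(set(selected)) != len(selected):
            # duplicates across rules are collapsed, preserving order
            seen: set[int] = set()
            selected = [i for i in selected if not (i in seen or seen.add(i))]
        return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# Least-squares superposition (Kabsch)
# ---------------------------------------------------------------------------

def _check_fit_points(points: np.ndarray) -> None:
    if len(points) < 3:
        raise DegenerateFitError("superposition needs >= 3 selected atoms")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateFitError("selected atoms are collinear")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Optimal rigid-body fit of ``mobile`` onto ``reference``.

    The rotation/translation minimising the least-squares deviation over
    ``selection`` (all atoms when None) is applied to the whole mobile frame.
    Returns (fitted frame, RMSD over the selection in Angstrom).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    P, Q = mobile[sel], reference[sel]
    if P.shape != Q.shape:
        raise ValueError("selection resolves differently on mobile and reference")
    _check_fit_points(Q)
    _check_fit_points(P)
    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    H = (P - p_mean).T @ (Q - q_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    fitted = (mobile - p_mean) @ R.T + q_mean
    diff = fitted[sel] - Q
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return fitted, rmsd
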