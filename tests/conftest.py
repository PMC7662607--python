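"""Shared builders: hand-written PDB text and in-memory toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from thermodrn.core import Structure


def pdb_line(serial: int, name: str, resname: str, chain: str, resid: int,
             x: float, y: float, z: float, altloc: str = " ", occ: float = 1.0,
             element: str | None = None, record: str = "ATOM",
             icode: str = " ") -> str:
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resid:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_structure(atoms: list[tuple]) -> Structure:
    """Build a Structure from (chain, resid, resname, atom_name, element, xyz[, hetero])."""
    rows = [(a + (False,))[:7] for a in atoms]
    return Structure(
        chain_ids=np.array([r[0] for r in rows]),
        res_ids=np.array([r[1] for r in rows]),
        icodes=np.array(["" for _ in rows]),
        res_names=np.array([r[2] for r in rows]),
        atom_names=np.array([r[3] for r in rows]),
        elements=np.array([r[4] for r in rows]),
        hetero=np.array([r[6] for r in rows]),
        coords=np.array([r[5] for r in rows], dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
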