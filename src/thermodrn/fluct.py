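"""Per-temperature fluctuation and compactness metrics.

RMSF per residue (reference = first frame by default, per the study's
convention, with a mean-structure option), radius of gyration for chains
and catalytic pockets, per-frame RMSD with a kernel-density summary, and an
equilibration check on the tail of the RMSD series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    ATOMIC_MASSES, SelectionError, Structure, Trajectory,
    select_network_atoms, superpose,
)

__all__ = [
    "RMSFProfile", "RgSeries", "PocketDefinition", "KDESummary",
    "rmsf", "rg", "rg_series", "rmsd_series", "equilibration_check",
]

KDE_GRID_POINTS = 256
KDE_BANDWIDTH_FLOOR = 1e-3        # A, keeps degenerate (all-equal) series finite
EQUILIBRATION_SLOPE_LIMIT = 0.01  # A/ns drift tolerated in the tail window
EQUILIBRATION_WINDOW = 0.2        # fraction of frames forming the tail window


@dataclass
class RMSFProfile:
    values: np.ndarray                     # A, one per selected residue
    residue_keys: list                     # parallel to values
    selection: np.ndarray                  # atom indices used
    superposed: bool
    reference: str                         # 'first' | 'mean'
    temperature_label: float | None


@dataclass
class RgSeries:
    target: str
    values: np.ndarray                     # A per frame

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def range(self) -> float:
        """max - min; the study's compactness-maintenance readout."""
        return self.max - self.min


@dataclass
class PocketDefinition:
    """A catalytic pocket: listed residues (heavy atoms) plus the Zn het atom."""

    name: str
    residues: list[tuple[str, int]]        # (chain, residue_index)
    include_zn: bool = True

    def atom_indices(self, structure: Structure) -> np.ndarray:
        if not self.residues:
            raise SelectionError(f"pocket {self.name!r} lists no residues")
        idx: list[int] = []
        for chain, rid in self.residues:
            mask = (
                (structure.chain_ids == chain)
                & (structure.res_ids == rid)
                & (structure.elements != "H")
                & ~structure.hetero
            )
            rows = np.nonzero(mask)[0]
            if len(rows) == 0:
                raise SelectionError(
                    f"pocket {self.name!r}: residue {chain}:{rid} not in topology"
                )
            idx.extend(rows.tolist())
        if self.include_zn:
            chains = {c for c, _ in self.residues}
            zn = np.nonzero(
                (structure.atom_names == "ZN")
                & np.isin(structure.chain_ids, list(chains))
            )[0]
            idx.extend(zn.tolist())
        return np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def rmsf(trajectory: Trajectory, selection: np.ndarray | None = None,
         superpose_frames: bool = True, reference: str = "first") -> RMSFProfile:
    """Root mean square fluctuation per selected atom (residue).

    RMSF_i = sqrt(mean_t |r_i(t) - r_i(ref)|^2) where ref is the first frame
    (default) or the across-frame mean position, after optionally
    superposing every frame onto the first frame over the selection.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    topo = trajectory.topology
    sel = select_network_atoms(topo) if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise SelectionError("empty RMSF selection")

    frames = trajectory.coords
    if superpose_frames:
        ref_frame = frames[0]
        fitted = np.empty((trajectory.n_frames, len(sel), 3))
        for t in range(trajectory.n_frames):
            full, _ = superpose(frames[t], ref_frame, sel)
            fitted[t] = full[sel]
    else:
        fitted = frames[:, sel, :]

    if reference == "first":
        ref = fitted[0]
    elif reference == "mean":
        ref = fitted.mean(axis=0)
    else:
        raise ValueError("reference must be 'first' or 'mean'")
    sq = ((fitted - ref[None]) ** 2).sum(axis=2)
    values = np.sqrt(sq.mean(axis=0))
    keys = [topo.residue_key(int(i)) for i in sel]
    return RMSFProfile(
        values=values, residue_keys=keys, selection=sel,
        superposed=superpose_frames, reference=reference,
        temperature_label=trajectory.temperature_label,
    )


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def rg(points: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of a point set (unit masses if None)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("need a non-empty (n, 3) point array")
    m = np.ones(len(points)) if masses is None else np.asarray(masses, dtype=np.float64)
    if (m <= 0).any():
        raise ValueError("masses must be > 0")
    com = (m[:, None] * points).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((points - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(trajectory: Trajectory,
              target: str | PocketDefinition,
              mass_weighted: bool = True) -> RgSeries:
    """Per-frame Rg of a chain or pocket (no superposition: Rg is rigid-invariant)."""
    topo = trajectory.topology
    if isinstance(target, PocketDefinition):
        idx = target.atom_indices(topo)
        name = target.name
    else:
        mask = (topo.chain_ids == target) & (topo.elements != "H") & ~topo.hetero
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise SelectionError(f"chain {target!r} not in topology")
        name = f"chain {target}"
    masses = topo.masses()[idx] if mass_weighted else None
    values = np.array([
        rg(trajectory.coords[t, idx, :], masses) for t in range(trajectory.n_frames)
    ])
    return RgSeries(target=name, values=values)


# ---------------------------------------------------------------------------
# RMSD series + KDE summary
# ---------------------------------------------------------------------------

@dataclass
class KDESummary:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mean: float


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    s = values.std(ddof=1) if n > 1 else 0.0
    bw = 1.06 * s * n ** (-1 / 5) if s > 0 else 0.0
    return max(bw, KDE_BANDWIDTH_FLOOR)


def _kde_reflected(values: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Gaussian KDE with reflection at zero (RMSD is non-negative)."""
    z1 = (grid[:, None] - values[None, :]) / bw
    z2 = (grid[:, None] + values[None, :]) / bw
    norm = 1.0 / (bw * np.sqrt(2.0 * np.pi))
    return norm * (np.exp(-0.5 * z1 ** 2) + np.exp(-0.5 * z2 ** 2)).mean(axis=1)


def rmsd_series(trajectory: Trajectory, selection: np.ndarray | None = None,
                reference_frame: int = 0) -> tuple[np.ndarray, KDESummary]:
    """Per-frame superposed RMSD to a reference frame, with a KDE summary.

    The density is evaluated on a 256-point grid over [0, 1.1 * max] with a
    Silverman bandwidth (floored at 1e-3 A) and reflection at zero, so it
    integrates to ~1 even for series concentrated near zero.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSD series needs >= 2 frames")
    topo = trajectory.topology
    sel = select_network_atoms(topo) if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise SelectionError("empty RMSD selection")
    ref = trajectory.coords[reference_frame]
    values = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        _, values[t] = superpose(trajectory.coords[t], ref, sel)

    vmax = values.max()
    bw = _silverman_bandwidth(values)
    # span [0, 1.1*max], but always cover a few bandwidths so the density of a
    # degenerate (near-constant) series still integrates to ~1
    hi = max(1.1 * vmax, 5.0 * bw)
    grid = np.linspace(0.0, hi, KDE_GRID_POINTS)
    density = _kde_reflected(values, grid, bw)
    return values, KDESummary(grid=grid, density=density, bandwidth=bw,
                              mean=float(values.mean()))


def equilibration_check(rmsd_values: np.ndarray, times_ns: np.ndarray,
                        window: float = EQUILIBRATION_WINDOW,
                        slope_limit: float = EQUILIBRATION_SLOPE_LIMIT
                        ) -> tuple[bool, float]:
    """Drift check over the trailing window of an RMSD series.

    Returns (equilibrated, slope in A/ns): equilibrated iff the
    least-squares slope over the last ``window`` fraction of frames is
    below ``slope_limit`` in magnitude.
    """
    rmsd_values = np.asarray(rmsd_values, dtype=float)
    times_ns = np.asarray(times_ns, dtype=float)
    if len(rmsd_values) < 10:
        raise ValueError("equilibration check needs >= 10 frames")
    n_tail = max(2, int(round(window * len(rmsd_values))))
    y = rmsd_values[-n_tail:]
    x = times_ns[-n_tail:]
    slope = float(np.polyfit(x, y, 1)[0])
    return abs(slope) < slope_limit, slope
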