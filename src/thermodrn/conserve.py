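"""Sequence-side summaries: pairwise identity matrices and motif conservation.

The identity "fraction of the sequence length" is ambiguous when aligned
sequences have different ungapped lengths; the default denominator is the
shorter ungapped length (which keeps the matrix symmetric and bounded by
1), with alignment-length and mean-ungapped-length conventions selectable
and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSA", "IdentityMatrix", "read_msa", "identity_matrix",
    "motif_conservation", "trim_signal_peptide",
]

GAP = "-"


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("one id per aligned row required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must share one length")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped_lengths(self) -> np.ndarray:
        return np.array([len(r) - r.count(GAP) for r in self.rows])


def read_msa(path: str | Path, fmt: str | None = None) -> MSA:
    """Read an aligned FASTA or Clustal file (format sniffed by default)."""
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        head = path.read_text()[:64].lstrip()
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA(ids=[rec.id for rec in aln], rows=[str(rec.seq).upper() for rec in aln])


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


@dataclass
class IdentityMatrix:
    matrix: np.ndarray
    ids: list[str]
    denominator: str   # 'shorter_sequence' | 'alignment_length' | 'mean_ungapped'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def identity_matrix(msa: MSA, denominator: str = "shorter_sequence") -> IdentityMatrix:
    """All-versus-all fraction of identical aligned positions.

    Identical positions are columns where both rows carry the same non-gap
    residue (gap-gap never counts); the fraction's denominator follows the
    chosen convention.  Diagonal is exactly 1.
    """
    if msa.n_seqs < 2:
        raise ValueError("identity matrix needs >= 2 sequences")
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != GAP
    ungapped = msa.ungapped_lengths()
    n = msa.n_seqs
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = int(np.sum((arr[i] == arr[j]) & nongap[i] & nongap[j]))
            if denominator == "shorter_sequence":
                denom = min(ungapped[i], ungapped[j])
            elif denominator == "alignment_length":
                denom = msa.length
            elif denominator == "mean_ungapped":
                denom = 0.5 * (ungapped[i] + ungapped[j])
            else:
                raise ValueError(f"unknown denominator convention {denominator!r}")
            M[i, j] = M[j, i] = ident / denom if denom else 0.0
    return IdentityMatrix(matrix=M, ids=list(msa.ids), denominator=denominator)


def motif_conservation(hit_table: pd.DataFrame,
                       motif_universe: Sequence[str]
                       ) -> tuple[pd.Series, pd.DataFrame]:
    """Motif occurrence frequencies and a presence/absence matrix.

    ``hit_table`` columns: sequence_id, motif_id (start/end/e_value
    optional).  frequency_m = #sequences containing motif m / #sequences.
    """
    for col in ("sequence_id", "motif_id"):
        if col not in hit_table.columns:
            raise ValueError(f"hit table missing column {col!r}")
    universe = list(motif_universe)
    unknown = set(hit_table["motif_id"]) - set(universe)
    if unknown:
        raise ValueError(f"motif ids outside the declared universe: {sorted(unknown)}")
    seqs = list(dict.fromkeys(hit_table["sequence_id"]))
    presence = pd.DataFrame(False, index=seqs, columns=universe)
    for _, row in hit_table.iterrows():
        presence.loc[row["sequence_id"], row["motif_id"]] = True
    freq = presence.sum(axis=0) / len(seqs)
    return freq, presence


def trim_signal_peptide(sequence: str, cleavage_site: int
                        ) -> tuple[str, dict[int, int]]:
    """Remove the signal peptide before ``cleavage_site`` (0-based count of
    residues removed) and return the trimmed sequence with an old->new
    1-based index mapping."""
    if not 0 <= cleavage_site <= len(sequence):
        raise ValueError(
            f"cleavage site {cleavage_site} outside sequence of length {len(sequence)}"
        )
    trimmed = sequence[cleavage_site:]
    mapping = {old: old - cleavage_site
               for old in range(cleavage_site + 1, len(sequence) + 1)}
    return trimmed, mapping
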