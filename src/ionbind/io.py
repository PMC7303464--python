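"""Domain types and file I/O.

Three plain-text inputs drive the pipeline:

* protein chains as FASTA;
* per-residue binding annotations as a tab-separated table
  (chain_id, residue_index, ligand_id) with 1-based residue indices;
* per-residue predicted structural tracks as a tab-separated table
  (chain_id, residue_index, ss, rsa, phi, psi), where ss is one of
  H/E/C, rsa is a relative solvent accessibility in [0, 1] and phi/psi
  are backbone dihedral angles in degrees.

Residue indices are 1-based at every file interface and converted to
0-based exactly once, inside this module.  On ingest, RSA is clamped
into [0, 1] and dihedral angles are wrapped into [-180, 180] so the
downstream discretization functions have closed domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AMINO_ACIDS, SS_SYMBOLS

logger = logging.getLogger("ionbind")

_STANDARD = set(AMINO_ACIDS)

#: Fallback substitutions for the "map" non-standard-residue policy:
#: ambiguity codes go to their most common resolution, rare residues to
#: their structural analogue.
NONSTANDARD_SUBSTITUTIONS = {
    "B": "N",
    "Z": "Q",
    "J": "L",
    "U": "C",
    "O": "K",
    "X": "A",
}


@dataclass
class StructuralTracks:
    """Per-residue predicted structure: ss (H/E/C), rsa, phi, psi."""

    ss: str
    rsa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.ss)
        if not (self.rsa.size == self.phi.size == self.psi.size == n):
            raise ValueError("structural tracks have unequal lengths")
        bad = set(self.ss) - set(SS_SYMBOLS)
        if bad:
            raise ValueError(f"secondary-structure symbols outside H/E/C: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ss)


@dataclass
class ProteinChain:
    """A protein chain: sequence over the 20 standard amino acids, plus
    optional structural tracks and per-ligand binding masks."""

    chain_id: str
    sequence: str
    tracks: StructuralTracks | None = None
    binding_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: non-standard residues {sorted(bad)} "
                "(padding 'X' is introduced only by segmentation)"
            )
        if self.tracks is not None and len(self.tracks) != self.length:
            raise ValueError(
                f"chain {self.chain_id!r}: tracks length {len(self.tracks)} "
                f"!= sequence length {self.length}"
            )
        for ligand, mask in self.binding_masks.items():
            if np.asarray(mask).size != self.length:
                raise ValueError(
                    f"chain {self.chain_id!r}: binding mask for {ligand!r} has "
                    f"wrong length"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BindingAnnotation:
    """Binding records for one ligand: a set of (chain_id, residue_index),
    residue indices 1-based."""

    ligand_id: str
    records: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chain_id, idx in self.records:
            if idx < 1:
                raise ValueError(
                    f"annotation for {self.ligand_id!r}: residue index {idx} on "
                    f"chain {chain_id!r} violates the 1-based convention"
                )

    def mask_for(self, chain: ProteinChain) -> np.ndarray:
        """Boolean binding mask over the chain's residues (0-based array)."""
        mask = np.zeros(chain.length, dtype=bool)
        for chain_id, idx in self.records:
            if chain_id == chain.chain_id:
                if idx > chain.length:
                    raise ValueError(
                        f"annotation for {self.ligand_id!r}: residue index {idx} "
                        f"exceeds length {chain.length} of chain {chain_id!r}"
                    )
                mask[idx - 1] = True
        return mask

    def validate_against(self, chains: Iterable[ProteinChain]) -> None:
        lengths = {c.chain_id: c.length for c in chains}
        for chain_id, idx in self.records:
            if chain_id not in lengths:
                raise ValueError(
                    f"annotation for {self.ligand_id!r}: unknown chain {chain_id!r}"
                )
            if idx > lengths[chain_id]:
                raise ValueError(
                    f"annotation for {self.ligand_id!r}: residue index {idx} "
                    f"exceeds length {lengths[chain_id]} of chain {chain_id!r}"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(
    path: str | Path,
    nonstandard: Literal["drop", "map"] = "drop",
) -> list[ProteinChain]:
    """Read protein chains from FASTA, in file order.

    Records containing residues outside the 20 standard letters are, under
    the default ``drop`` policy, excluded with a warning; under ``map``
    they are rewritten with :data:`NONSTANDARD_SUBSTITUTIONS` ('*' stop
    symbols are removed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chains: list[ProteinChain] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _STANDARD
        if bad:
            if nonstandard == "drop":
                logger.warning(
                    "dropping chain %r: non-standard residues %s", record.id, sorted(bad)
                )
                continue
            seq = seq.replace("*", "")
            seq = "".join(NONSTANDARD_SUBSTITUTIONS.get(c, c) for c in seq)
            leftover = set(seq) - _STANDARD
            if leftover:
                logger.warning(
                    "dropping chain %r: unmappable symbols %s", record.id, sorted(leftover)
                )
                continue
            if not seq:
                logger.warning("dropping chain %r: empty after mapping", record.id)
                continue
        chains.append(ProteinChain(chain_id=record.id, sequence=seq))
    if not chains:
        logger.warning("no usable chains read from %s", path)
    return chains


def write_fasta(chains: Iterable[ProteinChain], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Delimited tables (header line starts with '#')

def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=columns, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    # drop comment/header lines
    df = df[~df[columns[0]].astype(str).str.startswith("#")].reset_index(drop=True)
    return df


def read_annotations(
    path: str | Path,
    ligand_id: str,
    chains: Iterable[ProteinChain] | None = None,
) -> BindingAnnotation:
    """Read the binding table and keep rows for ``ligand_id``.

    Duplicate rows collapse; indices are validated as 1-based, and against
    chain lengths when ``chains`` is supplied.
    """
    df = _read_table(path, ["chain_id", "residue_index", "ligand_id"])
    if df.empty:
        logger.warning("annotation table %s is empty", path)
        return BindingAnnotation(ligand_id=ligand_id, records=set())
    df = df[df["ligand_id"] == ligand_id]
    records = {
        (str(row.chain_id), int(row.residue_index)) for row in df.itertuples()
    }
    ann = BindingAnnotation(ligand_id=ligand_id, records=records)
    if chains is not None:
        ann.validate_against(chains)
    return ann


def write_annotations(annotation: BindingAnnotation, path: str | Path) -> None:
    rows = sorted(annotation.records)
    df = pd.DataFrame(
        {
            "chain_id": [r[0] for r in rows],
            "residue_index": [r[1] for r in rows],
            "ligand_id": annotation.ligand_id,
        },
        columns=["chain_id", "residue_index", "ligand_id"],
    )
    _write_table(df, path)


def wrap_degrees(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-180, 180] (the +180 representative maps to -180)."""
    return ((np.asarray(x, dtype=float) + 180.0) % 360.0) - 180.0


def read_structural_tracks(
    path: str | Path,
    chains: Iterable[ProteinChain] | None = None,
) -> dict[str, StructuralTracks]:
    """Read per-residue track rows and assemble per-chain tracks.

    Rows of a chain must cover residue indices 1..n with no gaps.  RSA is
    clamped into [0, 1] (with a warning) and phi/psi wrapped into
    [-180, 180].  If ``chains`` is given, track lengths are checked
    against chain lengths.
    """
    df = _read_table(path, ["chain_id", "residue_index", "ss", "rsa", "phi", "psi"])
    result: dict[str, StructuralTracks] = {}
    if df.empty:
        logger.warning("track table %s is empty", path)
        return result
    df["residue_index"] = df["residue_index"].astype(int)
    for chain_id, grp in df.groupby("chain_id", sort=False):
        grp = grp.sort_values("residue_index")
        idx = grp["residue_index"].to_numpy()
        n = idx.size
        if idx[0] != 1 or not np.array_equal(idx, np.arange(1, n + 1)):
            raise ValueError(
                f"track table: chain {chain_id!r} has gaps or does not start at "
                "residue 1"
            )
        rsa = grp["rsa"].astype(float).to_numpy()
        if (rsa < 0).any() or (rsa > 1).any():
            logger.warning(
                "chain %r: %d RSA values outside [0,1] clamped", chain_id,
                int(((rsa < 0) | (rsa > 1)).sum()),
            )
            rsa = np.clip(rsa, 0.0, 1.0)
        phi = wrap_degrees(grp["phi"].astype(float).to_numpy())
        psi = wrap_degrees(grp["psi"].astype(float).to_numpy())
        result[str(chain_id)] = StructuralTracks(
            ss="".join(grp["ss"]), rsa=rsa, phi=phi, psi=psi
        )
    if chains is not None:
        for chain in chains:
            tracks = result.get(chain.chain_id)
            if tracks is not None and len(tracks) != chain.length:
                raise ValueError(
                    f"chain {chain.chain_id!r}: {len(tracks)} track rows but "
                    f"{chain.length} residues"
                )
    return result


def write_structural_tracks(
    tracks: Mapping[str, StructuralTracks], path: str | Path
) -> None:
    rows = []
    for chain_id, t in tracks.items():
        for i in range(len(t)):
            rows.append(
                (chain_id, i + 1, t.ss[i], f"{t.rsa[i]:.4f}",
                 f"{t.phi[i]:.1f}", f"{t.psi[i]:.1f}")
            )
    df = pd.DataFrame(rows, columns=["chain_id", "residue_index", "ss", "rsa", "phi", "psi"])
    _write_table(df, path)


def attach_tracks(
    chains: Iterable[ProteinChain], tracks: Mapping[str, StructuralTracks]
) -> list[ProteinChain]:
    """Return chains with their tracks attached; missing tracks are an error."""
    out = []
    for chain in chains:
        if chain.chain_id not in tracks:
            raise ValueError(f"no structural tracks for chain {chain.chain_id!r}")
        chain.tracks = tracks[chain.chain_id]
        if len(chain.tracks) != chain.length:
            raise ValueError(
                f"chain {chain.chain_id!r}: track length {len(chain.tracks)} != "
                f"sequence length {chain.length}"
            )
        out.append(chain)
    return out
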