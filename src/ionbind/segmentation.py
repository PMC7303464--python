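"""Sliding-window segmentation with virtual-residue padding.

Each residue of a chain becomes the center of exactly one length-L
window (L odd).  To make terminal residues eligible centers, (L-1)/2
virtual residues 'X' are appended at both termini; the padding symbol
propagates into every discretized track window.  A segment is positive
when its center residue is annotated as binding the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alphabets import PAD
from .features import DihedralScheme, classify_angles, combine_dihedral_model, rsa_classes
from .io import BindingAnnotation, ProteinChain

#: Shipped default window lengths per ligand, overridable in any call.
DEFAULT_WINDOW_LENGTHS: dict[str, int] = {
    "ZN": 7,
    "FE2": 9,
    "FE3": 9,
    "CU": 13,
    "MN": 7,
    "CO": 11,
    "CA": 9,
    "MG": 9,
    "NA": 9,
    "K": 11,
    "NO2": 13,
    "CO3": 15,
    "SO4": 13,
    "PO4": 13,
}


def default_window(ligand_id: str) -> int:
    try:
        return DEFAULT_WINDOW_LENGTHS[ligand_id.upper()]
    except KeyError:
        raise KeyError(
            f"no default window length for ligand {ligand_id!r}; pass one explicitly"
        ) from None


def _check_window(L: int) -> int:
    if not isinstance(L, int) or L < 3 or L % 2 == 0:
        raise ValueError(f"window length must be an odd integer >= 3, got {L!r}")
    return L


def pad_chain(sequence: str, L: int) -> str:
    """Append (L-1)/2 padding symbols at both termini."""
    _check_window(L)
    pad = PAD * ((L - 1) // 2)
    return pad + sequence + pad


@dataclass
class SequenceSegment:
    """A length-L window centered on one residue.

    ``center_index`` is 1-based on the source chain.  Track windows are
    class-symbol strings aligned with ``residues``; padding positions
    carry 'X' in every track.  Tracks are ``None`` for chains without
    structural information.
    """

    residues: str
    center_index: int
    label: bool
    source_chain: str
    ss: str | None = None
    rsa_cls: str | None = None
    phi_cls: str | None = None
    psi_cls: str | None = None

    @property
    def L(self) -> int:
        return len(self.residues)

    @property
    def center(self) -> str:
        return self.residues[(self.L - 1) // 2]


def segment_chain(
    chain: ProteinChain,
    annotation: BindingAnnotation | None,
    L: int,
    phi_scheme: DihedralScheme | None = None,
    psi_scheme: DihedralScheme | None = None,
    require_tracks: bool = False,
) -> list[SequenceSegment]:
    """Cut a chain into one labeled segment per residue.

    Structural-track windows are discretized here (RSA into I/J/M/N,
    dihedrals under the given schemes, default model 1) so downstream
    feature code sees only symbol strings.
    """
    _check_window(L)
    if require_tracks and chain.tracks is None:
        raise ValueError(f"chain {chain.chain_id!r} has no structural tracks")
    half = (L - 1) // 2
    padded = pad_chain(chain.sequence, L)
    mask = annotation.mask_for(chain) if annotation is not None else None

    ss_p = rsa_p = phi_p = psi_p = None
    if chain.tracks is not None:
        if phi_scheme is None or psi_scheme is None:
            default_phi, default_psi = combine_dihedral_model(1)
            phi_scheme = phi_scheme or default_phi
            psi_scheme = psi_scheme or default_psi
        pad = PAD * half
        ss_p = pad + chain.tracks.ss + pad
        rsa_p = pad + rsa_classes(chain.tracks.rsa) + pad
        phi_p = pad + classify_angles(chain.tracks.phi, phi_scheme) + pad
        psi_p = pad + classify_angles(chain.tracks.psi, psi_scheme) + pad

    segments = []
    for i in range(chain.length):
        window = slice(i, i + L)
        segments.append(
            SequenceSegment(
                residues=padded[window],
                center_index=i + 1,
                label=bool(mask[i]) if mask is not None else False,
                source_chain=chain.chain_id,
                ss=ss_p[window] if ss_p is not None else None,
                rsa_cls=rsa_p[window] if rsa_p is not None else None,
                phi_cls=phi_p[window] if phi_p is not None else None,
                psi_cls=psi_p[window] if psi_p is not None else None,
            )
        )
    return segments


def segment_chains(
    chains: Iterable[ProteinChain],
    annotation: BindingAnnotation | None,
    L: int,
    phi_scheme: DihedralScheme | None = None,
    psi_scheme: DihedralScheme | None = None,
    require_tracks: bool = False,
) -> list[SequenceSegment]:
    out: list[SequenceSegment] = []
    for chain in chains:
        out.extend(
            segment_chain(chain, annotation, L, phi_scheme, psi_scheme, require_tracks)
        )
    return out


def write_segments(segments: Sequence[SequenceSegment], path: str | Path) -> None:
    """Serialize segments to a tab-separated table for inspection."""
    cols = ["chain_id", "center_index", "label", "residues", "ss", "rsa", "phi", "psi"]
    rows = [
        (s.source_chain, s.center_index, int(s.label), s.residues,
         s.ss or "", s.rsa_cls or "", s.phi_cls or "", s.psi_cls or "")
        for s in segments
    ]
    df = pd.DataFrame(rows, columns=cols)
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
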