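"""Synthetic chains, annotations and structural tracks with plantable signal.

The generator emulates the statistical structure of an ion-ligand
dataset at desk scale: random chains whose binding residues (planted
independently per residue) are enriched for a coordinating residue set
(default C/H/D/E, the classic metal-chelating side chains), prefer
coil, intermediate-to-exposed RSA, and the phi region [-180, -75)
(psi region [135, 180]) that the dihedral reclassification separates.
Track-signal strengths are the probability mass moved from the shared
background distribution to the class-specific one, so 0 is an exact
null and values near 1 give nearly separable classes.

Angle sampling uses mixtures of uniform distributions over the
discretization intervals (not von Mises), so planted class boundaries
align exactly with the dihedral bins and recovery tests are clean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .io import (
    BindingAnnotation,
    ProteinChain,
    StructuralTracks,
    write_annotations,
    write_fasta,
    write_structural_tracks,
)
from .alphabets import AMINO_ACIDS


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give ~9,000 residues over 100 chains with a 10% binding
    rate, i.e. balanced training sets of roughly 1,800 segments.
    """

    n_chains: int = 100
    length_range: tuple[int, int] = (60, 120)
    binding_rate: float = 0.1
    enriched_residues: str = "CHDE"
    enrichment_strength: float = 8.0
    dihedral_signal: float = 0.8
    rsa_signal: float = 0.6
    ss_signal: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.binding_rate < 0.5:
            raise ValueError("binding_rate must be in (0, 0.5)")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid chain length range")
        if self.enrichment_strength <= 0:
            raise ValueError("enrichment_strength must be positive")
        if self.enrichment_strength != 1 and not self.enriched_residues:
            raise ValueError("enrichment requested but enriched residue set is empty")
        for name in ("dihedral_signal", "rsa_signal", "ss_signal"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def null(self) -> "SimulationConfig":
        """The matching no-signal configuration (same sizes and seed)."""
        return replace(
            self, enrichment_strength=1.0,
            dihedral_signal=0.0, rsa_signal=0.0, ss_signal=0.0,
        )


_SS = np.array(list("HEC"))


def _sample_angles(
    rng: np.random.Generator,
    n: int,
    signal: float,
    interval: tuple[float, float],
) -> np.ndarray:
    """Mixture: with prob ``signal`` uniform on ``interval``, else uniform
    on [-180, 180]; rounded to one decimal like predicted angles."""
    lo, hi = interval
    use_signal = rng.random(n) < signal
    angles = rng.uniform(-180.0, 180.0, size=n)
    angles[use_signal] = rng.uniform(lo, hi, size=int(use_signal.sum()))
    return np.round(angles, 1)


def _sample_rsa(rng: np.random.Generator, n: int, signal: float, binder: bool) -> np.ndarray:
    use_signal = rng.random(n) < signal
    rsa = rng.uniform(0.0, 1.0, size=n)
    k = int(use_signal.sum())
    if binder:
        rsa[use_signal] = rng.uniform(0.45, 0.85, size=k)
    else:
        rsa[use_signal] = rng.uniform(0.0, 0.45, size=k)
    return np.round(rsa, 4)


def _sample_ss(rng: np.random.Generator, n: int, signal: float, binder: bool) -> np.ndarray:
    use_signal = rng.random(n) < signal
    ss = _SS[rng.integers(0, 3, size=n)]
    k = int(use_signal.sum())
    if binder:
        ss[use_signal] = "C"
    else:
        ss[use_signal] = _SS[rng.integers(0, 2, size=k)]  # H or E
    return ss


def generate(
    config: SimulationConfig, ligand_id: str = "SIM"
) -> tuple[list[ProteinChain], BindingAnnotation]:
    """Draw a dataset of chains with tracks plus its binding annotation."""
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    weights = np.ones(len(aa))
    for r in config.enriched_residues:
        weights[AMINO_ACIDS.index(r)] *= config.enrichment_strength
    p_binder = weights / weights.sum()
    p_background = np.full(len(aa), 1.0 / len(aa))

    chains: list[ProteinChain] = []
    records: set[tuple[str, int]] = set()
    lo, hi = config.length_range
    for c in range(config.n_chains):
        chain_id = f"synth_{c + 1:04d}"
        n = int(rng.integers(lo, hi + 1))
        mask = rng.random(n) < config.binding_rate
        residues = aa[rng.choice(len(aa), size=n, p=p_background)]
        k = int(mask.sum())
        if k:
            residues[mask] = aa[rng.choice(len(aa), size=k, p=p_binder)]
            records.update((chain_id, int(i) + 1) for i in np.flatnonzero(mask))

        ss = np.empty(n, dtype="<U1")
        rsa = np.empty(n)
        phi = np.empty(n)
        psi = np.empty(n)
        for binder, idx in ((True, np.flatnonzero(mask)), (False, np.flatnonzero(~mask))):
            m = idx.size
            if m == 0:
                continue
            ss[idx] = _sample_ss(rng, m, config.ss_signal, binder)
            rsa[idx] = _sample_rsa(rng, m, config.rsa_signal, binder)
            phi_iv = (-180.0, -75.0) if binder else (-75.0, 180.0)
            psi_iv = (135.0, 180.0) if binder else (15.0, 135.0)
            phi[idx] = _sample_angles(rng, m, config.dihedral_signal, phi_iv)
            psi[idx] = _sample_angles(rng, m, config.dihedral_signal, psi_iv)

        tracks = StructuralTracks(ss="".join(ss), rsa=rsa, phi=phi, psi=psi)
        chains.append(
            ProteinChain(
                chain_id=chain_id,
                sequence="".join(residues),
                tracks=tracks,
                binding_masks={ligand_id: mask},
            )
        )
    return chains, BindingAnnotation(ligand_id=ligand_id, records=records)


def write_fixture(
    chains: list[ProteinChain],
    annotation: BindingAnnotation,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit the three standard input files into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "chains.fasta",
        "annotations": out_dir / "annotations.tsv",
        "tracks": out_dir / "tracks.tsv",
    }
    write_fasta(chains, paths["fasta"])
    write_annotations(annotation, paths["annotations"])
    write_structural_tracks(
        {c.chain_id: c.tracks for c in chains if c.tracks is not None},
        paths["tracks"],
    )
    return paths
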