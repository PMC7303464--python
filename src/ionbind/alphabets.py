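"""Residue class alphabets.

Every feature track (amino acids, secondary structure, RSA classes,
dihedral classes, physicochemical classes) is a string over a small
alphabet that always contains the virtual padding residue 'X' as its own
category.  A :class:`ClassAlphabet` maps track symbols to class symbols
and assigns each class a stable integer code used by the vectorised
feature code.

The two physicochemical groupings (polarization charge, q=4 including
'X'; hydropathy, q=7 including 'X') are configuration, not code: they
ship as editable tab-separated tables under ``ionbind/data/`` and can be
replaced with :func:`load_class_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

PAD = "X"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SS_SYMBOLS = "HEC"
RSA_SYMBOLS = "IJMN"


@dataclass(frozen=True)
class ClassAlphabet:
    """A total mapping from track symbols to q class symbols.

    ``classes`` fixes the ordering used for integer encoding; ``q`` is
    the number of distinct classes, counting the padding class 'X'.
    """

    name: str
    mapping: Mapping[str, str]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.classes:
            seen: list[str] = []
            for cls in self.mapping.values():
                if cls not in seen:
                    seen.append(cls)
            object.__setattr__(self, "classes", tuple(seen))
        image = set(self.mapping.values())
        if image != set(self.classes):
            raise ValueError(
                f"alphabet {self.name!r}: classes {self.classes} do not match "
                f"the image of the mapping {sorted(image)}"
            )
        object.__setattr__(
            self, "_codes", {s: self.classes.index(c) for s, c in self.mapping.items()}
        )

    @property
    def q(self) -> int:
        return len(self.classes)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def encode(self, s: str) -> np.ndarray:
        """Integer class codes for every symbol of ``s``."""
        codes = self._codes
        try:
            return np.fromiter((codes[c] for c in s), dtype=np.intp, count=len(s))
        except KeyError as exc:
            raise ValueError(
                f"symbol {exc.args[0]!r} is not in alphabet {self.name!r}"
            ) from None

    def encode_many(self, strings: Iterable[str]) -> np.ndarray:
        """(n, L) code matrix for equal-length strings."""
        rows = [self.encode(s) for s in strings]
        if not rows:
            raise ValueError("no strings to encode")
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"strings have unequal lengths {sorted(lengths)}")
        return np.vstack(rows)


def identity_alphabet(name: str, symbols: str, pad: bool = True) -> ClassAlphabet:
    syms = symbols + (PAD if pad and PAD not in symbols else "")
    return ClassAlphabet(name, {s: s for s in syms})


AA_ALPHABET = identity_alphabet("amino_acid", AMINO_ACIDS)  # q = 21
SS_ALPHABET = identity_alphabet("secondary_structure", SS_SYMBOLS)  # q = 4
RSA_ALPHABET = identity_alphabet("rsa_class", RSA_SYMBOLS)  # q = 5


def load_class_table(path: str | Path, name: str | None = None) -> ClassAlphabet:
    """Read a residue→class table (two tab-separated columns, '#' comments).

    The padding residue 'X' is appended as its own class if the table
    does not list it, so user tables need only cover the 20 amino acids.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 'residue<TAB>class', got {line!r}")
        residue, cls = parts[0].strip(), parts[1].strip()
        if residue in mapping:
            raise ValueError(f"{path}: residue {residue!r} listed twice")
        mapping[residue] = cls
    missing = set(AMINO_ACIDS) - set(mapping)
    if missing:
        raise ValueError(f"{path}: no class for residues {sorted(missing)}")
    mapping.setdefault(PAD, PAD)
    return ClassAlphabet(name or path.stem, mapping)


def _default_table(filename: str, name: str) -> ClassAlphabet:
    ref = resources.files("ionbind.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_class_table(path, name)


# Polarization charge: positive / negative / uncharged / 'X'  (q = 4).
CHARGE_ALPHABET = _default_table("charge.tsv", "charge")

# Hydropathy: P, G, C singletons, hydrophobic, polar-uncharged, charged,
# plus 'X'  (q = 7).
HYDROPATHY_ALPHABET = _default_table("hydropathy.tsv", "hydropathy")
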