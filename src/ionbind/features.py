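"""Feature extraction.

The per-segment feature vector concatenates, for each track (amino
acids, secondary structure, RSA class, phi class, psi class):

* a composition block — relative class frequencies over the window, q
  values summing to 1;
* a 2L-dimensional position-conservation block — the segment scored
  against a position weight matrix (PWM) built from the positive
  training segments (L values) followed by the score against the
  negative-segment PWM (L values);

plus two scalar information-entropy features over the polarization
charge (q=4) and hydropathy (q=7) class alphabets.

PWM elements are pseudocounted natural-log odds

    m[i][j] = ln(p[i][j] / p0[j]),   p[i][j] = (n[i][j] + N_i/q) / (2 N_i)

where n[i][j] counts class j at window position i, N_i is the number of
training segments and q the alphabet size.  The background p0 uses the
same pseudocount form pooled over all positions of all training
segments (positive and negative together), which keeps every ratio
finite.  Entropy uses the same pseudocount:

    H = -sum_j p_j log2 p_j,   p_j = (n_j + N/q) / (2N)

so 0 < H <= log2 q, with equality exactly at uniform class counts.

RSA is discretized into four buried-to-exposed classes I/J/M/N with
right-closed boundaries 0.2 / 0.45 / 0.6 / 0.85 (values above 0.85
clamp to N).  Dihedral angles are discretized by interval schemes:
phi by g (2 classes) or f (4 classes), psi by h or p (3 classes each);
the four phi x psi combinations form dihedral models 1-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabets import (
    AA_ALPHABET,
    CHARGE_ALPHABET,
    HYDROPATHY_ALPHABET,
    PAD,
    RSA_ALPHABET,
    SS_ALPHABET,
    ClassAlphabet,
    identity_alphabet,
)

__all__ = [
    "PositionWeightMatrix",
    "build_pwm",
    "pseudocount_background",
    "score_positional",
    "composition",
    "rsa_class",
    "rsa_classes",
    "DihedralScheme",
    "classify_angle",
    "classify_angles",
    "angle_distribution",
    "segment_entropy",
    "combine_dihedral_model",
    "PHI_SCHEMES",
    "PSI_SCHEMES",
    "DIHEDRAL_MODELS",
    "FeatureVector",
    "FeatureExtractor",
    "ClassAlphabet",
]


# ---------------------------------------------------------------------------
# Position weight matrices

@dataclass
class PositionWeightMatrix:
    """L x q natural-log-odds matrix with its audit counts."""

    alphabet: ClassAlphabet
    counts: np.ndarray          # (L, q) integer class counts per position
    totals: np.ndarray          # (L,) segments counted per position
    probabilities: np.ndarray   # (L, q) pseudocounted p[i][j]
    background: np.ndarray      # (q,) pseudocounted background p0[j]
    m: np.ndarray               # (L, q) log-odds

    @property
    def L(self) -> int:
        return self.m.shape[0]

    def score(self, segment: str) -> np.ndarray:
        """Per-position log-odds of ``segment`` under this matrix."""
        codes = self.alphabet.encode(segment)
        if codes.size != self.L:
            raise ValueError(f"segment length {codes.size} != matrix length {self.L}")
        return self.m[np.arange(self.L), codes]

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised scoring of an (n, L) code matrix -> (n, L) scores."""
        if codes.shape[1] != self.L:
            raise ValueError("code matrix width does not match matrix length")
        return self.m[np.arange(self.L)[None, :], codes]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#alphabet={self.alphabet.name}\tL={self.L}\n")
            fh.write("#background\t" + "\t".join(f"{b:.10g}" for b in self.background) + "\n")
            fh.write("#position\t" + "\t".join(self.alphabet.classes) + "\n")
            for i in range(self.L):
                fh.write(
                    f"{i + 1}\t" + "\t".join(f"{v:.10g}" for v in self.m[i]) + "\n"
                )


def _count_codes(codes: np.ndarray, q: int) -> np.ndarray:
    """(L, q) per-position class counts from an (n, L) code matrix."""
    n, L = codes.shape
    counts = np.zeros((L, q), dtype=np.int64)
    for i in range(L):
        counts[i] = np.bincount(codes[:, i], minlength=q)
    return counts


def pseudocount_background(
    segments: Sequence[str], alphabet: ClassAlphabet
) -> np.ndarray:
    """Pooled pseudocounted class probabilities p0[j] = (n_j + N/q) / (2N)."""
    codes = alphabet.encode_many(segments)
    n_j = np.bincount(codes.ravel(), minlength=alphabet.q).astype(float)
    N = codes.size
    return (n_j + N / alphabet.q) / (2.0 * N)


def build_pwm(
    segments: Sequence[str],
    alphabet: ClassAlphabet,
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Build a pseudocounted log-odds matrix from equal-length segments.

    If ``background`` is omitted it is computed from ``segments``
    themselves; pipelines pass the background pooled over positive and
    negative training segments so both matrices share one reference.
    """
    if len(segments) == 0:
        raise ValueError("cannot build a position weight matrix from zero segments")
    codes = alphabet.encode_many(segments)
    n, L = codes.shape
    q = alphabet.q
    counts = _count_codes(codes, q)
    totals = np.full(L, n, dtype=np.int64)
    p = (counts + n / q) / (2.0 * n)
    if background is None:
        background = pseudocount_background(segments, alphabet)
    background = np.asarray(background, dtype=float)
    if background.shape != (q,):
        raise ValueError(f"background must have shape ({q},)")
    if (background <= 0).any():
        raise ValueError("background probabilities must be positive")
    m = np.log(p / background[None, :])
    return PositionWeightMatrix(
        alphabet=alphabet, counts=counts, totals=totals,
        probabilities=p, background=background, m=m,
    )


def score_positional(
    segment: str,
    pwm_pos: PositionWeightMatrix,
    pwm_neg: PositionWeightMatrix,
) -> np.ndarray:
    """2L position-conservation scores: positive-matrix block then negative."""
    return np.concatenate([pwm_pos.score(segment), pwm_neg.score(segment)])


# ---------------------------------------------------------------------------
# Composition and entropy

def composition(segment: str, alphabet: ClassAlphabet) -> np.ndarray:
    """Relative class frequencies over the window (length-q, sums to 1)."""
    codes = alphabet.encode(segment)
    if codes.size == 0:
        raise ValueError("empty segment")
    return np.bincount(codes, minlength=alphabet.q) / codes.size


def segment_entropy(segment: str, alphabet: ClassAlphabet) -> float:
    """Pseudocounted Shannon entropy of the segment's class composition.

    Counts run over all q classes of the alphabet, the padding class
    included; N is the full window length.
    """
    codes = alphabet.encode(segment)
    N = codes.size
    if N == 0:
        raise ValueError("empty segment")
    n_j = np.bincount(codes, minlength=alphabet.q)
    p = (n_j + N / alphabet.q) / (2.0 * N)
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# RSA discretization (four classes, right-closed boundaries)

_RSA_CUTS = np.array([0.2, 0.45, 0.6, 0.85])
_RSA_LABELS = "IJMN"


def rsa_classes(rsa: np.ndarray) -> str:
    """Vectorised four-class RSA discretization.

    I on [0, 0.2], J on (0.2, 0.45], M on (0.45, 0.6], N on (0.6, 1]
    (values above 0.85 clamp into N).
    """
    x = np.asarray(rsa, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("RSA values outside [0, 1]; clamp on ingest first")
    idx = np.minimum(np.searchsorted(_RSA_CUTS, x, side="left"), 3)
    return "".join(_RSA_LABELS[i] for i in idx)


def rsa_class(rsa: float) -> str:
    """Four-class RSA symbol for a single value."""
    return rsa_classes(np.array([rsa]))


# ---------------------------------------------------------------------------
# Dihedral reclassification

@dataclass(frozen=True)
class DihedralScheme:
    """Piecewise-constant classification of an angle in [-180, 180].

    ``cuts`` are the interior boundaries; intervals are left-closed and
    right-open, the last interval closed at +180, so every boundary
    value belongs to the interval on its right.
    """

    name: str
    cuts: tuple[float, ...]
    labels: str

    def __post_init__(self) -> None:
        c = np.asarray(self.cuts, dtype=float)
        if (np.diff(c) <= 0).any() or (c <= -180).any() or (c >= 180).any():
            raise ValueError("cuts must be strictly increasing inside (-180, 180)")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one label per interval")

    @property
    def alphabet(self) -> ClassAlphabet:
        return identity_alphabet(f"dihedral_{self.name}", self.labels)

    def classify(self, angles: np.ndarray) -> np.ndarray:
        x = np.asarray(angles, dtype=float)
        if (x < -180).any() or (x > 180).any():
            raise ValueError("angles outside [-180, 180]; wrap on ingest first")
        return np.searchsorted(np.asarray(self.cuts), x, side="right")


#: phi scheme g: A on [-180, -75), B on [-75, 180]
#: phi scheme f: A [-180,-105), B [-105,-75), C [-75,-60), D [-60,180]
PHI_SCHEMES: Mapping[str, DihedralScheme] = {
    "g": DihedralScheme("g", (-75.0,), "AB"),
    "f": DihedralScheme("f", (-105.0, -75.0, -60.0), "ABCD"),
}

#: psi scheme h: A [-180,15), B [15,135), C [135,180]
#: psi scheme p: A [-180,-15), B [-15,75), C [75,180]
PSI_SCHEMES: Mapping[str, DihedralScheme] = {
    "h": DihedralScheme("h", (15.0, 135.0), "ABC"),
    "p": DihedralScheme("p", (-15.0, 75.0), "ABC"),
}

#: Default mapping of the four dihedral combination models to
#: (phi scheme, psi scheme); configurable in combine_dihedral_model.
DIHEDRAL_MODELS: Mapping[int, tuple[str, str]] = {
    1: ("g", "h"),
    2: ("g", "p"),
    3: ("f", "h"),
    4: ("f", "p"),
}


def classify_angle(angle: float, scheme: DihedralScheme) -> str:
    """Class label of an angle (degrees in [-180, 180]) under a scheme."""
    return scheme.labels[int(scheme.classify(np.array([angle]))[0])]


def classify_angles(angles: np.ndarray, scheme: DihedralScheme) -> str:
    idx = scheme.classify(angles)
    return "".join(scheme.labels[i] for i in idx)


def combine_dihedral_model(
    model_id: int,
    mapping: Mapping[int, tuple[str, str]] | None = None,
) -> tuple[DihedralScheme, DihedralScheme]:
    """Resolve a combination-model id to its (phi, psi) scheme pair."""
    mapping = DIHEDRAL_MODELS if mapping is None else mapping
    if model_id not in mapping:
        raise ValueError(f"unknown dihedral model {model_id!r}; choose from {sorted(mapping)}")
    phi_name, psi_name = mapping[model_id]
    return PHI_SCHEMES[phi_name], PSI_SCHEMES[psi_name]


def angle_distribution(angles: Sequence[float], bin_width: float = 15.0) -> np.ndarray:
    """Percentage of angles per bin over [-180, 180].

    Bins are [-180,-165), ..., [165,180] for the default 15-degree width
    (24 bins); the result sums to 100.
    """
    x = np.asarray(angles, dtype=float)
    if x.size == 0:
        raise ValueError("no angles supplied")
    if 360.0 % bin_width:
        raise ValueError("bin width must divide 360")
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    hist, _ = np.histogram(x, bins=edges)
    return hist / x.size * 100.0


# ---------------------------------------------------------------------------
# Feature assembly

@dataclass
class FeatureVector:
    values: np.ndarray
    schema: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.values.size != sum(d for _, d in self.schema):
            raise ValueError("feature vector length does not match its schema")


_TRACKS = ("aa", "ss", "rsa", "phi", "psi")


class FeatureExtractor:
    """Fits track PWMs on training segments and assembles feature vectors.

    All matrices and backgrounds are training-split statistics: call
    :meth:`fit` with the training segments of a fold, then
    :meth:`transform` on any segments of the same window length.
    """

    def __init__(
        self,
        L: int,
        dihedral_model: int = 1,
        include_dihedral: bool = True,
        charge_alphabet: ClassAlphabet = CHARGE_ALPHABET,
        hydropathy_alphabet: ClassAlphabet = HYDROPATHY_ALPHABET,
        model_mapping: Mapping[int, tuple[str, str]] | None = None,
    ) -> None:
        if L < 3 or L % 2 == 0:
            raise ValueError("window length must be an odd integer >= 3")
        self.L = L
        self.dihedral_model = dihedral_model
        self.include_dihedral = include_dihedral
        self.charge_alphabet = charge_alphabet
        self.hydropathy_alphabet = hydropathy_alphabet
        phi_scheme, psi_scheme = combine_dihedral_model(dihedral_model, model_mapping)
        self.phi_scheme = phi_scheme
        self.psi_scheme = psi_scheme
        self._alphabets: dict[str, ClassAlphabet] = {
            "aa": AA_ALPHABET,
            "ss": SS_ALPHABET,
            "rsa": RSA_ALPHABET,
            "phi": phi_scheme.alphabet,
            "psi": psi_scheme.alphabet,
        }
        self._pwms: dict[str, tuple[PositionWeightMatrix, PositionWeightMatrix]] = {}
        self.fitted_on: tuple[tuple[str, int], ...] | None = None

    # -- access to track strings ------------------------------------------

    def _tracks_used(self) -> tuple[str, ...]:
        return _TRACKS if self.include_dihedral else _TRACKS[:3]

    @staticmethod
    def _track_string(segment, track: str) -> str:
        value = {
            "aa": segment.residues,
            "ss": segment.ss,
            "rsa": segment.rsa_cls,
            "phi": segment.phi_cls,
            "psi": segment.psi_cls,
        }[track]
        if value is None:
            raise ValueError(
                f"segment at {segment.source_chain}:{segment.center_index} has no "
                f"{track!r} track; structural tracks are required"
            )
        return value

    def _codes(self, segments: Sequence, track: str) -> np.ndarray:
        alphabet = self._alphabets[track]
        strings = [self._track_string(s, track) for s in segments]
        codes = alphabet.encode_many(strings)
        if codes.shape[1] != self.L:
            raise ValueError(
                f"segments have window length {codes.shape[1]}, extractor expects {self.L}"
            )
        return codes

    # -- fitting and transforming -----------------------------------------

    def fit(self, segments: Sequence) -> "FeatureExtractor":
        """Build positive/negative PWMs per track from training segments."""
        pos = [s for s in segments if s.label]
        neg = [s for s in segments if not s.label]
        if not pos or not neg:
            raise ValueError("training segments must contain both classes")
        for track in self._tracks_used():
            alphabet = self._alphabets[track]
            pos_strings = [self._track_string(s, track) for s in pos]
            neg_strings = [self._track_string(s, track) for s in neg]
            background = pseudocount_background(pos_strings + neg_strings, alphabet)
            self._pwms[track] = (
                build_pwm(pos_strings, alphabet, background),
                build_pwm(neg_strings, alphabet, background),
            )
        self.fitted_on = tuple((s.source_chain, s.center_index) for s in segments)
        return self

    @property
    def schema(self) -> tuple[tuple[str, int], ...]:
        blocks: list[tuple[str, int]] = []
        for track in self._tracks_used():
            q = self._alphabets[track].q
            blocks.append((f"{track}_comp", q))
            blocks.append((f"{track}_pwm", 2 * self.L))
        blocks.append(("charge_entropy", 1))
        blocks.append(("hydropathy_entropy", 1))
        return tuple(blocks)

    @property
    def n_features(self) -> int:
        return sum(d for _, d in self.schema)

    def transform(self, segments: Sequence) -> np.ndarray:
        """(n, M) feature matrix in schema order."""
        if not self._pwms:
            raise RuntimeError("extractor is not fitted; call fit() first")
        if len(segments) == 0:
            return np.empty((0, self.n_features))
        blocks: list[np.ndarray] = []
        for track in self._tracks_used():
            alphabet = self._alphabets[track]
            codes = self._codes(segments, track)
            comp = np.stack(
                [np.bincount(row, minlength=alphabet.q) / self.L for row in codes]
            )
            pwm_pos, pwm_neg = self._pwms[track]
            blocks.append(comp)
            blocks.append(pwm_pos.score_codes(codes))
            blocks.append(pwm_neg.score_codes(codes))
        blocks.append(
            np.array(
                [[segment_entropy(s.residues, self.charge_alphabet)] for s in segments]
            )
        )
        blocks.append(
            np.array(
                [[segment_entropy(s.residues, self.hydropathy_alphabet)] for s in segments]
            )
        )
        # interleave pwm_pos/pwm_neg into one 2L block per track
        out: list[np.ndarray] = []
        i = 0
        for track in self._tracks_used():
            comp, sp, sn = blocks[i], blocks[i + 1], blocks[i + 2]
            out.extend([comp, sp, sn])
            i += 3
        out.extend(blocks[i:])
        return np.hstack(out)

    def transform_one(self, segment) -> FeatureVector:
        return FeatureVector(self.transform([segment])[0], self.schema)
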