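import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionbind.alphabets import (
    AA_ALPHABET,
    CHARGE_ALPHABET,
    HYDROPATHY_ALPHABET,
    ClassAlphabet,
    load_class_table,
)
from ionbind.features import (
    DIHEDRAL_MODELS,
    PHI_SCHEMES,
    PSI_SCHEMES,
    FeatureExtractor,
    angle_distribution,
    build_pwm,
    classify_angle,
    combine_dihedral_model,
    composition,
    pseudocount_background,
    rsa_class,
    rsa_classes,
    score_positional,
    segment_entropy,
)
from ionbind.io import BindingAnnotation, ProteinChain, StructuralTracks
from ionbind.segmentation import segment_chains
from ionbind.synthetic import SimulationConfig, generate

TOY = ClassAlphabet("toy", {"A": "A", "B": "B"})


# ---------------------------------------------------------------------------
# Position weight matrices

def test_pwm_hand_example_balanced():
    """Counts (2,2) with q=2 give p=0.5 per class, log-odds 0 vs a flat background."""
    pwm = build_pwm(["A", "A", "B", "B"], TOY, np.array([0.5, 0.5]))
    assert pwm.probabilities[0, 0] == pytest.approx(0.5)
    np.testing.assert_allclose(pwm.m, 0.0, atol=1e-15)


def test_pwm_hand_example_single_class():
    pwm = build_pwm(["A", "A", "A", "A"], TOY, np.array([0.5, 0.5]))
    assert pwm.probabilities[0, 0] == pytest.approx(0.75)  # (4 + 4/2) / 8
    assert pwm.m[0, 0] == pytest.approx(math.log(1.5), abs=1e-9)
    assert pwm.m[0, 1] == pytest.approx(math.log(0.5), abs=1e-9)


def test_pwm_zero_rows_at_background_frequencies():
    # observed frequencies equal to the self-computed background -> ln(1) = 0
    segments = ["AB", "BA"]
    pwm = build_pwm(segments, TOY)
    np.testing.assert_allclose(pwm.m, 0.0, atol=1e-12)


def test_pwm_empty_input_error():
    with pytest.raises(ValueError):
        build_pwm([], TOY)


def _brute_force_pwm(segments, alphabet, background):
    """Independent oracle: explicit symbol counting, pure Python."""
    L, q, N = len(segments[0]), alphabet.q, len(segments)
    m = np.zeros((L, q))
    for i in range(L):
        for j, cls in enumerate(alphabet.classes):
            n_ij = sum(1 for s in segments if alphabet.mapping[s[i]] == cls)
            p_ij = (n_ij + N / q) / (N + N)
            m[i, j] = math.log(p_ij / background[j])
    return m


@pytest.mark.parametrize("trial", range(20))
def test_pwm_matches_brute_force_oracle(trial):
    rng = np.random.default_rng(trial)
    L = int(rng.integers(1, 4))
    q = int(rng.integers(2, 5))
    symbols = "ABCD"[:q]
    alphabet = ClassAlphabet(f"toy{q}", {s: s for s in symbols})
    segments = [
        "".join(rng.choice(list(symbols), size=L))
        for _ in range(int(rng.integers(1, 21)))
    ]
    background = rng.dirichlet(np.ones(q)) + 0.01
    background /= background.sum()
    pwm = build_pwm(segments, alphabet, background)
    np.testing.assert_allclose(pwm.m, _brute_force_pwm(segments, alphabet, background),
                               atol=1e-12)


def test_pwm_row_normalization():
    """Pseudocounted position probabilities sum to 1 at every position."""
    rng = np.random.default_rng(0)
    segments = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWYX"), size=7))
                for _ in range(50)]
    pwm = build_pwm(segments, AA_ALPHABET)
    np.testing.assert_allclose(pwm.probabilities.sum(axis=1), 1.0, atol=1e-12)
    assert (pwm.background > 0).all()


def test_pwm_serialization(tmp_path):
    pwm = build_pwm(["A", "B"], TOY)
    out = tmp_path / "pwm.tsv"
    pwm.write(out)
    text = out.read_text()
    assert text.startswith("#alphabet=toy")
    assert "background" in text


def test_score_positional_dimension_and_symmetry():
    rng = np.random.default_rng(1)
    segments = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=7))
                for _ in range(30)]
    pwm = build_pwm(segments, AA_ALPHABET)
    scores = score_positional(segments[0], pwm, pwm)
    assert scores.shape == (14,)  # 2L for L = 7
    np.testing.assert_array_equal(scores[:7], scores[7:])


def test_score_positional_zero_matrix():
    pwm = build_pwm(["AB", "BA"], TOY)  # log-odds identically 0
    np.testing.assert_allclose(score_positional("AB", pwm, pwm), 0.0, atol=1e-12)


def test_score_rejects_foreign_symbol():
    pwm = build_pwm(["A"], TOY)
    with pytest.raises(ValueError, match="alphabet"):
        pwm.score("Z")


# ---------------------------------------------------------------------------
# Composition

def test_composition_example():
    comp = composition("AAX", AA_ALPHABET)
    assert comp[AA_ALPHABET.classes.index("A")] == pytest.approx(2 / 3)
    assert comp[AA_ALPHABET.classes.index("X")] == pytest.approx(1 / 3)
    assert comp.sum() == pytest.approx(1.0)


def test_composition_order_invariance():
    np.testing.assert_array_equal(
        composition("XAC", AA_ALPHABET), composition("CAX", AA_ALPHABET)
    )


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=20))
def test_composition_normalized(segment):
    assert composition(segment, AA_ALPHABET).sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# RSA and dihedral discretization

@pytest.mark.parametrize(
    "rsa,symbol",
    [(0.1, "I"), (0.3, "J"), (0.5, "M"), (0.7, "N"),
     (0.2, "I"), (0.45, "J"), (0.6, "M"), (0.85, "N"),
     (0.0, "I"), (0.95, "N"), (1.0, "N")],
)
def test_rsa_class(rsa, symbol):
    assert rsa_class(rsa) == symbol


def test_rsa_class_rejects_out_of_range():
    with pytest.raises(ValueError):
        rsa_classes(np.array([1.2]))


@pytest.mark.parametrize(
    "scheme,angle,label",
    [
        ("g", -100.0, "A"), ("g", 0.0, "B"), ("g", -75.0, "B"),
        ("g", -180.0, "A"), ("g", 180.0, "B"),
        ("h", -180.0, "A"), ("h", 60.0, "B"), ("h", 150.0, "C"), ("h", 15.0, "B"),
        ("f", -120.0, "A"), ("f", -90.0, "B"), ("f", -70.0, "C"), ("f", 10.0, "D"),
        ("p", -100.0, "A"), ("p", 0.0, "B"), ("p", 100.0, "C"), ("p", -15.0, "B"),
    ],
)
def test_classify_angle_examples(scheme, angle, label):
    schemes = {**PHI_SCHEMES, **PSI_SCHEMES}
    assert classify_angle(angle, schemes[scheme]) == label


@given(st.floats(min_value=-180, max_value=180, allow_nan=False))
def test_classify_angle_total(angle):
    """Every in-range angle maps to exactly one class under every scheme."""
    for scheme in list(PHI_SCHEMES.values()) + list(PSI_SCHEMES.values()):
        label = classify_angle(angle, scheme)
        assert label in scheme.labels


def test_angle_distribution_bins():
    grid = np.arange(-180.0, 180.0, 15.0) + 7.5  # one angle per 15-degree bin
    dist = angle_distribution(grid)
    assert dist.shape == (24,)
    np.testing.assert_allclose(dist, 100.0 / 24, atol=1e-9)
    assert dist.sum() == pytest.approx(100.0)


def test_angle_distribution_point_mass():
    dist = angle_distribution(np.zeros(10))
    assert dist[12] == pytest.approx(100.0)  # bin [0, 15)
    assert dist.sum() == pytest.approx(100.0)


def test_angle_distribution_errors():
    with pytest.raises(ValueError):
        angle_distribution([])
    with pytest.raises(ValueError):
        angle_distribution([0.0], bin_width=17.0)


# ---------------------------------------------------------------------------
# Entropy

def test_entropy_single_class_hand_value():
    """All residues in one charge class: p = (0.625, 0.125 x3) -> H = 1.548795."""
    for segment in ["KKKK", "DD", "A" * 9]:
        assert segment_entropy(segment, CHARGE_ALPHABET) == pytest.approx(
            1.548795, abs=1e-5
        )


def test_entropy_uniform_counts_is_log2_q():
    # one residue per charge class, padding included: exact maximum
    assert segment_entropy("KDAX", CHARGE_ALPHABET) == pytest.approx(2.0, abs=1e-12)


@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=15))
def test_entropy_bounds(segment):
    for alphabet in (CHARGE_ALPHABET, HYDROPATHY_ALPHABET):
        h = segment_entropy(segment, alphabet)
        assert 0.0 < h <= np.log2(alphabet.q) + 1e-12


def test_charge_and_hydropathy_category_counts():
    assert CHARGE_ALPHABET.q == 4
    assert HYDROPATHY_ALPHABET.q == 7


def test_load_class_table_round_trip(tmp_path):
    table = tmp_path / "charge.tsv"
    lines = [f"{r}\t{CHARGE_ALPHABET.mapping[r]}" for r in "ACDEFGHIKLMNPQRSTVWY"]
    table.write_text("# custom\n" + "\n".join(lines) + "\n")
    alphabet = load_class_table(table)
    assert alphabet.q == 4
    assert alphabet.mapping["X"] == "X"
    bad = tmp_path / "bad.tsv"
    bad.write_text("K\t+\n")
    with pytest.raises(ValueError, match="no class"):
        load_class_table(bad)


# ---------------------------------------------------------------------------
# Dihedral combination models

def test_combine_models_enumerate_product():
    pairs = {combine_dihedral_model(i) for i in (1, 2, 3, 4)}
    names = {(phi.name, psi.name) for phi, psi in pairs}
    assert names == {("g", "h"), ("g", "p"), ("f", "h"), ("f", "p")}


def test_combine_model_default_and_remap():
    phi, psi = combine_dihedral_model(1)
    assert (phi.name, psi.name) == ("g", "h")
    phi, psi = combine_dihedral_model(1, mapping={1: ("f", "p")})
    assert (phi.name, psi.name) == ("f", "p")
    with pytest.raises(ValueError):
        combine_dihedral_model(5)


# ---------------------------------------------------------------------------
# Feature assembly

@pytest.fixture(scope="module")
def fitted_extractor():
    chains, annotation = generate(
        SimulationConfig(n_chains=8, length_range=(30, 50), seed=3)
    )
    segments = segment_chains(chains, annotation, 7, require_tracks=True)
    extractor = FeatureExtractor(L=7, dihedral_model=1)
    extractor.fit(segments)
    return extractor, segments


def test_feature_dimension_l7_model1(fitted_extractor):
    """(21+14) + (4+14) + (5+14) + (3+14) + (4+14) + 1 + 1 = 109."""
    extractor, segments = fitted_extractor
    assert extractor.n_features == 109
    X = extractor.transform(segments[:5])
    assert X.shape == (5, 109)


def test_feature_schema_no_dihedral():
    extractor = FeatureExtractor(L=7, include_dihedral=False)
    names = [n for n, _ in extractor.schema]
    assert not any("phi" in n or "psi" in n for n in names)
    assert extractor.n_features == 109 - (3 + 14) - (4 + 14)


def test_feature_determinism(fitted_extractor):
    extractor, segments = fitted_extractor
    X1 = extractor.transform(segments[:20])
    X2 = extractor.transform(segments[:20])
    np.testing.assert_array_equal(X1, X2)


def test_transform_before_fit_errors():
    with pytest.raises(RuntimeError):
        FeatureExtractor(L=7).transform([])


def test_fit_requires_both_classes(fitted_extractor):
    _, segments = fitted_extractor
    neg = [s for s in segments if not s.label][:10]
    with pytest.raises(ValueError, match="both classes"):
        FeatureExtractor(L=7).fit(neg)


def test_transform_one_matches_schema(fitted_extractor):
    extractor, segments = fitted_extractor
    fv = extractor.transform_one(segments[0])
    assert fv.values.shape == (extractor.n_features,)
    assert fv.schema == extractor.schema
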