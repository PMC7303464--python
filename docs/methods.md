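# Methods

## Problem and model

`ionbind` predicts, per residue of a protein chain, whether the residue
binds a given ion ligand, using only the sequence and per-residue
*predicted* structural tracks (secondary structure, relative solvent
accessibility, backbone dihedral angles).  The unit of classification
is a sequence window of odd length L centered on the residue; windows
centered on annotated binding residues are the positive class.  The
model assumes (i) binding propensity is a local property of the window,
(ii) the structural tracks, though predicted rather than measured,
carry class-dependent signal, and (iii) labels are per-residue and
independent — no attempt is made to model the spatial clustering of a
real binding pocket.

## Windows and padding

Chains are padded at *both* termini with (L−1)/2 virtual residues `X`
so that every residue, including terminal ones, is the center of
exactly one window; a chain of n residues yields exactly n windows.
`X` is a full category in every alphabet: q=21 for amino acids, and one
extra class in each discretized track alphabet.  Window length is
per-ligand configuration with shipped defaults (Zn²⁺ 7, Fe²⁺ 9, Fe³⁺ 9,
Cu²⁺ 13, Mn²⁺ 7, Co²⁺ 11, Ca²⁺ 9, Mg²⁺ 9, Na⁺ 9, K⁺ 11, NO₂⁻ 13,
CO₃²⁻ 15, SO₄²⁻ 13, PO₄³⁻ 13); no window-length search is implemented.

## Feature extraction

**Position weight matrices.**  For each track, two L×q matrices are
built from the training windows of a split — one from positives, one
from negatives — with matrix elements

    m[i][j] = ln(p[i][j] / p0[j]),   p[i][j] = (n[i][j] + N_i/q) / (2 N_i),

where n[i][j] is the count of class j at position i and N_i the number
of windows.  The additive pseudocount N_i/q guarantees p[i][j] > 0 and
Σ_j p[i][j] = 1 exactly.  The background p0 is not prescribed by the
position-probability form, so the package defines it with the same
pseudocount expression pooled over all positions of *all* training
windows (positives and negatives together); this keeps both matrices on
a common reference and every log-odds finite.  Scoring a window against
the positive then the negative matrix gives the 2L-dimensional
position-conservation block.

**Composition.**  Per-window relative class frequencies (counts divided
by L, so blocks are scale-free across window lengths).

**Information entropy.**  One scalar per window per physicochemical
alphabet: H = −Σ_j p_j log₂ p_j with p_j = (n_j + N/q)/(2N), N = L.
Counts run over all q classes *including* the padding class `X`
(q = 4 for polarization charge: positive {K,R,H}, negative {D,E},
uncharged, plus X; q = 7 for hydropathy: P, G, C singletons,
hydrophobic {A,V,L,I,M,F,W}, polar-uncharged {S,T,N,Q,Y,H}, charged
{D,E,K,R}, plus X).  The pseudocount bounds 0 < H ≤ log₂ q, with
equality exactly at uniform class counts.  Both groupings ship as
editable TSV tables (`src/ionbind/data/`), not code, so users can
substitute their preferred classification.

**RSA binning.**  Four classes I/J/M/N with right-closed boundaries
0.2, 0.45, 0.6, 0.85.  RSA is clamped into [0,1] on ingest; values of
exactly 0 fall in I and values above 0.85 clamp into N, so the map is
total.

**Dihedral reclassification.**  φ is discretized by scheme `g`
(A: [−180,−75), B: [−75,180]) or the finer `f` (cuts −105, −75, −60);
ψ by `h` (cuts 15, 135) or `p` (cuts −15, 75).  All schemes use
left-closed/right-open intervals with the last interval closed at
+180° — a uniform tie-break for boundary values that the published
interval notation leaves ambiguous; since predicted angles carry one
decimal, only exact boundary hits are affected.  The four φ×ψ
combinations are dihedral models 1=(g,h), 2=(g,p), 3=(f,h), 4=(f,p);
the id→pair mapping is configurable because no canonical numbering
exists.  "Combination" means concatenated per-angle feature blocks; a
product alphabet over (φ,ψ) pairs is not implemented.
`angle_distribution` provides the 24×15° binding/non-binding profiles
from which new interval thresholds can be read off manually; no
automatic boundary-selection algorithm is provided, since threshold
choice is a judgment about where the two profiles differ.

For L = 7 under model 1 the assembled vector has
(21+14)+(4+14)+(5+14)+(3+14)+(4+14)+1+1 = 109 dimensions; the
`--no-dihedral` variant drops the φ and ψ blocks (74 dimensions).

## Classifier

A random forest with the two parameters the method fixes: k = 500 trees
(default) and m = ⌊√M⌋ candidate features per split.  All other tree
hyperparameters stay at scikit-learn defaults and are recorded in the
model's training summary for reproducibility.  Prediction is majority
vote; the positive-vote fraction is returned alongside labels and exact
ties resolve to the positive class (recall-oriented, and only reachable
with an even tree count).

## Evaluation protocol

Negatives outnumber positives roughly 10:1 in the synthetic defaults
(50–100:1 in real ion-ligand datasets), so training sets are balanced:
all positives plus an equal-count uniform sample of negatives, drawn
independently n_rep = 10 times (seeds base+r); reported metrics are
arithmetic means over repeats.  Within each balanced set, 5-fold
segment-level cross-validation (unstratified by default, stratified by
flag) averages the five fold results; folds are nested inside repeats.
The independent test instead splits whole chains 80/20
(round(0.8·n) chains in training), trains on balanced training-side
sets and evaluates on *every* test-side window — the natural imbalanced
mixture, which is why independent-test MCC is much lower than balanced
CV MCC at similar accuracy.  PWMs and backgrounds are training-split
statistics and are recomputed inside every fold and repeat; computing
them once on the full data would leak test labels through the features.
Metrics are Sn, Sp, Acc (percent) and MCC, with MCC defined as 0
whenever a denominator factor vanishes.

## Synthetic data

The generator emulates the statistical structure of an ion-ligand
dataset at desk scale: chains of uniform random length (default 60–120,
100 chains ≈ 9,000 residues), binding planted independently per residue
(default rate 0.1, giving balanced sets of ≈1,800 windows).  Binding
residues are enriched for C/H/D/E (the classic metal-coordinating side
chains) with multiplicative propensity 8; binder tracks prefer coil,
RSA in (0.45, 0.85], φ in [−180,−75) and ψ in [135,180], while
non-binders prefer the complementary regions.  Track-signal strengths
(defaults: dihedral 0.8, RSA 0.6, SS 0.5) are the probability mass
moved from a shared background distribution to the class-specific one,
so 0 is an exact null; `SimulationConfig.null()` sets enrichment to 1
and all track signals to 0.  Angles are sampled from mixtures of
uniform distributions over the discretization intervals rather than von
Mises densities, so planted boundaries align exactly with the dihedral
bins and recovery tests are clean.

What the generator does **not** emulate: spatial clustering of binding
sites, sequence homology between chains, realistic amino-acid
background frequencies, autocorrelation along tracks, and the
50–100:1 class imbalance of real data.  Passing tests therefore show
that the pipeline recovers a per-residue signal of the planted kind and
that its protocol is leak-free — not that real-data performance will
match the synthetic numbers.

## Numerical and design choices

* Pseudocounts make every PWM probability and background strictly
  positive; row sums are exact to 1e−12 and tested at that tolerance.
* Angles are wrapped into [−180,180] on ingest ((x+180) mod 360 − 180;
  +180 maps to −180, which every scheme classifies identically to a
  first-interval value only at that single representative).
* Non-standard residues (B, Z, J, U, O, X, \*) in input FASTA drop the
  chain with a warning by default; a "map to nearest standard residue"
  policy is available.
* Vote ties → positive; MCC denominator zero → 0; 80% chain count →
  round(); balanced sampling without replacement requires |neg| ≥ |pos|.
* Seeds: every stochastic stage (generation, balancing, fold partition,
  forest) derives deterministically from one base seed, so identical
  configurations reproduce byte-identical reports.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full protocol on the
default synthetic conditions over a fixed 5-seed grid, with 2 balanced
repeats and 200 trees per run — enough averaging to place the planted
CV MCC (~0.93), the no-dihedral MCC (~0.69) and the null MCC (|MCC| <
0.02) well away from their acceptance thresholds while keeping a run to
a few minutes on one CPU; the shipped defaults for real analyses remain
10 repeats and 500 trees.

## Known limitations

* Structural tracks are consumed from files; the upstream predictor is
  not run, and track quality is the user's responsibility.
* No probability calibration: vote fractions are ensemble frequencies,
  not calibrated posteriors.
* The independent test reports a single 80/20 split per seed; chains
  are assigned uniformly, not stratified by positive count, so small
  datasets can land few positives on the test side (a warning is
  logged).
* Dihedral interval thresholds are per-ligand configuration; the
  shipped `g/h/f/p` schemes were chosen for Mn²⁺-like contrast profiles
  and may be suboptimal for other ligands.
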