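# Methods

## The model

A protein chain is reduced to its Cα trace: an ordered list of 3-D
coordinates (Å), one per residue, with a B-factor per residue.  Structural
information enters through the *smooth contact matrix*

    C_kt = 1 − d_kt/κ   if d_kt ≤ κ,     C_kt = 0 otherwise,

where `d_kt` is the Euclidean distance between residues *k* and *t* and κ
(Å) is the contact cutoff.  `C` has unit diagonal, hence `trace(C) = n`,
and is positive definite for suitable κ.  Its eigendecomposition
`C = U D Uᵀ` gives `R = √D Uᵀ` (columns of `R` are the intrinsic contact
vectors, `RᵀR = C`).  Each residue *i* is assigned the eigenvalue of the
nearest eigenspace: the λ_p maximizing |R_pi| over rows with λ_p > 0.
Unlike a principal-component truncation, small positive eigenvalues
compete on equal terms; the fingerprint is a *sequence* of eigenvalues,
one per residue, invariant to rigid motion because it depends only on
pairwise distances.

Two chains are compared through the normalized dissimilarity
`S_ij = |λ_i − λ_j| / |λ_i + λ_j| ∈ [0, 1)` and a global, terminal-gap-
penalized, monotone alignment minimizing total cost under an affine gap
model: a gap run of length L costs `ρ_o + (L−1)·ρ_c`.  With
`ρ_o = ρ_c = ρ` this reduces exactly to the single-penalty recursion
`V_ij = min(V_{i−1,j}+ρ, V_{i,j−1}+ρ, V_{i−1,j−1}+S_ij)`.  The
whole-alignment *comparison score* is the optimal raw value divided by the
number of alignment columns; it is 0 for identical fingerprints and stays
in [0, 1] whenever all S entries are < 1 and both penalties ≤ 1.  The
length normalization is this package's own convention — the per-pair
scores it produces are bounded and comparable across chain lengths, but
other normalizations (e.g. by the shorter chain) would be defensible.

## Stability intervals

Every monotone alignment path's cost is *linear* in the gap penalty ρ
(slope = its number of gap columns, single-ρ regime) and in any single
entry S_ij (slope 1 if the path pairs (i, j), else 0).  The maximal open
interval over which a fixed optimal path stays optimal is therefore
computed exactly: enumerate all paths (the count is the Delannoy number
D(m, n); enumeration refuses above 10⁶ paths), compare cost lines
pairwise, and intersect the resulting half-lines.  Endpoints are
*excluded*: a tie with a competitor is treated as the boundary of
stability, which reproduces the open-interval breakpoints of the worked
4×5 reference instance (0.15 for ρ; 0.2 / 0.3 for on-path entries).  No
numeric bisection is involved, so there are no tolerance artifacts.

## Coordinate perturbation

B-factor mode: `B = 8π²·E‖r − r̄‖²` is a scaled total positional variance;
we split it isotropically over the three axes and scale by s², giving
per-axis standard deviation `√(s²·B/(24π²))` — so `B = 24π²` at `s = 1`
yields exactly 1 Å.  NMR mode: per-axis variances are `s²` times the
(n−1)-denominator sample variances over the deposited models (at least two
models required; with one model the variance is undefined and an error is
raised).  All draws are independent across residues, axes and samples; the
deliberate lack of correlation *overstates* real variability, making the
robustness verdict one-sided (a method that survives large s survives the
correlated truth).  Per-sample seeds are derived deterministically from
`(master seed, s index, sample index, chain index)` via numpy
`SeedSequence`, so experiments are bit-reproducible while samples remain
statistically independent.

## Evaluation

A pair of chains is predicted same-family when its comparison score is at
most τ.  Candidate thresholds are the distinct scores, the midpoints
between consecutive distinct scores, and sentinels below the minimum and
above the maximum, so the curve always attains (0, 0) and (1, 1).  AUROC
is the trapezoidal area over the FPR-sorted points, which equals the
Mann–Whitney concordance probability with ties counted ½ (cross-checked
against scikit-learn in the tests to 1e−12).  The best operating point
minimizes Euclidean distance to (FPR, TPR) = (0, 1), ties broken toward
smaller τ.  The trimmed interval over sampled AUROCs deliberately keeps
the idiosyncratic drop-one-max-drop-one-min rule (95% nominal coverage at
40 samples); other sample counts are accepted but logged.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| κ | contact cutoff (Å) | 19 | grid 4–23 Å; below ~7 Å contact matrices are too sparse to discriminate folds |
| ρ_o | gap-opening penalty | 0.5 | grid 0.0–0.9 step 0.1 |
| ρ_c | gap-continuation penalty | 0.3 | grid 0.0–0.9 step 0.1; very small values permit near-free long gaps |
| s | uncertainty scale | 1 | s = 1 reproduces the experiment's own spread |
| n_samples | perturbed datasets per s | 40 | drop-min/drop-max trimming gives a 95% interval |

The default grid is 20 × 10 × 10 = 2,000 triples.  The gap-penalty axes
stop at 0.9: with ten values per axis the grid size works out exactly, and
a penalty of 1.0 can never be preferred over the worst possible pair cost.
Note that ρ_o = 0 is degenerate under this cost model: alternating
single-column gaps each open a fresh run at zero cost, so every alignment
can be driven to ~0 and all pairs tie (AUROC 0.5).  The grid retains
ρ_o = 0 for completeness; tuning never selects it.

## Synthetic families

The generator emulates labelled fold families as self-avoiding 3-D walks:
consecutive Cα spacing fixed at 3.8 Å, directions redrawn whenever a
non-consecutive pair would come closer than 4 Å (backbone-like excluded
volume).  One template per family (from `template_seed`); members add
independent per-coordinate Gaussian jitter of standard deviation
`jitter_sd` (0.3 Å in the frozen benchmark — comfortably inside one
B-factor standard deviation); B-factors are drawn once per template,
uniform on 20–60 Å², the mid range of crystallographic values, and shared
by members.  The frozen benchmark used throughout the tests is two
families × four members × 40 residues (template seeds 11/22, member seeds
101/202).

What the generator does *not* emulate: secondary-structure regularity,
hydrophobic-core/surface B-factor gradients, insertions/deletions between
family members (members are equal-length jittered copies), and the fuzzy
between-family similarity continuum of real fold space.  Passing tests
therefore demonstrate the machinery's correctness and its qualitative
robustness behaviour (perfect separation at adequate κ, graceful
degradation with s), not the quantitative recognition rates achievable on
real structure benchmarks — `scripts/reproduce_full_benchmark.py`
documents the full-scale workflow for users with downloaded data.

## Numerical choices

* Eigendecomposition via `numpy.linalg.eigh`; eigenvalues sorted
  descending.  Negative eigenvalues (C indefinite for some κ) are clamped
  to 0 inside √D, excluded from assignment, and counted with a logged
  warning; if *no* eigenvalue is positive the encoding errors out.
* Assignment ties in |R_pi| resolve toward the larger eigenvalue
  (first-index argmax over the descending spectrum).
* DP traceback is deterministic with tie preference diagonal > up > left;
  boundary gap costs are built by cumulative addition so traceback
  equality tests are float-exact.
* Switching gap type (gap in one chain immediately after a gap in the
  other) opens a new run and is charged ρ_o.
* Stability endpoints come from exact rational-style line intersections of
  enumerated path costs; reported lower bounds are clipped at 0.
* Sample statistics of coinciding ensemble models are snapped to the shared
  value / exact zero to honour the "zero iff identical" contract.
* PDB coordinates are rounded to the format's printed precision (3
  decimals; B-factors 2) on input, making write/read round trips exact.
* Chains must be selected explicitly when a file holds several; altloc
  conformers resolve to the highest-occupancy one ('A' on ties); residues
  without a Cα are skipped with a warning.

## Problem sizes

The shipped tests and examples run the full pipeline at desk scale: chains
of 20–60 residues, 8–18 chains per experiment, grids of a handful of
triples, 3–40 perturbation samples per scale.  These sizes were chosen so
every stage — including the 100-instance DP-vs-enumeration cross-check and
two 10,000-draw Monte-Carlo checks — completes in well under a minute
while still exercising every code path; all drivers accept larger inputs
unchanged.

## Known limitations

* Sequential alignments only; non-sequential topologies (circular
  permutations) are outside the model.
* Isotropic, uncorrelated perturbation only; ANISOU records are ignored.
* The stability analysis varies one parameter at a time; simultaneous
  multi-parameter stability regions are not computed, and the gap-penalty
  interval analysis applies to the single-ρ regime.
* mmCIF input is not supported; use single-model or multi-model PDB text.
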