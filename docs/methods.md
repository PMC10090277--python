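# Methods

## Activity transform

IC50 values are taken in µM as tabulated and transformed to
`activity = offset − log10(IC50)` with `offset = 6`; the offset absorbs
the µM→M unit conversion, so 1 µM ↦ 6.0. Both the 2D and 3D halves use the
same configurable offset: an additive constant shifts only the intercept
of any downstream model, never its ranks or its cross-validation
statistics, so using one offset throughout removes an inconsistency
without changing any conclusion. `inverse_pic50` back-transforms
predictions to IC50, which is positive by construction.

One quirk of the source material is documented here deliberately: the 3D
protocol names compound I1 the template "because it has the highest IC50",
yet I1 has the *lowest* IC50 in the activity table (1.7 µM — the most
potent compound, and the one whose substituent row is the design anchor).
The pipeline resolves this as "template = most active compound
(lowest IC50)", which is the standard alignment choice for a congeneric
series.

Train/test membership is read from a `split` column when present; the
bundled table marks the four 2D held-out compounds. Where a split must be
drawn, it is drawn from an explicit seed (`Dataset.with_random_split`)
rather than system time, so every run is reproducible.

## Descriptor matrix

Quantum-chemical descriptors (minimum electrophilic reactivity index of a
carbon, minimum C–C exchange energy, minimum C–H total interaction, total
dipole) require a semi-empirical wavefunction; they are import-only
columns, supplied as CSV. The two graph-derivable descriptors in the
published model — nitrogen count NN and average carbon valency AVC — are
computed from SMILES/SDF via RDKit (AVC = mean total valence over carbons,
hydrogens included; undefined, and reported as missing, for a
carbon-free molecule).

Screening: columns with any missing value are dropped, then columns with
variance < 1e-8 (an arbitrary-but-stated floor standing in for the
unspecified pre-screen of descriptor-generation suites). Screening is
idempotent and order-preserving, and a drop log names every removed
column.

## Heuristic stepwise MLR

The classical "heuristic method" of descriptor-selection software is not
published as an algorithm, so the implemented search is fully specified
here: beam-width-B forward selection (default B = 10). Size-1 models are
ranked by R² after discarding descriptors whose single-descriptor F < 1;
each larger size extends every beam member with every descriptor whose
pairwise Pearson |r| with all included descriptors is below the
collinearity cap (default 0.8, matching the reported practice for this
series). Ties in R² break toward the larger minimum |t|, then by
descriptor name, making the search deterministic.

Each candidate is an OLS fit reporting R², overall F, per-coefficient t,
s² = RSS/(n−p−1), and R²cv computed from the hat-matrix identity
`e_i/(1−h_ii)` — algebraically identical to n refits, and tested for
1e-10 agreement with the package's brute-force LOO loop. A saturated fit
(n = p+1) is allowed for prediction (its residual statistics are NaN),
which is what the two-point LOO folds of tiny examples need.

The model size is chosen where the best-model R²cv gain between
consecutive sizes first falls below `size_choice_delta` (default 0.02) —
an automated version of reading the statistic-vs-size curve by eye; the
user can override the size outright. The published six-descriptor choice
was such a by-eye judgement, and its printed coefficients are not
reproducible without the unpublished descriptor values, so coefficients
are never compared against it.

## Gene expression programming

Karva encoding: each gene has a head of length h (functions or terminals)
and a tail of length t = h·(a_max − 1) + 1 (terminals only), which
guarantees every gene decodes to a complete tree; decoding is
breadth-first from position 0, and trailing unused symbols are
non-coding. The function set is {+, −, *, /} (binary) and {Ln, sin}
(unary); terminals map to descriptor columns.

Invalid arithmetic is not "protected": division with |denominator| <
1e-12, Ln of a non-positive argument, or a non-finite intermediate marks
the affected rows NaN, and any NaN on the training block zeroes the
chromosome's fitness. Protected operators distort the search space toward
degenerate expressions; invalidation is simpler to reason about and test.
Fitness is R² floored at 0 so roulette weights stay non-negative.

The source material names the operator set and the generation at which
its best model appeared, but not the population size, head length, gene
count, rates or selection scheme. Defaults follow canonical GEP practice:
h = 8, 3 genes linked by `+`, population 50, ≤ 200 generations, mutation
0.044, inversion 0.1, IS/RIS/gene transposition 0.1 each, one-point 0.3,
two-point 0.3, gene recombination 0.1, roulette selection with a single
elite clone (best-so-far fitness is therefore non-decreasing). All are
exposed in `GEPConfig`; a run is a pure function of its seed.

## CoMSIA-style fields and PLS

The similarity-index field at lattice point q for property type F is
`−Σ_a w_probe·w_a,F·exp(−α·r_aq²)` with probe weight +1 and α = 0.3 (the
Klebe sign convention: more negative where the property concentrates).
Lattice: spacing 2 Å, extending 4 Å beyond the joint bounding box of the
aligned set, points at origin + integer multiples of the spacing — a
single atom therefore spans 5×5×5 = 125 points. When molecules are read
from SDF, per-atom properties default to steric = r_vdW³, electrostatic =
Gasteiger charge, hydrophobic = Crippen atomic logP contribution,
donor/acceptor = N/O rules, all overridable via `COMSIA_W_*` tags; the
synthetic molecule format carries explicit property values so 3D tests do
not depend on any toolkit's property assignment.

Alignment is Kabsch superposition over user-supplied atom pairs (≥ 3,
non-collinear), with the determinant correction forcing a proper
rotation. No automatic common-substructure search is attempted — the
reference alignment for this series was manual/template-based.

Column pretreatment before PLS: columns with stdev < 1e-6 dropped
(minimum-sigma analogue), all kept columns centred, and each field block
scaled to unit total variance (CoMFA-standard-style block scaling) so no
field dominates by raw magnitude alone. Whether the original analysis
used block scaling or autoscaling is unknowable from the text; block
scaling is the conventional choice for similarity-index fields and is
fixed here for determinism. PLS itself is NIPALS PLS1 (tested against
scikit-learn's implementation and, at full rank, against OLS). The
component count maximises leave-one-out Q² over 1…min(10, n−2), smallest
on ties, with PRESS from exact refits in which the pretreatment is
recomputed inside every fold; SEE and F use n − ONC − 1 degrees of
freedom.

Contours and contributions: per-column score = coefficient × column
stdev (the StDev·Coeff convention); field fractions are the per-field
sums of |score| normalised to 1; favorable/unfavorable contour levels sit
at the 80th/20th percentile of each field's scores.

## External validation

`R²ext = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ_tr)²` over the test set, with ȳ_tr the
*training* activity mean — a model predicting the training mean scores
exactly 0. The robustness call uses a strict `> 0.5`. The "average error"
reported alongside 2D models is read as mean absolute error on the
transformed-activity scale (the term is otherwise undefined).

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical shape* each stage assumes, not
nitrogen-mustard chemistry:

- `gen_descriptor_table` — standard-normal descriptor columns (optionally
  a correlated block at pairwise r ≈ 0.7), activity a sparse linear
  combination plus Gaussian noise expressed as a fraction of the signal
  sd (default 0.1, a low-noise QSAR regime). Defaults n = 60, p = 30:
  large enough for subset recovery to be statistically meaningful, small
  enough that 25-seed sweeps run in seconds.
- `gen_symbolic_dataset` — three catalog targets built only from the GEP
  alphabet (sin(x0)+x1; x0·x1+sin(x2); x0/x1+Ln(x2)), sampled on domains
  bounded away from the singularities (all columns in [0.5, 3] for the
  division/log target).
- `gen_aligned_molecules` — a rigid 8-atom scaffold with identical
  coordinates across molecules (the series is already superposed, as
  after template alignment) plus two substituent sites whose per-field
  properties vary per molecule; activity = effect × property(site, field)
  + noise. All five fields vary, only one carries signal.

Passing recovery tests therefore shows the estimators find planted
structure of the kind the models assume; it does not show that real
nitrogen-mustard descriptor tables satisfy those assumptions, that
conformers or alignments are right, or anything about binding. Headline
statistics of the original study that depend on its unpublished inputs
(printed regression coefficients, q² = 0.532-class values, the designed
compounds' predictions) are out of reach by construction and are not
asserted anywhere.

## Numerical choices and edge cases

- Rank-deficient OLS designs raise, naming a dependent column; constant
  columns raise in the correlation matrix (named).
- Division guard 1e-12; GEP fitness is total (never raises on math).
- PLS NIPALS stops early when residual covariance ‖Xᵀy‖ < 1e-14 (exactly
  collinear blocks), so asking for more components than the data carries
  degrades gracefully to the attainable number.
- Grid counts use ceil with a 1e-9 slack so exact multiples of the
  spacing do not gain a phantom point.
- All report JSON is written with sorted keys and no timestamps; a rerun
  with the same config and seed is byte-identical.

## Problem sizes

Defaults used by the analysis drivers and the acceptance script: 25-seed
recovery sweeps at n = 60, p = 30 for the stepwise search; 20-seed pair
sweeps at p = 10 against exhaustive search; 5 seeded GEP runs per target
at n = 100 train / 50 test; 10-seed field-recovery sweeps at 20 molecules
(≈ 1,700 field columns each). These sizes give stable rates while keeping
a full run in the tens of seconds on one core.

## Known limitations

- No conformer generation, energy minimisation, or automatic alignment:
  3D inputs must arrive aligned, or with explicit atom pairs to align on.
- Quantum-chemical descriptors cannot be computed, only imported.
- The GEP engine optimises raw R²; no parsimony pressure, so recovered
  expressions are often algebraically redundant (e.g. `(X0−X0)+X1+sin(X0)`
  for sin(x0)+x1).
- Contour output is numeric (levels + masks + CSV export); rendering is
  left to the user's plotting stack.
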