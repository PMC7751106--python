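# Methods

## Problem and model

The task is binary: membrane protein (positive) vs non-membrane protein,
over *all* membrane classes.  Transmembrane proteins carry hydrophobic
membrane-spanning segments that sequence features capture readily;
surface-bound membrane proteins (peripheral, lipid-anchored, GPI-anchored)
do not, which is why a dedicated classifier is combined with — rather than
replaced by — a transmembrane-topology predictor.

The pipeline has four stages: feature encoding, a bank of base classifiers,
vote fusion with member selection, and topology integration.  Each stage is
usable on its own; `memdetect.pipeline` wires them together.

## Encodings

All encodings order amino acids alphabetically by one-letter code
(A, C, D, …, Y); every file reader permutes external column orders into
this canonical order, so features can never be silently misaligned.

- **AAC / PAAC** are maximum-likelihood residue and dipeptide frequency
  vectors (dimensions 20 and 400); both sum to 1.
- **PseAAC** appends λ sequence-order correlation factors weighted by
  ω (default 0.05, legal range 0.05–0.7).  The correlation function
  averages squared differences of three standardized physicochemical
  scales.  The raw Tanford hydrophobicity, Hopp–Woods hydrophilicity and
  side-chain-mass tables are shipped as versioned constants
  (`memdetect.constants`) and are replaceable via
  `AminoAcidScaleSet.from_tables`; standardization uses the population
  (divide-by-20) standard deviation, since the 20 amino acids are the whole
  population, giving each standardized scale mean 0 and SD 1 exactly.
- **SAAC** concatenates the AAC of the N-terminal 25 residues, the
  interior, and the C-terminal 25 (dimension 60).  At the minimum legal
  length of 50 the interior is empty; its block is defined as the zero
  vector rather than an error, because the 50-residue floor itself makes
  L = 50 legal input.
- **Pse-PSSM** (dimension 40) works on PSI-BLAST profile matrices.  Rows
  are standardized to mean 0 *and* unit SD: centering alone would leave the
  λ-lag block scale-dependent across proteins.  A `center_only` flag
  restores the shift-only behaviour for sensitivity analyses.  A constant
  row standardizes to zeros.  For λ = 0 the lag block is identically zero.
  Profiles are read from the PSI-BLAST ASCII export; the first numeric
  block (log-odds) is used.  The weighted-percentage block is the plausible
  alternative; it is parsed and discarded, and switching would be a
  one-line change in `read_pssm`.

Sequence normalization: uppercase; ambiguity codes B/Z/J/U/O either error
("strict", default) or map to D/E/L/C/K ("map"); X always errors because it
carries no compositional information.

## Classifiers

- **Fused KNN**: plain Euclidean KNN for every K = 1..10, fused by majority
  vote.  The vote fraction is the classifier score.
- **Evidential KNN**: each of the K nearest neighbors lends its class a
  simple support mass `m({c}) = α₀·exp(−γ_c d²)` (α₀ = 0.95), the rest
  going to the whole frame; Dempster's rule combines the K masses, and the
  pignistic probability decides.  For a two-class frame the combination has
  the closed form implemented in `dempster_binary_masses`; the test suite
  checks it against explicit focal-set enumeration.
  The per-class kernel scale defaults to the standard heuristic
  γ_c = 1 / (mean squared distance among training members of class c).
  This is the main fidelity caveat of the toolkit: the published
  evidential-KNN variants differ in how (and whether) γ and α₀ are
  optimized, so absolute agreement with any particular implementation is
  not guaranteed, only the rule's structure.
- **Adapters**: RBF-kernel SVM, gradient boosting, and random forest from
  scikit-learn behind the same predict/score contract, with an optional
  accuracy-driven grid search (ties → smallest parameter values).

Tie rules are deterministic and data-driven everywhere: split votes resolve
to the K = 1 (nearest-evidence) decision; equal distances resolve to the
lower training index; equal vote counts in ensemble fusion follow the
first-ranked column.

Banks: one classifier per λ ("V50"; λ = 0..49 at full scale) or per (λ, K)
pair ("V500").  Desk-scale configurations truncate λ to 0..9 (100 members)
purely as a problem-size choice; the full range is a flag away.

## Ensemble fusion and selection

*All voting* takes the row-wise majority.  *Selective voting* ranks
members by greedy mRMR under the mutual-information-difference scheme, with
MI approximated from the Pearson (phi) correlation as −½ ln(1−ρ²).  The
approximation diverges at |ρ| = 1, so MI is capped at −½ ln(1e−12); a
zero-variance column is defined to carry zero information.  Scores within
1e−12 of the step maximum are treated as ties and resolve to the lowest
column index — two columns with mathematically identical information must
not have their order decided by floating-point round-off.

Incremental selection evaluates every ranked prefix by all-vote accuracy on
the leave-one-out vote matrix and keeps the best (ties → smallest prefix).
Because ranking and selection reuse the same LOOCV votes, the selection
accuracy is optimistically biased; treat it as a model-choice criterion,
not an unbiased performance estimate.  Held-out evaluation of the final
ensemble is what `predict` on fresh data provides.

## Topology integration

A topology call is membrane iff it reports ≥ 1 TMS.  Positive calls get
weight |S|−1 in a weighted vote with the |S| selected members — equivalent
(unit-tested for |S| = 2..21) to flipping the ensemble decision positive
iff at least one selected member agrees with the positive call.  Negative
calls carry weight 0: topology predictors are structurally blind to
surface-bound membrane proteins, so their negatives must never demote.
Consequently integration can only move sensitivity up and specificity down
(or leave both unchanged); both directions are asserted as invariants.
When several call files are supplied the CLI merges them by logical OR on
the membrane flag.

## Evaluation

LOOCV is the primary protocol.  Neighbor-based learners use a fast path —
one pairwise distance matrix with the self-distance masked to infinity —
proven equal to naive per-fold refitting in the tests.  Stratified k-fold
(seeded) is available as the cheaper alternative.  Metrics: sensitivity,
specificity, accuracy, MCC (defined 0 when any denominator factor vanishes,
matching the "no better than random" reading), and trapezoidal ROC/AUC
(equivalent to midrank pair counting).  Percentages are reported to two
decimals.

## Synthetic data

`memdetect.synth` generates the study conditions every test runs under:

- background residues drawn from Swiss-Prot-style frequencies;
- positives carry 1–7 hydrophobic stretches (18–25 residues from
  {A, I, L, M, F, V, W}) in disjoint slots, except a 20% surface-bound
  minority that gets only a 1.6× hydrophobic compositional shift;
- lengths 50–400 (the 50-residue fragment floor is enforced);
- profiles are BLOSUM62 rows per residue plus ±1 integer noise, so they
  inherit the class signal and round-trip exactly through the ASCII PSSM
  writer/reader;
- the simulated topology predictor detects stretch-bearing positives with
  sensitivity 0.72, never detects surface-bound positives, and false-calls
  negatives at rate 0.003 — the operating profile of a high-specificity
  consensus topology tool.

What the generator does *not* emulate: homology structure between
sequences, realistic PSSM pseudo-count statistics, signal peptides, and
β-barrel geometry.  Passing tests therefore demonstrate the correctness and
the qualitative behaviour of the method (selection helps; integration
trades specificity for sensitivity favourably), not its accuracy on real
proteomes.

Acceptance-scale runs use 60+60 proteins and λ = 0..9 (a 100-member bank);
these sizes were fixed once as desk-scale study conditions.

## Known limitations

- The evidential-KNN γ/α₀ parameterization is the heuristic default, not a
  fitted optimum; an LOO-error optimization hook exists but is off by
  default.
- mRMR uses the correlation approximation of MI, not a discrete MI
  estimator; for binary votes these coincide up to the phi coefficient.
- Selection accuracy is resubstitution-flavoured (see above).
- The toolkit ingests topology calls and PSSM profiles; it does not run
  topology predictors or PSI-BLAST.
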