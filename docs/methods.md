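# Methods

## Problem setting

A protein carries a set of high-level functional labels (GO Slim terms); it
also contains one or more intrinsically disordered regions (IDRs). The
package asks how much of the protein's labelling is recoverable from IDR
sequence alone. Each IDR is treated as an independent instance carrying its
parent protein's full label set — no attempt is made to resolve which IDR
is responsible for which function — and the multi-label problem is reduced
to independent one-vs-rest binary problems, one per term.

## Feature extractors

All extractors operate on the 20-letter alphabet in the fixed order
`ACDEFGHIKLMNPQRSTVWY`; residues outside it (B, Z, X, U, O, J) are dropped
during input sanitization with a logged count, since the descriptors are
defined only over the standard alphabet.

* **Chemical composition (5).** Class fractions in the order positive,
  negative, polar, hydrophobic, special. Histidine is placed in the
  positive (chargeable) class so the five classes partition the alphabet
  and the vector sums to exactly 1.
* **Amino-acid composition (20) / occurrence (20).** Fractions,
  respectively raw counts, per residue.
* **CTD blocks (21 per property).** For each of five physicochemical
  properties the alphabet is split into three groups (standard
  fold-recognition groupings, shipped as configuration rather than
  hard-coded: hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, and helix/strand/coil-former classes standing in for
  predicted secondary structure, since no per-IDR structure prediction is
  part of this pipeline — an external 3-state partition can be supplied
  instead). The block is [C1..C3, T12, T13, T23, D...]: group fractions;
  boundary-crossing adjacent-pair frequencies normalized by L−1 (0 when
  L=1); and per group the 1-based positions of the first, ⌈0.25·n_g⌉-th,
  ⌈0.50·n_g⌉-th, ⌈0.75·n_g⌉-th and last occurrence, each divided by L
  (zeros for absent groups). The two Dubchak families are the 20-component
  head concatenated with the five 21-blocks (dimension 125).
* **Bigrams (400 each).** Ordered pair counts at gap 0 (adjacent) or gap 1,
  divided by the number of windows (L−1, resp. L−2) so the vectors are
  probabilities and length-independent; this window-count normalization is
  a deliberate reading of "pair probabilities" where no denominator is
  fixed by convention. Sequences too short for a family (L<2, resp. L<3)
  yield all-zero vectors plus a warning instead of failing, keeping
  protein-level collation total; these instances participate downstream as
  ordinary all-zero rows.
* **Profile bigrams (400).** From a row-normalized L×20 profile E,
  T_{m,n} = Σ_{i=1..L−1} e_{i,m} e_{i+1,n}, flattened row-major so the
  column order matches the sequence bigrams; the vector sums to L−1. Rows
  that do not sum to 1 (tolerance 1e-6) are rejected.

PSI-BLAST ASCII profiles contain both log-odds and weighted-observed
percentage columns; which one the "relative probability" interpretation
refers to is reader configuration. The default `percentages` mode divides
the percentage block by 100 and renormalizes rows; `logodds_sigmoid`
squashes log-odds through 1/(1+e^−x) and normalizes. The parser maps the
file's native ARNDC… column order to the canonical alphabet via the header
line, and turns all-zero rows into uniform rows with a warning.

## Classifier

Per term and feature family, a two-class Gaussian Naive Bayes: per-component
class-conditional means and variances with empirical class priors, evaluated
in log-space. Variances are floored at 1e-9 × the component's global
(pooled) variance plus 1e-12 absolute, because constant components are
routine in sparse bigram vectors. Terms with fewer than 10 positive IDRs
(or with a class smaller than the fold count) are skipped and reported as
not evaluated — cross-validation is not meaningful with near-empty positive
classes. The decision rule is posterior ≥ 0.5, inclusive.

Folds are stratified on the term's binary label, shuffled with a fixed
seed (sklearn `StratifiedKFold`); stratification keeps rare terms trainable
in every fold. Folds are drawn at the IDR level: IDRs of one protein may
land in different folds. This is the literal reading of the
IDR-independence assumption; it does mean sibling IDRs with identical
labels (and correlated composition) can straddle the train/test boundary,
which slightly flatters absolute CV numbers on data with strong
protein-level signals — a caveat for interpreting the synthetic results,
not a defect of the procedure being studied.

## Evaluation

Counting unit is the IDR. Sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP); zero-denominator ratios are reported as
0 with an explicit `undefined` flag rather than NaN, so term averages stay
computable and auditable. MCC uses the standard product formula with the
convention MCC = 0 when any marginal is empty. A classifier is "better than
random" iff its true-positive rate exceeds its false-positive rate.
Per-family summaries are unweighted means over evaluated terms.

The per-IDR protocol holds out a uniform random test set (default 105 IDRs),
trains every term classifier on the remainder, and sweeps a posterior
threshold grid (default 0 to 1 in steps of 0.05). At threshold p an IDR
predicts S = {t : posterior ≥ p}; against its known (ancestor-expanded) set
K this gives TP/FP/FN, a per-IDR recall ρ = TP/(TP+FN) and precision
π = TP/(TP+FP). The curve reports the overall precision N_correct/N_total
(IDRs with TP ≥ 1) and the average recall (mean ρ over all test IDRs, with
ρ = 0 for IDRs predicting nothing); the mean π is emitted alongside since
both summaries are informative. Known sets are intersected with the trained
term vocabulary so that untrainable terms cannot contribute irreducible
false negatives.

## Synthetic data generator

The generator produces the structure the analysis assumes, not a biological
simulation: 250 proteins by default, each with uniform 1–3 IDRs (matching
the ~1.7 IDRs/protein ratio of large human IDR collections), IDR lengths
uniform 30–300, 8 leaf terms under 4 parents (depth-2 hierarchy — exactly
enough to exercise single-step ancestor expansion), and 1–6 leaf terms per
protein. Residues are drawn i.i.d. from a disorder-like background
(elevated P, S, E, K; depleted W, C, F, I; D+E = 12%); proteins annotated
with a signal term have that term's residue set re-weighted to its target
total fraction (default: D+E to 30%). PSSM rows are Dirichlet draws with
concentration vector `c·one_hot(residue) + 0.5·20·background` (c = 30), so
rows sharpen to one-hot as c → ∞ and at the default retain enough signal
that profile bigrams correlate with the source sequence bigrams (Pearson
r > 0.5 at L = 100).

What the generator does **not** emulate: positional structure (motifs,
autocorrelation — residues are i.i.d., so bigram families carry no
information beyond composition here), realistic GO term co-occurrence,
conservation structure, or homology-search artefacts (missing profiles are
modelled only as an optional missing-PSSM fraction). Passing tests on this
generator therefore demonstrate that the machinery recovers planted
compositional signals and is calibrated under the null — not that any
particular feature family would win on real proteome data.

The null dataset permutes term sets across proteins (IDRs keep their
protein's permuted set), preserving label marginals and the
labels-shared-within-protein structure while severing the sequence–label
link.

## Numerical and design choices

* Deterministic throughout: one integer seed fixes the dataset, the folds,
  the test-set draw and hence every output byte.
* Degenerate inputs: empty sequences are rejected at construction;
  too-short sequences give zero vectors with warnings; single-class or
  too-rare terms are skipped with logged reasons; ties at posterior 0.5 are
  positive calls.
* Problem sizes: the shipped tests and the acceptance script run at ~500
  IDRs / 12 terms, where the planted 30%-vs-12% acidic signal is recovered
  at MCC > 0.9 by composition features while unsignaled terms stay near
  chance; the same code scales linearly in IDRs × terms × families.
* The signal term's parent inherits the signal by construction (its label
  is implied by the child's after expansion), so calibration checks on
  "unsignaled" terms exclude it.
* TSV everywhere with mandatory headers (GO ids contain colons, which makes
  comma-separated layouts ambiguous); FASTA via Biopython; the PSI-BLAST
  ASCII writer emits percentages to 4 decimals so probabilities round-trip
  to within 1e-4 (the real tool prints integers; the reader accepts both).

## Known limitations

* Gaussian class-conditionals are a crude density model for sparse bigram
  vectors; the variance floor keeps them defined but heavily zero-inflated
  components are poorly described.
* IDR-level folds (see above) and i.i.d. residue generation both push
  synthetic CV numbers toward the optimistic side for compositional
  signals.
* Ancestor expansion is single-step by design; deeper ontology propagation
  is out of scope.
* No feature combination or per-term feature selection — families are
  evaluated independently.
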