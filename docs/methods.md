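# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `phylonull`, in the order data flows through the
package.

## Alignment representation and statistics

Alignments are integer matrices over a 21-symbol alphabet: gap `-` is
code 0 and is treated as a full 21st state everywhere — column
frequencies, pair frequencies, Hamming distances, model fitting.  No
sequence weighting is applied anywhere.  Readers accept FASTA and
Stockholm; insert states (lowercase residues and `.`) are removed
column-consistently before encoding, and ambiguous residue codes
(X, B, Z, U, O, J) map to gap with a logged count rather than erroring,
since real family alignments contain them.

Column statistics are f_i(a) (with optional symmetric pseudocount),
pair statistics f_ij(a,b), and the covariance
c_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b), flattened to a symmetric
(L·q)×(L·q) matrix for spectral analysis.  Hamming distances are
normalized by L (fractions in [0,1]); gap–gap agreement counts as a
match, a convention declared here because the literature rarely states
one.  Indices are 0-based in the API, 1-based in all TSV output.

## Null model I — column permutation

Each column is permuted independently with a seeded generator.  Column
multisets are preserved exactly (so f_i(a) is invariant to the last
digit), while inter-column and inter-sequence correlations are
destroyed.  The output is an i.i.d.-like sample of the profile model
∏_i f_i(a_i).

## Null model II — annealed distance-matrix matching

State: the current randomized alignment plus an incrementally maintained
integer matrix of differing-column counts.  A proposal picks a uniform
(column, row, row) triple and swaps the two entries; the objective is
the Frobenius norm over the upper triangle (i<j) of the difference
between current and target normalized distance matrices.  The upper
triangle avoids double counting; full-matrix and upper-triangle norms
are monotonically equivalent, so the accepted-move set is unchanged.
The swap changes only the 2(M−2) distances involving the two rows, so
the exact objective change is computed in O(M); an oracle test checks it
against full recomputation to 1e−9.

Annealing schedule (all exposed in `AnnealSchedule`):

* `beta0` — calibrated at initialization so that β·median|Δ| ≈ 0.1,
  i.e. the chain starts near the infinite-temperature (null-I) regime;
* `growth` — geometric, sized so β rises by 10^4 over the run;
* `n_sweeps` — 200 by default, one sweep = M·L attempted swaps;
* early stop once the Pearson correlation between randomized and target
  distance upper triangles reaches `target_corr` = 0.97, the fidelity
  level this construction is designed to attain.  Falling short emits a
  warning (with the full per-sweep trace), not an error: on
  weakly-structured inputs (e.g. equilibrium Potts samples, whose
  distance matrices are mostly noise) partial convergence is expected
  and harmless.

Proposals where the two entries are equal are identity moves and are
excluded from the acceptance bookkeeping.  The per-sweep inner loop is
numba-compiled; all randomness is pre-drawn from one numpy Generator so
a seed fully determines the output.

## Null model III — Felsenstein resampling on a tree

The independent-site kernel P(b|a,t) = e^{−μt} δ_ab + (1 − e^{−μt}) ω_i(b)
has stationary distribution ω_i and satisfies Chapman–Kolmogorov
exactly; both identities are asserted analytically in tests to 1e−12.
Likelihood evaluation uses Felsenstein pruning with per-node
max-rescaling, vectorized over sites; because the kernel is a rank-one
perturbation of identity, each child message is O(q) rather than O(q²).

Trees come from Newick input or, by default
(`fit_resampling_model`), from neighbor joining with midpoint rooting
on saturation-corrected distances: observed Hamming fractions plateau
at b = 1 − mean_i Σ_a f_i(a)² (the expected distance between two
independent profile draws), so the correction t = −b·log(1 − d/b)
(the Jukes–Cantor form with a profile-estimated plateau) undoes the
compression of deep branches before tree building; distances at the
plateau are capped, and negative NJ branch estimates clamped to 0.
Correcting the distances raises the distance-matrix fidelity of
resampled families by about 0.07 in Pearson correlation across
benchmark seeds.  Fitting, on the fixed tree:

1. ω_i initialized at empirical column frequencies with pseudocount 1/M
   (also regularizing single-symbol columns);
2. μ maximized by bounded 1-D search over log μ ∈ [−6, 3], tolerance
   1e−4 (scipy bounded minimizer);
3. by default, up to 5 EM rounds: the E-step computes expected counts of
   emissions from ω (one at the root, one per substitution event on a
   branch) via an up–down pass; the M-step re-normalizes them into ω;
   μ is re-optimized after each round, stopping when the log-likelihood
   gains less than 1e−3.

The EM refinement is on by default because the empirical initialization
is a biased moment estimate — leaf frequencies overweight shallow,
oversampled parts of the tree — which inflates μ̂ by roughly 50% at
benchmark scale and measurably degrades the distance structure of
resampled alignments.  With refinement, μ is recovered within 25%
relative error at M=200 in simulation, and resampled families reach
distance-matrix correlations in the 0.7–0.95 band.  Branch lengths and
μ are jointly identifiable only up to rescaling; the convention is to
keep the input tree's lengths fixed and fit μ alone.

Resampling draws the root from ∏ ω_i, applies the kernel independently
per site down every branch, and returns the leaf sequences.  Gap is a
mutable 21st state in this model, consistent with the rest of the
package.

## plmDCA

Each site's conditional distribution given the rest is a multiclass
logistic model; its L2-regularized log-likelihood is maximized by
L-BFGS with an analytic gradient (deterministic: fixed iteration order,
gradient tolerance 1e−5, so identical inputs give bit-identical
scores).  Defaults λ_J = 0.01·(q−1), λ_h = 0.01 per conditional.  The
two asymmetric estimates of each coupling block are averaged and the
result projected to the zero-sum gauge.

One subtlety: within a single conditional, the row components of the
coupling block and the intercept are interchangeable (both shift the
logits by an a-dependent constant), so the split between them is fixed
by the regularizer, not the data.  The per-site field is therefore
assembled as intercept plus the row means of that site's own couplings
— the gauge-invariant combination — rather than read off the averaged
coupling tensor.  With this convention the exactly-normalized fitted
model reproduces the empirical pair statistics of a tiny (L=4, q=3)
training sample to a few 1e−4 as λ→0, verified against exact
enumeration of all 81 states.

Scores: F_ij is the Frobenius norm of the zero-sum coupling block over
the 20×20 non-gap states (the gap state is fitted but excluded from the
norm, the standard plmDCA convention); the average-product correction
subtracts row-mean·row-mean/overall-mean.  Ranking ties are broken
lexicographically by (i, j) so every evaluation is deterministic.

## Contact evaluation

Contacts are residue pairs with minimum heavy-atom distance ≤ 8 Å
(hydrogens excluded); trivial pairs are removed by |i−j| > 4 (24 for
the long-range view).  Alignment columns without a mapped structure
residue are masked out of every histogram and PPV computation.
Histograms are normalized to unit area.  PPV curves rank eligible pairs
by descending score; the joint multi-family curve pools all pairs into
one ranking, the averaged curve takes the per-rank mean over families
that still have pairs at that rank (families differ in length, so the
average uses whichever families remain — a declared choice).  z-scores
use per-pair mean and n−1 standard deviation over ≥2 null samples;
pairs with null SD < 1e−12 are flagged undefined, never zeroed.  The
"hypothetical" PPV substitutes null-model scores on non-contact pairs,
an upper bound on what exact background removal could achieve.

## Synthetic benchmarks

The generator produces the two study conditions used throughout the
tests:

* **Phylogeny-only families** — Yule (pure-birth, rescaled to mean
  root-to-tip depth 1), Kingman-coalescent, or star trees; site
  profiles ω_i ~ Dirichlet(0.5) (heterogeneous conservation); evolution
  under the Felsenstein kernel.  Defaults M=150, L=50, q=21 and
  μ=0.55, the rate at which the default family's mean pairwise Hamming
  distance is ≈0.5 — calibrated once against that stated condition.
  Zero intrinsic couplings by construction.
* **Planted-contact Potts families** — couplings with a ferromagnetic
  diagonal block of strength s=2.0 on the 20 non-gap states over a
  random contact graph (|i−j| > 4), fields from a Dirichlet profile;
  sampled by single-chain systematic-scan Gibbs (burn-in 1000 sweeps,
  thinning 10); a lag-1 autocorrelation of the thinned log-weights
  above 0.2 triggers a mixing warning.  Defaults for the recovery
  experiments: L=30, 20 planted pairs, M=2000.

The two signals are deliberately generated separately: coupled
(epistatic) evolution *on* a tree is a non-equilibrium process whose
global inference is an open problem, and the package's claims only
require each signal in isolation.  Consequently, passing tests show
that the null models preserve/destroy exactly what they are designed
to on data matching their assumptions; they do not certify behaviour
on real families where phylogeny and couplings interact, where gaps
arise from indel processes, or where alignment errors correlate
columns.

## Problem sizes in the test suite

Experiments are sized to run comfortably on one CPU.  The annealing
and resampling fidelity checks use the reference family (M=150, L=50);
planted-contact recovery runs at full depth (M=2000); the z-score study
(50 null-II samples, each re-fitted with plmDCA) uses the same planted
graph at M=400, where each anneal-plus-fit takes seconds — the
package's own choice of scale for a 51-fit experiment.  Exact-
enumeration oracles use L=4, q≤3 (81 states) and ≤5-leaf trees.  The
spectral comparison uses M=100, L=30 over 100 seeds.

## Known limitations

* Null model II matches only the pairwise distance matrix, not higher-
  order phylogenetic structure; it is not a sample from any hierarchical
  generative process.
* The Felsenstein model has a single global rate (no Gamma rate
  variation) and no amino-acid exchangeability structure (no WAG/LG);
  tree topology search beyond neighbor joining is out of scope.
* plmDCA inherits pseudo-likelihood's finite-sample bias; couplings are
  only asymptotically consistent estimates.
* PDB mapping between alignment columns and structure residues must be
  supplied by the caller; no automated HMM-based mapping is attempted.
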