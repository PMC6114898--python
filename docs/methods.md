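# Methods

This note documents the models implemented in tirnakit, the conventions and
numerical choices behind them, and what the synthetic data used by the test
suite does and does not establish.

## The built-in folding engine

The built-in engine exists so that every downstream stage — feature
quantification, pruning, design selection, modelling — runs exactly and
reproducibly with no external thermodynamic dependency, and so that every
folding primitive can be verified against brute-force enumeration.

**Energy model.** Nested (pseudoknot-free) secondary structures; an energy
per base pair of G·C = −3.0, A·U = −2.0, G·U = −1.0 kcal/mol; no stacking,
loop, or dangle terms; minimum hairpin loop of 3 unpaired nt; T = 37 °C with
kT = 0.6163 kcal/mol. This is deliberately not a nearest-neighbour model:
the point is exactness and enumerability, not calorimetric accuracy. For
realistic energies the ViennaRNA adapter (below) is the right engine.

**MFE.** Minimised by the standard O(n³) interval recursion. Among co-optimal
structures the engine returns the lexicographically smallest dot-bracket
(with `(` < `)` < `.`), reconstructed by memoised traceback — a pure
determinism convention.

**Partition function and pair probabilities.** McCaskill-style inside
(Z(i,j) = Z(i+1,j) + Σ_k w(i,k)·Z(i+1,k−1)·Z(k+1,j)) and outside passes over
the same recursion, giving the full base-pair probability matrix and the
ensemble free energy −kT·ln Z. To avoid overflow, Z is computed with a
per-nucleotide scale factor u = exp(G_MFE/(n·kT)) so that the MFE structure
has scaled weight 1; all probabilities are scale-invariant. Exactness is
asserted against exhaustive Boltzmann sums (tolerance 1e−9) in the tests.

**Stochastic sampling.** Standard stochastic traceback of the inside
recursion; i.i.d. draws from the Boltzmann distribution, seeded through
`numpy.random.default_rng` — identical (sequence, seed) reproduces the
identical structure list. Sampled frequencies are χ²-tested against exact
enumeration probabilities.

**Cofolding.** Two strands are concatenated with an explicit nick; pairs
across the nick are exempt from the minimum-loop rule and carry no
initiation penalty (configurable, default 0). Because the nested-structure
ensemble of a concatenation is order-dependent in general, the engine
canonicalises strand order internally (lexicographic by residues) and maps
the structure and probability blocks back to the caller's order; this makes
mfe(A,B) = mfe(B,A) hold exactly, as the dimer contract requires.

**Interaction energetics (accessibility framework).** The energy of binding
a query (an unpaired tiRNA stretch) to a target site [a,b] is decomposed as

    e_total = e_interaction + dG_open,   dG_open = −kT·ln(Z_[a,b] unpaired / Z) ≥ 0,

where Z with the site forced open is a constrained partition function
(every pair touching [a,b] forbidden) — the same semantics as RNAup, not
the cheaper "unpaired probability of the window" shortcut. The engine
minimises e_total over all sites up to 25 nt wide (the classic maximal
interaction length; configurable). Implementation notes:

* opening energies for all O(n·w) sites of a target are precomputed in one
  pass from the inside and outside arrays (a bilinear form per site) and
  cached per target;
* the duplex term is the optimal antiparallel, intermolecular-only
  hybridisation with both footprint endpoints paired, computed by a
  prefix-minimum DP per footprint end;
* results are memoised per (query, target), which matters because the seed
  features evaluate many repeated unpaired runs.

If no energetically favourable site exists the result is (0, 0, empty site, 0).

## ViennaRNA adapter

The `external` engine drives the ViennaRNA Python bindings with options
equivalent to `--noLP -d2`, validates and logs the engine version, and
raises a named backend error if the bindings are absent. Sampling uses the
bindings' stochastic backtracking (`uniq_ML` mode) seeded via `init_rand`.
Interaction energetics scan target windows with `duplexfold` and price each
footprint by a hard-constrained partition function, mirroring the built-in
definition. `verify_reference_fold` checks the adapter against a published
UTR free energy when the user supplies the sequence. All downstream modules
take an engine argument and depend only on this contract, never on engine
internals.

## Candidate library

Candidates are concatenations of k ≥ 1 non-overlapping substrings ("parts",
each ≥ 2 nt) of the reverse complement of the target UTR, in their order of
occurrence, with total length drawn from {20, 30, 40} nt. The sampling
scheme (the composition process itself is a design choice): total length
uniform over the permitted lengths; k uniform on 1..min(6, L/2); the integer
composition of L into k parts uniform by stars-and-bars; the placement of
the parts in the reverse complement uniform over feasible placements.
"Different parts" is read conservatively as non-overlapping intervals.
Duplicates are rejected against a hash set (cap: 1000 × the requested count,
then an error reporting the attained number). A DP verifier that re-derives
a valid ordered decomposition for any sequence is part of the public API
and of the test suite.

## Feature conventions

* **Coordinates** are 0-based, half-open everywhere.
* **ETS/EIS** average, over 100 Boltzmann-sampled tiRNA structures (the
  ensemble treatment of the seed step), the minimum over that structure's
  maximal unpaired runs of e_total and e_interaction respectively. Runs
  shorter than 3 nt are skipped — under the built-in model's minimum-loop
  geometry shorter runs cannot nucleate a duplex. A structure with no
  qualifying run contributes 0 (logged).
* **PT** counts base *pairs* joining the halves [0, ⌊L/2⌋) and [⌊L/2⌋, L)
  (a pair is one binding event, not two bound nucleotides); for odd L the
  middle nucleotide belongs to the 3′ half.
* **PAU and RBS coverage** are computed from ensemble base-pair probability
  matrices, not single MFE structures: w_i, the probability that context
  position i is bound by the tiRNA, is the inter-strand column sum of the
  tiRNA–context dimer matrix; PAU = Σ w_i·u_i / Σ w_i with u_i the context
  monomer unpaired probability (0 with a warning when the tiRNA binds
  nowhere); RBS5/RBS11 are means of w_i over windows of half-width 2 and 5
  around the RBS centre, truncated at the context ends with the truncated
  length as denominator.
* **C_RBS** is the probability-weighted mean context position bound by the
  anti-Shine-Dalgarno fragment in an anti-SD/context cofold, rounded half
  toward the CDS. The default anti-SD, `ACCUCCUUA` (reverse complement of
  the consensus AAGGAGGU with a flank), is organism-specific and
  config-overridable; C_RBS may also be supplied directly, which skips the
  anti-SD cofold entirely.
* **Reproducibility.** The feature table derives one child seed per
  candidate from (master seed, row index) via `numpy.random.SeedSequence`,
  so tables are byte-identical across runs and independent of evaluation
  order. Per-candidate failures become NaN rows with recorded reasons.

## Feature pruning

Pearson correlations on complete rows; constant columns get correlation 0
with a warning. Features are grouped as connected components of the
|PCC| > 0.75 graph — a deliberate convention (correlation is not
transitive; components make the outcome order-independent, and the chain
case is tested explicitly). One representative per component is retained,
chosen by a preference list defaulting to FAA, FAB, EIS, PAU, RBS11, PT and
then alphabetically. Pruning is idempotent on the retained submatrix.

## Design of experiments

The default design is the regular 2^(6−2) fraction with the standard
minimum-aberration generators E = ABC, F = BCD (defining relation
I = ABCE = BCDF = ADEF, resolution IV: main effects clear of two-factor
interactions), plus two all-zero centre points — 18 runs. The generator
group is expanded symbolically; a generator set whose shortest word is
below the requested resolution is rejected with the offending word named.

Raw features map to coded units by centring/scaling on the 0.1/0.9 library
quantiles (type-7 linear interpolation, stated in output metadata), after
multiplying FAB and EIS by −1 so that "more repressive" is the high coded
level; values outside [−1, 1] are expected in the library tails. The
quantile-midpoint definition of the centre point is used throughout.

Candidates are matched to design rows by the residual sum of squares
between the coded design point and the candidate's scaled features —
greedily in run order without replacement by default, or as a global
minimum-cost assignment (`linear_sum_assignment`) in `--optimal` mode.
The achieved mean RSS depends entirely on library size and target; it is
reported, not asserted.

## Expression normalisation

(FP/OD)_corrected = (FP − FP_bg)/(OD − OD_bg), with OD_bg from medium
blanks and FP_bg from a no-fluorophore control strain; wells with
OD ≤ OD_bg are flagged and excluded, never silently dropped. Relative
expression is 100 × mean(with)/mean(without) over replicates — a ratio of
means, since the defining relation is written on single corrected values —
with the replicate standard deviation propagated by the delta method. Both
conventions are recorded in the output metadata.

## Regression models

**Log-linear OLS.** log₁₀(Y) regressed on raw (unprocessed) FAB via
statsmodels, with a normal-theory 95% confidence band and slope inference;
non-positive responses are rejected with the offending rows listed.

**Kernel PLS.** The covariance-recursion ("improved kernel") algorithm of
Dayal & MacGregor: works entirely from X'X and X'y, deflating only X'y;
scores, loadings and per-component-count coefficient vectors are recovered
from the recursion. (The NIPALS and kernel variants agree in exact
arithmetic; an independent NIPALS implementation guards the coefficients in
the tests, and full-rank PLS is checked to equal OLS.) Predictors are
centred and scaled by the sample standard deviation; the response is
centred but not scaled — a literal reading of "predictors were scaled".
When X'y deflates to numerical zero the model is truncated at the realised
number of components (an error in strict mode).

**Model selection.** Leave-one-out RMSEP over 1..A_max components with
centring/scaling recomputed inside each fold (no leakage); the global
RMSEP minimiser is chosen, ties toward fewer components.

**Train/validation split.** Records ordered by mean response, cut into 3
equal strata (remainder to the lower strata), validation members drawn
uniformly per stratum to a 5:1 ratio — 36 records give 30/6 with 2
validators per stratum, 18 give 15/3.

**Goodness of fit** is model efficiency, R² = 1 − Σ(o−p)²/Σ(o−ō)²
(Nash–Sutcliffe form; negative when the model is worse than the mean), the
primary metric wherever an R² is reported.

## Synthetic data: what it shows and what it does not

The generators produce deterministic toy inputs with known ground truth:

* **Toy UTRs** — i.i.d. sequences at a requested GC content with one
  consensus SD motif (AGGAGG) ending 7 nt upstream of an AUG-initiated
  50-nt CDS prefix; the motif is guaranteed unique in the context.
* **Responses** — y = 10^(β₀ + Σβ_m·x_m + ε) with a chosen coefficient
  vector and log-scale noise, clipped to (0, 100]. The default pipeline
  truth (positive FAB coefficient ≈ 0.04 log₁₀ %/kcal·mol⁻¹, smaller
  negative FAA/PAU/PT/RBS11 contributions) encodes the expected repression
  logic: stable tiRNA–UTR duplexes, accessible targets and occluded RBS
  lower expression.
* **Plate tables** — FP/OD wells (with blanks and no-FP controls) whose
  normalisation recovers prescribed truths exactly at zero noise.
* **Latent-factor problems** — X = T·Lᵀ exactly rank 4 by default
  (orthonormal loadings, latent scales 5/4/3/2), y loading on all four
  directions with noise sd 0.15; these defaults make the recoverable
  dimension unambiguously 4, which is what the dimension-recovery study
  measures.

Passing tests on these data establish the *correctness of the machinery* —
exact folding, feature identities, design geometry, estimator behaviour —
under a simplified energy model and an idealised response process. They do
not establish that real riboregulators follow the simulated coefficients,
that the built-in energies predict in-vivo structure, or that measured
repression spans the simulated range; those are properties of the wet-lab
system, reachable only by supplying real sequences (via the ViennaRNA
engine) and measured plate data to the same interfaces.

## Problem sizes and runtime choices

The test suite and the acceptance script run a 60-nt toy UTR (110-nt
folding context), libraries of 60–500 candidates, 100-structure ensemble
averages (10,000 where a sampled mean is compared with an exact
expectation), 2,000-sequence enumeration sweeps for engine exactness,
50–100 replicates for the recovery studies and 300–1,000 for CI coverage —
sizes at which the exact oracles remain cheap while every estimate is
stable. The demonstration pipeline measures each selected candidate against
two contexts (the full toy UTR and a 5′-truncated variant), mirroring the
two-target layout that doubles 18 selections into 36 modelling records.

## Known limitations

* The built-in energy model has no stacking, loop or dangle terms; its
  energies are structural-combinatorial, not calorimetric.
* Pseudoknots, kinetic folding and 3D structure are out of scope, as are
  Hfq-dependent sRNA features, RNase-site annotation and transcriptome-wide
  off-target screening.
* The interaction scan bounds the site width at 25 nt; bulged duplexes
  wider than that are not considered.
* Candidate generation keeps parts non-overlapping ("different parts" read
  conservatively as disjoint intervals of the reverse complement).
* The greedy design matching is order-dependent by construction; the
  optimal mode removes this at the cost of assigning all runs jointly.
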