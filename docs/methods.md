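# Methods

## The modeling problem

Given a table of nitrogen heterocycles with measured Hs-NMT IC50 values
(µM), the pipeline fits a small multiple linear regression of
pIC50 = −log₁₀(IC50 · 10⁻⁶) on a handful of 3D molecular descriptors chosen
from a large candidate pool, and judges that model by internal
cross-validation, response scrambling, genuine external prediction and an
applicability domain. The design goal is a model that is simultaneously
predictive and interpretable; every stage of the published protocol is
implemented as an importable, separately testable function.

## Structure preparation

Molecules enter as SMILES (CSV/SMI) or as pre-computed 3D SDF. Hydrogens are
always made explicit before embedding because three of the five model
descriptors count hydrogen atoms. One conformer is generated with RDKit's
ETKDGv3 at a fixed seed and relaxed with MMFF94 (default 1000 steps); MMFF94
also supplies the partial charges used by the charge-binned surface
descriptors. Multi-fragment inputs keep the largest fragment (salt
stripping, logged). Amines are used in the neutral form as written in the
input SMILES; no tautomer or protonation enumeration is attempted.

Exact reproduction of any particular third-party geometry is not a goal —
conformers are software- and seed-dependent — so the contract is
determinism: identical input and seed give identical coordinates, charges
and descriptors, and re-minimizing an optimized conformer moves the MMFF94
energy by less than 10⁻³ kcal/mol.

## Descriptors

**Per-atom SASA.** Shrake–Rupley quadrature: each atom carries a
golden-spiral point set on the sphere of radius r_vdw + r_probe (Bondi
radii, probe 1.4 Å); the accessible fraction of points times the sphere area
is the atom's SASA. The default density of 960 points/atom mirrors the
"high-accuracy" dot-density level of common surface tools and is
configurable (`SasaConfig.n_points`, floor 100). Exactly coincident
equal-radius atoms are collapsed to a single sphere (degenerate-input rule);
a coincident smaller sphere is naturally buried. Tests compare against an
independent random-direction point-rejection implementation at 10× density;
agreement is within 1 % of each atom's sphere area (the natural scale of
quadrature error).

**Named descriptors.**

* `all_HASA2` — sum of SASA over atoms with partial charge in
  [+0.10, +0.20] e (window closed on both ends).
* `C_AbSA` — sum of SASA over carbon atoms. The source literature describes
  this quantity once as carbon surface area and once as a SASA−MSA
  difference; the two readings conflict, and the carbon-sum reading matching
  the descriptor's name is implemented. The alternative reading would
  require a molecular-surface (zero-probe) calculation and is noted here
  rather than guessed at.
* `fNH4B` — hydrogens whose *nearest* nitrogen is exactly 4 bonds away.
* `flipoH3B` — hydrogens whose nearest lipophilic atom is exactly 3 bonds
  away. Lipophilic atoms (not defined in the source) follow standard
  pharmacophoric typing: carbons not bonded to N/O or to a formally charged
  atom, halogens, and uncharged divalent sulfur; the mask is a public
  function so the typing can be audited or replaced.
* `fringNH2A` — hydrogens whose nearest ring nitrogen lies in the
  [1.0, 2.0) Å shell (so a covalent N–H at ~1.01 Å counts; an H within
  1 Å of some other ring N is excluded).

All "exactly k bonds from the nearest center" semantics reduce to
min-distance binning, which makes the published exclusion clauses ("unless
simultaneously closer to another center") automatic. Distance intervals are
half-open at the top, [a, b), to keep bins disjoint; whether the original
descriptor software used open or closed bounds at 1.0/2.0 Å is unstated, and
this choice is fixed and documented rather than tuned. Bond distances are
shortest paths in the bond graph with orders ignored.

**Pool families.** The full published pool (>29 000 descriptors) is neither
available nor needed; the generator builds a realistic ~106-column pool:
simple counts, per-element SASA sums, charge-binned SASA and atom counts on
a width-0.10 e grid spanning [−0.5, +0.5], topological frequencies for six
center classes × bond shells 1–8, and geometric frequencies for four center
classes × 1 Å shells up to 5 Å. Column names follow the grammar above and
each carries provenance (family + parameters).

## Feature selection

**Objective (OFS).** Zero-variance columns go first, then columns whose
modal value covers ≥ 95 % of molecules, then greedy |R| > 0.90 pruning that
repeatedly removes one column of the worst remaining pair. Tie-break when a
pair exceeds the cutoff: drop the column less correlated with the response
if a response is supplied, else the later column in name order —
deterministic either way. The exchange workflow runs OFS unsupervised (no
response) on the full pool, so no activity information crosses the split.

**Subjective (GA-MLR).** Fixed-cardinality subset search: tournament
selection (size 2), uniform crossover on the membership mask repaired back
to the model size, single-member swap mutation (rate 0.05), elitism of one,
population 200, generations 10 000 by default (the published run count);
all knobs sit in `GAConfig`, and tests/acceptance use smaller populations
and generation counts because the planted problems they pose converge in
well under a hundred generations. Fitness is Q²LOO of the OLS fit — the
same function the validation module exports, so search and report cannot
disagree — computed via the hat-matrix identity with fitness −∞ for
singular designs. Fitness values are memoized per subset, making long runs
cheap once the population converges. An exhaustive enumerator with the same
ranking key serves as the reference search for pools where C(p, k) ≤ 10⁶.

**Breaking point.** The published protocol picks the model size at the elbow
of the Q²-vs-size curve by eye; here the rule is quantified: the smallest
size s where the next marginal gain falls below a configurable fraction
(default 0.25) of the preceding gain. A curve with no elbow returns the
largest size with a warning; Q² dips are logged, not fatal.

## Validation statistics

Fitting: R², R²adj, RMSE, MAE, s, F, Friedman LOF
(RSS/n)/(1−(p+1+d·p)/n)² with smoothing d = 0.5 by default — the published
LOF values are not reproducible without the original tool's exact
parameterization, so d is exposed and LOF is reported but never gated on.
Lin's CCC uses population moments. Kxx is Todeschini's multivariate K
computed from the eigenvalues of the descriptor correlation matrix,
Σ|λⱼ/Σλ − 1/p| / (2(p−1)/p); ΔK appends the response column.

Internal validation: Q²LOO = 1 − PRESS/TSS with LOO residuals from the
hat-matrix identity (an explicit refit loop is kept as the test oracle, and
points with leverage ≈ 1 fall back to it); Q²LMO averages, over 2000
repetitions with 30 % of objects left out, 1 − Σ(y_out−ŷ)²/Σ(y_out−ȳ_train)²;
Y-scrambling refits after permuting the response (default 2000 repetitions,
seeded) and reports mean R² and Q².

External validation: Q²F1 (training-mean centering), Q²F2 (external-mean
centering, always ≤ Q²F1), Q²F3 (PRESS/n_ext scaled by training TSS/n_train),
CCCext, and the Golbraikh–Tropsha block: origin-regression slopes
k = Σyŷ/Σŷ² and k′ = Σyŷ/Σy², the corresponding Ro²/R′o², and
r²m = r²(1 − √|r² − Ro²|) in both directions.

Applicability domain: leverages from the training design's projection
matrix (external points scored against the same (ZᵀZ)⁻¹), warning cutoff
h* = 3(p+1)/n, standardized residuals = residual/s with the conventional ±3
outlier band (the source states no cutoff).

The acceptance check evaluates the published rule set verbatim and returns
per-rule verdicts; a report missing any gated statistic raises with the
missing field names.

## Exchange workflow

The dataset is split into two near-equal halves; the default assignment
sorts by activity and alternates, so both halves span the full potency range
(a seeded random split is also available — the original assignment mechanism
is unpublished). Each arm selects on its training half, fits, and validates
on the other half; the two arms' top descriptor sets are intersected into a
consensus note. The two published models are interpreted as the two arms of
this exchange (their printed RSS/RMSE pairs are consistent with 155- and
154-molecule training halves of 309), without asserting which half produced
which. The published equations ship as `MODEL_1`/`MODEL_2` fixtures for
prediction; predictions are affine in the descriptors, and an optional
leverage argument yields an in-domain flag against that model's h*.

## Synthetic data

`gen_descriptor_dataset` emulates the statistical structure the selection
and validation stages assume: an iid standard-normal informative block, a
sparse linear response y = X[planted]·β + N(0, σ²), and declared degenerate
columns (constants, 96 %-modal near-constants, ×2 duplicates with optional
jitter to probe both sides of the |R| = 0.90 cutoff). Defaults — 100
molecules, a 20-column pool, a 3-descriptor signal with β = (1.0, −1.5, 2.0)
and σ = 0.1 — are the high signal-to-noise regime in which subset recovery
has a unique right answer; the GA/exhaustive equivalence battery varies n
over 60–120 at those settings. What passing these tests shows is that the
machinery (filtering, search, statistics) is correct; it does not show that
a five-descriptor model is recoverable from any particular real assay, where
descriptors are collinear, the signal is weaker, and the noise is not
Gaussian. `toy_molecules` supplies hand-enumerable micro-molecules (with
expected frequency-descriptor counts derived by path enumeration) and the
ten published example compounds with their IC50/pIC50 values.

## Numerical choices and limitations

* LOO via the hat matrix is exact for OLS; equality with the refit loop is
  asserted to 10⁻¹⁰ in tests.
* OLS fits go through statsmodels; half-widths are two-sided 95 % t
  intervals, matching the "(±)" convention of published equations.
* Singular or near-singular subset designs are gated by a Cholesky check on
  the normal equations and scored −∞ in the search.
* pIC50 is computed at full precision and rounded to 3 decimals only for
  table output.
* Published full-dataset statistics (R²tr = 0.788 etc.) cannot be recomputed
  here: they require the full 309-compound appendix and the original
  conformer/descriptor software. What is reproduced instead are the exact
  arithmetic identities among the printed numbers (RMSE = √(RSS/n), s,
  R²adj, RMSEcv/RMSEext from PRESS, h*) at the printed split sizes, plus the
  behavioral properties above on synthetic data at stated sizes
  (50 GA instances, 500 recovery replicates, 20 LOO instances — all chosen
  to run in seconds).
* The SASA-based descriptor values of this stack are internally consistent
  but not interchangeable with those of other surface implementations;
  cross-package absolute agreement is out of scope.
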