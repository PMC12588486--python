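# Methods

## Model

A first-order dynamic Bayesian network over k continuous variables is
represented as a DAG over 2k slice nodes. Folding a length-T series at
Markov order p = 1 yields n = T − 1 transition rows pairing each
observation (slice 0) with its lag (slice 1); the shift consistency
`column(v, slice s)[r + s] == column(v, slice 0)[r]` is the defining
invariant. Arcs may only terminate in slice 0 — lag → present
(inter-slice) and present → present (intra-slice) arcs are learnable,
everything else is structurally blacklisted. This is the standard
transition-network convention: arcs into the past have no causal
reading, and the lag slice's own dependence structure belongs to the
previous transition window.

Local models are linear-Gaussian: node X with parent set Pa is fitted by
OLS with intercept, residual variance taken as RSS/n (maximum-likelihood
denominator, since the criteria penalize the maximized likelihood). The
network log-likelihood decomposes as a sum over all 2k nodes; parentless
lag nodes enter as marginal Gaussians. Each node contributes
|Pa| + 2 parameters (coefficients, intercept, variance). Scoring the
full folded network, rather than the slice-0 conditionals alone, is a
deliberate scope choice: it makes scores comparable across structures
with any parent configuration and matches the magnitude conventions of
common BN software, which scores every column of the folded table.

Fits solve the centered Gram system cached on the folded dataset, so a
node fit costs O(d³) independent of n after one O(n·k²) pass. Exact
collinearity raises a singular-fit error naming the offending columns;
an exact functional dependence (zero residual variance) is clamped to
1e−12 with a warning instead of producing an infinite log-likelihood.

## Score criteria

All eight criteria are decomposable penalized log-likelihoods reported
on the higher-is-better scale ln L − (c/2)·k_params, where c is the
per-parameter factor on the conventional −2 ln L + c·k scale: AIC 2,
KIC 3, AIC4 4, CAIC ln n + 1, BIC ln n, BICadj ln((n+2)/24), HBIC
ln(n/2π), BICQ ln n − 2 ln(q/(1−q)). n is the folded row count (the
likelihood's sample size), not the raw series length. BICQ equals BIC
at q = 0.5 exactly (identical floating-point arithmetic, so paired runs
are bit-identical) and penalizes harder for q < 0.5; the default
q = 0.25 adds 2 ln 3 ≈ 2.197 per parameter on top of BIC. BICadj's
penalty factor is negative for n < 22 — it then rewards complexity;
this is allowed but warned about.

## Restrict phase

Conditional independence is tested by the Fisher z-transform of the
partial correlation, computed from the inverse of the relevant
correlation submatrix (the unconditional case uses the raw correlation
directly, which also handles singular perfectly-correlated pairs).
Tests with n ≤ |Z| + 3 are refused and reported as independence with a
warning. IAMB runs per slice-0 target over all other folded columns:
the grow phase repeatedly admits the candidate with maximal Gaussian
conditional mutual information −½ ln(1 − r²) given the current blanket,
provided its test rejects at α, re-ranking all remaining candidates
after each admission; the shrink phase removes members independent of
the target given the rest. Ties break deterministically by column name.

The default test level is α = 0.05. Note the operating characteristic:
at any fixed α, each non-member survives into the blanket with
probability ≈ α no matter how large n is, so the probability of an
*exactly* correct blanket is ≈ (1−α)^m for m irrelevant candidates
(~72% for m = 7 at α = 0.05, ~96% at α = 0.01). Consistency therefore
requires α to shrink with n; the large-sample recovery test in the
suite runs at α = 0.01 accordingly, while also asserting that the
default level never misses a true member at n = 10,000.

Blanket symmetrization uses the OR rule: an arc u → v allowed by the
temporal pattern survives iff u ∈ MB(v) or v ∈ MB(u). Both orientations
of a claimed pair remain candidates; the score phase settles direction.
The stricter AND rule is available (`rule="and"`), where a node without
a computed blanket (lag slices, which are never targets) cannot veto.

## Maximize phase

Tabu search starts from the empty graph (deterministic and
reproducible; the empty graph is always feasible). The neighborhood is
all single-arc adds, deletes and reverses that respect the blacklist
and acyclicity; only intra-slice arcs can form cycles, so the cycle
check walks slice-0 ancestors only. Reversal of an inter-slice arc is
never legal (the reverse would point backward in time). Each applied
move pushes its inverse's (operation, arc) attribute onto a
fixed-length tabu list (default 10); the best non-tabu move is taken
even when it worsens the score, and a tabu move is taken if it strictly
improves the global best (aspiration). Search stops after 10
consecutive iterations without improving the incumbent or 2000
iterations. Local scores are memoized per (child, parent set), and move
deltas touch only the affected child terms, so iterations are cheap.
On every random 3-variable instance tested the search attains the
exhaustive-enumeration optimum; this is a property check, not a
guarantee — tabu search is a heuristic.

## Simulator and benchmark design

Data come from stationary VAR(1) processes x_t = C·x_{t−1} + e_t with
diagonal Gaussian noise. Three coefficient matrices (k = 5, 7, 10) are
built in; each parse is checksummed at import against its reference
eigenvalue spectrum (5e−3 modulus tolerance), and simulation refuses
non-stationary processes (spectral radius ≥ 1). The recursion starts at
the zero vector and discards 200 burn-in steps by default, so retained
rows are effectively draws from the stationary law.

The benchmark's defaults are the study conditions: 30 replicates, each
an independent T = 1000 simulation with residual variances drawn
uniformly on [1, 5] (fresh draw per replicate by default;
`variance_mode="config"` freezes one draw across replicates), nested
prefixes of 100/500/1000 rows, p = 1 folding, IAMB restriction at
α = 0.05, one Tabu run per criterion, and SHD against the structure
implied by the nonzero entries of C (no intra-slice arcs in truth —
noise is diagonal). Every learned structure is re-scored under a single
common criterion (default Gaussian BIC; `eval_mode="own"` scores each
learner by its own criterion). Per-replicate randomness derives from
SeedSequence([master_seed, replicate]), so results are reproducible and
criteria see identical data within a replicate — the q-sweep and
pairwise comparisons are paired by construction.

SHD is computed on directed graphs as-is (additions + deletions +
reversals, a reversal costing 1), not on CPDAG equivalence classes: the
temporal blacklist compels inter-slice orientations and the true
structure has no intra-slice arcs, so class-collapsing would be a no-op
for the truth, but comparisons against CPDAG-based SHD implementations
should note the difference.

Statistical summaries: SE = sd/√R per (criterion, n) cell; pairwise
mean differences use the per-replicate SHD averaged over the three
subset sizes as the within-subject measure, with paired t-tests
Bonferroni-multiplied by the number of pairs (identical columns report
p = 1 exactly); the repeated-measures ANOVA uses the textbook
within-subject decomposition (df m−1 and (m−1)(R−1)) with
Greenhouse–Geisser ε from the double-centered covariance of the
measures, clipped to [1/(m−1), 1]. Shapiro–Wilk normality screening is
delegated to scipy. The ANOVA and pairwise routines are cross-checked
in the test suite against pingouin and direct arithmetic.

## What the generator does and does not emulate

The simulator produces exactly the benchmark's data-generating process:
linear dynamics, Gaussian diagonal noise, stationarity, no missingness,
no regime changes. Real systems-biology series violate most of this —
nonlinearity, non-Gaussian noise, contemporaneous confounding,
non-stationarity, measurement error — so passing benchmarks here
demonstrates correct behavior *under the model's assumptions*, not
performance on arbitrary real data. Within those assumptions the
temporal blacklist plus IAMB restriction makes recovery markedly easier
than unconstrained BN learning on the folded table: mean SHD for the
5-variable process at n = 100 is ≈ 1.7 (BICQ) to 2.3–2.6 (AIC) and
*decreases* with n, whereas learners that admit arcs among lag-slice
nodes accumulate extra arcs (lag nodes are marginally dependent under
the stationary law) and report SHD that grows with n. Heavier penalties
(BICQ at q = 0.25) dominate lighter ones (AIC family) at every sample
size, and the mean paired SHD gap AIC − BICQ at the full design is
≈ 1.1 arcs.

## Numerical and interface choices

- Column naming `v_t_s` with slice 0 = present; input variable names are
  sanitized (non-alphanumerics → underscore) with collisions an error.
- Structures serialize to bracket model strings
  (`[A_t_0|A_t_1:B_t_1][A_t_1]…`); parse/serialize round-trips exactly.
- "Nonzero" in truth derivation is exact inequality with 0 — reference
  matrices carry exact zeros.
- Score ties in the search break lexicographically by (operation, arc),
  making every run deterministic for fixed inputs.
- Benchmark replicates that fail are excluded and counted in the
  manifest, never imputed.

## Known limitations

- Only lag-1 structures are learned (the folding supports p > 1 and the
  temporal pattern generalizes, but the benchmark and simulator are
  VAR(1)); noise covariances are diagonal.
- No parameter learning beyond the OLS fits needed for scoring, and no
  inference/prediction from a fitted network.
- Tabu search offers no optimality guarantee beyond the empty-graph
  lower bound; random restarts are not implemented.
- SHD on directed graphs (see above) and exact-zero truth thresholds
  limit comparability with CPDAG-based toolchains.
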