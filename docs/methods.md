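# Methods

## The generative model

One genome is a sequence of `M` fixed-width bins (100 bp by default). Three
binary chains run along it:

- `mc` — cancer-cohort methylation: first-order Markov with initial
  probability `tau_c = P(mc_1 = 1)` and row-stochastic transition `A_c`.
- `mn` — normal-cohort methylation: conditioned on its own previous state
  *and* on (`mc_i`, `dm_i`) through the mixture transition
  `alpha * A_n[mn_{i-1}, mn_i] + (1 - alpha) * C(mn_i | mc_i, dm_i)`, where
  the coupling `C` is the indicator `1{mn = mc XOR dm}`. At bin 1 the
  chain's initial pmf stands in for the transition row.
- `dm` — differential status: first-order Markov (`tau_dm`, `A_dm`),
  carrying no emission of its own.

Counts: for each bin and sample, a categorical draw over count categories
`0..K` from the cohort's state-conditional pmf `B[state]`, replicates
i.i.d.; raw counts above `K` are collapsed into category `K`. An optional
additive Poisson noise term models nonspecific background reads.

The coupling table is the hard 0/1 indicator. Soft tables (e.g. 0.9/0.1)
are sometimes convenient for initialization experiments, so an optional
softening `coupling_eps` (default 0, i.e. the model as defined) replaces
0/1 with `eps`/`1-eps`.

## Inference

**First layer.** Each cohort's `(tau, A, B)` is estimated by Baum-Welch and
then frozen. The replicate-product emission means the per-bin sufficient
statistic is the category histogram `H[i, k]` (how many samples fell in
category `k`), and the emission update is
`B[d, k] ∝ sum_i gamma[i, d] * H[i, k]`. Label switching is resolved by
declaring state 1 the state with the higher emission mean. Note that when
`alpha < 1` the marginal normal-cohort chain is *not* the free Markov chain
`A_n`; Baum-Welch on normal data estimates the marginal dynamics, and that
estimate is what the second layer consumes. This is deliberate and
reproduces the reference procedure; the small downward shift of the normal
`P(0|0)` estimate relative to its generating value is expected and grows as
`alpha` shrinks.

**Second layer.** With the cohort HMMs frozen, `Psi = {tau_dm, A_dm, alpha}`
is fit by EM over the joint chain of 8 states `(dm, mc, mn)`, indexed
`4*dm + 2*mc + mn`. The E-step is a scaled forward-backward pass (per-bin
normalizers; data log-likelihood is the sum of their logs plus the per-bin
emission shifts). `tau_dm` updates to the posterior probability that bin 1
is differential; `A_dm` rows update as expected dm-transition counts over
expected dm-occupancies, both read off the pairwise posterior mass
aggregated over bins (the map from joint-state pairs to dm pairs does not
depend on the bin, so the aggregate is sufficient).

**The alpha update.** Collecting the mixture terms, the expected
complete-data log-likelihood as a function of `alpha` is
`Q(alpha) = sum_g w_g * log(alpha * a_g + (1 - alpha) * b_g)` with one group
`g` per (previous `mn`, current joint state) pair plus bin-1 groups using
the initial pmf; `a_g` is the free-transition leg, `b_g` the coupling leg,
`w_g` posterior mass. `Q` is concave (`Q'' = -sum w (a-b)^2 / (.)^2 <= 0`),
so Newton-Raphson from the current value converges quadratically; steps are
confined to `[1e-6, 1 - 1e-6]`, a boundary gradient check accepts boundary
optima, and a bounded golden-section search is the fallback if curvature
degenerates. A published closed form for this derivative exists only in a
typographically corrupted form, so the gradient here is derived directly
from the mixture expression and validated in the tests against a dense grid
search (resolution 1e-4, agreement required within 1e-3).

**Decoding.** Viterbi over the 8-state chain with ties broken toward the
lower state index; per-bin soft score `P(dm_i = 1 | X)` is the posterior
mass on the four `dm = 1` states. Because adjacent bins share the dm state,
a locally uninformative bin inside a differential stretch is still called
differential — the neighbor-smoothing behavior that per-bin tests lack.

## Numerical choices

- All emission pmfs and transition/initial probabilities are floored at
  1e-10 before logs inside EM; the exact scalar API (`emission_logpmf_bin`,
  `complete_data_loglik`) leaves zeros as `-inf` so impossible
  configurations are visible.
- Convergence: absolute log-likelihood change below 1e-4 (both layers);
  `max_iter` 100. At 200,000 bins this resolves the weight to ~1e-3.
- Monotonicity of the EM trace is asserted in tests with slack 1e-6 to
  absorb float accumulation at log-likelihood magnitudes of ~1e6.
- Chains are treated as one contiguous sequence; multi-chromosome inputs
  are concatenated in file order (the transition across a boundary is a
  single negligible factor at genome scale).
- Default second-layer initialization: all transition matrices
  `[[0.9, 0.1], [0.1, 0.9]]`, `tau_dm = 1e-5`, `alpha = 0.01`; the
  first-layer default starts from a median split of per-bin mean counts
  (bins above the median seed the methylated state) because transition
  seeds alone leave the emission labeling ambiguous.

## The simulator and what it does (not) capture

`simulate` draws `dm`, then `mc`, then `mn` from the mixture, then counts —
exactly the generative law the model assumes. Defaults are the reference
study conditions: 200,000 bins, 10 samples per cohort, self-transitions
0.97/0.71 (differential), 0.76/0.97 (cancer), 0.66/0.92 (normal), initial
state-1 probability 1e-5 per chain, the reference emission pmfs over
categories 0..5, and no Poisson noise. The noise rate for the additive
Poisson term is not part of the stated conditions, so runs that reproduce
reference numbers use 0; `poisson_lambda=0.5` is a reasonable nonzero
choice for robustness experiments.

Because data are drawn from the model's own law, passing recovery tests
shows correctness of the inference machinery, not robustness to real
MBDCap-seq artifacts: no GC/mappability bias, no copy-number distortion of
counts in tumors, no inter-sample depth variation (all samples share one
emission pmf), and no read-level effects. Real-data use should precede this
model with depth normalization of the binned counts.

## Benchmark design

The evaluation harness compares three rankings of bins against simulated
truth: the model's posterior `P(dm=1|X)`, and `1 - p` from per-bin Welch
t-tests and Wilcoxon rank-sum tests (exact enumeration for small tie-free
groups, tie-corrected normal approximation otherwise). Curves and
trapezoidal AUCs come from scikit-learn; the ROC AUC therefore equals the
Mann-Whitney statistic, which the tests exploit as an independent identity
check. Two sweeps are built in: the differential chain's state-1
self-transition at 0.9/0.8/0.7 (weight held at 0.3519 — the weight printed
with the reference simulation parameter set) and the weight at 0.1/0.2/0.3
(reference transitions). Benchmarks run at 20,000 bins, a scale at which
AUC standard errors are ~0.005 while a full sweep stays under a minute.

## Known limitations

- The differential state is binary; hyper vs hypo direction is annotated
  post hoc from the decoded `(mn, mc)` pair, and a `dm=1` bin can decode
  with `mn == mc` when `alpha > 0` (labeled `inconsistent`).
- EM finds a stationary point, not a guaranteed global optimum; the
  initialization-robustness tests show insensitivity across the tested
  inits, not global convergence.
- The permutation test rotates the genome-wide call vector (circular
  shift), preserving run-length structure but assuming approximate
  stationarity of the background differential rate along the genome.
- Gene/region rate summaries support two denominators (bins of the region
  class vs bins of the chromosome) because published per-class rates are
  ambiguous about normalization; pick explicitly.
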