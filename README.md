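# bimmer

A two-layer hidden Markov model for calling differential DNA methylation
regions (DMRs) from binned MBDCap-seq read counts, for epigenomics analysts
comparing a cancer cohort against matched normals.

MBDCap-seq enriches methylated DNA; after alignment the genome is summarized
as read counts in consecutive 100 bp bins, one track per sample. The common
two-step approach — call methylation per cohort, then diff the calls — lets
errors from the first step propagate into the second. This package instead
models both cohorts and their difference *jointly* and infers differential
status in one pass.

## Model

Per bin `i` there are three coupled binary hidden states:

- `mn_i`, `mc_i` — methylation status in the normal and cancer cohorts, each a
  2-state Markov chain with a categorical emission over count categories
  `0..K` (replicate samples i.i.d. within a bin, so the bin likelihood is the
  product over samples);
- `dm_i` — differential status, its own Markov chain
  (`tau_dm`, `A_dm`), with `dm_i = 1` meaning `mn_i != mc_i`.

The layers are tied through the normal chain's transition:

    P(mn_i | mn_{i-1}, mc_i, dm_i)
        = alpha * A_n[mn_{i-1}, mn_i] + (1 - alpha) * P(mn_i | mc_i, dm_i)

where `P(mn | mc, dm)` is the hard coupling indicator `1{mn = mc XOR dm}` and
`alpha` in [0, 1] weights the chain's own dynamics against the coupling.

Inference: each cohort's HMM (`tau`, `A`, `B`) is trained by Baum-Welch and
frozen; the remaining parameters `Psi = {tau_dm, A_dm, alpha}` are estimated
by EM with an exact scaled forward-backward pass over the 8 joint
`(dm, mc, mn)` states, expected-count updates for `tau_dm`/`A_dm`, and
safeguarded Newton-Raphson for `alpha` (the expected log-likelihood is
concave in `alpha`). DMRs are decoded by Viterbi over the joint chain; the
per-bin soft score is the posterior `P(dm_i = 1 | X)`.

## Worked example

`python examples/01_simulate_and_fit.py` simulates 20,000 bins (10 + 10
samples, true weight 0.3) and recovers the parameters:

```
simulated 20000 bins; 9.5% truly differential

Baum-Welch self-transitions (estimate vs truth):
  normal  P(0|0)=0.6303 vs 0.66, P(1|1)=0.9202 vs 0.92
  cancer  P(0|0)=0.7575 vs 0.76, P(1|1)=0.9710 vs 0.97

EM converged in 45 iterations
  mixture weight alpha = 0.3056 (truth 0.30)
  differential self-transitions = 0.9720/0.7252 (truth 0.97/0.71)

Viterbi per-bin differential-call accuracy: 0.959
```

The normal cohort's estimated `P(0|0)` sits below its generating value
because when `alpha < 1` the marginal normal chain is not the free Markov
chain — part of its dynamics is inherited from the cancer chain through the
coupling; the second-layer EM accounts for exactly this.

`examples/02_benchmark_callers.py` scores the model against per-bin Welch
t-tests and Wilcoxon rank-sum tests (ROC AUC ~0.95-0.99 vs ~0.79-0.91 across
the six reference scenarios), and `examples/03_call_and_annotate.py` merges
calls into regions, labels hyper/hypo direction, and screens per-gene
differential rates with a circular-shift permutation test.

A thin CLI mirrors the workflow:
`bimmer simulate | train-first-layer | fit | call | evaluate | annotate`
(see `bimmer --help`).

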