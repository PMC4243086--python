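"""Baseline differential callers and the PR/ROC evaluation harness.

The comparison methods are per-bin two-sample tests on the raw counts: a
Welch t-test and a Wilcoxon rank-sum test (exact when group sizes are small
and tie-free, otherwise tie-corrected normal approximation).  Rankings from
each method (posterior P(dm=1|X) for the HMM, 1 - p for the tests) are
scored against the simulated truth with precision-recall and ROC curves and
trapezoidal AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from . import em, first_layer, simulate

__all__ = [
    "EvaluationReport",
    "per_bin_t_test",
    "per_bin_wilcoxon",
    "pr_roc_auc",
    "benchmark_scenarios",
    "run_benchmark",
    "parameter_recovery_run",
]


@dataclass
class EvaluationReport:
    """Curves and areas for one score vector against binary truth."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    auc_roc: float
    auc_pr: float
    confusion: dict | None = None


def _counts(x) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(x, "counts", x), dtype=float))


def per_bin_t_test(counts_n, counts_c) -> np.ndarray:
    """Two-sided Welch t-test p-value per bin.

    Bins where both groups are constant get p = 1 when the means agree and
    p = 0 when they differ (the limit of the statistic).
    """
    a, b = _counts(counts_n), _counts(counts_c)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("t-test needs at least 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def per_bin_wilcoxon(counts_n, counts_c) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per bin.

    Uses exact enumeration when both groups are small and tie-free,
    otherwise the tie-corrected normal approximation; fully tied bins get
    p = 1.
    """
    a, b = _counts(counts_n), _counts(counts_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                 method="auto")
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0
    return np.minimum(p, 1.0)


def pr_roc_auc(
    scores: np.ndarray, truth: np.ndarray, hard_calls: np.ndarray | None = None
) -> EvaluationReport:
    """Threshold sweep of a per-bin score against binary truth.

    AUCs are trapezoidal; the ROC AUC therefore equals the Mann-Whitney
    probability that a random positive bin outscores a random negative one
    (ties counted half).  Optional hard calls add a confusion-count dict.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=np.int64)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    fpr, tpr, roc_thr = roc_curve(truth, scores)
    prec, rec, pr_thr = precision_recall_curve(truth, scores)
    confusion = None
    if hard_calls is not None:
        hard_calls = np.asarray(hard_calls, np.int64)
        confusion = {
            "TP": int(np.sum((hard_calls == 1) & (truth == 1))),
            "FP": int(np.sum((hard_calls == 1) & (truth == 0))),
            "TN": int(np.sum((hard_calls == 0) & (truth == 0))),
            "FN": int(np.sum((hard_calls == 0) & (truth == 1))),
        }
    return EvaluationReport(
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=roc_thr,
        precision=prec,
        recall=rec,
        pr_thresholds=pr_thr,
        auc_roc=float(auc(fpr, tpr)),
        auc_pr=float(auc(rec[::-1], prec[::-1])),
        confusion=confusion,
    )


def parameter_recovery_run(
    alpha_true: float,
    seed: int,
    M: int = 200_000,
    n_normal: int = 10,
    n_cancer: int = 10,
    init_alphas: tuple[float, ...] = (0.01,),
) -> dict:
    """One full recovery experiment at reference scale.

    Simulates a dataset with the reference transitions and the given true
    mixture weight, trains both cohort HMMs by Baum-Welch, then runs the
    second-layer EM once per initial weight.  Returns the Baum-Welch
    transition estimates and, per init, the converged second-layer
    parameters.
    """
    config = simulate.SimulationConfig(
        M=M, n_normal=n_normal, n_cancer=n_cancer,
        params=simulate.reference_params(alpha=alpha_true), seed=seed,
    )
    ds = simulate.simulate_dataset(config)
    nres = first_layer.baum_welch(ds.counts_n)
    cres = first_layer.baum_welch(ds.counts_c)
    out = {
        "normal_A": nres.params.A,
        "cancer_A": cres.params.A,
        "fits": {},
        "dataset": ds,
    }
    for a0 in init_alphas:
        init = em.SecondLayerParams(
            tau_dm=1e-5, A_dm=np.array([[0.9, 0.1], [0.1, 0.9]]), alpha=a0
        )
        out["fits"][a0] = em.fit(
            ds.counts_n, ds.counts_c, nres.params, cres.params, init=init
        )
    return out


def benchmark_scenarios() -> list[dict]:
    """The two reference sweeps.

    Transition sweep: the differential chain's state-1 self-transition at
    0.9/0.8/0.7 with the weight held at 0.3519; weight sweep: alpha at
    0.1/0.2/0.3 with the reference transitions.
    """
    scen = []
    for t in (0.9, 0.8, 0.7):
        scen.append(
            {
                "name": f"transition_{t:g}",
                "params": simulate.reference_params(alpha=0.3519, dm_self=(0.97, t)),
            }
        )
    for w in (0.1, 0.2, 0.3):
        scen.append(
            {"name": f"weight_{w:g}", "params": simulate.reference_params(alpha=w)}
        )
    return scen


def run_benchmark(
    scenarios: list[dict] | None = None,
    M: int = 20_000,
    n_normal: int = 10,
    n_cancer: int = 10,
    seed: int = 0,
    init_alpha: float = 0.01,
    return_curves: bool = False,
):
    """Simulate each scenario and score the HMM against both baselines.

    For every scenario a dataset is drawn, the two cohort HMMs are trained
    by Baum-Welch, the second-layer EM is run, and all three methods are
    ranked against the simulated dm truth.  Returns a tidy DataFrame of
    AUCs (and, optionally, the per-method reports).
    """
    scenarios = scenarios if scenarios is not None else benchmark_scenarios()
    rows = []
    curves: dict[str, dict[str, EvaluationReport]] = {}
    ss = np.random.SeedSequence(seed)
    for scen, child in zip(scenarios, ss.spawn(len(scenarios))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        config = simulate.SimulationConfig(
            M=M, n_normal=n_normal, n_cancer=n_cancer, params=scen["params"],
            seed=sub_seed,
        )
        ds = simulate.simulate_dataset(config)
        nres = first_layer.baum_welch(ds.counts_n)
        cres = first_layer.baum_welch(ds.counts_c)
        state = em.fit(
            ds.counts_n, ds.counts_c, nres.params, cres.params,
            init=em.SecondLayerParams(
                tau_dm=1e-5, A_dm=np.array([[0.9, 0.1], [0.1, 0.9]]),
                alpha=init_alpha,
            ),
        )
        posterior = em.forward_backward(ds.counts_n, ds.counts_c, state.params)
        dm_hat, _, _ = em.viterbi_joint(ds.counts_n, ds.counts_c, state.params)
        method_scores = {
            "bimmer": (em.dm_posterior_score(posterior), dm_hat),
            "ttest": (1.0 - per_bin_t_test(ds.counts_n, ds.counts_c), None),
            "wilcoxon": (1.0 - per_bin_wilcoxon(ds.counts_n, ds.counts_c), None),
        }
        curves[scen["name"]] = {}
        for method, (score, hard) in method_scores.items():
            rep = pr_roc_auc(score, ds.truth_dm, hard_calls=hard)
            curves[scen["name"]][method] = rep
            rows.append(
                {
                    "scenario": scen["name"],
                    "method": method,
                    "auc_roc": rep.auc_roc,
                    "auc_pr": rep.auc_pr,
                    "alpha_hat": state.second.alpha if method == "bimmer" else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    return (table, curves) if return_curves else table
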