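"""Generative simulator for the two-layer methylation model.

Emulates the model end to end: a differential chain ``dm`` is drawn first,
the cancer methylation chain ``mc`` follows its own Markov dynamics, the
normal chain ``mn`` is drawn from the alpha-weighted mixture of its own
transition and the coupling indicator, and per-sample read counts are drawn
from the state-conditional categorical pmfs, optionally with additive
Poisson noise.  Defaults reproduce the reference simulation conditions:
200,000 bins, 10 samples per cohort, the printed emission pmfs and
self-transitions (differential 0.97/0.71, cancer 0.76/0.97, normal
0.66/0.92), and no Poisson noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .io import BinnedCounts, read_binned_counts, write_binned_counts
from .params import FirstLayerParams, ModelParams, SecondLayerParams

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "reference_params",
    "REFERENCE_B_NORMAL",
    "REFERENCE_B_CANCER",
    "simulate_dm_chain",
    "simulate_state_chains",
    "simulate_counts",
    "simulate_dataset",
    "make_fixture",
    "load_fixture",
]

#: Reference categorical emission pmfs over count categories 0..5.
REFERENCE_B_CANCER = np.array(
    [[0.9, 0.04, 0.03, 0.01, 0.01, 0.01], [0.26, 0.24, 0.2, 0.18, 0.08, 0.04]]
)
REFERENCE_B_NORMAL = np.array(
    [[0.8, 0.08, 0.07, 0.03, 0.01, 0.01], [0.22, 0.26, 0.20, 0.16, 0.1, 0.06]]
)


def _self_to_matrix(self0: float, self1: float) -> np.ndarray:
    return np.array([[self0, 1.0 - self0], [1.0 - self1, self1]])


def reference_params(
    alpha: float = 0.3,
    dm_self: tuple[float, float] = (0.97, 0.71),
    cancer_self: tuple[float, float] = (0.76, 0.97),
    normal_self: tuple[float, float] = (0.66, 0.92),
    tau: float = 1e-5,
) -> ModelParams:
    """Ground-truth parameter set of the reference simulation study.

    ``*_self`` are the state-0 and state-1 self-transition probabilities of
    each chain; ``tau`` is the (shared, near-degenerate) probability of
    starting in state 1.
    """
    return ModelParams(
        normal=FirstLayerParams(
            tau=tau, A=_self_to_matrix(*normal_self), B=REFERENCE_B_NORMAL
        ),
        cancer=FirstLayerParams(
            tau=tau, A=_self_to_matrix(*cancer_self), B=REFERENCE_B_CANCER
        ),
        second=SecondLayerParams(
            tau_dm=tau, A_dm=_self_to_matrix(*dm_self), alpha=alpha
        ),
    )


@dataclass
class SimulationConfig:
    """Simulation conditions; defaults are the reference study's."""

    M: int = 200_000
    n_normal: int = 10
    n_cancer: int = 10
    params: ModelParams = field(default_factory=reference_params)
    poisson_lambda: float = 0.0
    seed: int = 0
    bin_width: int = 100
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.n_normal < 1 or self.n_cancer < 1:
            raise ValueError("need at least one sample per cohort")
        if self.poisson_lambda < 0:
            raise ValueError("poisson_lambda must be >= 0")

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "n_normal": self.n_normal,
            "n_cancer": self.n_cancer,
            "params": self.params.to_dict(),
            "poisson_lambda": self.poisson_lambda,
            "seed": self.seed,
            "bin_width": self.bin_width,
            "chrom": self.chrom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["params"] = ModelParams.from_dict(d["params"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    counts_n: BinnedCounts
    counts_c: BinnedCounts
    truth_dm: np.ndarray
    truth_mc: np.ndarray
    truth_mn: np.ndarray
    config: SimulationConfig


@njit(cache=True)
def _markov_chain(p1_init: float, A: np.ndarray, u: np.ndarray) -> np.ndarray:
    M = u.shape[0]
    out = np.empty(M, dtype=np.int64)
    out[0] = 1 if u[0] < p1_init else 0
    for i in range(1, M):
        out[i] = 1 if u[i] < A[out[i - 1], 1] else 0
    return out


@njit(cache=True)
def _mixture_chain(
    pi_n1: float,
    A_n: np.ndarray,
    alpha: float,
    eps: float,
    dm: np.ndarray,
    mc: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    M = u.shape[0]
    out = np.empty(M, dtype=np.int64)
    coupled = mc[0] ^ dm[0]
    c1 = (1.0 - eps) if coupled == 1 else eps
    p1 = alpha * pi_n1 + (1.0 - alpha) * c1
    out[0] = 1 if u[0] < p1 else 0
    for i in range(1, M):
        coupled = mc[i] ^ dm[i]
        c1 = (1.0 - eps) if coupled == 1 else eps
        p1 = alpha * A_n[out[i - 1], 1] + (1.0 - alpha) * c1
        out[i] = 1 if u[i] < p1 else 0
    return out


def simulate_dm_chain(
    tau_dm: float, A_dm: np.ndarray, M: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the differential chain: dm_1 ~ Bernoulli(tau_dm), then Markov."""
    if M < 1:
        raise ValueError("M must be >= 1")
    A_dm = np.ascontiguousarray(A_dm, dtype=np.float64)
    return _markov_chain(float(tau_dm), A_dm, rng.random(M))


def simulate_state_chains(
    dm: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mc, mn) given dm: mc Markov, mn from the coupling mixture.

    Bin 1 of mn uses the normal chain's initial pmf inside the mixture.
    """
    dm = np.ascontiguousarray(dm, dtype=np.int64)
    M = dm.shape[0]
    mc = _markov_chain(
        float(params.cancer.tau),
        np.ascontiguousarray(params.cancer.A, dtype=np.float64),
        rng.random(M),
    )
    mn = _mixture_chain(
        float(params.normal.tau),
        np.ascontiguousarray(params.normal.A, dtype=np.float64),
        float(params.second.alpha),
        float(params.coupling_eps),
        dm,
        mc,
        rng.random(M),
    )
    return mc, mn


def _emit(chain, B, n_samples, lam, rng):
    M = chain.shape[0]
    K1 = B.shape[1]
    X = np.empty((M, n_samples), dtype=np.int64)
    for state in (0, 1):
        idx = np.nonzero(chain == state)[0]
        X[idx] = rng.choice(K1, size=(len(idx), n_samples), p=B[state])
    if lam > 0:
        X += rng.poisson(lam, size=X.shape)
    return X


def simulate_counts(
    mn: np.ndarray,
    mc: np.ndarray,
    Bn: np.ndarray,
    Bc: np.ndarray,
    n_normal: int,
    n_cancer: int,
    poisson_lambda: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-sample counts from the state-conditional pmfs (+ Poisson)."""
    Xn = _emit(np.asarray(mn), np.asarray(Bn), n_normal, poisson_lambda, rng)
    Xc = _emit(np.asarray(mc), np.asarray(Bc), n_cancer, poisson_lambda, rng)
    return Xn, Xc


def _grid(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    start = np.arange(config.M, dtype=np.int64) * config.bin_width
    return (
        np.full(config.M, config.chrom, dtype=object),
        start,
        start + config.bin_width,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full generative draw: chains then counts, on a single synthetic
    chromosome with ``bin_width`` bp bins starting at 0."""
    rng = np.random.default_rng(config.seed)
    p = config.params
    dm = simulate_dm_chain(p.second.tau_dm, p.second.A_dm, config.M, rng)
    mc, mn = simulate_state_chains(dm, p, rng)
    Xn, Xc = simulate_counts(
        mn, mc, p.normal.B, p.cancer.B, config.n_normal, config.n_cancer,
        config.poisson_lambda, rng,
    )
    chrom, start, end = _grid(config)
    counts_n = BinnedCounts(
        chrom=chrom, start=start, end=end, counts=Xn,
        samples=[f"normal_{j:02d}" for j in range(config.n_normal)],
    )
    counts_c = BinnedCounts(
        chrom=chrom, start=start, end=end, counts=Xc,
        samples=[f"cancer_{j:02d}" for j in range(config.n_cancer)],
    )
    return SimulatedDataset(counts_n, counts_c, dm, mc, mn, config)


def make_fixture(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Simulate and write a complete on-disk dataset.

    Layout: ``normal/``, ``cancer/`` per-sample BED-like count files, a
    3-column ``truth.tsv`` (dm, mc, mn) and ``config.json``.  Deterministic
    given the seed.
    """
    outdir = Path(outdir)
    ds = simulate_dataset(config)
    write_binned_counts(ds.counts_n, outdir / "normal")
    write_binned_counts(ds.counts_c, outdir / "cancer")
    truth = np.column_stack([ds.truth_dm, ds.truth_mc, ds.truth_mn])
    np.savetxt(
        outdir / "truth.tsv", truth, fmt="%d", delimiter="\t",
        header="dm\tmc\tmn", comments="",
    )
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    return ds


def load_fixture(fixture_dir: str | Path) -> SimulatedDataset:
    """Read back a dataset written by :func:`make_fixture`."""
    d = Path(fixture_dir)
    config = SimulationConfig.from_dict(json.loads((d / "config.json").read_text()))
    counts_n = read_binned_counts(sorted((d / "normal").glob("*.bed")))
    counts_c = read_binned_counts(sorted((d / "cancer").glob("*.bed")))
    truth = np.loadtxt(d / "truth.tsv", dtype=np.int64, delimiter="\t", skiprows=1)
    truth = np.atleast_2d(truth)
    return SimulatedDataset(
        counts_n, counts_c, truth[:, 0], truth[:, 1], truth[:, 2], config
    )
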