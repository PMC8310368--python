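"""Accuracy metrics with bootstrap confidence intervals.

MUE is the mean unsigned error, RMSE the root-mean-square error, both in
kcal/mol for free-energy comparisons. Confidence intervals resample
(prediction, observation) pairs jointly with replacement to account for the
finite ligand sample size, and report the 2.5/97.5 percentiles of the
resampled metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricReport:
    metric: str  # "MUE" or "RMSE"
    value: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int


def _check(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and obs must be equal-length nonempty 1-D vectors")
    return p, o


def mue(pred, obs) -> float:
    """Mean unsigned error, mean |pred - obs|."""
    p, o = _check(pred, obs)
    return float(np.mean(np.abs(p - o)))


def rmse(pred, obs) -> float:
    """Root mean squared error; always >= MUE (power-mean inequality)."""
    p, o = _check(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


_METRICS = {"MUE": mue, "RMSE": rmse}


def bootstrap_ci(pred, obs, metric: str = "RMSE", n_boot: int = 10_000, seed: int = 0) -> MetricReport:
    """Percentile bootstrap interval for MUE or RMSE, resampling pairs."""
    p, o = _check(pred, obs)
    if p.size < 2:
        raise ValueError("bootstrap needs at least 2 pairs")
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p.size, size=(n_boot, p.size))
    resid = p - o
    r = resid[idx]
    if metric == "MUE":
        samples = np.mean(np.abs(r), axis=1)
    else:
        samples = np.sqrt(np.mean(r * r, axis=1))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return MetricReport(
        metric=metric,
        value=fn(p, o),
        ci_low=float(lo),
        ci_high=float(hi),
        n=int(p.size),
        n_boot=n_boot,
        seed=seed,
    )
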