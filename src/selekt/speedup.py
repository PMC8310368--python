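"""Numerical models of synthesis speedup from free-energy triage.

The error of a predicted change in selectivity combines a systematic part,
correlated between targets with coefficient rho, and a statistical part,
independent between targets:

    sigma_selectivity = sqrt(s1^2 + s2^2 - 2 rho s1 s2 + t1^2 + t2^2)

with s = sigma_sys and t = sigma_stat per target (kcal/mol). True changes
in selectivity proposed by a chemist are modeled as dS ~ N(0, 1 kcal/mol);
a free-energy method predicts dS + N(0, sigma_selectivity^2); compounds
predicted above a threshold are synthesized. The speedup is the fold
enrichment of truly selective compounds among those synthesized.

Three schemes are implemented: unlimited resources (pure enrichment ratio),
a resource-constrained triage (rank, synthesize at most ``max_synthesized``
compounds meeting a synthesis rule), and an effort sweep where statistical
error follows sigma_stat(N) = sigma_stat_base / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

#: The rounded field convention: 1 log10 unit of affinity ratio ~ 1.4 kcal/mol.
KCAL_PER_LOG10 = 1.4


def threshold_from_fold(fold: float) -> float:
    """Selectivity threshold in kcal/mol for a fold-change goal (10x -> 1.4)."""
    if fold <= 1:
        raise ValueError("fold-change must exceed 1")
    return KCAL_PER_LOG10 * math.log10(fold)


@dataclass(frozen=True)
class ErrorModel:
    """Per-target systematic and statistical errors with correlation rho."""

    sigma_sys_1: float
    sigma_sys_2: float
    rho: float
    sigma_stat_1: float = 0.0
    sigma_stat_2: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        for s in (self.sigma_sys_1, self.sigma_sys_2, self.sigma_stat_1, self.sigma_stat_2):
            if s < 0:
                raise ValueError("error standard deviations must be non-negative")


@dataclass(frozen=True)
class TriageDesign:
    """Design of a triage experiment.

    ``threshold`` is the true-selectivity success bar; ``synthesis_rule`` the
    predicted-selectivity bar a compound must clear to be made (both
    kcal/mol). ``n_proposals`` feeds the unlimited-resources model,
    ``n_scored``/``max_synthesized``/``n_replicates`` the constrained one.
    """

    threshold: float = KCAL_PER_LOG10
    synthesis_rule: float = 2 * KCAL_PER_LOG10
    n_scored: int = 1000
    max_synthesized: int = 10
    n_replicates: int = 1000
    n_proposals: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.max_synthesized < 1:
            raise ValueError("max_synthesized must be at least 1")
        if self.n_scored < 1 or self.n_replicates < 1 or self.n_proposals < 1:
            raise ValueError("counts must be at least 1")


@dataclass(frozen=True)
class EffortSchedule:
    """Statistical error vs sampling effort: sigma_stat(N) = base / sqrt(N)."""

    sigma_stat_base: float = 0.2
    efforts: tuple[float, ...] = (0.25, 1.0, 4.0, 16.0, 48.0, math.inf)


@dataclass(frozen=True)
class SpeedupEstimate:
    """Monte-Carlo speedup with a 95% interval over replicates."""

    mean: float
    ci_low: float
    ci_high: float
    n_replicates: int


def sigma_selectivity(model: ErrorModel) -> float:
    """Standard error of a predicted change in selectivity, kcal/mol."""
    s1, s2 = model.sigma_sys_1, model.sigma_sys_2
    var = (
        s1 * s1
        + s2 * s2
        - 2.0 * model.rho * s1 * s2
        + model.sigma_stat_1**2
        + model.sigma_stat_2**2
    )
    # |rho| <= 1 guarantees non-negativity; clip rounding residue
    return math.sqrt(max(var, 0.0))


def sigma_stat_at_effort(schedule: EffortSchedule, effort: float) -> float:
    """Per-target statistical error at a relative sampling effort N."""
    if effort == math.inf:
        return 0.0
    if effort <= 0:
        raise ValueError("effort must be positive")
    return schedule.sigma_stat_base / math.sqrt(effort)


# ---------------------------------------------------------------------------
# Unlimited-resources scheme


def speedup_unlimited(
    model: ErrorModel, design: TriageDesign, return_se: bool = False
) -> float | tuple[float, float]:
    """Monte-Carlo enrichment of truly selective compounds after triage.

    Draws ``n_proposals`` true dS ~ N(0,1), corrupts them with prediction
    error of width ``sigma_selectivity``, keeps compounds predicted at or
    above ``design.threshold`` and returns the ratio of the truly-selective
    fraction among those kept to the unconditional truly-selective fraction.
    With ``return_se=True`` also returns a delta-method standard error of
    the estimate.
    """
    rng = np.random.default_rng(design.seed)
    sigma = sigma_selectivity(model)
    theta = design.threshold
    n = design.n_proposals
    n_sel = 0
    n_hit = 0
    chunk = 5_000_000
    for start in range(0, n, chunk):
        m = min(chunk, n - start)
        true = rng.standard_normal(m)
        pred = true + sigma * rng.standard_normal(m) if sigma > 0 else true
        sel = pred >= theta
        n_sel += int(sel.sum())
        n_hit += int((sel & (true >= theta)).sum())
    if n_sel == 0:
        raise RuntimeError(
            "no compound passed the predicted-selectivity filter; "
            "increase n_proposals or lower the threshold"
        )
    base_rate = stats.norm.sf(theta)
    frac = n_hit / n_sel
    speedup = frac / base_rate
    if not return_se:
        return speedup
    # binomial error on the conditional fraction, base rate is analytic
    se = math.sqrt(max(frac * (1 - frac), 1e-300) / n_sel) / base_rate
    return speedup, se


def speedup_unlimited_analytic(model: ErrorModel, threshold: float) -> float:
    """Closed-form oracle for the unlimited-resources speedup.

    With T ~ N(0,1) and prediction P = T + E, E ~ N(0, sigma^2), (T, P) is
    bivariate normal with Var(P) = 1 + sigma^2 and corr(T, P) =
    1/sqrt(1+sigma^2). The speedup is the orthant ratio
    Pr(T>=theta, P>=theta) / [Pr(T>=theta) Pr(P>=theta)].
    """
    sigma = sigma_selectivity(model)
    theta = threshold
    if sigma == 0.0:
        return 1.0 / stats.norm.sf(theta)
    sd_p = math.sqrt(1.0 + sigma * sigma)
    r = 1.0 / sd_p
    a = theta  # standardized bound for T
    b = theta / sd_p  # standardized bound for P
    # Pr(Z1 >= a, Z2 >= b) = Pr(Z1 <= -a, Z2 <= -b) by central symmetry
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    joint = float(mvn.cdf([-a, -b]))
    return joint / (stats.norm.sf(a) * stats.norm.sf(b))


# ---------------------------------------------------------------------------
# Resource-constrained scheme


def speedup_constrained(model: ErrorModel, design: TriageDesign) -> SpeedupEstimate:
    """Triage with limited scoring and synthesis budgets.

    Per replicate: draw ``n_scored`` true dS ~ N(0,1); add prediction error;
    among compounds predicted at or above ``design.synthesis_rule``,
    synthesize the top-ranked up to ``max_synthesized``. The replicate's
    speedup is (number synthesized with true dS >= threshold) divided by the
    expected number of successes had the same count been drawn at random,
    ``Pr(dS >= threshold) * n_synthesized`` (normal tail, computed
    analytically). Replicates where nothing qualifies score 1 by convention.
    Returns the replicate mean and a 2.5/97.5-percentile interval.
    """
    rng = np.random.default_rng(design.seed)
    sigma = sigma_selectivity(model)
    p_true = stats.norm.sf(design.threshold)
    speedups = np.empty(design.n_replicates)
    for r in range(design.n_replicates):
        true = rng.standard_normal(design.n_scored)
        pred = true + sigma * rng.standard_normal(design.n_scored) if sigma > 0 else true
        qualifying = np.flatnonzero(pred >= design.synthesis_rule)
        if qualifying.size == 0:
            speedups[r] = 1.0
            continue
        order = qualifying[np.argsort(pred[qualifying])[::-1]]
        made = order[: design.max_synthesized]
        hits = int((true[made] >= design.threshold).sum())
        speedups[r] = hits / (p_true * made.size)
    lo, hi = np.percentile(speedups, [2.5, 97.5])
    return SpeedupEstimate(
        mean=float(speedups.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=design.n_replicates,
    )


# ---------------------------------------------------------------------------
# Statistical-error effort sweep


def speedup_with_statistical_error(
    model: ErrorModel, design: TriageDesign, schedule: EffortSchedule | None = None
) -> dict[float, float]:
    """Unlimited-model speedup at each sampling-effort level.

    At effort N the per-target statistical error is
    ``sigma_stat_base/sqrt(N)``, injected independently for the two targets
    (quadrature in sigma_selectivity); the systematic part of ``model`` is
    kept and its ``sigma_stat`` fields are ignored.
    """
    if schedule is None:
        schedule = EffortSchedule()
    out: dict[float, float] = {}
    for k, effort in enumerate(schedule.efforts):
        t = sigma_stat_at_effort(schedule, effort)
        m = replace(model, sigma_stat_1=t, sigma_stat_2=t)
        d = replace(design, seed=design.seed + k)
        out[effort] = speedup_unlimited(m, d)
    return out


# ---------------------------------------------------------------------------
# Posterior-marginal speedup


def speedup_posterior_marginal(
    rho_mean: float,
    rho_sd: float,
    sigma_sys_1: float,
    sigma_sys_2: float,
    design: TriageDesign,
    n_replicates: int = 10_000,
    method: str = "mc",
) -> np.ndarray:
    """Marginal distribution of speedup over posterior uncertainty in rho.

    Each replicate draws rho ~ N(rho_mean, rho_sd^2) truncated to [-1, 1]
    (an untruncated draw can produce an invalid error model), forms
    sigma_selectivity with zero statistical error, and evaluates the
    unlimited-resources speedup — by Monte Carlo with ``design.n_proposals``
    proposals (``method="mc"``), or with the closed-form orthant formula
    (``method="analytic"``), which is exact and much faster. Returns the
    sample of speedups.
    """
    if rho_sd < 0:
        raise ValueError("rho_sd must be non-negative")
    rng = np.random.default_rng(design.seed)
    if rho_sd == 0:
        rhos = np.full(n_replicates, rho_mean)
    else:
        a, b = (-1.0 - rho_mean) / rho_sd, (1.0 - rho_mean) / rho_sd
        rhos = stats.truncnorm.rvs(
            a, b, loc=rho_mean, scale=rho_sd, size=n_replicates, random_state=rng
        )
    out = np.empty(n_replicates)
    for k, rho in enumerate(rhos):
        m = ErrorModel(sigma_sys_1, sigma_sys_2, float(rho))
        if method == "analytic":
            out[k] = speedup_unlimited_analytic(m, design.threshold)
        elif method == "mc":
            d = replace(design, seed=int(rng.integers(2**31)))
            out[k] = speedup_unlimited(m, d)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
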