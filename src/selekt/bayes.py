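"""Hierarchical Bayesian decomposition of free-energy prediction error.

The model conditions jointly on two targets' perturbation maps and on
experimental binding free energies, and separates prediction error into a
statistical part (per-pair posterior spread) and a systematic part (the
reproducible residual), whose correlation between targets is the quantity
of interest.

Per target and phase, each ligand's absolute free energy G (defined up to
an arbitrary additive constant per phase) gets a broad Normal(0, 25^2)
prior, with one reference ligand pinned by a Normal(0, 1^2) prior instead.
Each map edge (i -> j) carries a dummy-atom contribution
c_ij ~ Normal(0, 25^2), shared between phases so it cancels exactly in the
binding free energy. The calculated edge values are observations

    ddG_calc(phase, i, j) ~ Normal(G_j - G_i + c_ij, (alpha * delta_BAR)^2)

with one scaling factor alpha per target (Lognormal(0,1) prior) that
absorbs BAR under-reporting of the true sampling error. Experimental
values are observations dG_obs ~ Normal(dG_true, 0.3^2) with a weak
Normal(0, 50^2) prior on each true free energy.

Derived per posterior draw: dG_FEP = G_complex - G_solvent per ligand,
relative values ddG_FEP and ddG_true over all unordered ligand pairs, the
pair error eps = ddG_FEP - ddG_true, and the inter-target correlation
rho = cov(eps_1, eps_2) / (sd(eps_1) sd(eps_2)).

Sampling exploits the model's structure: conditional on alpha the model is
linear-Gaussian, so the sampler marginalizes the Gaussian block
analytically, draws alpha from its (1-D, per-target) marginal posterior on
a fine grid, and then draws the node/edge block exactly from the
conditional multivariate normal. Draws are therefore independent and
exact up to the grid resolution in alpha. An affine-invariant ensemble
MCMC backend over the same log-posterior is provided for cross-checking
and for the optional heavy-tailed (Student-t) likelihood, which is not
conjugate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .affinity import BindingFreeEnergy
from .fepmap import FEPMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Priors, likelihood options and sampling controls.

    ``n_tune`` only affects the ensemble-MCMC backend (burn-in); the exact
    sampler needs no warmup. ``alpha_grid`` is (min, max, points) for the
    per-target marginal posterior of alpha, log-spaced.
    """

    g_prior_sd: float = 25.0
    reference_prior_sd: float = 1.0
    c_prior_sd: float = 25.0
    exp_obs_sd: float = 0.3
    dg_true_prior_sd: float = 50.0
    n_tune: int = 3000
    n_draws: int = 20000
    seed: int = 0
    likelihood: str = "normal"  # or "student-t"
    t_dof: float = 4.0
    alpha_grid: tuple[float, float, int] = (0.05, 20.0, 241)

    def __post_init__(self) -> None:
        for sd in (
            self.g_prior_sd,
            self.reference_prior_sd,
            self.c_prior_sd,
            self.exp_obs_sd,
            self.dg_true_prior_sd,
        ):
            if not sd > 0:
                raise ValueError("all prior/likelihood sds must be positive")
        if self.n_draws < 1 or self.n_tune < 0:
            raise ValueError("n_draws must be >= 1 and n_tune >= 0")
        if self.likelihood not in {"normal", "student-t"}:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


def pair_set(ligand_ids: Sequence[str], reference: str | None = None) -> list[tuple[str, str]]:
    """All unordered distinct ligand pairs, one orientation each.

    Self-pairs and reversed duplicates are excluded by construction. The
    ``reference`` argument is accepted for interface symmetry (pairs
    containing it are not special here) and validated if given.
    """
    ids = list(ligand_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 ligands to form pairs")
    if reference is not None and reference not in ids:
        raise ValueError(f"reference {reference!r} not among the ligands")
    return [(ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))]


# ---------------------------------------------------------------------------
# Model assembly


@dataclass
class _TargetBlock:
    """Design matrices for one target's linear-Gaussian FEP block."""

    target_id: str
    map_ligands: list[str]  # all map nodes, reference first
    n_edges: int
    A: np.ndarray  # (2m, 2n + m) observation design
    y: np.ndarray  # (2m,) calculated edge values
    delta: np.ndarray  # (2m,) reported BAR uncertainties
    prior_var: np.ndarray  # (2n + m,) prior variances
    exp_dg: np.ndarray  # (n_analysis,) observed free energies, analysis order


@dataclass
class BayesErrorModel:
    """A built (not yet sampled) two-target error model."""

    spec: ModelSpec
    targets: tuple[str, str]
    reference: str
    analysis_ligands: list[str]  # ligands with experimental data for both targets
    pairs: list[tuple[str, str]]
    blocks: dict[str, _TargetBlock]

    def log_density_at_prior_mean(self) -> float:
        """Joint log density with all latents at 0 and alpha = 1 (smoke check)."""
        total = 0.0
        for t in self.targets:
            b = self.blocks[t]
            x = np.zeros(b.A.shape[1])
            total += _log_posterior_xu(b, self.spec, x, 0.0)
            total += float(
                stats.norm.logpdf(b.exp_dg, 0.0, self.spec.exp_obs_sd).sum()
            )  # dG_true at prior mean 0
            total += float(
                stats.norm.logpdf(np.zeros_like(b.exp_dg), 0.0, self.spec.dg_true_prior_sd).sum()
            )
        return total


def build_model(
    map_1: FEPMap,
    map_2: FEPMap,
    exp_1: Sequence[BindingFreeEnergy],
    exp_2: Sequence[BindingFreeEnergy],
    spec: ModelSpec | None = None,
) -> BayesErrorModel:
    """Assemble the joint model from two maps and two experimental tables.

    The two maps must cover the same ligand set. Ligands missing an
    experimental value for either target stay in the perturbation graph
    (their edges still inform the node free energies) but are dropped, with
    a log message, from the pair-error analysis; at least two ligands must
    survive.
    """
    spec = spec or ModelSpec()
    set1, set2 = set(map_1.ligand_ids), set(map_2.ligand_ids)
    if set1 != set2:
        orphans = sorted(set1 ^ set2)
        raise ValueError(f"maps do not share a ligand set; orphans: {orphans}")
    if map_1.reference_ligand != map_2.reference_ligand:
        raise ValueError("maps disagree on the reference ligand")
    reference = map_1.reference_ligand
    exp_by_target = {
        map_1.target_id: {e.ligand_id: e.dG for e in exp_1},
        map_2.target_id: {e.ligand_id: e.dG for e in exp_2},
    }
    if map_1.target_id == map_2.target_id:
        raise ValueError("the two maps must describe different targets")

    map_ligands = sorted(set1)
    map_ligands.remove(reference)
    map_ligands.insert(0, reference)

    analysis = [
        l for l in map_ligands if all(l in exp_by_target[t] for t in exp_by_target)
    ]
    dropped = [l for l in map_ligands if l not in analysis]
    if dropped:
        logger.info("dropping ligands without experimental data: %s", dropped)
    if reference not in analysis:
        raise ValueError("the reference ligand needs experimental data for both targets")
    if len(analysis) < 2:
        raise ValueError("fewer than 2 ligands have experimental data for both targets")

    blocks = {}
    for fep_map in (map_1, map_2):
        blocks[fep_map.target_id] = _build_block(
            fep_map, map_ligands, exp_by_target[fep_map.target_id], analysis, spec
        )
    return BayesErrorModel(
        spec=spec,
        targets=(map_1.target_id, map_2.target_id),
        reference=reference,
        analysis_ligands=analysis,
        pairs=pair_set(analysis, reference),
        blocks=blocks,
    )


def _build_block(
    fep_map: FEPMap,
    map_ligands: list[str],
    exp_dg: dict[str, float],
    analysis: list[str],
    spec: ModelSpec,
) -> _TargetBlock:
    n = len(map_ligands)
    idx = {l: k for k, l in enumerate(map_ligands)}
    transformations = fep_map.transformations
    m = len(transformations)
    edge_idx = {e: k for k, e in enumerate(transformations)}
    dim = 2 * n + m  # [G_complex | G_solvent | c]

    prior_var = np.empty(dim)
    prior_var[: 2 * n] = spec.g_prior_sd**2
    prior_var[idx[fep_map.reference_ligand]] = spec.reference_prior_sd**2
    prior_var[n + idx[fep_map.reference_ligand]] = spec.reference_prior_sd**2
    prior_var[2 * n :] = spec.c_prior_sd**2

    rows = []
    y = []
    delta = []
    for e in fep_map.edges:
        row = np.zeros(dim)
        phase_off = 0 if e.phase == "complex" else n
        row[phase_off + idx[e.ligand_j]] = 1.0
        row[phase_off + idx[e.ligand_i]] = -1.0
        row[2 * n + edge_idx[(e.ligand_i, e.ligand_j)]] = 1.0
        rows.append(row)
        y.append(e.ddg_calc)
        delta.append(e.bar_uncertainty)
    return _TargetBlock(
        target_id=fep_map.target_id,
        map_ligands=map_ligands,
        n_edges=m,
        A=np.asarray(rows),
        y=np.asarray(y),
        delta=np.asarray(delta),
        prior_var=prior_var,
        exp_dg=np.asarray([exp_dg[l] for l in analysis]),
    )


# ---------------------------------------------------------------------------
# Exact collapsed sampler (normal likelihood)


def _alpha_log_marginal(block: _TargetBlock, spec: ModelSpec, alpha: float) -> float:
    """log p(y | alpha): Gaussian marginal of the linear block."""
    A, P, d = block.A, block.prior_var, block.delta
    cov = (A * P) @ A.T
    cov[np.diag_indices_from(cov)] += (alpha * d) ** 2
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:  # pragma: no cover - PD by construction
        return -np.inf
    sol = np.linalg.solve(cov, block.y)
    return -0.5 * (logdet + block.y @ sol + len(block.y) * math.log(2 * math.pi))


def _alpha_posterior_grid(
    block: _TargetBlock, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized marginal posterior of alpha on a log-spaced grid."""
    lo, hi, num = spec.alpha_grid
    u = np.linspace(math.log(lo), math.log(hi), num)
    logp = np.array(
        [stats.norm.logpdf(ui) + _alpha_log_marginal(block, spec, math.exp(ui)) for ui in u]
    )
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    return np.exp(u), w


def _conditional_draws(
    block: _TargetBlock,
    spec: ModelSpec,
    alphas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draws of [G_complex | G_solvent | c] given per-draw alpha."""
    A, P, d, y = block.A, block.prior_var, block.delta, block.y
    draws = np.empty((len(alphas), A.shape[1]))
    for alpha in np.unique(alphas):
        w = 1.0 / (alpha * d) ** 2
        lam = (A.T * w) @ A
        lam[np.diag_indices_from(lam)] += 1.0 / P
        L = np.linalg.cholesky(lam)
        mean = np.linalg.solve(lam, A.T @ (w * y))
        sel = np.flatnonzero(alphas == alpha)
        z = rng.standard_normal((len(sel), A.shape[1]))
        # x = mean + L^{-T} z has covariance lam^{-1}
        draws[sel] = mean + np.linalg.solve(L.T, z.T).T
    return draws


@dataclass
class PosteriorSamples:
    """Posterior draws and per-draw derived quantities.

    Arrays are indexed (draw, ...) with ligands in ``ligands`` order and
    pairs in ``pairs`` order. ``rho`` is the per-draw inter-target
    correlation of pair errors; draws with degenerate (zero-variance) error
    vectors are NaN-flagged.
    """

    targets: tuple[str, str]
    reference: str
    ligands: list[str]
    pairs: list[tuple[str, str]]
    G: dict[str, np.ndarray]  # target -> (ndraws, 2n + m) latent block
    alpha: dict[str, np.ndarray]  # target -> (ndraws,)
    dg_true: dict[str, np.ndarray]  # target -> (ndraws, n)
    dg_fep: dict[str, np.ndarray]  # target -> (ndraws, n)
    ddg_fep: dict[str, np.ndarray]  # target -> (ndraws, npairs)
    ddg_true: dict[str, np.ndarray]
    epsilon: dict[str, np.ndarray]
    rho: np.ndarray  # (ndraws,)
    diagnostics: dict[str, float] = field(default_factory=dict)


def rho_per_draw(epsilon_1: np.ndarray, epsilon_2: np.ndarray) -> float | np.ndarray:
    """Correlation of two equal-length error vectors (population convention).

    Accepts 1-D vectors over pairs (returns a scalar) or 2-D (draw, pair)
    arrays (returns a per-draw vector). Zero-variance draws return NaN.
    """
    e1 = np.atleast_2d(np.asarray(epsilon_1, dtype=float))
    e2 = np.atleast_2d(np.asarray(epsilon_2, dtype=float))
    if e1.shape != e2.shape or e1.shape[1] < 2:
        raise ValueError("need equal-length vectors over at least 2 pairs")
    a = e1 - e1.mean(axis=1, keepdims=True)
    b = e2 - e2.mean(axis=1, keepdims=True)
    va = (a * a).mean(axis=1)
    vb = (b * b).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).mean(axis=1) / np.sqrt(va * vb)
    r = np.where((va == 0) | (vb == 0), np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    return float(r[0]) if np.asarray(epsilon_1).ndim == 1 else r


def sample_posterior(model: BayesErrorModel, spec: ModelSpec | None = None) -> PosteriorSamples:
    """Draw from the joint posterior and attach derived quantities.

    For the normal likelihood this uses the exact collapsed sampler; draws
    are independent, so effective sample size equals the number of draws
    and split-R-hat is 1 up to noise (both are still computed and
    attached). The Student-t likelihood routes through the ensemble-MCMC
    backend.
    """
    spec = spec or model.spec
    if spec.likelihood == "student-t":
        return _sample_posterior_emcee(model, spec)
    rng = np.random.default_rng(spec.seed)
    nd = spec.n_draws
    n_all = len(model.blocks[model.targets[0]].map_ligands)
    analysis_idx = [
        model.blocks[model.targets[0]].map_ligands.index(l) for l in model.analysis_ligands
    ]
    li = {l: k for k, l in enumerate(model.analysis_ligands)}
    pi = np.array([[li[a], li[b]] for a, b in model.pairs])

    G: dict[str, np.ndarray] = {}
    alpha: dict[str, np.ndarray] = {}
    dg_true: dict[str, np.ndarray] = {}
    dg_fep: dict[str, np.ndarray] = {}
    ddg_fep: dict[str, np.ndarray] = {}
    ddg_true: dict[str, np.ndarray] = {}
    epsilon: dict[str, np.ndarray] = {}
    for t in model.targets:
        b = model.blocks[t]
        grid, w = _alpha_posterior_grid(b, spec)
        alpha[t] = rng.choice(grid, size=nd, p=w)
        G[t] = _conditional_draws(b, spec, alpha[t], rng)
        # conjugate posterior for dG_true given observations
        var_post = 1.0 / (1.0 / spec.dg_true_prior_sd**2 + 1.0 / spec.exp_obs_sd**2)
        mean_post = var_post * b.exp_dg / spec.exp_obs_sd**2
        dg_true[t] = mean_post + math.sqrt(var_post) * rng.standard_normal((nd, len(b.exp_dg)))
        full_fep = G[t][:, :n_all] - G[t][:, n_all : 2 * n_all]
        dg_fep[t] = full_fep[:, analysis_idx]
        ddg_fep[t] = dg_fep[t][:, pi[:, 1]] - dg_fep[t][:, pi[:, 0]]
        ddg_true[t] = dg_true[t][:, pi[:, 1]] - dg_true[t][:, pi[:, 0]]
        epsilon[t] = ddg_fep[t] - ddg_true[t]

    t1, t2 = model.targets
    rho = rho_per_draw(epsilon[t1], epsilon[t2])
    samples = PosteriorSamples(
        targets=model.targets,
        reference=model.reference,
        ligands=model.analysis_ligands,
        pairs=model.pairs,
        G=G,
        alpha=alpha,
        dg_true=dg_true,
        dg_fep=dg_fep,
        ddg_fep=ddg_fep,
        ddg_true=ddg_true,
        epsilon=epsilon,
        rho=np.asarray(rho),
    )
    samples.diagnostics = _diagnostics(samples)
    return samples


def _diagnostics(samples: PosteriorSamples) -> dict[str, float]:
    """Split-R-hat and ESS of rho and alpha via arviz (4 pseudo-chains)."""
    try:
        import arviz as az
    except ImportError:  # pragma: no cover
        return {}
    out: dict[str, float] = {}
    for name, arr in [("rho", samples.rho)] + [
        (f"alpha_{t}", samples.alpha[t]) for t in samples.targets
    ]:
        arr = np.asarray(arr, dtype=float)
        arr = arr[np.isfinite(arr)]
        k = len(arr) // 4
        if k < 2:
            continue
        chains = arr[: 4 * k].reshape(4, k)
        out[f"rhat_{name}"] = float(az.rhat(chains))
        out[f"ess_{name}"] = float(az.ess(chains))
    return out


# ---------------------------------------------------------------------------
# Ensemble-MCMC backend (cross-check; Student-t likelihood)


def _log_posterior_xu(block: _TargetBlock, spec: ModelSpec, x: np.ndarray, u: float) -> float:
    """Log prior + likelihood for one target's latent block and u = log alpha."""
    alpha = math.exp(u)
    lp = -0.5 * float(np.sum(x * x / block.prior_var) + np.sum(np.log(2 * np.pi * block.prior_var)))
    lp += float(stats.norm.logpdf(u))
    resid = block.y - block.A @ x
    scale = alpha * block.delta
    if spec.likelihood == "student-t":
        lp += float(stats.t.logpdf(resid, df=spec.t_dof, scale=scale).sum())
    else:
        lp += float(stats.norm.logpdf(resid, scale=scale).sum())
    return lp


def _sample_block_emcee(
    block: _TargetBlock, spec: ModelSpec, rng: np.random.Generator, n_draws: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-MCMC draws of (x, alpha) for one target block."""
    import emcee

    dim = block.A.shape[1] + 1
    nwalkers = max(2 * dim + 2, 64)

    def logp(theta: np.ndarray) -> float:
        return _log_posterior_xu(block, spec, theta[:-1], theta[-1])

    # start walkers near the collapsed-sampler solution at alpha = 1
    w = 1.0 / block.delta**2
    lam = (block.A.T * w) @ block.A
    lam[np.diag_indices_from(lam)] += 1.0 / block.prior_var
    mean = np.linalg.solve(lam, block.A.T @ (w * block.y))
    p0 = np.concatenate([mean, [0.0]]) + 0.05 * rng.standard_normal((nwalkers, dim))
    sampler = emcee.EnsembleSampler(nwalkers, dim, logp)
    sampler.random_state = np.random.RandomState(int(rng.integers(2**31))).get_state()
    burn = max(spec.n_tune, 500)
    state = sampler.run_mcmc(p0, burn, progress=False)
    sampler.reset()
    thin = 5
    steps = max(math.ceil(thin * n_draws / nwalkers), 300)
    sampler.run_mcmc(state, steps, progress=False)
    flat = sampler.get_chain(flat=True, thin=thin)
    take = rng.choice(len(flat), size=n_draws, replace=len(flat) < n_draws)
    theta = flat[take]
    return theta[:, :-1], np.exp(theta[:, -1])


def _sample_posterior_emcee(model: BayesErrorModel, spec: ModelSpec) -> PosteriorSamples:
    """Full posterior via the ensemble backend (used for Student-t)."""
    rng = np.random.default_rng(spec.seed)
    nd = spec.n_draws
    n_all = len(model.blocks[model.targets[0]].map_ligands)
    analysis_idx = [
        model.blocks[model.targets[0]].map_ligands.index(l) for l in model.analysis_ligands
    ]
    li = {l: k for k, l in enumerate(model.analysis_ligands)}
    pi = np.array([[li[a], li[b]] for a, b in model.pairs])
    G, alpha, dg_true, dg_fep, ddg_fep, ddg_true, epsilon = {}, {}, {}, {}, {}, {}, {}
    for t in model.targets:
        b = model.blocks[t]
        G[t], alpha[t] = _sample_block_emcee(b, spec, rng, nd)
        var_post = 1.0 / (1.0 / spec.dg_true_prior_sd**2 + 1.0 / spec.exp_obs_sd**2)
        mean_post = var_post * b.exp_dg / spec.exp_obs_sd**2
        dg_true[t] = mean_post + math.sqrt(var_post) * rng.standard_normal((nd, len(b.exp_dg)))
        full_fep = G[t][:, :n_all] - G[t][:, n_all : 2 * n_all]
        dg_fep[t] = full_fep[:, analysis_idx]
        ddg_fep[t] = dg_fep[t][:, pi[:, 1]] - dg_fep[t][:, pi[:, 0]]
        ddg_true[t] = dg_true[t][:, pi[:, 1]] - dg_true[t][:, pi[:, 0]]
        epsilon[t] = ddg_fep[t] - ddg_true[t]
    t1, t2 = model.targets
    samples = PosteriorSamples(
        targets=model.targets,
        reference=model.reference,
        ligands=model.analysis_ligands,
        pairs=model.pairs,
        G=G,
        alpha=alpha,
        dg_true=dg_true,
        dg_fep=dg_fep,
        ddg_fep=ddg_fep,
        ddg_true=ddg_true,
        epsilon=epsilon,
        rho=np.asarray(rho_per_draw(epsilon[t1], epsilon[t2])),
    )
    samples.diagnostics = _diagnostics(samples)
    return samples


# ---------------------------------------------------------------------------
# Posterior summaries


@dataclass(frozen=True)
class CorrelationEstimate:
    """Posterior summary consumed by the speedup models."""

    rho_mean: float
    rho_sd: float
    rho_ci: tuple[float, float]
    sigma_sys: dict[str, float]  # per target, kcal/mol
    sigma_stat: dict[str, dict[tuple[str, str], float]]  # target -> pair -> kcal/mol


def systematic_error_estimate(
    samples: PosteriorSamples, reference: str | None = None
) -> dict[str, float]:
    """Per-target systematic error: mean |eps_{i,ref}| over draws and ligands."""
    reference = reference or samples.reference
    ref_pairs = [k for k, (a, b) in enumerate(samples.pairs) if reference in (a, b)]
    if not ref_pairs:
        raise ValueError(f"no pair involves the reference {reference!r}")
    return {
        t: float(np.mean(np.abs(samples.epsilon[t][:, ref_pairs])))
        for t in samples.targets
    }


def statistical_error_estimate(samples: PosteriorSamples) -> dict[str, dict[tuple[str, str], float]]:
    """Per-pair, per-target statistical error: posterior sd of ddG_FEP."""
    return {
        t: {
            pair: float(np.std(samples.ddg_fep[t][:, k]))
            for k, pair in enumerate(samples.pairs)
        }
        for t in samples.targets
    }


def summarize(samples: PosteriorSamples, reference: str | None = None) -> CorrelationEstimate:
    """Rho posterior mean and central 95% interval plus error components."""
    rho = samples.rho[np.isfinite(samples.rho)]
    if rho.size == 0:
        raise ValueError("all rho draws are degenerate")
    lo, hi = np.percentile(rho, [2.5, 97.5])
    return CorrelationEstimate(
        rho_mean=float(rho.mean()),
        rho_sd=float(rho.std()),
        rho_ci=(float(lo), float(hi)),
        sigma_sys=systematic_error_estimate(samples, reference),
        sigma_stat=statistical_error_estimate(samples),
    )
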