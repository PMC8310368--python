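"""Ground-truthed synthetic congeneric series for two targets.

Emulates the statistical structure of a paired free-energy campaign without
any molecular simulation: each ligand carries a per-target systematic
prediction offset, and the offsets of the two targets are drawn from a
bivariate normal with correlation ``rho_true``. Perturbation-map edges see
the true phase difference plus the offset difference (complex phase only)
plus Gaussian statistical noise whose true standard deviation is
``alpha_true`` times the reported BAR uncertainty — so ``alpha_true > 1``
emulates BAR under-reporting. Experimental observations are the true
binding free energies corrupted by ``exp_sd`` Gaussian noise.

Injecting systematic error at the node (per-ligand) level keeps maps
cycle-consistent: the systematic part of any edge error is a difference of
node offsets and cancels around every closed cycle, so hysteresis reflects
statistical noise only, and pair errors eps_ij = e_j - e_i inherit the
inter-target correlation rho_true.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .affinity import BindingFreeEnergy
from .fepmap import FEPEdge, FEPMap, write_fep_map

TOPOLOGIES = ("star", "ring", "star_plus_ring")

#: Reported BAR uncertainty floor so noise-free maps still carry a valid
#: (strictly positive) per-edge error estimate.
BAR_FLOOR = 0.01


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic two-target dataset.

    Defaults mirror the conditions analyzed throughout: per-target
    systematic error of 1 kcal/mol, a baseline per-edge statistical error
    of 0.2 kcal/mol, honest BAR reporting (alpha_true = 1), experimental
    noise of 0.3 kcal/mol and a true dynamic range of ~3 kcal/mol.
    """

    n_ligands: int = 16
    rho_true: float = 0.5
    sigma_sys_true: tuple[float, float] = (1.0, 1.0)
    sigma_edge_stat: float = 0.2
    alpha_true: float = 1.0
    exp_sd: float = 0.3
    topology: str = "star_plus_ring"
    dg_range: float = 3.0
    seed: int = 0
    target_ids: tuple[str, str] = ("target1", "target2")

    def __post_init__(self) -> None:
        if self.n_ligands < 2:
            raise ValueError("need at least 2 ligands")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [-1, 1]")
        if min(self.sigma_sys_true) < 0 or self.sigma_edge_stat < 0 or self.exp_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.alpha_true > 0:
            raise ValueError("alpha_true must be positive")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "ring" and self.n_ligands < 3:
            raise ValueError("ring topology needs at least 3 ligands")
        if self.topology == "star_plus_ring" and self.n_ligands < 4:
            raise ValueError("star_plus_ring topology needs at least 4 ligands")


@dataclass
class SyntheticDataset:
    """Ground truth plus emulated maps and observations."""

    config: SyntheticConfig
    ligand_ids: list[str]
    reference_ligand: str
    true_dg: dict[str, dict[str, float]]  # target -> ligand -> kcal/mol
    true_offsets: dict[str, dict[str, float]]  # target -> ligand -> e_i
    maps: dict[str, FEPMap]
    observations: dict[str, list[BindingFreeEnergy]]


def _edge_list(ligands: list[str], topology: str) -> list[tuple[str, str]]:
    ref, others = ligands[0], ligands[1:]
    star = [(ref, l) for l in others]
    if topology == "star":
        return star
    if topology == "ring":
        return [(ligands[k], ligands[(k + 1) % len(ligands)]) for k in range(len(ligands))]
    # star_plus_ring: spanning star plus one closing ring over the non-reference
    # ligands, so the map has cycles to exercise hysteresis diagnostics.
    ring = [(others[k], others[(k + 1) % len(others)]) for k in range(len(others))]
    return star + ring


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one fully seeded two-target dataset.

    Distinct random sub-streams drive the true free energies, the
    systematic offsets, the per-edge statistical noise and the experimental
    noise, so changing one noise source never perturbs the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_dg, rng_off, rng_edge, rng_exp = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n_ligands
    width = max(len(str(n - 1)), 2)
    ligands = [f"L{k:0{width}d}" for k in range(n)]
    reference = ligands[0]
    t1, t2 = config.target_ids

    # (1) true binding free energies: uniform over a window of span dg_range
    # centered on -9 kcal/mol, reference pinned at the center.
    center = -9.0
    true_dg: dict[str, dict[str, float]] = {}
    for t in (t1, t2):
        vals = center + config.dg_range * (rng_dg.random(n) - 0.5)
        vals[0] = center
        true_dg[t] = dict(zip(ligands, vals.tolist()))

    # (2) per-ligand systematic offsets, bivariate normal across targets,
    # reference offset fixed at 0 for both targets.
    s1, s2 = config.sigma_sys_true
    cov = np.array(
        [
            [s1 * s1, config.rho_true * s1 * s2],
            [config.rho_true * s1 * s2, s2 * s2],
        ]
    )
    e = rng_off.multivariate_normal(np.zeros(2), cov, size=n, method="svd")
    e[0, :] = 0.0
    true_offsets = {
        t1: dict(zip(ligands, e[:, 0].tolist())),
        t2: dict(zip(ligands, e[:, 1].tolist())),
    }

    # arbitrary per-phase node constants: solvent free energies; complex is
    # solvent + binding, so phase differences reproduce the true dG.
    g_solv = {t: dict(zip(ligands, (2.0 * rng_dg.random(n) - 1.0).tolist())) for t in (t1, t2)}

    # (3) maps: per edge and phase, truth + (complex-only offset difference)
    # + statistical noise of sd alpha_true * delta, delta = sigma_edge_stat.
    delta_true = config.alpha_true * config.sigma_edge_stat
    delta_reported = max(config.sigma_edge_stat, BAR_FLOOR)
    pairs = _edge_list(ligands, config.topology)
    maps: dict[str, FEPMap] = {}
    for t in (t1, t2):
        edges = []
        for (i, j) in pairs:
            gs_i, gs_j = g_solv[t][i], g_solv[t][j]
            gc_i = gs_i + true_dg[t][i]
            gc_j = gs_j + true_dg[t][j]
            off = true_offsets[t][j] - true_offsets[t][i]
            for phase, base in (("complex", gc_j - gc_i + off), ("solvent", gs_j - gs_i)):
                noise = delta_true * rng_edge.standard_normal() if delta_true > 0 else 0.0
                edges.append(
                    FEPEdge(
                        ligand_i=i,
                        ligand_j=j,
                        phase=phase,
                        ddg_calc=base + noise,
                        bar_uncertainty=delta_reported,
                    )
                )
        maps[t] = FEPMap(target_id=t, reference_ligand=reference, edges=edges)

    # (4) experimental observations: truth + exp noise.
    observations = {
        t: [
            BindingFreeEnergy(
                ligand_id=l,
                target_id=t,
                dG=true_dg[t][l]
                + (config.exp_sd * rng_exp.standard_normal() if config.exp_sd > 0 else 0.0),
                uncertainty=config.exp_sd,
            )
            for l in ligands
        ]
        for t in (t1, t2)
    }

    return SyntheticDataset(
        config=config,
        ligand_ids=ligands,
        reference_ligand=reference,
        true_dg=true_dg,
        true_offsets=true_offsets,
        maps=maps,
        observations=observations,
    )


def generate_proposals(n: int, seed: int) -> np.ndarray:
    """True selectivity changes proposed by a chemist: n iid N(0, 1) kcal/mol."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return np.random.default_rng(seed).standard_normal(n)


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write maps, affinity tables and ground truth to ``directory``.

    Emits one FEP-map CSV and one affinity CSV (dG rows, kcal/mol) per
    target, plus ``truth.json`` echoing the configuration and ground truth.
    Files round-trip through :mod:`selekt.fepmap` and
    :mod:`selekt.affinity`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t, fep_map in dataset.maps.items():
        p = directory / f"map_{t}.csv"
        write_fep_map(fep_map, p)
        paths[f"map_{t}"] = p
    import pandas as pd

    for t, obs in dataset.observations.items():
        p = directory / f"affinity_{t}.csv"
        pd.DataFrame(
            {
                "ligand_id": [o.ligand_id for o in obs],
                "target_id": [o.target_id for o in obs],
                "quantity": "dG",
                "value": [repr(o.dG) for o in obs],
                "unit": "kcal/mol",
                "km_atp_uM": "",
                "s0_atp_uM": "",
                "temperature_K": 300.0,
            }
        ).to_csv(p, index=False)
        paths[f"affinity_{t}"] = p
    truth = {
        "config": asdict(dataset.config),
        "ligand_ids": dataset.ligand_ids,
        "reference_ligand": dataset.reference_ligand,
        "true_dg": dataset.true_dg,
        "true_offsets": dataset.true_offsets,
    }
    p = directory / "truth.json"
    p.write_text(json.dumps(truth, indent=1))
    paths["truth"] = p
    return paths
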