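"""Perturbation-map data model for relative free-energy calculations.

A map is a graph whose nodes are ligands of a congeneric series and whose
edges are alchemical transformations, each estimated in two thermodynamic
phases (ligand-in-complex and ligand-in-solvent) with a BAR standard error.
The per-edge binding free energy is the phase difference
``ddG_bind = ddG_complex - ddG_solvent``, and the signed sum of binding
estimates around any closed cycle (the hysteresis) is zero for a
thermodynamically consistent, noise-free map.

Edge orientation convention: ``ddg_calc`` for edge (i, j) is the free energy
of transforming ligand i into ligand j, i.e. in the ``G_j - G_i`` sense.
A file containing both (i, j) and (j, i) for the same phase is rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import networkx as nx
import pandas as pd

PHASES = ("complex", "solvent")

SCHEMA_VERSION = "selekt-fepmap-1"

FEPMAP_COLUMNS = [
    "target_id",
    "ligand_i",
    "ligand_j",
    "phase",
    "ddg_kcal",
    "bar_err_kcal",
    "ddg_ccc_kcal",
]


@dataclass(frozen=True)
class FEPEdge:
    """One alchemical transformation in one phase, kcal/mol."""

    ligand_i: str
    ligand_j: str
    phase: str
    ddg_calc: float
    bar_uncertainty: float
    ddg_ccc: float | None = None  # cycle-closure-corrected estimate, metadata only

    def __post_init__(self) -> None:
        if self.ligand_i == self.ligand_j:
            raise ValueError(f"self-edge ({self.ligand_i}, {self.ligand_j}) forbidden")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.bar_uncertainty > 0:
            raise ValueError("bar_uncertainty must be strictly positive")
        if not math.isfinite(self.ddg_calc):
            raise ValueError("ddg_calc must be finite")


@dataclass
class FEPMap:
    """A validated perturbation graph for one target."""

    target_id: str
    reference_ligand: str
    edges: list[FEPEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def ligand_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.ligand_i)
            seen.setdefault(e.ligand_j)
        return list(seen)

    @property
    def transformations(self) -> list[tuple[str, str]]:
        """Unique (i, j) transformations, in first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for e in self.edges:
            seen.setdefault((e.ligand_i, e.ligand_j))
        return list(seen)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ligand_ids)
        g.add_edges_from(self.transformations)
        return g

    def validate(self) -> None:
        by_key: dict[tuple[str, str, str], FEPEdge] = {}
        for e in self.edges:
            key = (e.ligand_i, e.ligand_j, e.phase)
            if key in by_key:
                raise ValueError(f"duplicate edge {key}")
            rev = (e.ligand_j, e.ligand_i, e.phase)
            if rev in by_key:
                raise ValueError(
                    f"edge ({e.ligand_i}, {e.ligand_j}) duplicates the reciprocal "
                    f"({e.ligand_j}, {e.ligand_i}) in phase {e.phase}"
                )
            by_key[key] = e
        self._by_key = by_key
        for (i, j) in self.transformations:
            for phase in PHASES:
                if (i, j, phase) not in by_key:
                    raise ValueError(
                        f"transformation ({i}, {j}) missing phase {phase!r}"
                    )
        if not self.edges:
            raise ValueError("map has no edges")
        if self.reference_ligand not in set(self.ligand_ids):
            raise ValueError(
                f"reference ligand {self.reference_ligand!r} not in the map"
            )
        g = self.graph()
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(f"perturbation graph is disconnected: {comps}")

    # -- queries -----------------------------------------------------------

    def edge(self, ligand_i: str, ligand_j: str, phase: str) -> FEPEdge:
        """The edge for (i, j) in ``phase``; a reversed query negates ddg."""
        key = (ligand_i, ligand_j, phase)
        if key in self._by_key:
            return self._by_key[key]
        rev = (ligand_j, ligand_i, phase)
        if rev in self._by_key:
            e = self._by_key[rev]
            return replace(
                e,
                ligand_i=ligand_i,
                ligand_j=ligand_j,
                ddg_calc=-e.ddg_calc,
                ddg_ccc=None if e.ddg_ccc is None else -e.ddg_ccc,
            )
        raise KeyError(f"no edge ({ligand_i}, {ligand_j}) in phase {phase!r}")


@dataclass(frozen=True)
class CycleReport:
    """Hysteresis of one closed cycle in a map, kcal/mol."""

    cycle: tuple[str, ...]
    hysteresis: float  # signed sum of binding ddG around the cycle
    hysteresis_complex: float
    hysteresis_solvent: float


def binding_ddg(fep_map: FEPMap, ligand_i: str, ligand_j: str) -> tuple[float, float]:
    """Relative binding free energy of (i -> j) and its propagated BAR error.

    Returns ``(ddg_complex - ddg_solvent, sqrt(d_complex^2 + d_solvent^2))``.
    """
    ec = fep_map.edge(ligand_i, ligand_j, "complex")
    es = fep_map.edge(ligand_i, ligand_j, "solvent")
    ddg = ec.ddg_calc - es.ddg_calc
    err = math.hypot(ec.bar_uncertainty, es.bar_uncertainty)
    return ddg, err


def enumerate_cycles(fep_map: FEPMap, all_simple: bool = False) -> list[CycleReport]:
    """Cycle-closure report for a map.

    By default only a fundamental cycle basis of the graph is enumerated
    (every independent loop appears once); ``all_simple=True`` enumerates
    every simple cycle, which is exponential and only sensible for small
    maps. Tree-shaped maps return an empty list.
    """
    g = fep_map.graph()
    if all_simple:
        cycles = [c for c in nx.simple_cycles(g) if len(c) >= 3]
    else:
        cycles = nx.cycle_basis(g)
    reports = []
    for cyc in cycles:
        hyst = {p: 0.0 for p in PHASES}
        closed = list(cyc) + [cyc[0]]
        for a, b in zip(closed[:-1], closed[1:]):
            for p in PHASES:
                hyst[p] += fep_map.edge(a, b, p).ddg_calc
        reports.append(
            CycleReport(
                cycle=tuple(cyc),
                hysteresis=hyst["complex"] - hyst["solvent"],
                hysteresis_complex=hyst["complex"],
                hysteresis_solvent=hyst["solvent"],
            )
        )
    return reports


# ---------------------------------------------------------------------------
# I/O


def read_fep_map(path: str | Path, reference_ligand: str | None = None) -> FEPMap:
    """Read one target's map from the FEP-map CSV or JSON schema."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path, reference_ligand)
    df = pd.read_csv(path, comment="#")
    missing = set(FEPMAP_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"FEP-map CSV missing columns: {sorted(missing)}")
    targets = df["target_id"].unique()
    if len(targets) != 1:
        raise ValueError(f"expected one target per file, found {list(targets)}")
    reference = reference_ligand
    if reference is None:
        if "reference_ligand" in df.columns:
            reference = str(df["reference_ligand"].iloc[0])
        else:
            raise ValueError("reference ligand not given and not in the file")
    edges = []
    for row in df.itertuples(index=False):
        ccc = getattr(row, "ddg_ccc_kcal", None)
        edges.append(
            FEPEdge(
                ligand_i=str(row.ligand_i),
                ligand_j=str(row.ligand_j),
                phase=str(row.phase),
                ddg_calc=float(row.ddg_kcal),
                bar_uncertainty=float(row.bar_err_kcal),
                ddg_ccc=None if ccc is None or pd.isna(ccc) else float(ccc),
            )
        )
    return FEPMap(target_id=str(targets[0]), reference_ligand=reference, edges=edges)


def write_fep_map(fep_map: FEPMap, path: str | Path) -> None:
    """Write a map in the CSV (or JSON, by extension) schema; round-trips."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "schema": SCHEMA_VERSION,
            "target": fep_map.target_id,
            "reference": fep_map.reference_ligand,
            "edges": [
                {
                    "ligand_i": e.ligand_i,
                    "ligand_j": e.ligand_j,
                    "phase": e.phase,
                    "ddg_kcal": e.ddg_calc,
                    "bar_err_kcal": e.bar_uncertainty,
                    "ddg_ccc_kcal": e.ddg_ccc,
                }
                for e in fep_map.edges
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = [
        {
            "target_id": fep_map.target_id,
            "ligand_i": e.ligand_i,
            "ligand_j": e.ligand_j,
            "phase": e.phase,
            "ddg_kcal": repr(e.ddg_calc),
            "bar_err_kcal": repr(e.bar_uncertainty),
            "ddg_ccc_kcal": "" if e.ddg_ccc is None else repr(e.ddg_ccc),
            "reference_ligand": fep_map.reference_ligand,
        }
        for e in fep_map.edges
    ]
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def _read_json(path: Path, reference_ligand: str | None) -> FEPMap:
    payload = json.loads(Path(path).read_text())
    edges = [
        FEPEdge(
            ligand_i=str(e["ligand_i"]),
            ligand_j=str(e["ligand_j"]),
            phase=str(e["phase"]),
            ddg_calc=float(e["ddg_kcal"]),
            bar_uncertainty=float(e["bar_err_kcal"]),
            ddg_ccc=None if e.get("ddg_ccc_kcal") is None else float(e["ddg_ccc_kcal"]),
        )
        for e in payload["edges"]
    ]
    return FEPMap(
        target_id=str(payload["target"]),
        reference_ligand=str(reference_ligand or payload["reference"]),
        edges=edges,
    )
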