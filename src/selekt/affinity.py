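"""Binding affinities, free energies and selectivity for congeneric series.

Experimental potencies for ATP-competitive kinase inhibitors are usually
reported as IC50 or Ki. Under Michaelis-Menten competition the two are
related by the Cheng-Prusoff correction ``Ki = IC50 / (1 + [S0]/Km)``, and
an inhibition constant maps onto a binding free energy through
``dG = kB T ln Ki`` (Ki in molar; potent binders are more negative).
Selectivity of a ligand between two
targets is the free-energy difference ``S = dG_target2 - dG_target1``; a
chemical modification changes selectivity by ``dS = S_j - S_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 0.0019872

#: Default absolute temperature (room temperature), K.
DEFAULT_TEMPERATURE = 300.0

_CONC_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class AffinityMeasurement:
    """One experimental assay result with its assay context.

    ``value`` is a concentration (nM unless ``unit`` says otherwise) for
    IC50/Ki, or a free energy in kcal/mol for dG. ``km_atp`` and ``s0_atp``
    are in µM and are only needed when the Cheng-Prusoff correction applies.
    """

    ligand_id: str
    target_id: str
    quantity: str  # one of {"IC50", "Ki", "dG"}
    value: float
    unit: str = "nM"
    km_atp: float | None = None
    s0_atp: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.quantity not in {"IC50", "Ki", "dG"}:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.quantity in {"IC50", "Ki"} and not self.value > 0:
            raise ValueError(f"{self.quantity} must be strictly positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be strictly positive")
        if self.km_atp is not None and not self.km_atp > 0:
            raise ValueError("km_atp must be strictly positive")
        if self.s0_atp is not None and self.s0_atp < 0:
            raise ValueError("s0_atp must be non-negative")


@dataclass(frozen=True)
class BindingFreeEnergy:
    """Binding free energy of one ligand for one target, kcal/mol."""

    ligand_id: str
    target_id: str
    dG: float
    uncertainty: float = 0.3  # assumed random experimental error, kcal/mol

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG):
            raise ValueError("dG must be finite")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass(frozen=True)
class SelectivityRecord:
    """Selectivity S of one ligand for an ordered target pair, kcal/mol.

    ``S = dG(target2) - dG(target1)``; swapping the pair negates S.
    """

    ligand_id: str
    target_pair: tuple[str, str]
    S: float


@dataclass(frozen=True)
class SeriesSummary:
    """Per-series selectivity statistics (kcal/mol)."""

    mean_S: float
    std_S: float
    range_S: float
    n_ligands: int


def ki_from_ic50(ic50: float, s0: float, km: float) -> float:
    """Cheng-Prusoff conversion of an IC50 to Ki for an ATP-competitive inhibitor.

    ``Ki = IC50 / (1 + s0/km)``; same units as ``ic50``. ``s0`` is the assay
    ATP concentration and ``km`` the Michaelis constant for ATP (same units
    as each other).
    """
    if ic50 <= 0 or km <= 0 or s0 < 0:
        raise ValueError("ic50 and km must be positive, s0 non-negative")
    return ic50 / (1.0 + s0 / km)


def dg_from_ki(ki_molar: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy of an inhibition constant, kcal/mol.

    ``dG = -kB T ln(1/Ki) = kB T ln(Ki)`` with Ki in molar, so a more potent
    inhibitor (smaller Ki) has a more negative dG: 1 nM corresponds to about
    -12.4 kcal/mol at 300 K.
    """
    if ki_molar <= 0:
        raise ValueError("Ki must be strictly positive")
    if temperature <= 0:
        raise ValueError("temperature must be strictly positive")
    return KB_KCAL * temperature * math.log(ki_molar)


def selectivity(dg_target1: float, dg_target2: float) -> float:
    """Selectivity S = dG(target2) - dG(target1), kcal/mol."""
    if not (math.isfinite(dg_target1) and math.isfinite(dg_target2)):
        raise ValueError("free energies must be finite")
    return dg_target2 - dg_target1


def delta_selectivity(s_i: float, s_j: float) -> float:
    """Change in selectivity dS_ij = S_j - S_i on modifying ligand i into j."""
    if not (math.isfinite(s_i) and math.isfinite(s_j)):
        raise ValueError("selectivities must be finite")
    return s_j - s_i


def relative_dg(dg_i: float, dg_ref: float) -> float:
    """Relative binding free energy ddG_{i,ref} = dG_i - dG_ref, kcal/mol."""
    return dg_i - dg_ref


def series_summary(records: Sequence[SelectivityRecord]) -> SeriesSummary:
    """Mean, sample standard deviation and range of S across one series.

    All records must share a single (ordered) target pair. The standard
    deviation uses the sample (n-1) convention; a single-record series
    reports std 0.
    """
    if len(records) == 0:
        raise ValueError("series_summary requires at least one record")
    pairs = {r.target_pair for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records span multiple target pairs: {sorted(pairs)}")
    s = np.asarray([r.S for r in records], dtype=float)
    std = float(np.std(s, ddof=1)) if len(s) > 1 else 0.0
    return SeriesSummary(
        mean_S=float(np.mean(s)),
        std_S=std,
        range_S=float(np.max(s) - np.min(s)),
        n_ligands=len(s),
    )


# ---------------------------------------------------------------------------
# Tabular I/O

AFFINITY_COLUMNS = [
    "ligand_id",
    "target_id",
    "quantity",
    "value",
    "unit",
    "km_atp_uM",
    "s0_atp_uM",
    "temperature_K",
]


def read_affinity_csv(path: str | Path, apply_exclusions: bool = True) -> list[AffinityMeasurement]:
    """Read assay measurements from the affinity CSV schema.

    Rows flagged ``exclude_from_analysis`` (optional boolean column, e.g. a
    charged ligand kept in a perturbation map only for cycle closure) are
    dropped unless ``apply_exclusions=False``.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(AFFINITY_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"affinity CSV missing columns: {sorted(missing)}")
    if apply_exclusions and "exclude_from_analysis" in df.columns:
        df = df[~df["exclude_from_analysis"].astype(bool)]
    out = []
    for row in df.itertuples(index=False):
        km = getattr(row, "km_atp_uM", None)
        s0 = getattr(row, "s0_atp_uM", None)
        temp = getattr(row, "temperature_K", DEFAULT_TEMPERATURE)
        out.append(
            AffinityMeasurement(
                ligand_id=str(row.ligand_id),
                target_id=str(row.target_id),
                quantity=str(row.quantity),
                value=float(row.value),
                unit=str(getattr(row, "unit", "nM")),
                km_atp=None if km is None or pd.isna(km) else float(km),
                s0_atp=None if s0 is None or pd.isna(s0) else float(s0),
                temperature=DEFAULT_TEMPERATURE if pd.isna(temp) else float(temp),
            )
        )
    return out


def to_free_energy(m: AffinityMeasurement, uncertainty: float = 0.3) -> BindingFreeEnergy:
    """Convert one measurement into a binding free energy.

    IC50 values are Cheng-Prusoff-corrected when the assay Km(ATP) is given;
    without a Km the IC50 is taken as the Ki (valid when Km >> [S0]). All
    concentration-to-molar conversion happens here, in one place.
    """
    if m.quantity == "dG":
        if m.unit not in {"kcal/mol", "kcal_per_mol"}:
            raise ValueError("dG measurements must be in kcal/mol")
        return BindingFreeEnergy(m.ligand_id, m.target_id, m.value, uncertainty)
    value = m.value
    if m.quantity == "IC50":
        if m.km_atp is not None:
            s0 = 0.0 if m.s0_atp is None else m.s0_atp
            value = ki_from_ic50(value, s0, m.km_atp)
        # otherwise IC50 ~ Ki under the Km >> [S0] assumption
    try:
        scale = _CONC_TO_MOLAR[m.unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {m.unit!r}") from None
    dg = dg_from_ki(value * scale, m.temperature)
    return BindingFreeEnergy(m.ligand_id, m.target_id, dg, uncertainty)


def free_energies(
    measurements: Iterable[AffinityMeasurement], uncertainty: float = 0.3
) -> list[BindingFreeEnergy]:
    """Convert a collection of measurements to binding free energies."""
    return [to_free_energy(m, uncertainty) for m in measurements]


def selectivity_records(
    energies: Iterable[BindingFreeEnergy], target_pair: tuple[str, str]
) -> list[SelectivityRecord]:
    """Pair up per-target free energies into per-ligand selectivities.

    Only ligands measured against both targets contribute a record.
    """
    t1, t2 = target_pair
    by_ligand: dict[str, dict[str, float]] = {}
    for e in energies:
        by_ligand.setdefault(e.ligand_id, {})[e.target_id] = e.dG
    records = []
    for ligand in by_ligand:
        d = by_ligand[ligand]
        if t1 in d and t2 in d:
            records.append(
                SelectivityRecord(ligand, target_pair, selectivity(d[t1], d[t2]))
            )
    if not records:
        raise ValueError(f"no ligand measured against both of {target_pair}")
    return records
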