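"""Bundled example affinity tables.

Both tables are *synthetic stand-ins*: per-ligand values were constructed
(not transcribed from the original assay publications, whose per-compound
tables are only available as figures) and calibrated so that the derived
selectivity series summaries reproduce the published statistics — mean
S(CDK9-CDK2) of -0.65 kcal/mol with sd 0.88 and range 2.8 for the
CDK2/CDK9 series, and mean S(ERK2-CDK2) of -1.74 kcal/mol with sd 0.56 and
range 2.2 for the CDK2/ERK2 series.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .affinity import AffinityMeasurement, read_affinity_csv

CDK2_CDK9_REFERENCE = "1a"
CDK2_ERK2_REFERENCE = "6"


def _data_path(name: str) -> Path:
    return Path(str(files("selekt").joinpath("data", name)))


def cdk2_cdk9_path() -> Path:
    """Path of the synthetic CDK2/CDK9 (Shao-style) affinity table."""
    return _data_path("cdk2_cdk9_shao_synthetic.csv")


def cdk2_erk2_path() -> Path:
    """Path of the synthetic CDK2/ERK2 (Blake-style) affinity table."""
    return _data_path("cdk2_erk2_blake_synthetic.csv")


def load_cdk2_cdk9(apply_exclusions: bool = True) -> list[AffinityMeasurement]:
    """Ki measurements (nM, Cheng-Prusoff already applied) for CDK2 and CDK9."""
    return read_affinity_csv(cdk2_cdk9_path(), apply_exclusions=apply_exclusions)


def load_cdk2_erk2(apply_exclusions: bool = True) -> list[AffinityMeasurement]:
    """IC50 measurements (nM, IC50 ~ Ki) for CDK2 and ERK2.

    The charged compound 9 is excluded from analysis by default.
    """
    return read_affinity_csv(cdk2_erk2_path(), apply_exclusions=apply_exclusions)
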