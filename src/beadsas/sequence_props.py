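"""Sequence-derived macromolecular properties.

Computes unhydrated (dry) and hydrated volumes, molecular weight, partial
specific volume, bound-water count and the 280 nm absorption coefficient of
a protein, glycoprotein or carbohydrate from its residue composition.  The
dry volume is the sum of per-residue unhydrated crystal-structure volumes;
the hydrated volume adds a monolayer of bound water (0.3 g water per gram of
macromolecule, 0.0245 nm^3 per bound water molecule, compared with
0.0299 nm^3 in bulk water).

The dry volume is the quantity that constrains coarse-grained sphere-model
construction (see :mod:`beadsas.sphere_models`); the hydrated volume
constrains the hydration-shell cutoff used for X-ray modelling.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import yaml

from .datatypes import MacromoleculeProperties, SequenceCounts

__all__ = [
    "ResidueVolumeTable",
    "load_volume_tables",
    "default_volume_table",
    "known_codes",
    "residue_volume",
    "dry_volume",
    "molecular_weight",
    "bound_water_count",
    "hydrated_volume",
    "partial_specific_volume",
    "absorption_coefficient_280",
    "compute_properties",
    "report",
    "HYDRATION_RATIO",
    "BOUND_WATER_VOLUME",
    "BULK_WATER_VOLUME",
    "WATER_MOLAR_MASS",
    "RESIDUE_MASSES",
]

#: grams of bound water per gram of protein or glycoprotein
HYDRATION_RATIO = 0.3
#: volume of one hydration-shell water molecule (nm^3)
BOUND_WATER_VOLUME = 0.0245
#: volume of one bulk water molecule (nm^3), for reference
BULK_WATER_VOLUME = 0.0299
#: molar mass of water (g/mol)
WATER_MOLAR_MASS = 18.015

AVOGADRO = 6.02214076e23
NM3_TO_CM3 = 1.0e-21

DEFAULT_VOLUME_SET = "consensus_crystal"

# Average residue masses (g/mol): free monomer minus one water, i.e. the
# mass contributed per residue inside a chain.  Monosaccharides are the
# glycosidically linked (anhydro) masses.  One water per chain is added for
# the termini when computing a molecular weight.
RESIDUE_MASSES: dict[str, float] = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
    "FUC": 146.14, "GAL": 162.14, "GLC": 162.14, "MAN": 162.14,
    "NAG": 203.19, "NGA": 203.19, "SIA": 291.26,
}


class UnknownResidueError(KeyError):
    """A residue code absent from the active parameter table."""


@dataclass(frozen=True)
class ResidueVolumeTable:
    """A labelled residue-volume parameter set (values in 1e-3 nm^3)."""

    label: str
    volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        for code, v in self.volumes.items():
            if v <= 0:
                raise ValueError(f"non-positive volume for {code!r} in {self.label!r}")

    def __contains__(self, code: str) -> bool:
        return code in self.volumes


def load_volume_tables(path=None) -> dict[str, ResidueVolumeTable]:
    """Load residue-volume parameter sets from a YAML file.

    The file maps a set label to a ``CODE: volume`` mapping with volumes in
    1e-3 nm^3.  With no ``path`` the packaged data file is used.
    """
    if path is None:
        source = importlib.resources.files("beadsas").joinpath(
            "data/residue_volumes.yml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as handle:
            raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ValueError("volume file must map set labels to code: volume maps")
    return {
        label: ResidueVolumeTable(label, {str(c).upper(): float(v)
                                          for c, v in table.items()})
        for label, table in raw.items()
    }


@lru_cache(maxsize=1)
def default_volume_table() -> ResidueVolumeTable:
    """The consensus unhydrated crystal-structure volume set."""
    return load_volume_tables()[DEFAULT_VOLUME_SET]


def known_codes() -> frozenset[str]:
    """Residue/monosaccharide codes recognised by the default tables."""
    return frozenset(default_volume_table().volumes)


def residue_volume(code: str, table: ResidueVolumeTable | None = None) -> float:
    """Tabulated unhydrated volume of one residue, in 1e-3 nm^3."""
    table = table or default_volume_table()
    code = code.strip().upper()
    try:
        return float(table.volumes[code])
    except KeyError:
        raise UnknownResidueError(
            f"residue code {code!r} not in volume set {table.label!r}") from None


def _require_counts(counts: SequenceCounts) -> dict[str, int]:
    if counts.total() < 1:
        raise ValueError("sequence is empty")
    return counts.counts


def dry_volume(counts: SequenceCounts,
               table: ResidueVolumeTable | None = None) -> float:
    """Unhydrated macromolecular volume (nm^3) from residue frequencies."""
    table = table or default_volume_table()
    total = 0.0
    for code, n in _require_counts(counts).items():
        total += n * residue_volume(code, table)
    return total * 1.0e-3  # tabulated values are 1e-3 nm^3


def molecular_weight(counts: SequenceCounts, n_chains: int = 1) -> float:
    """Molecular weight (g/mol) from average residue masses.

    One water is added per polypeptide/polysaccharide chain for the termini.
    """
    if n_chains < 0:
        raise ValueError("n_chains must be non-negative")
    total = 0.0
    for code, n in _require_counts(counts).items():
        try:
            total += n * RESIDUE_MASSES[code]
        except KeyError:
            raise UnknownResidueError(
                f"residue code {code!r} has no tabulated mass") from None
    return total + n_chains * WATER_MOLAR_MASS


def bound_water_count(molecular_weight: float,
                      hydration_ratio: float = HYDRATION_RATIO,
                      water_molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Number of hydration-shell waters bound per macromolecule."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if hydration_ratio < 0:
        raise ValueError("hydration ratio must be non-negative")
    return hydration_ratio * molecular_weight / water_molar_mass


def hydrated_volume(dry: float, waters: float,
                    shell_water_volume: float = BOUND_WATER_VOLUME) -> float:
    """Hydrated volume (nm^3): dry volume plus the bound-water shell."""
    if dry <= 0:
        raise ValueError("dry volume must be positive")
    if waters < 0:
        raise ValueError("bound water count must be non-negative")
    return dry + waters * shell_water_volume


def partial_specific_volume(dry_volume: float, molecular_weight: float) -> float:
    """Partial specific volume v-bar (cm^3/g) = N_A * V / M."""
    if dry_volume <= 0 or molecular_weight <= 0:
        raise ValueError("dry volume and molecular weight must be positive")
    return AVOGADRO * dry_volume * NM3_TO_CM3 / molecular_weight


def absorption_coefficient_280(counts: SequenceCounts,
                               molecular_weight_value: float | None = None) -> float:
    """Absorption coefficient A(280 nm, 1%, 1 cm) from Trp/Tyr/cystine content.

    Uses molar extinctions 5500 (Trp), 1490 (Tyr) and 125 (cystine)
    M^-1 cm^-1; all cysteines are assumed paired into cystines.
    """
    c = _require_counts(counts)
    mw = molecular_weight_value or molecular_weight(counts)
    epsilon = (5500.0 * c.get("TRP", 0) + 1490.0 * c.get("TYR", 0)
               + 125.0 * (c.get("CYS", 0) // 2))
    return 10.0 * epsilon / mw


def compute_properties(counts: SequenceCounts,
                       table: ResidueVolumeTable | None = None,
                       n_chains: int = 1) -> MacromoleculeProperties:
    """All sequence-derived properties in one bundle."""
    v_dry = dry_volume(counts, table)
    mw = molecular_weight(counts, n_chains)
    waters = bound_water_count(mw)
    return MacromoleculeProperties(
        dry_volume=v_dry,
        hydrated_volume=hydrated_volume(v_dry, waters),
        molecular_weight=mw,
        partial_specific_volume=partial_specific_volume(v_dry, mw),
        bound_water_count=waters,
        absorption_coefficient=absorption_coefficient_280(counts, mw),
    )


_REPORT_LINES = {
    "molecular_weight": "Molecular weight:            {p.molecular_weight:12.1f} g/mol",
    "absorption_coefficient": "Absorption coefficient A280: {p.absorption_coefficient:12.3f} (1%, 1 cm)",
    "partial_specific_volume": "Partial specific volume:     {p.partial_specific_volume:12.4f} cm^3/g",
    "dry_volume": "Macromolecular volume:       {p.dry_volume:12.3f} nm^3",
}

REPORT_MODES = {
    "model": ("dry_volume",),
    "auc": ("molecular_weight", "absorption_coefficient",
            "partial_specific_volume"),
    "project": ("molecular_weight", "absorption_coefficient",
                "partial_specific_volume", "dry_volume"),
    # classic: project fields plus labelled extras
    "classic": ("molecular_weight", "absorption_coefficient",
                "partial_specific_volume", "dry_volume"),
}


def report(properties: MacromoleculeProperties, mode: str = "project") -> str:
    """Render a text report of the selected property fields.

    ``model`` prints the macromolecular volume only; ``auc`` the weight,
    absorption coefficient and partial specific volume; ``project`` all
    four; ``classic`` the project fields plus hydration extras.
    """
    try:
        fields = REPORT_MODES[mode]
    except KeyError:
        raise ValueError(f"unknown report mode {mode!r}; "
                         f"choose from {sorted(REPORT_MODES)}") from None
    lines = [f"Report mode: {mode}"]
    lines += [_REPORT_LINES[f].format(p=properties) for f in fields]
    if mode == "classic":
        lines.append(
            f"Hydrated volume:             {properties.hydrated_volume:12.3f} nm^3")
        lines.append(
            f"Bound water molecules:       {properties.bound_water_count:12.1f}")
        lines.append(
            f"Shell water volume:          {BOUND_WATER_VOLUME:12.4f} nm^3 "
            f"(bulk {BULK_WATER_VOLUME:.4f} nm^3)")
    return "\n".join(lines)
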