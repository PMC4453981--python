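"""Readers and writers for the file formats used in constrained modelling.

PDB atomistic input (ATOM/HETATM records), sphere-model PDB output,
two-column scattering-curve text, sequence files (FASTA, PDB-derived or
residue-frequency YAML) and the YAML analysis-parameter file.

PDB coordinates are Angstrom on disk and nm in memory; this module is the
only place the conversion happens.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO

from .datatypes import AtomModel, ScatterCurve, SequenceCounts, SphereModel

__all__ = [
    "read_pdb_atoms",
    "write_pdb_atoms",
    "write_sphere_model_pdb",
    "read_sphere_model_pdb",
    "read_experimental_curve",
    "write_curve",
    "read_sequence",
    "sequence_to_yaml",
    "AnalysisParams",
    "FitWindow",
    "RangeParams",
    "SphereParams",
    "HydrateParams",
    "CurveParams",
    "read_params",
    "ParameterError",
]

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

# standard one-letter -> three-letter amino acid codes for FASTA input
AA_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# ---------------------------------------------------------------------------
# PDB atoms


def read_pdb_atoms(path) -> AtomModel:
    """Read all ATOM and HETATM records of a PDB file, in file order.

    Coordinates are converted from Angstrom to nm.  Other record types are
    ignored.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` if no record parses.
    """
    codes: list[str] = []
    coords: list[tuple[float, float, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinate fields") from None
            codes.append(line[17:20].strip().upper())
            coords.append((x / ANGSTROM_PER_NM, y / ANGSTROM_PER_NM,
                           z / ANGSTROM_PER_NM))
    if not coords:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return AtomModel(residue_codes=codes, coords=np.array(coords),
                     source_path=str(path))


def write_pdb_atoms(model: AtomModel, path) -> None:
    """Write an atom model as minimal PDB ATOM records (nm -> Angstrom)."""
    if len(model) == 0:
        raise ValueError("cannot write an empty atom model")
    with open(path, "w") as handle:
        for idx, ((x, y, z), code) in enumerate(
                zip(model.coords, model.residue_codes)):
            handle.write(
                f"ATOM  {idx % 99999 + 1:5d}  CA  {code:>3s} A"
                f"{idx % 9999 + 1:4d}    "
                f"{x * ANGSTROM_PER_NM:8.3f}{y * ANGSTROM_PER_NM:8.3f}"
                f"{z * ANGSTROM_PER_NM:8.3f}  1.00  0.00           C\n")
        handle.write("END\n")


_SPHERE_RADIUS_REMARK = "REMARK 265 SPHERE RADIUS"
_SPHERE_HYDRATED_REMARK = "REMARK 265 HYDRATED"


def write_sphere_model_pdb(model: SphereModel, path) -> None:
    """Write a sphere model as a PDB file, one ATOM record per sphere.

    The common sphere radius (Angstrom) is recorded in a REMARK line.  The
    atom name/residue fields are cosmetic placeholders for visualization.
    """
    if len(model) == 0:
        raise ValueError("cannot write an empty sphere model")
    with open(path, "w") as handle:
        handle.write(f"{_SPHERE_RADIUS_REMARK} "
                     f"{model.radius * ANGSTROM_PER_NM:.4f} ANGSTROM\n")
        if model.hydrated:
            handle.write(f"{_SPHERE_HYDRATED_REMARK} TRUE\n")
        for idx, (x, y, z) in enumerate(model.centres):
            serial = idx % 99999 + 1
            resseq = idx % 9999 + 1
            handle.write(
                f"ATOM  {serial:5d}  C   SER A{resseq:4d}    "
                f"{x * ANGSTROM_PER_NM:8.3f}{y * ANGSTROM_PER_NM:8.3f}"
                f"{z * ANGSTROM_PER_NM:8.3f}  1.00  0.00           C\n")
        handle.write("END\n")


def read_sphere_model_pdb(path) -> SphereModel:
    """Re-read a sphere model written by :func:`write_sphere_model_pdb`."""
    radius_nm = None
    hydrated = False
    with open(path) as handle:
        for line in handle:
            if line.startswith(_SPHERE_RADIUS_REMARK):
                radius_nm = float(line.split()[4]) / ANGSTROM_PER_NM
            elif line.startswith(_SPHERE_HYDRATED_REMARK):
                hydrated = True
    if radius_nm is None:
        raise ValueError(f"{path}: no sphere-radius REMARK found")
    atoms = read_pdb_atoms(path)
    return SphereModel(centres=atoms.coords, boxside=2.0 * radius_nm,
                       hydrated=hydrated)


# ---------------------------------------------------------------------------
# scattering curves


def read_experimental_curve(path) -> ScatterCurve:
    """Read a whitespace-separated two-or-more-column scattering curve.

    First column Q (nm^-1), second I; further columns (e.g. errors) are kept
    in ``metadata['extra_columns']`` but unused.  ``#`` comment lines and
    blank lines are skipped, rows are sorted by Q and duplicate Q values are
    rejected.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (Q, I)")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise ValueError(f"{path}: duplicate Q values")
    meta = {}
    if data.shape[1] > 2:
        meta["extra_columns"] = data[:, 2:]
    return ScatterCurve(q=data[:, 0], i=data[:, 1], kind="experimental",
                        source_path=str(path), metadata=meta)


def write_curve(curve: ScatterCurve, path) -> None:
    """Write a curve as two-column text (Q nm^-1, I)."""
    with open(path, "w") as handle:
        for q, i in zip(curve.q, curve.i):
            handle.write(f"{q:14.6e} {i:14.6e}\n")


# ---------------------------------------------------------------------------
# sequences


def read_sequence(path, format: str, on_unknown: str = "error") -> SequenceCounts:
    """Read a residue-frequency map from a PDB, FASTA or YAML file.

    PDB input counts one residue per unique (chain, residue number,
    insertion code) among ATOM/HETATM records, so residues missing from the
    structure are not counted.  FASTA input uses one-letter amino-acid
    codes; YAML input holds ``CODE: frequency`` pairs with three-letter
    codes.  Unknown codes raise by default (``on_unknown="skip"`` drops
    them with a log notice).
    """
    from .sequence_props import known_codes

    fmt = format.lower()
    if fmt == "fasta":
        counts: dict[str, int] = {}
        n_records = 0
        for record in SeqIO.parse(str(path), "fasta"):
            n_records += 1
            for pos, letter in enumerate(str(record.seq).upper(), start=1):
                try:
                    code = AA_ONE_TO_THREE[letter]
                except KeyError:
                    raise ValueError(
                        f"{path}: unknown residue code {letter!r} at position "
                        f"{pos} of record {record.id!r}") from None
                counts[code] = counts.get(code, 0) + 1
        if n_records == 0 or not counts:
            raise ValueError(f"{path}: empty FASTA sequence")
        return SequenceCounts(counts)

    if fmt == "yaml":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict) or not raw:
            raise ValueError(f"{path}: expected a CODE: frequency mapping")
        counts = {}
        valid = known_codes()
        for pos, (code, n) in enumerate(raw.items(), start=1):
            code = str(code).strip().upper()
            if code not in valid:
                if on_unknown == "skip":
                    logger.info("skipping unknown residue code %r", code)
                    continue
                raise ValueError(
                    f"{path}: unknown residue code {code!r} (entry {pos})")
            counts[code] = counts.get(code, 0) + int(n)
        if not counts:
            raise ValueError(f"{path}: no known residues")
        return SequenceCounts(counts)

    if fmt == "pdb":
        valid = known_codes()
        seen: set[tuple[str, str, str]] = set()
        counts = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.startswith(("ATOM  ", "HETATM")):
                    continue
                code = line[17:20].strip().upper()
                key = (line[21:22], line[22:26].strip(), line[26:27])
                if key in seen:
                    continue
                seen.add(key)
                if code not in valid:
                    if on_unknown == "skip":
                        logger.info("skipping unknown residue %r at line %d",
                                    code, lineno)
                        continue
                    raise ValueError(
                        f"{path}:{lineno}: unknown residue code {code!r}")
                counts[code] = counts.get(code, 0) + 1
        if not counts:
            raise ValueError(f"{path}: no residues found")
        return SequenceCounts(counts)

    raise ValueError(f"unknown sequence format {format!r}")


def sequence_to_yaml(counts: SequenceCounts, path) -> None:
    """Write residue frequencies as ``CODE: n`` lines, sorted by code."""
    if counts.total() < 1:
        raise ValueError("cannot write an empty sequence")
    with open(path, "w") as handle:
        for code in sorted(counts.counts):
            handle.write(f"{code}: {counts.counts[code]}\n")


# ---------------------------------------------------------------------------
# analysis parameters


class ParameterError(ValueError):
    """A missing, mistyped or inconsistent analysis parameter."""


@dataclass(frozen=True)
class RangeParams:
    qmin: float
    qmax: float


@dataclass(frozen=True)
class FitWindow:
    qmin: float
    qmax: float
    fitmin: float
    fitmax: float


@dataclass(frozen=True)
class SphereParams:
    cutoff: int  # atoms per grid box needed to spawn a sphere
    boxside: float  # nm


@dataclass(frozen=True)
class HydrateParams:
    positions: int  # hydration positions per sphere (26-point cube shell)
    cutoff: int  # Step-2 filter cutoff, spheres per grid box


@dataclass(frozen=True)
class CurveParams:
    qmax: float
    npoints: int
    radbins: int
    smear: bool
    wavelength: float | None = None
    spread: float | None = None
    divergence: float | None = None


@dataclass(frozen=True)
class AnalysisParams:
    """Validated analysis-parameter bundle (mirrors the YAML input file)."""

    wide: RangeParams
    rg: FitWindow
    sphere: SphereParams
    hydrate: HydrateParams
    curve: CurveParams
    rfac: RangeParams
    rxs1: FitWindow | None = None
    rxs2: FitWindow | None = None


_SCHEMA = {
    "wide": {"qmin": float, "qmax": float},
    "rg": {"qmin": float, "qmax": float, "fitmin": float, "fitmax": float},
    "sphere": {"cutoff": int, "boxside": float},
    "hydrate": {"positions": int, "cutoff": int},
    "curve": {"qmax": float, "npoints": int, "radbins": int, "smear": bool},
    "rfac": {"qmin": float, "qmax": float},
}
_RXS_SCHEMA = {"qmin": float, "qmax": float, "fitmin": float, "fitmax": float}


def _coerce(block: str, field: str, value, kind):
    if value is None:
        raise ParameterError(f"missing parameter {block}.{field}")
    if kind is bool:
        if not isinstance(value, bool):
            raise ParameterError(f"{block}.{field} must be a boolean")
        return value
    if kind is int:
        if isinstance(value, bool) or (isinstance(value, float)
                                       and not value.is_integer()):
            raise ParameterError(f"{block}.{field} must be an integer")
        try:
            return int(value)
        except (TypeError, ValueError):
            raise ParameterError(f"{block}.{field} must be an integer") from None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParameterError(f"{block}.{field} must be a number") from None


def _read_block(raw: dict, block: str, schema: dict) -> dict:
    if block not in raw or raw[block] is None:
        raise ParameterError(f"missing parameter block {block!r}")
    if not isinstance(raw[block], dict):
        raise ParameterError(f"parameter block {block!r} must be a mapping")
    out = {}
    for field, kind in schema.items():
        if field not in raw[block]:
            raise ParameterError(f"missing parameter {block}.{field}")
        out[field] = _coerce(block, field, raw[block][field], kind)
    return out


def _check_window(block: str, w: FitWindow) -> None:
    if not w.qmin < w.qmax:
        raise ParameterError(f"{block}: qmin must be below qmax")
    if not w.fitmin < w.fitmax:
        raise ParameterError(f"{block}: fitmin must be below fitmax")


def read_params(path) -> AnalysisParams:
    """Read and validate the YAML analysis-parameter file.

    Required top-level blocks: wide, rg, sphere, hydrate, curve, rfac; the
    rxs1/rxs2 blocks are optional but must appear as a pair (they only
    apply to elongated-molecule analyses).  Every violation is reported
    with the offending ``block.field`` name.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: not a YAML mapping")

    blocks = {name: _read_block(raw, name, schema)
              for name, schema in _SCHEMA.items()}

    curve_extra: dict[str, float | None] = {
        "wavelength": None, "spread": None, "divergence": None}
    if blocks["curve"]["smear"]:
        for field in curve_extra:
            if field not in raw["curve"]:
                raise ParameterError(
                    f"curve.smear is true but curve.{field} is missing "
                    "(smearing needs wavelength, spread and divergence)")
            value = _coerce("curve", field, raw["curve"][field], float)
            if value <= 0:
                raise ParameterError(f"curve.{field} must be positive")
            curve_extra[field] = value

    params = AnalysisParams(
        wide=RangeParams(**blocks["wide"]),
        rg=FitWindow(**blocks["rg"]),
        sphere=SphereParams(**blocks["sphere"]),
        hydrate=HydrateParams(**blocks["hydrate"]),
        curve=CurveParams(**blocks["curve"], **curve_extra),
        rfac=RangeParams(**blocks["rfac"]),
        rxs1=FitWindow(**_read_block(raw, "rxs1", _RXS_SCHEMA))
        if "rxs1" in raw else None,
        rxs2=FitWindow(**_read_block(raw, "rxs2", _RXS_SCHEMA))
        if "rxs2" in raw else None,
    )

    if (params.rxs1 is None) != (params.rxs2 is None):
        raise ParameterError("rxs1 and rxs2 must be supplied together")

    for name in ("wide", "rfac"):
        block = getattr(params, name)
        if not block.qmin < block.qmax:
            raise ParameterError(f"{name}: qmin must be below qmax")
    _check_window("rg", params.rg)
    if params.rxs1 is not None:
        _check_window("rxs1", params.rxs1)
        _check_window("rxs2", params.rxs2)
        if params.rxs1.fitmin < params.rg.fitmax:
            raise ParameterError(
                "rxs1 fit window must lie above the rg fit window")
        if params.rxs2.fitmin < params.rxs1.fitmax:
            raise ParameterError(
                "rxs2 fit window must lie above the rxs1 fit window")

    if params.sphere.cutoff < 1:
        raise ParameterError("sphere.cutoff must be >= 1")
    if params.sphere.boxside <= 0:
        raise ParameterError("sphere.boxside must be positive")
    if params.hydrate.cutoff < 1:
        raise ParameterError("hydrate.cutoff must be >= 1")
    if params.hydrate.positions != 26:
        raise ParameterError(
            "hydrate.positions: only the 26-position cube shell is supported")
    if params.curve.npoints < 2:
        raise ParameterError("curve.npoints must be >= 2")
    if params.curve.radbins < 1:
        raise ParameterError("curve.radbins must be >= 1")
    if params.curve.qmax <= 0:
        raise ParameterError("curve.qmax must be positive")

    return params
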