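"""Core data containers shared across the package.

Unit conventions
----------------
All lengths are nanometres (nm) and all scattering vector magnitudes Q are
nm^-1.  PDB files store coordinates in Angstrom; conversion to nm happens at
the single point of entry/exit in :mod:`beadsas.io_formats` and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "AtomModel",
    "SequenceCounts",
    "SphereModel",
    "ScatterCurve",
    "DistanceHistogram",
    "GuinierResult",
    "RFactorResult",
    "SmearingSpec",
    "MacromoleculeProperties",
    "FWHM_TO_SIGMA",
]

#: conversion from a full-width-at-half-maximum to a Gaussian standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class AtomModel:
    """Ordered list of labelled atomic coordinates from an atomistic model.

    Parameters
    ----------
    residue_codes
        Upper-case three-letter residue code of each atom, in record order.
    coords
        ``(n, 3)`` array of coordinates in nm.
    source_path
        Originating file, if any (provenance only).
    metadata
        Free-form annotations; fixture generators record analytic truths
        (``true_rg``, ``true_volume``) here.
    """

    residue_codes: list[str]
    coords: np.ndarray
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_codes) != len(self.coords):
            raise ValueError("residue_codes and coords lengths differ")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atomic coordinates")
        self.residue_codes = [str(c).strip().upper() for c in self.residue_codes]

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SequenceCounts:
    """Residue-code -> frequency map describing a macromolecular composition."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for code, n in self.counts.items():
            code = str(code).strip().upper()
            n = int(n)
            if n < 0:
                raise ValueError(f"negative frequency for residue {code!r}")
            clean[code] = clean.get(code, 0) + n
        self.counts = clean

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SphereModel:
    """Set of equal-radius sphere centres representing a coarse-grained model.

    The sphere radius is tied to the grid used to build the model: it is
    always half the grid box side, so only ``boxside`` is stored.
    """

    centres: np.ndarray
    boxside: float
    hydrated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.size == 0:
            self.centres = self.centres.reshape(0, 3)
        self.centres = np.atleast_2d(self.centres)
        if self.centres.ndim != 2 or self.centres.shape[1] != 3:
            raise ValueError("centres must be an (n, 3) array")
        if not np.isfinite(self.boxside) or self.boxside <= 0:
            raise ValueError("boxside must be positive")
        if not np.all(np.isfinite(self.centres)):
            raise ValueError("non-finite sphere centres")

    @property
    def radius(self) -> float:
        """Uniform sphere radius (nm); half the grid box side."""
        return self.boxside / 2.0

    def __len__(self) -> int:
        return len(self.centres)


@dataclass
class ScatterCurve:
    """Paired (Q, I) arrays with provenance.

    ``q`` must be strictly increasing and non-negative (nm^-1); intensities
    are in arbitrary units.  ``kind`` is ``"theoretical"`` or
    ``"experimental"``; ``smeared`` marks curves already convolved with an
    instrumental resolution function.
    """

    q: np.ndarray
    i: np.ndarray
    kind: str = "theoretical"
    smeared: bool = False
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.q.ndim != 1 or self.i.ndim != 1:
            raise ValueError("q and i must be 1-D arrays")
        if len(self.q) != len(self.i):
            raise ValueError("q and i lengths differ")
        if len(self.q) and (not np.all(np.isfinite(self.q)) or np.any(self.q < 0)):
            raise ValueError("q values must be finite and non-negative")
        if len(self.q) > 1 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q values must be strictly increasing")
        if len(self.i) and not np.all(np.isfinite(self.i)):
            raise ValueError("intensities must be finite")
        if self.kind not in ("theoretical", "experimental"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class DistanceHistogram:
    """Pair-distance histogram of a sphere model.

    ``bin_centres`` (nm) are the representative distances d_j, ``counts`` the
    number of sphere pairs per bin A_j; the total count is n(n-1)/2 for a
    model of n spheres.
    """

    bin_centres: np.ndarray
    counts: np.ndarray
    n_spheres: int
    bin_width: float
    mode: str = "modern"

    def __post_init__(self) -> None:
        self.bin_centres = np.asarray(self.bin_centres, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_centres) != len(self.counts):
            raise ValueError("bin_centres and counts lengths differ")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        expected = self.n_spheres * (self.n_spheres - 1) // 2
        if int(self.counts.sum()) != expected:
            raise ValueError(
                f"histogram holds {int(self.counts.sum())} pair distances, "
                f"expected n(n-1)/2 = {expected}"
            )

    @property
    def nbins(self) -> int:
        return len(self.bin_centres)


@dataclass
class GuinierResult:
    """Result of a linear Guinier-type fit.

    ``kind`` is ``"rg"`` (ln I vs Q^2, overall radius of gyration) or
    ``"rxs"`` (ln IQ vs Q^2, cross-sectional radius of gyration).
    ``intercept`` is the intercept of the straight-line fit on the
    transformed ordinate, so for an Rg fit ``exp(intercept)`` is I(0).
    """

    value: float
    kind: str
    intercept: float
    window: tuple[float, float]
    n_points: int
    qrg_range: tuple[float, float]
    correlation: float

    @property
    def i0(self) -> float:
        """Forward scattered intensity I(0) (Rg fits only)."""
        if self.kind != "rg":
            raise ValueError("I(0) is only defined for an Rg fit")
        return float(np.exp(self.intercept))


@dataclass
class RFactorResult:
    """Goodness of fit between a theoretical and an experimental curve."""

    r_factor: float  # percent; lower is better
    eta: float  # scale applied to the theoretical curve
    window: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.r_factor < 0:
            raise ValueError("R factor cannot be negative")
        if self.eta <= 0:
            raise ValueError("scale factor eta must be positive")


@dataclass
class SmearingSpec:
    """Gaussian beam-smearing description for SANS curves.

    Parameters
    ----------
    wavelength
        Neutron wavelength lambda (nm).
    spread
        Fractional wavelength spread Delta-lambda/lambda, as a FWHM.
    divergence
        Beam angular divergence Delta-theta (radians), as a FWHM.
    sigma_func
        Optional override returning the Gaussian standard deviation sigma(Q)
        directly, for instrument-exact resolution functions.

    Notes
    -----
    The default width model adds the divergence and wavelength-spread FWHM
    contributions in quadrature,

        FWHM(Q) = sqrt[ ((4 pi / lambda) * divergence)^2 + (Q * spread)^2 ]

    and converts to a standard deviation.  This is a documented convention
    of this package; pass ``sigma_func`` for other instrument models.
    """

    wavelength: float
    spread: float
    divergence: float
    sigma_func: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.spread < 0 or self.divergence < 0:
            raise ValueError("spread and divergence must be non-negative")

    def sigma(self, q: np.ndarray) -> np.ndarray:
        """Gaussian standard deviation of the smearing kernel at each Q."""
        q = np.asarray(q, dtype=float)
        if self.sigma_func is not None:
            return np.asarray(self.sigma_func(q), dtype=float)
        fwhm = np.hypot((4.0 * np.pi / self.wavelength) * self.divergence,
                        q * self.spread)
        return fwhm * FWHM_TO_SIGMA


@dataclass
class MacromoleculeProperties:
    """Sequence-derived physical properties of a macromolecule."""

    dry_volume: float  # nm^3
    hydrated_volume: float  # nm^3
    molecular_weight: float  # g/mol
    partial_specific_volume: float  # cm^3/g
    bound_water_count: float  # molecules per macromolecule
    absorption_coefficient: float  # A(280 nm, 1%, 1 cm)

    def __post_init__(self) -> None:
        for name in ("dry_volume", "hydrated_volume", "molecular_weight",
                     "partial_specific_volume"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")
        if self.hydrated_volume < self.dry_volume:
            raise ValueError("hydrated volume cannot be below dry volume")
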