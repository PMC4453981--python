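"""Coarse-grained sphere (bead) models.

Grid transformation of atomistic coordinates into equal-radius sphere
models, the four-step hydration-monolayer construction used for SAXS
modelling, sphere-model volume and radius of gyration, and optimization of
the grid box side and hydration cutoff against sequence-derived target
volumes.

Grid semantics
--------------
The grid is anchored at the per-axis minimum coordinate of the input
points.  A box spawns a sphere when it holds at least ``cutoff`` points
(inclusive threshold; pass ``strict=True`` for a strictly-greater-than
reading).  The sphere sits at the box centre with radius half the box side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import AtomModel, SphereModel

__all__ = [
    "DEFAULT_GRID_CUTOFF",
    "GridSpec",
    "grid_transform",
    "sphere_model_volume",
    "hydration_positions",
    "hydrate_sphere_model",
    "sphere_rg",
    "optimize_box_side",
    "optimize_hydration_cutoff",
    "BoxSideResult",
    "HydrationCutoffResult",
]

logger = logging.getLogger(__name__)

#: atoms per grid box needed to spawn a sphere (the value used for the
#: published structure determinations)
DEFAULT_GRID_CUTOFF = 4

#: Step-2 hydration filter candidates; the typical optimum lies at 10-12
DEFAULT_HYDRATION_CUTOFFS = tuple(range(1, 15))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the 3-D counting grid used for a transformation."""

    origin: tuple[float, float, float]
    boxside: float
    extents: tuple[int, int, int]
    cutoff: int


def _points_of(model) -> np.ndarray:
    if isinstance(model, AtomModel):
        return model.coords
    if isinstance(model, SphereModel):
        return model.centres
    points = np.atleast_2d(np.asarray(model, dtype=float))
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of points")
    return points


def _grid_indices(points: np.ndarray, boxside: float,
                  origin: np.ndarray | None = None):
    """Integer box indices of each point on a min-anchored grid."""
    if origin is None:
        origin = points.min(axis=0)
    idx = np.floor((points - origin) / boxside).astype(np.int64)
    # guard against negative indices from float fuzz at the origin
    np.maximum(idx, 0, out=idx)
    extents = idx.max(axis=0) + 1
    return idx, np.asarray(origin, dtype=float), extents


def grid_transform(model, boxside: float, cutoff: int = DEFAULT_GRID_CUTOFF,
                   strict: bool = False,
                   origin=None) -> SphereModel:
    """Convert atoms (or sphere centres) into a sphere model on a grid.

    Each grid box holding at least ``cutoff`` points (``> cutoff`` when
    ``strict``) becomes one sphere at the box centre with radius
    ``boxside / 2``.  An empty result is returned with a warning rather
    than silently, so thousand-model runs can record the failure and move
    on.

    Parameters
    ----------
    model
        ``AtomModel``, ``SphereModel`` or an ``(n, 3)`` coordinate array (nm).
    boxside
        Grid box side (nm); also twice the output sphere radius.
    cutoff
        Occupancy threshold per box.
    strict
        Use a strictly-greater-than threshold instead of the default
        inclusive one.
    origin
        Optional fixed grid origin (nm) for reproducibility across models;
        default anchors at the input minimum coordinate.
    """
    points = _points_of(model)
    if len(points) < 1:
        raise ValueError("cannot grid-transform an empty model")
    if boxside <= 0:
        raise ValueError("boxside must be positive")
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")

    idx, grid_origin, extents = _grid_indices(points, boxside,
                                              None if origin is None
                                              else np.asarray(origin, float))
    flat = np.ravel_multi_index(idx.T, extents)
    occupied, counts = np.unique(flat, return_counts=True)
    keep = counts > cutoff if strict else counts >= cutoff
    kept = np.array(np.unravel_index(occupied[keep], extents)).T

    logger.debug(
        "grid_transform: %d points, boxside=%.4f nm, cutoff=%d (%s), "
        "%d/%d occupied boxes kept",
        len(points), boxside, cutoff,
        "count > cutoff" if strict else "count >= cutoff",
        len(kept), len(occupied))

    if len(kept) == 0:
        warnings.warn(
            f"grid_transform produced no spheres ({len(points)} points, "
            f"cutoff {cutoff}); model below occupancy threshold",
            stacklevel=2)
    centres = grid_origin + (kept + 0.5) * boxside
    return SphereModel(
        centres=centres.reshape(-1, 3), boxside=boxside,
        metadata={"grid": GridSpec(tuple(grid_origin), boxside,
                                   tuple(int(e) for e in extents), cutoff)})


def sphere_model_volume(model: SphereModel, convention: str = "box") -> float:
    """Volume of a sphere model (nm^3).

    ``box`` (default) counts one full grid box per sphere, n * boxside^3,
    self-consistent with grid occupancy; ``sphere`` sums literal sphere
    volumes n * (4/3) pi (boxside/2)^3.
    """
    if len(model) == 0:
        raise ValueError("empty sphere model has no volume")
    if convention == "box":
        return len(model) * model.boxside ** 3
    if convention == "sphere":
        return len(model) * (4.0 / 3.0) * np.pi * model.radius ** 3
    raise ValueError(f"unknown volume convention {convention!r}")


def hydration_positions(centre, radius: float) -> np.ndarray:
    """The 26 candidate hydration positions around one sphere.

    Corners, edge mid-points and face centres of a cube of side four times
    the sphere radius centred on the sphere: offsets {-2r, 0, +2r}^3 minus
    the centre itself.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    steps = np.array([-2.0 * radius, 0.0, 2.0 * radius])
    offsets = np.array([(dx, dy, dz)
                        for dx in steps for dy in steps for dz in steps
                        if (dx, dy, dz) != (0.0, 0.0, 0.0)])
    return np.asarray(centre, dtype=float) + offsets


def hydrate_sphere_model(dry: SphereModel, hydration_cutoff: int) -> SphereModel:
    """Add a hydration monolayer to a dry sphere model (four-step scheme).

    Step 1 surrounds every sphere with its 26 candidate hydration
    positions; Step 2 filters the expanded set on the dry model's grid with
    ``hydration_cutoff`` spheres per box; Step 3 restores the original dry
    spheres (extended structures can be lost in Step 2); Step 4 re-grids at
    a cutoff of one sphere per box, keeping the first sphere per box with
    the dry spheres ordered first so every dry centre survives.

    A higher ``hydration_cutoff`` removes more candidate waters, so the
    final sphere count never increases with the cutoff.
    """
    if len(dry) == 0:
        raise ValueError("cannot hydrate an empty sphere model")
    if hydration_cutoff < 1:
        raise ValueError("hydration cutoff must be >= 1")

    # Step 1: dry spheres plus the full 26-position shell of each
    offsets = hydration_positions((0.0, 0.0, 0.0), dry.radius)
    shell = (dry.centres[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    expanded = np.vstack([dry.centres, shell])

    # Step 2: grid filter of the expanded set at the hydration cutoff
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty step-2 output handled below
        filtered = grid_transform(expanded, dry.boxside,
                                  cutoff=hydration_cutoff)

    # Step 3: the dry spheres are added back, ordered first
    union = np.vstack([dry.centres, filtered.centres])

    # Step 4: deduplicate, one sphere per grid box, keep-first
    idx, _, extents = _grid_indices(union, dry.boxside)
    flat = np.ravel_multi_index(idx.T, extents)
    _, first = np.unique(flat, return_index=True)
    kept = union[np.sort(first)]

    logger.debug(
        "hydrate: %d dry -> %d candidates -> %d after step 2 (cutoff %d) "
        "-> %d hydrated", len(dry), len(expanded), len(filtered),
        hydration_cutoff, len(kept))
    return SphereModel(centres=kept, boxside=dry.boxside, hydrated=True)


def sphere_rg(model: SphereModel, include_sphere_term: bool = False) -> float:
    """Radius of gyration (nm) of the sphere centres.

    Root-mean-square distance of the centres from their centroid.  With
    ``include_sphere_term`` the (3/5) r^2 self-term of a uniform sphere is
    added inside the root; the default treats spheres as point scatterers,
    matching the Debye-curve treatment where the sphere size enters through
    the form factor instead.
    """
    if len(model) == 0:
        raise ValueError("empty sphere model has no radius of gyration")
    centred = model.centres - model.centres.mean(axis=0)
    mean_sq = float(np.mean(np.sum(centred ** 2, axis=1)))
    if include_sphere_term:
        mean_sq += 0.6 * model.radius ** 2
    return float(np.sqrt(mean_sq))


@dataclass(frozen=True)
class BoxSideResult:
    """Outcome of a grid box-side search against a target dry volume."""

    boxside: float  # nm
    volume: float  # nm^3, box convention, at the returned side
    target_volume: float  # nm^3
    relative_error: float  # |volume - target| / target
    cutoff: int
    n_spheres: int


def optimize_box_side(atoms: AtomModel, target_dry_volume: float,
                      cutoff: int = DEFAULT_GRID_CUTOFF,
                      side_range: tuple[float, float] = (0.1, 1.5),
                      resolution: float = 1.0e-3,
                      warn_tolerance: float = 0.02) -> BoxSideResult:
    """Find the grid box side whose sphere-model volume best matches a target.

    The sphere-model volume (box convention) is a piecewise-constant
    function of the box side, so the side grid spanning ``side_range`` at
    ``resolution`` (nm) is scanned exhaustively and the best grid point
    returned.  If no side achieves a relative volume error below
    ``warn_tolerance`` a warning is issued and the best side is still
    returned.
    """
    if target_dry_volume <= 0:
        raise ValueError("target volume must be positive")
    if len(atoms) < 2:
        raise ValueError("box-side optimization needs at least 2 atoms; "
                         "degenerate single-point input")
    lo, hi = side_range
    if not 0 < lo < hi:
        raise ValueError("invalid side range")
    sides = np.arange(lo, hi + resolution / 2, resolution)

    best: BoxSideResult | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty models score infinitely badly
        for side in sides:
            model = grid_transform(atoms, float(side), cutoff)
            if len(model) == 0:
                continue
            volume = sphere_model_volume(model, "box")
            err = abs(volume - target_dry_volume) / target_dry_volume
            if best is None or err < best.relative_error:
                best = BoxSideResult(float(side), volume, target_dry_volume,
                                     err, cutoff, len(model))
    if best is None:
        raise ValueError("no box side in range produced any spheres")
    if best.relative_error > warn_tolerance:
        warnings.warn(
            f"best box side {best.boxside:.3f} nm reaches only "
            f"{100 * best.relative_error:.1f}% relative volume error "
            f"(target {target_dry_volume:.2f} nm^3)", stacklevel=2)
    logger.info("optimize_box_side: side %.3f nm, volume %.2f nm^3 "
                "(target %.2f, %.2f%% off)", best.boxside, best.volume,
                target_dry_volume, 100 * best.relative_error)
    return best


@dataclass(frozen=True)
class HydrationCutoffResult:
    """Hydrated volumes over candidate Step-2 cutoffs and the best match."""

    best_cutoff: int
    best_volume: float  # nm^3
    target_volume: float  # nm^3
    table: tuple[tuple[int, float], ...]  # (cutoff, hydrated volume) rows


def optimize_hydration_cutoff(
        dry: SphereModel, target_hydrated_volume: float,
        cutoff_candidates=DEFAULT_HYDRATION_CUTOFFS) -> HydrationCutoffResult:
    """Hydrate at each candidate cutoff and pick the closest-volume one.

    Returns the full (cutoff, hydrated volume) table so the user can judge
    the trade-off; volumes are non-increasing in the cutoff.
    """
    candidates = list(cutoff_candidates)
    if not candidates:
        raise ValueError("cutoff candidate list is empty")
    if target_hydrated_volume <= 0:
        raise ValueError("target volume must be positive")
    rows = []
    for cutoff in candidates:
        hydrated = hydrate_sphere_model(dry, cutoff)
        rows.append((int(cutoff), sphere_model_volume(hydrated, "box")))
    best_cutoff, best_volume = min(
        rows, key=lambda row: abs(row[1] - target_hydrated_volume))
    return HydrationCutoffResult(best_cutoff, best_volume,
                                 target_hydrated_volume, tuple(rows))
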