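"""Deterministic synthetic inputs with known analytic properties.

Atom clouds sampled uniformly inside simple shapes (ball, rod, dumbbell,
lattice) carry their analytic radius of gyration and envelope volume in
``metadata``, so grid transformation, hydration, curve calculation and
fitting can all be exercised against closed-form truths without any
downloaded structure.  Matched "experimental" curves add seeded
multiplicative Gaussian noise to a theoretical curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AtomModel, ScatterCurve

__all__ = ["FixtureSpec", "make_atom_cloud", "make_experimental_curve"]

_SHAPES = ("ball", "rod", "dumbbell", "lattice")


@dataclass(frozen=True)
class FixtureSpec:
    """Description of a synthetic atom cloud.

    ``radius`` is the ball (or rod cross-section) radius in nm; ``length``
    the rod length or dumbbell centre separation; ``n_points`` the sample
    size; ``seed`` fixes the stream.  For ``lattice``, ``n_points`` is the
    number of lattice points per axis and ``radius`` the spacing.
    """

    shape: str
    radius: float = 3.0
    length: float = 0.0
    n_points: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; "
                             f"choose from {_SHAPES}")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _ball_points(rng, n, radius, centre=(0.0, 0.0, 0.0)):
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(centre) + directions * radii[:, None]


def make_atom_cloud(spec: FixtureSpec) -> AtomModel:
    """Sample a uniform atom cloud inside the requested shape.

    The analytic radius of gyration and envelope volume of the shape are
    recorded in ``metadata['true_rg']`` / ``metadata['true_volume']``:
    ball sqrt(3/5) R; rod of length L and cross-section radius a
    sqrt(L^2/12 + a^2/2); dumbbell of two balls at separation D via the
    parallel-axis theorem sqrt(3/5 R^2 + (D/2)^2).
    """
    rng = np.random.default_rng(spec.seed)
    r, n = spec.radius, spec.n_points

    if spec.shape == "ball":
        coords = _ball_points(rng, n, r)
        true_rg = np.sqrt(3.0 / 5.0) * r
        true_volume = 4.0 / 3.0 * np.pi * r ** 3
    elif spec.shape == "rod":
        if spec.length <= 0:
            raise ValueError("rod fixture needs a positive length")
        radial = r * np.sqrt(rng.random(n))
        theta = 2.0 * np.pi * rng.random(n)
        z = spec.length * (rng.random(n) - 0.5)
        coords = np.column_stack([radial * np.cos(theta),
                                  radial * np.sin(theta), z])
        true_rg = np.sqrt(spec.length ** 2 / 12.0 + r ** 2 / 2.0)
        true_volume = np.pi * r ** 2 * spec.length
    elif spec.shape == "dumbbell":
        if spec.length <= 0:
            raise ValueError("dumbbell fixture needs a positive separation")
        half = n // 2
        coords = np.vstack([
            _ball_points(rng, half, r, (0.0, 0.0, -spec.length / 2.0)),
            _ball_points(rng, n - half, r, (0.0, 0.0, spec.length / 2.0)),
        ])
        true_rg = np.sqrt(0.6 * r ** 2 + (spec.length / 2.0) ** 2)
        true_volume = 2.0 * (4.0 / 3.0) * np.pi * r ** 3
    else:  # lattice
        side = np.arange(n) * r
        grid = np.meshgrid(side, side, side, indexing="ij")
        coords = np.column_stack([g.ravel() for g in grid])
        coords = coords - coords.mean(axis=0)
        centred = coords - coords.mean(axis=0)
        true_rg = float(np.sqrt(np.mean(np.sum(centred ** 2, axis=1))))
        true_volume = (n * r) ** 3

    return AtomModel(
        residue_codes=["GLY"] * len(coords), coords=coords,
        metadata={"spec": spec, "true_rg": float(true_rg),
                  "true_volume": float(true_volume)})


def make_experimental_curve(curve: ScatterCurve, noise_fraction: float,
                            seed: int = 0) -> ScatterCurve:
    """Turn a theoretical curve into a noisy "experimental" one.

    Applies multiplicative Gaussian noise of fractional standard deviation
    ``noise_fraction`` (0 reproduces the curve exactly) with a fixed seed.
    """
    if noise_fraction < 0:
        raise ValueError("noise fraction cannot be negative")
    rng = np.random.default_rng(seed)
    factors = 1.0 + noise_fraction * rng.standard_normal(len(curve))
    return ScatterCurve(q=curve.q.copy(), i=curve.i * factors,
                        kind="experimental", smeared=curve.smeared,
                        metadata={"noise_fraction": noise_fraction,
                                  "seed": seed})
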