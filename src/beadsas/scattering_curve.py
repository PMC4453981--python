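"""Theoretical scattering curves and their comparison with experiment.

The scattered intensity of a sphere model is computed with the Debye
equation adapted to identical spheres: a histogram of the inter-sphere
distances d_j with counts A_j turns the O(n^2) double sum into a sum over
bins,

    I(Q)/I(0) = g(Q) [ 1/n + (2/n^2) sum_j A_j sin(Q d_j)/(Q d_j) ],

where g(Q) is the squared form factor of a uniform sphere of radius r,

    g(Q) = [ 3 (sin(Qr) - Qr cos(Qr)) / (Qr)^3 ]^2 .

Because sum_j A_j = n(n-1)/2 the curve is normalized to 1 at Q -> 0.

SANS curves are smeared by convolution with a unit-area Gaussian whose
width combines the instrument's wavelength spread and beam divergence
(:class:`beadsas.datatypes.SmearingSpec`).  Guinier fits extract Rg from
the slope of ln I vs Q^2 (slope = -Rg^2/3) and, for elongated particles,
Rxs from ln(IQ) vs Q^2 (slope = -Rxs^2/2) in a higher, non-overlapping Q
window.  Model-to-experiment agreement is scored with a crystallographic-
style R factor,

    R = 100 * sum | |I_expt| - eta |I_calc| | / sum |I_expt| ,

minimized exactly over the scale factor eta.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.spatial.distance import pdist

from .datatypes import (DistanceHistogram, GuinierResult, RFactorResult,
                        ScatterCurve, SmearingSpec, SphereModel)

__all__ = [
    "CLASSIC_NBINS",
    "GUINIER_QRG_BAND",
    "theoretical_q_grid",
    "distance_histogram",
    "squared_form_factor",
    "debye_curve",
    "smear_curve",
    "apply_incoherent_baseline",
    "guinier_rg",
    "guinier_rxs",
    "match_q_grid",
    "r_factor",
]

logger = logging.getLogger(__name__)

#: number of histogram bins in classic mode
CLASSIC_NBINS = 400
#: recommended Q*Rg range for a valid Guinier fit
GUINIER_QRG_BAND = (0.5, 1.5)

# above this sphere count pair distances are histogrammed in row blocks
# rather than materialised with pdist
_PDIST_LIMIT = 6000
_BLOCK_ROWS = 256


def theoretical_q_grid(qmax: float, npoints: int) -> np.ndarray:
    """``npoints`` equally spaced Q values on (0, qmax], excluding Q = 0."""
    if qmax <= 0 or npoints < 2:
        raise ValueError("need qmax > 0 and npoints >= 2")
    return qmax * np.arange(1, npoints + 1) / npoints


def _pair_distance_blocks(centres: np.ndarray):
    """Yield blocks of unique pair distances without O(n^2) memory."""
    n = len(centres)
    for start in range(0, n - 1, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, n - 1)
        block = centres[start:stop, None, :] - centres[None, start + 1:, :]
        dists = np.sqrt(np.sum(block ** 2, axis=-1))
        rows = np.arange(start, stop)
        cols = np.arange(start + 1, n)
        mask = cols[None, :] > rows[:, None]
        yield dists[mask]


def distance_histogram(model: SphereModel, mode: str = "modern",
                       nbins: int | None = None,
                       bin_width: float | None = None,
                       dmax: float | None = None) -> DistanceHistogram:
    """Histogram of all inter-sphere distances.

    ``classic`` mode uses 400 equal bins (unless ``nbins`` overrides)
    starting at zero with a user-supplied ``bin_width``; a pair distance
    beyond the last bin is an error, not a silent truncation.  ``modern``
    mode spans the observed [min, max] pair distance (or ``dmax`` if
    given) with ``nbins`` bins.  In both modes the counts sum to
    n(n-1)/2.
    """
    n = len(model)
    if n < 2:
        raise ValueError("distance histogram needs at least 2 spheres")

    if n <= _PDIST_LIMIT:
        blocks = [pdist(model.centres)]
    else:
        blocks = list(_pair_distance_blocks(model.centres))

    if mode == "classic":
        if bin_width is None or bin_width <= 0:
            raise ValueError("classic mode requires a positive bin_width")
        m = CLASSIC_NBINS if nbins is None else int(nbins)
        edges = np.arange(m + 1) * bin_width
        overflow = sum(int(np.count_nonzero(b > edges[-1])) for b in blocks)
        if overflow:
            raise ValueError(
                f"{overflow} pair distances exceed the classic histogram "
                f"range {m} x {bin_width} = {edges[-1]:.4f} nm")
    elif mode == "modern":
        if nbins is None or nbins < 1:
            raise ValueError("modern mode requires nbins >= 1")
        dmin = min(float(b.min()) for b in blocks)
        upper = float(dmax) if dmax is not None else max(
            float(b.max()) for b in blocks)
        if upper < dmin:
            raise ValueError("dmax below the minimum pair distance")
        edges = np.histogram_bin_edges([], bins=int(nbins),
                                       range=(dmin, upper))
    else:
        raise ValueError(f"unknown histogram mode {mode!r}")

    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for block in blocks:
        c, _ = np.histogram(block, bins=edges)
        counts += c
    centres = 0.5 * (edges[:-1] + edges[1:])
    return DistanceHistogram(bin_centres=centres, counts=counts, n_spheres=n,
                             bin_width=float(edges[1] - edges[0]), mode=mode)


def squared_form_factor(q, r: float):
    """Squared scattering amplitude g(Q) of a uniform sphere of radius r.

    g(0) = 1; the first zero lies at Qr = 4.4934 (root of tan x = x).  A
    series expansion is used below Qr = 1e-3 for numerical stability.
    """
    q = np.asarray(q, dtype=float)
    if r <= 0:
        raise ValueError("sphere radius must be positive")
    if np.any(q < 0):
        raise ValueError("negative Q")
    x = q * r
    amp = np.empty_like(x)
    small = x < 1.0e-3
    amp[small] = 1.0 - x[small] ** 2 / 10.0
    xl = x[~small]
    amp[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl ** 3
    out = amp ** 2
    return float(out) if out.ndim == 0 else out


def debye_curve(hist: DistanceHistogram, r: float,
                q_grid: np.ndarray) -> ScatterCurve:
    """Normalized theoretical I(Q) from a pair-distance histogram.

    Evaluates the sphere-adapted Debye equation on ``q_grid``; the curve
    tends to 1 as Q -> 0 because the histogram counts sum to n(n-1)/2.
    """
    if hist.nbins == 0 or hist.counts.sum() == 0:
        raise ValueError("empty distance histogram")
    if r <= 0:
        raise ValueError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    n = hist.n_spheres
    # sin(x)/x via np.sinc handles the Q d -> 0 limit exactly
    x = np.outer(q, hist.bin_centres) / np.pi
    interference = np.sinc(x) @ hist.counts.astype(float)
    intensity = squared_form_factor(q, r) * (1.0 / n
                                             + 2.0 / n ** 2 * interference)
    return ScatterCurve(q=q, i=intensity, kind="theoretical",
                        metadata={"n_spheres": n, "sphere_radius": r})


def smear_curve(curve: ScatterCurve, spec: SmearingSpec) -> ScatterCurve:
    """Convolve a theoretical curve with the Gaussian beam-smearing kernel.

    Discrete convolution on the curve's (uniform) Q grid with a unit-area
    Gaussian of Q-dependent standard deviation ``spec.sigma(Q)``; the edges
    are handled by reflecting the curve about its end points, which
    preserves constants.  Refuses a curve already flagged as smeared.
    """
    if curve.smeared:
        raise ValueError("curve is already smeared")
    if len(curve) < 3:
        raise ValueError("curve too short to smear")
    dq = np.diff(curve.q)
    if not np.allclose(dq, dq[0], rtol=1e-6):
        raise ValueError("smearing requires a uniform Q grid")
    step = float(dq[0])

    sigma = spec.sigma(curve.q)
    if np.all(sigma == 0):
        return ScatterCurve(q=curve.q.copy(), i=curve.i.copy(),
                            kind=curve.kind, smeared=True,
                            metadata=dict(curve.metadata))

    pad = int(np.ceil(5.0 * float(sigma.max()) / step)) + 1
    if pad > len(curve) - 1:
        raise ValueError(
            f"curve shorter than the kernel support (needs {pad} points of "
            f"padding, has {len(curve) - 1})")

    # reflective padding of both Q and I about the end points
    q0, qn = curve.q[0], curve.q[-1]
    q_ext = np.concatenate([2 * q0 - curve.q[pad:0:-1], curve.q,
                            2 * qn - curve.q[-2:-pad - 2:-1]])
    i_ext = np.concatenate([curve.i[pad:0:-1], curve.i,
                            curve.i[-2:-pad - 2:-1]])

    smeared = np.empty_like(curve.i)
    for k, (qk, sk) in enumerate(zip(curve.q, sigma)):
        if sk == 0:
            smeared[k] = curve.i[k]
            continue
        w = np.exp(-0.5 * ((q_ext - qk) / sk) ** 2)
        smeared[k] = np.dot(w, i_ext) / w.sum()
    return ScatterCurve(q=curve.q.copy(), i=smeared, kind=curve.kind,
                        smeared=True, metadata=dict(curve.metadata))


def apply_incoherent_baseline(curve: ScatterCurve,
                              fraction_of_i0: float) -> ScatterCurve:
    """Add a flat incoherent-scattering baseline of ``fraction * I(0)``.

    Corrects for residual proton content in heavy-water SANS samples;
    typical fractions are 0.005-0.015.  This correction belongs *after*
    curve fitting: :func:`r_factor` refuses baseline-corrected theoretical
    curves.
    """
    if fraction_of_i0 < 0:
        raise ValueError("baseline fraction cannot be negative")
    if fraction_of_i0 > 0.05:
        raise ValueError("baseline fraction above 5% of I(0) is unphysical")
    if fraction_of_i0 > 0.015:
        warnings.warn("baseline fraction above the typical 0.5-1.5% band",
                      stacklevel=2)
    i0 = curve.i[0]
    meta = dict(curve.metadata)
    meta["baseline_fraction"] = fraction_of_i0
    return ScatterCurve(q=curve.q.copy(), i=curve.i + fraction_of_i0 * i0,
                        kind=curve.kind, smeared=curve.smeared, metadata=meta)


def _fit_window(curve: ScatterCurve, fitmin: float, fitmax: float):
    mask = (curve.q >= fitmin) & (curve.q <= fitmax)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"fewer than 3 points in the fit window [{fitmin}, {fitmax}]")
    return curve.q[mask], curve.i[mask]


def _linear_fit(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    corr = float(np.corrcoef(x, y)[0, 1])
    return float(slope), float(intercept), corr


def guinier_rg(curve: ScatterCurve, fitmin: float,
               fitmax: float) -> GuinierResult:
    """Guinier fit: Rg and I(0) from the slope of ln I vs Q^2.

    Requires at least 3 points with positive intensity in the window and a
    negative slope (Rg^2 = -3 * slope).  Warns when the Q*Rg range of the
    fitted points leaves the recommended 0.5-1.5 band.
    """
    q, i = _fit_window(curve, fitmin, fitmax)
    if np.any(i <= 0):
        raise ValueError("non-positive intensity inside the Guinier window")
    slope, intercept, corr = _linear_fit(q ** 2, np.log(i))
    if slope >= 0:
        raise ValueError("non-negative Guinier slope: Rg undefined "
                         "(is the window in the low-Q region?)")
    rg = float(np.sqrt(-3.0 * slope))
    qrg = (float(q[0] * rg), float(q[-1] * rg))
    if qrg[0] < GUINIER_QRG_BAND[0] - 1e-12 or qrg[1] > GUINIER_QRG_BAND[1] + 1e-12:
        warnings.warn(
            f"Q*Rg range {qrg[0]:.2f}-{qrg[1]:.2f} outside the recommended "
            f"{GUINIER_QRG_BAND[0]}-{GUINIER_QRG_BAND[1]} band", stacklevel=2)
    return GuinierResult(value=rg, kind="rg", intercept=intercept,
                         window=(fitmin, fitmax), n_points=len(q),
                         qrg_range=qrg, correlation=corr)


def guinier_rxs(curve: ScatterCurve, fitmin: float, fitmax: float,
                rg_window: tuple[float, float] | None = None) -> GuinierResult:
    """Cross-sectional Guinier fit: Rxs from the slope of ln(IQ) vs Q^2.

    For elongated particles; the window must lie above (and not overlap)
    the Rg window, validated when ``rg_window`` is supplied.
    Rxs^2 = -2 * slope.
    """
    if rg_window is not None and fitmin < rg_window[1]:
        raise ValueError(
            f"Rxs window [{fitmin}, {fitmax}] overlaps the Rg window "
            f"{rg_window}; cross-section fits need a higher Q range")
    q, i = _fit_window(curve, fitmin, fitmax)
    if np.any(i <= 0):
        raise ValueError("non-positive intensity inside the Rxs window")
    slope, intercept, corr = _linear_fit(q ** 2, np.log(i * q))
    if slope >= 0:
        raise ValueError("non-negative cross-sectional slope: Rxs undefined")
    rxs = float(np.sqrt(-2.0 * slope))
    return GuinierResult(value=rxs, kind="rxs", intercept=intercept,
                         window=(fitmin, fitmax), n_points=len(q),
                         qrg_range=(float(q[0] * rxs), float(q[-1] * rxs)),
                         correlation=corr)


def match_q_grid(theoretical: ScatterCurve, experimental: ScatterCurve,
                 qmin: float, qmax: float):
    """Pair each experimental point with the nearest theoretical Q.

    Returns ``(q_expt, i_expt, i_theo)`` arrays for the experimental points
    inside [qmin, qmax]; equidistant ties resolve toward the lower
    theoretical Q.
    """
    if len(theoretical) == 0 or len(experimental) == 0:
        raise ValueError("cannot match empty curves")
    mask = (experimental.q >= qmin) & (experimental.q <= qmax)
    qe, ie = experimental.q[mask], experimental.i[mask]
    if len(qe) == 0:
        raise ValueError(f"no experimental points in [{qmin}, {qmax}]")
    qt = theoretical.q
    if qe[0] > qt[-1] or qe[-1] < qt[0]:
        raise ValueError("theoretical and experimental Q ranges do not overlap")
    pos = np.searchsorted(qt, qe)
    lo = np.clip(pos - 1, 0, len(qt) - 1)
    hi = np.clip(pos, 0, len(qt) - 1)
    # strict inequality: equidistant pairs keep the lower neighbour
    nearest = np.where(np.abs(qt[hi] - qe) < np.abs(qe - qt[lo]), hi, lo)
    return qe, ie, theoretical.i[nearest]


def _optimal_eta(i_expt: np.ndarray, i_theo: np.ndarray) -> float:
    """Exact minimizer of sum |a - eta b| over eta > 0.

    The objective is piecewise linear and convex in eta with breakpoints at
    the ratios a_k / b_k; the weighted median of those ratios (weights b_k)
    is an exact minimizer.  Ties resolve to the lower breakpoint.
    """
    a = np.abs(i_expt)
    b = np.abs(i_theo)
    usable = b > 0
    if not np.any(usable):
        raise ValueError("theoretical intensities are all zero in the window")
    ratios = a[usable] / b[usable]
    weights = b[usable]
    order = np.argsort(ratios, kind="stable")
    ratios, weights = ratios[order], weights[order]
    half = 0.5 * weights.sum()
    k = int(np.searchsorted(np.cumsum(weights), half))
    eta = float(ratios[min(k, len(ratios) - 1)])
    return eta if eta > 0 else float(ratios[ratios > 0][0])


def r_factor(theoretical: ScatterCurve, experimental: ScatterCurve,
             qmin: float, qmax: float) -> RFactorResult:
    """R factor (%) between a theoretical and an experimental curve.

    R(eta) = 100 sum||I_e| - eta |I_t|| / sum|I_e| is minimized exactly
    over the scale factor eta applied to the theoretical curve.  One
    theoretical curve can be scored against any number of experimental
    data sets by repeated calls.
    """
    if theoretical.metadata.get("baseline_fraction"):
        raise ValueError(
            "theoretical curve already carries an incoherent baseline; "
            "the baseline must be applied after curve fitting")
    _, ie, it = match_q_grid(theoretical, experimental, qmin, qmax)
    denom = float(np.abs(ie).sum())
    if denom == 0:
        raise ValueError("experimental intensities sum to zero in the window")
    eta = _optimal_eta(ie, it)
    r = 100.0 * float(np.abs(np.abs(ie) - eta * np.abs(it)).sum()) / denom
    return RFactorResult(r_factor=r, eta=eta, window=(qmin, qmax),
                         n_points=len(ie))
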