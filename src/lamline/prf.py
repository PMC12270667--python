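"""Divisive-normalization pRF model and participant-tailored stimulus design.

A population receptive field (pRF) summarises the region of visual space a
cortical patch responds to.  Here it is modelled with a divisive-normalization
(DN) form: the response to a stimulus is the ratio of an *activation* pool
(narrow Gaussian, width ``sigma1``) and a *normalization* pool (broader
Gaussian, width ``sigma2``), each integrating the binary stimulus aperture:

    R(S) = (amp_act * <S, G1> + b) / (amp_norm * <S, G2> + d) - b / d

so that the empty stimulus maps to exactly zero.  Because the normalization
pool is wider, enlarging a stimulus beyond the activation pool recruits
proportionally more suppression, producing size tuning with an interior peak
(surround suppression).

From the size-tuning curve three stimuli are derived per participant: a
*center* disc at the radius maximising the modelled response, a *large*
2-dva-wide annulus pushed as far into the surround as the screen allows, and
a *medium* annulus halfway in between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import square


@dataclass(frozen=True)
class PRFParams:
    """Location and DN-model parameters of one target pRF.

    Positions and widths are in degrees of visual angle (dva); amplitudes and
    the two baseline constants ``b`` (numerator) and ``d`` (denominator) are
    in arbitrary units.  ``r2`` is the variance explained of the pRF fit.
    """

    x: float
    y: float
    sigma1: float
    sigma2: float
    amp_act: float = 1.0
    amp_norm: float = 0.0
    b: float = 0.0
    d: float = 1.0
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.sigma2 < self.sigma1:
            raise ValueError("sigma2 must be >= sigma1 (normalization pool is broader)")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass(frozen=True)
class ScreenGeometry:
    """Visible screen half-extents (dva) and raster resolution (px/dva)."""

    half_width: float = 8.0
    half_height: float = 4.5
    pixels_per_dva: float = 20.0

    def __post_init__(self) -> None:
        if min(self.half_width, self.half_height, self.pixels_per_dva) <= 0:
            raise ValueError("screen geometry values must be positive")

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (X, Y) in dva covering the screen."""
        nx = int(round(2 * self.half_width * self.pixels_per_dva))
        ny = int(round(2 * self.half_height * self.pixels_per_dva))
        xs = (np.arange(nx) + 0.5) / self.pixels_per_dva - self.half_width
        ys = (np.arange(ny) + 0.5) / self.pixels_per_dva - self.half_height
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry of one checkerboard stimulus (all radii in dva)."""

    kind: str  # center | medium | large
    inner_radius: float
    outer_radius: float
    radial_cycles_per_deg: float = 2.0
    angular_cycles_per_deg: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")


@dataclass
class SizeTuningCurve:
    radii: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.radii.shape != self.responses.shape:
            raise ValueError("radii and responses must have the same length")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


def _gaussian_raster(prf: PRFParams, screen: ScreenGeometry, sigma: float) -> np.ndarray:
    X, Y = screen.grids()
    return np.exp(-((X - prf.x) ** 2 + (Y - prf.y) ** 2) / (2.0 * sigma**2))


def dn_response(stim_mask: np.ndarray, prf: PRFParams, screen: ScreenGeometry) -> float:
    """DN response of ``prf`` to a binary stimulus aperture on the screen raster.

    The raster must cover +-3*sigma2 around the pRF center, otherwise the
    normalization pool is truncated and a warning is emitted.
    """
    if (
        prf.x - 3 * prf.sigma2 < -screen.half_width
        or prf.x + 3 * prf.sigma2 > screen.half_width
        or prf.y - 3 * prf.sigma2 < -screen.half_height
        or prf.y + 3 * prf.sigma2 > screen.half_height
    ):
        warnings.warn("truncated pRF support", stacklevel=2)
    g1 = _gaussian_raster(prf, screen, prf.sigma1)
    g2 = _gaussian_raster(prf, screen, prf.sigma2)
    mask = np.asarray(stim_mask, dtype=float)
    if mask.shape != g1.shape:
        raise ValueError("stimulus mask and screen raster shapes differ")
    num = prf.amp_act * float(np.sum(mask * g1)) + prf.b
    den = prf.amp_norm * float(np.sum(mask * g2)) + prf.d
    return num / den - prf.b / prf.d


def disc_mask(radius: float, center: tuple[float, float], screen: ScreenGeometry) -> np.ndarray:
    X, Y = screen.grids()
    return ((X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2).astype(float)


def size_tuning_curve(
    prf: PRFParams,
    screen: ScreenGeometry,
    n_radii: int = 101,
    max_radius: float = 10.0,
) -> SizeTuningCurve:
    """Model response to centered discs of increasing radius (0 .. 10 dva)."""
    if n_radii < 2:
        raise ValueError("need at least 2 radii")
    radii = np.linspace(0.0, max_radius, n_radii)
    X, Y = screen.grids()
    r2grid = (X - prf.x) ** 2 + (Y - prf.y) ** 2
    g1 = _gaussian_raster(prf, screen, prf.sigma1)
    g2 = _gaussian_raster(prf, screen, prf.sigma2)
    responses = np.empty(n_radii)
    for i, r in enumerate(radii):
        mask = r2grid <= r**2
        num = prf.amp_act * float(np.sum(g1[mask])) + prf.b
        den = prf.amp_norm * float(np.sum(g2[mask])) + prf.d
        responses[i] = num / den - prf.b / prf.d
    return SizeTuningCurve(radii, responses)


def optimal_center_size(curve: SizeTuningCurve) -> float:
    """Radius of the global response maximum; ties go to the smaller radius."""
    if curve.radii.size == 0:
        raise ValueError("empty tuning curve")
    if np.allclose(curve.responses, curve.responses[0]):
        raise ValueError("flat tuning curve")
    return float(curve.radii[int(np.argmax(curve.responses))])


def largest_annulus_radius(prf: PRFParams, screen: ScreenGeometry) -> float:
    """Outer radius of the largest non-occluded annulus centered on the pRF.

    Equals the smallest distance from the pRF position to any screen edge.
    """
    if abs(prf.x) >= screen.half_width or abs(prf.y) >= screen.half_height:
        raise ValueError("pRF position outside the visible screen")
    return float(
        min(
            screen.half_width - prf.x,
            screen.half_width + prf.x,
            screen.half_height - prf.y,
            screen.half_height + prf.y,
        )
    )


def medium_annulus_radius(center_outer: float, large_outer: float) -> tuple[float, tuple[float, float]]:
    """Mid-radius halfway between center disc and large annulus, as a 2-dva ring.

    Returns ``(mid, (inner, outer))``; warns when the ring spatially overlaps
    either neighbouring stimulus.
    """
    if large_outer <= center_outer:
        raise ValueError("large annulus must be larger than the center stimulus")
    mid = (center_outer + large_outer) / 2.0
    ring = (mid - 1.0, mid + 1.0)
    # the ring should fit strictly between the center disc edge and the large
    # annulus outer edge ("preferably without spatial overlap")
    if ring[0] <= center_outer or ring[1] >= large_outer:
        warnings.warn("medium annulus overlaps a neighbouring stimulus", stacklevel=2)
    return mid, ring


def render_checkerboard(
    spec: StimulusSpec,
    prf: PRFParams,
    screen: ScreenGeometry,
    phase: int = 0,
) -> np.ndarray:
    """Radial checkerboard raster (+1/-1 contrast, 0 outside the ring).

    Radial frequency is ``radial_cycles_per_deg`` cycles per dva of radius;
    the angular pattern has ``angular_cycles_per_deg * outer_radius`` wedge
    cycles per turn, rounded to an integer so the pattern closes at 2*pi.
    ``phase`` in {0, 1} selects the flicker frame (contrast reversal).
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    X, Y = screen.grids()
    r = np.hypot(X - prf.x, Y - prf.y)
    theta = np.arctan2(Y - prf.y, X - prf.x)
    n_ang = max(1, int(round(spec.angular_cycles_per_deg * spec.outer_radius)))
    radial = square(2 * np.pi * spec.radial_cycles_per_deg * r)
    angular = square(n_ang * (theta + np.pi))
    img = np.sign(radial * angular)
    img[(r < spec.inner_radius) | (r > spec.outer_radius)] = 0.0
    return -img if phase else img


def spatial_profile_markers(
    prf: PRFParams,
    extent: float = 10.0,
    n: int = 2001,
) -> tuple[tuple[float, float], tuple[float, float] | None]:
    """FWHM band and zero crossings of the 1-D DN spatial profile.

    The profile is the pointwise DN response along a ray through the pRF
    center, ``p(r) = (amp_act*G1(r) + b)/(amp_norm*G2(r) + d) - b/d``; for a
    purely excitatory pRF (amp_norm = 0) it is a scaled Gaussian with FWHM
    ``2*sqrt(2*ln 2)*sigma1`` and no zero crossing.
    """

    def p(r: float | np.ndarray) -> np.ndarray:
        g1 = np.exp(-np.square(r) / (2 * prf.sigma1**2))
        g2 = np.exp(-np.square(r) / (2 * prf.sigma2**2))
        return (prf.amp_act * g1 + prf.b) / (prf.amp_norm * g2 + prf.d) - prf.b / prf.d

    rs = np.linspace(0.0, extent, n)
    vals = p(rs)
    pmax = vals[0]  # profile peaks at the pRF center
    half = pmax / 2.0

    def _first_crossing(target: float) -> float | None:
        f = vals - target
        idx = np.nonzero(np.diff(np.sign(f)) != 0)[0]
        if idx.size == 0:
            return None
        i = idx[0]
        return float(brentq(lambda r: float(p(r)) - target, rs[i], rs[i + 1]))

    r_half = _first_crossing(half)
    if r_half is None:  # half-max not reached within extent; fall back to grid edge
        r_half = extent
    fwhm_band = (-r_half, r_half)

    zc = _first_crossing(0.0)
    zero_crossings = None if zc is None else (-zc, zc)
    return fwhm_band, zero_crossings


#: vertex-selection rules: eccentricity band, meridian clearance, fit quality,
#: and a minimum pRF size.
PRF_FILTER_RULES = {
    "ecc_min": 1.5,
    "ecc_max": 3.0,
    "meridian_min": 1.0,
    "r2_min": 0.55,  # strict >
    "sigma1_min": 0.50,  # strict >
}


def filter_prf_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Keep candidate pRFs in the 1.5-3 dva eccentricity band, >= 1 dva from
    the vertical meridian, with r2 > 0.55 and sigma1 > 0.50 dva."""
    required = {"eccentricity", "merid_dist", "r2", "sigma1"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    rules = PRF_FILTER_RULES
    keep = (
        (table["eccentricity"] >= rules["ecc_min"])
        & (table["eccentricity"] <= rules["ecc_max"])
        & (table["merid_dist"] >= rules["meridian_min"])
        & (table["r2"] > rules["r2_min"])
        & (table["sigma1"] > rules["sigma1_min"])
    )
    out = table.loc[keep]
    if out.empty:
        warnings.warn("no pRF candidates survive the selection rules", stacklevel=2)
    return out


def design_stimulus_set(
    prf: PRFParams, screen: ScreenGeometry, n_radii: int = 101
) -> dict[str, StimulusSpec]:
    """Derive the center / medium / large stimulus set for one pRF."""
    curve = size_tuning_curve(prf, screen, n_radii=n_radii)
    center_r = optimal_center_size(curve)
    large_outer = largest_annulus_radius(prf, screen)
    _, (med_in, med_out) = medium_annulus_radius(center_r, large_outer)
    return {
        "center": StimulusSpec("center", 0.0, center_r),
        "medium": StimulusSpec("medium", med_in, med_out),
        "large": StimulusSpec("large", large_outer - 2.0, large_outer),
    }
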