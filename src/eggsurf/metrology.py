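"""Areal surface texture metrology.

Implements the standard areal height parameters Sa, Sq, Ssk and Sku on
masked height maps, polynomial form correction for the near-spherical
curvature of eggshell fragments, and the coverage-based quality-control
crop/reject step used before any texture value enters the analysis.

All moments use the population (1/n) convention over valid pixels only:

    Sa  = (1/n) Σ |z - z̄|
    Sq  = sqrt((1/n) Σ (z - z̄)²)
    Ssk = (1/n) Σ (z - z̄)³ / Sq³      (sign: <0 valley-dominated, >0 peaks)
    Sku = (1/n) Σ (z - z̄)⁴ / Sq⁴      (3 = Gaussian reference)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .io import HeightMap

__all__ = [
    "TextureSummary",
    "RejectionReport",
    "DegenerateSurfaceError",
    "FitDegeneracyError",
    "plane_correct",
    "compute_texture",
    "assess_and_crop",
]


class DegenerateSurfaceError(ValueError):
    """Ssk/Sku are undefined on a perfectly flat surface (Sq = 0).

    Carries ``sa`` and ``sq`` (both 0) so callers can still report them.
    """

    def __init__(self, message: str):
        super().__init__(message)
        self.sa = 0.0
        self.sq = 0.0


class FitDegeneracyError(ValueError):
    """Too few valid pixels, or a rank-deficient design, for form fitting."""


@dataclass(frozen=True)
class TextureSummary:
    """Texture parameters for one scan.

    Invariants (checked in the test-suite, guaranteed by construction):
    Sa >= 0, Sq >= Sa, Sku >= 1, Sku >= Ssk² + 1, coverage = n_valid/(nrow·ncol).
    """

    sa: float
    sq: float
    ssk: float
    sku: float
    n_valid: int
    coverage: float
    corrected: bool


@dataclass(frozen=True)
class RejectionReport:
    """Why a scan was dropped by quality control."""

    reason: str  # "low-coverage" or "too-small-after-crop"
    coverage: float
    nrow: int
    ncol: int
    meta: dict


def _poly_terms(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """Bivariate monomials x^i y^j with total degree i+j <= order."""
    cols = [np.ones_like(x)]
    for deg in range(1, order + 1):
        for i in range(deg + 1):
            cols.append(x ** (deg - i) * y ** i)
    return np.column_stack(cols)


def plane_correct(hm: HeightMap, order: int = 2) -> HeightMap:
    """Remove the large-scale form (tilt + curvature) from a height map.

    A least-squares bivariate polynomial of total degree <= ``order`` is
    fitted to the valid pixels and subtracted, then the surface is shifted so
    the lowest valid height is exactly 0 nm.  Degree 2 suits the roughly
    spherical cap presented by an eggshell fragment.  The validity mask is
    left untouched.

    The polynomial basis is evaluated on coordinates centred and scaled to
    [-1, 1]² for conditioning; the fit itself is ordinary least squares.
    """
    n_terms = (order + 1) * (order + 2) // 2
    if hm.n_valid < n_terms:
        raise FitDegeneracyError(
            f"{hm.n_valid} valid pixels, need at least {n_terms} "
            f"for an order-{order} surface fit")
    rows, cols = np.nonzero(hm.valid)
    # centred/scaled coordinates for conditioning
    x = (cols - (hm.ncol - 1) / 2.0) / max((hm.ncol - 1) / 2.0, 1.0)
    y = (rows - (hm.nrow - 1) / 2.0) / max((hm.nrow - 1) / 2.0, 1.0)
    design = _poly_terms(x, y, order)
    z = hm.heights[rows, cols]
    coef, _, rank, _ = np.linalg.lstsq(design, z, rcond=None)
    if rank < n_terms:
        raise FitDegeneracyError(
            f"rank-deficient form fit (rank {rank} < {n_terms}); "
            "valid pixels may be collinear")
    residual = z - design @ coef
    residual -= residual.min()  # lowest valid height adjusted to exactly 0 nm
    out = np.full_like(hm.heights, np.nan)
    out[rows, cols] = residual
    meta = dict(hm.meta)
    meta["corrected"] = True
    meta["form_order"] = order
    return HeightMap(out, hm.valid.copy(), hm.pitch_x, hm.pitch_y, meta)


def compute_texture(hm: HeightMap) -> TextureSummary:
    """Compute Sa, Sq, Ssk, Sku over the valid pixels of a height map.

    Raises :class:`DegenerateSurfaceError` when the surface is perfectly
    flat (Sq = 0), because the standardized moments are then undefined.
    Computing texture on a map that has not been form-corrected is legal but
    warned about, since raw curvature dominates the moments.
    """
    z = hm.valid_heights()
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 valid pixels to compute texture")
    corrected = bool(hm.meta.get("corrected", False))
    if not corrected:
        warnings.warn("computing texture on an uncorrected height map; "
                      "form (tilt/curvature) will inflate the parameters",
                      stacklevel=2)
    zc = z - z.mean()
    sa = float(np.abs(zc).mean())
    sq = float(np.sqrt((zc ** 2).mean()))
    if sq == 0.0:
        raise DegenerateSurfaceError(
            "flat surface: Sq = 0, skewness and kurtosis undefined "
            "(Sa = 0, Sq = 0)")
    ssk = float((zc ** 3).mean() / sq ** 3)
    sku = float((zc ** 4).mean() / sq ** 4)
    return TextureSummary(sa=sa, sq=sq, ssk=ssk, sku=sku, n_valid=n,
                          coverage=hm.coverage, corrected=corrected)


def assess_and_crop(hm: HeightMap, coverage_threshold: float = 0.40,
                    min_area: int = 10000) -> Union[HeightMap, RejectionReport]:
    """Coverage-based scan QC: accept, crop the low-quality border, or reject.

    Scans at or above the coverage threshold pass unchanged.  Below it, border
    rows/columns whose own valid fraction is below the threshold are trimmed
    iteratively (missing pixels concentrate at scan edges and corners, which
    fall outside the interferometer's focal plane); the crop is accepted if
    its coverage reaches the threshold and its area is at least ``min_area``
    pixels, otherwise a :class:`RejectionReport` is returned — rejection is a
    report, never an exception.
    """
    if hm.coverage >= coverage_threshold:
        return hm
    r0, r1, c0, c1 = 0, hm.nrow, 0, hm.ncol
    v = hm.valid
    while r1 - r0 > 0 and c1 - c0 > 0:
        lines = []
        width = c1 - c0
        height = r1 - r0
        if height > 1:
            lines.append(("top", v[r0, c0:c1].mean()))
            lines.append(("bottom", v[r1 - 1, c0:c1].mean()))
        if width > 1:
            lines.append(("left", v[r0:r1, c0].mean()))
            lines.append(("right", v[r0:r1, c1 - 1].mean()))
        qualifying = [(frac, name) for name, frac in lines if frac < coverage_threshold]
        if not qualifying:
            break
        _, worst = min(qualifying)
        if worst == "top":
            r0 += 1
        elif worst == "bottom":
            r1 -= 1
        elif worst == "left":
            c0 += 1
        else:
            c1 -= 1
    window = v[r0:r1, c0:c1]
    area = window.size
    cov = float(window.mean()) if area else 0.0
    if area >= min_area and cov >= coverage_threshold and (r1 - r0) >= 2 and (c1 - c0) >= 2:
        meta = dict(hm.meta)
        meta["crop"] = (r0, r1, c0, c1)
        return HeightMap(hm.heights[r0:r1, c0:c1], window.copy(),
                         hm.pitch_x, hm.pitch_y, meta)
    reason = "too-small-after-crop" if cov >= coverage_threshold else "low-coverage"
    return RejectionReport(reason=reason, coverage=cov,
                           nrow=r1 - r0, ncol=c1 - c0, meta=dict(hm.meta))
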