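"""Closed-form structure-property correlations for fibrous tissue.

Empirical correlations relate porosity ``phi`` to hydraulic permeability
(Darcy) along and across the fibre direction,

    KL = exp(4.719 ln(phi) + phi + 5.097),
    KT = exp(5.567 ln(phi) + phi + 4.239),

and to the Young's modulus normalized by the fully dense material,

    En = 1 - 1.1456 phi^2 + 0.0853 phi,

which equals 1 at zero porosity and decays toward zero at high porosity.
The coefficients are fixed constants of the package (fitted on large
ensembles of tissue reconstructions); :func:`fit_permeability_model` and
:func:`fit_modulus_model` refit the same functional forms to user data and
deliberately do NOT share these coefficients.

The module also maps 2D CT images to porosity via a user-calibrated linear
anchor pair and broadcasts the correlations into property maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KL_COEFFS",
    "KT_COEFFS",
    "EN_COEFFS",
    "PorosityMap",
    "PropertyMaps",
    "predict_KL",
    "predict_KT",
    "predict_En",
    "permeability_reduction",
    "porosity_from_ct",
    "property_maps",
    "fit_permeability_model",
    "fit_modulus_model",
]

# K = exp(a * ln(phi) + phi + b); natural logarithm.
KL_COEFFS = (4.719, 5.097)
KT_COEFFS = (5.567, 4.239)
# En = 1 + c2 * phi^2 + c1 * phi
EN_COEFFS = (-1.1456, 0.0853)


def _check_open_unit(phi: np.ndarray | float, name: str) -> np.ndarray:
    arr = np.asarray(phi, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1)")
    return arr


def _eval_log_exp(phi, coeffs) -> np.ndarray | float:
    a, b = coeffs
    arr = _check_open_unit(phi, "porosity")
    out = np.exp(a * np.log(arr) + arr + b)
    return float(out) if np.isscalar(phi) else out


def predict_KL(phi):
    """Longitudinal (along-fibre) permeability in Darcy at porosity ``phi``.

    Valid for ``0 < phi < 1``; scalar in gives scalar out.
    """
    return _eval_log_exp(phi, KL_COEFFS)


def predict_KT(phi):
    """Transverse (across-fibre) permeability in Darcy at porosity ``phi``."""
    return _eval_log_exp(phi, KT_COEFFS)


def predict_En(phi, clamp: bool = False):
    """Normalized Young's modulus at porosity ``phi`` in [0, 1].

    Exactly 1 at ``phi = 0``.  The quadratic dips slightly below zero near
    ``phi = 1`` (a fit artefact); ``clamp=True`` floors the result at 0.
    """
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("porosity must lie in [0, 1]")
    c2, c1 = EN_COEFFS
    out = 1.0 + c2 * arr**2 + c1 * arr
    if clamp:
        out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(phi) else out


def permeability_reduction(k_start: float, k_end: float) -> float:
    """Fractional permeability loss ``(K_start - K_end) / K_start``
    (e.g. across a compression step)."""
    if k_start <= 0:
        raise ValueError("k_start must be positive")
    if k_end < 0:
        raise ValueError("k_end must be non-negative")
    return (k_start - k_end) / k_start


@dataclass(frozen=True)
class PorosityMap:
    """2D field of porosity fractions; NaN marks excluded pixels."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("porosity map must be 2D")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("porosity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PropertyMaps:
    """Permeability and normalized-modulus maps on a porosity map's grid."""

    KL: np.ndarray
    KT: np.ndarray
    En: np.ndarray
    pixel_size: float = 1.0


def porosity_from_ct(image: np.ndarray,
                     calibration: tuple[tuple[float, float], tuple[float, float]],
                     mask: np.ndarray | None = None,
                     pixel_size: float = 1.0) -> PorosityMap:
    """Linear CT-number -> porosity mapping from two anchor pairs.

    ``calibration`` holds two ``(ct_value, porosity)`` anchors with distinct
    CT values; the linear map through them is applied per pixel and clipped
    to [0, 1].  Masked (True) pixels become NaN and propagate as missing.
    """
    (ct0, phi0), (ct1, phi1) = calibration
    if ct0 == ct1:
        raise ValueError("calibration anchors must have distinct CT values")
    img = np.asarray(image, dtype=float)
    slope = (phi1 - phi0) / (ct1 - ct0)
    phi = np.clip(phi0 + slope * (img - ct0), 0.0, 1.0)
    if mask is not None:
        phi = np.where(np.asarray(mask, dtype=bool), np.nan, phi)
    return PorosityMap(phi, pixel_size=pixel_size)


def property_maps(pmap: PorosityMap) -> PropertyMaps:
    """Element-wise KL / KT / En maps from a porosity map.

    Missing pixels stay NaN everywhere.  Pixels at exactly 0 or 1 porosity
    fall outside the permeability correlations' domain and are NaN in the
    KL/KT maps, but are still evaluated in the En map.
    """
    phi = pmap.values
    valid = np.isfinite(phi)
    open_dom = valid & (phi > 0.0) & (phi < 1.0)

    kl = np.full(phi.shape, np.nan)
    kt = np.full(phi.shape, np.nan)
    if open_dom.any():
        kl[open_dom] = predict_KL(phi[open_dom])
        kt[open_dom] = predict_KT(phi[open_dom])
    en = np.full(phi.shape, np.nan)
    if valid.any():
        en[valid] = predict_En(phi[valid])
    return PropertyMaps(kl, kt, en, pixel_size=pmap.pixel_size)


def fit_permeability_model(phi: np.ndarray, k_darcy: np.ndarray
                           ) -> tuple[float, float]:
    """Least-squares fit of ``K = exp(a ln(phi) + phi + b)`` to user data.

    Returns ``(a, b)``.  These are fitted to the *given* data and are not
    the package's built-in correlation coefficients.
    """
    phi = _check_open_unit(np.asarray(phi, dtype=float), "porosity")
    k = np.asarray(k_darcy, dtype=float)
    if np.any(k <= 0):
        raise ValueError("permeability values must be positive")
    # ln K - phi = a ln phi + b  is linear in (a, b)
    y = np.log(k) - phi
    X = np.column_stack([np.log(phi), np.ones_like(phi)])
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(a), float(b)


def fit_modulus_model(phi: np.ndarray, en: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``En = 1 + c2 phi^2 + c1 phi``; returns
    ``(c2, c1)``.  Not the package's built-in coefficients."""
    phi = np.asarray(phi, dtype=float)
    en = np.asarray(en, dtype=float)
    X = np.column_stack([phi**2, phi])
    (c2, c1), *_ = np.linalg.lstsq(X, en - 1.0, rcond=None)
    return float(c2), float(c1)
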