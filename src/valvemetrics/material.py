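"""Incompressible isotropic Lee-Sacks leaflet material under uniaxial extension.

The strain-energy density combines a neo-Hookean ground-matrix term with an
exponential collagen-recruitment term,

    W(I1) = c0/2 * (I1 - 3) + c1/2 * (exp(c2 * (I1 - 3)^2) - 1),

with c0, c1 in kPa and c2 dimensionless.  Under incompressible uniaxial
extension with stretch lambda, I1 = lambda^2 + 2/lambda and the axial Cauchy
stress (transverse stresses zero, pressure eliminated analytically) is

    sigma(lambda) = 2 * (lambda^2 - 1/lambda) * dW/dI1.

The same closed form replaces the single-element finite element uniaxial
test used to derive softer "extensibility variant" parameter sets: because
sigma is jointly linear in (c0, c1), scaling both by a common factor s
rescales the whole stress-strain curve, so the factor that raises the
stretch-at-reference-stress by a prescribed percentage has the closed form
s = sigma_ref / sigma_base(lambda_target).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LeeSacksParams",
    "VariantSpec",
    "UniaxialCurve",
    "uniaxial_stress",
    "stretch_at_stress",
    "derive_variant",
    "extensibility_pct",
    "uniaxial_curve",
    "REFERENCE_MITRAL",
]


@dataclass(frozen=True)
class LeeSacksParams:
    """Lee-Sacks coefficients plus leaflet thickness (mm)."""

    c0: float  # kPa, neo-Hookean ground matrix stiffness
    c1: float  # kPa, collagen exponential prefactor
    c2: float  # dimensionless, collagen recruitment exponent
    thickness: float = 0.396

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


#: Representative adult mitral leaflet parameters.
REFERENCE_MITRAL = LeeSacksParams(c0=200.0, c1=2968.4, c2=0.2661, thickness=0.396)


@dataclass(frozen=True)
class VariantSpec:
    """Target extensibility increase, in percent of stretch at a reference stress."""

    target_pct: float
    sigma_ref: float  # kPa

    def __post_init__(self):
        if self.target_pct < 0:
            raise ValueError("target_pct must be >= 0")
        if self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")


@dataclass(frozen=True)
class UniaxialCurve:
    stretches: np.ndarray
    stresses: np.ndarray  # kPa


def uniaxial_stress(params: LeeSacksParams, stretch) -> float | np.ndarray:
    """Axial Cauchy stress (kPa) at uniaxial stretch lambda (scalar or array)."""
    lam = np.asarray(stretch, dtype=np.float64)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    q = lam**2 + 2.0 / lam - 3.0  # I1 - 3
    dw = 0.5 * params.c0 + params.c1 * params.c2 * q * np.exp(params.c2 * q * q)
    sigma = 2.0 * (lam**2 - 1.0 / lam) * dw
    return float(sigma) if np.isscalar(stretch) else sigma


def stretch_at_stress(params: LeeSacksParams, sigma: float) -> float:
    """Unique stretch lambda >= 1 with uniaxial_stress(params, lambda) = sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0 (tensile branch)")
    if sigma == 0.0:
        return 1.0
    hi = 1.0 + 1e-3
    while uniaxial_stress(params, hi) < sigma:
        hi = 1.0 + 2.0 * (hi - 1.0)
        if hi > 1e6:  # unreachable for valid params; defensive
            raise RuntimeError("failed to bracket the stress level")
    lam = brentq(lambda x: uniaxial_stress(params, x) - sigma, 1.0, hi,
                 xtol=1e-14, rtol=8.9e-16)
    return float(lam)


def derive_variant(base: LeeSacksParams, spec: VariantSpec) -> LeeSacksParams:
    """Parameters with increased extensibility at a reference stress level.

    c0 and c1 are scaled by a common factor s (c2 and thickness preserved, so
    the curve shape is unchanged) such that the stretch at ``spec.sigma_ref``
    rises by ``spec.target_pct`` percent relative to ``base``.
    """
    if spec.target_pct == 0:
        return base
    lam_base = stretch_at_stress(base, spec.sigma_ref)
    lam_target = (1.0 + spec.target_pct / 100.0) * lam_base
    sigma_target = uniaxial_stress(base, lam_target)
    if not np.isfinite(sigma_target) or sigma_target <= 0:
        raise RuntimeError(
            f"extensibility target {spec.target_pct}% at {spec.sigma_ref} kPa is "
            f"unreachable (stress at target stretch = {sigma_target})")
    s = spec.sigma_ref / sigma_target
    variant = replace(base, c0=base.c0 * s, c1=base.c1 * s)
    achieved = stretch_at_stress(variant, spec.sigma_ref)
    if abs(achieved - lam_target) > 1e-3 * lam_target:
        raise RuntimeError(
            f"variant derivation did not converge: requested stretch {lam_target}, "
            f"achieved {achieved}")
    return variant


def extensibility_pct(a: LeeSacksParams, b: LeeSacksParams, sigma_ref: float) -> float:
    """Percent stretch-ratio difference of b relative to a at a reference stress."""
    if sigma_ref <= 0:
        raise ValueError("sigma_ref must be positive")
    lam_a = stretch_at_stress(a, sigma_ref)
    lam_b = stretch_at_stress(b, sigma_ref)
    return 100.0 * (lam_b - lam_a) / lam_a


def uniaxial_curve(params: LeeSacksParams, lam_max: float = 1.3, n: int = 100) -> UniaxialCurve:
    """Sampled tensile stress-stretch curve from lambda = 1 to ``lam_max``."""
    if lam_max <= 1.0:
        raise ValueError("lam_max must exceed 1")
    lam = np.linspace(1.0, lam_max, n)
    return UniaxialCurve(stretches=lam, stresses=uniaxial_stress(params, lam))
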