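"""Closed-form ¹⁵N relaxation equations and spectral-density models.

This module is the computational kernel of the package.  It implements the
standard two-spin (¹H–¹⁵N) relaxation expressions for R1, R2, the
heteronuclear NOE and the transverse CSA/dipole cross-correlated relaxation
rate η_xy, together with the Woessner spectral density for axially symmetric
rotational diffusion, and the scalar relations that connect them:

* ``r2r1_from_tauc`` — the large-molecule R2/R1 ↔ τC relation
  (R2/R1 = (2/3)(ω_N τC)² + 7/6) and its inverse;
* ``tauc_from_etaxy`` — TRACT-style conversion of η_xy to an effective
  correlation time, τC = 5 η_xy / (8 S² p δ_N (3cos²θ − 1));
* ``rex_from_r2_etaxy`` — conformational-exchange estimation
  Rex = R2 − [(3d² + 4c²)/(2√3 c d (3cos²θ − 1))] η_xy.

All quantities are SI internally; τC crosses the API boundary in
nanoseconds and the CSA in ppm.  The η_xy expression keeps only the J(0)
and J(ω_N) terms; for τC ≳ 20 ns at high field the neglected
high-frequency spectral densities contribute < 1 %.

Note on the trace relation: the effective correlation time of a diffusion
tensor D is computed as τC = 1/(2 tr D) = 1/(2 (D_x + D_y + D_z)), the
dimensionally consistent form of the usual "one over twice the trace" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PhysicalConstants",
    "FieldContext",
    "DiffusionTensor",
    "SpectralDensityExpansion",
    "make_field_context",
    "jw_isotropic",
    "expand_axial",
    "jw_aniso",
    "predict_rates",
    "r2r1_from_tauc",
    "tauc_from_r2r1",
    "tauc_from_tensor",
    "tauc_from_etaxy",
    "etaxy_from_tauc",
    "rex_from_r2_etaxy",
    "rex_bracket_factor",
    "MAGIC_ANGLE_DEG",
]

#: Angle (degrees) at which 3cos²θ − 1 vanishes.
MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))

NS = 1e-9  # ns -> s


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental and spin-system constants of the amide ¹H–¹⁵N pair.

    Attributes
    ----------
    mu0 : float
        Vacuum permeability (H m⁻¹).
    h : float
        Planck constant (J s).
    gammaN : float
        ¹⁵N gyromagnetic ratio (rad s⁻¹ T⁻¹, negative).
    gammaH : float
        ¹H gyromagnetic ratio (rad s⁻¹ T⁻¹).
    rNH : float
        N–H bond length (Å).
    deltaSigma : float
        ¹⁵N chemical shielding anisotropy (ppm).
    theta : float
        Angle between the N–H vector and the unique axis of the ¹⁵N
        shielding tensor (degrees).
    """

    mu0: float = 4.0e-7 * math.pi
    h: float = 6.62607e-34
    gammaN: float = -27.116e6
    gammaH: float = 267.5221874e6
    rNH: float = 1.02
    deltaSigma: float = 172.0
    theta: float = 17.0

    def __post_init__(self) -> None:
        for name in ("mu0", "h", "gammaN", "gammaH", "rNH", "deltaSigma", "theta"):
            if getattr(self, name) == 0:
                raise ValueError(f"constant {name!r} must be nonzero")


@dataclass(frozen=True)
class FieldContext:
    """Field-dependent interaction constants (all rad s⁻¹ except B0).

    ``d`` and ``c`` are the dipolar and CSA autorelaxation constants of the
    standard R1/R2/NOE expressions; ``p`` and ``deltaN`` are the dipolar and
    CSA cross-correlation constants entering η_xy:

        d  = μ0 h γN γH / (8π² r³)
        c  = Δσ ω_N / √3
        p  = μ0 γH γN h / (16π² √2 r³)  (= d / (2√2))
        δN = γN B0 Δσ / (3√2)           (= ω_N Δσ / (3√2))
    """

    B0: float
    omegaH: float
    omegaN: float
    d: float
    c: float
    p: float
    deltaN: float
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)


def make_field_context(
    frequency_mhz: float, constants: PhysicalConstants | None = None
) -> FieldContext:
    """Derive all field-dependent constants from a spectrometer ¹H frequency.

    Parameters
    ----------
    frequency_mhz : float
        ¹H Larmor frequency in MHz (e.g. 900 for a 21.1 T magnet).
    constants : PhysicalConstants, optional
        Spin-system constants; defaults are the standard amide values.
    """
    if frequency_mhz <= 0:
        raise ValueError("spectrometer frequency must be positive")
    k = constants or PhysicalConstants()
    omegaH = 2.0 * math.pi * frequency_mhz * 1e6
    B0 = omegaH / k.gammaH
    omegaN = abs(k.gammaN) * B0
    r3 = (k.rNH * 1e-10) ** 3
    d = k.mu0 * k.h * abs(k.gammaN) * k.gammaH / (8.0 * math.pi**2 * r3)
    dsig = k.deltaSigma * 1e-6
    c = dsig * omegaN / math.sqrt(3.0)
    p = d / (2.0 * math.sqrt(2.0))
    deltaN = omegaN * dsig / (3.0 * math.sqrt(2.0))
    return FieldContext(
        B0=B0, omegaH=omegaH, omegaN=omegaN, d=d, c=c, p=p, deltaN=deltaN, constants=k
    )


@dataclass
class DiffusionTensor:
    """Axially symmetric rotational diffusion tensor.

    Parameters
    ----------
    Dperp, Dpar : float
        Perpendicular and parallel principal components (s⁻¹).
    alpha, beta : float
        Orientation of the symmetry axis in the molecular frame (degrees);
        canonical ranges are β ∈ [0, 90], α ∈ [0, 360).
    gamma_angle : float
        Third Euler angle; irrelevant for axial symmetry, kept for
        completeness.
    """

    Dperp: float
    Dpar: float
    alpha: float = 0.0
    beta: float = 0.0
    gamma_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.Dperp <= 0 or self.Dpar <= 0:
            raise ValueError("principal components must be positive")

    @property
    def zeta(self) -> float:
        """Anisotropy ratio D_par / D_perp."""
        return self.Dpar / self.Dperp

    @property
    def tauC_ns(self) -> float:
        """Effective overall correlation time 1/(2 tr D), in ns."""
        return tauc_from_tensor(self)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the symmetry axis in the molecular frame."""
        a = math.radians(self.alpha)
        b = math.radians(self.beta)
        return np.array(
            [math.sin(b) * math.cos(a), math.sin(b) * math.sin(a), math.cos(b)]
        )

    def canonicalized(self) -> "DiffusionTensor":
        """Return an equivalent tensor with β ∈ [0, 90], α ∈ [0, 360).

        The only orientational degeneracy of an axially symmetric tensor is
        axis ↔ −axis, so the canonical axis lives on the upper hemisphere;
        the azimuth cannot be restricted further without changing the
        tensor.
        """
        a = self.alpha % 360.0
        b = self.beta % 360.0
        if b > 180.0:  # wrap polar angle into [0, 180]
            b = 360.0 - b
            a = (a + 180.0) % 360.0
        if b > 90.0:  # axis and -axis are equivalent
            b = 180.0 - b
            a = (a + 180.0) % 360.0
        return DiffusionTensor(self.Dperp, self.Dpar, a, b, 0.0)


@dataclass
class SpectralDensityExpansion:
    """Multi-exponential expansion of the orientational correlation function.

    J(ω) = (2/5) S² Σ_k A_k τ_k / (1 + (ω τ_k)²), with Σ A_k = 1.
    """

    weights: np.ndarray
    times: np.ndarray
    S2: Optional[float] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("expansion weights must sum to 1")
        if np.any(self.times <= 0):
            raise ValueError("correlation times must be positive")


def jw_isotropic(omega: float | np.ndarray, tauC_s: float) -> float | np.ndarray:
    """Isotropic Lorentzian spectral density J(ω) = (2/5) τC/(1+(ωτC)²).

    ``tauC_s`` is in seconds (this is an internal SI routine).
    """
    if tauC_s <= 0:
        raise ValueError("tauC must be positive")
    return 0.4 * tauC_s / (1.0 + (omega * tauC_s) ** 2)


def expand_axial(
    tensor: DiffusionTensor, nh_unit_vector: np.ndarray, S2: Optional[float] = None
) -> SpectralDensityExpansion:
    """Woessner three-term expansion for an axially symmetric tensor.

    With φ the angle between the N–H vector and the tensor symmetry axis:

        A0 = (3cos²φ − 1)²/4,  A1 = 3 sin²φ cos²φ,  A2 = (3/4) sin⁴φ
        1/τ_k = 6 D_perp + k² (D_par − D_perp),  k = 0, 1, 2
    """
    v = np.asarray(nh_unit_vector, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("NH vector must have unit norm")
    cos_phi = float(np.clip(np.dot(v, tensor.axis), -1.0, 1.0))
    c2, s2 = cos_phi**2, 1.0 - cos_phi**2
    weights = np.array([(3.0 * c2 - 1.0) ** 2 / 4.0, 3.0 * s2 * c2, 0.75 * s2**2])
    ks = np.array([0.0, 1.0, 2.0])
    rates = 6.0 * tensor.Dperp + ks**2 * (tensor.Dpar - tensor.Dperp)
    return SpectralDensityExpansion(weights=weights, times=1.0 / rates, S2=S2)


def jw_aniso(
    expansion: SpectralDensityExpansion, omega: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the expanded spectral density at angular frequency ω."""
    om = np.asarray(omega, dtype=float)
    terms = expansion.weights * expansion.times / (
        1.0 + (om[..., None] * expansion.times) ** 2
    )
    out = 0.4 * terms.sum(axis=-1)
    if expansion.S2 is not None:
        out = expansion.S2 * out
    if np.ndim(omega) == 0:
        return float(out)
    return out


def predict_rates(jw, fc: FieldContext) -> tuple[float, float, float, float]:
    """Predict (R1, R2, NOE, η_xy) from a spectral density function.

    Parameters
    ----------
    jw : callable
        J(ω) in seconds, taking ω in rad s⁻¹ (e.g. a closure over
        :func:`jw_isotropic` or :func:`jw_aniso`).
    fc : FieldContext

    The R2 prediction is the rigid value (Rex = 0); η_xy is the truncated
    form keeping the J(0) and J(ω_N) terms only.
    """
    wH, wN = fc.omegaH, fc.omegaN
    d2, c2 = fc.d**2, fc.c**2
    J0 = jw(0.0)
    JN = jw(wN)
    JH = jw(wH)
    Jm = jw(wH - wN)
    Jp = jw(wH + wN)
    R1 = 0.25 * d2 * (Jm + 3.0 * JN + 6.0 * Jp) + c2 * JN
    R2 = (d2 / 8.0) * (4.0 * J0 + Jm + 3.0 * JN + 6.0 * JH + 6.0 * Jp) + (
        c2 / 6.0
    ) * (4.0 * J0 + 3.0 * JN)
    k = fc.constants
    noe = 1.0 + (d2 / (4.0 * R1)) * (k.gammaH / k.gammaN) * (6.0 * Jp - Jm)
    th = math.radians(k.theta)
    eta_xy = fc.p * fc.deltaN * (4.0 * J0 + 3.0 * JN) * (3.0 * math.cos(th) ** 2 - 1.0)
    return R1, R2, noe, eta_xy


def r2r1_from_tauc(tauC_ns: float | np.ndarray, fc: FieldContext) -> float | np.ndarray:
    """Large-molecule R2/R1 ratio: (2/3)(ω_N τC)² + 7/6."""
    tau = np.asarray(tauC_ns, dtype=float) * NS
    if np.any(tau <= 0):
        raise ValueError("tauC must be positive")
    out = (2.0 / 3.0) * (fc.omegaN * tau) ** 2 + 7.0 / 6.0
    return float(out) if np.ndim(tauC_ns) == 0 else out


def tauc_from_r2r1(ratio: float | np.ndarray, fc: FieldContext) -> float | np.ndarray:
    """Invert :func:`r2r1_from_tauc`; returns τC in ns (positive root)."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 7.0 / 6.0):
        raise ValueError("R2/R1 ratio must exceed 7/6")
    tau = np.sqrt(1.5 * (r - 7.0 / 6.0)) / fc.omegaN
    out = tau / NS
    return float(out) if np.ndim(ratio) == 0 else out


def tauc_from_tensor(tensor: DiffusionTensor) -> float:
    """Effective τC = 1/(2 (D_par + 2 D_perp)) in ns."""
    return 1.0 / (2.0 * (tensor.Dpar + 2.0 * tensor.Dperp)) / NS


def tauc_from_etaxy(eta_xy: float, S2: float, fc: FieldContext) -> float:
    """TRACT-style effective correlation time from η_xy, in ns.

    τC = 5 η_xy / (8 S² p δ_N (3cos²θ − 1)); S² corrects for fast
    picosecond N–H librations (default calibration in this work: 0.88).
    """
    if eta_xy <= 0:
        raise ValueError("eta_xy must be positive")
    if not (0.0 < S2 <= 1.0):
        raise ValueError("S2 must lie in (0, 1]")
    th = math.radians(fc.constants.theta)
    geom = 3.0 * math.cos(th) ** 2 - 1.0
    if abs(geom) < 1e-12:
        raise ZeroDivisionError("theta at the magic angle: eta_xy carries no tauC information")
    return 5.0 * eta_xy / (8.0 * S2 * fc.p * fc.deltaN * geom) / NS


def etaxy_from_tauc(tauC_ns: float, S2: float, fc: FieldContext) -> float:
    """Inverse of :func:`tauc_from_etaxy` (J(0)-only form)."""
    th = math.radians(fc.constants.theta)
    geom = 3.0 * math.cos(th) ** 2 - 1.0
    return 8.0 * S2 * fc.p * fc.deltaN * geom * (tauC_ns * NS) / 5.0


def rex_bracket_factor(fc: FieldContext) -> float:
    """Prefactor (3d² + 4c²)/(2√3 c d (3cos²θ − 1)) linking η_xy to R2."""
    th = math.radians(fc.constants.theta)
    geom = 3.0 * math.cos(th) ** 2 - 1.0
    return (3.0 * fc.d**2 + 4.0 * fc.c**2) / (
        2.0 * math.sqrt(3.0) * fc.c * fc.d * geom
    )


def rex_from_r2_etaxy(
    R2: float,
    eta_xy: float,
    fc: FieldContext,
    sigma_R2: float | None = None,
    sigma_eta: float | None = None,
) -> tuple[float, float]:
    """Exchange contribution Rex = R2 − bracket·η_xy, with quadrature error.

    Because η_xy is immune to µs–ms exchange while R2 is not, the residual
    after scaling η_xy onto the exchange-free R2 isolates Rex.
    """
    B = rex_bracket_factor(fc)
    rex = R2 - B * eta_xy
    if sigma_R2 is None or sigma_eta is None:
        return rex, float("nan")
    if sigma_R2 <= 0 or sigma_eta <= 0:
        raise ValueError("uncertainties must be positive")
    sigma = math.hypot(sigma_R2, B * sigma_eta)
    return rex, sigma
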