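"""Density-dependent bone constitutive laws and the interpubic-disc hyperelastic model.

Bone is treated as an inhomogeneous, isotropic, elastoplastic material whose
properties follow power laws of the apparent density ``rho`` (g/cm^3), itself
obtained from the CT calibration density ``rho_CT`` by an affine calibration.
Above the yield stress the material is perfectly plastic up to a softening
onset strain, then degrades linearly down to a residual stress.

The interpubic disc (fibrocartilage of the pubic symphysis) is modelled with a
three-parameter Mooney-Rivlin strain-energy function; a near-incompressible
linearization consistent with its initial shear modulus is provided for the
small-strain FE solver.

Units: mm-N-MPa-g/cm^3 consistent system.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tissue",
    "BoneLawParams",
    "MooneyRivlinParams",
    "StressStrainCurve",
    "DegenerateMaterialError",
    "RHO_THRESHOLD",
    "DENSITY_FLOOR",
    "POISSON_BONE",
    "density_from_ct",
    "classify_tissue",
    "elastic_modulus",
    "yield_stress",
    "softening_params",
    "bone_curve",
    "mr_energy",
    "mr_uniaxial_stress",
    "disc_linear_elastic",
    "material_table",
]

#: Apparent-density threshold (g/cm^3) separating cancellous from compact bone.
#: The two yield-stress power laws intersect near this density.
RHO_THRESHOLD = 0.945

#: Lower clip on apparent density to avoid numerically singular elements.
DENSITY_FLOOR = 0.05

#: Poisson ratio, identical for compact and cancellous tissue.
POISSON_BONE = 0.3


class DegenerateMaterialError(ValueError):
    """Raised when a density is too low for the softening law to be defined."""


class Tissue(str, enum.Enum):
    COMPACT = "compact"
    CANCELLOUS = "cancellous"


def density_from_ct(rho_ct):
    """Apparent density rho (g/cm^3) from the CT calibration density rho_CT.

    Affine calibration ``rho = 1.54 * rho_CT + 0.0784`` against a calibration
    sample imaged at the distal femur.

    Parameters
    ----------
    rho_ct : float or array_like
        Calibration-scale density, g/cm^3.  Must be non-negative.
    """
    rho_ct = np.asarray(rho_ct, dtype=float)
    if np.any(rho_ct < 0):
        raise ValueError("rho_ct must be non-negative")
    out = 1.54 * rho_ct + 0.0784
    return float(out) if out.ndim == 0 else out


def classify_tissue(rho) -> Tissue | np.ndarray:
    """Classify bone tissue by apparent density.

    ``rho >= 0.945`` g/cm^3 is compact (cortical), below is cancellous —
    the same threshold that switches the yield-stress branch.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:
        return Tissue.COMPACT if float(rho) >= RHO_THRESHOLD else Tissue.CANCELLOUS
    return np.where(rho >= RHO_THRESHOLD, Tissue.COMPACT.value, Tissue.CANCELLOUS.value)


def _check_rho(rho) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("apparent density rho must be positive")
    return rho


def elastic_modulus(rho, tissue: Tissue | str | None = None):
    """Elastic modulus E (MPa) from apparent density.

    Compact:    E = 2065 * rho^3.09
    Cancellous: E = 1904 * rho^1.64

    If ``tissue`` is None the branch is chosen by the 0.945 g/cm^3 threshold.
    """
    rho = _check_rho(rho)
    if tissue is None:
        compact = rho >= RHO_THRESHOLD
    else:
        compact = np.full(rho.shape, Tissue(tissue) is Tissue.COMPACT)
    out = np.where(compact, 2065.0 * rho**3.09, 1904.0 * rho**1.64)
    return float(out) if out.ndim == 0 else out


def yield_stress(rho):
    """Yield stress sigma_y (MPa) from apparent density.

    sigma_y = 57.75 * rho^1.73   for rho >= 0.945  (compact)
    sigma_y = 76.5  * rho^6.7    for rho <  0.945  (cancellous)

    The branches intersect near the threshold, so the curve is continuous to
    within ~0.1 MPa there.
    """
    rho = _check_rho(rho)
    out = np.where(rho >= RHO_THRESHOLD, 57.75 * rho**1.73, 76.5 * rho**6.7)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SofteningParams:
    """Post-yield degradation parameters at one density."""

    sigma_min: float  # residual stress, MPa
    E_p: float  # softening slope, MPa (negative)
    eps_ab: float  # total strain at softening onset
    eps_bc: float  # printed end-of-softening quantity (reported verbatim)

    def __iter__(self):
        return iter((self.sigma_min, self.E_p, self.eps_ab, self.eps_bc))


def softening_params(rho) -> SofteningParams:
    """Degradation ("softening") parameters of bone at density ``rho``.

    sigma_min = 8.5 * rho^3.68      residual stress, MPa
    E_p       = -244 * rho^2.2      softening slope, MPa
    eps_ab    = 0.258 * rho - 0.07  strain at softening onset
    eps_bc    = |(sigma_y - sigma_min)/E_p + eps_ab|

    ``eps_bc`` is evaluated exactly as printed and reported verbatim; note that
    its interior is negative for plausible densities, so the softening terminus
    used by :func:`bone_curve` is derived from ``(sigma_y - sigma_min)/|E_p|``
    instead.

    Raises
    ------
    DegenerateMaterialError
        If ``eps_ab <= 0`` (requires rho > 0.07/0.258 ~ 0.2713): softening is
        undefined at very low density.
    """
    rho = float(_check_rho(rho))
    eps_ab = 0.258 * rho - 0.07
    if eps_ab <= 0:
        raise DegenerateMaterialError(
            f"softening undefined at rho={rho:.4g} g/cm^3 (eps_ab={eps_ab:.4g} <= 0)"
        )
    sigma_min = 8.5 * rho**3.68
    E_p = -244.0 * rho**2.2
    sigma_y = yield_stress(rho)
    eps_bc = abs((sigma_y - sigma_min) / E_p + eps_ab)
    return SofteningParams(sigma_min, E_p, eps_ab, eps_bc)


@dataclass(frozen=True)
class BoneLawParams:
    """Full per-element bone material card at one apparent density."""

    rho: float
    tissue: Tissue
    E: float
    nu: float
    sigma_y: float
    sigma_min: float
    E_p: float
    eps_ab: float
    eps_bc: float

    @classmethod
    def from_density(cls, rho: float, tissue: Tissue | str | None = None) -> "BoneLawParams":
        rho = float(_check_rho(rho))
        tis = classify_tissue(rho) if tissue is None else Tissue(tissue)
        soft = softening_params(rho)
        return cls(
            rho=rho,
            tissue=tis,
            E=elastic_modulus(rho, tis),
            nu=POISSON_BONE,
            sigma_y=yield_stress(rho),
            sigma_min=soft.sigma_min,
            E_p=soft.E_p,
            eps_ab=soft.eps_ab,
            eps_bc=soft.eps_bc,
        )

    def __post_init__(self):
        if not (self.rho > 0 and self.E > 0 and self.sigma_y > 0 and self.sigma_min > 0):
            raise ValueError("rho, E, sigma_y, sigma_min must be positive")
        if self.sigma_min >= self.sigma_y:
            raise ValueError("residual stress must lie below the yield stress")
        if self.E_p >= 0:
            raise ValueError("softening slope E_p must be negative")


@dataclass(frozen=True)
class StressStrainCurve:
    """Piecewise-linear uniaxial stress-strain law of elastoplastic bone.

    Segments: linear elastic with slope E up to (sigma_y/E, sigma_y); perfectly
    plastic plateau at sigma_y to strain eps_ab; linear softening with slope
    E_p down to sigma_min; constant sigma_min beyond.
    """

    breakpoints: tuple[tuple[float, float], ...]  # (strain, stress MPa), ordered
    E: float = field(repr=False, default=0.0)

    def __post_init__(self):
        eps = np.array([b[0] for b in self.breakpoints])
        if np.any(np.diff(eps) <= 0):
            raise ValueError("breakpoint strains must be strictly increasing")

    @property
    def strains(self) -> np.ndarray:
        return np.array([b[0] for b in self.breakpoints])

    @property
    def stresses(self) -> np.ndarray:
        return np.array([b[1] for b in self.breakpoints])

    def stress(self, eps):
        """Stress (MPa) at total strain ``eps``; constant beyond the last breakpoint."""
        out = np.interp(np.abs(np.asarray(eps, dtype=float)), self.strains, self.stresses)
        return float(out) if out.ndim == 0 else out

    def secant_modulus(self, eps):
        """sigma(eps)/eps, continuously extended to E at eps -> 0."""
        eps = np.abs(np.asarray(eps, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            sec = np.where(eps > 0, self.stress(eps) / np.maximum(eps, 1e-300), self.E)
        return float(sec) if sec.ndim == 0 else sec


def bone_curve(rho, tissue: Tissue | str | None = None) -> StressStrainCurve:
    """Uniaxial stress-strain curve of bone at density ``rho``.

    The softening terminus strain is ``eps_ab + (sigma_y - sigma_min)/|E_p|``
    (the printed eps_bc formula gives a smaller-than-eps_ab value and is only
    reported, never used to shape the curve).
    """
    rho = float(_check_rho(rho))
    E = elastic_modulus(rho, tissue)
    sigma_y = yield_stress(rho)
    soft = softening_params(rho)
    eps_y = sigma_y / E
    if eps_y >= soft.eps_ab:
        raise DegenerateMaterialError(
            f"yield strain {eps_y:.4g} exceeds softening onset {soft.eps_ab:.4g} at rho={rho:.4g}"
        )
    if soft.sigma_min >= sigma_y:
        # Below rho ~ 0.483 g/cm^3 the residual-stress law overtakes the yield
        # law, so there is no stress drop to degrade to: the material stays
        # elastic-perfectly-plastic at sigma_y.
        pts = ((0.0, 0.0), (eps_y, sigma_y))
        return StressStrainCurve(breakpoints=pts, E=E)
    eps_end = soft.eps_ab + (sigma_y - soft.sigma_min) / abs(soft.E_p)
    pts = (
        (0.0, 0.0),
        (eps_y, sigma_y),
        (soft.eps_ab, sigma_y),
        (eps_end, soft.sigma_min),
    )
    return StressStrainCurve(breakpoints=pts, E=E)


# ---------------------------------------------------------------------------
# Interpubic disc: Mooney-Rivlin hyperelasticity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Three-parameter Mooney-Rivlin material of the interpubic disc (MPa)."""

    C10: float = 0.1
    C01: float = 0.45
    C11: float = 0.6

    def __post_init__(self):
        if 2.0 * (self.C10 + self.C01) <= 0:
            raise ValueError("initial shear modulus 2*(C10+C01) must be positive")

    @property
    def shear_modulus(self) -> float:
        """Initial (small-strain) shear modulus, MPa."""
        return 2.0 * (self.C10 + self.C01)


def mr_energy(I1, I2, p: MooneyRivlinParams = MooneyRivlinParams()):
    """Mooney-Rivlin strain-energy density W (MPa).

    ``W = C10 (I1-3) + C01 (I2-3) + C11 (I1-3)(I2-3)`` with I1, I2 the first
    and second invariants of the deviatoric stretch tensor (both 3 in the
    undeformed state).
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if np.any(I1 < 3.0 - 1e-12) or np.any(I2 < 3.0 - 1e-12):
        raise ValueError("stretch invariants must satisfy I1 >= 3, I2 >= 3")
    out = p.C10 * (I1 - 3.0) + p.C01 * (I2 - 3.0) + p.C11 * (I1 - 3.0) * (I2 - 3.0)
    return float(out) if out.ndim == 0 else out


def mr_uniaxial_stress(lam, p: MooneyRivlinParams = MooneyRivlinParams()):
    """Cauchy stress (MPa) of an incompressible uniaxial Mooney-Rivlin state.

    For stretch lambda the incompressible uniaxial invariants are
    ``I1 = lam^2 + 2/lam`` and ``I2 = 2 lam + 1/lam^2`` and

        sigma = 2 (lam^2 - 1/lam) (dW/dI1 + (1/lam) dW/dI2).

    Used to exercise the disc law on a closed-form path; the FE solver uses
    the consistent small-strain linearization instead.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    I1 = lam**2 + 2.0 / lam
    I2 = 2.0 * lam + 1.0 / lam**2
    dWdI1 = p.C10 + p.C11 * (I2 - 3.0)
    dWdI2 = p.C01 + p.C11 * (I1 - 3.0)
    out = 2.0 * (lam**2 - 1.0 / lam) * (dWdI1 + dWdI2 / lam)
    return float(out) if out.ndim == 0 else out


def disc_linear_elastic(
    p: MooneyRivlinParams = MooneyRivlinParams(), nu: float = 0.475
) -> tuple[float, float]:
    """(E, nu) of the near-incompressible linearization of the disc material.

    E = 2 G (1 + nu) with G = 2 (C10 + C01) the initial shear modulus.
    """
    G = p.shear_modulus
    return 2.0 * G * (1.0 + nu), nu


# ---------------------------------------------------------------------------
# Material tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "element_id",
    "rho",
    "tissue",
    "E",
    "nu",
    "sigma_y",
    "sigma_min",
    "E_p",
    "eps_ab",
]


def material_table(element_ids, rho_ct, floor: float = DENSITY_FLOOR):
    """Per-element bone material table from a CT-density field.

    Applies the density calibration, clips apparent density below at ``floor``
    and evaluates all density power laws.  Returns a pandas DataFrame with
    columns ``element_id, rho, tissue, E, nu, sigma_y, sigma_min, E_p, eps_ab``
    that round-trips through CSV.
    """
    import pandas as pd

    rho = np.maximum(density_from_ct(np.asarray(rho_ct, dtype=float)), floor)
    rows = []
    for eid, r in zip(element_ids, np.atleast_1d(rho)):
        r = float(r)
        tis = classify_tissue(r)
        try:
            soft = softening_params(r)
            s_min, e_p, e_ab = soft.sigma_min, soft.E_p, soft.eps_ab
        except DegenerateMaterialError:
            # below ~0.27 g/cm^3 the softening law is undefined: elastic only
            s_min = e_p = e_ab = np.nan
        rows.append(
            (
                eid,
                r,
                tis.value,
                elastic_modulus(r, tis),
                POISSON_BONE,
                yield_stress(r),
                s_min,
                e_p,
                e_ab,
            )
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
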