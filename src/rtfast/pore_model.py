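"""Geometric conductance model of a conical nanopipette blocked by a cylindrical oligomer.

The tip of a pulled quartz nanopipette is modelled as a truncated cone of tip
radius ``r_p`` and half-cone angle ``alpha`` filled with electrolyte of
conductivity ``kappa``.  An oligomer transiting the tip is modelled as a
cylinder of radius ``r_o`` and length ``L_o = 2 r_o`` seated coaxially at the
tip, where it produces the maximal current blockade.  The particle removes a
cylindrical core from the conducting cone, leaving an annular channel whose
excess resistance over the open pipette is

    R_max = integral_0^{L_o} [ 1 / (kappa pi ((r_p + a x)^2 - r_o^2))
                             - 1 / (kappa pi (r_p + a x)^2) ] dx,

with ``a = tan(alpha)``.  The relative current blockade follows from the
series-resistance picture,

    dI_max / I_0 = R_max / (1/G + R_max),

where ``G`` is the open-pipette conductance.  Both the forward map
(``r_o -> dI/I_0``) and its inverse (measured blockade -> oligomer radius,
volume and size) are provided; the forward map is strictly increasing in
``r_o``, so the inversion is unique on the feasible range.

Unit conventions (consistent throughout the package): lengths in nm,
conductivity in S/m, conductance in nS.  With these units the excess
resistance integral evaluates numerically in GOhm and ``1/G`` (nS) is also in
GOhm, so no explicit conversion factors appear in the blockade formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "PipetteGeometry",
    "CylindricalOligomer",
    "BlockadeModelResult",
    "InfeasibleParticleError",
    "SaturatedBlockadeError",
    "tip_radius_from_conductance",
    "detectability_window",
    "excess_resistance",
    "relative_blockade",
    "oligomer_from_blockade",
    "size_from_volume",
]


class InfeasibleParticleError(ValueError):
    """The cylindrical particle does not fit inside the pore at the tip."""


class SaturatedBlockadeError(ValueError):
    """A measured blockade exceeds what any feasible particle can produce."""


@dataclass(frozen=True)
class PipetteGeometry:
    """Conical nanopipette tip parameters.

    Parameters
    ----------
    tip_radius_nm
        Inner radius of the tip opening, r_p (nm).
    half_cone_angle_rad
        Half-cone angle alpha of the conical taper (rad), 0 < alpha < pi/2.
    conductivity_S_per_m
        Electrolyte conductivity kappa (S/m).
    open_conductance_nS
        Measured open-pipette conductance G (nS).
    """

    tip_radius_nm: float
    half_cone_angle_rad: float
    conductivity_S_per_m: float
    open_conductance_nS: float

    def __post_init__(self) -> None:
        if not self.tip_radius_nm > 0:
            raise ValueError(f"tip_radius_nm must be > 0, got {self.tip_radius_nm}")
        if not 0 < self.half_cone_angle_rad < math.pi / 2:
            raise ValueError(
                f"half_cone_angle_rad must lie in (0, pi/2), got {self.half_cone_angle_rad}"
            )
        if not self.conductivity_S_per_m > 0:
            raise ValueError("conductivity_S_per_m must be > 0")
        if not self.open_conductance_nS > 0:
            raise ValueError("open_conductance_nS must be > 0")

    @property
    def cone_slope(self) -> float:
        """a = tan(alpha), the radial growth rate of the cone."""
        return math.tan(self.half_cone_angle_rad)

    def to_dict(self) -> dict:
        return {
            "tip_radius_nm": self.tip_radius_nm,
            "half_cone_angle_rad": self.half_cone_angle_rad,
            "conductivity_S_per_m": self.conductivity_S_per_m,
            "open_conductance_nS": self.open_conductance_nS,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipetteGeometry":
        return cls(
            tip_radius_nm=float(d["tip_radius_nm"]),
            half_cone_angle_rad=float(d["half_cone_angle_rad"]),
            conductivity_S_per_m=float(d["conductivity_S_per_m"]),
            open_conductance_nS=float(d["open_conductance_nS"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipetteGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CylindricalOligomer:
    """Cylindrical oligomer with the aspect-ratio constraint L_o = 2 r_o."""

    radius_nm: float

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValueError(f"radius_nm must be > 0, got {self.radius_nm}")

    @property
    def length_nm(self) -> float:
        return 2.0 * self.radius_nm

    @property
    def volume_nm3(self) -> float:
        """V = pi r_o^2 L_o = 2 pi r_o^3."""
        return 2.0 * math.pi * self.radius_nm**3

    @property
    def size_nm(self) -> float:
        """Reported oligomer size: the diameter 2 r_o (= L_o)."""
        return 2.0 * self.radius_nm

    @classmethod
    def from_volume(cls, volume_nm3: float) -> "CylindricalOligomer":
        if volume_nm3 <= 0:
            raise ValueError(f"volume must be > 0, got {volume_nm3}")
        return cls(radius_nm=(volume_nm3 / (2.0 * math.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class BlockadeModelResult:
    """Forward-model output for one (geometry, oligomer) pair."""

    excess_resistance_GOhm: float
    relative_blockade: float


def tip_radius_from_conductance(
    conductance_nS: float,
    conductivity_S_per_m: float,
    half_cone_angle_rad: float,
    include_access: bool = True,
) -> float:
    """Estimate the tip radius r_p (nm) from the open-pipette conductance.

    The open pipette resistance is the conical-body term 1/(kappa pi r_p tan(alpha))
    in series with the access (convergence) resistance 1/(4 kappa r_p) at the
    tip mouth, which inverts to

        r_p = (G / kappa) * (1 / (pi tan(alpha)) + 1/4).

    Parameters
    ----------
    conductance_nS
        Open conductance G in nS.
    conductivity_S_per_m
        Electrolyte conductivity in S/m.
    half_cone_angle_rad
        Half-cone angle in rad, < pi/2.
    include_access
        If False, drop the access-resistance term (pure-cone limit).
    """
    if conductance_nS <= 0 or conductivity_S_per_m <= 0 or half_cone_angle_rad <= 0:
        raise ValueError("conductance, conductivity and angle must all be positive")
    if half_cone_angle_rad >= math.pi / 2:
        raise ValueError("half_cone_angle_rad must be < pi/2")
    access = 0.25 if include_access else 0.0
    # G[nS]/kappa[S/m] = 1e-9 m = 1 nm, so the result is directly in nm.
    return (conductance_nS / conductivity_S_per_m) * (
        1.0 / (math.pi * math.tan(half_cone_angle_rad)) + access
    )


def detectability_window(geom: PipetteGeometry) -> tuple[float, float]:
    """Detectable oligomer-diameter window (d_min, d_max) = (r_p, 2 r_p) in nm.

    Particles smaller than the tip radius produce blockades below the noise
    floor; particles larger than the tip diameter cannot enter the pore, so
    only oligomer diameters between the pipette radius and diameter are seen.
    """
    return (geom.tip_radius_nm, 2.0 * geom.tip_radius_nm)


def excess_resistance(geom: PipetteGeometry, olig: CylindricalOligomer) -> float:
    """Maximal excess resistance R_max (GOhm) of a tip-seated cylindrical particle.

    Closed form of the annular-channel integral (u = r_p + a x):

        R_max = 1/(kappa pi a) * [ (1/(2 r_o)) ln( ((u1-r_o)(u0+r_o)) /
                                                   ((u1+r_o)(u0-r_o)) )
                                   - (1/u0 - 1/u1) ],

    with u0 = r_p, u1 = r_p + a L_o.  Strictly increasing in r_o and -> 0 as
    r_o -> 0.  Raises :class:`InfeasibleParticleError` if r_o >= r_p.
    """
    rp = geom.tip_radius_nm
    ro = olig.radius_nm
    a = geom.cone_slope
    kappa = geom.conductivity_S_per_m
    if ro >= rp:
        raise InfeasibleParticleError(
            f"particle radius {ro} nm does not fit a {rp} nm tip"
        )
    L = olig.length_nm
    u0 = rp
    u1 = rp + a * L
    if a * L < 1e-9 * rp:
        # Degenerate near-cylindrical limit: integrand constant over the particle.
        return L * (1.0 / (rp**2 - ro**2) - 1.0 / rp**2) / (kappa * math.pi)
    if ro < 0.1 * rp:
        # The closed form cancels catastrophically for thin particles; use the
        # series atanh(x)/ro - 1/u = sum_k ro^{2k} / ((2k+1) u^{2k+1}), whose
        # truncation error is below 1e-16 relative at ro/rp < 0.1 with 8 terms.
        acc = 0.0
        for kk in range(1, 9):
            acc += ro ** (2 * kk) / (2 * kk + 1) * (
                u0 ** -(2 * kk + 1) - u1 ** -(2 * kk + 1)
            )
        return acc / (kappa * math.pi * a)
    log_term = math.log(((u1 - ro) * (u0 + ro)) / ((u1 + ro) * (u0 - ro)))
    return (log_term / (2.0 * ro) - (1.0 / u0 - 1.0 / u1)) / (kappa * math.pi * a)


def relative_blockade(geom: PipetteGeometry, olig: CylindricalOligomer) -> float:
    """Relative current blockade dI_max/I_0 in [0, 1) for a tip-seated particle.

    Series-resistance form: dI/I_0 = R_max / (1/G + R_max).
    """
    r_max = excess_resistance(geom, olig)
    g_inv = 1.0 / geom.open_conductance_nS  # GOhm
    return r_max / (g_inv + r_max)


def blockade_model(geom: PipetteGeometry, olig: CylindricalOligomer) -> BlockadeModelResult:
    """Evaluate the full forward model for one particle."""
    r_max = excess_resistance(geom, olig)
    g_inv = 1.0 / geom.open_conductance_nS
    return BlockadeModelResult(
        excess_resistance_GOhm=r_max,
        relative_blockade=r_max / (g_inv + r_max),
    )


#: Largest particle radius, as a fraction of the tip radius, used to bracket
#: the inversion.  Above this the annular gap is so thin that the model (and
#: the measurement) saturates.
MAX_RADIUS_FRACTION = 0.99

_BISECT_XTOL_NM = 1e-4
_BISECT_MAXITER = 200


def oligomer_from_blockade(
    geom: PipetteGeometry, rel_blockade: float
) -> CylindricalOligomer:
    """Invert a measured relative blockade to the unique cylindrical oligomer.

    Bisection on the strictly monotone forward map over
    ``r_o in [1e-3, 0.99 r_p]`` nm, absolute tolerance 1e-4 nm.

    Raises
    ------
    ValueError
        If ``rel_blockade`` is not strictly positive.
    SaturatedBlockadeError
        If ``rel_blockade`` exceeds the blockade of the largest feasible
        particle (the saturation bound is quoted in the message).
    """
    if not rel_blockade > 0:
        raise ValueError(f"relative blockade must be > 0, got {rel_blockade}")
    ro_max = MAX_RADIUS_FRACTION * geom.tip_radius_nm
    ceiling = relative_blockade(geom, CylindricalOligomer(ro_max))
    if rel_blockade >= ceiling:
        raise SaturatedBlockadeError(
            f"relative blockade {rel_blockade:.6g} is at or above the saturation "
            f"bound {ceiling:.6g} reached at r_o = {ro_max:.4g} nm "
            f"(tip radius {geom.tip_radius_nm:.4g} nm)"
        )
    ro_min = 1e-3
    if rel_blockade <= relative_blockade(geom, CylindricalOligomer(ro_min)):
        # Blockade below the bracket floor: the particle is vanishingly small;
        # return the floor rather than failing on an unbracketed root.
        return CylindricalOligomer(ro_min)

    def f(ro: float) -> float:
        return relative_blockade(geom, CylindricalOligomer(ro)) - rel_blockade

    root = bisect(f, ro_min, ro_max, xtol=_BISECT_XTOL_NM, maxiter=_BISECT_MAXITER)
    return CylindricalOligomer(float(root))


def size_from_volume(volume_nm3):
    """Oligomer size (nm) from volume (nm^3) under the cylindrical model.

    Size is the diameter 2 r_o with V = 2 pi r_o^3, i.e.
    ``size = 2 (V / 2 pi)^(1/3)``.  Accepts scalars or arrays; V must be
    non-negative.
    """
    v = np.asarray(volume_nm3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    size = 2.0 * (v / (2.0 * math.pi)) ** (1.0 / 3.0)
    if np.isscalar(volume_nm3) or v.ndim == 0:
        return float(size)
    return size
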