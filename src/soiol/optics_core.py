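"""Paraxial vergence optics of the pseudophakic eye with a silicone-oil vitreous.

The eye is modelled as a Gullstrand simplified (reduced, two-thin-lens) eye:
a thin cornea of power ``Fc`` in contact with aqueous humour, a thin
intraocular lens (IOL) a distance ``d`` (the effective lens position, ELP)
behind it, and a vitreous cavity filled with silicone oil of refractive
index ``n_oil`` instead of the usual aqueous/vitreous 1.336.

To add the two separated thin lenses, the cornea is referred to the IOL
plane: translating a lens of power ``Fc`` a distance ``d`` through a medium
of index ``n`` turns it into an equivalent lens of power

    Fe = n * Fc / (n - d * Fc).

An emmetropic pseudophakic eye must focus parallel light on the retina,
i.e. at a distance ``AL - d`` behind the IOL plane inside the oil, so the
total power at the IOL plane must equal ``n_oil / (AL - d)`` and the
required IOL power is

    F_IOL = n_oil / (AL - ELP) - Fe.

All lengths in this module are SI metres and all powers diopters (1/m);
millimetre-accepting conveniences live one layer up (see
:mod:`soiol.pipeline` and the command line).  A stepwise reduced-vergence
propagation (:func:`vergence_trace_oracle`) provides an independent check
of the closed form, and :func:`implied_elp` inverts the formula
numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "OpticalMedia",
    "EyeGeometry",
    "equivalent_corneal_power",
    "so_iol_power",
    "water_iol_power",
    "so_water_delta",
    "vergence_trace_oracle",
    "implied_elp",
]

#: Default refractive indices: air, aqueous humour, silicone oil.
N_AIR = 1.000
N_AQUEOUS = 1.336
N_SILICONE_OIL = 1.403


@dataclass(frozen=True)
class OpticalMedia:
    """Refractive-index set defining the eye model.

    ``n_oil`` is the index of the vitreous-cavity filler; with
    ``n_oil == n_aqueous`` the model degenerates to the ordinary
    water/vitreous-filled eye.
    """

    n_air: float = N_AIR
    n_aqueous: float = N_AQUEOUS
    n_oil: float = N_SILICONE_OIL

    def __post_init__(self) -> None:
        if not (1.0 < self.n_aqueous < 2.0):
            raise DomainError(f"n_aqueous={self.n_aqueous} outside (1, 2)")
        if not (1.0 < self.n_oil < 2.0):
            raise DomainError(f"n_oil={self.n_oil} outside (1, 2)")
        if self.n_oil < self.n_aqueous:
            raise DomainError(
                f"n_oil={self.n_oil} < n_aqueous={self.n_aqueous}: "
                "silicone-oil fillers are denser than aqueous; "
                "equality gives the water-filled eye"
            )


DEFAULT_MEDIA = OpticalMedia()


@dataclass(frozen=True)
class EyeGeometry:
    """One eye's paraxial geometry, SI units.

    axial_length : metres, corneal vertex to retina.
    corneal_power : diopters ("Average K" from the biometer).
    elp : metres, posterior corneal vertex to IOL optical plane.
    """

    axial_length: float
    corneal_power: float
    elp: float
    n_aqueous: float = N_AQUEOUS

    def __post_init__(self) -> None:
        if not (0.014 < self.axial_length < 0.040):
            raise DomainError(
                f"axial_length={self.axial_length} m outside (0.014, 0.040); "
                "did you pass millimetres?"
            )
        if not (0.0 <= self.elp < self.axial_length):
            raise DomainError(
                f"elp={self.elp} m outside [0, axial_length={self.axial_length})"
            )
        if self.corneal_power <= 0:
            raise DomainError(f"corneal_power={self.corneal_power} D must be > 0")
        if self.n_aqueous - self.elp * self.corneal_power <= 0:
            raise DomainError(
                f"equivalent-power denominator n_aqueous - elp*Fc = "
                f"{self.n_aqueous - self.elp * self.corneal_power:.4f} <= 0 "
                f"for elp={self.elp} m, Fc={self.corneal_power} D"
            )


def equivalent_corneal_power(
    corneal_power: float, elp: float, n_aqueous: float = N_AQUEOUS
) -> float:
    """Corneal power referred to the IOL plane.

    Translating the thin cornea a distance ``elp`` through aqueous humour
    gives ``Fe = n * Fc / (n - elp * Fc)``; ``Fe >= Fc`` and increases with
    ``elp`` up to the pole at ``elp = n / Fc``.

    Parameters use diopters and metres.
    """
    denom = n_aqueous - elp * corneal_power
    if denom <= 0:
        raise DomainError(
            f"n_aqueous - elp*Fc = {denom:.4f} <= 0 "
            f"(elp={elp} m, Fc={corneal_power} D): cornea focuses before the IOL plane"
        )
    return n_aqueous * corneal_power / denom


def _emmetropizing_power(geometry: EyeGeometry, n_fill: float) -> float:
    if geometry.axial_length <= geometry.elp:
        raise DomainError(
            f"axial_length={geometry.axial_length} m <= elp={geometry.elp} m"
        )
    fe = equivalent_corneal_power(
        geometry.corneal_power, geometry.elp, geometry.n_aqueous
    )
    return n_fill / (geometry.axial_length - geometry.elp) - fe


def so_iol_power(geometry: EyeGeometry, media: OpticalMedia = DEFAULT_MEDIA) -> float:
    """Emmetropizing IOL power (D) for a silicone-oil-filled vitreous cavity.

    ``F_IOL = n_oil / (AL - ELP) - n_ah * Fc / (n_ah - ELP * Fc)``.
    """
    return _emmetropizing_power(geometry, media.n_oil)


def water_iol_power(geometry: EyeGeometry, media: OpticalMedia = DEFAULT_MEDIA) -> float:
    """Reference counterpart with the vitreous cavity filled by water/vitreous.

    Identical closed form with ``n_aqueous`` in place of ``n_oil``; this is
    what conventional formulas assume.
    """
    return _emmetropizing_power(geometry, media.n_aqueous)


def so_water_delta(geometry: EyeGeometry, media: OpticalMedia = DEFAULT_MEDIA) -> float:
    """Closed-form oil-minus-water power difference ``(n_oil - n_ah)/(AL - ELP)``.

    Equals ``so_iol_power - water_iol_power`` to machine precision; for
    physiological ``AL - ELP`` it lands in the 3-5 D range that clinicians
    have historically added empirically.
    """
    if geometry.axial_length <= geometry.elp:
        raise DomainError(
            f"axial_length={geometry.axial_length} m <= elp={geometry.elp} m"
        )
    return (media.n_oil - media.n_aqueous) / (geometry.axial_length - geometry.elp)


def vergence_trace_oracle(
    geometry: EyeGeometry,
    iol_power: float,
    media: OpticalMedia = DEFAULT_MEDIA,
) -> float:
    """Image distance (m) behind the IOL plane by stepwise vergence propagation.

    Parallel light (zero vergence) hits the cornea: V1 = Fc.  The reduced
    vergence is translated ``elp`` through aqueous:
    V2 = n_ah * V1 / (n_ah - elp * V1).  The IOL adds its power:
    V3 = V2 + F_IOL.  The image forms at ``n_oil / V3`` inside the oil.

    This deliberately never uses the closed-form IOL power expression, so it
    serves as an independent brute-force check: the closed form is correct
    iff the traced image distance equals ``AL - ELP`` (image on the retina).
    """
    v1 = geometry.corneal_power
    denom = media.n_aqueous - geometry.elp * v1
    if denom <= 0:
        raise DomainError(
            f"corneal vergence focuses before the IOL plane (denominator {denom:.4f})"
        )
    v2 = media.n_aqueous * v1 / denom
    v3 = v2 + iol_power
    if v3 == 0:
        raise DomainError("zero vergence after the IOL: image at infinity")
    return media.n_oil / v3


def implied_elp(
    axial_length: float,
    corneal_power: float,
    iol_power: float,
    media: OpticalMedia = DEFAULT_MEDIA,
    tol_d: float = 1e-9,
) -> float:
    """Invert the oil-filled-eye formula: find the ELP giving ``iol_power``.

    The power is not monotone in ELP everywhere: both terms of
    ``n_oil/(AL - e) - Fe(e)`` grow toward their respective poles, and the
    derivative vanishes at the closed-form stationary point

        e* = (sqrt(n_oil) * n_ah - sqrt(n_ah) * Fc * AL)
             / (Fc * (sqrt(n_oil) - sqrt(n_ah))).

    The search bracket (0.1 mm, min(AL, n_ah/Fc) - 0.1 mm) is therefore
    split at ``e*`` when it lies inside, and each monotone piece is
    root-bracketed separately.  A unique root is refined to a residual
    below ``tol_d`` diopters and returned.  No root raises
    :class:`DomainError` ("no physical ELP"); two roots — possible on a
    thin ridge of very long, steep-cornea eyes where the power is locally
    flat in ELP — raise :class:`DomainError` ("ambiguous"), since the
    inverse does not exist there.
    """
    lo = 1e-4
    hi = min(axial_length, media.n_aqueous / corneal_power) - 1e-4
    if hi <= lo:
        raise DomainError("empty ELP search bracket")

    def residual(elp: float) -> float:
        g = EyeGeometry(axial_length, corneal_power, elp, media.n_aqueous)
        return so_iol_power(g, media) - iol_power

    import math

    edges = [lo, hi]
    if media.n_oil > media.n_aqueous:
        s_oil, s_aq = math.sqrt(media.n_oil), math.sqrt(media.n_aqueous)
        e_star = (s_oil * media.n_aqueous - s_aq * corneal_power * axial_length) / (
            corneal_power * (s_oil - s_aq)
        )
        if lo < e_star < hi:
            edges = [lo, e_star, hi]

    roots: list[float] = []
    for a, b in zip(edges, edges[1:]):
        ra, rb = residual(a), residual(b)
        if ra == 0.0:
            roots.append(a)
        elif ra * rb < 0:
            roots.append(brentq(residual, a, b, xtol=1e-13, rtol=8.9e-16))
    if residual(edges[-1]) == 0.0:
        roots.append(edges[-1])
    # collapse duplicates from shared sub-bracket edges
    roots = sorted(set(round(r, 15) for r in roots))
    if len(roots) > 1 and roots[-1] - roots[0] < 1e-9:
        roots = roots[:1]

    if not roots:
        raise DomainError(
            f"no physical ELP in ({lo}, {hi}) m yields {iol_power} D "
            f"for AL={axial_length} m, Fc={corneal_power} D"
        )
    if len(roots) > 1:
        # Tie-break: keep the root in the anatomically plausible pseudophakic
        # ELP range (2, 9) mm when exactly one of the two lands there.
        plausible = [r for r in roots if 0.002 < r < 0.009]
        if len(plausible) == 1:
            roots = plausible
    if len(roots) > 1:
        raise DomainError(
            f"ambiguous ELP: {iol_power} D is attained at "
            f"{roots[0] * 1e3:.3f} mm and {roots[-1] * 1e3:.3f} mm "
            f"(power locally flat in ELP for AL={axial_length} m, "
            f"Fc={corneal_power} D); no unique inverse exists"
        )
    elp = roots[0]
    if abs(residual(elp)) > tol_d:
        raise DomainError(f"ELP inversion residual {residual(elp):.3e} D > {tol_d}")
    return elp
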